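import pytest

from tcrlineage import SimConfig, filter_single_pair_cells, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Small deterministic cohort with specificity tags, no dropout."""
    cfg = SimConfig(seed=7, clones_per_donor=30, specificity_fraction=0.15)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def paired(cohort):
    return filter_single_pair_cells(cohort.contigs, cohort.metadata)
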