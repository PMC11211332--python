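"""Single-pair filtering and clonal-expansion calls."""

import numpy as np
import pandas as pd
import pytest

from tcrlineage import call_expansion, compare_expansion, filter_single_pair_cells
from tcrlineage.clonotype import clone_key_str


def contig(barcode, chain, v="V1", j="J1", nt="TGT", productive=True):
    return {
        "barcode": barcode,
        "chain": chain,
        "v_gene": v,
        "j_gene": j,
        "cdr3_aa": "CASS",
        "cdr3_nt": nt,
        "productive": productive,
        "umis": 1,
    }


def meta(barcode, donor="D1", cluster=4):
    return {
        "barcode": barcode,
        "donor": donor,
        "cluster": cluster,
        "population": "x",
        "response": "R",
    }


def test_hand_enumerated_single_pair_filter():
    """5 cells: a 2-TRA doublet, a TRB-only cell, 3 clean pairs (one absent
    from metadata) -> 2 retained."""
    contigs = pd.DataFrame(
        [
            contig("doublet", "TRA"),
            contig("doublet", "TRA", nt="TGC"),
            contig("doublet", "TRB"),
            contig("beta_only", "TRB"),
            contig("clean1", "TRA"),
            contig("clean1", "TRB"),
            contig("clean2", "TRA"),
            contig("clean2", "TRB"),
            contig("absent", "TRA"),
            contig("absent", "TRB"),
        ]
    )
    metadata = pd.DataFrame([meta("doublet"), meta("beta_only"), meta("clean1"), meta("clean2")])
    paired = filter_single_pair_cells(contigs, metadata)
    assert sorted(paired["barcode"]) == ["clean1", "clean2"]
    report = paired.attrs["filter_report"]
    assert report["n_barcodes_with_tcr"] == 5
    assert report["n_single_pair"] == 3
    assert report["n_in_metadata"] == 2


def test_paired_cell_carries_both_clone_keys():
    contigs = pd.DataFrame([contig("c", "TRA", v="trav1", nt="AAA"), contig("c", "TRB", v="TRBV9", nt="CCC")])
    paired = filter_single_pair_cells(contigs, pd.DataFrame([meta("c")]))
    assert paired.loc[0, "tra_key"] == clone_key_str("TRA", "TRAV1", "J1", "AAA")
    assert paired.loc[0, "trb_key"] == "TRB|TRBV9|J1|CCC"


def make_paired(cells):
    """cells: list of (barcode, donor, cluster, tra_nt)."""
    rows = []
    for barcode, donor, cluster, nt in cells:
        rows.append(
            {
                "barcode": barcode,
                "donor": donor,
                "cluster": cluster,
                "population": "x",
                "response": "R",
                "tra_v": "V1",
                "tra_j": "J1",
                "tra_cdr3_aa": "CASS",
                "tra_cdr3_nt": nt,
                "trb_v": "BV",
                "trb_j": "BJ",
                "trb_cdr3_aa": "CASS",
                "trb_cdr3_nt": "B" + nt,
                "tra_key": f"TRA|V1|J1|{nt}",
                "trb_key": f"TRB|BV|BJ|B{nt}",
            }
        )
    return pd.DataFrame(rows)


def test_expansion_fraction_direct_count():
    cells = [("b%d" % i, "D1", 5, "A") for i in range(3)] + [("b3", "D1", 5, "B")]
    paired = make_paired(cells)
    flags = call_expansion(paired)
    assert flags.mean() == pytest.approx(3 / 4)


def test_all_singletons_not_expanded():
    paired = make_paired([("b0", "D1", 5, "A"), ("b1", "D1", 5, "B"), ("b2", "D1", 6, "C")])
    assert not call_expansion(paired).any()


def test_expansion_scope_sensitivity():
    """Clone X a singleton in each of two donors: donor-scoped calls flag
    neither, pooled-across-donor calls flag both."""
    paired = make_paired([("b0", "D1", 5, "X"), ("b1", "D2", 5, "X")])
    assert not call_expansion(paired, scope="donor_cluster").any()
    assert call_expansion(paired, scope="cluster").all()


def test_expansion_invariant_to_row_order_and_donor_names():
    cells = [("b%d" % i, "D1", 5, "A") for i in range(3)] + [("b3", "D2", 6, "B"), ("b4", "D2", 6, "B")]
    paired = make_paired(cells)
    base = call_expansion(paired).to_numpy()
    shuffled = paired.sample(frac=1, random_state=0)
    reordered = call_expansion(shuffled).to_numpy()
    assert (reordered == base[shuffled.index]).all()
    renamed = paired.assign(donor=paired["donor"].map({"D1": "zz", "D2": "aa"}))
    assert (call_expansion(renamed).to_numpy() == base).all()


def expansion_cells(donor, cluster, n_exp, n_single, tag):
    cells = [(f"{tag}e{i}", donor, cluster, f"{tag}E") for i in range(n_exp)]
    cells += [(f"{tag}s{i}", donor, cluster, f"{tag}S{i}") for i in range(n_single)]
    return cells


def test_identical_fractions_give_t_zero_p_one():
    cells = []
    for donor, (ne, ns) in (("D1", (2, 2)), ("D2", (2, 6))):
        cells += expansion_cells(donor, 7, ne, ns, f"{donor}tex")
        cells += expansion_cells(donor, 1, ne, ns, f"{donor}non")
    res = compare_expansion(make_paired(cells), tex_clusters={7}, nonex_clusters={1})
    assert res.statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)
    assert not res.degenerate_variance


def test_zero_variance_groups_flagged_degenerate():
    cells = []
    for donor in ("D1", "D2", "D3"):
        cells += expansion_cells(donor, 7, 2, 0, f"{donor}tex")  # fraction 1
        cells += expansion_cells(donor, 1, 0, 2, f"{donor}non")  # fraction 0
    res = compare_expansion(make_paired(cells), tex_clusters={7}, nonex_clusters={1})
    assert res.degenerate_variance
    assert res.pvalue == 0.0
    assert res.statistic > 0 and np.isinf(res.statistic)


def test_planted_higher_tex_expansion_detected():
    from tcrlineage import SimConfig, generate_cohort

    cfg = SimConfig(
        seed=42,
        clones_per_donor=60,
        trajectory_mixture=(0.2, 0.2, 0.2, 0.1, 0.3),
        clone_size_p=0.25,  # Tex clones mean size 4
        nontex_clone_size_p=1.0,  # non-Tex singletons
    )
    cohort = generate_cohort(cfg)
    paired = filter_single_pair_cells(cohort.contigs, cohort.metadata)
    res = compare_expansion(paired, tex_clusters={5, 6, 7, 8}, nonex_clusters={1, 2, 3})
    assert res.group_means["tex"] > res.group_means["nonex"]
    assert res.statistic > 0


def test_trb_expansion_flags_match_tra(paired):
    """TRB chains are clone-linked, so TRB flags replicate TRA flags."""
    tra = call_expansion(paired, chain="TRA")
    trb = call_expansion(paired, chain="TRB")
    assert (tra == trb).all()
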