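"""Synthetic cohort generator.

Emulates the data structure of a paired scRNA-seq + TCR-seq study of
exhausted CD8+ T cells: a cohort of donors split into responder (R) and
non-responder (NR) groups, cells partitioned into numbered clusters with
four cluster roles (a common precursor, a PD-1+ Tex cluster, CD57+ Tex
clusters, and non-exhausted clusters), and clones planted with known
differentiation trajectories so every downstream stage can be verified
against ground truth.

Each clone is drawn with a trajectory label from a mixture, given an
intended cluster set consistent with that label, and its cells are placed
first one per intended cluster and the remainder multinomially — so the
full signature is observable whenever the clone is at least as large as its
intended set.  Every cell carries one productive TRA and one productive TRB
contig (before dropout); the TRB chain is clone-linked (one fixed TRB per
clone) so TRB-based replication of any TRA analysis is exercisable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .clonotype import clone_key_str

__all__ = ["SimConfig", "Cohort", "ConfigError", "generate_cohort", "write_fixtures", "null_cohort_config"]

#: mixture component order
TRAJECTORY_ORDER = ["TexPD1", "TexCD57", "TexBranching", "TexFluid", "NonTexOnly"]

_FORWARD_TABLE = CodonTable.unambiguous_dna_by_id[1].forward_table
#: sense codons only, so synthetic CDR3 nucleotide strings translate cleanly
_CODONS = sorted(_FORWARD_TABLE)

_POPULATION_LABELS = {
    "precursor": "Precursor TEM",
    "pd1": "PD-1+ Tex",
    "cd57": "CD57+ Tex",
    "nonex": "Non-exhausted",
}

CONTIG_CSV_COLUMNS = [
    "barcode",
    "is_cell",
    "contig_id",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "productive",
    "umis",
]

SPECIFICITY_COLUMNS = ["complex.id", "Gene", "CDR3", "V", "J", "Species", "Epitope", "Epitope species"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the emulated study: 12 donors (6 R, 6 NR), clusters
    1-8 with cluster 4 the common precursor, cluster 7 the PD-1+ Tex
    population and clusters 5, 6, 8 the CD57+ Tex populations.  Clone sizes
    are geometric (support >= 1); the mixture over trajectory labels
    follows :data:`TRAJECTORY_ORDER`.
    """

    n_donors: int = 12
    n_responders: int = 6
    cluster_ids: tuple = tuple(range(1, 9))
    precursor_clusters: frozenset = frozenset({4})
    pd1_clusters: frozenset = frozenset({7})
    cd57_clusters: frozenset = frozenset({5, 6, 8})
    nonex_clusters: frozenset = frozenset({1, 2, 3})
    trajectory_mixture: tuple = (0.12, 0.18, 0.25, 0.10, 0.35)
    clones_per_donor: int = 100
    clone_size_p: float = 0.5
    #: separate geometric parameter for NonTexOnly clones (None: same as clone_size_p)
    nontex_clone_size_p: float | None = None
    cdr3_nt_length_range: tuple = (24, 60)
    dropout_rate: float = 0.0
    dropout_mode: str = "cell"  # "cell": whole TCR lost; "chain": each chain independently
    specificity_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        mix = np.asarray(self.trajectory_mixture, dtype=float)
        if mix.size != len(TRAJECTORY_ORDER) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"trajectory_mixture must be {len(TRAJECTORY_ORDER)} non-negative weights summing to 1"
            )
        roles = [
            set(self.precursor_clusters),
            set(self.pd1_clusters),
            set(self.cd57_clusters),
            set(self.nonex_clusters),
        ]
        for a, b in itertools.combinations(roles, 2):
            if a & b:
                raise ConfigError("cluster role sets must be pairwise disjoint")
        if set().union(*roles) != set(self.cluster_ids):
            raise ConfigError("union of cluster role sets must equal cluster_ids")
        lo, hi = self.cdr3_nt_length_range
        if lo < 3 or hi < lo or ((lo + 2) // 3) * 3 > hi:
            raise ConfigError("cdr3_nt_length_range must contain a multiple of 3, >= 3")
        if not (0 < self.clone_size_p <= 1):
            raise ConfigError("clone_size_p must be in (0, 1]")
        if self.nontex_clone_size_p is not None and not (0 < self.nontex_clone_size_p <= 1):
            raise ConfigError("nontex_clone_size_p must be in (0, 1]")
        if not (0 <= self.dropout_rate <= 1):
            raise ConfigError("dropout_rate must be in [0, 1]")
        if self.dropout_mode not in ("cell", "chain"):
            raise ConfigError("dropout_mode must be 'cell' or 'chain'")
        if not (0 <= self.specificity_fraction <= 1):
            raise ConfigError("specificity_fraction must be in [0, 1]")
        if not (0 <= self.n_responders <= self.n_donors):
            raise ConfigError("n_responders must be in [0, n_donors]")
        # labels with positive weight must have the cluster roles they span
        needs = {
            "TexPD1": (self.precursor_clusters, self.pd1_clusters),
            "TexCD57": (self.precursor_clusters, self.cd57_clusters),
            "TexBranching": (self.precursor_clusters, self.pd1_clusters, self.cd57_clusters),
            "TexFluid": (self.pd1_clusters, self.cd57_clusters),
            "NonTexOnly": (self.nonex_clusters,),
        }
        for label, w in zip(TRAJECTORY_ORDER, mix):
            if w > 0 and any(len(r) == 0 for r in needs[label]):
                raise ConfigError(f"mixture gives weight to {label} but a required cluster role is empty")

    def population_label(self, cluster) -> str:
        if cluster in self.precursor_clusters:
            return _POPULATION_LABELS["precursor"]
        if cluster in self.pd1_clusters:
            return _POPULATION_LABELS["pd1"]
        if cluster in self.cd57_clusters:
            return _POPULATION_LABELS["cd57"]
        return _POPULATION_LABELS["nonex"]


def null_cohort_config(**overrides) -> SimConfig:
    """A cohort with no precursor or trajectory structure.

    All clusters carry the non-exhausted role and every clone is
    NonTexOnly, spanning a random cluster subset with no cluster preferred:
    the candidate precursor clusters are exchangeable, making this the null
    reference for the precursor-sharing and expansion-difference tests.
    """
    defaults = dict(
        precursor_clusters=frozenset(),
        pd1_clusters=frozenset(),
        cd57_clusters=frozenset(),
        nonex_clusters=frozenset(range(1, 9)),
        trajectory_mixture=(0.0, 0.0, 0.0, 0.0, 1.0),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class Cohort:
    """In-memory synthetic cohort: tables plus planted ground truth."""

    contigs: pd.DataFrame
    metadata: pd.DataFrame
    specificity: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimConfig = None


def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> tuple[str, str]:
    lengths = [n for n in range(lo, hi + 1) if n % 3 == 0]
    n_codons = int(rng.choice(lengths)) // 3
    codons = [_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons)]
    nt = "".join(codons)
    aa = "".join(_FORWARD_TABLE[c] for c in codons)
    return nt, aa


def _draw_size(rng: np.random.Generator, p: float, min_size: int, max_attempts: int = 10000) -> int:
    """Geometric clone size (support >= 1), resampled until >= min_size."""
    for _ in range(max_attempts):
        size = int(rng.geometric(p))
        if size >= min_size:
            return size
    raise ConfigError(
        f"clone_size distribution (geometric p={p}) cannot reach the intended "
        f"cluster-set size {min_size}"
    )


def _intended_clusters(rng: np.random.Generator, label: str, cfg: SimConfig) -> list:
    precursor = sorted(cfg.precursor_clusters)
    pd1 = sorted(cfg.pd1_clusters)
    cd57 = sorted(cfg.cd57_clusters)
    nonex = sorted(cfg.nonex_clusters)

    def some_cd57():
        k = int(rng.integers(1, len(cd57) + 1))
        return sorted(rng.choice(cd57, size=k, replace=False).tolist())

    if label == "TexPD1":
        return sorted(precursor + pd1)
    if label == "TexCD57":
        return sorted(precursor + some_cd57())
    if label == "TexBranching":
        return sorted(precursor + pd1 + some_cd57())
    if label == "TexFluid":
        return sorted(pd1 + some_cd57())
    if label == "NonTexOnly":
        p_nontex = cfg.nontex_clone_size_p if cfg.nontex_clone_size_p is not None else cfg.clone_size_p
        max_size = 1 if p_nontex == 1.0 else len(nonex)
        sizes = list(range(1, min(3, len(nonex), max_size) + 1))
        weights = np.array([0.7, 0.2, 0.1][: len(sizes)])
        k = int(rng.choice(sizes, p=weights / weights.sum()))
        return sorted(rng.choice(nonex, size=k, replace=False).tolist())
    raise ValueError(f"unknown trajectory label {label!r}")


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate one synthetic cohort (deterministic for a given config).

    Returns a :class:`Cohort` whose contig table holds one productive TRA
    and one productive TRB row per cell surviving dropout, whose metadata
    lists every cell (cells that lost their TCR to dropout remain — they
    count toward cells without a sequenced TCR), and whose ground truth
    records every planted clone exactly once.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    mix = np.asarray(cfg.trajectory_mixture, dtype=float)
    donors = [f"D{i + 1:02d}" for i in range(cfg.n_donors)]
    responses = ["R" if i < cfg.n_responders else "NR" for i in range(cfg.n_donors)]
    lo, hi = cfg.cdr3_nt_length_range

    contig_rows, meta_rows, gt_rows, spec_rows = [], [], [], []
    clone_serial = 0
    for donor, response in zip(donors, responses):
        cell_serial = 0
        seen_cdr3: set[str] = set()
        for _ in range(cfg.clones_per_donor):
            clone_serial += 1
            label = TRAJECTORY_ORDER[int(rng.choice(len(mix), p=mix))]
            intended = _intended_clusters(rng, label, cfg)
            p_size = (
                cfg.nontex_clone_size_p
                if (label == "NonTexOnly" and cfg.nontex_clone_size_p is not None)
                else cfg.clone_size_p
            )
            size = _draw_size(rng, p_size, len(intended))

            # clone-level receptor: one fixed TRA and one clone-linked TRB
            while True:
                tra_nt, tra_aa = _random_cdr3(rng, lo, hi)
                if tra_nt not in seen_cdr3:
                    seen_cdr3.add(tra_nt)
                    break
            while True:
                trb_nt, trb_aa = _random_cdr3(rng, lo, hi)
                if trb_nt not in seen_cdr3:
                    seen_cdr3.add(trb_nt)
                    break
            tra_v = f"TRAV{int(rng.integers(1, 41))}"
            tra_j = f"TRAJ{int(rng.integers(1, 51))}"
            trb_v = f"TRBV{int(rng.integers(1, 31))}"
            trb_j = f"TRBJ{int(rng.integers(1, 13))}"

            # first one cell per intended cluster, remainder multinomial
            placements = list(intended)
            if size > len(intended):
                extra = rng.choice(intended, size=size - len(intended), replace=True)
                placements += [c.item() if hasattr(c, "item") else c for c in extra]

            species = ""
            if cfg.specificity_fraction > 0 and rng.random() < cfg.specificity_fraction:
                species = "CMV" if rng.random() < 0.7 else "EBV"
                epitope = "".join(
                    sorted(_FORWARD_TABLE.values())[i] for i in rng.integers(0, 20, size=9)
                )
                spec_rows.append(
                    {
                        "complex.id": str(clone_serial),
                        "Gene": "TRA",
                        "CDR3": tra_aa,
                        "V": tra_v,
                        "J": tra_j,
                        "Species": "HomoSapiens",
                        "Epitope": epitope,
                        "Epitope species": species,
                    }
                )
                spec_rows.append(
                    {
                        "complex.id": str(clone_serial),
                        "Gene": "TRB",
                        "CDR3": trb_aa,
                        "V": trb_v,
                        "J": trb_j,
                        "Species": "HomoSapiens",
                        "Epitope": epitope,
                        "Epitope species": species,
                    }
                )

            gt_rows.append(
                {
                    "clone_id": f"C{clone_serial:06d}",
                    "donor": donor,
                    "label": label,
                    "intended_clusters": ",".join(str(c) for c in intended),
                    "clone_size": size,
                    "tra_key": clone_key_str("TRA", tra_v, tra_j, tra_nt),
                    "trb_key": clone_key_str("TRB", trb_v, trb_j, trb_nt),
                    "epitope_species": species,
                }
            )

            for cluster in placements:
                cell_serial += 1
                barcode = f"{donor}-{cell_serial:05d}-1"
                meta_rows.append(
                    {
                        "barcode": barcode,
                        "donor": donor,
                        "cluster": cluster,
                        "population": cfg.population_label(cluster),
                        "response": response,
                    }
                )
                if cfg.dropout_mode == "cell":
                    keep_tra = keep_trb = rng.random() >= cfg.dropout_rate
                else:
                    keep_tra = rng.random() >= cfg.dropout_rate
                    keep_trb = rng.random() >= cfg.dropout_rate
                if keep_tra:
                    contig_rows.append(
                        {
                            "barcode": barcode,
                            "chain": "TRA",
                            "v_gene": tra_v,
                            "j_gene": tra_j,
                            "cdr3_aa": tra_aa,
                            "cdr3_nt": tra_nt,
                            "productive": True,
                            "umis": int(rng.integers(1, 11)),
                        }
                    )
                if keep_trb:
                    contig_rows.append(
                        {
                            "barcode": barcode,
                            "chain": "TRB",
                            "v_gene": trb_v,
                            "j_gene": trb_j,
                            "cdr3_aa": trb_aa,
                            "cdr3_nt": trb_nt,
                            "productive": True,
                            "umis": int(rng.integers(1, 11)),
                        }
                    )

    contig_cols = ["barcode", "chain", "v_gene", "j_gene", "cdr3_aa", "cdr3_nt", "productive", "umis"]
    meta_cols = ["barcode", "donor", "cluster", "population", "response"]
    gt_cols = [
        "clone_id",
        "donor",
        "label",
        "intended_clusters",
        "clone_size",
        "tra_key",
        "trb_key",
        "epitope_species",
    ]
    cohort = Cohort(
        contigs=pd.DataFrame(contig_rows, columns=contig_cols),
        metadata=pd.DataFrame(meta_rows, columns=meta_cols),
        specificity=pd.DataFrame(spec_rows, columns=SPECIFICITY_COLUMNS),
        ground_truth=pd.DataFrame(gt_rows, columns=gt_cols),
        config=cfg,
    )
    return cohort


def write_fixtures(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as on-disk fixtures.

    The contig CSV uses the 10x ``filtered_contig_annotations`` dialect
    (bit-exact header); metadata, specificity and ground truth go to TSV.
    Empty cohorts yield valid header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    contigs = cohort.contigs
    n = len(contigs)
    per_barcode = contigs.groupby("barcode").cumcount() + 1 if n else pd.Series([], dtype=int)
    contig_csv = pd.DataFrame(
        {
            "barcode": contigs["barcode"],
            "is_cell": ["true"] * n,
            "contig_id": (
                contigs["barcode"] + "_contig_" + per_barcode.astype(str) if n else pd.Series([], dtype=str)
            ),
            "chain": contigs["chain"],
            "v_gene": contigs["v_gene"],
            "j_gene": contigs["j_gene"],
            "cdr3": contigs["cdr3_aa"],
            "cdr3_nt": contigs["cdr3_nt"],
            "productive": ["true"] * n,
            "umis": contigs["umis"],
        },
        columns=CONTIG_CSV_COLUMNS,
    )

    paths = {
        "contigs": out_dir / "filtered_contig_annotations.csv",
        "metadata": out_dir / "cell_metadata.tsv",
        "specificity": out_dir / "specificity_db.tsv",
        "ground_truth": out_dir / "ground_truth.tsv",
    }
    contig_csv.to_csv(paths["contigs"], index=False, lineterminator="\n")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False, lineterminator="\n")
    cohort.specificity.to_csv(paths["specificity"], sep="\t", index=False, lineterminator="\n")
    cohort.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False, lineterminator="\n")
    return paths
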