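"""Cluster-membership signatures, four-way trajectory classification,
and Shannon-Wiener clonal diversity.

Each clone's *signature* is the set of clusters its cells occupy (per
donor).  Relative to three cluster roles — a common precursor population, a
PD-1+ exhausted (Tex) population, and CD57+ Tex populations — the signature
assigns the clone to one of four differentiation trajectories:

* ``TexPD1``       precursor and PD-1+ Tex only,
* ``TexCD57``      precursor and CD57+ Tex only,
* ``TexBranching`` precursor and both Tex populations,
* ``TexFluid``     both Tex populations but no precursor,

and ``Unassigned`` otherwise.  Membership in any other (non-exhausted)
cluster never changes the label; it is recorded as an ``extended`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .clonotype import _key_column

logger = logging.getLogger(__name__)

__all__ = [
    "TRAJECTORY_LABELS",
    "build_signatures",
    "decompose_combinations",
    "classify_trajectory",
    "classify_all",
    "shannon_diversity",
    "diversity_table",
    "diversity_comparison",
    "DiversityComparison",
]

#: the four trajectory classes plus the catch-all
TRAJECTORY_LABELS = ["TexPD1", "TexCD57", "TexBranching", "TexFluid", "Unassigned"]
TEX_LABELS = TRAJECTORY_LABELS[:4]


def build_signatures(paired: pd.DataFrame, chain: str = "TRA", scope: str = "per_donor") -> pd.DataFrame:
    """One cluster-membership signature per (clone key, donor).

    Returns a frame with columns clone_key, donor, clusters (frozenset),
    cells_per_cluster (dict), n_cells.  Single-cluster signatures are
    retained — they feed the singleton combination counts and the
    Unassigned class.  ``scope='pooled'`` aggregates donors (donor column
    set to ``'all'``).
    """
    key = _key_column(chain)
    if paired.empty:
        return pd.DataFrame(columns=["clone_key", "donor", "clusters", "cells_per_cluster", "n_cells"])
    df = paired if scope == "per_donor" else paired.assign(donor="all")
    if scope not in ("per_donor", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")

    counts = df.groupby([key, "donor", "cluster"], sort=True).size()
    rows = []
    for (ck, donor), sub in counts.groupby(level=[0, 1], sort=True):
        per_cluster = {c: int(n) for (_, _, c), n in sub.items()}
        rows.append(
            {
                "clone_key": ck,
                "donor": donor,
                "clusters": frozenset(per_cluster),
                "cells_per_cluster": per_cluster,
                "n_cells": int(sub.sum()),
            }
        )
    return pd.DataFrame(rows)


def decompose_combinations(signatures: pd.DataFrame) -> pd.DataFrame:
    """Exact partition of clones by their full cluster combination.

    Each clone is counted once, under its complete signature (the upset-plot
    decomposition): combination counts therefore sum to the number of unique
    (clone, donor) signatures.
    """
    if signatures.empty:
        return pd.DataFrame(columns=["combination", "n_clones"])
    counts = signatures.groupby("clusters", sort=False).size()
    out = pd.DataFrame({"combination": counts.index, "n_clones": counts.values})
    out = out.sort_values(
        ["n_clones", "combination"],
        ascending=[False, True],
        key=lambda s: s if s.name == "n_clones" else s.map(lambda x: sorted(x, key=str)).astype(str),
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def _check_roles(precursor, pd1, cd57):
    precursor, pd1, cd57 = set(precursor), set(pd1), set(cd57)
    if precursor & pd1 or precursor & cd57 or pd1 & cd57:
        raise ValueError("cluster role sets (precursor, pd1, cd57) must be pairwise disjoint")
    return precursor, pd1, cd57


def classify_trajectory(
    signature: Iterable,
    precursor=frozenset({4}),
    pd1=frozenset({7}),
    cd57=frozenset({5, 6, 8}),
) -> str:
    """Trajectory label of one cluster signature.

    The label depends only on which of the three role sets the signature
    touches; clusters outside all roles are ignored here (see
    :func:`classify_all` for the extended flag).
    """
    precursor, pd1, cd57 = _check_roles(precursor, pd1, cd57)
    sig = set(signature)
    has_p = bool(sig & precursor)
    has_pd1 = bool(sig & pd1)
    has_cd57 = bool(sig & cd57)
    if has_p and has_pd1 and has_cd57:
        return "TexBranching"
    if has_p and has_pd1:
        return "TexPD1"
    if has_p and has_cd57:
        return "TexCD57"
    if has_pd1 and has_cd57:
        return "TexFluid"
    return "Unassigned"


def classify_all(
    signatures: pd.DataFrame,
    precursor=frozenset({4}),
    pd1=frozenset({7}),
    cd57=frozenset({5, 6, 8}),
) -> pd.DataFrame:
    """Label every signature; adds ``label`` and ``extended`` columns.

    ``extended`` flags clones that also touch clusters outside all three
    role sets (e.g. non-exhausted clusters); the label itself is unaffected.
    """
    precursor, pd1, cd57 = _check_roles(precursor, pd1, cd57)
    roles = precursor | pd1 | cd57
    out = signatures.copy()
    out["label"] = [
        classify_trajectory(s, precursor, pd1, cd57) for s in signatures.get("clusters", [])
    ]
    out["extended"] = [bool(set(s) - roles) for s in signatures.get("clusters", [])]
    return out


def shannon_diversity(clone_cell_counts, base: float | None = None) -> float:
    """Shannon-Wiener diversity H = -sum p_i log p_i of a clone-abundance vector.

    Natural log (nats) by default; ``base`` switches the logarithm.
    Zero-count clones are excluded; an all-zero vector is an error.
    """
    counts = np.asarray(list(clone_cell_counts), dtype=float)
    if counts.size == 0 or np.all(counts == 0):
        raise ValueError("need at least one positive clone count")
    if np.any(counts < 0):
        raise ValueError("negative clone count")
    counts = counts[counts > 0]
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def diversity_table(assignments: pd.DataFrame, base: float | None = None) -> pd.DataFrame:
    """Per-donor, per-trajectory Shannon-Wiener diversity.

    Diversity is abundance-weighted: computed on cell counts per clone
    (richness and evenness), not mere clone presence.
    """
    rows = []
    for (donor, label), sub in assignments.groupby(["donor", "label"], sort=True):
        counts = sub["n_cells"].to_numpy()
        rows.append(
            {
                "donor": donor,
                "label": label,
                "shannon_h": shannon_diversity(counts, base=base),
                "n_clones": len(sub),
                "n_cells": int(counts.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["donor", "label", "shannon_h", "n_clones", "n_cells"])


@dataclass
class DiversityComparison:
    statistic: float | None
    pvalue: float | None
    group_medians: dict = field(default_factory=dict)
    not_testable: bool = False
    no_variation: bool = False

    def summary(self) -> pd.DataFrame:
        row = {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "not_testable": self.not_testable,
            "no_variation": self.no_variation,
        }
        for k, v in self.group_medians.items():
            row[f"median_h_{k}"] = v
        return pd.DataFrame([row])


def diversity_comparison(div_table: pd.DataFrame, labels=tuple(TEX_LABELS)) -> DiversityComparison:
    """Kruskal-Wallis comparison of per-donor diversity across trajectories."""
    groups, medians = [], {}
    for lab in labels:
        vals = div_table.loc[div_table["label"] == lab, "shannon_h"].to_numpy()
        if len(vals) >= 2:
            groups.append(vals)
            medians[lab] = float(np.median(vals))
    if len(groups) < 2:
        return DiversityComparison(None, None, medians, not_testable=True)
    values = np.concatenate(groups)
    if np.all(values == values[0]):
        return DiversityComparison(None, None, medians, no_variation=True)
    stat, p = stats.kruskal(*groups)
    return DiversityComparison(float(stat), float(p), medians)
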