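"""Clonal identity, single-pair filtering, and clonal-expansion summaries.

A clone is identified by its TCR chain, V gene, J gene, and CDR3 nucleotide
sequence: at nucleotide resolution this combination is effectively a private
lineage barcode, so cells sharing it are clonally related.  Only cells with
exactly one productive TRA and one productive TRB contig are analysed, which
removes cell doublets at the cost of cells with partial TCR recovery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CloneKey",
    "clone_key_str",
    "filter_single_pair_cells",
    "call_expansion",
    "compare_expansion",
    "ExpansionComparison",
]

PAIRED_COLUMNS = [
    "barcode",
    "donor",
    "cluster",
    "population",
    "response",
    "tra_v",
    "tra_j",
    "tra_cdr3_aa",
    "tra_cdr3_nt",
    "trb_v",
    "trb_j",
    "trb_cdr3_aa",
    "trb_cdr3_nt",
    "tra_key",
    "trb_key",
]


class CloneKey(NamedTuple):
    """Clonal identity: chain + V gene + J gene + CDR3 nucleotide sequence."""

    chain: str
    v_gene: str
    j_gene: str
    cdr3_nt: str

    def as_str(self) -> str:
        return "|".join(self)


def clone_key_str(chain, v_gene, j_gene, cdr3_nt) -> str:
    """Serialize a clone key; V/J gene names are case-normalized."""
    return f"{chain}|{str(v_gene).upper()}|{str(j_gene).upper()}|{cdr3_nt}"


def filter_single_pair_cells(contigs: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Keep cells with exactly one productive TRA and one productive TRB.

    Parameters
    ----------
    contigs
        Productive-filtered contig table from
        :func:`tcrlineage.io.read_contig_annotations`.
    metadata
        Per-cell metadata; only barcodes present here are retained (TCR
        calls are mapped back onto the expression-QC'd cells).

    Returns
    -------
    pandas.DataFrame
        One row per retained cell with both clone keys.  Filter-step counts
        are attached as ``attrs["filter_report"]``.
    """
    counts = contigs.groupby(["barcode", "chain"]).size().unstack(fill_value=0)
    for ch in ("TRA", "TRB"):
        if ch not in counts.columns:
            counts[ch] = 0
    single_pair_barcodes = counts.index[(counts["TRA"] == 1) & (counts["TRB"] == 1)]

    n_barcodes_with_tcr = counts.shape[0]
    n_single_pair = len(single_pair_barcodes)

    sub = contigs[contigs["barcode"].isin(single_pair_barcodes)]
    tra = sub[sub["chain"] == "TRA"].set_index("barcode")
    trb = sub[sub["chain"] == "TRB"].set_index("barcode")

    cells = metadata.set_index("barcode")
    retained = [b for b in single_pair_barcodes if b in cells.index]

    rows = []
    for b in retained:
        a, bb, m = tra.loc[b], trb.loc[b], cells.loc[b]
        rows.append(
            {
                "barcode": b,
                "donor": m["donor"],
                "cluster": m["cluster"],
                "population": m["population"],
                "response": m["response"],
                "tra_v": a["v_gene"],
                "tra_j": a["j_gene"],
                "tra_cdr3_aa": a["cdr3_aa"],
                "tra_cdr3_nt": a["cdr3_nt"],
                "trb_v": bb["v_gene"],
                "trb_j": bb["j_gene"],
                "trb_cdr3_aa": bb["cdr3_aa"],
                "trb_cdr3_nt": bb["cdr3_nt"],
                "tra_key": clone_key_str("TRA", a["v_gene"], a["j_gene"], a["cdr3_nt"]),
                "trb_key": clone_key_str("TRB", bb["v_gene"], bb["j_gene"], bb["cdr3_nt"]),
            }
        )
    paired = pd.DataFrame(rows, columns=PAIRED_COLUMNS)
    paired = paired.sort_values("barcode", kind="mergesort").reset_index(drop=True)
    paired.attrs["filter_report"] = {
        "n_barcodes_with_tcr": n_barcodes_with_tcr,
        "n_single_pair": n_single_pair,
        "n_in_metadata": len(paired),
    }
    logger.info(
        "single-pair filter: %d barcodes with a TCR -> %d single-pair -> %d in metadata",
        n_barcodes_with_tcr,
        n_single_pair,
        len(paired),
    )
    return paired


def _key_column(chain: str) -> str:
    if chain not in ("TRA", "TRB"):
        raise ValueError(f"chain must be TRA or TRB, got {chain!r}")
    return "tra_key" if chain == "TRA" else "trb_key"


def _scope_columns(scope: str) -> list[str]:
    scopes = {
        "donor_cluster": ["donor", "cluster"],
        "cluster": ["cluster"],  # pooled across donors
        "donor": ["donor"],  # pooled across clusters
    }
    if scope not in scopes:
        raise ValueError(f"unknown expansion scope {scope!r}; choose from {sorted(scopes)}")
    return scopes[scope]


def call_expansion(paired: pd.DataFrame, chain: str = "TRA", scope: str = "donor_cluster") -> pd.Series:
    """Flag each cell as clonally expanded within its scope group.

    A cell is expanded iff its clone key occurs in more than one cell within
    the scope group (default: within donor x cluster).
    """
    if paired.empty:
        return pd.Series([], dtype=bool, name="expanded")
    key = _key_column(chain)
    group_cols = _scope_columns(scope) + [key]
    sizes = paired.groupby(group_cols)[key].transform("size")
    return pd.Series(sizes > 1, name="expanded")


@dataclass
class ExpansionComparison:
    """Two-sample comparison of per-donor expanded-cell fractions."""

    statistic: float
    pvalue: float
    per_donor: pd.DataFrame
    group_means: dict = field(default_factory=dict)
    degenerate_variance: bool = False
    equal_var: bool = True

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [self.statistic],
                "pvalue": [self.pvalue],
                "mean_tex": [self.group_means.get("tex", float("nan"))],
                "mean_nonex": [self.group_means.get("nonex", float("nan"))],
                "degenerate_variance": [self.degenerate_variance],
                "equal_var": [self.equal_var],
            }
        )


def compare_expansion(
    paired: pd.DataFrame,
    tex_clusters,
    nonex_clusters,
    chain: str = "TRA",
    scope: str = "donor_cluster",
    equal_var: bool = True,
) -> ExpansionComparison:
    """Compare per-donor expanded-cell fractions between two cluster groups.

    For each donor the fraction of cells carrying an expanded clone (per
    :func:`call_expansion`) is computed separately over cells in
    ``tex_clusters`` and in ``nonex_clusters``; the two sets of per-donor
    fractions are compared with a two-sided two-sample t-test
    (equal-variance by default, Welch via ``equal_var=False``).  Donors with
    zero cells in a group are omitted from that group with a warning.
    """
    tex_clusters, nonex_clusters = set(tex_clusters), set(nonex_clusters)
    expanded = call_expansion(paired, chain=chain, scope=scope)
    df = paired.assign(expanded=expanded.to_numpy())

    records = []
    for group_name, clusters in (("tex", tex_clusters), ("nonex", nonex_clusters)):
        sub = df[df["cluster"].isin(clusters)]
        for donor in sorted(df["donor"].unique()):
            dsub = sub[sub["donor"] == donor]
            if len(dsub) == 0:
                logger.warning("donor %s has 0 cells in group %s; omitted", donor, group_name)
                continue
            records.append(
                {
                    "donor": donor,
                    "cluster_group": group_name,
                    "n_cells": len(dsub),
                    "n_expanded_cells": int(dsub["expanded"].sum()),
                    "fraction_expanded": float(dsub["expanded"].mean()),
                }
            )
    per_donor = pd.DataFrame(
        records, columns=["donor", "cluster_group", "n_cells", "n_expanded_cells", "fraction_expanded"]
    )

    a = per_donor.loc[per_donor["cluster_group"] == "tex", "fraction_expanded"].to_numpy()
    b = per_donor.loc[per_donor["cluster_group"] == "nonex", "fraction_expanded"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 donors contributing to each group")

    means = {"tex": float(np.mean(a)), "nonex": float(np.mean(b))}
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    if var_a == 0 and var_b == 0:
        # zero pooled variance: the t statistic is unbounded unless the
        # means coincide; report a flagged result instead of NaN
        if means["tex"] == means["nonex"]:
            stat, p = 0.0, 1.0
        else:
            stat = math.copysign(math.inf, means["tex"] - means["nonex"])
            p = 0.0
        return ExpansionComparison(stat, p, per_donor, means, degenerate_variance=True, equal_var=equal_var)

    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return ExpansionComparison(
        float(res.statistic), float(res.pvalue), per_donor, means, equal_var=equal_var
    )
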