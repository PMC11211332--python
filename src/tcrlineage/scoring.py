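"""Peak-set and gene-set signature scoring.

Implements the interval-level overlap rule (any overlap of at least one
base, 0-based half-open coordinates), peak-set Jaccard similarity with
hypergeometric enrichment, peak-to-gene annotation within a fixed window of
a feature start (TSS/miRNA/exon), per-sample aggregate signature scores
over a gene list (e.g. a "CD57+ Tex ATAC score" over differentially
accessible genes), and z-score-adjusted cluster-mean expression summaries.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed",
    "overlap_peaks",
    "peakset_jaccard",
    "hypergeometric_enrichment",
    "annotate_peaks_to_genes",
    "atac_signature_score",
    "zscore_cluster_means",
]

PEAK_COLUMNS = ["chrom", "start", "end", "id"]
FEATURE_COLUMNS = ["chrom", "pos", "strand", "feature_type", "gene"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ peak file into a peak table (0-based half-open).

    Column 4, when present, becomes the interval id; otherwise ids are
    ``chrom:start-end``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].str.strip(),
            "start": pd.to_numeric(df[1]),
            "end": pd.to_numeric(df[2]),
            "id": df[3].str.strip() if df.shape[1] >= 4 else None,
        }
    )
    coord_id = out["chrom"] + ":" + out["start"].astype(str) + "-" + out["end"].astype(str)
    out["id"] = out["id"].where(out["id"].notna() & (out["id"].astype(str) != ""), coord_id)
    _validate_peaks(out, path)
    return out.reset_index(drop=True)


def _validate_peaks(peaks: pd.DataFrame, label="peak table") -> None:
    if (peaks["end"] <= peaks["start"]).any() or (peaks["start"] < 0).any():
        raise ValueError(f"{label}: malformed interval (need 0 <= start < end)")
    if (peaks["chrom"].astype(str) == "").any():
        raise ValueError(f"{label}: empty chrom")


def _build_trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(zip(sub["start"], sub["end"]))
    return trees


def overlap_peaks(query: pd.DataFrame, subject: pd.DataFrame) -> tuple[pd.Series, int]:
    """Flag each query interval that overlaps >= 1 subject interval by >= 1 bp.

    Coordinates are 0-based half-open, so abutting intervals ([0,10) and
    [10,20)) do not overlap.  Returns ``(per-query boolean Series, hit count)``.
    """
    _validate_peaks(query, "query")
    _validate_peaks(subject, "subject")
    trees = _build_trees(subject)
    hits = [
        bool(trees[c].overlap(s, e)) if c in trees else False
        for c, s, e in zip(query["chrom"], query["start"], query["end"])
    ]
    flags = pd.Series(hits, index=query.index, name="overlaps")
    return flags, int(flags.sum())


def peakset_jaccard(a: pd.DataFrame, b: pd.DataFrame, symmetric: bool = False) -> float:
    """Jaccard similarity of two peak sets under the any-overlap relation.

    Element identity is the interval: |X n Y| is the number of ``a``
    intervals hitting ``b`` and |X u Y| = |a| + |b| - |X n Y|.  The
    intersection is counted from the query side; ``symmetric=True`` returns
    the mean of both directions.  Defined 0 (logged) when both sets are
    empty.
    """
    if len(a) == 0 and len(b) == 0:
        logger.info("both peak sets empty; J defined 0")
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return 0.0
    _, k_ab = overlap_peaks(a, b)
    j_ab = k_ab / (len(a) + len(b) - k_ab)
    if not symmetric:
        return j_ab
    _, k_ba = overlap_peaks(b, a)
    j_ba = k_ba / (len(a) + len(b) - k_ba)
    return 0.5 * (j_ab + j_ba)


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric enrichment p-value, P(X >= k) inclusive.

    Drawing ``n`` items from a universe of ``N`` containing ``K`` successes,
    the p-value is the probability of observing at least the ``k`` overlaps
    seen.  The universe ``N`` must be supplied by the caller (e.g. the
    consensus-peak count); it is never inferred.
    """
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def annotate_peaks_to_genes(
    peaks: pd.DataFrame, features: pd.DataFrame, window: int = 5000
) -> pd.DataFrame:
    """Annotate each peak to the nearest feature within ``window`` bp.

    ``features`` needs columns chrom, pos, strand, feature_type, gene; the
    window is taken symmetrically around the feature start position (-5000
    to +5000 bp by default, on either strand).  A peak overlapping the
    feature position has distance 0; otherwise distance is from the nearest
    peak edge.  Peaks with no feature in range are unannotated (NA gene).
    Ties go to the feature that appears first in the table.
    """
    _validate_peaks(peaks, "peaks")
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {', '.join(missing)}")
    if features["strand"].isna().any() or (~features["strand"].isin(["+", "-"])).any():
        raise ValueError("feature table has missing or invalid strand values")

    feats_by_chrom = {c: sub.reset_index(drop=True) for c, sub in features.groupby("chrom")}
    rows = []
    for _, peak in peaks.iterrows():
        gene, ftype, dist = None, None, None
        sub = feats_by_chrom.get(peak["chrom"])
        if sub is not None:
            pos = sub["pos"].to_numpy(dtype=float)
            # distance from interval [start, end) to point pos; 0 if inside
            d = np.maximum.reduce([pos - (peak["end"] - 1), peak["start"] - pos, np.zeros_like(pos)])
            in_range = d <= window
            if in_range.any():
                best = int(np.flatnonzero(in_range)[np.argmin(d[in_range])])
                gene = sub.loc[best, "gene"]
                ftype = sub.loc[best, "feature_type"]
                dist = int(d[best])
        rows.append(
            {
                "peak_id": peak["id"],
                "chrom": peak["chrom"],
                "start": peak["start"],
                "end": peak["end"],
                "gene": gene,
                "feature_type": ftype,
                "distance": dist,
            }
        )
    return pd.DataFrame(rows)


def atac_signature_score(
    log_norm_matrix: pd.DataFrame, gene_list, aggregation: str = "mean"
) -> pd.Series:
    """Per-sample aggregate signature score over a gene list.

    ``log_norm_matrix`` is samples x genes of log-normalized scores.  The
    default aggregation is the mean over the gene list (invariant to gene-
    list size); ``aggregation='sum'`` is available.  Genes absent from the
    matrix are dropped with a warning; an empty effective list is an error.
    Duplicate gene columns are the caller's responsibility and are logged.
    """
    gene_list = list(dict.fromkeys(gene_list))
    present = [g for g in gene_list if g in log_norm_matrix.columns]
    missing = [g for g in gene_list if g not in log_norm_matrix.columns]
    if missing:
        logger.warning("%d gene(s) absent from matrix, dropped: %s", len(missing), missing[:10])
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if log_norm_matrix.columns.duplicated().any():
        logger.warning("matrix has duplicated gene columns; all occurrences aggregated")
    sub = log_norm_matrix[present]
    if aggregation == "mean":
        score = sub.mean(axis=1)
    elif aggregation == "sum":
        score = sub.sum(axis=1)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    score = score.rename("score")
    score.attrs["genes_used"] = present
    score.attrs["genes_dropped"] = missing
    return score


def zscore_cluster_means(
    expression: pd.DataFrame, cluster_labels: pd.Series | list, gene_list=None
) -> tuple[pd.DataFrame, pd.Series]:
    """Z-score-adjusted mean expression of genes across clusters.

    For each gene: mean over cells within each cluster, then z-scored
    across clusters (sample standard deviation).  Returns ``(gene x cluster
    frame, zero-variance flags)``; zero-variance genes get an all-zero row.
    Clusters with no cells are excluded with a warning upstream of the mean
    (they simply do not appear among the labels).
    """
    labels = pd.Series(list(cluster_labels), index=expression.index, name="cluster")
    genes = list(gene_list) if gene_list is not None else list(expression.columns)
    missing = [g for g in genes if g not in expression.columns]
    if missing:
        raise ValueError(f"gene(s) not in expression matrix: {missing[:10]}")

    means = expression[genes].groupby(labels).mean().T  # gene x cluster
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    zero_var = pd.Series(sd.fillna(0.0) == 0.0, name="zero_variance")
    z = means.sub(mu, axis=0).div(sd.where(~zero_var, 1.0), axis=0)
    z[zero_var] = 0.0
    if zero_var.any():
        logger.warning("%d gene(s) with identical cluster means; rows zeroed and flagged", int(zero_var.sum()))
    return z, zero_var
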