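"""Cross-cluster repertoire sharing: Jaccard matrices, sharing networks,
and the candidate-precursor analysis.

Clusters that exchange many clonotypes are lineage-related: a clone observed
in two clusters implies a differentiation path between them (or a common
ancestor).  The repertoire of a cluster is its set of unique clone keys;
pairwise overlap is summarized by shared counts and the Jaccard similarity
J(X,Y) = |X n Y| / |X u Y|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .clonotype import _key_column

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterRepertoire",
    "SharingMatrix",
    "build_repertoires",
    "jaccard_matrix",
    "sharing_network",
    "precursor_sharing",
    "PrecursorSharingResult",
]


@dataclass(frozen=True)
class ClusterRepertoire:
    """Unique clone keys observed in one cluster (optionally one donor)."""

    cluster: object
    clone_keys: frozenset
    n_cells_with_tcr: int
    donor: str | None = None  # None for pooled scope

    def __post_init__(self):
        if len(self.clone_keys) > self.n_cells_with_tcr:
            raise ValueError("more unique clones than cells in repertoire")


def build_repertoires(
    paired: pd.DataFrame,
    chain: str = "TRA",
    scope: str = "pooled",
    cluster_ids=None,
) -> list[ClusterRepertoire]:
    """Build per-cluster (or per donor x cluster) clone repertoires.

    ``cluster_ids``, when given, fixes the cluster universe: unknown cluster
    labels in the cells raise, and clusters with no cells get an empty
    repertoire.
    """
    key = _key_column(chain)
    observed = list(pd.unique(paired["cluster"])) if len(paired) else []
    if cluster_ids is not None:
        unknown = set(observed) - set(cluster_ids)
        if unknown:
            raise ValueError(f"unknown cluster id(s) in cells: {sorted(unknown, key=str)}")
        clusters = list(cluster_ids)
    else:
        clusters = sorted(observed, key=str)

    reps: list[ClusterRepertoire] = []
    if scope == "pooled":
        for c in clusters:
            sub = paired[paired["cluster"] == c]
            reps.append(ClusterRepertoire(c, frozenset(sub[key]), len(sub)))
    elif scope == "per_donor":
        donors = sorted(paired["donor"].unique()) if len(paired) else []
        for d in donors:
            dsub = paired[paired["donor"] == d]
            for c in clusters:
                sub = dsub[dsub["cluster"] == c]
                reps.append(ClusterRepertoire(c, frozenset(sub[key]), len(sub), donor=d))
    else:
        raise ValueError(f"unknown scope {scope!r}; choose 'pooled' or 'per_donor'")
    return reps


@dataclass
class SharingMatrix:
    """Symmetric shared-clone counts and Jaccard similarities between clusters."""

    clusters: list
    shared_counts: pd.DataFrame
    jaccard: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, ci in enumerate(self.clusters):
            for cj in self.clusters[i:]:
                rows.append(
                    {
                        "cluster_a": ci,
                        "cluster_b": cj,
                        "shared_count": int(self.shared_counts.loc[ci, cj]),
                        "jaccard": float(self.jaccard.loc[ci, cj]),
                    }
                )
        return pd.DataFrame(rows)


def jaccard_matrix(repertoires: list[ClusterRepertoire]) -> SharingMatrix:
    """Pairwise shared-clone counts and Jaccard similarity between repertoires.

    The diagonal of the count matrix holds repertoire sizes; J is defined 0
    (and logged) when both sets are empty.
    """
    if not repertoires:
        raise ValueError("need at least one repertoire")
    clusters = [r.cluster for r in repertoires]
    if len(set(clusters)) != len(clusters):
        raise ValueError("duplicate cluster in repertoire list (use pooled scope or filter one donor)")
    sets = {r.cluster: r.clone_keys for r in repertoires}

    n = len(clusters)
    shared = np.zeros((n, n), dtype=int)
    jac = np.zeros((n, n), dtype=float)
    for i, ci in enumerate(clusters):
        for j, cj in enumerate(clusters):
            inter = len(sets[ci] & sets[cj])
            union = len(sets[ci] | sets[cj])
            shared[i, j] = inter
            if union == 0:
                logger.info("both repertoires empty for (%s, %s); J defined 0", ci, cj)
                jac[i, j] = 0.0
            else:
                jac[i, j] = inter / union
    return SharingMatrix(
        clusters,
        pd.DataFrame(shared, index=clusters, columns=clusters),
        pd.DataFrame(jac, index=clusters, columns=clusters),
    )


def sharing_network(paired: pd.DataFrame, chain: str = "TRA", cluster_ids=None) -> nx.Graph:
    """Cluster-level clone-sharing network.

    Nodes are clusters sized by the number of cells with a sequenced TCR;
    an edge (i, j), i != j, carries the number of unique clones shared
    between the two clusters; a self-loop on i carries the number of
    distinct clones expanded (>= 2 cells) within cluster i.
    """
    reps = build_repertoires(paired, chain=chain, scope="pooled", cluster_ids=cluster_ids)
    mat = jaccard_matrix(reps)
    key = _key_column(chain)

    g = nx.Graph()
    for r in reps:
        g.add_node(r.cluster, n_cells=r.n_cells_with_tcr)
    for i, ci in enumerate(mat.clusters):
        for cj in mat.clusters[i + 1 :]:
            w = int(mat.shared_counts.loc[ci, cj])
            if w > 0:
                g.add_edge(ci, cj, weight=w)
    # self-loops: clones with >=2 cells within one cluster
    within = paired.groupby(["cluster", key]).size()
    expanded_per_cluster = within[within > 1].groupby("cluster").size()
    for c, k in expanded_per_cluster.items():
        g.add_edge(c, c, weight=int(k))
    return g


def network_tables(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Node / edge / self-loop tables of a sharing network (for TSV output)."""
    nodes = pd.DataFrame(
        [{"cluster": n, "n_cells": d["n_cells"]} for n, d in sorted(g.nodes(data=True), key=lambda x: str(x[0]))]
    )
    edges, loops = [], []
    for u, v, d in g.edges(data=True):
        if u == v:
            loops.append({"cluster": u, "n_expanded_clones": d["weight"]})
        else:
            a, b = sorted((u, v), key=str)
            edges.append({"cluster_a": a, "cluster_b": b, "shared_count": d["weight"]})
    edges_df = pd.DataFrame(edges, columns=["cluster_a", "cluster_b", "shared_count"])
    loops_df = pd.DataFrame(loops, columns=["cluster", "n_expanded_clones"])
    if len(edges_df):
        edges_df = edges_df.sort_values(["cluster_a", "cluster_b"], key=lambda s: s.astype(str)).reset_index(drop=True)
    if len(loops_df):
        loops_df = loops_df.sort_values("cluster", key=lambda s: s.astype(str)).reset_index(drop=True)
    return nodes, edges_df, loops_df


@dataclass
class PrecursorSharingResult:
    """Per-donor sharing percentages with each candidate precursor cluster."""

    per_donor: pd.DataFrame  # donor, precursor_cluster, pct_shared, n_tex_cells
    statistic: float | None
    pvalue: float | None
    medians: dict = field(default_factory=dict)
    no_variation: bool = False

    def summary(self) -> pd.DataFrame:
        row = {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "no_variation": self.no_variation,
        }
        for c, m in self.medians.items():
            row[f"median_pct_cluster_{c}"] = m
        return pd.DataFrame([row])


def precursor_sharing(
    paired: pd.DataFrame,
    tex_clusters=(5, 6, 7, 8),
    candidate_precursors=(1, 2, 3, 4),
    chain: str = "TRA",
) -> PrecursorSharingResult:
    """Which candidate cluster shares the most clones with the Tex compartment?

    For each donor and each candidate precursor cluster c, computes the
    percentage of that donor's Tex-cluster cells whose clone key is also
    present in cluster c of the same donor, then compares the candidate
    groups of per-donor percentages with a Kruskal-Wallis one-way test.
    Sharing is evaluated within donor: nucleotide-level clone keys are
    effectively donor-private.
    """
    tex_clusters = set(tex_clusters)
    candidates = list(candidate_precursors)
    key = _key_column(chain)

    donors = sorted(paired["donor"].unique())
    if len(donors) < 3:
        raise ValueError("need at least 3 donors")

    records = []
    for d in donors:
        dsub = paired[paired["donor"] == d]
        tex_cells = dsub[dsub["cluster"].isin(tex_clusters)]
        if len(tex_cells) == 0:
            logger.warning("donor %s has 0 Tex cells; omitted", d)
            continue
        for c in candidates:
            rep = set(dsub.loc[dsub["cluster"] == c, key])
            pct = 100.0 * tex_cells[key].isin(rep).mean()
            records.append(
                {"donor": d, "precursor_cluster": c, "pct_shared": pct, "n_tex_cells": len(tex_cells)}
            )
    per_donor = pd.DataFrame(records, columns=["donor", "precursor_cluster", "pct_shared", "n_tex_cells"])

    groups = [
        per_donor.loc[per_donor["precursor_cluster"] == c, "pct_shared"].to_numpy() for c in candidates
    ]
    medians = {c: float(np.median(g)) if len(g) else float("nan") for c, g in zip(candidates, groups)}
    values = np.concatenate(groups) if groups else np.array([])
    if len(values) == 0 or np.all(values == values[0]):
        return PrecursorSharingResult(per_donor, None, None, medians, no_variation=True)
    stat, p = stats.kruskal(*groups)
    return PrecursorSharingResult(per_donor, float(stat), float(p), medians)
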