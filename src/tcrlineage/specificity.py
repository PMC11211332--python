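"""Antigen-specificity annotation by exact matching to a VDJdb-style table.

Clones are annotated when their V gene, J gene, CDR3 amino-acid sequence and
chain exactly match a database record.  Matching is at amino-acid
resolution (convergent recombination: distinct nucleotide clones with the
same V/J/CDR3aa share specificity), while clone identity elsewhere in the
package stays at nucleotide resolution.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["normalize_gene_name", "match_specificity", "specificity_by_trajectory"]


def normalize_gene_name(name: str, strip_alleles: bool = True) -> str:
    """Case-normalize a V/J gene name, optionally stripping allele suffixes.

    VDJdb exports carry allele-level names (``TRAV1-2*01``) where 10x output
    does not; allele suffixes are stripped by default so the two dialects
    match.
    """
    name = str(name).strip().upper()
    if strip_alleles:
        name = name.split("*", 1)[0]
    return name


def _chain_cols(chain: str) -> tuple[str, str, str, str]:
    if chain == "TRA":
        return "tra_v", "tra_j", "tra_cdr3_aa", "tra_key"
    if chain == "TRB":
        return "trb_v", "trb_j", "trb_cdr3_aa", "trb_key"
    raise ValueError(f"chain must be TRA or TRB, got {chain!r}")


def match_specificity(
    paired: pd.DataFrame,
    specificity_db: pd.DataFrame,
    chain: str = "TRA",
    strip_alleles: bool = True,
) -> pd.DataFrame:
    """Annotate clones with known antigen specificities.

    Exact match on (chain, V gene, J gene, CDR3 amino acids).  The database
    is deduplicated before matching; a clone matching several epitopes of
    one species yields a single species annotation (epitopes ';'-joined),
    and a clone matching multiple species gets every species row flagged
    ``ambiguous_species``.

    Returns columns clone_key, donor, epitope_species, epitope, matched_on,
    ambiguous_species.
    """
    vcol, jcol, cdr3col, keycol = _chain_cols(chain)

    db = specificity_db[specificity_db["chain"] == chain].copy()
    db["v_norm"] = db["v_gene"].map(lambda g: normalize_gene_name(g, strip_alleles))
    db["j_norm"] = db["j_gene"].map(lambda g: normalize_gene_name(g, strip_alleles))
    db = db.drop_duplicates(subset=["v_norm", "j_norm", "cdr3_aa", "epitope_species", "epitope"])

    clones = paired.drop_duplicates(subset=[keycol, "donor"])[[keycol, "donor", vcol, jcol, cdr3col]]
    clones = clones.rename(columns={keycol: "clone_key", vcol: "v_norm", jcol: "j_norm", cdr3col: "cdr3_aa"})
    clones = clones.assign(
        v_norm=clones["v_norm"].map(lambda g: normalize_gene_name(g, strip_alleles)),
        j_norm=clones["j_norm"].map(lambda g: normalize_gene_name(g, strip_alleles)),
    )

    hits = clones.merge(db, on=["v_norm", "j_norm", "cdr3_aa"], how="inner")
    if hits.empty:
        return pd.DataFrame(
            columns=["clone_key", "donor", "epitope_species", "epitope", "matched_on", "ambiguous_species"]
        )

    rows = []
    for (ck, donor, species), sub in hits.groupby(["clone_key", "donor", "epitope_species"], sort=True):
        epitopes = sorted({e for e in sub["epitope"] if e})
        rows.append(
            {
                "clone_key": ck,
                "donor": donor,
                "epitope_species": species,
                "epitope": ";".join(epitopes),
                "matched_on": chain,
            }
        )
    out = pd.DataFrame(rows)
    n_species = out.groupby(["clone_key", "donor"])["epitope_species"].transform("nunique")
    out["ambiguous_species"] = n_species > 1
    if out["ambiguous_species"].any():
        logger.warning(
            "%d clone(s) match multiple epitope species; all reported with ambiguity flag",
            int(out.loc[out["ambiguous_species"], ["clone_key", "donor"]].drop_duplicates().shape[0]),
        )
    return out.sort_values(["clone_key", "donor", "epitope_species"]).reset_index(drop=True)


def specificity_by_trajectory(
    annotations: pd.DataFrame, assignments: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize which trajectories carry each antigen specificity.

    Returns ``(summary, per_donor)``: the pooled summary has one row per
    epitope species with the number of donors carrying at least one
    annotated clone and the sorted set of trajectory labels represented;
    ``per_donor`` has one row per (species, donor, label) with clone counts.
    Annotations whose clone is absent from the assignments are logged and
    excluded.
    """
    merged = annotations.merge(
        assignments[["clone_key", "donor", "label"]], on=["clone_key", "donor"], how="left"
    )
    orphan = merged["label"].isna()
    if orphan.any():
        logger.warning("%d annotation(s) for clones absent from assignments; excluded", int(orphan.sum()))
        merged = merged[~orphan]
    if merged.empty:
        return (
            pd.DataFrame(columns=["epitope_species", "n_donors", "trajectories"]),
            pd.DataFrame(columns=["epitope_species", "donor", "label", "n_clones"]),
        )

    per_donor = (
        merged.groupby(["epitope_species", "donor", "label"], sort=True)
        .size()
        .rename("n_clones")
        .reset_index()
    )
    summary = (
        merged.groupby("epitope_species", sort=True)
        .agg(
            n_donors=("donor", "nunique"),
            trajectories=("label", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
    )
    return summary, per_donor
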