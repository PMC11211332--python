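"""Readers and writers for the standard input/output formats.

Supported inputs are 10x-style ``filtered_contig_annotations`` CSV tables,
per-cell metadata TSVs, and VDJdb-style specificity exports.  All readers are
loss-accounting: every dropped row is counted by reason and the tally is
attached to the returned frame as ``df.attrs["read_report"]`` with
``rows_in == rows_kept + sum(dropped.values())``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "IntegrityError",
    "read_contig_annotations",
    "read_cell_metadata",
    "read_vdjdb",
    "write_table",
    "CONTIG_COLUMNS",
    "METADATA_COLUMNS",
]

#: required columns of the 10x contig-annotation dialect (bit-exact header)
CONTIG_COLUMNS = [
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "productive",
    "umis",
]

METADATA_COLUMNS = ["barcode", "donor", "cluster", "population", "response"]

_TRUE_STRINGS = {"true", "t", "1", "yes"}
_VALID_RESPONSES = {"R", "NR", "NA"}


class FormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


class IntegrityError(ValueError):
    """The file violates a uniqueness or consistency constraint."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().isin(_TRUE_STRINGS)


def coerce_cluster(value):
    """Canonicalize a cluster identifier: numeric-looking ids become ints."""
    try:
        return int(value)
    except (TypeError, ValueError):
        return str(value).strip()


def read_contig_annotations(path: str | Path) -> pd.DataFrame:
    """Read a 10x-style contig-annotation CSV.

    Rows that are not productive or whose chain is not TRA/TRB are dropped;
    the per-reason counts are exposed in ``attrs["read_report"]`` and logged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CONTIG_COLUMNS, path)
    rows_in = len(df)

    productive = _as_bool(df["productive"])
    abc_chain = df["chain"].isin(["TRA", "TRB"])
    # a row failing both filters is attributed to the productivity filter
    dropped = {
        "non_productive": int((~productive).sum()),
        "non_tra_trb_chain": int((productive & ~abc_chain).sum()),
    }
    kept = df[productive & abc_chain].copy()
    kept["productive"] = True
    kept["umis"] = pd.to_numeric(kept["umis"], errors="coerce").fillna(0).astype(int)
    if (kept["umis"] < 0).any():
        raise FormatError(f"{path}: negative umi count")
    kept = kept.rename(columns={"cdr3": "cdr3_aa"})
    kept = kept[["barcode", "chain", "v_gene", "j_gene", "cdr3_aa", "cdr3_nt", "productive", "umis"]]
    kept = kept.reset_index(drop=True)
    kept.attrs["read_report"] = {
        "rows_in": rows_in,
        "rows_kept": len(kept),
        "dropped": dropped,
    }
    logger.info(
        "read %d contig rows from %s: kept %d, dropped %s", rows_in, path, len(kept), dropped
    )
    return kept


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-cell metadata TSV (barcode, donor, cluster, population, response)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, METADATA_COLUMNS, path)
    rows_in = len(df)

    dup = df.duplicated(subset=["barcode", "donor"])
    if dup.any():
        example = df.loc[dup, ["barcode", "donor"]].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate (barcode, donor) pair, e.g. ({example['barcode']}, {example['donor']})"
        )

    df = df.copy()
    df["cluster"] = df["cluster"].map(coerce_cluster)
    bad_response = ~df["response"].isin(_VALID_RESPONSES)
    if bad_response.any():
        logger.warning(
            "%s: %d cells with unknown response value recorded as NA",
            path,
            int(bad_response.sum()),
        )
        df.loc[bad_response, "response"] = "NA"
    df = df[METADATA_COLUMNS].reset_index(drop=True)
    df.attrs["read_report"] = {"rows_in": rows_in, "rows_kept": len(df), "dropped": {}}
    return df


def read_vdjdb(path: str | Path) -> pd.DataFrame:
    """Read a VDJdb-style TSV export into specificity records.

    The ``Gene`` column is mapped to the chain; rows whose gene is neither
    TRA nor TRB are skipped with a warning.  Returns columns
    chain, cdr3_aa, v_gene, j_gene, epitope_species, epitope.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["Gene", "CDR3", "V", "J", "Epitope species"], path)
    rows_in = len(df)

    chain = df["Gene"].str.strip().str.upper()
    parseable = chain.isin(["TRA", "TRB"])
    n_skipped = int((~parseable).sum())
    if n_skipped:
        logger.warning("%s: skipped %d rows with unparseable Gene value", path, n_skipped)

    out = pd.DataFrame(
        {
            "chain": chain[parseable],
            "cdr3_aa": df.loc[parseable, "CDR3"].str.strip(),
            "v_gene": df.loc[parseable, "V"].str.strip(),
            "j_gene": df.loc[parseable, "J"].str.strip(),
            "epitope_species": df.loc[parseable, "Epitope species"].str.strip(),
            "epitope": df.loc[parseable, "Epitope"].str.strip()
            if "Epitope" in df.columns
            else "",
        }
    ).reset_index(drop=True)
    empty_cdr3 = out["cdr3_aa"] == ""
    if empty_cdr3.any():
        logger.warning("%s: skipped %d rows with empty CDR3", path, int(empty_cdr3.sum()))
        out = out[~empty_cdr3].reset_index(drop=True)
        n_skipped += int(empty_cdr3.sum())
    out.attrs["read_report"] = {
        "rows_in": rows_in,
        "rows_kept": len(out),
        "dropped": {"unparseable_or_empty": n_skipped},
    }
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as a deterministic TSV (fixed float format, LF)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    return path
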