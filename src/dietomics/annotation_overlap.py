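"""Join significant markers against local QTL and GWAS-trait tables.

A purely local replacement for a catalogue lookup: significant markers are
inner-joined to their QTL variants, then left-joined to GWAS trait rows by
exact variant-identifier match.  Markers with a QTL but no catalogued trait
are retained with empty trait fields.
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError

__all__ = ["overlap_report", "QTL_COLUMNS", "GWAS_COLUMNS", "REPORT_COLUMNS"]

QTL_COLUMNS = ("marker_id", "variant_id", "nearest_gene")
GWAS_COLUMNS = ("variant_id", "trait", "study_accession")
REPORT_COLUMNS = ("marker_id", "variant_id", "nearest_gene",
                  "trait", "study_accession")


def _require_columns(df: pd.DataFrame, cols, label: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table missing columns {missing}")


def overlap_report(significant_markers, qtl: pd.DataFrame,
                   gwas: pd.DataFrame) -> pd.DataFrame:
    """Build the marker -> variant -> trait overlap table.

    One output row per (marker, variant, trait); variants without any trait
    contribute a single row with empty trait fields.
    """
    _require_columns(qtl, QTL_COLUMNS, "QTL")
    _require_columns(gwas, GWAS_COLUMNS, "GWAS")
    if qtl.duplicated(subset=["marker_id", "variant_id"]).any():
        raise SchemaError("duplicate (marker_id, variant_id) pairs in QTL table")

    sig = set(significant_markers)
    hits = qtl[qtl["marker_id"].isin(sig)].loc[:, list(QTL_COLUMNS)]
    if hits.empty:
        return pd.DataFrame(columns=list(REPORT_COLUMNS))
    joined = hits.merge(gwas.loc[:, list(GWAS_COLUMNS)].drop_duplicates(),
                        on="variant_id", how="left")
    joined[["trait", "study_accession"]] = (
        joined[["trait", "study_accession"]].fillna("")
    )
    return (joined[list(REPORT_COLUMNS)]
            .sort_values(["marker_id", "variant_id", "trait"], kind="stable")
            .reset_index(drop=True))
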