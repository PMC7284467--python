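"""Marker-matrix preprocessing and table alignment.

Proteins are handled per assay batch: natural-log transform, least-squares
residualization on age and sex, then scaling of every marker to mean 0 and
sample SD 1 within the batch.  Metabolites are analyzed on their delivered
scale (an optional log transform exists but defaults off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    InputError,
    PipelineError,
    SchemaError,
)

__all__ = [
    "MarkerMatrix",
    "ExclusionReport",
    "preprocess_proteins",
    "preprocess_metabolites",
    "align_tables",
]

PLATFORMS = ("protein", "metabolite")


@dataclass
class MarkerMatrix:
    """Participant x marker value matrix with platform and batch metadata.

    ``values`` is a DataFrame indexed by participant id with one column per
    marker.  Proteins must carry a per-participant ``batch`` label.
    """

    values: pd.DataFrame
    platform: str
    batch: pd.Series | None = None

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise InputError(f"unknown platform {self.platform!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise InputError(f"duplicated marker ids: {sorted(set(dupes))}")
        if self.platform == "protein":
            if self.batch is None:
                raise InputError("protein matrices require batch labels")
            self.batch = self.batch.reindex(self.values.index)
            if self.batch.isna().any():
                raise InputError("batch labels missing for some participants")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participant_ids(self) -> pd.Index:
        return self.values.index

    def to_frame(self, batch_col: str = "batch") -> pd.DataFrame:
        """Flatten to one writable table (batch as a leading column)."""
        out = self.values.copy()
        if self.batch is not None:
            out.insert(0, batch_col, self.batch)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, platform: str,
                   batch_col: str = "batch") -> "MarkerMatrix":
        batch = None
        if batch_col in frame.columns:
            batch = frame[batch_col]
            frame = frame.drop(columns=[batch_col])
        return cls(values=frame.astype(float), platform=platform, batch=batch)


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of every column of Y on the design X (with intercept)."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def preprocess_proteins(raw: MarkerMatrix, covariates: pd.DataFrame,
                        age_col: str = "age", sex_col: str = "sex",
                        adjust_age_sex: bool = True) -> MarkerMatrix:
    """Per-batch log transform, age/sex adjustment, and standardization.

    Within each batch every marker is log_e-transformed, residualized on age
    and a binary sex indicator by least squares, and scaled to mean 0 / sample
    SD 1.  Raises :class:`InputError` naming the offending marker and
    participant on nonpositive values, and :class:`DegenerateDataError` for
    any marker constant within a batch.
    """
    if raw.platform != "protein":
        raise InputError("preprocess_proteins expects a protein matrix")
    vals = raw.values
    if (vals <= 0).any().any():
        bad = vals.le(0)
        marker = bad.any(axis=0).idxmax()
        participant = bad[marker].idxmax()
        raise InputError(
            f"nonpositive value for marker {marker!r}, participant {participant!r}"
        )
    cov = covariates.reindex(vals.index)
    if cov[[age_col, sex_col]].isna().any().any():
        raise InputError("age/sex missing for some participants")
    sex_ind = _binary_sex(cov[sex_col])

    out = np.empty(vals.shape)
    logged = np.log(vals.to_numpy(dtype=float))
    batch = raw.batch.to_numpy()
    for b in pd.unique(batch):
        mask = batch == b
        block = logged[mask]
        sd0 = block.std(axis=0, ddof=1)
        if (sd0 == 0).any():
            marker = vals.columns[int(np.argmax(sd0 == 0))]
            raise DegenerateDataError(
                f"marker {marker!r} constant within batch {b!r}"
            )
        if adjust_age_sex:
            X = np.column_stack([
                np.ones(mask.sum()),
                cov[age_col].to_numpy(dtype=float)[mask],
                sex_ind[mask],
            ])
            block = _residualize(block, X)
        sd = block.std(axis=0, ddof=1)
        if (sd == 0).any():
            marker = vals.columns[int(np.argmax(sd == 0))]
            raise DegenerateDataError(
                f"marker {marker!r} degenerate after adjustment in batch {b!r}"
            )
        out[mask] = (block - block.mean(axis=0)) / sd
    return MarkerMatrix(
        values=pd.DataFrame(out, index=vals.index, columns=vals.columns),
        platform="protein",
        batch=raw.batch,
    )


def preprocess_metabolites(raw: MarkerMatrix, log_transform: bool = False) -> MarkerMatrix:
    """Metabolites pass through on their delivered scale by default."""
    if raw.platform != "metabolite":
        raise InputError("preprocess_metabolites expects a metabolite matrix")
    vals = raw.values
    if log_transform:
        if (vals <= 0).any().any():
            raise InputError("log transform requires strictly positive values")
        vals = np.log(vals)
    return MarkerMatrix(values=vals.copy(), platform="metabolite")


def _binary_sex(sex: pd.Series) -> np.ndarray:
    """Encode sex as a 0/1 indicator (female = 1); accepts strings or numbers."""
    if sex.dtype == object or isinstance(sex.dtype, pd.CategoricalDtype):
        known = {"female": 1.0, "male": 0.0}
        bad = set(sex.unique()) - set(known)
        if bad:
            raise InputError(f"unknown sex categories {sorted(bad)}")
        return sex.map(known).to_numpy(dtype=float)
    return sex.to_numpy(dtype=float)


@dataclass
class ExclusionReport:
    """Counts from the two-step exclusion cascade applied before analysis."""

    eligible: int
    excluded_diet: int
    excluded_covariates: int
    excluded_diet_ids: list = field(default_factory=list, repr=False)
    excluded_covariate_ids: list = field(default_factory=list, repr=False)

    @property
    def analyzed(self) -> int:
        return self.eligible - self.excluded_diet - self.excluded_covariates

    def to_dict(self) -> dict:
        return {
            "eligible": self.eligible,
            "excluded_diet": self.excluded_diet,
            "excluded_covariates": self.excluded_covariates,
            "analyzed": self.analyzed,
        }


def align_tables(scores: pd.DataFrame, covariates: pd.DataFrame,
                 markers: MarkerMatrix,
                 covariate_cols: list[str] | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame, MarkerMatrix, ExclusionReport]:
    """Inner-join the analysis tables and report the exclusion cascade.

    Eligibility is defined by presence in the marker matrix.  Participants
    are first dropped for missing/invalid dietary scores, then for missing
    covariates — in that order, so the report's counts mirror the cascade.
    """
    eligible_ids = markers.participant_ids
    if len(eligible_ids) == 0:
        raise PipelineError("marker matrix has no participants")
    cols = covariate_cols or list(covariates.columns)
    missing_cols = [c for c in cols if c not in covariates.columns]
    if missing_cols:
        raise SchemaError(f"covariate table missing columns {missing_cols}")

    has_diet = scores.dropna().index
    diet_ok = eligible_ids.isin(has_diet)
    excluded_diet_ids = list(eligible_ids[~diet_ok])

    remaining = eligible_ids[diet_ok]
    cov_sub = covariates.reindex(remaining)[cols]
    cov_ok = ~cov_sub.isna().any(axis=1)
    excluded_cov_ids = list(remaining[~cov_ok.to_numpy()])

    analyzed_ids = remaining[cov_ok.to_numpy()]
    if len(analyzed_ids) == 0:
        raise PipelineError("no participants remain after exclusions")

    report = ExclusionReport(
        eligible=len(eligible_ids),
        excluded_diet=len(excluded_diet_ids),
        excluded_covariates=len(excluded_cov_ids),
        excluded_diet_ids=excluded_diet_ids,
        excluded_covariate_ids=excluded_cov_ids,
    )
    aligned_markers = MarkerMatrix(
        values=markers.values.loc[analyzed_ids],
        platform=markers.platform,
        batch=None if markers.batch is None else markers.batch.loc[analyzed_ids],
    )
    return (scores.loc[analyzed_ids], covariates.loc[analyzed_ids],
            aligned_markers, report)
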