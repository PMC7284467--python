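"""Marker-wide multivariable linear regression scan with multiplicity control.

For every (diet index, marker) pair an ordinary-least-squares model relates
the marker (dependent) to the standardized index plus the adjustment
covariates: age, sex, total caloric intake, current smoking, physical
activity, lipid-lowering medication, anti-hypertensive medication, and BMI.
Significance is controlled per (index, platform) family by Benjamini-
Hochberg FDR (q <= alpha) and flagged by a Bonferroni threshold alpha/m
where m is the platform's marker count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InputError, SingularDesignError
from .omics_preprocess import MarkerMatrix, _binary_sex

__all__ = [
    "DEFAULT_COVARIATES",
    "fit_marker_model",
    "bh_fdr",
    "run_scan",
    "overlap_sets",
    "OverlapSummary",
]

#: adjustment set of the multivariable model (sex is encoded 0/1 internally)
DEFAULT_COVARIATES = (
    "age", "sex", "energy_kcal", "current_smoker",
    "physical_activity", "lipid_med", "htn_med", "bmi",
)

RECORD_COLUMNS = (
    "index_name", "marker_id", "platform", "beta", "se", "t", "p", "q",
    "fdr_sig", "bonferroni_sig", "status",
)


def _design_matrix(index_std: np.ndarray, covariates: pd.DataFrame | None
                   ) -> np.ndarray:
    cols = [np.ones(index_std.shape[0]), index_std]
    if covariates is not None:
        for name in covariates.columns:
            if name == "sex":
                cols.append(_binary_sex(covariates["sex"]))
            else:
                cols.append(covariates[name].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise InputError("design matrix contains missing values")
    return X


def _ols_multi(Y: np.ndarray, X: np.ndarray):
    """Closed-form OLS of every column of Y on X; returns slope stats for
    the column-1 (index) coefficient: (beta, se, t, p)."""
    n, p = X.shape
    if n <= p:
        raise InputError(f"n={n} too small for {p} design columns")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y
    resid = Y - X @ coef
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_val = 2.0 * stats.t.sf(np.abs(t), df)
    # exact fits give p = 0; clamp into (0, 1] for downstream BH validity
    p_val = np.clip(p_val, np.finfo(float).tiny, 1.0)
    return beta, se, t, p_val


def fit_marker_model(y, index_std, covariates: pd.DataFrame | None = None
                     ) -> tuple[float, float, float, float]:
    """OLS of one marker on the standardized index plus covariates.

    Returns ``(beta, se, t, p)`` for the index coefficient, with the p-value
    from the two-sided t distribution on n - p degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(index_std, dtype=float)
    if y.shape != z.shape:
        raise InputError("y and index vectors differ in length")
    if np.isnan(y).any():
        raise InputError("marker vector contains missing values")
    if np.ptp(y) == 0:
        raise DegenerateDataError("marker is constant")
    X = _design_matrix(z, covariates)
    beta, se, t, p = _ols_multi(y[:, None], X)
    return float(beta[0]), float(se[0]), float(t[0]), float(p[0])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min over j >= i of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("p_values must be a nonempty 1-D vector")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_scan(scores_std: pd.DataFrame,
             markers: dict[str, MarkerMatrix] | MarkerMatrix,
             covariates: pd.DataFrame | None = None,
             covariate_cols=DEFAULT_COVARIATES,
             alpha: float = 0.05,
             fdr_family: str = "per_index",
             bonferroni_m: dict[str, int] | None = None) -> pd.DataFrame:
    """Fit every (index, marker) model and apply multiplicity control.

    Parameters
    ----------
    scores_std
        Participant-indexed frame of standardized index values, one column
        per index.
    markers
        Marker matrices keyed by platform (a bare matrix is accepted).
    covariates
        Covariate table; ``covariate_cols`` selects the adjustment set
        (columns absent from the table are ignored with a warning).
    fdr_family
        ``per_index`` (default) applies BH within each (index, platform)
        family; ``pooled`` pools all indices of a platform into one family.
    bonferroni_m
        Optional per-platform test counts overriding the scanned marker
        count in the Bonferroni threshold alpha/m.

    Per-marker fit failures are recorded with a ``status`` flag instead of
    aborting the scan.
    """
    if isinstance(markers, MarkerMatrix):
        markers = {markers.platform: markers}
    if fdr_family not in ("per_index", "pooled"):
        raise InputError(f"unknown fdr_family {fdr_family!r}")
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must lie in (0, 1)")

    cov_used = None
    if covariates is not None:
        present = [c for c in covariate_cols if c in covariates.columns]
        absent = [c for c in covariate_cols if c not in covariates.columns]
        if absent:
            warnings.warn(f"covariates absent from table, skipped: {absent}",
                          stacklevel=2)
        cov_used = covariates[present]

    rows = []
    for platform, mm in markers.items():
        ids = scores_std.index.intersection(mm.participant_ids)
        if len(ids) == 0:
            raise InputError(f"no shared participants with {platform} matrix")
        Y = mm.values.loc[ids].to_numpy(dtype=float)
        cov_block = None if cov_used is None else cov_used.loc[ids]
        m_platform = (bonferroni_m or {}).get(platform, mm.values.shape[1])
        for index_name in scores_std.columns:
            z = scores_std.loc[ids, index_name].to_numpy(dtype=float)
            X = _design_matrix(z, cov_block)
            ok = np.ptp(Y, axis=0) > 0
            beta = np.full(Y.shape[1], np.nan)
            se = np.full(Y.shape[1], np.nan)
            t = np.full(Y.shape[1], np.nan)
            p = np.full(Y.shape[1], np.nan)
            if ok.any():
                b_, s_, t_, p_ = _ols_multi(Y[:, ok], X)
                beta[ok], se[ok], t[ok], p[ok] = b_, s_, t_, p_
            for j, mid in enumerate(mm.marker_ids):
                rows.append({
                    "index_name": index_name, "marker_id": mid,
                    "platform": platform,
                    "beta": beta[j], "se": se[j], "t": t[j], "p": p[j],
                    "q": np.nan, "fdr_sig": False, "bonferroni_sig": False,
                    "status": "ok" if ok[j] else "degenerate",
                    "m_platform": m_platform,
                })
    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS) + ["m_platform"])

    family_keys = (["platform"] if fdr_family == "pooled"
                   else ["index_name", "platform"])
    fitted = records["status"] == "ok"
    for _, idx in records[fitted].groupby(family_keys).groups.items():
        records.loc[idx, "q"] = bh_fdr(records.loc[idx, "p"].to_numpy())
    records.loc[fitted, "fdr_sig"] = records.loc[fitted, "q"] <= alpha
    records.loc[fitted, "bonferroni_sig"] = (
        records.loc[fitted, "p"] <= alpha / records.loc[fitted, "m_platform"]
    )
    return records.drop(columns=["m_platform"])


@dataclass
class OverlapSummary:
    """Set algebra over FDR-significant markers across indices."""

    sets: dict[str, set]

    @property
    def index_names(self) -> list[str]:
        return sorted(self.sets)

    def intersection(self, *names: str) -> set:
        out = None
        for nm in names:
            s = self.sets[nm]
            out = s if out is None else out & s
        return out if out is not None else set()

    def union(self) -> set:
        out: set = set()
        for s in self.sets.values():
            out |= s
        return out

    def counts(self) -> dict[str, int]:
        names = self.index_names
        out = {nm: len(self.sets[nm]) for nm in names}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                out[f"{a}&{b}"] = len(self.intersection(a, b))
        if len(names) >= 3:
            out["&".join(names)] = len(self.intersection(*names))
        out["union"] = len(self.union())
        return out

    def check_inclusion_exclusion(self) -> bool:
        """Verify |A u B u C| against the inclusion-exclusion identity."""
        names = self.index_names
        if len(names) != 3:
            return True
        a, b, c = (self.sets[nm] for nm in names)
        lhs = len(a | b | c)
        rhs = (len(a) + len(b) + len(c)
               - len(a & b) - len(a & c) - len(b & c) + len(a & b & c))
        return lhs == rhs


def overlap_sets(records: pd.DataFrame, platform: str | None = None
                 ) -> OverlapSummary:
    """Collect FDR-significant marker sets per index from scan records."""
    df = records if platform is None else records[records["platform"] == platform]
    if df.empty:
        raise InputError("no records to summarize")
    sets = {
        str(nm): set(grp.loc[grp["fdr_sig"].fillna(False), "marker_id"])
        for nm, grp in df.groupby("index_name")
    }
    return OverlapSummary(sets=sets)
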