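"""Covariate-adjusted partial Spearman correlation among significant markers.

The partial Spearman coefficient is operationalized as: rank-transform both
variables (average ranks for ties), residualize each rank vector on the
covariates by least squares (with intercept), and take the Pearson
correlation of the residuals.  With no covariates this reduces exactly to
the ordinary Spearman coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateDataError, InputError
from .omics_preprocess import MarkerMatrix, _binary_sex, _residualize

__all__ = [
    "CorrelationMatrix",
    "partial_spearman",
    "correlation_matrix",
    "cluster_order",
]


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of partial Spearman coefficients."""

    rho: pd.DataFrame
    covariates_used: tuple[str, ...] = ()

    @property
    def marker_ids(self) -> list[str]:
        return list(self.rho.columns)

    def to_tsv(self, path) -> None:
        self.rho.to_csv(path, sep="\t")


def _covariate_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        for name in covariates.columns:
            if name == "sex":
                cols.append(_binary_sex(covariates["sex"]))
            else:
                cols.append(covariates[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def partial_spearman(x, y, covariates: pd.DataFrame | None = None) -> float:
    """Age/sex-style covariate-adjusted Spearman correlation of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D vectors")
    n_cov = 0 if covariates is None else covariates.shape[1]
    if x.size < n_cov + 3:
        raise InputError(f"need at least {n_cov + 3} observations")
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateDataError("constant vector after ranking")
    X = _covariate_design(covariates, x.size)
    res = _residualize(np.column_stack([rx, ry]), X)
    sd = res.std(axis=0)
    if (sd == 0).any():
        raise DegenerateDataError("residuals are constant")
    return float(np.corrcoef(res[:, 0], res[:, 1])[0, 1])


def correlation_matrix(markers: MarkerMatrix | pd.DataFrame,
                       covariates: pd.DataFrame | None = None
                       ) -> CorrelationMatrix:
    """All-pairs partial Spearman among a marker set (>= 2 markers).

    Per-pair failures (degenerate rank vectors) yield NaN cells with a
    warning rather than aborting.
    """
    vals = markers.values if isinstance(markers, MarkerMatrix) else markers
    if vals.shape[1] < 2:
        raise InputError("need at least two markers")
    mat = vals.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)
    X = _covariate_design(covariates, mat.shape[0])
    res = _residualize(ranks, X)
    sd = res.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} marker(s) degenerate; cells set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(res, rowvar=False)
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    frame = pd.DataFrame(rho, index=vals.columns, columns=vals.columns)
    used = () if covariates is None else tuple(covariates.columns)
    return CorrelationMatrix(rho=frame, covariates_used=used)


def cluster_order(matrix: CorrelationMatrix) -> list[str]:
    """Deterministic display order from average-linkage clustering.

    Distance is ``1 - rho``; missing cells are imputed as rho = 0 (distance
    1) with a warning.  Single-marker input returns the identity ordering.
    """
    rho = matrix.rho.to_numpy(dtype=float).copy()
    ids = matrix.marker_ids
    if len(ids) == 1:
        return list(ids)
    if np.isnan(rho).any():
        warnings.warn("missing correlations imputed as 0 for clustering",
                      stacklevel=2)
        rho = np.where(np.isnan(rho), 0.0, rho)
        np.fill_diagonal(rho, 1.0)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)  # enforce exact symmetry
    Z = linkage(squareform(dist, checks=False), method="average")
    return [ids[i] for i in leaves_list(Z)]
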