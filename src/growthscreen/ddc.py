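"""DetectDeviatingCells: cellwise outlier flagging via robust cell prediction.

Unlike rowwise detectors, DDC points at the individual offending cell.
The algorithm, entirely deterministic, proceeds in four steps:

1. **Standardize** each column robustly: ``z = (x - median) / (1.4826 * MAD)``.
   Cells with ``|z| > c`` (``c = sqrt(chi2.ppf(tolProb, 1))``, about
   2.576 at the default tolProb = 0.99) are set aside — treated as
   missing — for the correlation and prediction steps.
2. **Correlate**: product-moment correlations between standardized
   columns over the rows where neither cell was set aside (robustness
   comes from the univariate trimming).  Columns k with
   ``|r_jk| >= corrlim`` form the connected set H_j of column j; a
   column with empty H_j is *standalone*.
3. **Predict** each cell from its connected columns: per pair a
   median-of-ratios slope (ratios of pairwise-median-centered values,
   so exact dependences give exact slopes), combined as a
   ``|r_jk|``-weighted mean, then a per-column deshrinkage factor (the
   median ratio of observed to predicted) undoes the shrinkage of the
   weighted average.  Standalone columns predict 0 (the column median
   in data units).
4. **Flag**: residuals ``z - predicted`` are rescaled per column by
   their own 1.4826*MAD; cells with |standardized residual| > c are
   flagged.  Rows are flagged when the average chi-square(1) CDF of
   their squared residuals is anomalously large (robustly standardized
   value above c).

Predicted values are also returned in data units; they double as
single-imputation candidates, though that use is not evaluated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .univariate import MAD_CONSISTENCY

__all__ = [
    "DDCParams",
    "DDCResult",
    "ddc_standardize",
    "ddc_correlations",
    "ddc_predict",
    "ddc_flag_cells",
    "ddc_flag_rows",
    "ddc_fit",
]

_RATIO_EPS = 1e-6
_SCALE_EPS = 1e-12


@dataclass(frozen=True)
class DDCParams:
    """Tuning parameters; ``c`` is derived from ``tol_prob`` at run time."""

    corrlim: float = 0.5
    tol_prob: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.corrlim < 1:
            raise ValueError("corrlim must lie in (0, 1)")
        if not 0 < self.tol_prob < 1:
            raise ValueError("tol_prob must lie in (0, 1)")

    @property
    def c(self) -> float:
        return float(np.sqrt(stats.chi2.ppf(self.tol_prob, 1)))


@dataclass
class DDCResult:
    z: np.ndarray
    corr: np.ndarray
    connected: list[list[int]]
    predicted_z: np.ndarray
    predicted: np.ndarray
    residual: np.ndarray
    cell_flags: np.ndarray
    row_stat: np.ndarray
    row_flags: np.ndarray
    params: DDCParams = field(default_factory=DDCParams)


def _column_scales(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    return med, MAD_CONSISTENCY * mad


def ddc_standardize(X, params: DDCParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Robustly standardize columns; returns (z, aside) where aside marks |z| > c."""
    params = params or DDCParams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x p matrix with p >= 2")
    med, scale = _column_scales(X)
    if np.any(scale == 0):
        j = int(np.flatnonzero(scale == 0)[0])
        raise ValueError(f"column {j} has zero MAD: cannot standardize")
    z = (X - med) / scale
    aside = np.abs(z) > params.c
    return z, aside


def ddc_correlations(
    z: np.ndarray, aside: np.ndarray, params: DDCParams | None = None
) -> tuple[np.ndarray, list[list[int]]]:
    """Trimmed pairwise correlations and the connected sets H_j.

    r_jk is the product-moment correlation over rows where neither cell
    was set aside; pairs with fewer than 3 complete rows get r = 0.
    """
    params = params or DDCParams()
    p = z.shape[1]
    corr = np.eye(p)
    for j in range(p):
        for k in range(j + 1, p):
            ok = ~aside[:, j] & ~aside[:, k]
            if np.count_nonzero(ok) < 3:
                r = 0.0
            else:
                zj, zk = z[ok, j], z[ok, k]
                sj, sk = zj.std(), zk.std()
                if sj == 0 or sk == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(zj, zk)[0, 1])
            corr[j, k] = corr[k, j] = r
    connected = [
        [k for k in range(p) if k != j and abs(corr[j, k]) >= params.corrlim]
        for j in range(p)
    ]
    return corr, connected


def _pair_fit(z: np.ndarray, aside: np.ndarray, j: int, k: int) -> tuple[float, float, float]:
    """Median-of-ratios fit of column j on column k over usable rows.

    Both columns are centered by their medians over the usable rows
    before taking ratios, so an exact (affine) dependence yields the
    exact slope even when a corrupted cell has nudged a column median.
    Returns (slope, center_j, center_k).
    """
    ok = ~aside[:, j] & ~aside[:, k]
    if np.count_nonzero(ok) < 2:
        return 0.0, 0.0, 0.0
    mj = float(np.median(z[ok, j]))
    mk = float(np.median(z[ok, k]))
    num = z[ok, j] - mj
    den = z[ok, k] - mk
    usable = np.abs(den) > _RATIO_EPS
    if not usable.any():
        return 0.0, mj, mk
    return float(np.median(num[usable] / den[usable])), mj, mk


def ddc_predict(
    z: np.ndarray,
    corr: np.ndarray,
    params: DDCParams | None = None,
    aside: np.ndarray | None = None,
    connected: list[list[int]] | None = None,
) -> np.ndarray:
    """Predicted standardized value for every cell.

    Cell (i, j) is the |r_jk|-weighted mean of the per-pair fits
    m_j + b_jk * (z_ik - m_k) over the connected columns k whose cell
    in row i is available, deshrunk per column by the median
    observed/predicted ratio.  Standalone columns (and rows with no
    available connected cell) predict 0.
    """
    params = params or DDCParams()
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    if aside is None:
        aside = np.abs(z) > params.c
    if connected is None:
        connected = [
            [k for k in range(p) if k != j and abs(corr[j, k]) >= params.corrlim]
            for j in range(p)
        ]
    pred = np.zeros_like(z)
    for j in range(p):
        H = connected[j]
        if not H:
            continue  # standalone: predicted z stays 0 (the column median)
        num = np.zeros(n)
        den = np.zeros(n)
        num_aside = np.zeros(n)
        den_aside = np.zeros(n)
        for k in H:
            b, mj, mk = _pair_fit(z, aside, j, k)
            w = abs(corr[j, k])
            fit_k = mj + b * (z[:, k] - mk)
            avail = ~aside[:, k]
            num[avail] += w * fit_k[avail]
            den[avail] += w
            num_aside[~avail] += w * fit_k[~avail]
            den_aside[~avail] += w
        # rows whose every connected cell was set aside still borrow the
        # aside cells: a row that is extreme but internally consistent
        # should not have its cells flagged for extremeness alone
        last_resort = (den == 0) & (den_aside > 0)
        num[last_resort] = num_aside[last_resort]
        den[last_resort] = den_aside[last_resort]
        raw = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        # deshrinkage: robust slope of observed on predicted
        ok = ~aside[:, j] & (np.abs(raw) > _RATIO_EPS)
        if ok.any():
            factor = float(np.median(z[ok, j] / raw[ok]))
            if np.isfinite(factor):
                raw = raw * factor
        pred[:, j] = raw
    return pred


def ddc_flag_cells(
    z: np.ndarray, predicted: np.ndarray, params: DDCParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized residuals and the cellwise flags |residual| > c.

    A column whose residual MAD collapses to zero (exact dependence)
    has its scale floored at a small epsilon so any nonzero raw
    residual still flags.
    """
    params = params or DDCParams()
    raw = np.asarray(z, dtype=float) - np.asarray(predicted, dtype=float)
    med = np.median(raw, axis=0)
    scale = MAD_CONSISTENCY * np.median(np.abs(raw - med), axis=0)
    scale = np.maximum(scale, _SCALE_EPS)
    residual = raw / scale
    return residual, np.abs(residual) > params.c


def _bates_quantile(p: int, prob: float) -> float:
    """Quantile of the mean of p iid Uniform(0,1) via the Irwin-Hall CDF."""
    from math import comb, factorial

    from scipy.optimize import brentq

    def ih_cdf(x: float) -> float:  # CDF of the sum of p uniforms
        return sum(
            (-1) ** k * comb(p, k) * max(x - k, 0.0) ** p for k in range(p + 1)
        ) / factorial(p)

    return brentq(lambda x: ih_cdf(x) - prob, 0.0, float(p)) / p


def ddc_flag_rows(
    residual: np.ndarray, params: DDCParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rowwise statistic T_i = mean_j F_chi2(1)(residual^2) and its flags.

    Under the null each F-transformed squared residual is Uniform(0,1),
    so T is compared against the tolProb quantile of the mean of p
    uniforms (the Bates distribution).  T is bounded by 1, which rules
    out flagging it through a MAD-standardized cutoff; the explicit
    null quantile keeps the intended ~(1 - tolProb) null flag rate.
    """
    params = params or DDCParams()
    residual = np.asarray(residual, dtype=float)
    T = stats.chi2.cdf(residual ** 2, df=1).mean(axis=1)
    threshold = _bates_quantile(residual.shape[1], params.tol_prob)
    return T, T > threshold


def ddc_fit(X, params: DDCParams | None = None) -> DDCResult:
    """Run the full DetectDeviatingCells pipeline on an n x p matrix."""
    params = params or DDCParams()
    X = np.asarray(X, dtype=float)
    med, scale = _column_scales(X)
    z, aside = ddc_standardize(X, params)
    corr, connected = ddc_correlations(z, aside, params)
    pred_z = ddc_predict(z, corr, params, aside=aside, connected=connected)
    residual, cell_flags = ddc_flag_cells(z, pred_z, params)
    row_stat, row_flags = ddc_flag_rows(residual, params)
    predicted = med + scale * pred_z
    return DDCResult(
        z=z,
        corr=corr,
        connected=connected,
        predicted_z=pred_z,
        predicted=predicted,
        residual=residual,
        cell_flags=cell_flags,
        row_stat=row_stat,
        row_flags=row_flags,
        params=params,
    )
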