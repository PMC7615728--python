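"""Mahalanobis-distance outlier detection with classic and robust estimates.

Squared Mahalanobis distances of (age, height, log-weight) rows are
compared against the 0.99 chi-square quantile with 3 degrees of
freedom.  The location/scatter pair can be estimated three ways:

* ``classic`` — sample mean and covariance, vulnerable to *masking*
  (outliers inflating the very estimates meant to expose them);
* ``mcd`` — minimum covariance determinant: the h-subset with the
  smallest covariance determinant, found by a FastMCD-style search
  (random (p+1)-seeds followed by concentration C-steps);
* ``mve`` — minimum volume ellipsoid: the smallest ellipsoid covering
  at least h points, searched over random (p+1)-subset shapes.

Robust scatters are rescaled for consistency under normality so the
chi-square cutoff keeps its nominal size on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LocationScatter",
    "DistanceResult",
    "classic_estimates",
    "mcd_estimates",
    "mve_estimates",
    "mahalanobis_sq",
    "distance_flags",
    "default_h",
]

_DET_TOL = 1e-12


@dataclass(frozen=True)
class LocationScatter:
    """A location vector and symmetric positive-definite scatter matrix."""

    center: np.ndarray
    scatter: np.ndarray
    method: str
    h: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "scatter", np.asarray(self.scatter, dtype=float))
        if self.scatter.shape != (self.center.size, self.center.size):
            raise ValueError("scatter shape does not match center")


@dataclass(frozen=True)
class DistanceResult:
    d2: np.ndarray
    threshold: float
    flags: np.ndarray


def default_h(n: int, p: int) -> int:
    """Default subset size floor((n + p + 1) / 2), the high-breakdown choice."""
    return (n + p + 1) // 2


def _check_h(n: int, p: int, h: int) -> None:
    if not (n // 2 + 1 <= h <= n):
        raise ValueError(f"h must lie in [{n // 2 + 1}, {n}], got {h}")


def classic_estimates(X) -> LocationScatter:
    """Sample mean and covariance (denominator n-1)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns")
    center = X.mean(axis=0)
    scatter = np.cov(X, rowvar=False, ddof=1)
    if np.linalg.det(scatter) <= _DET_TOL * np.trace(scatter) ** p:
        raise np.linalg.LinAlgError("sample covariance is singular")
    return LocationScatter(center=center, scatter=scatter, method="classic")


def mahalanobis_sq(X, est: LocationScatter) -> np.ndarray:
    """Squared Mahalanobis distance of each row under a location/scatter pair."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    diff = X - est.center
    try:
        sol = np.linalg.solve(est.scatter, diff.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("scatter matrix is singular") from exc
    return np.einsum("ij,ji->i", diff, sol)


def distance_flags(d2, df: int = 3, tol_prob: float = 0.99) -> DistanceResult:
    """Flag rows whose squared distance strictly exceeds the chi-square quantile."""
    d2 = np.asarray(d2, dtype=float)
    if np.any(d2 < 0):
        raise ValueError("squared distances must be non-negative")
    threshold = float(stats.chi2.ppf(tol_prob, df))
    return DistanceResult(d2=d2, threshold=threshold, flags=d2 > threshold)


# ---------------------------------------------------------------------------
# FastMCD
# ---------------------------------------------------------------------------

def _subset_stats(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = X[idx]
    return sub.mean(axis=0), np.cov(sub, rowvar=False, ddof=1)


def _c_step(X: np.ndarray, center: np.ndarray, scatter: np.ndarray, h: int) -> np.ndarray:
    """One concentration step: keep the h rows closest under the current estimates."""
    d2 = mahalanobis_sq(X, LocationScatter(center, scatter, "tmp"))
    return np.argpartition(d2, h - 1)[:h]

def _mcd_consistency(n: int, p: int, h: int) -> float:
    """Scale factor making the h-subset covariance consistent under normality."""
    alpha = h / n
    q = stats.chi2.ppf(alpha, p)
    return alpha / stats.chi2.cdf(q, p + 2)


def _initial_subset(X: np.ndarray, rng: np.random.Generator, p: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Mean/cov of a random (p+1)-subset, enlarged until nonsingular (or give up)."""
    n = len(X)
    size = p + 1
    idx = rng.choice(n, size=size, replace=False)
    for _ in range(p + 15):
        center, scatter = _subset_stats(X, idx)
        if np.linalg.det(scatter) > _DET_TOL:
            return center, scatter
        if len(idx) >= n:
            return None
        extra = rng.choice(np.setdiff1d(np.arange(n), idx), size=1)
        idx = np.concatenate([idx, extra])
    return None

def _concentrate(X, center, scatter, h, max_iter=100, tol=1e-9):
    """C-steps until the determinant stops improving; returns (det, center, scatter)."""
    det_prev = np.inf
    for _ in range(max_iter):
        idx = _c_step(X, center, scatter, h)
        center, scatter = _subset_stats(X, idx)
        det = np.linalg.det(scatter)
        if det <= _DET_TOL:
            return det, center, scatter  # exact-fit situation
        if det_prev - det < tol:
            break
        det_prev = det
    return det, center, scatter


def mcd_estimates(
    X,
    h: int | None = None,
    n_trials: int = 500,
    seed: int | np.random.SeedSequence | None = None,
) -> LocationScatter:
    """Minimum covariance determinant location/scatter by FastMCD search.

    ``n_trials`` random (p+1)-seeds are each concentrated to a C-step
    fixed point; the h-subset with the smallest covariance determinant
    wins.  The winning covariance is multiplied by the normal-model
    consistency factor.  Raises on an exact-fit (singular) majority.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    h = default_h(n, p) if h is None else h
    _check_h(n, p, h)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    best = (np.inf, None, None)
    for _ in range(n_trials):
        init = _initial_subset(X, rng, p)
        if init is None:
            continue
        det, center, scatter = _concentrate(X, init[0], init[1], h)
        if det < best[0]:
            best = (det, center, scatter)
    if best[1] is None or best[0] <= _DET_TOL:
        raise np.linalg.LinAlgError(
            "exact-fit situation: best h-subset covariance is singular"
        )
    scatter = best[2] * _mcd_consistency(n, p, h)
    return LocationScatter(center=best[1], scatter=scatter, method="mcd", h=h)


# ---------------------------------------------------------------------------
# MVE
# ---------------------------------------------------------------------------

def mve_estimates(
    X,
    h: int | None = None,
    n_trials: int = 500,
    seed: int | np.random.SeedSequence | None = None,
) -> LocationScatter:
    """Minimum volume ellipsoid location/scatter by (p+1)-subset resampling.

    Each trial takes the shape matrix of a random (p+1)-subset and
    inflates it until the ellipsoid covers h points; the trial with the
    smallest covering-ellipsoid volume wins.  The final scatter is the
    winning shape scaled so the h-th distance matches the chi-square
    median, the usual consistency scaling for h near n/2.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    h = default_h(n, p) if h is None else h
    _check_h(n, p, h)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    best = (np.inf, None, None, None)  # volume^2 proxy, center, shape, m2h
    for _ in range(n_trials):
        init = _initial_subset(X, rng, p)
        if init is None:
            continue
        center, shape = init
        det = np.linalg.det(shape)
        if det <= _DET_TOL:
            continue
        m2 = mahalanobis_sq(X, LocationScatter(center, shape, "tmp"))
        m2h = np.partition(m2, h - 1)[h - 1]
        vol2 = det * m2h ** p  # squared volume up to the unit-ball constant
        if vol2 < best[0]:
            best = (vol2, center, shape, m2h)
    if best[1] is None:
        raise np.linalg.LinAlgError("all candidate subsets were singular")
    scatter = best[2] * best[3] / stats.chi2.ppf(0.5, p)
    return LocationScatter(center=best[1], scatter=scatter, method="mve", h=h)
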