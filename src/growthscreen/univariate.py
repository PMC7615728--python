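"""Univariate height-cell detectors: robust SDS and Tukey boxplot fences.

The robust standard-deviation score (SDS) of a value is its distance
from the column median in units of 1.4826 * MAD — the MAD rescaled to
estimate the standard deviation under normality.  Cells with |SDS|
beyond a limit (default 2) are flagged.  The boxplot rule flags values
strictly outside (Q1 - 1.5*IQR, Q3 + 1.5*IQR); quartiles use linear
interpolation of the empirical CDF (the "type 7" convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RobustScale",
    "BoxplotFences",
    "robust_scale",
    "robust_sds",
    "sds_flags",
    "boxplot_fences",
    "boxplot_flags",
]

MAD_CONSISTENCY = 1.4826


@dataclass(frozen=True)
class RobustScale:
    """Median and 1.4826*MAD of a variable."""

    center: float
    scale: float


@dataclass(frozen=True)
class BoxplotFences:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float


def robust_scale(x) -> RobustScale:
    x = np.asarray(x, dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return RobustScale(center=med, scale=MAD_CONSISTENCY * mad)


def robust_sds(x) -> np.ndarray:
    """Robust SDS: (x - median) / (1.4826 * MAD).

    Raises ``ValueError`` when the MAD is zero (constant-majority
    data), in which case no scores are defined.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rs = robust_scale(x)
    if rs.scale == 0:
        raise ValueError("MAD is zero: robust SDS undefined")
    return (x - rs.center) / rs.scale


def sds_flags(scores, limit: float = 2.0) -> np.ndarray:
    """Flag scores strictly outside the (-limit, limit) interval."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return np.abs(scores) > limit


def boxplot_fences(x) -> BoxplotFences:
    """Quartiles and the 1.5*IQR fences of a sample (type-7 quartiles)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return BoxplotFences(q1=float(q1), q3=float(q3), iqr=float(iqr),
                         lower=float(q1 - 1.5 * iqr), upper=float(q3 + 1.5 * iqr))


def boxplot_flags(x, fences: BoxplotFences | None = None) -> np.ndarray:
    """Flag values strictly outside the boxplot fences (a value exactly on a fence is kept)."""
    x = np.asarray(x, dtype=float)
    f = fences if fences is not None else boxplot_fences(x)
    return (x < f.lower) | (x > f.upper)
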