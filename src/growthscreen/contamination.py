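"""Injection of error patterns into height cells of a simulated cohort.

Four patterns of increasing detection difficulty are supported, acting
on the integer-centimetre height column only:

* ``skip_last_digit`` — drop the final decimal digit (176 -> 17), a
  gross transcription error;
* ``swap_last_digits`` — exchange the last two digits (163 -> 136), a
  transcription error that often stays plausible;
* ``add_shift`` — add a fixed offset (default 40 cm), mimicking unit or
  calibration mistakes;
* ``sample_first_percentile`` — replace the value with a draw from a
  normal distribution truncated above at the age/sex-specific first
  percentile, mimicking inclusion of individuals from a different
  growth population.

Contamination marks exactly ``round(prevalence * n)`` cells, chosen
uniformly without replacement, and returns the ground-truth mask.
Cells not marked are bit-identical before and after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .lms import lms_quantile

__all__ = [
    "ErrorPattern",
    "PATTERN_NAMES",
    "select_error_cells",
    "skip_last_digit",
    "swap_last_digits",
    "add_shift",
    "sample_first_percentile",
    "contaminate",
]

PATTERN_NAMES = (
    "skip_last_digit",
    "swap_last_digits",
    "add_shift",
    "sample_first_percentile",
)


@dataclass(frozen=True)
class ErrorPattern:
    """A named error pattern; ``shift_cm`` applies to ``add_shift`` only."""

    name: str
    shift_cm: float = 40.0

    def __post_init__(self) -> None:
        if self.name not in PATTERN_NAMES:
            raise ValueError(f"unknown pattern {self.name!r}; choose from {PATTERN_NAMES}")
        if self.name == "add_shift" and not self.shift_cm > 0:
            raise ValueError("shift_cm must be positive for add_shift")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_error_cells(
    n: int, prevalence: float, seed: int | np.random.SeedSequence | None = None
) -> np.ndarray:
    """Boolean mask marking exactly ``round(prevalence * n)`` cells.

    Cells are sampled uniformly without replacement; rounding is
    half-up.  Reproducible under a fixed seed.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    k = _round_half_up(prevalence * n)
    if k < 1:
        raise ValueError("prevalence * n rounds to zero cells")
    rng = np.random.default_rng(seed)
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def _as_positive_int(h, minimum: int):
    h = np.asarray(h)
    if not np.issubdtype(h.dtype, np.integer):
        hi = np.asarray(h, dtype=float)
        if np.any(hi != np.rint(hi)):
            raise ValueError("height must be integer centimetres")
        h = np.rint(hi).astype(int)
    if np.any(h < minimum):
        raise ValueError(f"height below {minimum} cm is degenerate for this pattern")
    return h


def skip_last_digit(h):
    """Delete the final decimal digit: floor(h / 10).  Requires h >= 10."""
    h = _as_positive_int(h, minimum=10)
    out = h // 10
    return out if out.ndim else int(out)


def swap_last_digits(h):
    """Exchange the last two decimal digits; other digits unchanged.  Requires h >= 10."""
    h = _as_positive_int(h, minimum=10)
    rest, last2 = h // 100, h % 100
    out = rest * 100 + (last2 % 10) * 10 + last2 // 10
    return out if out.ndim else int(out)


def add_shift(h, shift_cm: float = 40.0):
    """Add a positive constant shift (cm) to the height value(s)."""
    if not shift_cm > 0:
        raise ValueError("shift_cm must be positive")
    out = np.asarray(h) + shift_cm
    return out if out.ndim else out.item()


def truncated_below_p1_draws(
    L, M, S, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Continuous draws from Normal(M, M*S) truncated above at the LMS first percentile.

    Inverse-CDF sampling: ``h = mu + sigma * Phi^-1(U * Phi((P1-mu)/sigma))``
    with ``P1 = lms_quantile(L, M, S, 0.01)`` and U ~ Uniform(0,1).
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    p1 = np.asarray(lms_quantile(L, M, S, 0.01), dtype=float)
    mu, sigma = M, M * S
    if size is None:
        size = np.broadcast(L, M, S).shape or (1,)
    u = rng.uniform(size=size)
    draws = mu + sigma * ndtri(u * ndtr((p1 - mu) / sigma))
    return draws


def sample_first_percentile(entry, seed: int | np.random.Generator | None = None):
    """One rounded draw below the age/sex first percentile for an LMS entry.

    ``entry`` is anything with attributes/fields L, M, S (an
    :class:`~growthscreen.lms.LMSEntry` or a table row).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = getattr(entry, "L", None)
    if L is None:
        L, M, S = entry["L"], entry["M"], entry["S"]
    else:
        M, S = entry.M, entry.S
    draw = truncated_below_p1_draws(L, M, S, rng, size=1)[0]
    return int(np.rint(draw))


def contaminate(
    table: pd.DataFrame,
    pattern: ErrorPattern,
    prevalence: float,
    seed: int | np.random.SeedSequence | None = None,
    stature_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Apply an error pattern to randomly selected height cells.

    Returns a copy of the table with contaminated heights and the
    ground-truth boolean mask.  Only the marked height cells change;
    age, sex and weight columns are untouched.  ``stature_table`` is
    required for the ``sample_first_percentile`` pattern (per-record
    LMS parameters).

    Note: a ``swap_last_digits`` cell whose two final digits are equal
    keeps its value but is still recorded as an error in the mask.
    """
    if len(table) == 0:
        raise ValueError("table is empty")
    n = len(table)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    mask_seed, draw_seed = ss.spawn(2)
    mask = select_error_cells(n, prevalence, mask_seed)

    out = table.copy(deep=True)
    h = out["height_cm"].to_numpy()
    sel = h[mask]
    if pattern.name == "skip_last_digit":
        new = skip_last_digit(sel)
    elif pattern.name == "swap_last_digits":
        new = swap_last_digits(sel)
    elif pattern.name == "add_shift":
        new = np.asarray(add_shift(sel, pattern.shift_cm))
        if np.issubdtype(h.dtype, np.integer) and np.all(new == np.rint(new)):
            new = np.rint(new).astype(h.dtype)
    else:  # sample_first_percentile
        if stature_table is None:
            raise ValueError("sample_first_percentile needs the stature LMS table")
        st = stature_table.set_index(["sex", "age_months"])
        rows = out.loc[mask, ["sex", "age_months"]]
        params = st.loc[pd.MultiIndex.from_frame(rows), ["L", "M", "S"]].to_numpy()
        rng = np.random.default_rng(draw_seed)
        draws = truncated_below_p1_draws(
            params[:, 0], params[:, 1], params[:, 2], rng, size=len(rows)
        )
        new = np.rint(draws).astype(h.dtype if np.issubdtype(h.dtype, np.integer) else float)
    h = h.copy()
    h[mask] = new
    out["height_cm"] = h
    return out, mask
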