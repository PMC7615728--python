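"""Growth-cohort simulation from LMS (Box-Cox) reference tables.

The LMS method parameterizes an age- and sex-specific measurement
distribution by a Box-Cox power (L), median (M) and generalized
coefficient of variation (S).  A measurement at standard-normal deviate
Z is

    x = M * (1 + L*S*Z) ** (1/L)        (L != 0)
    x = M * exp(S*Z)                    (L == 0, the limit form)

Tables in the CDC growth-chart dialect (sex coded 1=male / 2=female,
age in months, columns L, M, S) can be loaded from CSV; a built-in
synthetic stand-in table is provided so that nothing requires a
download.  Cohorts are generated with equal numbers per (age, sex)
group, heights rounded to whole centimetres and weights kept
continuous with a natural-log companion column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "LMSEntry",
    "lms_value",
    "lms_quantile",
    "load_lms_table",
    "builtin_lms_table",
    "simulate_growth",
    "AGE_MIN_MONTHS",
    "AGE_MAX_MONTHS",
]

AGE_MIN_MONTHS = 24.0
AGE_MAX_MONTHS = 241.0

#: columns of an LMS table DataFrame
LMS_COLUMNS = ["sex", "age_months", "L", "M", "S"]


@dataclass(frozen=True)
class LMSEntry:
    """One (sex, age) row of LMS parameters for a measure."""

    sex: str
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.M > 0:
            raise ValueError(f"M must be positive, got {self.M}")
        if not self.S > 0:
            raise ValueError(f"S must be positive, got {self.S}")


def lms_value(L, M, S, Z):
    """Measurement value at standard-normal deviate ``Z`` under LMS parameters.

    Implements ``M * (1 + L*S*Z)**(1/L)`` with the ``M * exp(S*Z)`` limit
    at ``L == 0``.  Strictly increasing in ``Z``.  Raises ``ValueError``
    when ``1 + L*S*Z <= 0`` for nonzero L (an implausible deviate for
    these parameters).  Accepts scalars or broadcastable arrays.
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    base = 1.0 + L * S * Z
    nonzero = L != 0
    if np.any((base <= 0) & nonzero):
        raise ValueError("1 + L*S*Z <= 0: deviate out of the Box-Cox domain")
    L_safe = np.where(nonzero, L, 1.0)  # base is exactly 1 where L == 0
    # log1p keeps precision as L -> 0, where base -> 1
    out = np.where(nonzero, M * np.exp(np.log1p(L * S * Z) / L_safe), M * np.exp(S * Z))
    if out.ndim == 0:
        return float(out)
    return out


def lms_quantile(L, M, S, p):
    """Value at probability ``p`` of the LMS distribution: ``lms_value`` at Z = Phi^-1(p)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    return lms_value(L, M, S, ndtri(p))


def _validate_lms_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    bad = df.index[(df["M"] <= 0) | (df["S"] <= 0)]
    if len(bad):
        raise ValueError(f"{source}: non-positive M or S in row {bad[0]}")
    if df["sex"].nunique() < 1:
        raise ValueError(f"{source}: no sex groups present")
    for sex, grp in df.groupby("sex", observed=True):
        ages = grp["age_months"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"{source}: ages not strictly increasing for sex {sex}")
    dup = df.duplicated(subset=["sex", "age_months"])
    if dup.any():
        raise ValueError(f"{source}: duplicate (sex, age) row {df.index[dup][0]}")
    return df.reset_index(drop=True)


def load_lms_table(path: str | Path, measure: str) -> pd.DataFrame:
    """Read an LMS parameter table in the CDC percentile-data-file dialect.

    Expects a header row with columns ``Sex`` (1=male, 2=female),
    ``Agemos``, ``L``, ``M``, ``S`` (case-insensitive; extra percentile
    columns are ignored).  Rows with age below 24 months are dropped
    (the 2-20 y charts).  Returns a DataFrame with columns
    ``sex, age_months, L, M, S`` sorted by (sex, age), with
    ``attrs['measure']`` set.
    """
    if measure not in ("stature", "weight"):
        raise ValueError(f"measure must be 'stature' or 'weight', got {measure!r}")
    raw = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in raw.columns}
    required = {"sex", "agemos", "l", "m", "s"}
    missing = required - set(cols)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = pd.DataFrame(
        {
            "sex_code": pd.to_numeric(raw[cols["sex"]], errors="coerce"),
            "age_months": pd.to_numeric(raw[cols["agemos"]], errors="coerce"),
            "L": pd.to_numeric(raw[cols["l"]], errors="coerce"),
            "M": pd.to_numeric(raw[cols["m"]], errors="coerce"),
            "S": pd.to_numeric(raw[cols["s"]], errors="coerce"),
        }
    )
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed row {bad[0] + 2} (1-based, incl. header)")
    bad = df.index[~df["sex_code"].isin([1, 2])]
    if len(bad):
        raise ValueError(f"{path}: sex code not in {{1,2}} in row {bad[0] + 2}")
    df["sex"] = np.where(df["sex_code"] == 1, "male", "female")
    df = df[df["age_months"] >= AGE_MIN_MONTHS]
    df = df[["sex", "age_months", "L", "M", "S"]].sort_values(["sex", "age_months"])
    out = _validate_lms_frame(df, str(path))
    out.attrs["measure"] = measure
    return out


# ---------------------------------------------------------------------------
# Built-in fallback table
# ---------------------------------------------------------------------------
# SYNTHETIC stand-in for the downloadable growth-chart files: L fixed at 1
# (no skew), M piecewise-linear in age between per-sex anchor medians, S
# constant per measure.  Anchors are typical 50th-percentile stature (cm)
# and weight (kg) values by age in years; they emulate the scale and the
# age/sex structure of real charts but are NOT reference values.

_ANCHOR_YEARS = np.array([2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20], dtype=float)

_STATURE_ANCHORS = {
    "male": np.array([86.9, 95.3, 102.5, 109.2, 115.7, 121.8, 127.5, 133.0, 138.3,
                      143.5, 149.3, 156.0, 163.2, 169.0, 173.1, 175.2, 176.1, 176.5, 176.8]),
    "female": np.array([85.7, 94.2, 101.6, 108.4, 115.0, 121.1, 127.0, 132.7, 138.6,
                        145.0, 151.2, 157.0, 160.4, 162.0, 162.9, 163.1, 163.2, 163.3, 163.4]),
}
_WEIGHT_ANCHORS = {
    "male": np.array([12.7, 14.3, 16.3, 18.4, 20.7, 23.1, 25.8, 28.7, 31.9,
                      35.7, 40.2, 45.3, 50.8, 56.0, 60.3, 63.5, 65.9, 67.8, 69.5]),
    "female": np.array([12.1, 13.9, 15.9, 18.0, 20.2, 22.8, 25.8, 29.1, 32.9,
                        37.2, 41.6, 45.8, 49.4, 51.9, 53.4, 54.4, 55.1, 56.0, 56.7]),
}
_BUILTIN_S = {"stature": 0.042, "weight": 0.15}


def builtin_lms_table(measure: str) -> pd.DataFrame:
    """Synthetic stand-in LMS table spanning ages 24-240 months, both sexes.

    L = 1 everywhere (normal within age), M piecewise-linear between the
    anchor medians, S constant per measure; monthly age grid.  Use for
    download-free simulation; values are not chart reference values.
    """
    if measure not in ("stature", "weight"):
        raise ValueError(f"measure must be 'stature' or 'weight', got {measure!r}")
    anchors = _STATURE_ANCHORS if measure == "stature" else _WEIGHT_ANCHORS
    ages = np.arange(24, 241, dtype=float)
    frames = []
    for sex in ("female", "male"):
        M = np.interp(ages, _ANCHOR_YEARS * 12.0, anchors[sex])
        frames.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age_months": ages,
                    "L": 1.0,
                    "M": M,
                    "S": _BUILTIN_S[measure],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True).sort_values(["sex", "age_months"]).reset_index(drop=True)
    out.attrs["measure"] = measure
    out.attrs["synthetic"] = True
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _group_sizes(n_groups: int, n: int) -> np.ndarray:
    """Allocate n records to groups as evenly as possible.

    The remainder goes round-robin to the first groups in (sex, age)
    sort order, so the allocation is seed-independent.
    """
    base, rem = divmod(n, n_groups)
    sizes = np.full(n_groups, base, dtype=int)
    sizes[:rem] += 1
    return sizes


def _draw_z(rng: np.random.Generator, L, S, size: int) -> np.ndarray:
    """Standard-normal deviates, redrawing any that leave the Box-Cox domain.

    For strongly skewed tables (L well below 0) a |Z| above ~4 can make
    1+L*S*Z non-positive; such draws are implausible under the chart and
    are redrawn.  For L >= 0 tables this never triggers.
    """
    z = rng.standard_normal(size)
    for _ in range(100):
        bad = (1.0 + np.asarray(L) * np.asarray(S) * z) <= 0
        if not bad.any():
            return z
        z[bad] = rng.standard_normal(int(bad.sum()))
    raise RuntimeError("could not draw admissible deviates for these LMS parameters")


def simulate_growth(
    n: int,
    stature_table: pd.DataFrame,
    weight_table: pd.DataFrame,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Simulate a growth cohort of ``n`` records from LMS tables.

    Records are allocated as evenly as possible across the (age, sex)
    groups shared by the two tables.  For each record one Z deviate per
    measure is drawn independently; height is rounded to whole cm,
    weight stays continuous and is accompanied by its natural log.

    Returns a DataFrame with columns
    ``id, age_months, sex, height_cm, weight_kg, log_weight``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if len(stature_table) == 0 or len(weight_table) == 0:
        raise ValueError("empty LMS table")
    st = stature_table.sort_values(["sex", "age_months"]).reset_index(drop=True)
    wt = weight_table.sort_values(["sex", "age_months"]).reset_index(drop=True)
    key_s = list(zip(st["sex"], st["age_months"]))
    key_w = list(zip(wt["sex"], wt["age_months"]))
    if set(st["sex"]) != set(wt["sex"]):
        raise ValueError("stature and weight tables cover different sexes")
    if key_s != key_w:
        raise ValueError("stature and weight tables must share the same (sex, age) grid")

    rng = np.random.default_rng(seed)
    sizes = _group_sizes(len(st), n)

    age = np.repeat(st["age_months"].to_numpy(), sizes)
    sex = np.repeat(st["sex"].to_numpy(), sizes)
    Ls = np.repeat(st["L"].to_numpy(), sizes)
    Ms = np.repeat(st["M"].to_numpy(), sizes)
    Ss = np.repeat(st["S"].to_numpy(), sizes)
    Lw = np.repeat(wt["L"].to_numpy(), sizes)
    Mw = np.repeat(wt["M"].to_numpy(), sizes)
    Sw = np.repeat(wt["S"].to_numpy(), sizes)

    z_height = _draw_z(rng, Ls, Ss, n)
    z_weight = _draw_z(rng, Lw, Sw, n)
    height = lms_value(Ls, Ms, Ss, z_height)
    weight = lms_value(Lw, Mw, Sw, z_weight)

    out = pd.DataFrame(
        {
            "id": np.arange(n),
            "age_months": age,
            "sex": sex,
            "height_cm": np.rint(height).astype(int),
            "weight_kg": weight,
            "log_weight": np.log(weight),
        }
    )
    return out
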