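"""Orchestration of the error-detection simulation study.

A *study* simulates one growth cohort per replicate, contaminates its
height column under every configured (pattern, prevalence) scenario,
runs every configured detector on the same contaminated table, and
evaluates each detector cellwise against the ground-truth mask.

Detectors and their height-cell attribution:

========================  ==============================  ================
method key                score (ROC)                     binary flag
========================  ==============================  ================
sds                       |robust SDS| of height          |SDS| > 2
boxplot                   (none)                          outside fences
bagplot_age_height        (none)                          outside fence
bagplot_height_weight     (none)                          outside fence
maha_classic              squared Mahalanobis distance    d2 > chi2(3, .99)
maha_mcd                  squared Mahalanobis distance    d2 > chi2(3, .99)
maha_mve                  squared Mahalanobis distance    d2 > chi2(3, .99)
ddc                       |standardized height residual|  |resid| > c
========================  ==============================  ================

Multivariable methods see (age, height, log-weight); sex is excluded.
Rowwise distance flags are attributed to the height cell, since errors
exist only in height.  Seeding is hierarchical: one master seed spawns
independent streams for simulation, contamination and the MCD/MVE
searches, so methods never perturb each other's draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bagplot import bagplot_flags, build_bagplot
from .contamination import PATTERN_NAMES, ErrorPattern, contaminate
from .ddc import DDCParams, ddc_fit
from .evaluation import binary_metrics, confusion, roc_summary
from .lms import builtin_lms_table, load_lms_table, simulate_growth
from .robust_distance import (
    classic_estimates,
    distance_flags,
    mahalanobis_sq,
    mcd_estimates,
    mve_estimates,
)
from .univariate import boxplot_flags, robust_sds, sds_flags

ALL_METHODS = (
    "sds",
    "boxplot",
    "bagplot_age_height",
    "bagplot_height_weight",
    "maha_classic",
    "maha_mcd",
    "maha_mve",
    "ddc",
)

#: methods with a continuous score usable for ROC analysis
SCORED_METHODS = ("sds", "maha_classic", "maha_mcd", "maha_mve", "ddc")

DESCRIPTIVE_STATS = ("mean", "sd", "mad", "min", "p1", "p5", "p10", "p25",
                     "median", "p75", "p90", "p95", "p99", "max")

__all__ = [
    "ALL_METHODS",
    "SCORED_METHODS",
    "ScenarioConfig",
    "DetectionResult",
    "StudyReport",
    "load_tables",
    "detect_all",
    "run_scenario",
    "descriptive_table",
    "run_study",
    "save_report",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the study grid."""

    pattern: ErrorPattern
    prevalence: float
    n: int = 5000
    methods: tuple[str, ...] = ALL_METHODS
    seed: int = 0
    replicates: int = 1
    lms_source: str = "builtin"

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s) {sorted(unknown)}")


@dataclass
class DetectionResult:
    """Per-method output on one contaminated table."""

    method: str
    flags: np.ndarray
    scores: np.ndarray | None = None
    error: str | None = None


@dataclass
class StudyReport:
    descriptives: pd.DataFrame
    metrics: pd.DataFrame
    auc: pd.DataFrame
    roc_points: pd.DataFrame
    manifest: dict


def load_tables(lms_source: str | tuple[str | Path, str | Path] = "builtin"):
    """Resolve an LMS source to (stature_table, weight_table).

    ``"builtin"`` uses the synthetic stand-in tables; otherwise pass a
    (stature_csv, weight_csv) pair of CDC-dialect files.
    """
    if lms_source == "builtin":
        return builtin_lms_table("stature"), builtin_lms_table("weight")
    stature_path, weight_path = lms_source
    return load_lms_table(stature_path, "stature"), load_lms_table(weight_path, "weight")


def _multivariable_matrix(table: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [table["age_months"].to_numpy(float),
         table["height_cm"].to_numpy(float),
         table["log_weight"].to_numpy(float)]
    )


def detect_all(
    table: pd.DataFrame,
    methods: tuple[str, ...] = ALL_METHODS,
    seed: int | np.random.SeedSequence | None = None,
    ddc_params: DDCParams | None = None,
) -> dict[str, DetectionResult]:
    """Run the requested detectors on one (contaminated) growth table.

    Every method sees the same table.  A method that raises is isolated:
    its result carries the error message and all-False flags.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    mcd_seed, mve_seed = ss.spawn(2)
    height = table["height_cm"].to_numpy(float)
    X = _multivariable_matrix(table)
    n = len(table)
    results: dict[str, DetectionResult] = {}

    def run(name, fn):
        try:
            results[name] = fn()
        except Exception as exc:  # per-method isolation
            results[name] = DetectionResult(
                method=name, flags=np.zeros(n, dtype=bool), error=str(exc)
            )

    for method in methods:
        if method == "sds":
            def _sds():
                scores = np.abs(robust_sds(height))
                return DetectionResult("sds", sds_flags(robust_sds(height)), scores)
            run(method, _sds)
        elif method == "boxplot":
            run(method, lambda: DetectionResult("boxplot", boxplot_flags(height)))
        elif method in ("bagplot_age_height", "bagplot_height_weight"):
            cols = (0, 1) if method == "bagplot_age_height" else (1, 2)
            def _bag(cols=cols, name=method):
                xy = X[:, cols]
                return DetectionResult(name, bagplot_flags(xy, build_bagplot(xy)))
            run(method, _bag)
        elif method in ("maha_classic", "maha_mcd", "maha_mve"):
            def _maha(name=method):
                if name == "maha_classic":
                    est = classic_estimates(X)
                elif name == "maha_mcd":
                    est = mcd_estimates(X, seed=mcd_seed)
                else:
                    est = mve_estimates(X, seed=mve_seed)
                d2 = mahalanobis_sq(X, est)
                return DetectionResult(name, distance_flags(d2).flags, d2)
            run(method, _maha)
        elif method == "ddc":
            def _ddc():
                fit = ddc_fit(X, ddc_params)
                return DetectionResult(
                    "ddc", fit.cell_flags[:, 1], np.abs(fit.residual[:, 1])
                )
            run(method, _ddc)
        else:  # pragma: no cover - guarded by ScenarioConfig
            raise ValueError(f"unknown method {method!r}")
    return results


def run_scenario(
    config: ScenarioConfig,
    table: pd.DataFrame,
    stature_table: pd.DataFrame,
    seed: int | np.random.SeedSequence | None = None,
) -> dict:
    """Contaminate ``table`` per the config and evaluate every method.

    Returns a dict with the contaminated table, truth mask, detection
    results, and tidy metric / ROC / AUC rows.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    contam_seed, detect_seed = ss.spawn(2)
    contaminated, mask = contaminate(
        table, config.pattern, config.prevalence, contam_seed, stature_table=stature_table
    )
    detections = detect_all(contaminated, config.methods, detect_seed)

    scenario = f"{config.pattern.name}@{config.prevalence:g}"
    metric_rows, auc_rows, roc_rows = [], [], []
    for name, det in detections.items():
        if det.error is not None:
            continue
        for m in binary_metrics(confusion(det.flags, mask)):
            metric_rows.append(
                {"scenario": scenario, "pattern": config.pattern.name,
                 "prevalence": config.prevalence, "method": name, "metric": m.name,
                 "estimate": m.estimate, "ci_low": m.ci_low, "ci_high": m.ci_high}
            )
        if name in SCORED_METHODS and det.scores is not None:
            roc = roc_summary(det.scores, mask)
            auc_rows.append(
                {"scenario": scenario, "pattern": config.pattern.name,
                 "prevalence": config.prevalence, "method": name, "auc": roc.auc,
                 "ci_low": roc.auc_ci[0], "ci_high": roc.auc_ci[1],
                 "youden_j": roc.youden_j, "youden_cutoff": roc.youden_cutoff,
                 "youden_se": roc.youden_se, "youden_sp": roc.youden_sp}
            )
            for (fpr, tpr), thr in zip(roc.points, roc.thresholds):
                roc_rows.append(
                    {"scenario": scenario, "method": name, "threshold": thr,
                     "se": tpr, "sp": 1.0 - fpr}
                )
    return {
        "config": config,
        "table": contaminated,
        "mask": mask,
        "detections": detections,
        "metrics": metric_rows,
        "auc": auc_rows,
        "roc_points": roc_rows,
    }


def _column_stats(x: np.ndarray) -> dict[str, float]:
    med = np.median(x)
    pct = np.percentile(x, [1, 5, 10, 25, 75, 90, 95, 99])
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "mad": float(1.4826 * np.median(np.abs(x - med))),
        "min": float(np.min(x)),
        "p1": float(pct[0]), "p5": float(pct[1]), "p10": float(pct[2]),
        "p25": float(pct[3]), "median": float(med), "p75": float(pct[4]),
        "p90": float(pct[5]), "p95": float(pct[6]), "p99": float(pct[7]),
        "max": float(np.max(x)),
    }


def descriptive_table(
    error_free: pd.DataFrame, contaminated: dict[str, pd.DataFrame] | None = None
) -> pd.DataFrame:
    """Summary statistics of age, log-weight and height.

    Height is summarized for the error-free table and for each entry of
    ``contaminated`` (pattern name -> table); rows are statistics.
    """
    cols = {
        "age_months": _column_stats(error_free["age_months"].to_numpy(float)),
        "log_weight": _column_stats(error_free["log_weight"].to_numpy(float)),
        "height_error_free": _column_stats(error_free["height_cm"].to_numpy(float)),
    }
    for name, tbl in (contaminated or {}).items():
        if len(tbl) != len(error_free):
            raise ValueError("all tables must have the same n")
        cols[f"height_{name}"] = _column_stats(tbl["height_cm"].to_numpy(float))
    return pd.DataFrame(cols).reindex(list(DESCRIPTIVE_STATS))


def run_study(
    n: int = 5000,
    prevalences: tuple[float, ...] = (0.02, 0.10),
    patterns: tuple[str, ...] = PATTERN_NAMES,
    methods: tuple[str, ...] = ALL_METHODS,
    seed: int = 0,
    replicates: int = 1,
    lms_source: str | tuple = "builtin",
    shift_cm: float = 40.0,
) -> StudyReport:
    """Run the full grid: patterns x prevalences x methods, per replicate.

    One cohort is simulated per replicate; all scenarios of that
    replicate contaminate the same cohort, and all methods within a
    scenario see the same contaminated table.
    """
    stature, weight = load_tables(lms_source)
    master = np.random.SeedSequence(seed)
    metric_rows, auc_rows, roc_rows = [], [], []
    descriptives = None
    for rep in range(replicates):
        rep_ss = np.random.SeedSequence(entropy=master.entropy, spawn_key=(rep,))
        sim_seed, *scenario_seeds = rep_ss.spawn(1 + len(patterns) * len(prevalences))
        base = simulate_growth(n, stature, weight, sim_seed)
        contaminated_10 = {}
        i = 0
        for pattern_name in patterns:
            for prevalence in prevalences:
                config = ScenarioConfig(
                    pattern=ErrorPattern(pattern_name, shift_cm=shift_cm),
                    prevalence=prevalence, n=n, methods=methods, seed=seed,
                    replicates=replicates,
                    lms_source="builtin" if lms_source == "builtin" else "file",
                )
                result = run_scenario(config, base, stature, scenario_seeds[i])
                i += 1
                for row in result["metrics"]:
                    row["replicate"] = rep
                for row in result["auc"]:
                    row["replicate"] = rep
                for row in result["roc_points"]:
                    row["replicate"] = rep
                metric_rows += result["metrics"]
                auc_rows += result["auc"]
                roc_rows += result["roc_points"]
                if rep == 0 and np.isclose(prevalence, 0.10):
                    contaminated_10[pattern_name] = result["table"]
        if rep == 0:
            descriptives = descriptive_table(base, contaminated_10)
    manifest = {
        "package": "growthscreen",
        "version": __version__,
        "n": n,
        "seed": seed,
        "replicates": replicates,
        "prevalences": list(prevalences),
        "patterns": list(patterns),
        "methods": list(methods),
        "shift_cm": shift_cm,
        "lms_source": "builtin" if lms_source == "builtin" else [str(p) for p in lms_source],
        "versions": _library_versions(),
    }
    return StudyReport(
        descriptives=descriptives,
        metrics=pd.DataFrame(metric_rows),
        auc=pd.DataFrame(auc_rows),
        roc_points=pd.DataFrame(roc_rows),
        manifest=manifest,
    )


def _library_versions() -> dict[str, str]:
    import scipy
    import shapely
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
        "shapely": shapely.__version__,
    }


def save_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the study tables and the reproducibility manifest as CSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.descriptives.to_csv(out / "descriptives.csv", index_label="statistic")
    report.metrics.to_csv(out / "metrics.csv", index=False)
    report.auc.to_csv(out / "auc.csv", index=False)
    report.roc_points.to_csv(out / "roc_points.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
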