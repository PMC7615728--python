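# growthscreen

Cellwise error detection methods evaluated on simulated growth data.

Observational datasets of children's height and weight accumulate
transcription errors, unit mistakes and out-of-population records.
Screening rules that flag whole records (rowwise) leave the analyst
hunting for the offending variable; *cellwise* detection points at the
single suspicious value.  This package provides a controlled test-bed
for comparing both kinds of rules: it simulates an age/sex-structured
cohort from LMS (Box-Cox) growth tables, plants errors of known shape
in single height cells, runs eight detectors on the same contaminated
data, and scores them against the ground truth.

**Detectors.** Robust standard-deviation scores
(SDS = (x − median)/(1.4826·MAD), flag outside ±2), the Tukey boxplot
rule, bivariate bagplots built from exact Tukey halfspace depth (bag =
deepest half of the data, fence = bag inflated ×3), and Mahalanobis
distances d² = (x−μ)ᵀΣ⁻¹(x−μ) on (age, height, log weight) with
classic, minimum covariance determinant (FastMCD) and minimum volume
ellipsoid estimates of (μ, Σ), flagged at d² > χ²₃,₀.₉₉.  The
centerpiece is a from-scratch DetectDeviatingCells (DDC): robust
standardization, trimmed pairwise correlations, prediction of every
cell from its correlated columns via median-of-ratios slopes, and
flagging of cells whose standardized residuals exceed
c = √χ²₁,₀.₉₉ ≈ 2.576 (plus rowwise flags from the aggregated
residuals).

**Evaluation.** Cellwise sensitivity, specificity, PPV and LR+ with
exact Clopper–Pearson / log-method 95% CIs; ROC curves with
Mann–Whitney AUC and DeLong intervals; Youden-index (J = Se + Sp − 1)
operating points.

## Worked example

```python
import numpy as np
from growthscreen import (builtin_lms_table, simulate_growth, contaminate,
                          ErrorPattern, ddc_fit, confusion, binary_metrics)

stature, weight = builtin_lms_table("stature"), builtin_lms_table("weight")
cohort = simulate_growth(5000, stature, weight, seed=20230215)
table, mask = contaminate(cohort, ErrorPattern("add_shift"), prevalence=0.02,
                          seed=1, stature_table=stature)

X = np.column_stack([table.age_months, table.height_cm, table.log_weight])
fit = ddc_fit(X)                      # deterministic
flags = fit.cell_flags[:, 1]          # height column
for m in binary_metrics(confusion(flags, mask)):
    print(f"{m.name:>12}: {m.estimate:.3f}  (95% CI {m.ci_low:.3f}-{m.ci_high:.3f})")
```

prints

```
 sensitivity: 1.000  (95% CI 0.964-1.000)
 specificity: 0.976  (95% CI 0.971-0.980)
         ppv: 0.461  (95% CI 0.393-0.530)
     lr_plus: 41.880  (95% CI 35.016-50.091)
```

— DDC catches all 100 heights shifted by 40 cm while flagging 2.4% of
clean cells; with errors this rare, fewer than half of all flags are
true errors, which is why PPV and LR+ are reported alongside Se/Sp.

## The analysis pipeline

Numbered drivers under `analysis/` rebuild the full study
(n = 5000; four error patterns × 2% and 10% prevalence; all eight
methods) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort + descriptive table
python analysis/02_inject_errors.py       # 8 contaminated scenarios + masks
python analysis/03_run_detectors.py       # per-cell scores/flags per method
python analysis/04_evaluate_performance.py # Se/Sp/PPV/LR+ tables, ROC/AUC tables
```

The same grid is available programmatically via
`growthscreen.study.run_study(...)` and from the shell via the
`growthscreen` CLI (`simulate`, `contaminate`, `detect`, `evaluate`,
`study` subcommands).  Typical headline behavior on the built-in
table: every method catches 100% of skipped digits at 2% prevalence;
at 10% prevalence the classic Mahalanobis distance collapses to ~38%
sensitivity by masking while MCD/MVE stay at 100%; univariate rules
are nearly blind to swapped digits (SDS ~6%) and first-percentile
replacements; DDC has the best AUC (~0.88–0.91) for the
first-percentile pattern.

Fidelity runs against real growth-chart files are supported by
`load_lms_table(path, measure)` (CDC percentile-data-file dialect);
the built-in table is a documented synthetic stand-in, not chart
values.

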