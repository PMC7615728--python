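#!/usr/bin/env python
"""Evaluate every detector cellwise and build the report tables.

Joins the detections from 03_run_detectors.py with the ground-truth
masks, computes sensitivity/specificity/PPV/LR+ with 95% CIs per
scenario and method, ROC curves with AUC (DeLong CIs) and Youden
operating points for the score-based methods, and prints the headline
comparisons.
"""

import argparse
from pathlib import Path

import pandas as pd

from growthscreen.evaluation import binary_metrics, confusion, roc_summary
from growthscreen.study import SCORED_METHODS

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

metric_rows, auc_rows = [], []
for det_path in sorted(args.out_dir.glob("detections_*.csv")):
    scenario = det_path.stem.replace("detections_", "")
    truth_path = det_path.with_name(det_path.name.replace("detections_", "contaminated_"))
    truth = pd.read_csv(truth_path)["is_error"].to_numpy(bool)
    detections = pd.read_csv(det_path)
    for method, grp in detections.groupby("method"):
        grp = grp.sort_values("id")
        flags = grp["flag"].to_numpy(bool)
        for m in binary_metrics(confusion(flags, truth)):
            metric_rows.append({"scenario": scenario, "method": method,
                                "metric": m.name, "estimate": m.estimate,
                                "ci_low": m.ci_low, "ci_high": m.ci_high})
        if method in SCORED_METHODS:
            roc = roc_summary(grp["score"].to_numpy(float), truth)
            auc_rows.append({"scenario": scenario, "method": method, "auc": roc.auc,
                             "ci_low": roc.auc_ci[0], "ci_high": roc.auc_ci[1],
                             "youden_j": roc.youden_j, "youden_se": roc.youden_se,
                             "youden_sp": roc.youden_sp})

metrics = pd.DataFrame(metric_rows)
aucs = pd.DataFrame(auc_rows)
metrics.to_csv(args.out_dir / "performance_metrics.csv", index=False)
aucs.to_csv(args.out_dir / "auc_table.csv", index=False)

se = metrics[metrics.metric == "sensitivity"].pivot(
    index="scenario", columns="method", values="estimate"
)
print("sensitivity (%) by scenario and method:")
print((100 * se).round(1).to_string())
print("\nAUC by scenario (score-based methods):")
print(aucs.pivot(index="scenario", columns="method", values="auc").round(3).to_string())
print("\nwrote performance_metrics.csv and auc_table.csv")
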