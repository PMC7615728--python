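#!/usr/bin/env python
"""Run all eight detectors on every contaminated scenario table.

For each scenario CSV written by 02_inject_errors.py, runs robust SDS,
boxplot, the two bagplots, classic/MCD/MVE Mahalanobis distances and
DetectDeviatingCells on the same table, and writes per-cell scores and
flags (one long CSV per scenario).
"""

import argparse
import time
from pathlib import Path

import numpy as np
import pandas as pd

from growthscreen.study import ALL_METHODS, detect_all

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=20230215)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

scenario_files = sorted(args.out_dir.glob("contaminated_*.csv"))
if not scenario_files:
    raise SystemExit("no contaminated_*.csv found; run 02_inject_errors.py first")

master = np.random.SeedSequence(args.seed)
for path, seed in zip(scenario_files, master.spawn(len(scenario_files))):
    table = pd.read_csv(path)
    t0 = time.time()
    results = detect_all(table, ALL_METHODS, seed)
    rows = []
    for name, det in results.items():
        if det.error is not None:
            print(f"  {name} FAILED: {det.error}")
            continue
        scores = det.scores if det.scores is not None else np.full(len(table), np.nan)
        rows.append(pd.DataFrame(
            {"id": table["id"], "method": name, "score": scores,
             "flag": det.flags.astype(int)}
        ))
    out = path.with_name(path.name.replace("contaminated_", "detections_"))
    pd.concat(rows, ignore_index=True).to_csv(out, index=False)
    flagged = {name: int(det.flags.sum()) for name, det in results.items()}
    print(f"{path.stem}: {time.time() - t0:.1f}s, cells flagged per method: {flagged}")
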