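#!/usr/bin/env python
"""Time-frequency ROI power of the cue-target interval for one session.

Computes Morlet-wavelet power (f_b = 1, f_c = 1.5) on the CSD epochs,
flips left-hand-standard trials across the midline, normalizes to the
-250..-50 ms baseline and averages into the sensorimotor ROI x band
(mu 9-14 Hz, beta 15-25 Hz) time courses per cue condition.

Writes results/session/roi_power.tsv and prints the late-interval
(500-1100 ms) ipsilateral mu means, the single-subject view of the
condition ordering.
"""

import argparse
from pathlib import Path

import pandas as pd

from proctrl.pipeline import PipelineConfig, run_stage

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--workdir", type=Path, default=Path("results/session"))
args = ap.parse_args()

run_stage("tfr", PipelineConfig(seed=args.seed), args.workdir)
roi = pd.read_csv(args.workdir / "roi_power.tsv", sep="\t")
late = roi[(roi.time_s >= 0.5) & (roi.time_s < 1.1)
           & (roi.band == "mu") & (roi.side == "ipsi")]
means = late.groupby("condition").percent.mean()
print("ipsilateral mu, 500-1100 ms (single subject; group stats in 07):")
for c in ("EC", "EN", "EG"):
    print(f"  {c}: {means[c]:+6.1f} %")
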