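#!/usr/bin/env python
"""Alpha phase-locking maps from the sensorimotor seeds for one session.

Band-passes the CSD epochs to 9-14 Hz, takes Hilbert phases, and computes
the PLV from C3 and C4 (flip-corrected: C4 = ipsilateral to the standard
hand) to every electrode in the 900-1100 ms pre-target window, per cue
condition with equalized trial counts.

Writes results/session/plv.tsv and prints the seed->ipsilateral-frontal
values whose condition difference the group analysis tests.
"""

import argparse
from pathlib import Path

import pandas as pd

from proctrl.pipeline import PipelineConfig, run_stage

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--workdir", type=Path, default=Path("results/session"))
args = ap.parse_args()

run_stage("plv", PipelineConfig(seed=args.seed), args.workdir)
plv = pd.read_csv(args.workdir / "plv.tsv", sep="\t")
front = plv[(plv.seed == "C4") & plv.electrode.isin(["F6", "FC6", "F4"])]
print("C4 (ipsilateral) seed -> frontal electrodes, 900-1100 ms:")
print(front.pivot(index="electrode", columns="condition", values="plv")
      .round(2).to_string())
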