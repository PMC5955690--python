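#!/usr/bin/env python
"""Simulate one subject's raw EEG session and write it as EDF+.

Runs the ``simulate`` pipeline stage: task design + behavior, then the
64-channel synthetic session with the default injected oscillatory effects
(condition-dependent mu/beta envelopes at C3/C4, target-evoked prefrontal
beta bursts at F5/F6, seed->frontal alpha coupling) over pink-noise
background, annotated with cue/target events.

Writes results/session/{session.edf, trials.tsv, design.json,
manifest_simulate.json}. Use --full for the complete 960-trial session
(~160 MB EDF; default is the 72-trial scaled session).
"""

import argparse
from pathlib import Path

from proctrl.design import DesignSpec
from proctrl.pipeline import PipelineConfig, run_stage

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--full", action="store_true",
                help="simulate the full 6x160-trial session")
ap.add_argument("--out", type=Path, default=Path("results/session"))
args = ap.parse_args()

cfg = PipelineConfig(seed=args.seed)
if args.full:
    cfg.design = DesignSpec(seed=args.seed)
man = run_stage("simulate", cfg, args.out)
edf = args.out / "session.edf"
print(f"wrote {edf} ({edf.stat().st_size / 1e6:.1f} MB), "
      f"{len(man['outputs'])} artifacts, manifest hash-linked")
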