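#!/usr/bin/env python
"""Preprocess the simulated session: re-reference, filter, epoch, reject.

Reads results/session/session.edf, re-references to the earlobe average,
applies the 0.5 Hz high-pass + 50 Hz notch (zero-phase), extracts cue- and
target-locked epochs (-1..+2 s, 100-ms pre-stimulus baseline), and marks
trials exceeding +/-80 uV. Writes the epoch containers and rejection log
into the same directory, hash-linked to the upstream manifest.
"""

import argparse
import json
from pathlib import Path

from proctrl.pipeline import PipelineConfig, run_stage

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--workdir", type=Path, default=Path("results/session"))
args = ap.parse_args()

man = run_stage("preprocess", PipelineConfig(seed=args.seed), args.workdir)
hdr = json.loads((args.workdir / "epochs_cue.json").read_text())
n_rej = sum(hdr["rejected"])
print(f"cue-locked epochs: {hdr['shape'][0]} trials x {hdr['shape'][1]} channels "
      f"x {hdr['shape'][2]} samples; {n_rej} rejected "
      f"({100 * n_rej / hdr['shape'][0]:.1f}% -> subject "
      f"{'EXCLUDED' if n_rej / hdr['shape'][0] > 0.3 else 'kept'})")
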