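#!/usr/bin/env python
"""Generate the full task design and a simulated behavioral cohort.

Builds the 960-trial cued go-nogo-change session (6 blocks x 160 trials,
equal cue probabilities, exact 25% rare targets, hand switch at mid-
session), simulates 22 subjects' responses from the generative RT/error
model, and computes the behavioral summary and tests (RT RM-ANOVA with
paired follow-ups, premature-error comparison).

Writes results/behavior/{trials_subject00.tsv, summary.tsv, tests.tsv}.
"""

import argparse
from pathlib import Path

import pandas as pd

from proctrl.design import (
    DesignSpec, BehaviorParams, generate_design, simulate_behavior,
    behavioral_summary, write_trial_table,
)
from proctrl import stats as st

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--subjects", type=int, default=22)
ap.add_argument("--out", type=Path, default=Path("results/behavior"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rows = []
for s in range(args.subjects):
    order = "RHB_first" if s % 2 == 0 else "LHB_first"
    spec = DesignSpec(seed=args.seed * 1000 + s, counterbalance_order=order)
    trials = simulate_behavior(generate_design(spec),
                               BehaviorParams(seed=args.seed * 1000 + 500 + s))
    if s == 0:
        write_trial_table(trials, args.out / "trials_subject00.tsv")
        spec.to_json(args.out / "design_spec.json")
    rows.append(behavioral_summary(trials, by=None).iloc[0])
summary = pd.DataFrame(rows)
summary["subject"] = range(args.subjects)
summary.to_csv(args.out / "summary.tsv", sep="\t", index=False)

rt = summary[["rt_go", "rt_no-change", "rt_no-nogo", "rt_change"]].to_numpy()
aov = st.rm_anova_oneway(rt)
tests = [{"test": "RT Condition (RM-ANOVA, GG)", "stat": aov.F,
          "df1": aov.df1, "df2": aov.df2, "p": aov.p}]
for a, b in [("go", "no-change"), ("go", "no-nogo"), ("go", "change"),
             ("no-change", "change"), ("no-nogo", "change"),
             ("no-change", "no-nogo")]:
    r = st.paired_t(summary[f"rt_{a}"], summary[f"rt_{b}"])
    tests.append({"test": f"RT {a} vs {b} (paired t)", "stat": r.t,
                  "df1": r.df, "df2": "", "p": r.p})
pre = summary[["premature_EG", "premature_EC", "premature_EN"]].to_numpy()
paov = st.rm_anova_oneway(pre)
tests.append({"test": "premature Condition (RM-ANOVA, GG)", "stat": paov.F,
              "df1": paov.df1, "df2": paov.df2, "p": paov.p})
pd.DataFrame(tests).to_csv(args.out / "tests.tsv", sep="\t", index=False)

print(f"{args.subjects} simulated subjects, {len(rt)} x 4 RT cells")
print(summary[["rt_go", "rt_no-change", "rt_no-nogo", "rt_change"]]
      .mean().round(1).to_string())
print(f"RT Condition effect: F({aov.df1},{aov.df2}) = {aov.F:.1f}, "
      f"p = {aov.p:.2g} -> proactive slowing pattern "
      f"(go < no-change/no-nogo < change) "
      f"{'recovered' if aov.p < 0.001 else 'NOT recovered'}")
print(f"tables under {args.out}/")
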