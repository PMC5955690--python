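"""Cued go-nogo-change task design and generative behavior.

The task has three cue conditions, each signalled by a colored square and
occurring with equal probability:

* ``EG`` (expecting go) — the cue is always followed by the standard target;
* ``EC`` (expecting change) — 75% standard targets, 25% *change* targets that
  require a button press with the non-standard hand;
* ``EN`` (expecting nogo) — 75% standard targets, 25% *nogo* targets that
  require withholding the response.

Cues last 100 ms, the target follows after a 1-s inter-stimulus interval and
lasts 100 ms; inter-trial intervals are jittered. Halfway through the
session the standard response hand switches (left-handed blocks, LHB, vs
right-handed blocks, RHB).

Derived (response) conditions used throughout the analysis:
``go`` (EG), ``no-change``/``change`` (EC), ``no-nogo``/``nogo`` (EN).

Reaction times are generated from a shifted log-normal family (right-skewed,
as empirical RT distributions are); error types are per-trial Bernoulli
draws: premature presses during the cue-target interval, omissions, choice
errors, and failed inhibitions on nogo trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "DERIVED_CONDITIONS",
    "DesignSpec",
    "BehaviorParams",
    "RTParams",
    "generate_design",
    "simulate_behavior",
    "behavioral_summary",
    "derived_condition",
    "read_trial_table",
    "write_trial_table",
]

CONDITIONS = ("EG", "EC", "EN")
DERIVED_CONDITIONS = ("go", "no-change", "change", "no-nogo", "nogo")


class DesignError(ValueError):
    """An allocation that cannot be realized exactly."""


@dataclass
class DesignSpec:
    """Parameters of the cued go-nogo-change session."""

    n_blocks: int = 6
    trials_per_block: int = 160
    p_condition: dict = field(
        default_factory=lambda: {"EG": 1 / 3, "EC": 1 / 3, "EN": 1 / 3}
    )
    p_rare_target: float = 0.25
    cue_duration_ms: float = 100.0
    isi_ms: float = 1000.0
    target_duration_ms: float = 100.0
    iti_range_ms: tuple = (1300.0, 1600.0)
    hand_switch_block: int = 3
    counterbalance_order: str = "RHB_first"  # or "LHB_first"
    start_offset_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        ps = [self.p_condition[c] for c in CONDITIONS]
        if any(p < 0 or p > 1 for p in ps) or abs(sum(ps) - 1.0) > 1e-9:
            raise ValueError("condition probabilities must lie in [0,1] and sum to 1")
        if not 0.0 <= self.p_rare_target <= 1.0:
            raise ValueError("p_rare_target must lie in [0,1]")
        if self.iti_range_ms[0] > self.iti_range_ms[1]:
            raise ValueError("iti range lower bound exceeds upper bound")
        if self.counterbalance_order not in ("RHB_first", "LHB_first"):
            raise ValueError("counterbalance_order must be RHB_first or LHB_first")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def soa_s(self) -> float:
        """Cue onset to target onset (cue duration + ISI)."""
        return (self.cue_duration_ms + self.isi_ms) / 1000.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignSpec":
        d = json.loads(Path(path).read_text())
        d["iti_range_ms"] = tuple(d["iti_range_ms"])
        return cls(**d)


def _block_condition_counts(spec: DesignSpec, block: int) -> dict:
    """Largest-remainder allocation, rotating the remainder across blocks.

    160 trials at 1/3 each gives 53/53/54; the extra trial rotates so
    condition totals balance over the session.
    """
    n = spec.trials_per_block
    raw = {c: n * spec.p_condition[c] for c in CONDITIONS}
    base = {c: int(np.floor(raw[c] + 1e-9)) for c in CONDITIONS}
    short = n - sum(base.values())
    order = sorted(CONDITIONS, key=lambda c: -(raw[c] - base[c]))
    for k in range(short):
        base[order[(k + block) % len(CONDITIONS)]] += 1
    return base


def generate_design(spec: DesignSpec, exact_allocation: bool = True) -> pd.DataFrame:
    """Generate the trial table (one row per trial, responses unfilled).

    With ``exact_allocation`` condition counts per block follow the rotating
    largest-remainder rule and rare-target counts inside EC and EN match
    ``p_rare_target`` exactly over the session (an error is raised if the
    session-wide count is not an integer). Otherwise conditions and targets
    are drawn i.i.d. per trial.
    """
    rng = np.random.default_rng(spec.seed)
    conds = np.empty(spec.n_trials, dtype=object)
    for b in range(spec.n_blocks):
        if exact_allocation:
            counts = _block_condition_counts(spec, b)
            block_conds = np.array(
                [c for c in CONDITIONS for _ in range(counts[c])], dtype=object
            )
        else:
            block_conds = rng.choice(
                np.array(CONDITIONS, dtype=object),
                size=spec.trials_per_block,
                p=[spec.p_condition[c] for c in CONDITIONS],
            )
        rng.shuffle(block_conds)
        sl = slice(b * spec.trials_per_block, (b + 1) * spec.trials_per_block)
        conds[sl] = block_conds

    target = np.where(conds == "EG", "standard", "standard").astype(object)
    for cond, rare in (("EC", "change"), ("EN", "nogo")):
        idx = np.flatnonzero(conds == cond)
        if exact_allocation:
            n_rare_f = len(idx) * spec.p_rare_target
            n_rare = int(round(n_rare_f))
            if abs(n_rare_f - n_rare) > 1e-9:
                raise DesignError(
                    f"rare-target count for {cond} is not an integer: "
                    f"{len(idx)} trials x {spec.p_rare_target} = {n_rare_f}"
                )
            chosen = rng.choice(idx, size=n_rare, replace=False)
        else:
            chosen = idx[rng.random(len(idx)) < spec.p_rare_target]
        target[chosen] = rare

    blocks = np.repeat(np.arange(spec.n_blocks), spec.trials_per_block)
    first = "right" if spec.counterbalance_order == "RHB_first" else "left"
    second = "left" if first == "right" else "right"
    hand = np.where(blocks < spec.hand_switch_block, first, second).astype(object)

    iti = rng.uniform(*[v / 1000.0 for v in spec.iti_range_ms], size=spec.n_trials)
    step = spec.soa_s + spec.target_duration_ms / 1000.0 + iti
    cue_onset = spec.start_offset_s + np.concatenate(([0.0], np.cumsum(step[:-1])))
    tbl = pd.DataFrame(
        {
            "trial": np.arange(spec.n_trials),
            "block": blocks,
            "condition": conds,
            "target_type": target,
            "cue_onset_s": cue_onset,
            "target_onset_s": cue_onset + spec.soa_s,
            "standard_hand": hand,
            "response": pd.array([None] * spec.n_trials, dtype=object),
            "rt_ms": np.full(spec.n_trials, np.nan),
            "correct": pd.array([None] * spec.n_trials, dtype=object),
        }
    )
    return tbl


def derived_condition(tbl: pd.DataFrame) -> pd.Series:
    """Map cue condition x target type to the response condition labels."""
    out = pd.Series(index=tbl.index, dtype=object)
    out[tbl.condition == "EG"] = "go"
    out[(tbl.condition == "EC") & (tbl.target_type == "standard")] = "no-change"
    out[(tbl.condition == "EC") & (tbl.target_type == "change")] = "change"
    out[(tbl.condition == "EN") & (tbl.target_type == "standard")] = "no-nogo"
    out[(tbl.condition == "EN") & (tbl.target_type == "nogo")] = "nogo"
    return out


@dataclass
class RTParams:
    """Shifted log-normal RT distribution, parameterized by target moments.

    ``X = shift + LogNormal(mu, sigma)`` with ``sigma`` fixed and
    ``shift``/``mu`` solved so that E[X] = mean_ms and SD[X] = sd_ms.
    """

    mean_ms: float
    sd_ms: float
    sigma: float = 0.4

    def lognormal_parts(self) -> tuple[float, float]:
        scale = self.sd_ms / np.sqrt(np.expm1(self.sigma**2))  # E of lognormal part
        shift = self.mean_ms - scale
        mu = np.log(scale) - self.sigma**2 / 2.0
        return shift, mu

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        shift, mu = self.lognormal_parts()
        return shift + rng.lognormal(mu, self.sigma, size=n)


def _default_rt() -> dict:
    # population means/SDs follow the reported group behavior
    return {
        "go": RTParams(250.0, 100.0),
        "no-change": RTParams(358.0, 76.0),
        "no-nogo": RTParams(354.0, 84.0),
        "change": RTParams(403.0, 88.0),
    }


@dataclass
class BehaviorParams:
    """Generative error rates and RT distributions per derived condition."""

    rt: dict = field(default_factory=_default_rt)
    premature_rate: dict = field(
        default_factory=lambda: {"EG": 0.098, "EC": 0.0045, "EN": 0.0034}
    )
    omission_rate: dict = field(
        default_factory=lambda: {
            "go": 0.005, "no-change": 0.005, "no-nogo": 0.005, "change": 0.03,
        }
    )
    choice_error_rate: dict = field(
        default_factory=lambda: {
            "go": 0.005, "no-change": 0.005, "no-nogo": 0.005, "change": 0.06,
        }
    )
    failed_inhibition_rate: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            list(self.premature_rate.values())
            + list(self.omission_rate.values())
            + list(self.choice_error_rate.values())
            + [self.failed_inhibition_rate]
        )
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("all rates must lie in [0,1]")


def _other(hand: str) -> str:
    return "left" if hand == "right" else "right"


def simulate_behavior(
    trials: pd.DataFrame, params: BehaviorParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fill responses, RTs and correctness columns of a trial table.

    Premature responses are drawn per cue condition and occur before target
    onset (no RT recorded); on nogo trials a failed inhibition produces a
    standard-hand press. Deterministic under ``params.seed``.
    """
    if trials["response"].notna().any():
        raise ValueError("trial table already contains responses")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    tbl = trials.copy()
    dcond = derived_condition(tbl)
    tbl["derived_condition"] = dcond

    n = len(tbl)
    response = np.array([None] * n, dtype=object)
    rt = np.full(n, np.nan)
    correct = np.zeros(n, dtype=bool)

    u_pre = rng.random(n)
    pre_rate = tbl.condition.map(params.premature_rate).to_numpy(float)
    premature = u_pre < pre_rate

    for i in range(n):
        if premature[i]:
            response[i] = "premature"
            continue
        dc = dcond.iloc[i]
        hand = tbl.standard_hand.iloc[i]
        if dc == "nogo":
            if rng.random() < params.failed_inhibition_rate:
                response[i] = hand
                rt[i] = params.rt["go"].draw(rng, 1)[0]
            else:
                response[i] = "none"
                correct[i] = True
            continue
        correct_hand = _other(hand) if dc == "change" else hand
        if rng.random() < params.omission_rate[dc]:
            response[i] = "none"
        elif rng.random() < params.choice_error_rate[dc]:
            response[i] = _other(correct_hand)
            rt[i] = params.rt[dc].draw(rng, 1)[0]
        else:
            response[i] = correct_hand
            rt[i] = params.rt[dc].draw(rng, 1)[0]
            correct[i] = True

    tbl["response"] = response
    tbl["rt_ms"] = rt
    tbl["correct"] = correct
    return tbl


def behavioral_summary(trials: pd.DataFrame, by: str | None = "subject") -> pd.DataFrame:
    """Per-subject behavioral summary.

    Mean RT of correct responses per derived condition, accuracy per derived
    condition, premature rate per cue condition and the failed-inhibition
    rate. Conditions without a valid RT yield NaN (flagged missing), never 0.
    """
    tbl = trials.copy()
    if "derived_condition" not in tbl:
        tbl["derived_condition"] = derived_condition(tbl)
    if by is None or by not in tbl:
        tbl = tbl.assign(_subj=0)
        by = "_subj"
    rows = []
    for subj, g in tbl.groupby(by, sort=True):
        row: dict = {"subject": subj}
        for dc in ("go", "no-change", "no-nogo", "change"):
            sel = g[(g.derived_condition == dc) & g.correct & g.rt_ms.notna()]
            row[f"rt_{dc}"] = sel.rt_ms.mean() if len(sel) else np.nan
        for dc in DERIVED_CONDITIONS:
            sel = g[g.derived_condition == dc]
            # accuracy is judged among non-premature trials
            val = sel[sel.response != "premature"]
            row[f"acc_{dc}"] = val.correct.mean() if len(val) else np.nan
        for c in CONDITIONS:
            sel = g[g.condition == c]
            row[f"premature_{c}"] = (
                (sel.response == "premature").mean() if len(sel) else np.nan
            )
        nogo = g[g.derived_condition == "nogo"]
        nogo = nogo[nogo.response != "premature"]
        row["failed_inhibition"] = (
            (nogo.response != "none").mean() if len(nogo) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_trial_table(tbl: pd.DataFrame, path: str | Path) -> None:
    tbl.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t")
    if "correct" in tbl:
        tbl["correct"] = tbl["correct"].astype("boolean").astype(object)
    return tbl
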