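"""End-to-end orchestration: simulate -> preprocess -> CSD -> TFR -> PLV -> stats.

Two execution paths share the same computational code:

* :func:`run_stage` — file-based single-session stages with hash-linked
  manifests (EDF+ raw, epoch containers, TSV tables), for the numbered
  analysis scripts;
* :func:`run_replica` — the in-memory "replica study": a cohort of virtual
  subjects is simulated with the default injected effect structure, pushed
  through the full pipeline, and the group statistics of the original
  analyses are computed (binned paired t-tests with FDR over the cue-target
  interval, target-locked RM-ANOVA with Greenhouse-Geisser correction,
  Wilcoxon/FDR PLV contrasts, behavioral tests).

The default effect configuration encodes the qualitative ground-truth
pattern: contralateral mu/beta desynchronization in all conditions (deeper
and earlier when the standard action is certain), ipsilateral mu increase
for EG / near-baseline for EN / decrease for EC, a target-locked prefrontal
beta burst ordered go < no-change/no-nogo < change/nogo, and seed->frontal
alpha phase coupling that drops in EC. Magnitudes are configuration, not
claims about effect sizes.

One global seed expands into per-stage, per-subject substreams through
``numpy.random.SeedSequence`` spawning, so any stage can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import Montage, standard_montage
from .design import (
    DesignSpec, BehaviorParams, generate_design, simulate_behavior,
    behavioral_summary, write_trial_table, read_trial_table, CONDITIONS,
)
from .simulate import SourceSpec, RawEEG, simulate_session, inject_coupling_level
from .edf import read_edf
from .preprocess import (
    EpochSet, rereference, filter_raw, epoch, reject_amplitude, exclude_subjects,
)
from .csd import build_basis, csd_transform
from .timefreq import (
    WaveletParams, ROISet, condition_mean_energy, baseline_normalize,
    roi_band_timecourse, flip_hemispheres,
)
from .connectivity import instantaneous_phase, seed_plv_map, ALPHA_BAND, PLV_WINDOW
from . import stats as st

__all__ = [
    "EffectConfig", "PipelineConfig", "default_sources", "run_stage",
    "run_replica", "analyze_subject", "group_statistics", "replica_report",
    "ReplicaResult", "IntegrityError",
]

TARGET_ONSET_S = 1.1  # cue onset to target onset
TARGET_WINDOW = (0.2, 0.5)  # prefrontal beta analysis window, target-locked
EFFECT_WINDOW = (0.5, 1.1)  # late cue-target interval used for orderings


# --------------------------------------------------------------------------
# configuration


@dataclass
class EffectConfig:
    """Injected ground-truth effect structure (amplitude factors).

    Power change in percent corresponds to factor^2 - 1 (a factor 0.70 is a
    -51% power change). ``null`` switches every condition difference off
    while keeping overall source structure, for type-I calibration.
    """

    mu_amp_uv: float = 6.0
    beta_amp_uv: float = 4.0
    prefrontal_beta_amp_uv: float = 3.0
    frontal_alpha_amp_uv: float = 2.5
    # ipsilateral mu amplitude factors in the late cue-target interval
    mu_ipsi: dict = field(default_factory=lambda: {"EG": 1.15, "EN": 1.0, "EC": 0.70})
    # contralateral mu: (onset_s, settle_s, factor)
    mu_contra: dict = field(default_factory=lambda: {
        "EG": (0.2, 0.5, 0.72), "EC": (0.4, 0.8, 0.85), "EN": (0.4, 0.8, 0.85)})
    beta_ipsi: dict = field(default_factory=lambda: {"EG": 1.0, "EN": 1.0, "EC": 0.78})
    beta_contra: dict = field(default_factory=lambda: {
        "EG": (0.2, 0.5, 0.78), "EC": (0.4, 0.8, 0.88), "EN": (0.4, 0.8, 0.88)})
    # target-locked prefrontal beta burst amplitude factors
    prefrontal_burst: dict = field(default_factory=lambda: {
        "go": 1.15, "no-change": 1.35, "no-nogo": 1.35, "change": 1.60, "nogo": 1.60})
    # expected PLV of the seed->ipsilateral-frontal alpha coupling
    plv_ipsi: dict = field(default_factory=lambda: {"EG": 0.6, "EN": 0.6, "EC": 0.2})
    plv_contra: float = 0.6
    spatial_width: float = 0.45
    subject_gain_sd: float = 0.15  # log-sd of per-subject source amplitudes
    null: bool = False

    def nulled(self) -> "EffectConfig":
        """Copy with all condition differences removed (type-I calibration)."""
        c = EffectConfig(
            mu_amp_uv=self.mu_amp_uv, beta_amp_uv=self.beta_amp_uv,
            prefrontal_beta_amp_uv=self.prefrontal_beta_amp_uv,
            frontal_alpha_amp_uv=self.frontal_alpha_amp_uv,
            spatial_width=self.spatial_width,
            subject_gain_sd=self.subject_gain_sd, null=True)
        c.mu_ipsi = {k: 1.0 for k in c.mu_ipsi}
        c.mu_contra = {k: (0.3, 0.6, 0.85) for k in c.mu_contra}
        c.beta_ipsi = {k: 1.0 for k in c.beta_ipsi}
        c.beta_contra = {k: (0.3, 0.6, 0.88) for k in c.beta_contra}
        c.prefrontal_burst = {k: 1.35 for k in c.prefrontal_burst}
        c.plv_ipsi = {k: 0.5 for k in c.plv_ipsi}
        c.plv_contra = 0.5
        return c


def _kappa(plv: float) -> float:
    """Invert the von-Mises mean resultant length numerically."""
    if plv <= 0:
        return 0.0
    lo, hi = 1e-6, 700.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if inject_coupling_level(mid) < plv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_CUE_TO_DERIVED = {"EG": ["go"], "EC": ["no-change", "change"], "EN": ["no-nogo", "nogo"]}


def _expand_cue_keys(env_by_cue: dict) -> dict:
    """Copy cue-condition envelopes to every derived condition they cover."""
    out = {}
    for cue, env in env_by_cue.items():
        for dc in _CUE_TO_DERIVED[cue]:
            out[dc] = env
    return out


def _ramp_env(onset: float, settle: float, factor: float, amp: float):
    """Baseline-hold envelope ramping to amp*factor and recovering post-trial."""
    return ([-1.0, onset, settle, 1.7, 2.2], [amp, amp, amp * factor, amp * factor, amp])


def _late_env(factor: float, amp: float, onset: float = 0.35, settle: float = 0.7):
    return _ramp_env(onset, settle, factor, amp)


def _burst_env(peak: float, amp: float):
    t0 = TARGET_ONSET_S
    return (
        [t0 + 0.1, t0 + 0.2, t0 + 0.45, t0 + 0.65],
        [amp, amp * peak, amp * peak, amp],
    )


def default_sources(eff: EffectConfig, gains: dict | None = None) -> list[SourceSpec]:
    """Build the source list realizing the injected effect structure.

    ``gains`` maps source names to per-subject multiplicative amplitude
    factors (default 1).
    """
    g = gains or {}

    def env_scale(env, k):
        ts, vs = env
        return (ts, [v * g.get(k, 1.0) for v in vs])

    sources: list[SourceSpec] = []
    # mu sources at C3/C4: roles swap with the standard hand
    for elec, ipsi_hand in (("C4", "right"), ("C3", "left")):
        env = {}
        for cue in CONDITIONS:
            ipsi = _late_env(eff.mu_ipsi[cue], eff.mu_amp_uv)
            contra = _ramp_env(*eff.mu_contra[cue], eff.mu_amp_uv)
            other = "left" if ipsi_hand == "right" else "right"
            for dc in _CUE_TO_DERIVED[cue]:
                env[f"{dc}:{ipsi_hand}"] = env_scale(ipsi, f"mu_{elec}")
                env[f"{dc}:{other}"] = env_scale(contra, f"mu_{elec}")
        sources.append(SourceSpec(
            name=f"mu_{elec}", center_electrode=elec, band=(9.0, 14.0),
            envelope=env, spatial_width=eff.spatial_width))
    # beta sources at C3/C4
    for elec, ipsi_hand in (("C4", "right"), ("C3", "left")):
        env = {}
        for cue in CONDITIONS:
            ipsi = _late_env(eff.beta_ipsi[cue], eff.beta_amp_uv)
            contra = _ramp_env(*eff.beta_contra[cue], eff.beta_amp_uv)
            other = "left" if ipsi_hand == "right" else "right"
            for dc in _CUE_TO_DERIVED[cue]:
                env[f"{dc}:{ipsi_hand}"] = env_scale(ipsi, f"beta_{elec}")
                env[f"{dc}:{other}"] = env_scale(contra, f"beta_{elec}")
        sources.append(SourceSpec(
            name=f"beta_{elec}", center_electrode=elec, band=(15.0, 25.0),
            envelope=env, spatial_width=eff.spatial_width))
    # target-evoked prefrontal beta bursts, bilateral, not hand-dependent
    for elec in ("F5", "F6"):
        env = {dc: env_scale(_burst_env(p, eff.prefrontal_beta_amp_uv), f"pfb_{elec}")
               for dc, p in eff.prefrontal_burst.items()}
        sources.append(SourceSpec(
            name=f"pfb_{elec}", center_electrode=elec, band=(15.0, 25.0),
            envelope=env, spatial_width=eff.spatial_width))
    # frontal alpha sources phase-coupled to the same-side mu seed
    for elec, seed, seed_ipsi_hand in (("F6", "mu_C4", "right"), ("F5", "mu_C3", "left")):
        kap: dict = {}
        for cue in CONDITIONS:
            for dc in _CUE_TO_DERIVED[cue]:
                kap[f"{dc}:{seed_ipsi_hand}"] = _kappa(eff.plv_ipsi[cue])
                other = "left" if seed_ipsi_hand == "right" else "right"
                kap[f"{dc}:{other}"] = _kappa(eff.plv_contra)
        amp = eff.frontal_alpha_amp_uv * g.get(f"fa_{elec}", 1.0)
        env = {"default": ([-1.0, 1.2, 1.7], [amp, amp, amp])}
        sources.append(SourceSpec(
            name=f"fa_{elec}", center_electrode=elec, band=ALPHA_BAND,
            envelope=env, spatial_width=eff.spatial_width,
            phase_mode="coupled", seed_source=seed, concentration=kap))
    return sources


def _replica_design(seed: int, counterbalance: str) -> DesignSpec:
    """Scaled-down session: 2 blocks x 36 trials, hand switch in between.

    Keeps the exact condition structure (1/3 cues, exact 25% rare targets:
    12 trials per cue condition per block, 3 rare) at desk-scale runtime.
    """
    return DesignSpec(
        n_blocks=2, trials_per_block=36, hand_switch_block=1,
        counterbalance_order=counterbalance, seed=seed,
    )


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, serializable to YAML."""

    n_subjects: int = 22
    design: DesignSpec | None = None  # None -> per-subject scaled replica design
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise_scale_uv: float = 3.0
    noise_alpha: float = 1.0
    noise_spatial_mix: float = 0.5
    artifact_rate: float = 0.02
    highpass_hz: float = 0.5
    notch_hz: float = 50.0
    epoch_window: tuple = (-1.0, 2.0)
    dc_baseline: tuple = (-0.1, 0.0)
    reject_uv: float = 80.0
    exclude_fraction: float = 0.30
    csd_order_m: int = 4
    csd_n_terms: int = 50
    csd_lambda: float = 1e-5
    wavelet_f_b: float = 1.0
    wavelet_f_c: float = 1.5
    # replica grid covers the analyzed mu+beta bands; the full grid is 1-40 Hz
    freqs: tuple = tuple(float(f) for f in range(9, 26))
    rois: ROISet = field(default_factory=ROISet)
    plv_band: tuple = ALPHA_BAND
    plv_window: tuple = PLV_WINDOW
    fdr_q: float = 0.05
    seed: int = 0

    def wavelet_params(self) -> WaveletParams:
        return WaveletParams(self.wavelet_f_b, self.wavelet_f_c,
                             np.array(self.freqs), (-0.250, -0.050))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return _config_from_dict(d)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _config_from_dict(d: dict) -> PipelineConfig:
    from .design import RTParams

    kw = dict(d)
    if kw.get("design"):
        dd = dict(kw["design"])
        dd["iti_range_ms"] = tuple(dd["iti_range_ms"])
        kw["design"] = DesignSpec(**dd)
    if kw.get("behavior"):
        bd = dict(kw["behavior"])
        bd["rt"] = {k: RTParams(**v) if isinstance(v, dict) else v
                    for k, v in bd.get("rt", {}).items()}
        kw["behavior"] = BehaviorParams(**bd)
    if kw.get("effects"):
        ed = dict(kw["effects"])
        ed["mu_contra"] = {k: tuple(v) for k, v in ed["mu_contra"].items()}
        ed["beta_contra"] = {k: tuple(v) for k, v in ed["beta_contra"].items()}
        kw["effects"] = EffectConfig(**ed)
    if kw.get("rois"):
        kw["rois"] = ROISet(**kw["rois"])
    for key in ("epoch_window", "dc_baseline", "freqs", "plv_band", "plv_window"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return PipelineConfig(**kw)


# --------------------------------------------------------------------------
# per-subject pipeline


def _spawn_seed(root: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root, spawn_key=tuple(path))


def simulate_subject(cfg: PipelineConfig, subject: int, effects: EffectConfig | None = None):
    """Design + behavior + raw EEG for one virtual subject."""
    eff = effects if effects is not None else cfg.effects
    ss = _spawn_seed(cfg.seed, 0, subject)
    s_design, s_beh, s_eeg, s_gain = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    counterbalance = "RHB_first" if subject % 2 == 0 else "LHB_first"
    design = cfg.design if cfg.design is not None else _replica_design(s_design, counterbalance)
    trials = generate_design(design)
    beh = dataclasses.replace(cfg.behavior, seed=s_beh)
    trials = simulate_behavior(trials, beh)

    grng = np.random.default_rng(s_gain)
    gains = {name: float(grng.lognormal(0.0, eff.subject_gain_sd))
             for name in ("mu_C3", "mu_C4", "beta_C3", "beta_C4",
                          "pfb_F5", "pfb_F6", "fa_F5", "fa_F6")}
    montage = standard_montage()
    raw = simulate_session(
        trials, montage, default_sources(eff, gains),
        noise_scale=cfg.noise_scale_uv, seed=s_eeg, noise_alpha=cfg.noise_alpha,
        noise_spatial_mix=cfg.noise_spatial_mix,
        artifact_rate=cfg.artifact_rate, dtype=np.float32,
    )
    return trials, raw


def preprocess_subject(cfg: PipelineConfig, raw: RawEEG, trials: pd.DataFrame):
    """Re-reference, filter and build cue- and target-locked epoch sets."""
    raw = rereference(raw)
    raw = filter_raw(raw, cfg.highpass_hz, cfg.notch_hz)
    cue = epoch(raw, trials["cue_onset_s"].to_numpy(), cfg.epoch_window,
                cfg.dc_baseline, locking="cue", trial_meta=trials)
    tgt = epoch(raw, trials["target_onset_s"].to_numpy(), cfg.epoch_window,
                cfg.dc_baseline, locking="target", trial_meta=trials)
    cue = reject_amplitude(cue, cfg.reject_uv)
    tgt = reject_amplitude(tgt, cfg.reject_uv)
    return cue, tgt


def analyze_subject(cfg: PipelineConfig, subject: int, basis=None,
                    effects: EffectConfig | None = None) -> dict:
    """Full single-subject pipeline; returns the group-level feature set."""
    trials, raw = simulate_subject(cfg, subject, effects)
    montage = raw.montage
    cue, tgt = preprocess_subject(cfg, raw, trials)
    if basis is None:
        basis = build_basis(montage, cue.ch_names, cfg.csd_order_m,
                            cfg.csd_n_terms, cfg.csd_lambda)
    cue = csd_transform(cue, basis)
    # prefrontal target analysis is unflipped and needs only a short window
    tgt = csd_transform(tgt.crop(-0.6, 1.0), basis)

    lhb = (trials["standard_hand"] == "left").to_numpy()
    cue_f = flip_hemispheres(cue, montage, lhb)

    wp = cfg.wavelet_params()
    rois = cfg.rois.rois
    bands = cfg.rois.bands
    central = rois["left_central"] + rois["right_central"]
    prefrontal = rois["left_prefrontal"] + rois["right_prefrontal"]

    valid = trials["correct"].astype(bool).to_numpy() & (
        trials["response"] != "premature").to_numpy()
    cue_cond = np.where(valid, trials["condition"].to_numpy(object), None)
    feats: dict = {"subject": subject}
    feats["rejection_fraction"] = float(cue.rejected.mean())
    feats["behavior"] = behavioral_summary(trials, by=None).iloc[0]

    # sensorimotor mu/beta, flipped frame: ipsi = right hemisphere
    energy = condition_mean_energy(cue_f, cue_cond, wp, central, list(CONDITIONS))
    for cond, tfr in energy.items():
        pct = baseline_normalize(tfr, params=wp)
        for band in ("mu", "beta"):
            feats[f"{band}_ipsi_{cond}"] = roi_band_timecourse(
                pct, rois["right_central"], bands[band])
            feats[f"{band}_contra_{cond}"] = roi_band_timecourse(
                pct, rois["left_central"], bands[band])
    feats["times_cue"] = energy[CONDITIONS[0]].times

    # prefrontal beta, unflipped, cue-locked (beta-band grid only)
    bsel = (wp.freqs >= bands["beta"][0]) & (wp.freqs <= bands["beta"][1])
    wp_beta = WaveletParams(wp.f_b, wp.f_c, wp.freqs[bsel], wp.baseline_window)
    energy_pf = condition_mean_energy(cue, cue_cond, wp_beta, prefrontal, list(CONDITIONS))
    for cond, tfr in energy_pf.items():
        pct = baseline_normalize(tfr, params=wp)
        for side in ("left", "right"):
            feats[f"pf_beta_{side}_{cond}"] = roi_band_timecourse(
                pct, rois[f"{side}_prefrontal"], bands["beta"])

    # prefrontal beta, unflipped, target-locked 200-500 ms
    dcond = np.where(valid, trials["derived_condition"].to_numpy(object), None)
    dlevels = ["go", "no-change", "no-nogo", "change", "nogo"]
    energy_t = condition_mean_energy(tgt, dcond, wp_beta, prefrontal, dlevels)
    tsel = (energy_t["go"].times >= TARGET_WINDOW[0]) & (
        energy_t["go"].times < TARGET_WINDOW[1])
    for cond, tfr in energy_t.items():
        if tfr.meta["n_trials"] == 0:
            continue
        pct = baseline_normalize(tfr, params=wp)
        for side in ("left", "right"):
            tc = roi_band_timecourse(pct, rois[f"{side}_prefrontal"], bands["beta"])
            feats[f"pf_target_{side}_{cond}"] = float(tc[tsel].mean())

    # alpha PLV, flipped frame, CSD signals; equalized trial counts.
    # Phases are computed on a cropped segment with a >=0.5 s guard around
    # the 900-1100 ms window, which dominates the per-subject runtime.
    seg = cue_f.crop(cfg.plv_window[0] - 0.6, cfg.plv_window[1] + 0.6)
    phase, margin = instantaneous_phase(seg, cfg.plv_band)
    keep = cue_f.kept()
    counts = {c: int(np.sum(keep & (cue_cond == c))) for c in CONDITIONS}
    n_eq = min(counts.values())
    prng = np.random.default_rng(
        int(_spawn_seed(cfg.seed, 1, subject).generate_state(1)[0] % (2**31)))
    for seed_elec, tag in (("C4", "ipsi"), ("C3", "contra")):
        for cond in CONDITIONS:
            sel = keep & (cue_cond == cond)
            m = seed_plv_map(seg, seed_elec, cfg.plv_band, cfg.plv_window,
                             trials=sel, n_equalize=n_eq, rng=prng,
                             phase=phase, margin=margin)
            feats[f"plv_{tag}_{cond}"] = m.plv
    feats["plv_electrodes"] = list(cue_f.ch_names)
    feats["n_trials_plv"] = n_eq
    return feats


# --------------------------------------------------------------------------
# group statistics and report


@dataclass
class ReplicaResult:
    features: list
    behavior: pd.DataFrame
    behavior_tests: dict
    bin_tables: dict  # family name -> DataFrame
    anova_tables: dict
    plv_tables: dict
    correlations: dict
    excluded: list
    times: np.ndarray
    config: PipelineConfig


_BIN_FAMILIES = [
    ("mu_ipsi", "EC", "EG"), ("mu_ipsi", "EN", "EG"), ("mu_ipsi", "EC", "EN"),
    ("mu_contra", "EC", "EG"), ("mu_contra", "EN", "EG"), ("mu_contra", "EC", "EN"),
    ("beta_ipsi", "EC", "EG"), ("beta_ipsi", "EN", "EG"), ("beta_ipsi", "EC", "EN"),
    ("beta_contra", "EC", "EG"), ("beta_contra", "EN", "EG"), ("beta_contra", "EC", "EN"),
    ("pf_beta_left", "EC", "EG"), ("pf_beta_left", "EN", "EG"), ("pf_beta_left", "EC", "EN"),
    ("pf_beta_right", "EC", "EG"), ("pf_beta_right", "EN", "EG"), ("pf_beta_right", "EC", "EN"),
]


def group_statistics(feats: list[dict], cfg: PipelineConfig) -> ReplicaResult:
    """Group-level inference over the per-subject feature sets."""
    frac = {f["subject"]: f["rejection_fraction"] for f in feats}
    kept_ids, excluded = exclude_subjects(frac, cfg.exclude_fraction)
    feats = [f for f in feats if f["subject"] in kept_ids]
    times = feats[0]["times_cue"]

    behavior = pd.DataFrame([f["behavior"] for f in feats]).reset_index(drop=True)
    behavior["subject"] = [f["subject"] for f in feats]
    rt = behavior[["rt_go", "rt_no-change", "rt_no-nogo", "rt_change"]].to_numpy()
    beh_tests = {"rt_anova": st.rm_anova_oneway(rt)}
    pairs = [("go", "no-change"), ("go", "no-nogo"), ("go", "change"),
             ("no-change", "change"), ("no-nogo", "change"), ("no-change", "no-nogo")]
    for a, b in pairs:
        beh_tests[f"rt_{a}_vs_{b}"] = st.paired_t(
            behavior[f"rt_{a}"].to_numpy(), behavior[f"rt_{b}"].to_numpy())
    pre = behavior[["premature_EG", "premature_EC", "premature_EN"]].to_numpy()
    beh_tests["premature_anova"] = st.rm_anova_oneway(pre)
    for a, b in [("EG", "EC"), ("EG", "EN"), ("EC", "EN")]:
        beh_tests[f"premature_{a}_vs_{b}"] = st.paired_t(
            behavior[f"premature_{a}"].to_numpy(), behavior[f"premature_{b}"].to_numpy())

    bin_tables = {}
    for measure, a, b in _BIN_FAMILIES:
        xa = np.vstack([f[f"{measure}_{a}"] for f in feats])
        xb = np.vstack([f[f"{measure}_{b}"] for f in feats])
        name = f"{measure}:{a}-{b}"
        bin_tables[name] = st.binned_contrast(xa, xb, times, q=cfg.fdr_q, label=name)

    anova_tables = {}
    # proactive: go vs no-change vs no-nogo x hemisphere; reactive adds change/nogo
    def cube(conds):
        rows = []
        for f in feats:
            if any(f"pf_target_left_{c}" not in f for c in conds):
                continue
            rows.append([[f[f"pf_target_{s}_{c}"] for s in ("left", "right")]
                         for c in conds])
        return np.array(rows)

    proa = cube(["go", "no-change", "no-nogo"])
    reac = cube(["go", "change", "nogo"])
    anova_tables["target_proactive"] = st.rm_anova_twoway(proa)
    anova_tables["target_reactive"] = st.rm_anova_twoway(reac)
    # pooled reactive contrast: change/nogo vs no-change/no-nogo (F = t^2)
    pooled_rare = cube(["change", "nogo"]).mean(axis=(1, 2))
    pooled_std = cube(["no-change", "no-nogo"]).mean(axis=(1, 2))
    tres = st.paired_t(pooled_rare, pooled_std)
    anova_tables["target_pooled_update"] = tres
    means = {c: float(cube([c]).mean()) for c in
             ("go", "no-change", "no-nogo", "change", "nogo")}
    anova_tables["target_means"] = means

    plv_tables = {}
    electrodes = feats[0]["plv_electrodes"]
    for tag in ("ipsi", "contra"):
        seed = "C4" if tag == "ipsi" else "C3"
        for a, b in [("EC", "EG"), ("EN", "EG"), ("EC", "EN")]:
            pa = np.vstack([f[f"plv_{tag}_{a}"] for f in feats])
            pb = np.vstack([f[f"plv_{tag}_{b}"] for f in feats])
            name = f"plv_{tag}:{a}-{b}"
            plv_tables[name] = st.plv_contrast(pa, pb, electrodes, q=cfg.fdr_q,
                                               label=name, skip=(seed,))

    correlations = {}
    rare_beta = pooled_rare - pooled_std
    rt_change = behavior["rt_change"].to_numpy()
    ok = np.isfinite(rare_beta) & np.isfinite(rt_change)
    if ok.sum() >= 3:
        correlations["beta_update_vs_rt_change"] = st.power_rt_correlation(
            rare_beta[ok], rt_change[ok])
        correlations["beta_change_vs_rt_change"] = st.power_rt_correlation(
            cube(["change"]).mean(axis=(1, 2))[ok], rt_change[ok])

    return ReplicaResult(
        features=feats, behavior=behavior, behavior_tests=beh_tests,
        bin_tables=bin_tables, anova_tables=anova_tables, plv_tables=plv_tables,
        correlations=correlations, excluded=excluded, times=times, config=cfg,
    )


def run_replica(cfg: PipelineConfig, effects: EffectConfig | None = None,
                progress: bool = False) -> ReplicaResult:
    """Simulate and analyze the whole virtual cohort."""
    montage = standard_montage()
    analysis = [l for l in montage.labels if l not in ("A1", "A2")]
    basis = build_basis(montage, analysis, cfg.csd_order_m, cfg.csd_n_terms,
                        cfg.csd_lambda)
    feats = []
    for s in range(cfg.n_subjects):
        t0 = time.time()
        feats.append(analyze_subject(cfg, s, basis=basis, effects=effects))
        if progress:
            print(f"subject {s}: {time.time() - t0:.1f} s", flush=True)
    return group_statistics(feats, cfg)


# -- qualitative-pattern evaluation (used by the replica report and tests) --


def effect_window_means(result: ReplicaResult, measure: str) -> dict:
    t = result.times
    sel = (t >= EFFECT_WINDOW[0]) & (t < EFFECT_WINDOW[1])
    return {c: float(np.mean([f[f"{measure}_{c}"][sel] for f in result.features]))
            for c in CONDITIONS}


def qualitative_pattern(result: ReplicaResult) -> dict:
    """Does the replica reproduce the reported direction of each key effect?"""
    mu = effect_window_means(result, "mu_ipsi")
    tbl = result.bin_tables["mu_ipsi:EC-EG"]
    late = tbl[tbl.bin_start_s >= EFFECT_WINDOW[0] - 1e-9]
    out = {
        "mu_ipsi_ordering": mu["EC"] < mu["EN"] < mu["EG"],
        "mu_ipsi_EC_EG_fdr": bool(late.significant.any()),
    }
    m = result.anova_tables["target_means"]
    rare = 0.5 * (m["change"] + m["nogo"])
    std = 0.5 * (m["no-change"] + m["no-nogo"])
    cond_eff = [e for e in result.anova_tables["target_proactive"]
                if e.name == "Condition"][0]
    out["pf_ordering"] = rare > std > m["go"]
    out["pf_condition_sig"] = bool(
        cond_eff.p < 0.05 and result.anova_tables["target_pooled_update"].p < 0.05
        and result.anova_tables["target_pooled_update"].mean_diff > 0)
    ec_eg = result.plv_tables["plv_ipsi:EC-EG"]
    hit = ec_eg[ec_eg.significant & (ec_eg.median_diff < 0)]
    out["plv_EC_drop"] = bool(len(hit) > 0)
    out["all"] = all(v for k, v in out.items())
    return out


def significant_family_count(result: ReplicaResult) -> tuple[int, int]:
    """(families with any FDR/alpha significance, total families).

    Families: each binned contrast (significant iff any FDR-significant
    bin), each PLV contrast (any FDR-significant connection), and the two
    target ANOVA Condition effects plus the pooled update test at alpha=.05.
    """
    sig = total = 0
    for tbl in result.bin_tables.values():
        total += 1
        sig += bool(tbl.significant.any())
    for tbl in result.plv_tables.values():
        total += 1
        sig += bool(tbl.significant.any())
    for key in ("target_proactive", "target_reactive"):
        total += 1
        cond = [e for e in result.anova_tables[key] if e.name == "Condition"][0]
        sig += bool(cond.p < 0.05)
    total += 1
    sig += bool(result.anova_tables["target_pooled_update"].p < 0.05)
    return sig, total


def replica_report(result: ReplicaResult) -> str:
    """Human-readable report mirroring the original result tables."""
    L: list[str] = []
    cfg = result.config
    L.append("Replica study report")
    L.append("====================")
    L.append(f"subjects analyzed: {len(result.features)}"
             f" (excluded for >30% rejected trials: {len(result.excluded)})")
    L.append("")
    L.append("Behavior")
    L.append("--------")
    rt = result.behavior[["rt_go", "rt_no-change", "rt_no-nogo", "rt_change"]]
    for c in rt.columns:
        L.append(f"  mean RT {c[3:]:>10}: {rt[c].mean():6.1f} +/- {rt[c].std():5.1f} ms")
    a = result.behavior_tests["rt_anova"]
    L.append(f"  RT Condition: F({a.df1},{a.df2}) = {a.F:.1f}, p = {a.p:.2g} (GG)")
    t = result.behavior_tests["rt_go_vs_change"]
    L.append(f"  go vs change: t({t.df}) = {t.t:.1f}, p = {t.p:.2g}")
    pa = result.behavior_tests["premature_anova"]
    L.append(f"  premature Condition: F({pa.df1},{pa.df2}) = {pa.F:.1f}, p = {pa.p:.2g}")
    L.append("")
    L.append("Cue-target interval (100-ms bins, 200-1100 ms, paired t + FDR)")
    L.append("---------------------------------------------------------------")
    for name, tbl in result.bin_tables.items():
        nb = int(tbl.significant.sum())
        stars = "*" if nb else " "
        first = tbl[tbl.significant].bin_start_s.min() if nb else float("nan")
        L.append(f"  {name:<24} significant bins: {nb}/9"
                 + (f" (from {first*1000:.0f} ms){stars}" if nb else ""))
    mu = effect_window_means(result, "mu_ipsi")
    L.append(f"  ipsilateral mu 500-1100 ms: EC {mu['EC']:+.1f}%"
             f"  EN {mu['EN']:+.1f}%  EG {mu['EG']:+.1f}%")
    L.append("")
    L.append("Target-locked prefrontal beta (200-500 ms, RM-ANOVA, GG-corrected)")
    L.append("-------------------------------------------------------------------")
    m = result.anova_tables["target_means"]
    L.append("  mean power: " + "  ".join(f"{k} {v:+.1f}%" for k, v in m.items()))
    for key in ("target_proactive", "target_reactive"):
        for e in result.anova_tables[key]:
            L.append(f"  {key[7:]:<10} {e.name:<24} F({e.df1},{e.df2}) = {e.F:6.2f},"
                     f" eps = {e.epsilon:.2f}, p = {e.p:.3g}")
    tp = result.anova_tables["target_pooled_update"]
    L.append(f"  change/nogo vs no-change/no-nogo: t({tp.df}) = {tp.t:.2f},"
             f" p = {tp.p:.3g} (F = t^2 = {tp.t**2:.2f})")
    for k, (r, p) in result.correlations.items():
        L.append(f"  correlation {k}: r = {r:+.2f}, p = {p:.2g}")
    L.append("")
    L.append("Alpha phase coupling 900-1100 ms (Wilcoxon + FDR per contrast)")
    L.append("---------------------------------------------------------------")
    for name, tbl in result.plv_tables.items():
        hits = tbl[tbl.significant]
        desc = ", ".join(f"{r.electrode}({r.median_diff:+.2f})"
                         for r in hits.itertuples()) or "none"
        L.append(f"  {name:<20} significant connections: {len(hits):2d}  {desc}")
    L.append("")
    q = qualitative_pattern(result)
    L.append("Qualitative pattern vs injected ground truth")
    L.append("---------------------------------------------")
    for k, v in q.items():
        L.append(f"  {k:<22} {'PASS' if v else 'FAIL'}")
    if cfg.effects.null or (result.features and cfg.effects.null):
        sig, total = significant_family_count(result)
        L.append(f"  null families significant: {sig}/{total}")
    return "\n".join(L)


# --------------------------------------------------------------------------
# file-based staged execution with hash-linked manifests


class IntegrityError(RuntimeError):
    pass


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


_STAGE_INPUTS = {
    "simulate": [],
    "preprocess": ["session.edf", "trials.tsv"],
    "csd": ["epochs_cue.json", "epochs_cue.f32"],
    "tfr": ["epochs_cue_csd.json", "epochs_cue_csd.f32", "trials.tsv"],
    "plv": ["epochs_cue_csd.json", "epochs_cue_csd.f32", "trials.tsv"],
}


def _check_upstream(workdir: Path, inputs: list[str]) -> dict:
    recorded = {}
    for mf in workdir.glob("manifest_*.json"):
        man = json.loads(mf.read_text())
        recorded.update(man.get("outputs", {}))
    hashes = {}
    for name in inputs:
        p = workdir / name
        if not p.exists():
            raise IntegrityError(f"missing upstream artifact: {name}")
        h = _sha(p)
        if name in recorded and recorded[name] != h:
            raise IntegrityError(f"upstream artifact modified since creation: {name}")
        hashes[name] = h
    return hashes


def run_stage(name: str, cfg: PipelineConfig, workdir, subject: int = 0) -> dict:
    """Run one file-based stage for a single subject's session.

    Verifies upstream artifact hashes against their manifests before
    computing, and writes ``manifest_<stage>.json`` (parameters, seed, input
    and output hashes) afterwards. Rerunning a stage with identical inputs
    is bit-identical for exact stages.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if name not in _STAGE_INPUTS:
        raise ValueError(f"unknown stage {name!r}")
    in_hashes = _check_upstream(workdir, _STAGE_INPUTS[name])
    outputs: list[str] = []

    if name == "simulate":
        trials, raw = simulate_subject(cfg, subject)
        write_trial_table(trials, workdir / "trials.tsv")
        (cfg.design or _replica_design(0, "RHB_first")).to_json(workdir / "design.json")
        raw.to_edf(workdir / "session.edf")
        outputs = ["trials.tsv", "design.json", "session.edf"]
    elif name == "preprocess":
        data, srate, ch_names, events = read_edf(workdir / "session.edf")
        trials = read_trial_table(workdir / "trials.tsv")
        raw = RawEEG(data, srate, ch_names, events, montage=standard_montage())
        cue, tgt = preprocess_subject(cfg, raw, trials)
        cue.save(workdir / "epochs_cue")
        tgt.save(workdir / "epochs_target")
        cue.rejection_log(workdir / "rejection_log.tsv")
        outputs = ["epochs_cue.json", "epochs_cue.f32", "epochs_cue.tsv",
                   "epochs_target.json", "epochs_target.f32", "epochs_target.tsv",
                   "rejection_log.tsv"]
    elif name == "csd":
        cue = EpochSet.load(workdir / "epochs_cue")
        montage = standard_montage()
        basis = build_basis(montage, cue.ch_names, cfg.csd_order_m,
                            cfg.csd_n_terms, cfg.csd_lambda)
        csd_transform(cue, basis).save(workdir / "epochs_cue_csd")
        outputs = ["epochs_cue_csd.json", "epochs_cue_csd.f32"]
    elif name == "tfr":
        cue = EpochSet.load(workdir / "epochs_cue_csd")
        trials = read_trial_table(workdir / "trials.tsv")
        montage = standard_montage()
        lhb = (trials["standard_hand"] == "left").to_numpy()
        cue_f = flip_hemispheres(cue, montage, lhb)
        wp = cfg.wavelet_params()
        rois = cfg.rois.rois
        central = rois["left_central"] + rois["right_central"]
        cond = trials["condition"].to_numpy(object)
        energy = condition_mean_energy(cue_f, cond, wp, central, list(CONDITIONS))
        rows = []
        for c, tfr in energy.items():
            pct = baseline_normalize(tfr, params=wp)
            for band in ("mu", "beta"):
                for side, roi in (("ipsi", rois["right_central"]),
                                  ("contra", rois["left_central"])):
                    tc = roi_band_timecourse(pct, roi, cfg.rois.bands[band])
                    for t, v in zip(pct.times, tc):
                        rows.append({"condition": c, "band": band, "side": side,
                                     "time_s": t, "percent": v})
        pd.DataFrame(rows).to_csv(workdir / "roi_power.tsv", sep="\t", index=False)
        outputs = ["roi_power.tsv"]
    elif name == "plv":
        cue = EpochSet.load(workdir / "epochs_cue_csd")
        trials = read_trial_table(workdir / "trials.tsv")
        montage = standard_montage()
        lhb = (trials["standard_hand"] == "left").to_numpy()
        cue_f = flip_hemispheres(cue, montage, lhb)
        phase, margin = instantaneous_phase(cue_f, cfg.plv_band)
        cond = trials["condition"].to_numpy(object)
        keep = cue_f.kept()
        n_eq = min(int(np.sum(keep & (cond == c))) for c in CONDITIONS)
        rng = np.random.default_rng(cfg.seed)
        rows = []
        for seed_elec in ("C4", "C3"):
            for c in CONDITIONS:
                m = seed_plv_map(cue_f, seed_elec, cfg.plv_band, cfg.plv_window,
                                 trials=keep & (cond == c), n_equalize=n_eq,
                                 rng=rng, phase=phase, margin=margin)
                for e, v in zip(m.electrodes, m.plv):
                    rows.append({"seed": seed_elec, "condition": c,
                                 "electrode": e, "plv": v})
        pd.DataFrame(rows).to_csv(workdir / "plv.tsv", sep="\t", index=False)
        outputs = ["plv.tsv"]

    manifest = {
        "stage": name,
        "seed": cfg.seed,
        "subject": subject,
        "params_hash": hashlib.sha256(
            json.dumps(_to_plain(cfg), sort_keys=True).encode()).hexdigest(),
        "inputs": in_hashes,
        "outputs": {o: _sha(workdir / o) for o in outputs},
    }
    (workdir / f"manifest_{name}.json").write_text(json.dumps(manifest, indent=2))
    return manifest
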