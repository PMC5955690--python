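"""Synthetic multichannel EEG with known oscillatory ground truth.

A session is a sum of band-limited oscillatory sources projected onto the
scalp through Gaussian spatial topographies, on top of 1/f (pink) background
noise. Each source carries a piecewise-linear amplitude envelope that can
differ between task conditions (and response hands), which is how
condition-dependent mu/beta (de)synchronization and target-evoked prefrontal
beta bursts are injected as ground truth. Sources may be phase-coupled to a
seed source through per-trial von-Mises phase offsets, giving a controllable
ground-truth phase-locking value (the expected PLV of concentration kappa is
I1(kappa)/I0(kappa)).

Oscillations are synthesized as band-limited filtered Gaussian noise rather
than sinusoids, so band power (not a line spectrum) carries the effect.
Earlobe reference channels A1/A2 carry near-zero signal so re-referencing is
exercised realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
from scipy.signal import hilbert
from scipy.special import i0, i1

from .montage import Montage, REFERENCE_CHANNELS
from .edf import write_edf

__all__ = [
    "SourceSpec",
    "RawEEG",
    "topography",
    "simulate_session",
    "inject_coupling_level",
    "pink_noise",
    "band_noise",
]


@dataclass
class SourceSpec:
    """One oscillatory source.

    ``envelope`` maps a condition key to piecewise-linear (times_s, amps_uV)
    breakpoints, times relative to cue onset; amplitude is held at the first/
    last breakpoint value outside the span. Keys may be derived-condition
    labels (``go``, ``change``, ...) or ``"<cond>:<hand>"`` for hand-specific
    envelopes; lookup tries ``cond:hand`` first, then ``cond``, then
    ``default``. ``phase_mode`` is ``independent`` or ``coupled``; coupled
    sources replay the seed source's instantaneous phase shifted by a
    per-trial von-Mises offset with condition-dependent ``concentration``.
    """

    name: str
    center_electrode: str
    band: tuple[float, float]
    envelope: dict = field(default_factory=dict)
    spatial_width: float = 0.6  # radians
    phase_mode: str = "independent"  # or "coupled"
    seed_source: str | None = None
    concentration: dict | float = 5.0
    phase_lag: float = 0.0

    def __post_init__(self) -> None:
        if self.band[0] <= 0 or self.band[1] <= self.band[0]:
            raise ValueError("band must be an increasing positive interval")
        for key, (ts, vs) in self.envelope.items():
            if np.any(np.asarray(vs) < 0):
                raise ValueError(f"negative envelope amplitude for {key!r}")
        if self.phase_mode not in ("independent", "coupled"):
            raise ValueError("phase_mode must be 'independent' or 'coupled'")
        if self.phase_mode == "coupled" and not self.seed_source:
            raise ValueError("coupled source needs a seed_source")

    def envelope_for(self, condition: str, hand: str):
        for key in (f"{condition}:{hand}", condition, "default"):
            if key in self.envelope:
                return self.envelope[key]
        return ([0.0], [0.0])

    def kappa_for(self, condition: str, hand: str) -> float:
        if isinstance(self.concentration, dict):
            for key in (f"{condition}:{hand}", condition, "default"):
                if key in self.concentration:
                    return float(self.concentration[key])
            return 0.0
        return float(self.concentration)


@dataclass
class RawEEG:
    """Continuous multichannel record in microvolts with event annotations."""

    data: np.ndarray  # channels x samples
    srate: float
    ch_names: list[str]
    events: list[tuple[float, str]]
    montage: Montage | None = None

    def __post_init__(self) -> None:
        dur = self.data.shape[1] / self.srate
        for t, _ in self.events:
            if not 0 <= t <= dur:
                raise ValueError(f"event at {t} s outside the {dur:.1f} s record")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawEEG":
        return RawEEG(self.data.copy(), self.srate, list(self.ch_names),
                      list(self.events), self.montage)

    def to_edf(self, path) -> None:
        write_edf(path, self.data, self.srate, self.ch_names, self.events)


def topography(montage: Montage, source: SourceSpec) -> np.ndarray:
    """Gaussian-in-angular-distance channel weights, 1 at the center."""
    ang = montage.angular_distances(source.center_electrode)
    if source.spatial_width <= 0:
        return (ang == 0).astype(float)
    w = np.exp(-(ang**2) / (2.0 * source.spatial_width**2))
    # reference channels never carry source signal
    for ref in REFERENCE_CHANNELS:
        if ref in montage.labels:
            w[montage.index(ref)] = 0.0
    return w


def pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int,
    srate: float, alpha: float = 1.0, dtype=np.float64,
) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum, unit per-channel RMS."""
    import scipy.fft

    freqs = np.fft.rfftfreq(n_samples, 1.0 / srate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    ctype = np.complex64 if dtype == np.float32 else np.complex128
    spec = (
        rng.standard_normal((n_channels, len(freqs)))
        + 1j * rng.standard_normal((n_channels, len(freqs)))
    ).astype(ctype) * amp.astype(dtype)
    spec[:, 0] = 0.0
    x = scipy.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def band_noise(
    rng: np.random.Generator, n_samples: int, srate: float,
    band: tuple[float, float], taper_hz: float = 1.0,
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (cosine-tapered FFT mask)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / srate)
    lo, hi = band
    mask = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    mask[inside] = 1.0
    for edge, sgn in ((lo, -1), (hi, 1)):
        ramp = (freqs - edge) * sgn
        sel = (ramp > 0) & (ramp < taper_hz)
        mask[sel] = 0.5 * (1 + np.cos(np.pi * ramp[sel] / taper_hz))
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * mask
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    return x / np.sqrt(np.mean(x**2))


def inject_coupling_level(concentration: float) -> float:
    """Expected PLV of a von-Mises phase jitter with given concentration.

    The mean resultant length of vonMises(mu, kappa) is I1(kappa)/I0(kappa);
    kappa=0 gives uniform phases (PLV 0), kappa->inf gives PLV 1.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    if concentration > 700:  # avoid overflow; ratio is ~1 - 1/(2k)
        return 1.0 - 1.0 / (2.0 * concentration)
    return float(i1(concentration) / i0(concentration))


def _sample_conditions(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial condition key: derived condition when available, else cue."""
    if "derived_condition" in trials:
        cond = trials["derived_condition"].to_numpy(object)
    else:
        cond = trials["condition"].to_numpy(object)
    hand = trials["standard_hand"].to_numpy(object)
    return cond, hand


def simulate_session(
    trials: pd.DataFrame,
    montage: Montage,
    sources: list[SourceSpec],
    noise_scale: float = 3.0,
    seed: int = 0,
    srate: float = 250.0,
    noise_alpha: float = 1.0,
    noise_spatial_mix: float = 0.5,
    tail_s: float = 3.5,
    artifact_rate: float = 0.0,
    artifact_amp_uv: float = 150.0,
    dtype=np.float64,
) -> RawEEG:
    """Synthesize a continuous session for one subject.

    The record is Sum_sources topography x (envelope-modulated band noise)
    plus pink noise of RMS ``noise_scale`` uV per channel; cue and target
    events are annotated for every trial. ``noise_spatial_mix`` blends in a
    spatially smoothed copy of the background noise (volume-conduction-like
    inter-channel correlation; 0 keeps channels independent). Optional
    square-pulse artifacts (Bernoulli per trial) exercise the amplitude
    rejector downstream.
    """
    rng = np.random.default_rng(seed)
    nyq = srate / 2.0
    for s in sources:
        if s.band[1] >= nyq:
            raise ValueError(f"source {s.name!r} band exceeds Nyquist ({nyq} Hz)")

    cues = trials["cue_onset_s"].to_numpy(float)
    targets = trials["target_onset_s"].to_numpy(float)
    # pad to an FFT-friendly length: noise synthesis and analytic phases run
    # whole-record transforms, and awkward (prime) lengths are several times
    # slower without changing the result in the recorded span
    n_samples = scipy.fft.next_fast_len(int(np.ceil((targets.max() + tail_s) * srate)))
    if cues.min() < 1.0:
        raise ValueError("first cue onset must leave >= 1 s of pre-trial record")
    t = np.arange(n_samples) / srate
    # each sample belongs to the nearest preceding trial (from 0.9 s pre-cue)
    owner = np.clip(np.searchsorted(cues - 0.9, t, side="right") - 1, 0, len(cues) - 1)
    t_rel = t - cues[owner]
    cond, hand = _sample_conditions(trials)

    n_ch = len(montage.labels)
    data = np.zeros((n_ch, n_samples), dtype=dtype)

    carriers: dict[str, np.ndarray] = {}
    phases: dict[str, np.ndarray] = {}
    for s in sources:
        if s.phase_mode == "independent":
            carriers[s.name] = band_noise(rng, n_samples, srate, s.band)

    for s in sources:
        if s.phase_mode == "independent":
            carrier = carriers[s.name]
        else:
            if s.seed_source not in carriers:
                raise ValueError(f"coupled source {s.name!r}: unknown seed {s.seed_source!r}")
            if s.seed_source not in phases:
                phases[s.seed_source] = hilbert(carriers[s.seed_source])
            kappas = np.array([s.kappa_for(c, h) for c, h in zip(cond, hand)])
            offsets = np.where(
                np.isinf(kappas), 0.0, rng.vonmises(0.0, np.maximum(kappas, 1e-12))
            )
            offsets = np.where(kappas <= 0, rng.uniform(-np.pi, np.pi, len(kappas)), offsets)
            # rotate the seed's analytic signal: spectrum (hence band) is
            # preserved exactly, so the injected phase offset survives the
            # band-pass + Hilbert estimation downstream without distortion
            rot = np.exp(1j * (offsets[owner] + s.phase_lag))
            carrier = (phases[s.seed_source] * rot).real  # unit RMS

        amp = np.empty(n_samples)
        env_cache: dict[tuple, tuple] = {}
        for k in range(len(trials)):
            key = (cond[k], hand[k])
            if key not in env_cache:
                ts, vs = s.envelope_for(*key)
                env_cache[key] = (np.asarray(ts, float), np.asarray(vs, float))
        # vectorized per-trial interpolation: group samples by envelope identity
        env_id = np.array([id(env_cache[(c, h)]) for c, h in zip(cond, hand)])
        for uid in np.unique(env_id):
            sel = env_id[owner] == uid
            ts, vs = next(v for (c, h), v in env_cache.items()
                          if id(env_cache[(c, h)]) == uid)
            amp[sel] = np.interp(t_rel[sel], ts, vs) if len(ts) else 0.0

        w = topography(montage, s)
        active = np.flatnonzero(w > 1e-3)
        data[active] += w[active, None] * (amp * carrier)[None, :]

    if noise_scale > 0:
        noise = pink_noise(rng, n_ch, n_samples, srate, noise_alpha, dtype=dtype)
        if noise_spatial_mix > 0:
            cosang = np.clip(montage.positions @ montage.positions.T, -1, 1)
            K = np.exp(-(np.arccos(cosang) ** 2) / (2 * 0.35**2)).astype(noise.dtype)
            K /= K.sum(axis=1, keepdims=True)
            noise = (1 - noise_spatial_mix) * noise + noise_spatial_mix * (K @ noise)
            noise /= np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
        data += noise_scale * noise
    # reference channels: only a sliver of instrument noise
    for ref in REFERENCE_CHANNELS:
        if ref in montage.labels:
            i = montage.index(ref)
            data[i] = 0.05 * rng.standard_normal(n_samples)

    if artifact_rate > 0:
        hit = rng.random(len(trials)) < artifact_rate
        for k in np.flatnonzero(hit):
            start = int((cues[k] + rng.uniform(-0.5, 1.5)) * srate)
            width = int(0.2 * srate)
            ch = rng.integers(0, n_ch - len(REFERENCE_CHANNELS))
            data[ch, start : start + width] += artifact_amp_uv

    events: list[tuple[float, str]] = []
    for k in range(len(trials)):
        events.append((float(cues[k]), f"cue/{trials['condition'].iloc[k]}"))
        events.append((float(targets[k]), f"target/{trials['target_type'].iloc[k]}"))
    return RawEEG(data=data, srate=srate, ch_names=list(montage.labels),
                  events=events, montage=montage)
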