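"""Alpha-band phase-locking value (PLV) from sensorimotor seeds.

The instantaneous phase is the angle of the analytic signal (Hilbert
transform) of the band-passed epoch. The PLV between two electrodes is the
modulus of the across-trial mean unit phasor of their phase difference,

    PLV = (1/N) | sum_k exp(i [phi1_k(t) - phi2_k(t)]) |,

computed per time sample and then averaged over the analysis window
(900-1100 ms after cue onset, directly preceding the target). The PLV is
positively biased at small N, so trial counts are equalized across
conditions by seeded subsampling before condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy.signal import butter, sosfiltfilt

from .preprocess import EpochSet

__all__ = ["PLVMap", "instantaneous_phase", "plv", "seed_plv_map"]

ALPHA_BAND = (9.0, 14.0)
PLV_WINDOW = (0.9, 1.1)


@dataclass
class PLVMap:
    """Window-averaged PLV from one seed to every electrode."""

    seed: str
    electrodes: list[str]
    plv: np.ndarray  # (n_electrodes,)
    n_trials: int
    band: tuple[float, float]
    window: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("PLV needs at least 2 trials")
        if np.any(self.plv < -1e-9) or np.any(self.plv > 1 + 1e-9):
            raise ValueError("PLV outside [0, 1]")


def _analytic_phase(x: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal along the last axis (dtype-preserving)."""
    n = x.shape[-1]
    spec = scipy.fft.fft(x, axis=-1)
    h = np.zeros(n, dtype=spec.real.dtype)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.angle(scipy.fft.ifft(spec * h, axis=-1))


def instantaneous_phase(
    epochs: EpochSet,
    band: tuple[float, float] = ALPHA_BAND,
    order: int = 4,
) -> tuple[np.ndarray, int]:
    """Band-passed analytic-signal phase per trial x channel x sample.

    Returns (phase in (-pi, pi], edge_margin_samples). The flagged margin is
    one full cycle of the band's low edge on each side, where the zero-phase
    band-pass and the Hilbert transform are edge-distorted.
    """
    nyq = epochs.srate / 2.0
    if band[1] >= nyq:
        raise ValueError("band exceeds Nyquist")
    if band[1] - band[0] < 2.0 * epochs.srate / epochs.data.shape[2]:
        raise ValueError("band too narrow for the epoch length / sampling rate")
    sos = butter(order, band, btype="bandpass", fs=epochs.srate, output="sos")
    filt = sosfiltfilt(sos, epochs.data, axis=-1)
    phase = _analytic_phase(filt)
    margin = int(np.ceil(epochs.srate / band[0]))
    return phase, margin


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> np.ndarray:
    """PLV time series: modulus of the trial-mean phasor of the difference.

    Inputs are (n_trials, n_time) phase arrays from the same trials.
    """
    phase_a, phase_b = np.asarray(phase_a), np.asarray(phase_b)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase arrays must have identical shapes")
    if phase_a.shape[0] < 2:
        raise ValueError("PLV needs at least 2 trials")
    return np.abs(np.exp(1j * (phase_a - phase_b)).mean(axis=0))


def seed_plv_map(
    epochs: EpochSet,
    seed_electrode: str,
    band: tuple[float, float] = ALPHA_BAND,
    window: tuple[float, float] = PLV_WINDOW,
    trials: np.ndarray | None = None,
    n_equalize: int | None = None,
    rng: np.random.Generator | None = None,
    phase: np.ndarray | None = None,
    margin: int | None = None,
) -> PLVMap:
    """PLV from the seed to every electrode, averaged over the window.

    ``trials`` selects the trial subset (e.g. one condition, flip-corrected);
    ``n_equalize`` subsamples to a fixed trial count (seeded via ``rng``) so
    conditions with unequal counts stay comparable. A precomputed ``phase``
    array (from :func:`instantaneous_phase`) can be passed to avoid
    refiltering per condition.
    """
    si = epochs.ch_names.index(seed_electrode)
    if phase is None:
        phase, margin = instantaneous_phase(epochs, band)
    sel = np.flatnonzero(trials) if trials is not None else np.flatnonzero(epochs.kept())
    if n_equalize is not None and len(sel) > n_equalize:
        rng = np.random.default_rng(0) if rng is None else rng
        sel = np.sort(rng.choice(sel, size=n_equalize, replace=False))

    times = epochs.times
    wsel = (times >= window[0]) & (times <= window[1])
    n_t = len(times)
    lo, hi = np.flatnonzero(wsel)[[0, -1]]
    if margin is not None and (lo < margin or hi >= n_t - margin):
        raise ValueError("PLV window overlaps the edge-distorted margin")

    ph = phase[sel][:, :, wsel]
    series = np.abs(np.exp(1j * (ph[:, si : si + 1, :] - ph)).mean(axis=0))
    return PLVMap(
        seed=seed_electrode,
        electrodes=list(epochs.ch_names),
        plv=series.mean(axis=-1),
        n_trials=len(sel),
        band=band,
        window=window,
    )
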