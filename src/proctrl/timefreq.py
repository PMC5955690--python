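"""Morlet-wavelet time-frequency power, normalization, ROIs and flipping.

The mother wavelet is the complex Morlet

    w(t) = (pi * f_b)^(-1/2) * exp(2i*pi*f_c*t) * exp(-t^2 / f_b)

with bandwidth parameter f_b = 1 and center frequency f_c = 1.5. The
analysis wavelet at frequency f is the mother compressed by the scale
a = f_c / f and L2-renormalized; "energy" is the squared magnitude of the
convolution with the signal. Power is expressed as percent change from the
mean energy in a pre-stimulus baseline window (-250..-50 ms), computed per
channel x frequency on the trial-averaged energy of each condition
(grand-average normalization; per-trial normalization is available).

Sensorimotor analyses flip the channels of left-hand-standard trials across
the midline so "contralateral"/"ipsilateral" mean the same hemisphere in
every trial; prefrontal analyses use unflipped data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .montage import Montage
from .preprocess import EpochSet

__all__ = [
    "WaveletParams",
    "TFRPower",
    "ROISet",
    "morlet_mother",
    "wavelet_kernel",
    "cwt_power",
    "condition_mean_energy",
    "baseline_normalize",
    "roi_band_timecourse",
    "flip_hemispheres",
]


@dataclass
class WaveletParams:
    f_b: float = 1.0
    f_c: float = 1.5
    freqs: np.ndarray = field(default_factory=lambda: np.arange(1.0, 41.0))
    baseline_window: tuple[float, float] = (-0.250, -0.050)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        if self.f_b <= 0:
            raise ValueError("f_b must be positive")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class ROISet:
    """Named electrode clusters and frequency bands."""

    rois: dict = field(
        default_factory=lambda: {
            "left_prefrontal": ["F3", "F5", "FC3", "FC5"],
            "right_prefrontal": ["F4", "F6", "FC4", "FC6"],
            "left_central": ["C3", "C5", "CP3", "CP5"],
            "right_central": ["C4", "C6", "CP4", "CP6"],
        }
    )
    bands: dict = field(
        default_factory=lambda: {"mu": (9.0, 14.0), "beta": (15.0, 25.0)}
    )


@dataclass
class TFRPower:
    """Power array (units: energy or percent change) with axes metadata."""

    power: np.ndarray  # (..., n_channels, n_freqs, n_time)
    freqs: np.ndarray
    times: np.ndarray
    ch_names: list[str]
    srate: float
    kind: str = "energy"  # or "percent"
    edge_mask: np.ndarray | None = None  # (n_freqs, n_time) True where edge-distorted
    meta: dict = field(default_factory=dict)


def morlet_mother(t, f_b: float = 1.0, f_c: float = 1.5) -> np.ndarray:
    """Complex Morlet mother wavelet sampled at times ``t`` (seconds)."""
    t = np.asarray(t, float)
    return (np.pi * f_b) ** -0.5 * np.exp(2j * np.pi * f_c * t) * np.exp(-(t**2) / f_b)


def wavelet_kernel(freq: float, srate: float, params: WaveletParams) -> np.ndarray:
    """Discrete analysis wavelet at ``freq`` Hz (scale f_c/f, L2-normalized)."""
    a = params.f_c / freq
    half = int(np.ceil(3.5 * np.sqrt(params.f_b) * a * srate))
    t = np.arange(-half, half + 1) / srate
    psi = morlet_mother(t / a, params.f_b, params.f_c) / np.sqrt(a)
    return psi


def _energy_margin(kernel: np.ndarray, frac: float = 0.95) -> int:
    """Samples from each edge where less than ``frac`` kernel energy overlaps."""
    e = np.abs(kernel) ** 2
    cum = np.cumsum(e) / e.sum()
    tail = (1.0 - frac) / 2.0
    lo = int(np.searchsorted(cum, tail))
    return len(kernel) // 2 - lo


def min_usable_freq(n_samples: int, srate: float, params: WaveletParams) -> float:
    """Lowest frequency whose 95%-energy wavelet support fits the epoch."""
    # energy envelope has std a*sqrt(f_b)/2 -> 95% support width 1.96*a*sqrt(f_b)
    return 1.96 * params.f_c * np.sqrt(params.f_b) / (n_samples / srate)


def _check_freqs(freqs: np.ndarray, n_samples: int, srate: float, params: WaveletParams):
    fmin = min_usable_freq(n_samples, srate, params)
    bad = freqs[freqs < fmin]
    if len(bad):
        raise ValueError(
            f"wavelet support exceeds the epoch for f={bad.min():g} Hz; "
            f"minimum usable frequency is {fmin:.2f} Hz"
        )
    if np.any(freqs >= srate / 2):
        raise ValueError("analysis frequency at or above Nyquist")


def cwt_power(
    epochs: EpochSet, params: WaveletParams, channels: list[str] | None = None
) -> TFRPower:
    """Per-trial wavelet energy: squared magnitude of the convolution.

    Returns (n_trials, n_channels, n_freqs, n_time); samples where less
    than 95% of the wavelet energy overlaps the epoch are flagged in
    ``edge_mask``.
    """
    chans = channels if channels is not None else epochs.ch_names
    ci = [epochs.ch_names.index(c) for c in chans]
    d = epochs.data[:, ci, :]
    n_tr, n_ch, n_t = d.shape
    _check_freqs(params.freqs, n_t, epochs.srate, params)

    power = np.empty((n_tr, n_ch, len(params.freqs), n_t), dtype=np.float32)
    edge = np.zeros((len(params.freqs), n_t), dtype=bool)
    for fi, f in enumerate(params.freqs):
        k = wavelet_kernel(f, epochs.srate, params)
        conv = fftconvolve(d, k[None, None, :], mode="same", axes=-1)
        power[:, :, fi, :] = (conv.real**2 + conv.imag**2)
        m = min(_energy_margin(k), n_t)
        if m > 0:
            edge[fi, :m] = True
            edge[fi, n_t - m:] = True
    return TFRPower(
        power=power, freqs=params.freqs.copy(), times=epochs.times,
        ch_names=list(chans), srate=epochs.srate, kind="energy", edge_mask=edge,
        meta={"locking": epochs.locking},
    )


def condition_mean_energy(
    epochs: EpochSet,
    condition_of_trial: np.ndarray,
    params: WaveletParams,
    channels: list[str] | None = None,
    conditions: list[str] | None = None,
) -> dict:
    """Trial-averaged wavelet energy per condition, memory-bounded.

    Rejected trials are excluded. Returns {condition: TFRPower} where each
    power array is (n_channels, n_freqs, n_time).
    """
    chans = channels if channels is not None else epochs.ch_names
    ci = [epochs.ch_names.index(c) for c in chans]
    keep = epochs.kept()
    cond = np.asarray(condition_of_trial, object)
    conds = conditions if conditions is not None else sorted({c for c in cond[keep]})
    n_t = epochs.data.shape[2]
    _check_freqs(params.freqs, n_t, epochs.srate, params)

    out = {}
    acc = {c: np.zeros((len(ci), len(params.freqs), n_t), dtype=np.float64) for c in conds}
    counts = {c: int(np.sum(keep & (cond == c))) for c in conds}
    edge = np.zeros((len(params.freqs), n_t), dtype=bool)
    # stack kernels zero-padded to a common odd length so one broadcast
    # convolution (single data FFT per condition) covers every frequency
    kernels = [wavelet_kernel(f, epochs.srate, params) for f in params.freqs]
    for fi, k in enumerate(kernels):
        m = min(_energy_margin(k), n_t)
        if m > 0:
            edge[fi, :m] = True
            edge[fi, n_t - m:] = True
    L = max(len(k) for k in kernels)
    stack = np.zeros((len(kernels), 1, 1, L), dtype=np.complex64)
    for fi, k in enumerate(kernels):
        pad = (L - len(k)) // 2
        stack[fi, 0, 0, pad : pad + len(k)] = k
    for c in conds:
        sel = np.flatnonzero(keep & (cond == c))
        if len(sel) == 0:
            continue
        d = np.ascontiguousarray(epochs.data[np.ix_(sel, ci)], dtype=np.float32)
        conv = fftconvolve(d[None], stack, mode="full", axes=-1)
        h = (L - 1) // 2
        conv = conv[..., h : h + n_t]
        acc[c][:] = (conv.real**2 + conv.imag**2).mean(axis=1).transpose(1, 0, 2)
    for c in conds:
        out[c] = TFRPower(
            power=acc[c], freqs=params.freqs.copy(), times=epochs.times,
            ch_names=list(chans), srate=epochs.srate, kind="energy",
            edge_mask=edge, meta={"locking": epochs.locking, "n_trials": counts[c]},
        )
    return out


def baseline_normalize(tfr: TFRPower, baseline_window: tuple[float, float] | None = None,
                       params: WaveletParams | None = None) -> TFRPower:
    """Percent change from the baseline-window mean energy.

    B is the time-mean energy in the baseline window per channel x frequency
    (of the array given — pass a condition-averaged TFR for grand-average
    normalization); output is 100*(P - B)/B.
    """
    if baseline_window is None:
        baseline_window = params.baseline_window if params else (-0.250, -0.050)
    t0, t1 = baseline_window
    sel = (tfr.times >= t0) & (tfr.times < t1)
    if not sel.any():
        raise ValueError("baseline window outside the epoch")
    B = tfr.power[..., sel].mean(axis=-1, keepdims=True)
    if np.any(B <= 0):
        raise ValueError("non-positive baseline energy; degenerate input")
    return TFRPower(
        power=100.0 * (tfr.power - B) / B, freqs=tfr.freqs, times=tfr.times,
        ch_names=tfr.ch_names, srate=tfr.srate, kind="percent",
        edge_mask=tfr.edge_mask, meta=dict(tfr.meta),
    )


def roi_band_timecourse(tfr: TFRPower, roi: list[str], band: tuple[float, float]) -> np.ndarray:
    """Mean over the cluster's electrodes and the band's frequency bins."""
    ci = [tfr.ch_names.index(c) for c in roi]
    fi = np.flatnonzero((tfr.freqs >= band[0]) & (tfr.freqs <= band[1]))
    if len(fi) == 0:
        raise ValueError(f"band {band} does not intersect the frequency grid")
    return tfr.power[..., ci, :, :][..., :, fi, :].mean(axis=(-3, -2))


def _flip_index(ch_names: list[str], montage: Montage) -> np.ndarray:
    idx = np.empty(len(ch_names), dtype=int)
    for i, c in enumerate(ch_names):
        mate = montage.homologue(c)
        if mate not in ch_names:
            raise ValueError(f"homologue {mate!r} of {c!r} not in channel set")
        idx[i] = ch_names.index(mate)
    return idx


def flip_hemispheres(data, montage: Montage, which_trials: np.ndarray):
    """Swap left/right homologue channels for the selected trials.

    Works on an :class:`EpochSet` (channel axis 1) or a trial-resolved
    :class:`TFRPower` (channel axis 1). Midline channels are unchanged;
    flip status is recorded and the operation is an involution.
    """
    which = np.asarray(which_trials, dtype=bool)
    if isinstance(data, EpochSet):
        out = data.copy()
        idx = _flip_index(out.ch_names, montage)
        out.data[which] = out.data[which][:, idx]
        prev = out.flipped if out.flipped is not None else np.zeros(out.n_trials, bool)
        out.flipped = prev ^ which
        return out
    if isinstance(data, TFRPower):
        idx = _flip_index(data.ch_names, montage)
        power = data.power.copy()
        power[which] = power[which][:, idx]
        meta = dict(data.meta)
        meta["flipped"] = np.asarray(meta.get("flipped", np.zeros(len(which), bool))) ^ which
        return TFRPower(power, data.freqs, data.times, data.ch_names, data.srate,
                        data.kind, data.edge_mask, meta)
    raise TypeError("flip_hemispheres expects an EpochSet or TFRPower")
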