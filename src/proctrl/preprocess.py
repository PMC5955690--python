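"""Re-referencing, filtering, epoching, artifact rejection and exclusion.

Fixed pipeline order: re-reference to the earlobe average -> 0.5 Hz
high-pass + 50 Hz notch (both zero-phase) -> epoch [-1, +2) s around the
locking event -> subtract the 100-ms pre-stimulus baseline -> reject trials
whose absolute voltage exceeds +/-80 uV on any analysis channel. Subjects
losing strictly more than 30% of trials are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, iirnotch, sosfiltfilt, tf2sos

from .montage import REFERENCE_CHANNELS
from .simulate import RawEEG

__all__ = [
    "EpochSet",
    "rereference",
    "filter_raw",
    "epoch",
    "reject_amplitude",
    "exclude_subjects",
]


@dataclass
class EpochSet:
    """Trials x channels x time voltage (or CSD) array with trial metadata."""

    data: np.ndarray
    srate: float
    ch_names: list[str]
    tmin: float  # window start relative to locking event (s)
    locking: str  # "cue" or "target"
    rejected: np.ndarray = field(default=None)  # bool per trial
    reject_reason: list = field(default_factory=list)
    trial_meta: pd.DataFrame | None = None
    flipped: np.ndarray | None = None  # bool per trial, set by hemisphere flip

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        if len(self.rejected) != self.data.shape[0]:
            raise ValueError("rejection mask length must equal trial count")
        if not self.reject_reason:
            self.reject_reason = [""] * self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.srate

    def kept(self) -> np.ndarray:
        return ~self.rejected

    def crop(self, t0: float, t1: float) -> "EpochSet":
        """Time-sliced copy covering [t0, t1) relative to the locking event."""
        sel = (self.times >= t0) & (self.times < t1)
        if not sel.any():
            raise ValueError("crop window outside the epoch")
        out = self.copy()
        out.data = np.ascontiguousarray(self.data[:, :, sel])
        out.tmin = float(self.times[sel][0])
        return out

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.srate, list(self.ch_names), self.tmin,
            self.locking, self.rejected.copy(), list(self.reject_reason),
            None if self.trial_meta is None else self.trial_meta.copy(),
            None if self.flipped is None else self.flipped.copy(),
        )

    # -- documented container: JSON header + channel-major float32 binary --
    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        hdr = {
            "shape": list(self.data.shape),
            "srate": self.srate,
            "ch_names": self.ch_names,
            "tmin": self.tmin,
            "locking": self.locking,
            "rejected": self.rejected.astype(int).tolist(),
            "reject_reason": self.reject_reason,
            "dtype": "float32",
            "order": "trial-channel-time",
        }
        stem.with_suffix(".json").write_text(json.dumps(hdr))
        self.data.astype("<f4").tofile(stem.with_suffix(".f32"))
        if self.trial_meta is not None:
            self.trial_meta.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, stem: str | Path) -> "EpochSet":
        stem = Path(stem)
        hdr = json.loads(stem.with_suffix(".json").read_text())
        data = np.fromfile(stem.with_suffix(".f32"), dtype="<f4").reshape(hdr["shape"])
        meta = None
        if stem.with_suffix(".tsv").exists():
            meta = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
        return cls(
            data.astype(float), hdr["srate"], hdr["ch_names"], hdr["tmin"],
            hdr["locking"], np.array(hdr["rejected"], dtype=bool),
            hdr["reject_reason"], meta,
        )

    def rejection_log(self, path: str | Path) -> None:
        pd.DataFrame(
            {"trial": np.arange(self.n_trials), "rejected": self.rejected,
             "reason": self.reject_reason}
        ).to_csv(path, sep="\t", index=False)


def rereference(raw: RawEEG, ref_channels: tuple[str, ...] = REFERENCE_CHANNELS) -> RawEEG:
    """Subtract the mean of the reference channels; drop them from the set."""
    missing = [r for r in ref_channels if r not in raw.ch_names]
    if missing:
        raise ValueError(f"missing reference channel(s): {missing}")
    idx = [raw.ch_names.index(r) for r in ref_channels]
    ref = raw.data[idx].mean(axis=0)
    keep = [i for i in range(len(raw.ch_names)) if i not in idx]
    return RawEEG(
        data=raw.data[keep] - ref,
        srate=raw.srate,
        ch_names=[raw.ch_names[i] for i in keep],
        events=list(raw.events),
        montage=raw.montage,
    )


def filter_raw(raw: RawEEG, highpass_hz: float = 0.5, notch_hz: float = 50.0) -> RawEEG:
    """Zero-phase 4th-order Butterworth high-pass plus Q=30 IIR notch."""
    nyq = raw.srate / 2.0
    if highpass_hz >= nyq or notch_hz >= nyq:
        raise ValueError("filter cutoff at or above Nyquist")
    out = raw.copy()
    stages = []
    if highpass_hz > 0:
        stages.append(butter(4, highpass_hz, btype="highpass", fs=raw.srate, output="sos"))
    if notch_hz > 0:
        stages.append(tf2sos(*iirnotch(notch_hz, Q=30.0, fs=raw.srate)))
    if stages:
        out.data = sosfiltfilt(np.vstack(stages), out.data, axis=1)
    return out


def epoch(
    raw: RawEEG,
    events: list[tuple[float, str]] | np.ndarray,
    window: tuple[float, float] = (-1.0, 2.0),
    baseline: tuple[float, float] = (-0.1, 0.0),
    locking: str = "cue",
    trial_meta: pd.DataFrame | None = None,
) -> EpochSet:
    """Extract half-open [onset+tmin, onset+tmax) epochs, baseline-corrected.

    ``events`` is a list of (onset_s, label) or an array of onsets. The
    baseline (mean of the 100 ms preceding the locking event, per channel)
    is subtracted from each epoch. Events whose window leaves the record are
    not extractable and come back as rejected trials (zero data, reason set).
    """
    onsets = np.asarray([e[0] if isinstance(e, (tuple, list)) else e for e in events], float)
    tmin, tmax = window
    n_samp = int(round((tmax - tmin) * raw.srate))
    n_ch = len(raw.ch_names)
    data = np.zeros((len(onsets), n_ch, n_samp), dtype=raw.data.dtype)
    rejected = np.zeros(len(onsets), dtype=bool)
    reasons = [""] * len(onsets)

    b0 = int(round((baseline[0] - tmin) * raw.srate))
    b1 = int(round((baseline[1] - tmin) * raw.srate))
    for k, onset in enumerate(onsets):
        start = int(round(onset * raw.srate)) + int(round(tmin * raw.srate))
        stop = start + n_samp
        if start < 0 or stop > raw.n_samples:
            rejected[k] = True
            reasons[k] = "window outside record"
            continue
        seg = raw.data[:, start:stop]
        data[k] = seg - seg[:, b0:b1].mean(axis=1, keepdims=True)
    return EpochSet(
        data=data, srate=raw.srate, ch_names=list(raw.ch_names), tmin=tmin,
        locking=locking, rejected=rejected, reject_reason=reasons,
        trial_meta=trial_meta,
    )


def reject_amplitude(epochs: EpochSet, threshold_uv: float = 80.0) -> EpochSet:
    """Mark trials with any |v| > threshold on any channel; data retained."""
    out = epochs.copy()
    bad = np.abs(out.data).max(axis=(1, 2)) > threshold_uv
    newly = bad & ~out.rejected
    out.rejected = out.rejected | bad
    out.reject_reason = [
        (f"amplitude > {threshold_uv:g} uV" if n else r)
        for n, r in zip(newly, out.reject_reason)
    ]
    return out


def exclude_subjects(rejection_fraction: dict, threshold: float = 0.30):
    """Split subjects into kept/excluded by the strict >30% rejection rule."""
    for s, f in rejection_fraction.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"rejection fraction for {s!r} outside [0,1]")
    excluded = [s for s, f in rejection_fraction.items() if f > threshold]
    kept = [s for s in rejection_fraction if s not in excluded]
    return kept, excluded
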