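"""Minimal EDF+C writer/reader for synthetic raw EEG with event annotations.

Implements just enough of the EDF+ interchange format (16-bit samples,
per-channel physical scaling, one ``EDF Annotations`` signal carrying
time-stamped annotation lists) to round-trip this package's simulated
sessions. Samples are quantized to the int16 grid spanned by each channel's
physical min/max; the quantization step for +/-200 uV data is ~6e-3 uV,
far below the noise floor of any simulated record.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]

_HDR = "ascii"


def _field(text: str, width: int) -> bytes:
    b = text.encode(_HDR)
    if len(b) > width:
        raise ValueError(f"header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    data: np.ndarray,
    srate: float,
    ch_names: list[str],
    events: list[tuple[float, str]] | None = None,
    physical_unit: str = "uV",
) -> None:
    """Write channels x samples data (physical units) as EDF+C.

    Events are (onset_seconds, label) pairs stored in an annotations signal.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(ch_names) != n_ch:
        raise ValueError("channel name count mismatch")
    if srate <= 0 or srate != int(srate):
        raise ValueError("srate must be a positive integer (1-s data records)")
    events = sorted(events or [], key=lambda e: e[0])

    spr = int(srate)  # samples per 1-s record per channel
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    pmin = np.minimum(data.min(axis=1), -1e-6)
    pmax = np.maximum(data.max(axis=1), 1e-6)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    # annotations: TALs per record; record k holds events with k <= onset < k+1
    tals: list[bytes] = []
    for k in range(n_rec):
        tal = f"+{k}\x14\x14\x00".encode(_HDR)
        for onset, label in events:
            if k <= onset < k + 1 or (k == n_rec - 1 and onset >= n_rec):
                tal += f"+{onset:.6f}\x14{label}\x14\x00".encode(_HDR)
        tals.append(tal)
    ann_bytes = max(len(t) for t in tals) if tals else 16
    ann_spr = int(np.ceil(ann_bytes / 2)) + 8  # int16 "samples" of slack

    ns = n_ch + 1
    header = b""
    header += _field("0", 8)
    header += _field("X X X X", 80)  # local patient id (anonymous synthetic)
    header += _field("Startdate X X X X", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (ns + 1)), 8)
    header += _field("EDF+C", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)  # record duration, seconds
    header += _field(str(ns), 4)

    labels = [f"EEG {c}"[:16] for c in ch_names] + ["EDF Annotations"]
    header += b"".join(_field(l, 16) for l in labels)
    header += b"".join(_field("", 80) for _ in range(ns))  # transducer
    header += b"".join(_field(physical_unit, 8) for _ in range(n_ch)) + _field("", 8)
    header += b"".join(_field(f"{v:.7g}"[:8], 8) for v in pmin) + _field("-1", 8)
    header += b"".join(_field(f"{v:.7g}"[:8], 8) for v in pmax) + _field("1", 8)
    header += b"".join(_field(str(dmin), 8) for _ in range(ns))
    header += b"".join(_field(str(dmax), 8) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_field(str(spr), 8) for _ in range(n_ch))
    header += _field(str(ann_spr), 8)
    header += b" " * (32 * ns)

    with open(path, "wb") as fh:
        fh.write(header)
        for k in range(n_rec):
            fh.write(digital[:, k * spr : (k + 1) * spr].astype("<i2").tobytes())
            buf = tals[k].ljust(ann_spr * 2, b"\x00")
            fh.write(buf)


def read_edf(path: str | Path):
    """Read an EDF/EDF+C file written by :func:`write_edf`.

    Returns ``(data, srate, ch_names, events)`` with data in physical units.
    """
    raw = Path(path).read_bytes()

    def f(off: int, width: int) -> str:
        return raw[off : off + width].decode(_HDR).strip()

    n_rec = int(f(236, 8))
    rec_dur = float(f(244, 8))
    ns = int(f(252, 4))
    off = 256
    labels = [f(off + 16 * i, 16) for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns
    pmin = np.array([float(f(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    pmax = np.array([float(f(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    dmin = np.array([float(f(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns
    dmax = np.array([float(f(off + 8 * i, 8)) for i in range(ns)])
    off += 8 * ns + 80 * ns
    spr = np.array([int(f(off + 8 * i, 8)) for i in range(ns)])
    header_bytes = int(f(184, 8))

    ann_idx = [i for i, l in enumerate(labels) if l == "EDF Annotations"]
    sig_idx = [i for i in range(ns) if i not in ann_idx]

    rec_len = int(spr.sum())
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    body = body[: n_rec * rec_len].reshape(n_rec, rec_len)
    starts = np.concatenate(([0], np.cumsum(spr)))

    chans = []
    for i in sig_idx:
        dig = body[:, starts[i] : starts[i + 1]].reshape(-1).astype(float)
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        chans.append((dig - dmin[i]) * scale + pmin[i])
    data = np.vstack(chans) if chans else np.empty((0, 0))

    events: list[tuple[float, str]] = []
    for i in ann_idx:
        for k in range(n_rec):
            blob = body[k, starts[i] : starts[i + 1]].tobytes()
            for tal in blob.split(b"\x00"):
                if b"\x14" not in tal:
                    continue
                parts = tal.split(b"\x14")
                onset_dur = parts[0].split(b"\x15")[0]
                try:
                    onset = float(onset_dur.decode(_HDR))
                except ValueError:
                    continue
                for label in parts[1:]:
                    if label:
                        events.append((onset, label.decode(_HDR)))
    events = sorted(set(events), key=lambda e: (e[0], e[1]))

    ch_names = [labels[i].removeprefix("EEG ").strip() for i in sig_idx]
    srate = spr[sig_idx[0]] / rec_dur if sig_idx else 0.0
    return data, srate, ch_names, events
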