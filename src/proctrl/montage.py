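"""Idealized 64-channel extended 10-20 montage on the unit sphere.

Electrode positions are constructed geometrically from the 10-10 placement
rules rather than digitized coordinates: the nasion-inion and ear-to-ear
arcs are divided in 10% steps (18 degrees on an ideal sphere), the outer
ring runs through Fpz, T7/T8 and Oz at 72 degrees from the vertex, and
intermediate electrodes (F3, FC5, CP1, ...) sit at quarter fractions of the
great-circle arc between the midline electrode of their row and the ring
electrode of the same row. Earlobe reference electrodes A1/A2 hang below
the ring. Axes: +x right, +y anterior, +z vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "standard_montage", "REFERENCE_CHANNELS"]

REFERENCE_CHANNELS = ("A1", "A2")

# (row prefix, midline polar angle [deg], anterior?(else posterior), ring azimuth [deg])
_ROWS = [
    ("AF", 54.0, True, 36.0),
    ("F", 36.0, True, 54.0),
    ("FC", 18.0, True, 72.0),
    ("C", 0.0, True, 90.0),
    ("CP", 18.0, False, 108.0),
    ("P", 36.0, False, 126.0),
    ("PO", 54.0, False, 144.0),
]

# ring electrodes: label pairs at azimuth (degrees from front midline)
_RING = [
    (("Fp1", "Fp2"), 18.0),
    (("AF7", "AF8"), 36.0),
    (("F7", "F8"), 54.0),
    (("FT7", "FT8"), 72.0),
    (("T7", "T8"), 90.0),
    (("TP7", "TP8"), 108.0),
    (("P7", "P8"), 126.0),
    (("PO7", "PO8"), 144.0),
    (("O1", "O2"), 162.0),
]

_MIDLINE = [
    ("Fpz", 72.0, True),
    ("AFz", 54.0, True),
    ("Fz", 36.0, True),
    ("FCz", 18.0, True),
    ("Cz", 0.0, True),
    ("CPz", 18.0, False),
    ("Pz", 36.0, False),
    ("POz", 54.0, False),
    ("Oz", 72.0, False),
    ("Iz", 90.0, False),
]

# which intermediate labels each row carries (left digit, right digit, arc fraction)
_INTERMEDIATE = {
    "AF": [(3, 4, 0.5)],
    "F": [(1, 2, 0.25), (3, 4, 0.5), (5, 6, 0.75)],
    "FC": [(1, 2, 0.25), (3, 4, 0.5), (5, 6, 0.75)],
    "C": [(1, 2, 0.25), (3, 4, 0.5), (5, 6, 0.75)],
    "CP": [(1, 2, 0.25), (3, 4, 0.5), (5, 6, 0.75)],
    "P": [(1, 2, 0.25), (3, 4, 0.5), (5, 6, 0.75)],
    "PO": [(3, 4, 0.5)],
}

# ring member label prefix per row (the "7/8" electrodes)
_RING_OF_ROW = {"AF": "AF", "F": "F", "FC": "FT", "C": "T", "CP": "TP", "P": "P", "PO": "PO"}


def _pos(polar_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector at polar angle from vertex and azimuth from front midline.

    Positive azimuth rotates toward the right ear (+x); negative toward the
    left; 180 degrees is posterior midline.
    """
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(azim_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp(u: np.ndarray, v: np.ndarray, f: float) -> np.ndarray:
    omega = np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))
    if omega < 1e-12:
        return u.copy()
    return (np.sin((1.0 - f) * omega) * u + np.sin(f * omega) * v) / np.sin(omega)


@dataclass
class Montage:
    """Electrode labels, unit-sphere positions and left/right homologue map."""

    labels: list[str]
    positions: np.ndarray  # (n, 3), unit norm
    lr_pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must have unit norm")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions shape mismatch")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label: {label!r}") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def homologue(self, label: str) -> str:
        """Left/right mirror electrode; midline electrodes map to themselves."""
        try:
            return self.lr_pairs[label]
        except KeyError:
            raise KeyError(f"no left/right homologue for {label!r}") from None

    def angular_distances(self, label: str) -> np.ndarray:
        """Great-circle angle (rad) from the named electrode to every electrode."""
        c = self.position(label)
        return np.arccos(np.clip(self.positions @ c, -1.0, 1.0))

    @property
    def analysis_labels(self) -> list[str]:
        return [l for l in self.labels if l not in REFERENCE_CHANNELS]


def _homologue_label(label: str) -> str:
    if label.endswith("z") or label in ("Iz",):
        return label
    # trailing number determines hemisphere: odd=left, even=right
    i = len(label)
    while i > 0 and label[i - 1].isdigit():
        i -= 1
    stem, num = label[:i], int(label[i:])
    mate = num + 1 if num % 2 == 1 else num - 1
    return f"{stem}{mate}"


def standard_montage(include_reference: bool = True) -> Montage:
    """Build the 64-channel idealized spherical montage (plus A1/A2 refs)."""
    labels: list[str] = []
    pos: list[np.ndarray] = []

    for lab, polar, ant in _MIDLINE:
        labels.append(lab)
        pos.append(_pos(polar, 0.0 if ant else 180.0))

    ring_pos: dict[str, np.ndarray] = {}
    for (left, right), az in _RING:
        pl, pr = _pos(72.0, -az), _pos(72.0, az)
        ring_pos[left], ring_pos[right] = pl, pr
        labels.extend([left, right])
        pos.extend([pl, pr])

    mid_pos = {lab: _pos(polar, 0.0 if ant else 180.0) for lab, polar, ant in _MIDLINE}
    for row, polar, ant, _az in _ROWS:
        m = mid_pos[row + "z"]
        ring_l = ring_pos[_RING_OF_ROW[row] + "7"]
        ring_r = ring_pos[_RING_OF_ROW[row] + "8"]
        for dl, dr, f in _INTERMEDIATE[row]:
            labels.append(f"{row}{dl}")
            pos.append(_slerp(m, ring_l, f))
            labels.append(f"{row}{dr}")
            pos.append(_slerp(m, ring_r, f))

    # inferior temporal pair below the ring (completes the 64-channel cap)
    labels.extend(["TP9", "TP10"])
    pos.extend([_pos(108.0, -108.0), _pos(108.0, 108.0)])

    if include_reference:
        labels.extend(list(REFERENCE_CHANNELS))
        pos.extend([_pos(112.0, -94.0), _pos(112.0, 94.0)])

    positions = np.array([p / np.linalg.norm(p) for p in pos])
    lr = {lab: _homologue_label(lab) for lab in labels}
    # A1/A2 pair as well (they are mirrored reference sites)
    lr["A1"], lr["A2"] = "A2", "A1"
    lr = {k: v for k, v in lr.items() if k in labels and v in labels}
    return Montage(labels=labels, positions=positions, lr_pairs=lr)
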