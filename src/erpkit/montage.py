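"""Scalp electrode geometry for the 10-20 / 10-10 placement system.

Positions are generated from the geometric construction of the standard
itself: the head is a unit sphere, the nasion-inion arc is the sagittal
half great-circle, and electrode rows sit at 10% fractions of that arc.
Lateral electrodes are placed along the great-circle arc from the midline
electrode of their row to the row's point on the 10% "ring" (the equator
through nasion, preauricular points and inion).  Sub-ring electrodes
(P9/P10, TP9/TP10, earlobes, mastoids) sit 10% of the arc below the ring.

2D positions are the azimuthal-equidistant projection from the vertex,
scaled so the ring has radius 1 (head radius = 1).  x is positive toward
the right ear, y positive toward the nasion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

#: floor of the neighbourhood radius (unit head radius). Chosen so that in
#: the classic 10-20 grid each electrode connects to its immediate row and
#: column neighbours (e.g. Fz-Cz = 0.40, Fz-F3 = 0.41) but not to
#: second-order ones (Fz-Pz = 0.80). On sparser montages the radius is
#: widened adaptively (see :func:`build_layout`) so no channel is isolated.
DEFAULT_NEIGHBOR_DELTA = 0.45

_ROW_FRACTION = {
    "Fp": 0.1, "AF": 0.2, "F": 0.3, "FC": 0.4, "C": 0.5,
    "CP": 0.6, "P": 0.7, "PO": 0.8, "O": 0.9,
}
# lateral labels per row, ordered from midline outward: (label stem, arc fraction)
_LATERAL = {
    "Fp": [("Fp1", 1.0)],
    "AF": [("AF3", 0.5), ("AF7", 1.0)],
    "F": [("F1", 0.25), ("F3", 0.5), ("F5", 0.75), ("F7", 1.0)],
    "FC": [("FC1", 0.25), ("FC3", 0.5), ("FC5", 0.75), ("FT7", 1.0)],
    "C": [("C1", 0.25), ("C3", 0.5), ("C5", 0.75), ("T7", 1.0)],
    "CP": [("CP1", 0.25), ("CP3", 0.5), ("CP5", 0.75), ("TP7", 1.0)],
    "P": [("P1", 0.25), ("P3", 0.5), ("P5", 0.75), ("P7", 1.0)],
    "PO": [("PO3", 0.5), ("PO7", 1.0)],
    "O": [("O1", 1.0)],
}
# (name_left, ring azimuth fraction of pi, vertex angle degrees) below the ring
_SUB_RING = [
    ("FT9", 0.4, 108.0),
    ("TP9", 0.6, 108.0),
    ("P9", 0.7, 108.0),
    ("A1", 0.5, 102.0),   # earlobe
    ("M1", 0.55, 105.0),  # mastoid
]


def _sph(vertex_angle_deg: float, azimuth_rad: float, side: int) -> np.ndarray:
    """Unit vector; azimuth measured from nasion toward the chosen ear."""
    va = math.radians(vertex_angle_deg)
    return np.array([
        side * math.sin(va) * math.sin(azimuth_rad),
        math.sin(va) * math.cos(azimuth_rad),
        math.cos(va),
    ])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    omega = math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0)))
    if omega < 1e-12:
        return a
    return (math.sin((1 - t) * omega) * a + math.sin(t * omega) * b) / math.sin(omega)


def _project2d(v: np.ndarray) -> tuple[float, float]:
    """Azimuthal-equidistant projection from the vertex, ring radius = 1."""
    r = math.acos(float(np.clip(v[2], -1.0, 1.0))) / (math.pi / 2)
    horiz = math.hypot(v[0], v[1])
    if horiz < 1e-12:
        return 0.0, 0.0
    return r * v[0] / horiz, r * v[1] / horiz


def _mirror_name(left: str) -> str:
    """Left-hemisphere label -> right-hemisphere label (odd -> even)."""
    digits = "".join(ch for ch in left if ch.isdigit())
    stem = left[: len(left) - len(digits)]
    return f"{stem}{int(digits) + 1}"


def standard_positions() -> dict[str, tuple[float, float]]:
    """2D coordinates of the built-in 10-20/10-10 electrode table."""
    pos: dict[str, tuple[float, float]] = {}
    midline = {"Fp": "Fpz", "AF": "AFz", "F": "Fz", "FC": "FCz", "C": "Cz",
               "CP": "CPz", "P": "Pz", "PO": "POz", "O": "Oz"}
    for row, p in _ROW_FRACTION.items():
        va_mid = abs(0.5 - p) * 180.0
        az_mid = 0.0 if p <= 0.5 else math.pi
        mid3 = _sph(va_mid, az_mid, side=1)
        pos[midline[row]] = _project2d(mid3)
        ring_az = p * math.pi
        for left_name, frac in _LATERAL[row]:
            for side, name in ((-1, left_name), (1, _mirror_name(left_name))):
                ring3 = _sph(90.0, ring_az, side)
                pos[name] = _project2d(_slerp(mid3, ring3, frac))
    # midline extremes and sub-ring electrodes
    pos["Iz"] = _project2d(_sph(108.0, math.pi, 1))
    for left_name, az_frac, va in _SUB_RING:
        for side, name in ((-1, left_name), (1, _mirror_name(left_name))):
            pos[name] = _project2d(_sph(va, az_frac * math.pi, side))
    return pos


def write_montage_table(path) -> None:
    """Write the built-in coordinate table as plain text (name, x, y)."""
    pos = standard_positions()
    with open(path, "w") as f:
        f.write("name\tx\ty\n")
        for name, (x, y) in sorted(pos.items()):
            f.write(f"{name}\t{x:.6f}\t{y:.6f}\n")


def load_montage_table() -> dict[str, tuple[float, float]]:
    """Read the shipped plain-text coordinate table."""
    pos = {}
    with resources.files("erpkit.data").joinpath("montage_1020.tsv").open() as f:
        next(f)
        for line in f:
            name, x, y = line.split("\t")
            pos[name] = (float(x), float(y))
    return pos


@dataclass
class ChannelLayout:
    """Channel names, projected 2D scalp positions and a neighbour graph."""

    names: list[str]
    pos2d: np.ndarray  # (n_channels, 2), head radius = 1
    neighbor_graph: dict[int, list[int]]

    def __post_init__(self) -> None:
        self.pos2d = np.asarray(self.pos2d, dtype=float)
        if self.pos2d.shape != (len(self.names), 2):
            raise ValueError("pos2d must be (n_channels, 2)")
        for i, nbrs in self.neighbor_graph.items():
            for j in nbrs:
                if i not in self.neighbor_graph[j]:
                    raise ValueError("neighbor graph is not symmetric")
        if len(self.names) >= 2:
            isolated = [self.names[i] for i, n in self.neighbor_graph.items() if not n]
            if isolated:
                raise ValueError(f"channels without neighbors: {isolated}")

    def neighbors(self, name: str) -> list[str]:
        i = self.names.index(name)
        return [self.names[j] for j in self.neighbor_graph[i]]


def build_layout(channel_names: list[str], delta: float | None = None) -> ChannelLayout:
    """Layout for a channel subset; neighbours are pairs closer than ``delta``.

    When ``delta`` is not given it defaults to
    ``max(0.45, 1.1 * max_i(min_j distance))`` — the 10-20 grid spacing
    floor, widened just enough on sparse montages that every channel keeps
    at least one neighbour.
    """
    table = standard_positions()
    unknown = [n for n in channel_names if n not in table]
    if unknown:
        raise KeyError(f"unknown channel name(s): {unknown}")
    if len(set(channel_names)) != len(channel_names):
        raise ValueError("channel names must be unique")
    pos = np.array([table[n] for n in channel_names], dtype=float)
    n = len(channel_names)
    if delta is None:
        delta = DEFAULT_NEIGHBOR_DELTA
        if n >= 2:
            dists = np.hypot(*(pos[:, None, :] - pos[None, :, :]).transpose(2, 0, 1))
            np.fill_diagonal(dists, np.inf)
            delta = max(delta, 1.1 * float(dists.min(axis=1).max()))
    graph: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pos[i] - pos[j])) < delta:
                graph[i].append(j)
                graph[j].append(i)
    return ChannelLayout(names=list(channel_names), pos2d=pos, neighbor_graph=graph)
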