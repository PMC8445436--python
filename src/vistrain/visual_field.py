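"""Visual-field maps on a regular perimetry grid, parametric scotomata,
point classification, border-zone extraction, and CSV I/O.

A field map is a square grid of cells at integer multiples of ``pitch_deg``
(default 0.75 deg, the resolution of the emulated perimeter output) out to
``extent_deg`` on each side of fixation.  Each cell is INTACT,
ABSOLUTE_DEFECT or UNTESTED.  Maps are eye-referenced: internally, positive
x is always the temporal side, so a single blind-spot model serves both
eyes; the CSV layer mirrors the x axis for left-eye maps.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .geometry import AngularPosition, angular_distance

__all__ = [
    "FieldStatus",
    "ScotomaSpec",
    "circle",
    "halfplane",
    "quadrant",
    "default_blind_spot",
    "VisualFieldMap",
    "make_field",
    "classify_point",
    "border_zone",
    "blind_spot_stimulus_sites",
    "read_field_csv",
    "write_field_csv",
]

DEFAULT_PITCH_DEG = 0.75

# Anatomical blind spot: the printed extent runs from ~12 deg medial to
# ~17 deg lateral, ~1 deg below the horizontal meridian; modelled as a
# circle at the midpoint.
BLIND_SPOT_CENTER = (14.5, -1.0)
BLIND_SPOT_RADIUS = 2.5


class FieldStatus(enum.Enum):
    INTACT = "intact"
    ABSOLUTE_DEFECT = "defect"
    UNTESTED = "untested"


@dataclass(frozen=True)
class ScotomaSpec:
    """A parametric region of absolute visual-field loss.

    shape:
      - ``circle``: ``center=(x, y)``, ``radius`` in degrees
      - ``halfplane``: defect strictly beyond ``boundary_x`` on ``side``
      - ``quadrant``: one of ``upper_left/upper_right/lower_left/lower_right``
    """

    shape: Literal["circle", "halfplane", "quadrant"]
    eye: Literal["left", "right"] = "right"
    center: tuple[float, float] | None = None
    radius: float | None = None
    boundary_x: float | None = None
    side: Literal["left", "right"] | None = None
    which: str | None = None

    def __post_init__(self) -> None:
        if self.shape == "circle":
            if self.center is None or self.radius is None:
                raise ValueError("circle scotoma requires center and radius")
            if self.radius <= 0:
                raise ValueError("circle radius must be > 0")
        elif self.shape == "halfplane":
            if self.boundary_x is None or self.side not in ("left", "right"):
                raise ValueError("halfplane scotoma requires boundary_x and side")
        elif self.shape == "quadrant":
            if self.which not in ("upper_left", "upper_right", "lower_left", "lower_right"):
                raise ValueError(f"unknown quadrant {self.which!r}")
        else:
            raise ValueError(f"unknown scotoma shape {self.shape!r}")

    def contains(self, x: float, y: float) -> bool:
        if self.shape == "circle":
            cx, cy = self.center  # type: ignore[misc]
            return math.hypot(x - cx, y - cy) <= self.radius  # type: ignore[operator]
        if self.shape == "halfplane":
            return x > self.boundary_x if self.side == "right" else x < self.boundary_x
        up, lr = self.which.split("_")  # type: ignore[union-attr]
        ok_y = y > 0 if up == "upper" else y < 0
        ok_x = x > 0 if lr == "right" else x < 0
        return ok_x and ok_y


def circle(center: tuple[float, float], radius: float, eye: str = "right") -> ScotomaSpec:
    return ScotomaSpec(shape="circle", eye=eye, center=center, radius=radius)  # type: ignore[arg-type]


def halfplane(boundary_x: float, side: str, eye: str = "right") -> ScotomaSpec:
    return ScotomaSpec(shape="halfplane", eye=eye, boundary_x=boundary_x, side=side)  # type: ignore[arg-type]


def quadrant(which: str, eye: str = "right") -> ScotomaSpec:
    return ScotomaSpec(shape="quadrant", eye=eye, which=which)  # type: ignore[arg-type]


def default_blind_spot(eye: str = "right") -> ScotomaSpec:
    """Anatomical blind spot in eye-referenced (temporal-positive) coordinates."""
    return circle(BLIND_SPOT_CENTER, BLIND_SPOT_RADIUS, eye=eye)


@dataclass
class VisualFieldMap:
    """Per-eye grid of field statuses.

    ``cells`` maps integer grid indices ``(i, j)`` (coordinate = index *
    pitch) to a :class:`FieldStatus`.
    """

    eye: Literal["left", "right"] = "right"
    pitch_deg: float = DEFAULT_PITCH_DEG
    extent_deg: float = 20.0
    cells: dict[tuple[int, int], FieldStatus] = field(default_factory=dict)

    @property
    def half_cells(self) -> int:
        return int(math.floor(self.extent_deg / self.pitch_deg + 1e-9))

    def cell_position(self, idx: tuple[int, int]) -> AngularPosition:
        return AngularPosition(idx[0] * self.pitch_deg, idx[1] * self.pitch_deg)

    def positions_with_status(self, status: FieldStatus) -> list[AngularPosition]:
        out = [self.cell_position(ij) for ij, st in self.cells.items() if st is status]
        out.sort(key=lambda p: (p.x_deg, p.y_deg))
        return out

    def status_counts(self) -> dict[FieldStatus, int]:
        counts = {s: 0 for s in FieldStatus}
        for st in self.cells.values():
            counts[st] += 1
        return counts


def make_field(
    specs: Iterable[ScotomaSpec],
    pitch: float = DEFAULT_PITCH_DEG,
    extent: float = 20.0,
    eye: str = "right",
) -> VisualFieldMap:
    """Build a field map whose cells inside any scotoma are ABSOLUTE_DEFECT.

    Deterministic, idempotent, and order-independent in ``specs``.
    """
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    if extent < pitch:
        raise ValueError("extent must be >= pitch (grid would be empty)")
    specs = list(specs)
    n = int(math.floor(extent / pitch + 1e-9))
    cells: dict[tuple[int, int], FieldStatus] = {}
    for i in range(-n, n + 1):
        x = i * pitch
        for j in range(-n, n + 1):
            y = j * pitch
            hit = any(s.contains(x, y) for s in specs)
            cells[(i, j)] = FieldStatus.ABSOLUTE_DEFECT if hit else FieldStatus.INTACT
    return VisualFieldMap(eye=eye, pitch_deg=pitch, extent_deg=extent, cells=cells)  # type: ignore[arg-type]


def _nearest_index(v: float, pitch: float) -> int:
    # round to nearest multiple of pitch; exact ties go to the smaller index
    return math.ceil(v / pitch - 0.5)


def classify_point(fmap: VisualFieldMap, p: AngularPosition) -> FieldStatus:
    """Status of the grid cell nearest to ``p``; UNTESTED outside the extent.

    Ties between equidistant cells resolve toward the cell with the smaller
    x, then smaller y.
    """
    i = _nearest_index(p.x_deg, fmap.pitch_deg)
    j = _nearest_index(p.y_deg, fmap.pitch_deg)
    return fmap.cells.get((i, j), FieldStatus.UNTESTED)


def _transition_midpoints(fmap: VisualFieldMap) -> list[tuple[float, float]]:
    """Midpoints of edges between 4-neighbouring INTACT/DEFECT cell pairs."""
    mids = []
    p = fmap.pitch_deg
    for (i, j), st in fmap.cells.items():
        if st is not FieldStatus.INTACT:
            continue
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if fmap.cells.get((i + di, j + dj)) is FieldStatus.ABSOLUTE_DEFECT:
                mids.append(((i + di / 2.0) * p, (j + dj / 2.0) * p))
    return mids


def border_zone(fmap: VisualFieldMap, width: float) -> list[AngularPosition]:
    """Cells forming the intact/defect transition strip of total ``width``.

    Returns every tested cell within ``width/2`` of an INTACT|DEFECT
    transition edge, sorted by (x, y).  Empty when the field has no defect
    (or no intact) cells.
    """
    if width < fmap.pitch_deg:
        raise ValueError("width must be >= grid pitch")
    mids = _transition_midpoints(fmap)
    if not mids:
        return []
    mids_arr = np.asarray(mids)
    out = []
    half = width / 2.0 + 1e-9
    for ij, st in fmap.cells.items():
        if st is FieldStatus.UNTESTED:
            continue
        pos = fmap.cell_position(ij)
        d = np.hypot(mids_arr[:, 0] - pos.x_deg, mids_arr[:, 1] - pos.y_deg).min()
        if d <= half:
            out.append(pos)
    out.sort(key=lambda q: (q.x_deg, q.y_deg))
    return out


def defect_centroid(fmap: VisualFieldMap) -> AngularPosition:
    """Centroid of all defect cells, snapped to the nearest grid cell."""
    defect = [ij for ij, st in fmap.cells.items() if st is FieldStatus.ABSOLUTE_DEFECT]
    if not defect:
        raise ValueError("field map contains no defect")
    cx = float(np.mean([ij[0] for ij in defect])) * fmap.pitch_deg
    cy = float(np.mean([ij[1] for ij in defect])) * fmap.pitch_deg
    i, j = _nearest_index(cx, fmap.pitch_deg), _nearest_index(cy, fmap.pitch_deg)
    return fmap.cell_position((i, j))


def blind_spot_stimulus_sites(
    fmap: VisualFieldMap,
    n: int,
    mode: Literal["centroid", "jitter"] = "centroid",
    rng: np.random.Generator | None = None,
) -> list[AngularPosition]:
    """``n`` stimulus positions inside the mapped defect.

    ``centroid`` (default) places all ``n`` at the defect's centroid cell;
    ``jitter`` spreads them uniformly within one pitch of the centroid,
    rejection-sampled so every site still classifies ABSOLUTE_DEFECT.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    c = defect_centroid(fmap)
    if classify_point(fmap, c) is not FieldStatus.ABSOLUTE_DEFECT:
        # centroid of a concave defect can fall outside it; fall back to the
        # defect cell nearest the centroid
        defect = fmap.positions_with_status(FieldStatus.ABSOLUTE_DEFECT)
        c = min(defect, key=lambda q: angular_distance(q, c))
    if mode == "centroid":
        return [c] * n
    if rng is None:
        rng = np.random.default_rng()
    sites: list[AngularPosition] = []
    while len(sites) < n:
        dx, dy = rng.uniform(-fmap.pitch_deg, fmap.pitch_deg, size=2)
        cand = AngularPosition(c.x_deg + dx, c.y_deg + dy)
        if classify_point(fmap, cand) is FieldStatus.ABSOLUTE_DEFECT:
            sites.append(cand)
    return sites


# ---------------------------------------------------------------------------
# CSV I/O: header x_deg,y_deg,status with status in {intact,defect,untested}.
# Left-eye maps are written (and read back) with the x axis in natural signs,
# i.e. mirrored relative to the internal temporal-positive convention.


def _io_sign(eye: str) -> float:
    return -1.0 if eye == "left" else 1.0


def write_field_csv(fmap: VisualFieldMap, path: str | Path) -> None:
    sign = _io_sign(fmap.eye)
    rows = []
    for (i, j), st in fmap.cells.items():
        rows.append((sign * i * fmap.pitch_deg, j * fmap.pitch_deg, st.value))
    rows.sort()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_deg", "y_deg", "status"])
        for x, y, s in rows:
            w.writerow([f"{x:g}", f"{y:g}", s])


def read_field_csv(path: str | Path, eye: str = "right") -> VisualFieldMap:
    """Read a field map, validating grid regularity (constant pitch, full square)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x_deg", "y_deg", "status"} <= set(reader.fieldnames):
            raise ValueError("field CSV must have header x_deg,y_deg,status")
        pts = [(float(r["x_deg"]), float(r["y_deg"]), r["status"]) for r in reader]
    if not pts:
        raise ValueError("field CSV is empty")
    sign = _io_sign(eye)
    xs = sorted({p[0] for p in pts})
    ys = sorted({p[1] for p in pts})
    steps = {round(b - a, 9) for a, b in zip(xs, xs[1:])} | {
        round(b - a, 9) for a, b in zip(ys, ys[1:])
    }
    if len(steps) > 1:
        raise ValueError(f"irregular grid: observed pitches {sorted(steps)}")
    pitch = steps.pop() if steps else DEFAULT_PITCH_DEG
    extent = max(abs(xs[0]), abs(xs[-1]), abs(ys[0]), abs(ys[-1]))
    by_status = {"intact": FieldStatus.INTACT, "defect": FieldStatus.ABSOLUTE_DEFECT,
                 "untested": FieldStatus.UNTESTED}
    cells: dict[tuple[int, int], FieldStatus] = {}
    for x, y, s in pts:
        if s not in by_status:
            raise ValueError(f"unknown status {s!r} at ({x}, {y})")
        i = round(sign * x / pitch)
        j = round(y / pitch)
        if abs(sign * x - i * pitch) > 1e-6 or abs(y - j * pitch) > 1e-6:
            raise ValueError(f"({x}, {y}) is not on the {pitch} deg grid")
        cells[(i, j)] = by_status[s]
    n = int(round(extent / pitch))
    if len(cells) != (2 * n + 1) ** 2:
        raise ValueError("grid is not a full square (missing or duplicate cells)")
    return VisualFieldMap(eye=eye, pitch_deg=pitch, extent_deg=extent, cells=cells)  # type: ignore[arg-type]
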