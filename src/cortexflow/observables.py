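"""Measurements on simulated trajectories.

The membrane is the phi = 0.5 level set; from its extracted contour the
module computes the quantities used to characterize polarization:

* furrow depth -- the maximum inward displacement of a *localized* contour
  arc relative to the undeformed (t = 0) membrane.  A furrow is a contiguous
  arc shorter than a quarter of the perimeter whose points have moved inward
  by more than a detection threshold; global shrinkage of a whole domain is
  deliberately excluded from the depth measure.
* T_pol -- the time for the tracked anterior-posterior position (the furrow
  bottom when a furrow exists, otherwise the steepest point of the cortical
  actomyosin profile along the membrane) to travel to the cell's AP midpoint.
* a three-way behavior classification: wild-type (bounded furrow travelling
  with the PAR interface), runaway invagination (unboundedly deepening,
  anteriorly oriented), or anterior collapse (strong anterior contraction
  with at most a very shallow furrow).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage import measure

from .grid import Grid

__all__ = [
    "MembraneContour",
    "ContourTopologyError",
    "BehaviorClass",
    "PolarizationReport",
    "extract_contour",
    "furrow_depth",
    "furrow_profile",
    "time_to_polarization",
    "classify_behavior",
]

#: Inward displacements below this (um, about half a coarse grid cell) do not
#: count as a furrow.
DETECTION_THRESHOLD = 0.2

#: A furrow arc must be shorter than this fraction of the perimeter.
MAX_FURROW_ARC_FRACTION = 0.25


class ContourTopologyError(RuntimeError):
    """phi = 0.5 does not have exactly one closed contour."""


class BehaviorClass(str, Enum):
    WILD_TYPE = "wild_type"
    RUNAWAY_INVAGINATION = "runaway_invagination"
    ANTERIOR_COLLAPSE = "anterior_collapse"


@dataclass
class MembraneContour:
    """Closed, counterclockwise polyline of membrane points in um."""

    points: np.ndarray  # (n, 2) array of (x, y)
    time: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("contour needs an (n>=3, 2) point array")
        # enforce counterclockwise orientation (positive shoelace area)
        if _signed_area(pts) < 0:
            pts = pts[::-1]
        self.points = pts

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def area(self) -> float:
        return abs(_signed_area(self.points))

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def midpoint_y(self) -> float:
        """AP midpoint: mean of the contour's extreme y values."""
        return 0.5 * (float(self.y.min()) + float(self.y.max()))


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_contour(grid: Grid, phi: np.ndarray, time: float = 0.0,
                    min_perimeter: float = 2.0) -> MembraneContour:
    """Sub-grid-accurate phi = 0.5 contour by marching squares.

    Contours shorter than ``min_perimeter`` (um) are ignored as numerical
    debris; exactly one closed contour must remain or a
    :class:`ContourTopologyError` is raised (e.g. furrow self-contact
    pinching the cell in two, or no interface at all).
    """
    raw = measure.find_contours(phi, 0.5)
    closed = []
    for c in raw:
        if not np.allclose(c[0], c[-1]):
            continue  # open contour: touches the box boundary
        pts = np.column_stack([
            grid.x[0] + c[:-1, 0] * grid.dx,
            grid.y[0] + c[:-1, 1] * grid.dy,
        ])
        if len(pts) >= 3:
            contour = MembraneContour(pts, time)
            if contour.perimeter() >= min_perimeter:
                closed.append(contour)
    if len(closed) != 1:
        raise ContourTopologyError(
            f"expected exactly 1 closed phi=0.5 contour, found {len(closed)}"
        )
    return closed[0]


def _inward_displacement(contour: MembraneContour,
                         reference: MembraneContour) -> np.ndarray:
    """Signed distance of each contour point to the reference membrane;
    positive inside the reference cell (i.e. the membrane moved inward)."""
    ref_poly = reference.polygon()
    boundary = ref_poly.exterior
    pts = shapely.points(contour.points)
    dist = shapely.distance(boundary, pts)
    inside = shapely.contains(ref_poly, pts)
    return np.where(inside, dist, -dist)


@dataclass
class FurrowMeasurement:
    depth: float
    bottom: tuple[float, float] | None  # deepest point (x, y)
    tip_angle_deg: float | None  # dent axis angle relative to the AP (+y) axis


def furrow_candidates(contour: MembraneContour,
                      reference: MembraneContour,
                      threshold: float = DETECTION_THRESHOLD,
                      ) -> list[FurrowMeasurement]:
    """All localized inward dents relative to the reference membrane.

    Candidate furrows are contiguous contour arcs with inward displacement
    above ``threshold`` spanning less than a quarter of the perimeter
    (whole-domain shrinkage is excluded).  The tip angle is the direction
    from the dent mouth to its deepest point, measured from the anterior
    (+y) axis; 0 deg means the furrow tip points anteriorly.
    """
    disp = _inward_displacement(contour, reference)
    mask = disp > threshold
    if not np.any(mask) or np.all(mask):
        return []
    n = len(mask)
    pts = contour.points
    seg = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)
    perimeter = float(seg.sum())
    # contiguous runs on the closed contour; roll so index 0 is outside a run
    start = int(np.argmin(mask))
    rolled = np.roll(mask, -start)
    runs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            runs.append(((i + start) % n, (j - 1 + start) % n))
            i = j
        else:
            i += 1
    out = []
    for lo, hi in runs:
        idx = (np.arange(lo, lo + ((hi - lo) % n) + 1)) % n
        arc_len = float(seg[idx[:-1]].sum()) if len(idx) > 1 else 0.0
        if arc_len >= MAX_FURROW_ARC_FRACTION * perimeter:
            continue  # whole-domain shrinkage, not a furrow
        k = idx[int(np.argmax(disp[idx]))]
        mouth = 0.5 * (pts[lo] + pts[hi])
        axis = pts[k] - mouth
        angle = float(np.degrees(np.arctan2(axis[0], axis[1])))
        out.append(FurrowMeasurement(float(disp[k]),
                                     (float(pts[k][0]), float(pts[k][1])),
                                     abs(angle)))
    return out


def furrow_profile(contour: MembraneContour,
                   reference: MembraneContour,
                   threshold: float = DETECTION_THRESHOLD,
                   near_y: float | None = None,
                   window: float = 8.0) -> FurrowMeasurement:
    """The deepest localized dent, optionally restricted to a y window.

    With ``near_y`` given, only candidates whose bottom lies within
    ``window`` um of that AP position are considered (used to follow the
    travelling pseudocleavage furrow through transient dents elsewhere on
    the membrane); if none qualify, the result is "no furrow".
    """
    cands = furrow_candidates(contour, reference, threshold)
    if near_y is not None:
        cands = [c for c in cands if abs(c.bottom[1] - near_y) <= window]
    if not cands:
        return FurrowMeasurement(0.0, None, None)
    return max(cands, key=lambda c: c.depth)


def furrow_depth(contour: MembraneContour,
                 reference: MembraneContour,
                 threshold: float = DETECTION_THRESHOLD) -> float:
    """Depth of the pseudocleavage furrow in um (0 if none detected)."""
    return furrow_profile(contour, reference, threshold).depth


def time_to_polarization(times: np.ndarray,
                         tracked_y: np.ndarray,
                         midpoint_y: np.ndarray | float) -> float | None:
    """First time the tracked AP position reaches the cell midpoint.

    The tracked position is the furrow bottom while a furrow exists,
    otherwise the steepest point of the actomyosin profile along the
    membrane (supplied by the caller); linear interpolation between samples.
    Returns None when the midpoint is not reached within the series
    (censored run).
    """
    times = np.asarray(times, dtype=float)
    tracked_y = np.asarray(tracked_y, dtype=float)
    mid = np.broadcast_to(np.asarray(midpoint_y, dtype=float), times.shape)
    excess = tracked_y - mid
    if excess[0] >= 0:
        return 0.0
    above = np.where(excess >= 0)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    t0, t1 = times[i - 1], times[i]
    e0, e1 = excess[i - 1], excess[i]
    return float(t0 + (t1 - t0) * (-e0) / (e1 - e0))


@dataclass
class PolarizationReport:
    """Summary measurements of one simulation run."""

    times: np.ndarray  # sample times, s (cadence 50 s)
    depths: np.ndarray  # furrow depth series, um
    tracked_y: np.ndarray  # AP position of furrow / PAR interface, um
    midpoint_y: np.ndarray  # AP midpoint of the current contour, um
    anterior_share: np.ndarray  # fraction of cell area anterior of y = 0
    t_pol: float | None = None
    behavior: BehaviorClass | None = None
    ambiguous: bool = False
    failure: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def average_depth(self) -> float:
        """Mean furrow depth over samples up to polarization (or run end)."""
        if self.t_pol is not None:
            sel = self.times <= self.t_pol + 1.0e-9
            if np.any(sel):
                return float(np.mean(self.depths[sel]))
        return float(np.mean(self.depths)) if len(self.depths) else 0.0

    @property
    def censored(self) -> bool:
        return self.t_pol is None

    def to_dict(self) -> dict:
        return {
            "t_pol": self.t_pol,
            "average_depth": self.average_depth,
            "max_depth": float(np.max(self.depths)) if len(self.depths) else 0.0,
            "behavior": self.behavior.value if self.behavior else None,
            "ambiguous": self.ambiguous,
            "censored": self.censored,
            "failure": self.failure,
            "times": self.times.tolist(),
            "depths": self.depths.tolist(),
            "tracked_y": self.tracked_y.tolist(),
            "midpoint_y": self.midpoint_y.tolist(),
            "anterior_share": self.anterior_share.tolist(),
            **self.extras,
        }


#: Classification thresholds (um / fractions); the source model gives none,
#: so these are tunable package defaults chosen to separate the three
#: canonical phenotypes cleanly.
RUNAWAY_DEPTH = 8.0
COLLAPSE_SHARE_FRACTION = 0.7
COLLAPSE_MAX_DEPTH = 1.0


def classify_behavior(report: PolarizationReport) -> tuple[BehaviorClass, bool]:
    """Deterministic three-way classification of a (completed or halted) run.

    Returns (behavior, ambiguous).  Runaway invagination: the furrow exceeds
    RUNAWAY_DEPTH um and is still deepening at the end of the record (or the
    run halted on furrow self-contact).  Anterior collapse: the anterior
    area share falls below COLLAPSE_SHARE_FRACTION of its initial value
    while the furrow stays below COLLAPSE_MAX_DEPTH um.  Everything else is
    wild-type.  The ambiguous flag marks runs straddling a threshold
    (within 10%).
    """
    depths = np.asarray(report.depths, dtype=float)
    share = np.asarray(report.anterior_share, dtype=float)
    if len(depths) == 0:
        raise ValueError("empty report")
    max_depth = float(np.max(depths))
    deepening = len(depths) >= 3 and depths[-1] >= 0.95 * max_depth > 0
    halted_on_contact = report.failure is not None and "topology" in report.failure
    share_ratio = float(share[-1] / share[0]) if share[0] > 0 else 1.0

    if (max_depth > RUNAWAY_DEPTH and deepening) or halted_on_contact:
        ambiguous = max_depth < 1.1 * RUNAWAY_DEPTH and not halted_on_contact
        return BehaviorClass.RUNAWAY_INVAGINATION, ambiguous
    if share_ratio < COLLAPSE_SHARE_FRACTION and max_depth < COLLAPSE_MAX_DEPTH:
        ambiguous = share_ratio > 0.9 * COLLAPSE_SHARE_FRACTION
        return BehaviorClass.ANTERIOR_COLLAPSE, ambiguous
    ambiguous = (max_depth > 0.9 * RUNAWAY_DEPTH) or (
        share_ratio < COLLAPSE_SHARE_FRACTION / 0.9
        and max_depth < COLLAPSE_MAX_DEPTH
    )
    return BehaviorClass.WILD_TYPE, ambiguous
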