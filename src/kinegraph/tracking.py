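"""Cell detection and tracking in time-lapse microscopy frames.

Cells of two size classes (large cancer cells, small immune cells) appear
as bright disks; they are detected per frame with a circular Hough
transform and linked across frames by solving the optimal assignment
problem (Hungarian/Munkres algorithm) with a cost equal to the inverse of
the candidate distance and a hard gate on the maximum link distance
(40 px for cancer cells, 20 px for immune cells by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "Detection",
    "CellTrack",
    "detect_cells",
    "link_frame",
    "track_population",
    "CANCER_MAX_LINK_PX",
    "IMMUNE_MAX_LINK_PX",
]

CANCER_MAX_LINK_PX = 40.0
IMMUNE_MAX_LINK_PX = 20.0

#: numerical guard for the inverse-distance assignment cost
_COST_EPS = 1e-6


@dataclass(frozen=True)
class Detection:
    """One detected circular object."""

    x: float
    y: float
    radius: float
    frame: int = 0
    score: float = 0.0

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class CellTrack:
    """Per-frame positions of one cell; gaps (missed frames) allowed."""

    track_id: int
    population: str = "cancer"
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)
    radii: list[float] = field(default_factory=list)

    def append(self, det: Detection) -> None:
        self.frames.append(det.frame)
        self.positions.append((det.x, det.y))
        self.radii.append(det.radius)

    @property
    def last_position(self) -> tuple[float, float]:
        return self.positions[-1]

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    def position_at(self, frame: int) -> tuple[float, float] | None:
        try:
            return self.positions[self.frames.index(frame)]
        except ValueError:
            return None

    def velocity_at(self, frame: int) -> float | None:
        """Instantaneous speed (px/frame) from the previous linked position."""
        try:
            i = self.frames.index(frame)
        except ValueError:
            return None
        if i == 0:
            return None
        dt = self.frames[i] - self.frames[i - 1]
        d = float(np.hypot(
            self.positions[i][0] - self.positions[i - 1][0],
            self.positions[i][1] - self.positions[i - 1][1],
        ))
        return d / dt


def detect_cells(
    frame_image: np.ndarray,
    radius_range: tuple[float, float],
    sensitivity: float = 0.5,
    max_cells: int = 50,
    frame: int = 0,
    min_separation: float | None = None,
) -> list[Detection]:
    """Circular-Hough detection of bright disk-like cells.

    Edges are extracted with a Canny filter; accumulator peaks above
    ``sensitivity`` (relative to the theoretical maximum) are returned as
    detections.  Call once per population with its radius range.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.size == 0 or np.ptp(img) == 0:
        return []
    img = (img - img.min()) / np.ptp(img)
    edges = canny(img, sigma=1.5)
    lo, hi = radius_range
    radii = np.arange(max(2, int(round(lo))), int(round(hi)) + 1)
    accum = hough_circle(edges, radii)
    if min_separation is None:
        min_separation = max(3, int(round(lo)))
    peaks = hough_circle_peaks(
        accum,
        radii,
        total_num_peaks=max_cells,
        min_xdistance=int(min_separation),
        min_ydistance=int(min_separation),
        threshold=sensitivity,
    )
    out = []
    h, w = img.shape
    for score, cx, cy, r in zip(*peaks):
        if 0 <= cx < w and 0 <= cy < h:
            out.append(Detection(float(cx), float(cy), float(r), frame, float(score)))
    return out


def assignment_cost(distance: float) -> float:
    """Inverse-distance pairing cost (regularized at zero distance)."""
    return 1.0 / (distance + _COST_EPS)


def link_frame(
    tracks: list[CellTrack],
    detections: list[Detection],
    max_link_distance: float,
    next_track_id: int | None = None,
    population: str = "cancer",
) -> list[CellTrack]:
    """Link one frame's detections to existing tracks (in place).

    Solves the globally optimal assignment under the inverse-distance cost;
    pairs farther apart than ``max_link_distance`` are forbidden.
    Unassigned detections start new tracks; unassigned tracks keep a gap.

    Note: minimizing total inverse-distance cost would *favor* distant
    pairs, so the optimal pairing maximizes total inverse-distance benefit
    (equivalently: the Munkres problem on negated benefits), which pairs
    nearest candidates globally.
    """
    if next_track_id is None:
        next_track_id = 1 + max((t.track_id for t in tracks), default=-1)
    if not detections:
        return tracks
    active = [t for t in tracks if t.positions]
    n_t, n_d = len(active), len(detections)
    if n_t:
        cost = np.zeros((n_t, n_d))
        feasible = np.zeros((n_t, n_d), dtype=bool)
        for i, t in enumerate(active):
            tx, ty = t.last_position
            for j, d in enumerate(detections):
                dist = float(np.hypot(d.x - tx, d.y - ty))
                if dist <= max_link_distance:
                    cost[i, j] = -assignment_cost(dist)
                    feasible[i, j] = True
        # an infeasible slot costs the same as leaving it unassigned, so
        # the optimum never trades a good pair to avoid an empty slot
        cost[~feasible] = 0.0
        rows, cols = linear_sum_assignment(cost)
        assigned = set()
        for i, j in zip(rows, cols):
            if feasible[i, j]:
                active[i].append(detections[j])
                assigned.add(j)
    else:
        assigned = set()
    for j, d in enumerate(detections):
        if j not in assigned:
            t = CellTrack(next_track_id, population)
            next_track_id += 1
            t.append(d)
            tracks.append(t)
    return tracks


def track_population(
    stack: np.ndarray,
    radius_range: tuple[float, float],
    max_link_distance: float,
    sensitivity: float = 0.5,
    population: str = "cancer",
    max_cells: int = 50,
) -> list[CellTrack]:
    """Detect and link one cell population across a whole image stack."""
    tracks: list[CellTrack] = []
    for f in range(stack.shape[0]):
        dets = detect_cells(
            stack[f], radius_range, sensitivity, max_cells=max_cells, frame=f
        )
        link_frame(tracks, dets, max_link_distance, population=population)
    return tracks
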