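"""Morphodynamic descriptors of the main cancer cell (MCC).

Fifteen descriptors per frame, in four groups:

* shape — area, perimeter, circularity (4*pi*area/perimeter^2),
  eccentricity of the second-moment ellipse, instantaneous shape change
  (absolute difference of equivalent diameters between consecutive frames);
  the equivalent diameter sqrt(4*area/pi) is reported as an auxiliary
  column;
* motility — instantaneous velocity, net displacement from the first
  position, directionality (net displacement / curvilinear distance);
* state — apoptosis and division step flags ("No" until the event, "Yes"
  afterwards), consumed from an event-annotation table;
* interaction — counts of immune cells within the contact radius
  r1 = r_im + r_ca + 2 and the vicinity radius r2 = 2 (r_im + r_ca),
  minimal cancer-immune distance within r2, and mean instantaneous immune
  speeds within each radius.

Distances are in pixels and times in frame intervals; at the reference
magnification 1 px = 0.645 um and 1 frame = 2 min (converters provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.segmentation import morphological_chan_vese

from .tracking import (
    CANCER_MAX_LINK_PX,
    IMMUNE_MAX_LINK_PX,
    CellTrack,
    track_population,
)

__all__ = [
    "PIXEL_SIZE_UM",
    "FRAME_INTERVAL_MIN",
    "IMMUNE_RADIUS_PX",
    "CANCER_RADIUS_PX",
    "interaction_radii",
    "px_to_um",
    "frames_to_minutes",
    "segment_mcc",
    "shape_descriptors",
    "circularity",
    "equivalent_diameter",
    "motility_descriptors",
    "interaction_descriptors",
    "state_flags",
    "extract_feature_table",
    "FEATURE_COLUMNS",
]

PIXEL_SIZE_UM = 0.645
FRAME_INTERVAL_MIN = 2.0
IMMUNE_RADIUS_PX = 4.0
CANCER_RADIUS_PX = 14.0

#: the 15 descriptors, plus the auxiliary equivalent diameter
FEATURE_COLUMNS = [
    "area",
    "perimeter",
    "circularity",
    "eccentricity",
    "equivalent_diameter",
    "instantaneous_shape_change",
    "velocity",
    "net_displacement",
    "directionality",
    "apoptosis",
    "division",
    "n_interactions_r2",
    "n_interactions_r1",
    "min_distance_r2",
    "mean_immune_velocity_r2",
    "mean_immune_velocity_r1",
]


def px_to_um(px: float) -> float:
    return px * PIXEL_SIZE_UM


def frames_to_minutes(frames: float) -> float:
    return frames * FRAME_INTERVAL_MIN


def interaction_radii(
    r_im: float = IMMUNE_RADIUS_PX, r_ca: float = CANCER_RADIUS_PX
) -> tuple[float, float]:
    """Contact and vicinity interaction radii around a cancer cell.

    r1 = r_im + r_ca + 2 (physical contact), r2 = 2 (r_im + r_ca) (close
    vicinity); 20 px and 36 px at the default cell radii."""
    return (r_im + r_ca + 2.0, 2.0 * (r_im + r_ca))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

_MIN_REGION_AREA_PX2 = 9.0


def segment_mcc(
    frame_image: np.ndarray,
    seed_xy: tuple[float, float],
    seed_radius: float,
    window_factor: float = 3.0,
    iterations: int = 60,
) -> np.ndarray | None:
    """Segment the cell around a detected circle with a deformable contour.

    A morphological Chan-Vese active contour runs in a window around the
    seed, initialized at the detected circle; the connected component
    containing the seed is returned as a full-frame boolean mask.  Falls
    back to Otsu thresholding when the contour collapses; returns None
    (collapse flag) when the region stays below 9 px^2.
    """
    img = np.asarray(frame_image, dtype=float)
    h, w = img.shape
    cx, cy = seed_xy
    half = int(round(window_factor * seed_radius))
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    win = img[y0:y1, x0:x1]
    if win.size == 0 or np.ptp(win) == 0:
        return None
    win = (win - win.min()) / np.ptp(win)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    init = (np.hypot(xx - cx, yy - cy) <= seed_radius).astype(np.int8)
    if init.sum() == 0:
        return None
    ls = morphological_chan_vese(win, num_iter=iterations, init_level_set=init)
    mask = _seed_component(ls.astype(bool), cx - x0, cy - y0)
    if not _acceptable(win, mask):
        # threshold fallback for low-contrast boundaries
        thr = threshold_otsu(win)
        mask = _seed_component(win > thr, cx - x0, cy - y0)
    if not _acceptable(win, mask):
        return None
    full = np.zeros((h, w), dtype=bool)
    full[y0:y1, x0:x1] = mask
    return full


def _acceptable(win: np.ndarray, mask: np.ndarray | None) -> bool:
    """A usable region is large enough and clearly brighter than the rest
    of the window (rejects regions carved out of pure background noise)."""
    if mask is None or mask.sum() < _MIN_REGION_AREA_PX2 or mask.all():
        return False
    fg = win[mask].mean()
    bg = win[~mask]
    return (fg - bg.mean()) > 3.0 * (bg.std() + 1e-9)


def _seed_component(binary: np.ndarray, sx: float, sy: float) -> np.ndarray | None:
    labels = measure.label(binary)
    iy, ix = int(round(sy)), int(round(sx))
    iy = min(max(iy, 0), labels.shape[0] - 1)
    ix = min(max(ix, 0), labels.shape[1] - 1)
    lab = labels[iy, ix]
    if lab == 0:
        # search a small neighborhood around the seed
        sub = labels[max(0, iy - 3): iy + 4, max(0, ix - 3): ix + 4]
        vals, counts = np.unique(sub[sub > 0], return_counts=True)
        if vals.size == 0:
            return None
        lab = vals[np.argmax(counts)]
    return labels == lab


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def circularity(area: float, perimeter: float) -> float:
    """4 * area * pi / perimeter^2; 1 for a perfect circle."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * area * np.pi / perimeter**2


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the same area, sqrt(4 * area / pi)."""
    return float(np.sqrt(4.0 * area / np.pi))


def shape_descriptors(mask: np.ndarray) -> dict[str, float]:
    """Area, perimeter, circularity, eccentricity, equivalent diameter of a
    binary region (largest connected component if several)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    props = max(
        measure.regionprops(measure.label(mask)), key=lambda p: p.area
    )
    area = float(props.area)
    # Crofton-formula perimeter: much less discretization bias than the
    # chain-code boundary length, keeping circularity <= 1 + O(0.05)
    perimeter = float(props.perimeter_crofton)
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": circularity(area, perimeter) if perimeter > 0 else np.nan,
        "eccentricity": float(props.eccentricity),
        "equivalent_diameter": equivalent_diameter(area),
    }


# ---------------------------------------------------------------------------
# motility
# ---------------------------------------------------------------------------

def motility_descriptors(
    positions: np.ndarray,
    diameters: np.ndarray | None = None,
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Velocity, net displacement, directionality and shape change per frame.

    ``positions`` is an (n, 2) array of consecutive (x, y) positions.  The
    first frame has undefined velocity/shape change (NaN).  Directionality
    is net displacement over curvilinear distance, 0 for a cell that has
    not moved.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
        raise ValueError("need an (n >= 2, 2) position array")
    steps = np.hypot(*np.diff(p, axis=0).T)
    velocity = np.concatenate(([np.nan], steps / frame_interval))
    net = np.hypot(p[:, 0] - p[0, 0], p[:, 1] - p[0, 1])
    curvilinear = np.concatenate(([0.0], np.cumsum(steps)))
    with np.errstate(invalid="ignore", divide="ignore"):
        directionality = np.where(curvilinear > 0, net / curvilinear, 0.0)
    out = pd.DataFrame(
        {
            "velocity": velocity,
            "net_displacement": net,
            "directionality": directionality,
        }
    )
    if diameters is not None:
        d = np.asarray(diameters, dtype=float)
        out["instantaneous_shape_change"] = np.concatenate(
            ([np.nan], np.abs(np.diff(d)))
        )
    return out


# ---------------------------------------------------------------------------
# interactions and state
# ---------------------------------------------------------------------------

def interaction_descriptors(
    mcc_position: tuple[float, float],
    immune_tracks: list[CellTrack],
    frame: int,
    r1: float | None = None,
    r2: float | None = None,
) -> dict[str, float]:
    """Immune-cell counts and kinetics around the MCC at one frame."""
    if r1 is None or r2 is None:
        d1, d2 = interaction_radii()
        r1 = d1 if r1 is None else r1
        r2 = d2 if r2 is None else r2
    if r1 > r2:
        raise ValueError("need r1 <= r2")
    mx, my = mcc_position
    dist_r2, speeds_r2, speeds_r1 = [], [], []
    n_r1 = 0
    for t in immune_tracks:
        pos = t.position_at(frame)
        if pos is None:
            continue
        d = float(np.hypot(pos[0] - mx, pos[1] - my))
        if d > r2:
            continue
        dist_r2.append(d)
        v = t.velocity_at(frame)
        if v is not None:
            speeds_r2.append(v)
        if d <= r1:
            n_r1 += 1
            if v is not None:
                speeds_r1.append(v)
    return {
        "n_interactions_r2": len(dist_r2),
        "n_interactions_r1": n_r1,
        "min_distance_r2": min(dist_r2) if dist_r2 else np.nan,
        "mean_immune_velocity_r2": float(np.mean(speeds_r2)) if speeds_r2 else np.nan,
        "mean_immune_velocity_r1": float(np.mean(speeds_r1)) if speeds_r1 else np.nan,
    }


def state_flags(
    n_frames: int,
    apoptosis_frame: int | None = None,
    division_frames: list[int] | tuple[int, ...] = (),
) -> pd.DataFrame:
    """'No'/'Yes' step flags: 'No' before the event, 'Yes' from it onwards."""
    for f in ([apoptosis_frame] if apoptosis_frame is not None else []) + list(
        division_frames
    ):
        if not (0 <= f < n_frames):
            raise ValueError(f"event frame {f} outside track span 0..{n_frames - 1}")
    apo = np.array(["No"] * n_frames, dtype=object)
    if apoptosis_frame is not None:
        apo[apoptosis_frame:] = "Yes"
    div = np.array(["No"] * n_frames, dtype=object)
    if division_frames:
        div[min(division_frames):] = "Yes"
    return pd.DataFrame({"apoptosis": apo, "division": div})


# ---------------------------------------------------------------------------
# full extraction pipeline
# ---------------------------------------------------------------------------

@dataclass
class ExtractionConfig:
    cancer_radius: float = CANCER_RADIUS_PX
    immune_radius: float = IMMUNE_RADIUS_PX
    cancer_radius_band: float = 4.0
    immune_radius_band: float = 2.0
    cancer_max_link: float = CANCER_MAX_LINK_PX
    immune_max_link: float = IMMUNE_MAX_LINK_PX
    sensitivity: float = 0.5
    max_gap: int = 5
    frame_interval: float = 1.0


def extract_feature_table(
    stack: np.ndarray,
    events: pd.DataFrame | None = None,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Full pipeline on one video crop: detect, track, segment, describe.

    The main cancer cell (MCC) is the cancer track starting nearest the
    image center.  ``events`` is an annotation table with columns
    ``track_id, event, frame`` (event in {"apoptosis", "division"}), with
    track_id 0 referring to the MCC.  Returns one row per frame with the
    15 descriptors (plus frame and equivalent diameter).
    """
    cfg = config or ExtractionConfig()
    stack = np.asarray(stack)
    n_frames, h, w = stack.shape

    cancer = track_population(
        stack,
        (cfg.cancer_radius - cfg.cancer_radius_band,
         cfg.cancer_radius + cfg.cancer_radius_band),
        cfg.cancer_max_link,
        cfg.sensitivity,
        population="cancer",
        max_cells=10,
    )
    immune = track_population(
        stack,
        (cfg.immune_radius - cfg.immune_radius_band,
         cfg.immune_radius + cfg.immune_radius_band),
        cfg.immune_max_link,
        cfg.sensitivity,
        population="immune",
        max_cells=60,
    )
    starters = [t for t in cancer if t.frames and t.frames[0] == 0]
    if not starters:
        raise ValueError("no cancer cell detected in the first frame")
    center = np.array([w / 2.0, h / 2.0])
    mcc = min(
        starters,
        key=lambda t: float(np.hypot(*(np.array(t.positions[0]) - center))),
    )

    # truncate at the first long gap in the MCC track
    kept_frames: list[int] = []
    for i, f in enumerate(mcc.frames):
        if i > 0 and f - mcc.frames[i - 1] > cfg.max_gap:
            import warnings

            warnings.warn(
                f"main cancer cell lost for more than {cfg.max_gap} frames; "
                f"feature table truncated at frame {mcc.frames[i - 1]}"
            )
            break
        kept_frames.append(f)

    rows = []
    diameters: list[float] = []
    positions: list[tuple[float, float]] = []
    for i, f in enumerate(kept_frames):
        pos = mcc.position_at(f)
        radius = mcc.radii[mcc.frames.index(f)]
        mask = segment_mcc(stack[f], pos, radius)
        if mask is None:
            shape = {k: np.nan for k in
                     ("area", "perimeter", "circularity", "eccentricity",
                      "equivalent_diameter")}
        else:
            shape = shape_descriptors(mask)
        positions.append(pos)
        diameters.append(shape["equivalent_diameter"])
        inter = interaction_descriptors(pos, immune, f)
        rows.append({"frame": f, **shape, **inter})

    table = pd.DataFrame(rows)
    mot = motility_descriptors(
        np.array(positions), np.array(diameters), cfg.frame_interval
    )
    for c in mot.columns:
        table[c] = mot[c].to_numpy()

    apoptosis_frame = None
    division_frames: list[int] = []
    if events is not None and len(events):
        mcc_events = events[events["track_id"] == 0]
        for r in mcc_events.itertuples(index=False):
            if r.event == "apoptosis":
                apoptosis_frame = int(r.frame)
            elif r.event == "division":
                division_frames.append(int(r.frame))
    idx_of = {f: i for i, f in enumerate(kept_frames)}
    flags = state_flags(
        len(kept_frames),
        idx_of.get(apoptosis_frame) if apoptosis_frame is not None else None,
        [idx_of[f] for f in division_frames if f in idx_of],
    )
    table["apoptosis"] = flags["apoptosis"].to_numpy()
    table["division"] = flags["division"].to_numpy()
    return table[["frame"] + FEATURE_COLUMNS]
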