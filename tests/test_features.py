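"""Shape, motility, state and interaction descriptors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinegraph.features import (
    circularity,
    equivalent_diameter,
    interaction_descriptors,
    interaction_radii,
    motility_descriptors,
    segment_mcc,
    shape_descriptors,
    state_flags,
)
from kinegraph.tracking import CellTrack, Detection


def test_interaction_radii_defaults():
    """r1 = r_im + r_ca + 2 = 20 px, r2 = 2 (r_im + r_ca) = 36 px."""
    r1, r2 = interaction_radii()
    assert r1 == 20.0
    assert r2 == 36.0


def test_circularity_ideal_circle():
    r = 7.3
    assert circularity(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)


def test_equivalent_diameter_formula():
    assert equivalent_diameter(100 * np.pi) == pytest.approx(20.0)


def _disk_mask(r, size=None):
    size = size or int(4 * r)
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(xx - size / 2, yy - size / 2) <= r


def _ellipse_mask(a, b, size=None):
    size = size or int(3 * a)
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - size / 2) / a) ** 2 + ((yy - size / 2) / b) ** 2 <= 1


def test_rasterized_disk_descriptors():
    sd = shape_descriptors(_disk_mask(40))
    assert sd["eccentricity"] <= 0.05
    assert sd["circularity"] == pytest.approx(1.0, abs=0.1)
    assert sd["area"] == pytest.approx(np.pi * 40**2, rel=0.02)
    assert sd["equivalent_diameter"] == pytest.approx(80, rel=0.02)


def test_rasterized_ellipse_eccentricity():
    sd = shape_descriptors(_ellipse_mask(20, 10))
    assert sd["eccentricity"] == pytest.approx(np.sqrt(1 - 0.25), abs=0.1)


def test_empty_mask_raises():
    with pytest.raises(ValueError):
        shape_descriptors(np.zeros((10, 10), dtype=bool))


def test_circularity_bounded_on_masks():
    rng = np.random.default_rng(0)
    for _ in range(5):
        mask = _disk_mask(rng.uniform(5, 30))
        assert shape_descriptors(mask)["circularity"] <= 1.1
        assert 0 <= shape_descriptors(mask)["eccentricity"] <= 1


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _render(mask, amp=170.0, noise=3.0, seed=0):
    rng = np.random.default_rng(seed)
    img = 30.0 + amp * mask.astype(float)
    img += rng.standard_normal(mask.shape) * noise
    return np.clip(img, 0, 255).astype(np.uint8)


def test_segment_disk_area():
    mask = _disk_mask(14, 100)
    img = _render(mask)
    seg = segment_mcc(img, (50, 50), 14)
    assert seg is not None
    assert seg.sum() == pytest.approx(np.pi * 14**2, rel=0.10)


def test_segment_ellipse_eccentricity():
    mask = _ellipse_mask(20, 10, 120)
    img = _render(mask)
    seg = segment_mcc(img, (60, 60), 15)
    sd = shape_descriptors(seg)
    assert sd["eccentricity"] == pytest.approx(0.866, abs=0.1)


def test_segment_blank_background_collapses():
    rng = np.random.default_rng(1)
    img = (30 + rng.standard_normal((100, 100)) * 2).astype(np.uint8)
    assert segment_mcc(img, (50, 50), 10) is None


# ---------------------------------------------------------------------------
# motility
# ---------------------------------------------------------------------------

def test_straight_track_oracle():
    """(3,4) steps: velocity 5 px/frame, directionality 1 throughout."""
    p = np.cumsum([[3, 4]] * 10, axis=0).astype(float)
    m = motility_descriptors(p)
    assert np.allclose(m["velocity"][1:], 5.0)
    assert np.allclose(m["directionality"][1:], 1.0)
    assert m["net_displacement"].iloc[-1] == pytest.approx(45.0)


def test_closed_loop_zero_directionality():
    square = np.array(
        [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float
    )
    m = motility_descriptors(square)
    assert m["net_displacement"].iloc[-1] == 0.0
    assert m["directionality"].iloc[-1] == 0.0


def test_stationary_cell_directionality_zero():
    m = motility_descriptors(np.zeros((5, 2)))
    assert (m["directionality"] == 0).all()


def test_shape_change_from_diameters():
    p = np.cumsum(np.ones((4, 2)), axis=0)
    m = motility_descriptors(p, diameters=np.array([10.0, 12.0, 11.0, 11.0]))
    assert np.isnan(m["instantaneous_shape_change"][0])
    assert list(m["instantaneous_shape_change"][1:]) == [2.0, 1.0, 0.0]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 1000))
def test_directionality_decreases_under_detours(seed):
    """Perturbing interior points (endpoints fixed) can only lower the
    final directionality: the net displacement is unchanged while the
    curvilinear distance grows."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 12))
    base = np.cumsum(rng.uniform(0.5, 2.0, (n, 2)), axis=0)
    d0 = motility_descriptors(base)["directionality"].iloc[-1]
    bent = base.copy()
    bent[1:-1] += rng.normal(0, 3.0, (n - 2, 2))
    d1 = motility_descriptors(bent)["directionality"].iloc[-1]
    assert d1 <= d0 + 1e-12


# ---------------------------------------------------------------------------
# interactions and state
# ---------------------------------------------------------------------------

def _immune_at(distances, frame=1):
    tracks = []
    for i, d in enumerate(distances):
        t = CellTrack(i, "immune")
        t.append(Detection(100.0 + d, 100.0, 4.0, frame - 1))
        t.append(Detection(100.0 + d, 100.0, 4.0, frame))
        tracks.append(t)
    return tracks


def test_interaction_counts_and_min_distance():
    tracks = _immune_at([10, 25, 50])
    out = interaction_descriptors((100.0, 100.0), tracks, frame=1)
    assert out["n_interactions_r1"] == 1
    assert out["n_interactions_r2"] == 2
    assert out["min_distance_r2"] == pytest.approx(10.0)
    assert out["mean_immune_velocity_r2"] == 0.0


def test_interaction_none_in_range():
    tracks = _immune_at([100, 200])
    out = interaction_descriptors((100.0, 100.0), tracks, frame=1)
    assert out["n_interactions_r2"] == 0
    assert np.isnan(out["min_distance_r2"])
    assert np.isnan(out["mean_immune_velocity_r2"])


def test_interaction_r1_le_r2_validation():
    with pytest.raises(ValueError):
        interaction_descriptors((0, 0), [], 0, r1=30, r2=20)


def test_state_flags_step_function():
    flags = state_flags(200, apoptosis_frame=100)
    assert (flags["apoptosis"][:100] == "No").all()
    assert (flags["apoptosis"][100:] == "Yes").all()
    assert (flags["division"] == "No").all()


def test_state_flags_boundary_and_none():
    flags = state_flags(50, division_frames=[0])
    assert (flags["division"] == "Yes").all()
    flags = state_flags(50)
    assert (flags == "No").all().all()


def test_state_flags_outside_span_errors():
    with pytest.raises(ValueError):
        state_flags(100, apoptosis_frame=100)
    with pytest.raises(ValueError):
        state_flags(100, division_frames=[-1])
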