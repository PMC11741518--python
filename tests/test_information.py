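"""Penalized information estimators against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinegraph.data import TimeSeriesDataset, VariableSpec
from kinegraph.information import (
    conditional_mutual_information,
    mutual_information,
    three_point_information,
    transfer_entropy,
)

CAT = VariableSpec("c", "categorical", 4)


def gaussian_pair(rho, n, rng):
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return x, y


@pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
def test_gaussian_oracle_within_15_percent(rho):
    """Raw MI tracks the bivariate-normal closed form -0.5*ln(1-rho^2)."""
    rng = np.random.default_rng(42)
    x, y = gaussian_pair(rho, 10_000, rng)
    truth = -0.5 * np.log(1 - rho**2)
    est = mutual_information(x, y)
    assert abs(est.raw_info - truth) <= 0.15 * truth


def test_discrete_plugin_oracle():
    """Categorical MI equals the plug-in formula by direct summation."""
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 400)
    y = np.where(rng.random(400) < 0.3, 1 - x, x)  # noisy copy
    spec = VariableSpec("b", "categorical", 2)
    est = mutual_information(x, y, spec, spec)
    joint = np.zeros((2, 2))
    for a, b in zip(x, y):
        joint[a, b] += 1
    joint /= joint.sum()
    px, py = joint.sum(1), joint.sum(0)
    direct = sum(
        joint[i, j] * np.log(joint[i, j] / (px[i] * py[j]))
        for i in range(2)
        for j in range(2)
        if joint[i, j] > 0
    )
    assert est.raw_info == pytest.approx(direct, abs=1e-12)


def test_self_information_uniform_discrete():
    """I(X;X) of a uniform 4-level variable approaches ln 4."""
    rng = np.random.default_rng(2)
    x = rng.integers(0, 4, 10_000)
    est = mutual_information(x, x, CAT, CAT)
    assert est.raw_info == pytest.approx(np.log(4), rel=0.01)


def test_noiseless_continuous_copy_significant():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(100)
    assert mutual_information(x, x).penalized > 0


def test_symmetry_exact():
    rng = np.random.default_rng(4)
    x, y = gaussian_pair(0.5, 500, rng)
    assert mutual_information(x, y).raw_info == mutual_information(y, x).raw_info


def test_independence_calibration():
    """Independent data is declared independent >= 95% of the time."""
    rng = np.random.default_rng(5)
    neg = 0
    reps = 100
    for _ in range(reps):
        x, y = rng.standard_normal((2, 500))
        if mutual_information(x, y).penalized <= 0:
            neg += 1
    assert neg >= 0.95 * reps


def test_constant_vector_zero_info():
    x = np.ones(100)
    y = np.arange(100.0)
    est = mutual_information(x, y)
    assert est.raw_info == 0.0
    assert est.penalized <= 0


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        mutual_information(np.zeros(10), np.zeros(11))


def test_empty_conditioning_reduces_to_mi():
    rng = np.random.default_rng(6)
    x, y = gaussian_pair(0.4, 800, rng)
    mi = mutual_information(x, y)
    cmi = conditional_mutual_information(x, y, [])
    assert cmi.raw_info == mi.raw_info
    assert cmi.complexity == mi.complexity


def test_markov_chain_conditional_independence():
    """X -> Z -> Y: dependent marginally, independent given Z."""
    rng = np.random.default_rng(7)
    n = 5000
    x = rng.standard_normal(n)
    z = 0.8 * x + 0.6 * rng.standard_normal(n)
    y = 0.8 * z + 0.6 * rng.standard_normal(n)
    assert mutual_information(x, y).penalized > 0
    assert conditional_mutual_information(x, y, [z]).penalized <= 0


def test_collider_activation():
    """X -> Z <- Y: independent marginally, dependent given Z."""
    rng = np.random.default_rng(8)
    n = 5000
    x, y = rng.standard_normal((2, n))
    z = x + y + 0.5 * rng.standard_normal(n)
    assert mutual_information(x, y).penalized <= 0
    assert conditional_mutual_information(x, y, [z]).penalized > 0


def test_three_point_signs():
    rng = np.random.default_rng(9)
    n = 5000
    x, y = rng.standard_normal((2, n))
    z_col = x + y + 0.5 * rng.standard_normal(n)
    assert three_point_information(x, y, z_col).penalized < 0  # collider
    x2 = rng.standard_normal(n)
    z_chain = 0.8 * x2 + 0.6 * rng.standard_normal(n)
    y2 = 0.8 * z_chain + 0.6 * rng.standard_normal(n)
    assert three_point_information(x2, y2, z_chain).penalized > 0  # chain
    irrelevant = rng.standard_normal(n)
    t = three_point_information(x2, y2, irrelevant)
    assert t.penalized <= 0 or abs(t.raw) < 0.01  # no significant 3-point


def test_three_point_chain_consistency():
    """Raw three-point info equals I(x;y) - I(x;y|z) of the estimators."""
    rng = np.random.default_rng(10)
    x, y = gaussian_pair(0.5, 2000, rng)
    z = 0.5 * x + rng.standard_normal(2000)
    t = three_point_information(x, y, z)
    base = mutual_information(x, y)
    cond = conditional_mutual_information(x, y, [z])
    assert t.raw == pytest.approx(base.raw_info - cond.raw_info, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_mi_nonnegative_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(50, 300))
    x = rng.standard_normal(n)
    y = rng.standard_normal(n) + (0.5 * x if seed % 2 else 0)
    a = mutual_information(x, y)
    b = mutual_information(y, x)
    assert a.raw_info >= 0
    assert a.raw_info == b.raw_info
    assert a.penalized <= a.n_samples * a.raw_info


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------

def test_transfer_entropy_vanishes_without_feedback(pair_model_a):
    _, ds = pair_model_a
    tyx = transfer_entropy(ds, "Y", "X", max_lag=2)
    txy = transfer_entropy(ds, "X", "Y", max_lag=2)
    assert tyx.penalized <= 0
    assert tyx.significant_info == 0.0
    assert txy.penalized > 0


def test_transfer_entropy_positive_with_lagged_feedback(pair_model_b):
    _, ds = pair_model_b
    assert transfer_entropy(ds, "Y", "X", max_lag=2).penalized > 0


def test_transfer_entropy_unknown_variable(pair_model_a):
    _, ds = pair_model_a
    with pytest.raises(KeyError):
        transfer_entropy(ds, "nope", "X")


def test_transfer_entropy_short_trajectories():
    import pandas as pd

    frame = pd.DataFrame(
        {"id": [0, 0, 1, 1, 1, 1, 1, 1], "X": np.arange(8.0),
         "Y": np.arange(8.0) ** 2}
    )
    ds = TimeSeriesDataset(frame, trajectory_col="id")
    with pytest.warns(UserWarning):
        est = transfer_entropy(ds, "X", "Y", max_lag=2)
    assert est.n_samples == 4  # only the 6-step trajectory contributes
    too_short = TimeSeriesDataset(frame.iloc[:2], trajectory_col="id")
    with pytest.raises(ValueError):
        transfer_entropy(too_short, "X", "Y", max_lag=2)
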