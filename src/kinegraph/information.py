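"""Penalized information estimators for mixed continuous/categorical data.

All quantities are in nats.  The estimators follow a supremum principle for
finite samples: continuous variables are rank-discretized on a grid of
equal-frequency partitions and the reported information is the supremum of
the bias-corrected plug-in estimate over that grid, while the independence
*statistic* is the supremum of the penalized score

    n * I_hat(partition) - complexity(partition)

with a model-selection complexity growing with the number of bins/levels and
with the size of the conditioning set.  A positive penalized score means the
dependence survives the finite-sample penalty; a score <= 0 is treated as
(conditional) independence.  This yields a signed statistic usable directly
as an independence test without any p-value machinery.

Transfer entropy ``T[X -> Y] = I(Y_t ; X_past | Y_past)`` is built on the
same primitive via the chain rule over the source lags, so each term stays
low-dimensional and individually penalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import TimeSeriesDataset, VariableSpec, KIND_CONTINUOUS

__all__ = [
    "EstimatorCache",
    "InfoEstimate",
    "ThreePointInfo",
    "mutual_information",
    "conditional_mutual_information",
    "three_point_information",
    "three_point_stat",
    "transfer_entropy",
]

#: hard cap on the number of bins for any single continuous variable
_MAX_BINS = 24
#: geometric ladder of candidate bin counts
_BIN_LADDER = (2, 3, 4, 6, 9, 14, 21)
#: shorter ladder used under conditioning (within-cell partitions)
_COND_BIN_LADDER = (2, 4, 8)


class EstimatorCache:
    """Memoizes per-column discretizations and conditioning-cell indexes.

    Pass one instance through repeated estimator calls on columns of the
    same sample matrix (keys identify columns) to avoid re-ranking them.
    """

    def __init__(self):
        self.codes: dict = {}  # (key, n_bins|'cat') -> (codes, n_levels)
        self.joint: dict = {}  # (tuple of (key, n_bins|'cat')) -> (codes, cells)


@dataclass(frozen=True)
class InfoEstimate:
    """Result of a penalized (conditional) mutual-information estimate.

    Attributes
    ----------
    raw_info : float
        Bias-corrected information estimate, clamped at 0 (nats).
    complexity : float
        Finite-sample penalty ``k`` such that ``penalized = n*raw_info - k``.
    n_samples : int
        Number of samples used.
    """

    raw_info: float
    complexity: float
    n_samples: int

    @property
    def penalized(self) -> float:
        """Signed independence statistic ``n * raw_info - complexity``."""
        return self.n_samples * self.raw_info - self.complexity

    @property
    def significant_info(self) -> float:
        """Shrunk per-sample information, ``max(0, penalized) / n`` (nats).

        Zero whenever the dependence does not survive the penalty."""
        return max(0.0, self.penalized) / self.n_samples


@dataclass(frozen=True)
class ThreePointInfo:
    """Signed three-point information ``I(x;y;z|U)`` with its penalization.

    ``raw = I(x;y|U) - I(x;y|U,z)``; a negative value means conditioning on
    ``z`` *increases* the information shared by x and y (collider signature),
    a positive value means ``z`` explains part of it (chain/fork signature).
    ``penalized`` shrinks ``n * raw`` toward zero by the complexity increment
    of the larger conditioning set: it is nonzero only when the three-point
    information is significant, and keeps the sign of ``raw``.
    """

    raw: float
    penalized: float
    n_samples: int


def three_point_stat(
    x,
    y,
    z,
    U: Sequence = (),
    spec_x: VariableSpec | None = None,
    spec_y: VariableSpec | None = None,
    spec_z: VariableSpec | None = None,
    u_specs: Sequence[VariableSpec] | None = None,
    cache: "EstimatorCache | None" = None,
    keys: tuple | None = None,
    margin: str = "bic",
    relative_guard: float = 0.05,
) -> float:
    """Shrunk, signed significance of the three-point information I(x;y;z|U).

    Both I(x;y|U) and I(x;y|U,z) are evaluated over the *same* ladder of
    pair partitions (the one affordable under the larger conditioning set),
    so the comparison isolates the effect of conditioning on ``z`` from
    partition-resolution effects.  Positive: z is a significant contributor
    (chain/fork); negative: z significantly raises the x-y dependence
    (collider); zero: no significant three-point interaction.

    ``margin`` selects the complexity increment charged per extra degree of
    freedom: "bic" (0.5 ln n, conservative; used for orientations) or "aic"
    (1, liberal; used when screening candidate contributors, where the final
    edge decision is still made by the fully penalized statistic).
    """
    x = _as_array(x)
    y = _as_array(y)
    n = x.size
    spec_x = spec_x or VariableSpec("x", KIND_CONTINUOUS)
    spec_y = spec_y or VariableSpec("y", KIND_CONTINUOUS)
    spec_z = spec_z or VariableSpec("z", KIND_CONTINUOUS)
    U = [_as_array(u) for u in U]
    if u_specs is None:
        u_specs = [VariableSpec(f"u{i}", KIND_CONTINUOUS) for i in range(len(U))]
    kx, ky, kz, ku = keys if keys is not None else (None, None, None, None)
    z = _as_array(z)
    bins0 = (
        _allocate_bins(U, list(u_specs), x, y, n, cache, ku, kx, ky)
        if U
        else None
    )
    zc0, c0, tag0 = _encode_conditioning(U, list(u_specs), n, cache, ku, bins0)
    ext = U + [z]
    ext_specs = list(u_specs) + [spec_z]
    ext_keys = None if (ku is None or kz is None) else (*ku, kz)
    bins1 = _allocate_bins(ext, ext_specs, x, y, n, cache, ext_keys, kx, ky)
    zc1, c1, tag1 = _encode_conditioning(
        ext, ext_specs, n, cache, ext_keys, bins1
    )
    if margin not in ("bic", "aic"):
        raise ValueError("margin must be 'bic' or 'aic'")
    coef = _Z_SCORE if margin == "bic" else 1.0
    cand0 = _pair_partitions(
        x, spec_x, y, spec_y, n, c1, cache, kx, ky,
        zc0 if len(U) else None, tag0,
    )
    cand1 = _pair_partitions(
        x, spec_x, y, spec_y, n, c1, cache, kx, ky, zc1, tag1
    )
    best = 0.0
    for (xc0, bx0, yc0, by0), (xc1, bx1, yc1, by1) in zip(cand0, cand1):
        if bx0 < 2 or by0 < 2 or bx1 < 2 or by1 < 2:
            continue
        i0 = _plugin_cmi(xc0, bx0, yc0, by0, zc0, c0, n)
        i1 = _plugin_cmi(xc1, bx1, yc1, by1, zc1, c1, n)
        df0 = (bx0 - 1) * (by0 - 1) * c0
        df1 = (bx1 - 1) * (by1 - 1) * c1
        i3_mm = (i0 - df0 / (2.0 * n)) - (i1 - df1 / (2.0 * n))
        shrink = coef * abs(np.sqrt(df1) - np.sqrt(df0))
        # the two estimates use slightly different partitions (global vs
        # within-cell): guard against capture mismatch with a relative term
        contributor = n * i3_mm - shrink - relative_guard * n * max(i0, 0.0)
        collider = -n * i3_mm - shrink - relative_guard * n * max(i1, 0.0)
        if contributor > abs(best):
            best = contributor
        if collider > abs(best):
            best = -collider
    return float(best)


# ---------------------------------------------------------------------------
# encoding helpers
# ---------------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError("value vectors must be one-dimensional")
    return arr


def _categorical_codes(x: np.ndarray) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(x, sort=True)
    if (codes < 0).any():
        raise ValueError("missing values are not supported")
    return codes.astype(np.int64), len(uniques)


def _rank_codes(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Equal-frequency codes; ties share a bin, so fewer bins may result."""
    x = x.astype(float)
    if not np.isfinite(x).all():
        raise ValueError("missing/non-finite values are not supported")
    n = x.size
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    codes = (ranks * n_bins) // n
    # merge bins split across tied values: force equal values to equal codes
    sx = x[order]
    sc = codes[order]
    tie_start = np.concatenate(([True], sx[1:] != sx[:-1]))
    sc = sc[np.maximum.accumulate(np.where(tie_start, np.arange(n), 0))]
    codes[order] = sc
    codes, uniq = pd.factorize(codes, sort=True)
    return codes.astype(np.int64), len(uniq)


def _conditional_rank_codes(
    x: np.ndarray, n_bins: int, zc: np.ndarray
) -> tuple[np.ndarray, int]:
    """Equal-frequency codes computed *within* each conditioning cell.

    Aligning the pair partition with the conditional (within-cell)
    distributions keeps the capture efficiency of the plug-in estimate
    independent of how concentrated the conditionals are; global marginal
    bins would cut concentrated conditionals arbitrarily unevenly."""
    x = x.astype(float)
    if not np.isfinite(x).all():
        raise ValueError("missing/non-finite values are not supported")
    n = x.size
    order = np.lexsort((x, zc))
    zs = zc[order]
    cell_change = np.concatenate(([True], zs[1:] != zs[:-1]))
    starts = np.flatnonzero(cell_change)
    sizes = np.diff(np.concatenate((starts, [n])))
    rep_starts = np.repeat(starts, sizes)
    rep_sizes = np.repeat(sizes, sizes)
    pos = np.arange(n) - rep_starts
    codes_sorted = (pos * n_bins) // rep_sizes
    # equal values within a cell share a bin
    sx = x[order]
    tie_start = np.concatenate(([True], sx[1:] != sx[:-1])) | cell_change
    idx = np.maximum.accumulate(np.where(tie_start, np.arange(n), 0))
    codes_sorted = codes_sorted[idx]
    codes = np.empty(n, dtype=np.int64)
    codes[order] = codes_sorted
    return codes, n_bins


def _cached_codes(
    x: np.ndarray,
    spec: VariableSpec,
    n_bins: int,
    cache: "EstimatorCache | None",
    key,
    zc: np.ndarray | None = None,
    z_tag=None,
) -> tuple[np.ndarray, int]:
    if spec.is_discrete:
        tag = "cat"
    elif zc is None:
        tag = n_bins
    else:
        tag = (n_bins, z_tag)
    if cache is not None and key is not None and (key, tag) in cache.codes:
        return cache.codes[(key, tag)]
    if spec.is_discrete:
        out = _categorical_codes(x)
    elif zc is None:
        out = _rank_codes(x, n_bins)
    else:
        out = _conditional_rank_codes(x, n_bins, zc)
    if cache is not None and key is not None and (zc is None or z_tag is not None):
        cache.codes[(key, tag)] = out
    return out


#: residual variance fraction of a standard normal after equal-frequency
#: binning -- the "leak" of a binned conditioner
_LEAK_FRACTION = {2: 0.363, 4: 0.139, 8: 0.039, 16: 0.010, 32: 0.0024,
                  64: 0.0006}
#: joint conditioning-cell budget divisor (budget = n / _BUDGET_DIV)
_BUDGET_DIV = 30.0
#: finest per-conditioner resolution
_MAX_COND_BINS = 16


def _normalized_ranks(
    x: np.ndarray, cache: "EstimatorCache | None", key
) -> np.ndarray:
    tag = (key, "rank")
    if cache is not None and key is not None and tag in cache.codes:
        return cache.codes[tag]
    order = np.argsort(x, kind="stable")
    r = np.empty(x.size)
    r[order] = np.arange(x.size)
    r = (r - r.mean()) / max(r.std(), 1.0)
    if cache is not None and key is not None:
        cache.codes[tag] = r
    return r


def _allocate_bins(
    Z: Sequence[np.ndarray],
    z_specs: Sequence[VariableSpec],
    x: np.ndarray,
    y: np.ndarray,
    n: int,
    cache: "EstimatorCache | None",
    z_keys,
    kx,
    ky,
) -> tuple[int, ...]:
    """Per-conditioner resolutions under a global cell budget.

    A coarsely binned conditioner leaks its within-bin residual into the
    pair, faking conditional dependence; the leak scales with how strongly
    the conditioner is associated with the pair.  Bins are therefore
    doubled greedily on the conditioner with the largest remaining leak
    proxy (rank correlation x residual bin variance) while the joint cell
    budget allows."""
    budget = max(16.0, n / _BUDGET_DIV)
    rx = _normalized_ranks(_as_array(x).astype(float), cache, kx)
    ry = _normalized_ranks(_as_array(y).astype(float), cache, ky)
    bins: list[int] = []
    strength: list[float] = []
    for i, (z, spec) in enumerate(zip(Z, z_specs)):
        if spec.is_discrete:
            bins.append(0)  # categorical: levels are fixed
            strength.append(0.0)
            continue
        rz = _normalized_ranks(
            z.astype(float), cache, None if z_keys is None else z_keys[i]
        )
        s = max(abs(float(rz @ rx)), abs(float(rz @ ry))) / n
        bins.append(2)
        strength.append(s)
    levels = [
        (b if b else max(2, s.n_levels or 2))
        for b, s in zip(bins, z_specs)
    ]
    while True:
        best_i, best_gain = -1, 0.0
        total = float(np.prod([max(l, 1) for l in levels]))
        for i, b in enumerate(bins):
            if b == 0 or b >= _MAX_COND_BINS:
                continue
            if total / levels[i] * (b * 2) > budget:
                continue
            gain = strength[i] * _LEAK_FRACTION[b]
            if gain > best_gain:
                best_i, best_gain = i, gain
        if best_i < 0:
            break
        bins[best_i] *= 2
        levels[best_i] = bins[best_i]
    return tuple(bins)


def _encode_conditioning(
    Z: Sequence[np.ndarray],
    z_specs: Sequence[VariableSpec],
    n: int,
    cache: "EstimatorCache | None" = None,
    z_keys: Sequence | None = None,
    bins: Sequence[int] | None = None,
) -> tuple[np.ndarray, int, tuple | None]:
    """Joint cell index over the conditioning set, compressed to observed
    cells.  ``bins`` holds the per-conditioner resolutions (0 = categorical).
    Returns (codes, n_cells, cache tag)."""
    if not Z:
        return np.zeros(n, dtype=np.int64), 1, None
    if bins is None:
        bins = [0 if s.is_discrete else 4 for s in z_specs]
    joint_key = None
    if cache is not None and z_keys is not None:
        joint_key = tuple(sorted(zip(z_keys, bins)))
        if joint_key in cache.joint:
            out = cache.joint[joint_key]
            return out[0], out[1], joint_key
    joint = np.zeros(n, dtype=np.int64)
    for i, (z, spec) in enumerate(zip(Z, z_specs)):
        z = _as_array(z)
        if z.size != n:
            raise ValueError("conditioning vector length mismatch")
        codes, levels = _cached_codes(
            z, spec, bins[i], cache, None if z_keys is None else z_keys[i]
        )
        joint = joint * max(levels, 1) + codes
    joint, uniq = pd.factorize(joint, sort=True)
    out = joint.astype(np.int64), len(uniq)
    if joint_key is not None:
        cache.joint[joint_key] = out
    return out[0], out[1], joint_key


def _candidate_codes(
    x: np.ndarray,
    spec: VariableSpec,
    n: int,
    n_zcells: int,
    cache: "EstimatorCache | None" = None,
    key=None,
    zc: np.ndarray | None = None,
    z_tag=None,
) -> list[tuple[np.ndarray, int]]:
    if spec.is_discrete:
        return [_cached_codes(x, spec, 0, cache, key)]
    # per-cell sample budget caps the partition size
    b_cap = int(min(_MAX_BINS, n ** (1.0 / 3.0), np.sqrt(n / (5.0 * n_zcells))))
    source = _BIN_LADDER if n_zcells <= 1 else _COND_BIN_LADDER
    ladder = [b for b in source if b <= max(2, b_cap)]
    if not ladder:
        ladder = [2]
    if n_zcells <= 1:
        zc = None
    return [_cached_codes(x, spec, b, cache, key, zc, z_tag) for b in ladder]


def _pair_partitions(
    x: np.ndarray,
    spec_x: VariableSpec,
    y: np.ndarray,
    spec_y: VariableSpec,
    n: int,
    n_zcells: int,
    cache: "EstimatorCache | None",
    kx,
    ky,
    zc: np.ndarray | None = None,
    z_tag=None,
) -> list[tuple[np.ndarray, int, np.ndarray, int]]:
    """Joint partition candidates for the (x, y) pair.

    Continuous variables are quantile-binned within each conditioning cell
    (see :func:`_conditional_rank_codes`).  Continuous-continuous pairs use
    matched (square) resolutions; a categorical side keeps its levels fixed
    while the other side walks the bin ladder."""
    cand_x = _candidate_codes(x, spec_x, n, n_zcells, cache, kx, zc, z_tag)
    cand_y = _candidate_codes(y, spec_y, n, n_zcells, cache, ky, zc, z_tag)
    if not spec_x.is_discrete and not spec_y.is_discrete:
        return [
            (xc, bx, yc, by) for (xc, bx), (yc, by) in zip(cand_x, cand_y)
        ]
    return [
        (xc, bx, yc, by) for xc, bx in cand_x for yc, by in cand_y
    ]


# ---------------------------------------------------------------------------
# plug-in conditional MI on integer codes
# ---------------------------------------------------------------------------

#: one-sided normal quantile guarding the conditioning-cell noise
_Z_SCORE = 2.8


def _complexity(df_pair: int, n_zcells: int, log_n: float) -> float:
    """Finite-sample penalty for one (pair partition, conditioning) choice.

    BIC-style term on the pair partition (guards the supremum over
    partitions) plus a noise-quantile term scaling like the standard
    deviation of the plug-in statistic over all cells (sqrt of the total
    degrees of freedom) -- so fine conditioning resolutions stay
    affordable and can certify conditional independence."""
    df_total = df_pair * n_zcells
    return 0.5 * df_pair * log_n + _Z_SCORE * np.sqrt(df_total)


def _plugin_cmi(
    xc: np.ndarray, bx: int, yc: np.ndarray, by: int, zc: np.ndarray, bz: int, n: int
) -> float:
    """Plug-in conditional MI (nats) from integer codes via contingency counts."""
    xy = xc * by + yc
    flat = zc * (bx * by) + xy
    counts = np.bincount(flat, minlength=bz * bx * by)
    nz = np.bincount(zc, minlength=bz)
    nxz = np.bincount(zc * bx + xc, minlength=bz * bx)
    nyz = np.bincount(zc * by + yc, minlength=bz * by)
    idx = np.nonzero(counts)[0]
    c = counts[idx].astype(float)
    y_i = idx % by
    t = idx // by
    x_i = t % bx
    z_i = t // bx
    # grouped so the expression and the final sum are exactly symmetric
    # under an (x, y) swap
    val = c * (
        (np.log(c) + np.log(nz[z_i]))
        - (np.log(nxz[z_i * bx + x_i]) + np.log(nyz[z_i * by + y_i]))
    )
    return float(np.sort(val).sum()) / n


def _estimate(
    x,
    y,
    Z: Sequence,
    spec_x: VariableSpec,
    spec_y: VariableSpec,
    z_specs: Sequence[VariableSpec],
    cache: EstimatorCache | None = None,
    keys: tuple | None = None,
) -> InfoEstimate:
    x = _as_array(x)
    y = _as_array(y)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if n < 2:
        raise ValueError("need at least 2 samples")
    kx, ky, kz = keys if keys is not None else (None, None, None)
    Z = [_as_array(z) for z in Z]
    log_n = np.log(n)

    bins = (
        _allocate_bins(Z, z_specs, x, y, n, cache, kz, kx, ky) if Z else None
    )
    zc, n_zcells, z_tag = _encode_conditioning(Z, z_specs, n, cache, kz, bins)

    best_raw = 0.0
    best_pen = -np.inf
    for xc, bx, yc, by in _pair_partitions(
        x, spec_x, y, spec_y, n, n_zcells, cache, kx, ky,
        zc if Z else None, z_tag,
    ):
        if bx < 2 or by < 2:
            # constant column: zero information by convention
            best_pen = max(best_pen, -_complexity(1, n_zcells, log_n))
            continue
        i_plug = _plugin_cmi(xc, bx, yc, by, zc, n_zcells, n)
        df = (bx - 1) * (by - 1) * n_zcells
        i_mm = i_plug - df / (2.0 * n)  # Miller-Madow bias correction
        pen = n * i_mm - _complexity((bx - 1) * (by - 1), n_zcells, log_n)
        # all-categorical pairs report the exact plug-in value
        raw_candidate = (
            i_plug if (spec_x.is_discrete and spec_y.is_discrete) else i_mm
        )
        if raw_candidate > best_raw:
            best_raw = raw_candidate
        if pen > best_pen:
            best_pen = pen
    raw = max(0.0, best_raw)
    penalized = min(best_pen, n * raw)
    return InfoEstimate(raw_info=raw, complexity=n * raw - penalized, n_samples=n)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def mutual_information(
    x, y, spec_x: VariableSpec | None = None, spec_y: VariableSpec | None = None
) -> InfoEstimate:
    """Penalized mutual information I(x;y).

    For a pair of categorical variables this is the exact plug-in MI of the
    joint table; for continuous or mixed pairs the discretization supremum
    described in the module docstring.
    """
    spec_x = spec_x or VariableSpec("x", KIND_CONTINUOUS)
    spec_y = spec_y or VariableSpec("y", KIND_CONTINUOUS)
    return _estimate(x, y, [], spec_x, spec_y, [])


def conditional_mutual_information(
    x,
    y,
    Z: Sequence = (),
    spec_x: VariableSpec | None = None,
    spec_y: VariableSpec | None = None,
    z_specs: Sequence[VariableSpec] | None = None,
    cache: EstimatorCache | None = None,
    keys: tuple | None = None,
) -> InfoEstimate:
    """Penalized conditional mutual information I(x;y|Z).

    An empty conditioning set reproduces :func:`mutual_information` exactly.
    ``cache``/``keys`` (column identifiers ``(key_x, key_y, tuple(z_keys))``)
    let repeated calls on columns of one sample matrix share
    discretizations.
    """
    spec_x = spec_x or VariableSpec("x", KIND_CONTINUOUS)
    spec_y = spec_y or VariableSpec("y", KIND_CONTINUOUS)
    Z = list(Z)
    if z_specs is None:
        z_specs = [VariableSpec(f"z{i}", KIND_CONTINUOUS) for i in range(len(Z))]
    if len(z_specs) != len(Z):
        raise ValueError("z_specs length must match Z")
    return _estimate(x, y, Z, spec_x, spec_y, list(z_specs), cache, keys)


def three_point_information(
    x,
    y,
    z,
    U: Sequence = (),
    spec_x: VariableSpec | None = None,
    spec_y: VariableSpec | None = None,
    spec_z: VariableSpec | None = None,
    u_specs: Sequence[VariableSpec] | None = None,
) -> ThreePointInfo:
    """Signed three-point information I(x;y;z|U) = I(x;y|U) - I(x;y|U,z).

    A negative value flags ``z`` as a collider between x and y; a positive
    value flags it as a significant contributor (chain or fork).
    """
    U = list(U)
    if u_specs is None:
        u_specs = [VariableSpec(f"u{i}", KIND_CONTINUOUS) for i in range(len(U))]
    spec_z = spec_z or VariableSpec("z", KIND_CONTINUOUS)
    base = conditional_mutual_information(x, y, U, spec_x, spec_y, list(u_specs))
    cond = conditional_mutual_information(
        x, y, U + [z], spec_x, spec_y, list(u_specs) + [spec_z]
    )
    stat = three_point_stat(x, y, z, U, spec_x, spec_y, spec_z, list(u_specs))
    return ThreePointInfo(
        raw=base.raw_info - cond.raw_info,
        penalized=stat,
        n_samples=base.n_samples,
    )


def _lagged_matrix(
    dataset: TimeSeriesDataset, names: list[str], lags: list[int]
) -> dict[tuple[str, int], np.ndarray]:
    """Stack lagged columns across trajectories; one row per valid anchor."""
    max_lag = max(lags) if lags else 0
    cols: dict[tuple[str, int], list[np.ndarray]] = {
        (v, l): [] for v in names for l in lags
    }
    kept = 0
    for traj in dataset.trajectories():
        T = len(traj)
        if T < max_lag + 2:
            warnings.warn("trajectory shorter than the lag window; skipped")
            continue
        kept += 1
        for v in names:
            arr = traj[v].to_numpy()
            for l in lags:
                cols[(v, l)].append(arr[max_lag - l : T - l])
    if kept == 0:
        raise ValueError("no trajectory is long enough for the requested max_lag")
    return {k: np.concatenate(v) for k, v in cols.items()}


def transfer_entropy(
    dataset: TimeSeriesDataset,
    source: str,
    target: str,
    max_lag: int = 2,
    extra_conditioning: Sequence[str] = (),
) -> InfoEstimate:
    """Penalized transfer entropy ``T[source -> target]``.

    Estimates ``I(Y_t ; X_{t-1..t-L} | Y_{t-1..t-L}, V_{t..t-L})`` where Y is
    the target, X the source and V the optional extra observed variables
    (which discard contributions from indirect observed paths).  The grouped
    source term is expanded by the chain rule into scalar conditional-MI
    terms, each with its own penalty; their raw and penalized values add.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    spec_s = dataset.spec(source)
    spec_t = dataset.spec(target)
    extra = list(extra_conditioning)
    extra_specs = [dataset.spec(v) for v in extra]

    names = sorted({source, target, *extra})
    lags = list(range(0, max_lag + 1))
    cols = _lagged_matrix(dataset, names, lags)

    y_now = cols[(target, 0)]
    base_Z = [cols[(target, l)] for l in range(1, max_lag + 1)]
    base_specs = [spec_t] * max_lag
    for v, sp in zip(extra, extra_specs):
        for l in range(0, max_lag + 1):
            base_Z.append(cols[(v, l)])
            base_specs.append(sp)

    n = y_now.size
    raw = 0.0
    penalized = -np.inf
    for k in range(1, max_lag + 1):
        Z = base_Z + [cols[(source, l)] for l in range(1, k)]
        z_specs = base_specs + [spec_s] * (k - 1)
        est = conditional_mutual_information(
            y_now, cols[(source, k)], Z, spec_t, spec_s, z_specs
        )
        raw += est.raw_info
        # the source past is independent of the target present iff every
        # chain term is: flag dependence when any term survives its penalty
        penalized = max(penalized, est.penalized)
    penalized = min(penalized, n * raw)
    return InfoEstimate(raw_info=raw, complexity=n * raw - penalized, n_samples=n)
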