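"""Ground-truthed synthetic data generators.

Two families of fixtures are produced here:

* **Temporal structural causal models** — stationary 15-node autoregressive
  networks with linear or nonlinear parent combinations and lags up to 2,
  emulating the sparse degree profile of cellular-feature networks, plus
  small two-variable models reproducing the textbook relation between
  transfer entropy and temporal v-structures, and a latent-confounder model.
* **Synthetic microscopy videos** — bright disk-like cells of two radius
  classes doing drifting random walks on a noisy background, with optional
  division and apoptosis events, together with machine-readable ground truth
  so detection/tracking can be scored end to end.

Every generator is deterministic given its seed and ships its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import TimeSeriesDataset

__all__ = [
    "BenchmarkEdge",
    "BenchmarkNetwork",
    "generate_linear",
    "simulate_linear_network",
    "generate_nonlinear",
    "make_nonstationary",
    "generate_pair_model",
    "generate_latent_pair",
    "render_synthetic_video",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BenchmarkEdge:
    source: str
    target: str
    lag: int
    weight: float
    form: str = "linear"


@dataclass
class BenchmarkNetwork:
    """Ground-truth temporal network used for scoring and parameter recovery."""

    n_nodes: int
    edges: list[BenchmarkEdge]
    node_names: list[str] = field(default_factory=list)
    latent_edges: list[BenchmarkEdge] = field(default_factory=list)

    def __post_init__(self):
        if not self.node_names:
            self.node_names = [f"X{i}" for i in range(self.n_nodes)]

    def edge_set(self) -> set[tuple[str, str, int]]:
        return {(e.source, e.target, e.lag) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.source, e.target, e.lag, e.weight, e.form, False) for e in self.edges
        ] + [
            (e.source, e.target, e.lag, e.weight, e.form, True)
            for e in self.latent_edges
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "lag", "weight", "form", "latent"]
        )


# ---------------------------------------------------------------------------
# linear autoregressive SCM
# ---------------------------------------------------------------------------

def _draw_structure(
    rng: np.random.Generator,
    n_nodes: int,
    density: float,
    p_contemporaneous: float,
) -> list[BenchmarkEdge]:
    """Sparse edge set: one autoregressive self-edge per node plus cross
    edges at mean cross-degree ``2 * density`` with lags in {0, 1, 2}."""
    names = [f"X{i}" for i in range(n_nodes)]
    if density == 0:
        return []  # independent white noise, empty ground truth
    edges = [
        BenchmarkEdge(v, v, 1, float(rng.uniform(0.3, 0.7))) for v in names
    ]
    n_cross = int(round(density * n_nodes))
    order = rng.permutation(n_nodes)  # topological order for lag-0 edges
    rank = {names[v]: i for i, v in enumerate(order)}
    seen = set()
    while sum(1 for e in edges if e.source != e.target) < n_cross:
        i, j = rng.choice(n_nodes, size=2, replace=False)
        lag = 0 if rng.random() < p_contemporaneous else int(rng.integers(1, 3))
        s, t = names[i], names[j]
        if lag == 0 and rank[s] > rank[t]:
            s, t = t, s
        if (s, t, lag) in seen or (lag == 0 and (t, s, 0) in seen):
            continue
        seen.add((s, t, lag))
        w = float(rng.uniform(0.2, 0.8)) * (1 if rng.random() < 0.5 else -1)
        edges.append(BenchmarkEdge(s, t, lag, w))
    return edges


def _coefficient_matrices(
    edges: Sequence[BenchmarkEdge], names: list[str]
) -> list[np.ndarray]:
    idx = {v: i for i, v in enumerate(names)}
    p = len(names)
    A = [np.zeros((p, p)) for _ in range(3)]
    for e in edges:
        A[e.lag][idx[e.target], idx[e.source]] = e.weight
    return A


def _spectral_radius(A: list[np.ndarray]) -> float:
    p = A[0].shape[0]
    M = np.linalg.inv(np.eye(p) - A[0])
    top = np.hstack([M @ A[1], M @ A[2]])
    companion = np.vstack([top, np.hstack([np.eye(p), np.zeros((p, p))])])
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def analytic_autocovariance(
    network: BenchmarkNetwork, max_lag: int = 2
) -> list[np.ndarray]:
    """Yule-Walker autocovariance matrices Gamma(0..max_lag) of a linear model.

    Solves the discrete Lyapunov equation of the companion VAR(2) form; used
    as the analytic oracle for the simulated sample covariances.
    """
    names = network.node_names
    p = len(names)
    A = _coefficient_matrices(network.edges, names)
    M = np.linalg.inv(np.eye(p) - A[0])
    B1, B2 = M @ A[1], M @ A[2]
    Sigma_e = M @ M.T  # unit innovations mapped through contemporaneous mixing
    F = np.vstack(
        [np.hstack([B1, B2]), np.hstack([np.eye(p), np.zeros((p, p))])]
    )
    Q = np.zeros((2 * p, 2 * p))
    Q[:p, :p] = Sigma_e
    from scipy.linalg import solve_discrete_lyapunov

    S = solve_discrete_lyapunov(F, Q)
    gammas = [S[:p, :p]]
    state = S[:, :p]
    # Gamma(k) = E[x_t x_{t-k}^T]: propagate the companion state covariance
    for _ in range(max_lag):
        state = F @ state
        gammas.append(state[:p, :p])
    return gammas


def _standardize_weights(
    edges: Sequence[BenchmarkEdge], names: list[str]
) -> list[BenchmarkEdge] | None:
    """Rescale cross-edge weights to act on unit-variance parents.

    Drawn coefficients are interpreted as effect sizes per parent standard
    deviation (the same convention as the nonlinear generator), which keeps
    all stationary variances of order one instead of compounding along
    strongly coupled paths.  Self-edges are dimensionless and untouched.
    Returns the effective (rescaled) edge list, or None if no stable fixed
    point is found."""
    idx = {v: i for i, v in enumerate(names)}
    sigma = np.ones(len(names))
    scaled = list(edges)
    for _ in range(30):
        scaled = [
            e if e.source == e.target
            else BenchmarkEdge(e.source, e.target, e.lag,
                               e.weight / sigma[idx[e.source]], e.form)
            for e in edges
        ]
        if _spectral_radius(_coefficient_matrices(scaled, names)) >= 0.95:
            return None
        gamma0 = analytic_autocovariance(
            BenchmarkNetwork(len(names), list(scaled), list(names)), 0
        )[0]
        new_sigma = np.sqrt(np.clip(np.diag(gamma0), 1e-6, None))
        if np.allclose(new_sigma, sigma, rtol=1e-4):
            break
        sigma = new_sigma
    return scaled


def _simulate_linear(
    edges: Sequence[BenchmarkEdge],
    names: list[str],
    T: int,
    rng: np.random.Generator,
    burn_in: int = 200,
) -> pd.DataFrame:
    p = len(names)
    A = _coefficient_matrices(edges, names)
    M = np.linalg.inv(np.eye(p) - A[0])
    B1, B2 = M @ A[1], M @ A[2]
    X = np.zeros((T + burn_in, p))
    eps = rng.standard_normal((T + burn_in, p))
    for t in range(2, T + burn_in):
        X[t] = B1 @ X[t - 1] + B2 @ X[t - 2] + M @ eps[t]
    return pd.DataFrame(X[burn_in:], columns=names)


def simulate_linear_network(
    network: BenchmarkNetwork, T: int, seed: int = 0, burn_in: int = 200
) -> TimeSeriesDataset:
    """Simulate a given linear temporal network with unit Gaussian
    innovations (contemporaneous part must be acyclic and the model
    stable)."""
    if _spectral_radius(
        _coefficient_matrices(network.edges, network.node_names)
    ) >= 1.0:
        raise ValueError("network is not stable (spectral radius >= 1)")
    rng = np.random.default_rng(seed)
    frame = _simulate_linear(network.edges, network.node_names, T, rng, burn_in)
    return TimeSeriesDataset(frame)


def generate_linear(
    n_nodes: int = 15,
    T: int = 10_000,
    seed: int = 0,
    density: float = 1.0,
    p_contemporaneous: float = 0.2,
    structure_seed: int | None = None,
) -> tuple[BenchmarkNetwork, TimeSeriesDataset]:
    """Stationary linear autoregressive SCM with lags up to 2.

    ``density`` scales the number of cross edges (``round(density * n_nodes)``,
    i.e. mean cross-degree ~= 2 at the default); coefficients are drawn in
    +/-[0.2, 0.8] and the model is redrawn until its companion spectral
    radius is < 0.9 (so relaxation times stay comparable to the model lags).
    Innovations are unit Gaussian.
    """
    if T < 100:
        raise ValueError("T must be >= 100")
    rng_structure = np.random.default_rng(
        seed if structure_seed is None else structure_seed
    )
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(n_nodes)]
    for _ in range(_MAX_REDRAWS):
        edges = _draw_structure(rng_structure, n_nodes, density, p_contemporaneous)
        if _spectral_radius(_coefficient_matrices(edges, names)) >= 0.9:
            continue
        effective = _standardize_weights(edges, names)
        if effective is None:
            continue
        network = BenchmarkNetwork(n_nodes, effective, list(names))
        frame = _simulate_linear(effective, names, T, rng)
        return network, TimeSeriesDataset(frame)
    raise RuntimeError("could not draw a stable model after 100 attempts")


# ---------------------------------------------------------------------------
# nonlinear SCM
# ---------------------------------------------------------------------------

_SQRT2 = np.sqrt(2.0)
_E_ABS = np.sqrt(2.0 / np.pi)
_SD_ABS = np.sqrt(1.0 - 2.0 / np.pi)


def _nonlinearity(form: str, u: np.ndarray, v: np.ndarray | None = None) -> np.ndarray:
    """Centered, roughly unit-variance link functions for N(0,1) inputs."""
    u = np.clip(u, -3.0, 3.0)
    if form == "quadratic":
        return (u * u - 1.0) / _SQRT2
    if form == "cosine":
        return (np.cos(np.pi * u)) / np.sqrt(0.5)
    if form == "piecewise":
        return (np.abs(u) - _E_ABS) / _SD_ABS
    if form == "multiplicative":
        v = u if v is None else np.clip(v, -3.0, 3.0)
        return u * v
    raise ValueError(f"unknown nonlinearity {form!r}")


def generate_nonlinear(
    n_nodes: int = 15,
    T: int = 10_000,
    seed: int = 0,
    density: float = 1.0,
    p_contemporaneous: float = 0.2,
    structure_seed: int | None = None,
) -> tuple[BenchmarkNetwork, TimeSeriesDataset]:
    """Stationary SCM whose cross-edge contributions pass through per-edge
    nonlinearities drawn from {quadratic, cosine, piecewise, multiplicative};
    self-dependence stays linear to preserve autocorrelation.  Node inputs
    are standardized by their running scale and the model is re-drawn if the
    running variance is unbounded."""
    if T < 100:
        raise ValueError("T must be >= 100")
    rng_structure = np.random.default_rng(
        seed if structure_seed is None else structure_seed
    )
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(n_nodes)]
    forms = ["quadratic", "cosine", "piecewise", "multiplicative"]
    probs = [0.3, 0.3, 0.3, 0.1]

    for _ in range(_MAX_REDRAWS):
        base = _draw_structure(rng_structure, n_nodes, density, p_contemporaneous)
        edges = []
        for e in base:
            if e.source == e.target:
                edges.append(e)
            else:
                form = rng_structure.choice(forms, p=probs)
                edges.append(
                    BenchmarkEdge(e.source, e.target, e.lag, e.weight, str(form))
                )
        frame = _simulate_nonlinear(edges, names, T, rng)
        if frame is not None:
            return BenchmarkNetwork(n_nodes, edges, list(names)), TimeSeriesDataset(
                frame
            )
    raise RuntimeError("could not draw a bounded nonlinear model after 100 attempts")


def _simulate_nonlinear(
    edges: Sequence[BenchmarkEdge],
    names: list[str],
    T: int,
    rng: np.random.Generator,
    burn_in: int = 300,
) -> pd.DataFrame | None:
    idx = {v: i for i, v in enumerate(names)}
    p = len(names)
    self_coef = np.zeros(p)
    cross = []  # (target, source, lag, weight, form, partner_source or -1)
    by_target: dict[int, list[int]] = {i: [] for i in range(p)}
    for e in edges:
        if e.source == e.target:
            self_coef[idx[e.source]] = e.weight
        else:
            cross.append([idx[e.target], idx[e.source], e.lag, e.weight, e.form, -1])
            by_target[idx[e.target]].append(len(cross) - 1)
    # multiplicative edges pair with another parent of the same node when one
    # exists (falling back to a pure square otherwise)
    for tgt, eids in by_target.items():
        for k, eid in enumerate(eids):
            if cross[eid][4] == "multiplicative" and len(eids) > 1:
                other = cross[eids[(k + 1) % len(eids)]]
                cross[eid][5] = other[1]

    n_total = T + burn_in
    X = np.zeros((n_total, p))
    eps = rng.standard_normal((n_total, p))
    scale = np.ones(p)
    for t in range(2, n_total):
        acc = self_coef * X[t - 1] + eps[t]
        # contemporaneous pass in two sweeps is unnecessary: lag-0 cross edges
        # follow a topological order by construction, so a single ordered
        # update suffices
        for tgt, src, lag, w, form, partner in cross:
            if lag == 0:
                continue
            u = X[t - lag, src] / scale[src]
            v = X[t - lag, partner] / scale[partner] if partner >= 0 else None
            acc[tgt] += w * _nonlinearity(form, np.asarray(u), None if v is None else np.asarray(v))
        X[t] = acc
        for tgt, src, lag, w, form, partner in cross:
            if lag != 0:
                continue
            u = X[t, src] / scale[src]
            v = X[t, partner] / scale[partner] if partner >= 0 else None
            X[t, tgt] += w * _nonlinearity(form, np.asarray(u), None if v is None else np.asarray(v))
        if t == burn_in:
            scale = np.maximum(X[burn_in // 2 : t].std(axis=0), 0.5)
    out = X[burn_in:]
    # stationarity guard: bounded values and stable running variance
    if not np.isfinite(out).all() or np.abs(out).max() > 100:
        return None
    half = len(out) // 2
    v1, v2 = out[:half].var(axis=0), out[half:].var(axis=0)
    if np.any(v2 > 5 * v1 + 1e-9) or np.any(v1 > 5 * v2 + 1e-9):
        return None
    return pd.DataFrame(out, columns=names)


# ---------------------------------------------------------------------------
# nonstationary variant and small didactic models
# ---------------------------------------------------------------------------

def make_nonstationary(
    dataset: TimeSeriesDataset,
    variables: Sequence[str],
    drift: str = "random_walk",
    amplitude: float = 5.0,
    seed: int = 0,
) -> TimeSeriesDataset:
    """Inject nonstationarity into the selected variables; the generating
    network is unchanged.

    The default is a random walk whose cumulative excursion is about
    ``amplitude`` marginal standard deviations over the series: it carries
    memory at every time scale, the behaviour that shows up as multiple
    lagged self-loops in the learned summary graph.  A deterministic linear
    trend ('trend') is also available; note that a trend of a few standard
    deviations over ten thousand steps is locally almost flat and therefore
    nearly invisible inside a short lag window."""
    frame = dataset.frame.copy()
    rng = np.random.default_rng(seed)
    for v in variables:
        col = frame[v].to_numpy(dtype=float)
        sd = col.std()
        T = len(col)
        if drift == "trend":
            col = col + amplitude * sd * np.linspace(0.0, 1.0, T)
        elif drift == "random_walk":
            steps = rng.standard_normal(T) * (amplitude * sd / np.sqrt(T))
            col = col + np.cumsum(steps)
        else:
            raise ValueError("drift must be 'trend' or 'random_walk'")
        frame[v] = col
    return TimeSeriesDataset(
        frame, trajectory_col=dataset.trajectory_col, specs=dataset.specs
    )


def generate_pair_model(
    case: str, T: int = 10_000, seed: int = 0
) -> tuple[BenchmarkNetwork, TimeSeriesDataset]:
    """Two-variable models relating transfer entropy to temporal v-structures.

    case 'a': X autonomous AR(1) (coefficient 0.6) driving Y contemporaneously
    (Y_t = 0.5 X_t + 0.5 Y_{t-1} + eta) -- transfer entropy Y->X vanishes
    structurally while the temporal v-structure Y_{t-1} -> Y_t <- X_t holds.

    case 'b': additionally Y_{t-2} -> X_t (weight 0.3) -- the v-structure at
    Y_t coexists with a strictly positive transfer entropy Y->X.
    """
    if case not in ("a", "b"):
        raise ValueError("case must be 'a' or 'b'")
    rng = np.random.default_rng(seed)
    burn = 200
    n = T + burn
    eps, eta = rng.standard_normal((2, n))
    x = np.zeros(n)
    y = np.zeros(n)
    for t in range(2, n):
        x[t] = 0.6 * x[t - 1] + (0.3 * y[t - 2] if case == "b" else 0.0) + eps[t]
        y[t] = 0.5 * x[t] + 0.5 * y[t - 1] + eta[t]
    edges = [
        BenchmarkEdge("X", "X", 1, 0.6),
        BenchmarkEdge("Y", "Y", 1, 0.5),
        BenchmarkEdge("X", "Y", 0, 0.5),
    ]
    if case == "b":
        edges.append(BenchmarkEdge("Y", "X", 2, 0.3))
    frame = pd.DataFrame({"X": x[burn:], "Y": y[burn:]})
    return BenchmarkNetwork(2, edges, ["X", "Y"]), TimeSeriesDataset(frame)


def generate_latent_pair(
    T: int = 10_000, seed: int = 0
) -> tuple[BenchmarkNetwork, TimeSeriesDataset]:
    """Hidden common cause L driving X_t and Y_{t+1}, plus two observed
    exogenous drivers W -> X and Z -> Y.

    The unobserved L induces an inseparable lagged edge X_{t-1} -- Y_t whose
    two arrowheads (one backward in time) are discoverable through the
    colliders W_{t-1} -> X_{t-1} <- Y_t and Z_t -> Y_t <- X_{t-1}; the
    expected summary edge is bidirected X <-> Y at lag 1.
    """
    rng = np.random.default_rng(seed)
    n = T + 2
    L = rng.standard_normal(n)
    W = rng.standard_normal(n)
    Z = rng.standard_normal(n)
    X = L + 0.7 * W + 0.5 * rng.standard_normal(n)
    Y = np.roll(L, 1) + 0.7 * Z + 0.5 * rng.standard_normal(n)
    frame = pd.DataFrame(
        {"X": X[2:], "Y": Y[2:], "W": W[2:], "Z": Z[2:]}
    )
    network = BenchmarkNetwork(
        4,
        [BenchmarkEdge("W", "X", 0, 0.7), BenchmarkEdge("Z", "Y", 0, 0.7)],
        ["X", "Y", "W", "Z"],
        latent_edges=[BenchmarkEdge("X", "Y", 1, 1.0, "latent")],
    )
    return network, TimeSeriesDataset(frame)


# ---------------------------------------------------------------------------
# synthetic microscopy videos
# ---------------------------------------------------------------------------

@dataclass
class VideoGroundTruth:
    """Per-frame cell positions/radii and event annotations of a rendering."""

    positions: pd.DataFrame  # frame, track_id, population, x, y, radius
    events: pd.DataFrame  # track_id, event, frame

    def at_frame(self, frame: int, population: str | None = None) -> pd.DataFrame:
        sel = self.positions[self.positions["frame"] == frame]
        if population is not None:
            sel = sel[sel["population"] == population]
        return sel


def _drifting_walk(
    rng: np.random.Generator,
    n_frames: int,
    start: np.ndarray,
    step_sd: float,
    drift_sd: float,
    bounds: tuple[int, int],
) -> np.ndarray:
    pos = np.zeros((n_frames, 2))
    pos[0] = start
    drift = rng.standard_normal(2) * drift_sd
    for t in range(1, n_frames):
        drift = 0.95 * drift + 0.2 * drift_sd * rng.standard_normal(2)
        pos[t] = pos[t - 1] + drift + step_sd * rng.standard_normal(2)
        for k, hi in enumerate(bounds):  # reflect at the borders
            if pos[t, k] < 0:
                pos[t, k] = -pos[t, k]
            if pos[t, k] > hi - 1:
                pos[t, k] = 2 * (hi - 1) - pos[t, k]
    return pos


def render_synthetic_video(
    n_immune: int = 6,
    n_cancer: int = 1,
    image_size: tuple[int, int] = (300, 300),
    n_frames: int = 30,
    noise_level: float = 5.0,
    cancer_radius: float = 14.0,
    immune_radius: float = 4.0,
    division_frame: int | None = None,
    apoptosis_frame: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, VideoGroundTruth]:
    """Render bright disk-like cells doing drifting random walks.

    The first cancer track starts at the image center (the main cancer cell
    convention).  ``division_frame`` splits the first cancer cell in two;
    ``apoptosis_frame`` makes it shrink and fade.  Returns a uint8 stack of
    shape (n_frames, H, W) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    records = []
    events = []

    walks = []  # (track_id, population, positions, radius, amplitude)
    tid = 0
    for i in range(n_cancer):
        start = (
            np.array([w / 2.0, h / 2.0])
            if i == 0
            else rng.uniform([30, 30], [w - 30, h - 30])
        )
        walks.append(
            (tid, "cancer", _drifting_walk(rng, n_frames, start, 0.6, 0.4, (w, h)),
             cancer_radius, 170.0)
        )
        tid += 1
    for _ in range(n_immune):
        start = rng.uniform([10, 10], [w - 10, h - 10])
        walks.append(
            (tid, "immune", _drifting_walk(rng, n_frames, start, 1.8, 0.8, (w, h)),
             immune_radius, 130.0)
        )
        tid += 1

    if division_frame is not None:
        events.append((0, "division", division_frame))
        # daughter cell budding off the main cancer cell
        angle = rng.uniform(0, 2 * np.pi)
        offset = np.array([np.cos(angle), np.sin(angle)]) * cancer_radius * 1.4
        parent = walks[0][2]
        n_rest = n_frames - division_frame
        start = parent[division_frame] + offset
        daughter = _drifting_walk(rng, n_rest, start, 0.6, 0.4, (w, h))
        walks.append((tid, "cancer_daughter", daughter, cancer_radius * 0.85, 170.0))
        tid += 1
    if apoptosis_frame is not None:
        events.append((0, "apoptosis", apoptosis_frame))

    stack = np.zeros((n_frames, h, w), dtype=np.uint8)
    for t in range(n_frames):
        img = np.full((h, w), 30.0)
        for track_id, pop, pos, radius, amp in walks:
            if pop == "cancer_daughter":
                if t < (division_frame or 0):
                    continue
                p = pos[t - division_frame]
            else:
                p = pos[t]
            r, a = radius, amp
            if track_id == 0 and apoptosis_frame is not None and t >= apoptosis_frame:
                fade = max(0.0, 1.0 - 0.08 * (t - apoptosis_frame))
                r = radius * max(0.4, fade)
                a = amp * max(0.2, fade)
                if fade <= 0.0:
                    continue
            d = np.hypot(xx - p[0], yy - p[1])
            img += a / (1.0 + np.exp((d - r) / 1.2))  # soft-edged disk
            records.append((t, track_id, pop.replace("_daughter", ""), p[0], p[1], r))
        img += rng.standard_normal((h, w)) * noise_level
        stack[t] = np.clip(img, 0, 255).astype(np.uint8)

    truth = VideoGroundTruth(
        positions=pd.DataFrame(
            records, columns=["frame", "track_id", "population", "x", "y", "radius"]
        ),
        events=pd.DataFrame(events, columns=["track_id", "event", "frame"]),
    )
    return stack, truth
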