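"""Temporal causal discovery on time-unfolded graphs.

The algorithm learns a translation-invariant causal graph over lagged
copies of the observed variables:

1. **Window selection** — the maximum lag ``tau`` is set to twice the mean
   autocorrelation relaxation time of the variables (the lag where the ACF
   first drops below 1/e), and the layer increment ``delta_tau`` keeps the
   number of lagged layers near a target (12 by default).
2. **Skeleton** — every pair of nodes with at least one contemporaneous
   endpoint starts connected; significant information contributors are
   collected greedily and an edge is removed as soon as its penalized
   conditional mutual information drops to zero or below.  The surviving
   edges are duplicated at earlier layers (translation closure).
3. **Orientation** — lagged edges get an arrowhead at their future
   endpoint; unshielded triples with negative penalized three-point
   information become colliders (probabilistically, via a logistic
   confidence score); a collider arrowhead landing on the *past* endpoint
   of a lagged edge yields an arrow-arrow edge, the signature of a
   time-lagged latent common cause.
4. **Summary** — shift-equivalence classes of edges collapse to a summary
   graph annotated with lags (in time steps), association signs and
   orientation confidence.

The public surface follows the Model/Results convention:
``TemporalCausalModel(frame, ...).fit()`` returns a
:class:`TemporalCausalResults` carrying the graphs, the per-edge audit
trail and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import TimeSeriesDataset, VariableSpec, KIND_CONTEXTUAL
from .information import (
    EstimatorCache,
    conditional_mutual_information,
    three_point_stat,
)
from .unfold import (
    ARROW,
    TAIL,
    UNKNOWN,
    LaggedNode,
    LayerLayout,
    SummaryGraph,
    TimeUnfoldedGraph,
    UnfoldedEdge,
    build_layout,
    close_translation,
    collapse_summary,
    lag_samples,
)

#: how many top contributor candidates are probed as potential separators
_KILL_K = 8

__all__ = [
    "DiscoveryConfig",
    "EdgeDecision",
    "estimate_tau",
    "learn_skeleton",
    "orient",
    "run",
    "TemporalCausalModel",
    "TemporalCausalResults",
]


@dataclass
class DiscoveryConfig:
    """Tunable parameters of the discovery run.

    tau / delta_tau : int or "auto"
        Maximum lag and layer increment, in time steps.
    target_layers : int
        Desired number of lagged layers when delta_tau is automatic.
    orientation_confidence_cutoff : float in (0.5, 1]
        Minimum logistic confidence for committing a collider orientation.
    latent_strength_min : float
        Minimum per-sample three-point strength (nats) for a backward
        arrowhead on a lagged edge: the latent-common-cause signature is a
        claim against the arrow of time and demands much stronger evidence
        than an ordinary collider.
    stride : int
        Anchor stride of the sliding window (1 = maximally overlapping).
    max_contributors : int
        Cap on the conditioning set collected per edge.
    """

    tau: int | str = "auto"
    delta_tau: int | str = "auto"
    target_layers: int = 12
    orientation_confidence_cutoff: float = 0.95
    latent_strength_min: float = 0.015
    stride: int = 1
    seed: int = 0
    max_contributors: int = 8

    def __post_init__(self):
        if not (0.5 < self.orientation_confidence_cutoff <= 1.0):
            raise ValueError("orientation_confidence_cutoff must be in (0.5, 1]")


@dataclass
class EdgeDecision:
    """Audit record for one candidate edge."""

    pair: tuple[LaggedNode, LaggedNode]
    status: str  # "retained" | "removed"
    contributors: tuple[LaggedNode, ...] = ()
    final_penalized_info: float = np.nan
    separating_set: tuple[LaggedNode, ...] | None = None


# ---------------------------------------------------------------------------
# window selection
# ---------------------------------------------------------------------------

def _relaxation_time(series: np.ndarray, max_lag: int) -> int | None:
    """Smallest lag where the autocorrelation drops below 1/e."""
    x = series - series.mean()
    denom = float(x @ x)
    if denom <= 0:
        return None
    for lag in range(1, max_lag + 1):
        ac = float(x[lag:] @ x[:-lag]) / denom
        if ac < 1.0 / np.e:
            return lag
    return None


def estimate_tau(
    dataset: TimeSeriesDataset, target_layers: int = 12
) -> tuple[int, int]:
    """Automatic window: tau = 2 x mean relaxation time, snapped to delta_tau.

    Variables whose autocorrelation never crosses 1/e within half the
    trajectory length are flagged nonstationary and excluded from the mean;
    if all are excluded a manual tau is required.
    """
    relaxations = []
    for spec in dataset.specs:
        if spec.kind == KIND_CONTEXTUAL:
            continue
        if spec.is_discrete and (spec.n_levels or 2) > 2:
            continue
        per_traj = []
        for traj in dataset.trajectories():
            arr = traj[spec.name].to_numpy(dtype=float)
            if arr.size < 50:
                continue
            r = _relaxation_time(arr, max_lag=arr.size // 2)
            if r is not None:
                per_traj.append(r)
        if per_traj:
            relaxations.append(float(np.mean(per_traj)))
        else:
            warnings.warn(
                f"variable {spec.name!r} shows no autocorrelation decay below "
                "1/e; flagged nonstationary and excluded from tau estimation"
            )
    if not relaxations:
        raise ValueError(
            "no variable with a measurable relaxation time; set tau manually"
        )
    tau = max(1, int(round(2.0 * float(np.mean(relaxations)))))
    delta_tau = max(1, int(round(tau / target_layers)))
    tau = max(delta_tau, (tau // delta_tau) * delta_tau)
    return tau, delta_tau


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

class _Estimator:
    """Column-aware penalized CMI over the lagged sample matrix."""

    def __init__(self, samples: pd.DataFrame, layout: LayerLayout):
        self.cache = EstimatorCache()
        self.layout = layout
        self.cols = {c: samples[c].to_numpy() for c in samples.columns}

    def spec(self, node: LaggedNode) -> VariableSpec:
        return self.layout.spec(node.variable)

    def cmi(self, a: LaggedNode, b: LaggedNode, Z: Sequence[LaggedNode] = ()):
        Z = list(Z)
        return conditional_mutual_information(
            self.cols[str(a)],
            self.cols[str(b)],
            [self.cols[str(z)] for z in Z],
            self.spec(a),
            self.spec(b),
            [self.spec(z) for z in Z],
            cache=self.cache,
            keys=(str(a), str(b), tuple(str(z) for z in Z)),
        )

    def tps(
        self,
        a: LaggedNode,
        b: LaggedNode,
        z: LaggedNode,
        U: Sequence[LaggedNode] = (),
        margin: str = "bic",
    ) -> float:
        U = list(U)
        return three_point_stat(
            self.cols[str(a)],
            self.cols[str(b)],
            self.cols[str(z)],
            [self.cols[str(u)] for u in U],
            self.spec(a),
            self.spec(b),
            self.spec(z),
            [self.spec(u) for u in U],
            cache=self.cache,
            keys=(str(a), str(b), str(z), tuple(str(u) for u in U)),
            margin=margin,
            relative_guard=0.0,
        )


def _candidate_pairs(layout: LayerLayout) -> list[tuple[LaggedNode, LaggedNode]]:
    nodes = layout.nodes()
    ctx = {n for n in nodes if layout.spec(n.variable).kind == KIND_CONTEXTUAL}
    pairs = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if a.variable == b.variable and a.lag == b.lag:
                continue
            if a in ctx or b in ctx:
                # contextual nodes attach to contemporaneous nodes only
                if (a in ctx and b.lag == 0) or (b in ctx and a.lag == 0):
                    pairs.append(tuple(sorted((a, b))))
                continue
            if min(a.lag, b.lag) == 0:
                pairs.append(tuple(sorted((a, b))))
    return sorted(set(pairs))


def learn_skeleton(
    samples: pd.DataFrame,
    layout: LayerLayout,
    config: DiscoveryConfig | None = None,
) -> tuple[TimeUnfoldedGraph, list[EdgeDecision]]:
    """Constraint-based skeleton with iterative information contributors.

    Candidate edges all touch the contemporaneous layer.  For each pair the
    contributor that most decreases the penalized conditional information is
    added greedily; the edge is removed once that information is <= 0 (the
    collected set is then its separating set).  The result is translation
    closed.
    """
    config = config or DiscoveryConfig()
    if len(samples) < 10:
        raise ValueError("need at least 10 sample rows")
    est = _Estimator(samples, layout)

    constant = [c for c, v in est.cols.items() if np.all(v == v[0])]
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
    usable = {c for c in est.cols if c not in constant}

    pairs = [
        p
        for p in _candidate_pairs(layout)
        if str(p[0]) in usable and str(p[1]) in usable
    ]

    decisions: list[EdgeDecision] = []
    graph = TimeUnfoldedGraph(layout)

    # phase 1: unconditional screening
    survivors = []
    for a, b in pairs:
        e = est.cmi(a, b)
        if e.penalized <= 0:
            decisions.append(
                EdgeDecision((a, b), "removed", (), e.penalized, ())
            )
        else:
            survivors.append((a, b, e.penalized))

    # phase 2: iterative contributor collection; a node joins the
    # conditioning set only when it explains a *significant* part of the
    # pairwise information (positive shrunk three-point score), which keeps
    # colliders out of the separating sets.  The pass repeats with the
    # pruned adjacency (sparser contributor pools) until no edge changes.
    current = {(a, b) for a, b, _ in survivors}
    retained_info: dict[tuple[LaggedNode, LaggedNode], tuple] = {}
    for _round in range(3):
        adj: dict[LaggedNode, set[LaggedNode]] = {}
        for a, b in current:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        removed_now: list[EdgeDecision] = []
        retained_info.clear()
        for a, b in sorted(current):
            pool = sorted((adj.get(a, set()) | adj.get(b, set())) - {a, b})
            U: list[LaggedNode] = []
            e0 = est.cmi(a, b)
            removed = False
            while True:
                if e0.penalized <= 0:
                    removed_now.append(
                        EdgeDecision((a, b), "removed", tuple(U),
                                     e0.penalized, tuple(U))
                    )
                    removed = True
                    break
                if len(U) >= config.max_contributors:
                    break
                scores = []
                for z in pool:
                    if z in U:
                        continue
                    scores.append((est.tps(a, b, z, U, margin="bic"), z))
                positives = sorted(
                    (s for s in scores if s[0] > 0), reverse=True
                )
                # candidate separators are the strongest contributors:
                # check whether extending the set reaches independence
                kill = None
                for score, z in positives[:_KILL_K]:
                    e1 = est.cmi(a, b, U + [z])
                    if e1.penalized <= 0 and (
                        kill is None or e1.penalized < kill[0]
                    ):
                        kill = (e1.penalized, z)
                if kill is not None:
                    sep = tuple(U) + (kill[1],)
                    removed_now.append(
                        EdgeDecision((a, b), "removed", tuple(U), kill[0],
                                     sep)
                    )
                    removed = True
                    break
                if not positives:
                    break  # no significant contributor left
                U.append(positives[0][1])
                e0 = est.cmi(a, b, U)
            if not removed:
                retained_info[(a, b)] = (e0.penalized, tuple(U))
        decisions.extend(removed_now)
        current = set(retained_info)
        if not removed_now:
            break
    for (a, b), (pen, U) in sorted(retained_info.items()):
        graph.add_edge(
            UnfoldedEdge(a, b, penalized_info=pen, contributors=U)
        )
        decisions.append(EdgeDecision((a, b), "retained", U, pen, None))
    return close_translation(graph), decisions


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def _confidence(pen3: float) -> float:
    """Logistic map from a penalized three-point score to (0.5, 1)."""
    return 1.0 / (1.0 + np.exp(-abs(pen3) / 2.0))


def _sepsets(decisions: Sequence[EdgeDecision]) -> dict:
    out = {}
    for d in decisions:
        if d.status == "removed":
            out[d.pair] = d.separating_set or ()
    return out


def _lookup_sepset(sepsets: dict, a: LaggedNode, b: LaggedNode, layout) -> tuple:
    """Separating set of (a, b), looked up on the anchored representative."""
    shift = min(a.lag, b.lag)
    key = tuple(
        sorted(
            (LaggedNode(a.variable, a.lag - shift),
             LaggedNode(b.variable, b.lag - shift))
        )
    )
    sep = sepsets.get(key, ())
    out = []
    for z in sep:
        zz = LaggedNode(z.variable, z.lag + shift)
        if zz.lag <= layout.tau:
            out.append(zz)
    return tuple(out)


def _harmonize_marks(g: TimeUnfoldedGraph) -> TimeUnfoldedGraph:
    """Re-close endpoint marks over shift-equivalence classes.

    Within a class, an oriented mark beats unknown; contradictory oriented
    marks downgrade to unknown (conflict resolution)."""
    classes: dict = {}
    for e in g.edges():
        shift = min(e.node_a.lag, e.node_b.lag)
        anchored = e.shifted(-shift)
        key = (anchored.node_a, anchored.node_b)
        marks = classes.setdefault(key, [set(), set()])
        marks[0].add(anchored.mark_at_a)
        marks[1].add(anchored.mark_at_b)

    def combine(marks: set) -> str:
        oriented = marks - {UNKNOWN}
        if len(oriented) == 1:
            return next(iter(oriented))
        return UNKNOWN  # no evidence, or tail/arrow conflict

    out = TimeUnfoldedGraph(g.layout)
    for e in g.edges():
        shift = min(e.node_a.lag, e.node_b.lag)
        anchored = e.shifted(-shift)
        marks = classes[(anchored.node_a, anchored.node_b)]
        e.mark_at_a = combine(marks[0])
        e.mark_at_b = combine(marks[1])
        out.add_edge(e)
    return out


def orient(
    g: TimeUnfoldedGraph,
    samples: pd.DataFrame,
    config: DiscoveryConfig | None = None,
    decisions: Sequence[EdgeDecision] = (),
) -> TimeUnfoldedGraph:
    """Orient a translation-closed skeleton.

    Phases: (i) temporal pre-orientation (arrowheads toward the future,
    tails at contextual condition nodes), (ii) probabilistic collider
    orientation from negative penalized three-point information -- the only
    rule allowed to place a backward arrowhead on a lagged edge (latent
    cause signature), (iii) orientation propagation that avoids creating
    new unshielded colliders.  Marks are re-closed by translation after
    each phase; conflicting orientations downgrade to unknown.
    """
    config = config or DiscoveryConfig()
    layout = g.layout
    est = _Estimator(samples, layout)
    sepsets = _sepsets(decisions)
    g = g.copy()

    # (i) pre-orientation
    for e in g.edges():
        a, b = e.node_a, e.node_b
        spec_a, spec_b = layout.spec(a.variable), layout.spec(b.variable)
        if spec_a.kind == KIND_CONTEXTUAL and spec_b.kind != KIND_CONTEXTUAL:
            g.set_marks(a, b, mark_at_a=TAIL, mark_at_b=ARROW)
        elif spec_b.kind == KIND_CONTEXTUAL and spec_a.kind != KIND_CONTEXTUAL:
            g.set_marks(a, b, mark_at_a=ARROW, mark_at_b=TAIL)
        elif a.lag != b.lag:
            future, past = (a, b) if a.lag < b.lag else (b, a)
            g.set_marks(future, past, mark_at_a=ARROW)

    # (ii) probabilistic triple orientation: negative three-point scores
    # propose colliders (arrowheads at the middle node), positive scores
    # propose non-colliders (a tail at the middle node on the second edge
    # whenever an arrowhead already points into it on the first)
    proposals: list[tuple[float, str, LaggedNode, LaggedNode, LaggedNode]] = []
    for c in sorted({n for e in g.edges() for n in e.pair}):
        nbrs = g.neighbors(c)
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1 :]:
                if g.has_edge(a, b):
                    continue
                sep_ab = _lookup_sepset(sepsets, a, b, layout)
                U = [z for z in sep_ab if z != c and str(z) in est.cols]
                if str(a) not in est.cols or str(b) not in est.cols:
                    continue
                pen3 = est.tps(a, b, c, U)
                conf = _confidence(pen3)
                if conf < config.orientation_confidence_cutoff:
                    continue
                if pen3 < 0 and c not in sep_ab:
                    proposals.append((conf, "collider", a, c, b, pen3))
                elif pen3 > 0:
                    proposals.append((conf, "noncollider", a, c, b, pen3))

    conflicts: set = set()

    n_samples = len(samples)

    def place_mark(node_from: LaggedNode, c: LaggedNode, mark: str, conf: float):
        edge = g.edge(node_from, c)
        if edge is None:
            return
        if any(
            layout.spec(node.variable).kind == KIND_CONTEXTUAL
            for node in edge.pair
        ):
            return  # contextual edges keep their a-priori orientation
        current = edge.mark_at(c)
        if current == mark or current == UNKNOWN:
            g.set_marks(node_from, c, mark_at_b=mark)
            if not (edge.confidence > conf):
                edge.confidence = conf
        else:
            conflicts.add((node_from, c))
            g.set_marks(node_from, c, mark_at_b=UNKNOWN)

    for conf, kind, a, c, b, pen3 in sorted(
        proposals, reverse=True, key=lambda t: (t[0], t[1], t[2], t[4])
    ):
        if layout.spec(c.variable).kind == KIND_CONTEXTUAL:
            continue  # conditions are externally set, never caused
        if kind == "collider":
            for tail_node in (a, b):
                if (
                    c.lag > tail_node.lag
                    and abs(pen3) / n_samples < config.latent_strength_min
                ):
                    # an arrowhead into the *past* endpoint claims a latent
                    # common cause against the arrow of time: require much
                    # stronger evidence than for an ordinary collider
                    continue
                place_mark(tail_node, c, ARROW, conf)
        else:
            # c mediates or is a common cause: with an arrowhead already
            # into c from one side, the other edge leaves c by a tail
            for first, second in ((a, b), (b, a)):
                e1 = g.edge(first, c)
                if e1 is None or e1.mark_at(c) != ARROW:
                    continue
                e2 = g.edge(second, c)
                if e2 is None:
                    continue
                place_mark(second, c, TAIL, conf)
                if second.lag == c.lag and layout.spec(
                    second.variable
                ).kind != KIND_CONTEXTUAL:
                    edge2 = g.edge(second, c)
                    if edge2 is not None and edge2.mark_at(c) == TAIL:
                        place_mark(c, second, ARROW, conf)
    if conflicts:
        warnings.warn(f"orientation conflicts on {len(conflicts)} edge(s)")

    g = _harmonize_marks(g)

    # (iii) propagation (Meek rule 1) on contemporaneous edges:
    # a -> c - b with a, b nonadjacent orients c -> b to avoid a new collider
    changed = True
    while changed:
        changed = False
        for e in g.edges():
            a, b = e.node_a, e.node_b
            if a.lag != b.lag or ARROW in (e.mark_at_a, e.mark_at_b):
                continue
            for c, other, mark_other in ((a, b, e.mark_at_b), (b, a, e.mark_at_a)):
                # is there x -> c with x not adjacent to `other`?
                done = False
                for x in g.neighbors(c):
                    if x == other or g.has_edge(x, other):
                        continue
                    ex = g.edge(x, c)
                    if ex.mark_at(c) == ARROW and ex.mark_at(x) != ARROW:
                        if layout.spec(other.variable).kind == KIND_CONTEXTUAL:
                            continue
                        g.set_marks(c, other, mark_at_a=TAIL, mark_at_b=ARROW)
                        changed = True
                        done = True
                        break
                if done:
                    break
    return _harmonize_marks(g)


# ---------------------------------------------------------------------------
# signs and full run
# ---------------------------------------------------------------------------

def _sign_function(samples: pd.DataFrame, layout: LayerLayout):
    cols = {c: samples[c].to_numpy() for c in samples.columns}

    def sign(edge: UnfoldedEdge) -> str:
        ka, kb = str(edge.node_a), str(edge.node_b)
        if ka not in cols or kb not in cols:
            return "none"
        va = cols[ka]
        vb = cols[kb]
        for node, v in ((edge.node_a, va), (edge.node_b, vb)):
            spec = layout.spec(node.variable)
            if spec.is_discrete and (spec.n_levels or 2) > 2:
                return "none"  # no natural ordering
        a = pd.factorize(va, sort=True)[0] if va.dtype == object else va.astype(float)
        b = pd.factorize(vb, sort=True)[0] if vb.dtype == object else vb.astype(float)
        if a.std() == 0 or b.std() == 0:
            return "none"
        r = float(np.corrcoef(a, b)[0, 1])
        return "+" if r > 0 else "-"

    return sign


def run(
    dataset: TimeSeriesDataset, config: DiscoveryConfig | None = None
) -> tuple[SummaryGraph, TimeUnfoldedGraph, list[EdgeDecision]]:
    """Full pipeline: window selection, skeleton, orientation, summary."""
    config = config or DiscoveryConfig()
    if config.tau == "auto" or config.delta_tau == "auto":
        tau, delta_tau = estimate_tau(dataset, config.target_layers)
        if config.tau != "auto":
            tau = int(config.tau)
            delta_tau = max(1, int(round(tau / config.target_layers)))
            tau = max(delta_tau, (tau // delta_tau) * delta_tau)
    else:
        tau, delta_tau = int(config.tau), int(config.delta_tau)
    layout = build_layout(dataset.specs, tau, delta_tau)
    samples = lag_samples(dataset, layout, stride=config.stride)
    skeleton, decisions = learn_skeleton(samples, layout, config)
    oriented = orient(skeleton, samples, config, decisions)
    summary = collapse_summary(oriented, signs=_sign_function(samples, layout))
    return summary, oriented, decisions


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class TemporalCausalModel:
    """Temporal causal discovery model over a multivariate time series.

    Parameters
    ----------
    data : DataFrame or TimeSeriesDataset
        Long-format time series (rows = time steps).
    trajectory_col : str, optional
        Column identifying independent trajectories.
    contextual : sequence of str
        Time-invariant experimental-condition columns.
    tau, delta_tau : int or "auto"
        Lag window geometry (time steps).
    **config_kwargs
        Remaining :class:`DiscoveryConfig` fields.

    Examples
    --------
    >>> model = TemporalCausalModel(frame, tau=2, delta_tau=1)  # doctest: +SKIP
    >>> res = model.fit()                                       # doctest: +SKIP
    >>> print(res.summary())                                    # doctest: +SKIP
    """

    def __init__(
        self,
        data,
        trajectory_col: str | None = None,
        contextual: Sequence[str] = (),
        tau: int | str = "auto",
        delta_tau: int | str = "auto",
        **config_kwargs,
    ):
        if isinstance(data, TimeSeriesDataset):
            self.dataset = data
        else:
            self.dataset = TimeSeriesDataset(
                data, trajectory_col=trajectory_col, contextual=contextual
            )
        self.config = DiscoveryConfig(tau=tau, delta_tau=delta_tau, **config_kwargs)

    @classmethod
    def from_csv(cls, path, trajectory_col=None, contextual=(), **kwargs):
        ds = TimeSeriesDataset.from_csv(
            path, trajectory_col=trajectory_col, contextual=contextual
        )
        return cls(ds, **kwargs)

    def fit(self, seed: int | None = None) -> "TemporalCausalResults":
        """Run the discovery pipeline and return the results object.

        The procedure is deterministic given the data and configuration;
        ``seed`` is stored for provenance."""
        if seed is not None:
            self.config.seed = seed
        summary, unfolded, decisions = run(self.dataset, self.config)
        return TemporalCausalResults(self, summary, unfolded, decisions)


@dataclass
class TemporalCausalResults:
    """Learned graphs plus the per-edge audit trail."""

    model: TemporalCausalModel
    summary_graph: SummaryGraph
    unfolded_graph: TimeUnfoldedGraph
    edge_decisions: list[EdgeDecision] = field(default_factory=list)

    @property
    def layout(self) -> LayerLayout:
        return self.unfolded_graph.layout

    def summary(self) -> str:
        lay = self.layout
        lines = [
            "Temporal causal discovery results",
            "=" * 49,
            f"variables: {len(lay.variables):>4}    samples: "
            f"{len(self.model.dataset):>8}",
            f"tau: {lay.tau} ts    delta_tau: {lay.delta_tau} ts    "
            f"layers: {lay.nu}",
            f"summary edges: {len(self.summary_graph.edges)}",
            "-" * 49,
            f"{'source':<14}{'target':<14}{'lag':>4} {'orient':<11}"
            f"{'sign':<5}{'conf':>5}",
        ]
        for e in self.summary_graph.to_frame().itertuples(index=False):
            conf = "" if np.isnan(e.confidence) else f"{e.confidence:.2f}"
            lines.append(
                f"{e.source:<14}{e.target:<14}{e.lag_ts:>4} "
                f"{e.orientation:<11}{e.sign:<5}{conf:>5}"
            )
        return "\n".join(lines)

    def audit_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.edge_decisions:
            rows.append(
                (
                    str(d.pair[0]),
                    str(d.pair[1]),
                    d.status,
                    ";".join(str(z) for z in d.contributors),
                    d.final_penalized_info,
                    ""
                    if d.separating_set is None
                    else ";".join(str(z) for z in d.separating_set),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["node_a", "node_b", "status", "contributors",
                     "penalized_info", "separating_set"],
        )

    def to_tsv(self, path) -> None:
        from .io import write_summary_graph

        write_summary_graph(self.summary_graph, path)
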