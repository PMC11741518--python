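"""Time-unfolded graphs with periodic (translation-invariant) structure.

A variable observed over time is represented by several *lagged nodes*, one
per relative time point ``t, t - dt, t - 2 dt, ..., t - tau`` (lags are
expressed in original time steps and are multiples of the layer increment
``delta_tau``).  Under stationarity the causal structure is the same at
every anchor time, so edges learned at the contemporaneous layer are
duplicated at earlier layers ("translation closure"), and the whole object
collapses to a *summary graph* with one node per variable and lag-annotated
edges.  Edge endpoints carry marks (tail / arrow / unknown); a lagged edge
with arrowheads at both ends encodes a time-lagged latent common cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .data import TimeSeriesDataset, VariableSpec, KIND_CONTEXTUAL

TAIL = "tail"
ARROW = "arrow"
UNKNOWN = "unknown"

__all__ = [
    "LaggedNode",
    "LayerLayout",
    "UnfoldedEdge",
    "TimeUnfoldedGraph",
    "SummaryEdge",
    "SummaryGraph",
    "build_layout",
    "lag_samples",
    "close_translation",
    "collapse_summary",
]


@dataclass(frozen=True, order=True)
class LaggedNode:
    """One variable at one relative time point; ``lag`` counts steps into
    the past (0 = contemporaneous layer)."""

    variable: str
    lag: int

    def __str__(self) -> str:  # matches the "var@-lag" export convention
        return f"{self.variable}@-{self.lag}"

    @classmethod
    def parse(cls, text: str) -> "LaggedNode":
        var, _, lag = text.rpartition("@-")
        return cls(var, int(lag))


@dataclass(frozen=True)
class LayerLayout:
    """Geometry of the unfolded window: variables x lags 0..tau step delta_tau."""

    variables: tuple[VariableSpec, ...]
    tau: int
    delta_tau: int

    @property
    def nu(self) -> int:
        """Number of time-lagged layers (excluding the contemporaneous one)."""
        return self.tau // self.delta_tau

    @property
    def lags(self) -> tuple[int, ...]:
        return tuple(range(0, self.tau + 1, self.delta_tau))

    def nodes(self) -> list[LaggedNode]:
        out = []
        for spec in self.variables:
            if spec.kind == KIND_CONTEXTUAL:
                out.append(LaggedNode(spec.name, 0))
            else:
                out.extend(LaggedNode(spec.name, l) for l in self.lags)
        return out

    def spec(self, name: str) -> VariableSpec:
        for s in self.variables:
            if s.name == name:
                return s
        raise KeyError(name)


def build_layout(
    variables: Sequence[VariableSpec], tau: int, delta_tau: int
) -> LayerLayout:
    """Validate the window geometry and build a :class:`LayerLayout`."""
    if delta_tau < 1 or tau < delta_tau:
        raise ValueError("need tau >= delta_tau >= 1")
    if tau % delta_tau != 0:
        raise ValueError(f"tau={tau} is not a multiple of delta_tau={delta_tau}")
    return LayerLayout(tuple(variables), tau, delta_tau)


@dataclass
class UnfoldedEdge:
    """Edge between two lagged nodes with endpoint marks and metadata."""

    node_a: LaggedNode
    node_b: LaggedNode
    mark_at_a: str = UNKNOWN
    mark_at_b: str = UNKNOWN
    penalized_info: float = np.nan
    contributors: tuple[LaggedNode, ...] = ()
    confidence: float = np.nan

    def __post_init__(self):
        if self.node_b < self.node_a:  # canonical endpoint order
            self.node_a, self.node_b = self.node_b, self.node_a
            self.mark_at_a, self.mark_at_b = self.mark_at_b, self.mark_at_a

    @property
    def pair(self) -> tuple[LaggedNode, LaggedNode]:
        return (self.node_a, self.node_b)

    def mark_at(self, node: LaggedNode) -> str:
        if node == self.node_a:
            return self.mark_at_a
        if node == self.node_b:
            return self.mark_at_b
        raise KeyError(node)

    def shifted(self, k_steps: int) -> "UnfoldedEdge":
        return replace(
            self,
            node_a=LaggedNode(self.node_a.variable, self.node_a.lag + k_steps),
            node_b=LaggedNode(self.node_b.variable, self.node_b.lag + k_steps),
        )


class TimeUnfoldedGraph:
    """Mixed graph over lagged nodes with endpoint marks."""

    def __init__(self, layout: LayerLayout, edges: Iterable[UnfoldedEdge] = ()):
        self.layout = layout
        self._edges: dict[tuple[LaggedNode, LaggedNode], UnfoldedEdge] = {}
        for e in edges:
            self.add_edge(e)

    # -- basic mutation/access --------------------------------------------
    def add_edge(self, edge: UnfoldedEdge) -> None:
        for node in edge.pair:
            if node.lag < 0 or node.lag > self.layout.tau:
                raise ValueError(f"node {node} outside the lag window")
        self._edges[edge.pair] = edge

    def remove_edge(self, a: LaggedNode, b: LaggedNode) -> None:
        self._edges.pop(tuple(sorted((a, b))), None)

    def edge(self, a: LaggedNode, b: LaggedNode) -> UnfoldedEdge | None:
        return self._edges.get(tuple(sorted((a, b))))

    def has_edge(self, a: LaggedNode, b: LaggedNode) -> bool:
        return tuple(sorted((a, b))) in self._edges

    def edges(self) -> list[UnfoldedEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def neighbors(self, node: LaggedNode) -> list[LaggedNode]:
        out = []
        for a, b in self._edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return sorted(out)

    def set_marks(
        self, a: LaggedNode, b: LaggedNode, mark_at_a: str | None = None,
        mark_at_b: str | None = None,
    ) -> None:
        e = self.edge(a, b)
        if e is None:
            raise KeyError((a, b))
        if mark_at_a is not None:
            if a == e.node_a:
                e.mark_at_a = mark_at_a
            else:
                e.mark_at_b = mark_at_a
        if mark_at_b is not None:
            if b == e.node_b:
                e.mark_at_b = mark_at_b
            else:
                e.mark_at_a = mark_at_b

    def copy(self) -> "TimeUnfoldedGraph":
        return TimeUnfoldedGraph(self.layout, (replace(e) for e in self.edges()))

    def __len__(self) -> int:
        return len(self._edges)

    # -- export -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (str(e.node_a), str(e.node_b), e.mark_at_a, e.mark_at_b,
             e.penalized_info, e.confidence)
            for e in self.edges()
        ]
        return pd.DataFrame(
            rows,
            columns=["node_a", "node_b", "mark_at_a", "mark_at_b",
                     "penalized_info", "confidence"],
        )


def close_translation(g: TimeUnfoldedGraph) -> TimeUnfoldedGraph:
    """Duplicate every edge at all time shifts that fit in [0, tau].

    Marks and metadata are copied.  Closing an already closed graph is a
    no-op (idempotent).  Contextual nodes exist only at lag 0 and are left
    unshifted (their edges are not duplicated).
    """
    layout = g.layout
    dt = layout.delta_tau
    out = TimeUnfoldedGraph(layout)
    for e in g.edges():
        is_ctx = any(
            layout.spec(n.variable).kind == KIND_CONTEXTUAL for n in e.pair
        )
        if is_ctx:
            out.add_edge(replace(e))
            continue
        lo = -min(e.node_a.lag, e.node_b.lag)
        hi = layout.tau - max(e.node_a.lag, e.node_b.lag)
        for k in range(lo, hi + 1, dt):
            shifted = e.shifted(k)
            existing = out.edge(*shifted.pair)
            if existing is None or k == 0:
                out.add_edge(shifted)
    return out


def lag_samples(
    dataset: TimeSeriesDataset, layout: LayerLayout, stride: int = 1
) -> pd.DataFrame:
    """Sliding-window sample matrix with one column per lagged node.

    The window anchored at time ``t`` contributes one row whose column
    ``(v, lag)`` holds v's value at ``t - lag``; contextual columns repeat
    the trajectory constant.  Anchors advance by ``stride`` within each
    trajectory; trajectories shorter than ``tau + 1`` are skipped.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    tau = layout.tau
    nodes = layout.nodes()
    chunks = []
    for traj in dataset.trajectories():
        T = len(traj)
        if T < tau + 1:
            continue
        anchors = np.arange(tau, T, stride)
        cols = {}
        for node in nodes:
            arr = traj[node.variable].to_numpy()
            cols[str(node)] = arr[anchors - node.lag]
        chunks.append(pd.DataFrame(cols))
    if not chunks:
        raise ValueError("no trajectory is long enough for the lag window")
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# summary graph
# ---------------------------------------------------------------------------

DIRECTED = "directed"
UNDIRECTED = "undirected"
BIDIRECTED = "bidirected"


@dataclass(frozen=True)
class SummaryEdge:
    """Collapsed edge: ``source -> target`` delayed by ``lag`` time steps.

    ``orientation`` is 'directed', 'undirected' or 'bidirected' (the latter
    marking a latent common cause); undirected/bidirected edges use the
    lexicographically smaller variable as ``source``.  Self-loops
    (source == target, lag > 0) flag long-range memory / nonstationarity.
    """

    source: str
    target: str
    lag: int
    orientation: str = UNDIRECTED
    sign: str = "none"
    confidence: float = np.nan


@dataclass
class SummaryGraph:
    variables: tuple[str, ...]
    edges: list[SummaryEdge] = field(default_factory=list)

    def edge_keys(self) -> set[tuple[str, str, int]]:
        """Unordered (pair, lag) keys -- the skeleton view."""
        out = set()
        for e in self.edges:
            a, b = sorted((e.source, e.target))
            out.add((a, b, e.lag))
        return out

    def self_loop_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            if e.source == e.target:
                counts[e.source] = counts.get(e.source, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.source, e.target, e.lag, e.orientation, e.sign, e.confidence)
            for e in sorted(
                self.edges, key=lambda e: (e.source, e.target, e.lag)
            )
        ]
        return pd.DataFrame(
            rows,
            columns=["source", "target", "lag_ts", "orientation", "sign",
                     "confidence"],
        )


def _classify(e: UnfoldedEdge) -> tuple[str, str, str]:
    """Map an anchored unfolded edge to (source, target, orientation)."""
    a, b = e.node_a, e.node_b
    if a.lag == b.lag:  # contemporaneous
        arrow_a = e.mark_at_a == ARROW
        arrow_b = e.mark_at_b == ARROW
        if arrow_a and arrow_b:
            src, tgt = sorted((a.variable, b.variable))
            return src, tgt, BIDIRECTED
        if arrow_b:
            return a.variable, b.variable, DIRECTED
        if arrow_a:
            return b.variable, a.variable, DIRECTED
        src, tgt = sorted((a.variable, b.variable))
        return src, tgt, UNDIRECTED
    past, future = (a, b) if a.lag > b.lag else (b, a)
    if e.mark_at(past) == ARROW:  # second, backward arrowhead: latent cause
        return past.variable, future.variable, BIDIRECTED
    return past.variable, future.variable, DIRECTED


def collapse_summary(
    g: TimeUnfoldedGraph,
    signs: Callable[[UnfoldedEdge], str] | None = None,
) -> SummaryGraph:
    """Collapse shift-equivalence classes of edges to summary edges.

    Each class is represented by its anchored member (minimum lag shifted to
    zero); the summary lag is the lag difference of the endpoints, in
    original time steps.  ``signs`` optionally maps an anchored edge to
    '+'/'-'/'none'.
    """
    seen: dict[tuple[str, str, int], SummaryEdge] = {}
    for e in g.edges():
        shift = min(e.node_a.lag, e.node_b.lag)
        anchored = e.shifted(-shift)
        src, tgt, orient = _classify(anchored)
        lag = abs(anchored.node_a.lag - anchored.node_b.lag)
        key = (*sorted((src, tgt)), lag)
        summary = SummaryEdge(
            source=src,
            target=tgt,
            lag=lag,
            orientation=orient,
            sign=signs(anchored) if signs is not None else "none",
            confidence=anchored.confidence,
        )
        prev = seen.get(key)
        # prefer the most informative orientation among shifted copies
        rank = {UNDIRECTED: 0, DIRECTED: 1, BIDIRECTED: 2}
        if prev is None or rank[summary.orientation] > rank[prev.orientation]:
            seen[key] = summary
    names = tuple(s.name for s in g.layout.variables)
    return SummaryGraph(names, [seen[k] for k in sorted(seen)])
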