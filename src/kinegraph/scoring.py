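"""Scoring of learned summary graphs against ground truth, and the
benchmark / robustness harnesses."""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .benchmarks import BenchmarkNetwork, generate_linear, generate_nonlinear
from .data import TimeSeriesDataset
from .discovery import DiscoveryConfig, run
from .unfold import BIDIRECTED, DIRECTED, SummaryGraph

__all__ = ["ScoreReport", "score_graph", "run_benchmark", "robustness_tau",
           "summary_edit_distance"]


@dataclass(frozen=True)
class ScoreReport:
    precision: float
    recall: float
    fscore: float
    mode: str
    tp: int
    fp: int
    fn: int

    @staticmethod
    def from_counts(tp: int, fp: int, fn: int, mode: str) -> "ScoreReport":
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        return ScoreReport(precision, recall, f, mode, tp, fp, fn)


def _truth_edges(truth: BenchmarkNetwork) -> dict[tuple[str, str, int], str]:
    out = {}
    for e in truth.edges:
        out[(e.source, e.target, e.lag)] = DIRECTED
    for e in truth.latent_edges:
        out[(e.source, e.target, e.lag)] = BIDIRECTED
    return out


def score_graph(
    predicted: SummaryGraph, truth: BenchmarkNetwork, mode: str = "skeleton"
) -> ScoreReport:
    """Precision/recall/F-score of a predicted summary graph.

    skeleton mode: an edge is a true positive iff its unordered (pair, lag)
    matches a ground-truth edge.  oriented mode: the arrow direction must
    match as well; a bidirected prediction only matches a latent
    (bidirected) truth edge, so e.g. bidirected-vs-directed counts as one
    false positive plus one false negative.
    """
    if mode not in ("skeleton", "oriented"):
        raise ValueError("mode must be 'skeleton' or 'oriented'")
    pred_vars = set(predicted.variables)
    truth_vars = set(truth.node_names)
    if not truth_vars <= pred_vars:
        raise ValueError(
            f"variable universes differ: truth has {sorted(truth_vars - pred_vars)}"
            " unknown to the prediction"
        )
    truth_map = _truth_edges(truth)
    if mode == "skeleton":
        truth_keys = {(*sorted((s, t)), l) for (s, t, l) in truth_map}
        pred_keys = predicted.edge_keys()
        tp = len(pred_keys & truth_keys)
        return ScoreReport.from_counts(
            tp, len(pred_keys - truth_keys), len(truth_keys - pred_keys), mode
        )
    matched_truth = set()
    tp = fp = 0
    for e in predicted.edges:
        key = None
        if e.orientation == DIRECTED:
            if truth_map.get((e.source, e.target, e.lag)) == DIRECTED:
                key = (e.source, e.target, e.lag)
        elif e.orientation == BIDIRECTED:
            for cand in ((e.source, e.target, e.lag), (e.target, e.source, e.lag)):
                if truth_map.get(cand) == BIDIRECTED:
                    key = cand
                    break
        if key is not None and key not in matched_truth:
            matched_truth.add(key)
            tp += 1
        else:
            fp += 1
    fn = len(truth_map) - len(matched_truth)
    return ScoreReport.from_counts(tp, fp, fn, mode)


_GENERATORS: dict[str, Callable] = {
    "linear": generate_linear,
    "nonlinear": generate_nonlinear,
}


def run_benchmark(
    generator: str | Callable = "linear",
    n_replicates: int = 10,
    sample_sizes: Sequence[int] = (10_000,),
    seed: int = 1,
    config: DiscoveryConfig | None = None,
) -> pd.DataFrame:
    """Replicate benchmark: generate, discover, score; one row per run.

    ``generator`` is 'linear', 'nonlinear', or any callable with the
    signature ``generator(T=..., seed=...) -> (network, dataset)``.
    Replicate seeds are ``seed, seed+1, ...``.
    """
    gen = _GENERATORS.get(generator, generator) if isinstance(generator, str) else generator
    if isinstance(generator, str) and generator not in _GENERATORS:
        raise ValueError(f"unknown generator {generator!r}")
    config = config or DiscoveryConfig(tau=2, delta_tau=1)
    rows = []
    for n in sample_sizes:
        for rep in range(n_replicates):
            net, dataset = gen(T=n, seed=seed + rep)
            t0 = time.perf_counter()
            summary, _, _ = run(dataset, config)
            elapsed = time.perf_counter() - t0
            sk = score_graph(summary, net, "skeleton")
            orr = score_graph(summary, net, "oriented")
            rows.append(
                dict(
                    sample_size=n,
                    replicate=rep,
                    seed=seed + rep,
                    precision_skeleton=sk.precision,
                    recall_skeleton=sk.recall,
                    fscore_skeleton=sk.fscore,
                    precision_oriented=orr.precision,
                    recall_oriented=orr.recall,
                    fscore_oriented=orr.fscore,
                    runtime_s=elapsed,
                )
            )
    return pd.DataFrame(rows)


def summary_edit_distance(a: SummaryGraph, b: SummaryGraph) -> int:
    """Symmetric difference of the (pair, lag) skeleton edge sets."""
    return len(a.edge_keys() ^ b.edge_keys())


def robustness_tau(
    dataset: TimeSeriesDataset,
    tau_values: Sequence[int] = (2, 5, 10),
    config: DiscoveryConfig | None = None,
) -> dict:
    """Re-run discovery at several maximum lags.

    Returns the per-tau summary graphs, the pairwise skeleton edit
    distances, and the per-variable self-loop counts (the nonstationarity
    diagnostic)."""
    base = config or DiscoveryConfig()
    graphs = {}
    for tau in tau_values:
        cfg = DiscoveryConfig(
            tau=int(tau),
            delta_tau=1,
            target_layers=base.target_layers,
            orientation_confidence_cutoff=base.orientation_confidence_cutoff,
            stride=base.stride,
            seed=base.seed,
            max_contributors=base.max_contributors,
        )
        summary, _, _ = run(dataset, cfg)
        graphs[tau] = summary
    taus = list(tau_values)
    distances = {
        (t1, t2): summary_edit_distance(graphs[t1], graphs[t2])
        for i, t1 in enumerate(taus)
        for t2 in taus[i + 1 :]
    }
    self_loops = {t: graphs[t].self_loop_counts() for t in taus}
    return {"graphs": graphs, "edit_distances": distances, "self_loops": self_loops}
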