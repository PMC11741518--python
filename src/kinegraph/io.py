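"""File I/O: time-series CSV, summary-graph and ground-truth TSV, TIFF
stacks and feature tables.  All round trips are lossless for the graph and
table formats."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .benchmarks import BenchmarkEdge, BenchmarkNetwork
from .data import TimeSeriesDataset
from .unfold import SummaryEdge, SummaryGraph

__all__ = [
    "read_timeseries_csv",
    "write_summary_graph",
    "read_summary_graph",
    "write_ground_truth",
    "read_ground_truth",
    "read_stack",
    "write_stack",
    "write_feature_table",
    "read_feature_table",
]

_GRAPH_COLUMNS = ["source", "target", "lag_ts", "orientation", "sign", "confidence"]
_TRUTH_COLUMNS = ["source", "target", "lag", "weight", "form", "latent"]


def read_timeseries_csv(path, trajectory_col=None, contextual=()) -> TimeSeriesDataset:
    return TimeSeriesDataset.from_csv(
        path, trajectory_col=trajectory_col, contextual=contextual
    )


def write_summary_graph(graph: SummaryGraph, path) -> None:
    frame = graph.to_frame()
    header = "#variables=" + ",".join(graph.variables)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_summary_graph(path) -> SummaryGraph:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#variables="):
            raise ValueError("missing '#variables=' header line")
        variables = tuple(v for v in first[len("#variables="):].split(",") if v)
        frame = pd.read_csv(fh, sep="\t")
    missing = [c for c in _GRAPH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"malformed summary graph file: missing column(s) {missing}")
    edges = [
        SummaryEdge(
            source=str(r.source),
            target=str(r.target),
            lag=int(r.lag_ts),
            orientation=str(r.orientation),
            sign=str(r.sign),
            confidence=float(r.confidence) if np.isfinite(r.confidence) else np.nan,
        )
        for r in frame.itertuples(index=False)
    ]
    return SummaryGraph(variables, edges)


def write_ground_truth(network: BenchmarkNetwork, path) -> None:
    network.to_frame().to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> BenchmarkNetwork:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _TRUTH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"malformed ground truth file: missing column(s) {missing}")
    edges, latent = [], []
    names: list[str] = []
    for r in frame.itertuples(index=False):
        e = BenchmarkEdge(str(r.source), str(r.target), int(r.lag),
                          float(r.weight), str(r.form))
        (latent if bool(r.latent) else edges).append(e)
        for v in (e.source, e.target):
            if v not in names:
                names.append(v)
    return BenchmarkNetwork(len(names), edges, sorted(names), latent_edges=latent)


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a (frames, H, W) grayscale array."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {stack.shape}")
    return stack


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def write_feature_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "frame" not in frame.columns:
        raise ValueError("malformed feature table: missing column(s) ['frame']")
    return frame
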