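"""Scorer arithmetic and file round trips."""

import numpy as np
import pandas as pd
import pytest

from kinegraph.benchmarks import BenchmarkEdge, BenchmarkNetwork
from kinegraph.io import (
    read_feature_table,
    read_ground_truth,
    read_stack,
    read_summary_graph,
    write_feature_table,
    write_ground_truth,
    write_stack,
    write_summary_graph,
)
from kinegraph.scoring import ScoreReport, score_graph, summary_edit_distance
from kinegraph.unfold import SummaryEdge, SummaryGraph


def _network(edges):
    names = sorted({v for e in edges for v in (e[0], e[1])})
    return BenchmarkNetwork(
        len(names),
        [BenchmarkEdge(s, t, l, 0.5) for s, t, l in edges],
        names,
    )


def _graph(edges, variables=None, orientation="directed"):
    names = variables or tuple(sorted({v for e in edges for v in (e[0], e[1])}))
    return SummaryGraph(
        tuple(names),
        [SummaryEdge(s, t, l, orientation) for s, t, l in edges],
    )


TRUTH = _network([("A", "B", 1), ("B", "C", 0), ("C", "C", 2), ("A", "C", 2)])


def test_perfect_prediction_scores_one():
    pred = _graph([("A", "B", 1), ("B", "C", 0), ("C", "C", 2), ("A", "C", 2)])
    for mode in ("skeleton", "oriented"):
        r = score_graph(pred, TRUTH, mode)
        assert (r.precision, r.recall, r.fscore) == (1.0, 1.0, 1.0)


def test_empty_prediction_convention():
    pred = _graph([], variables=("A", "B", "C"))
    r = score_graph(pred, TRUTH, "skeleton")
    assert (r.precision, r.recall, r.fscore) == (0.0, 0.0, 0.0)


def test_three_of_four_arithmetic():
    pred = _graph([("A", "B", 1), ("B", "C", 0), ("C", "C", 2), ("A", "C", 1)])
    r = score_graph(pred, TRUTH, "skeleton")
    assert r.precision == r.recall == r.fscore == 0.75


def test_oriented_direction_must_match():
    pred = _graph([("B", "A", 1)], variables=("A", "B", "C"))  # reversed
    r = score_graph(pred, TRUTH, "oriented")
    assert r.tp == 0 and r.fp == 1
    assert score_graph(pred, TRUTH, "skeleton").tp == 1


def test_bidirected_vs_directed_truth_counts_fp_fn():
    pred = _graph([("A", "B", 1)], variables=("A", "B", "C"),
                  orientation="bidirected")
    r = score_graph(pred, TRUTH, "oriented")
    assert r.tp == 0 and r.fp == 1 and r.fn == len(TRUTH.edges)


def test_bidirected_matches_latent_truth():
    truth = BenchmarkNetwork(
        2, [], ["X", "Y"],
        latent_edges=[BenchmarkEdge("X", "Y", 1, 1.0, "latent")],
    )
    pred = _graph([("Y", "X", 1)], variables=("X", "Y"),
                  orientation="bidirected")
    r = score_graph(pred, truth, "oriented")
    assert r.tp == 1 and r.fp == 0 and r.fn == 0


def test_scorer_symmetry_swaps_precision_recall():
    """Scoring A against B swaps precision and recall of B against A."""
    edges_a = [("A", "B", 1), ("B", "C", 0)]
    edges_b = [("A", "B", 1), ("A", "C", 2), ("C", "C", 1)]
    r_ab = score_graph(_graph(edges_a, ("A", "B", "C")), _network(edges_b),
                       "skeleton")
    r_ba = score_graph(_graph(edges_b, ("A", "B", "C")), _network(edges_a),
                       "skeleton")
    assert r_ab.precision == r_ba.recall
    assert r_ab.recall == r_ba.precision


def test_variable_mismatch_errors():
    pred = _graph([("A", "B", 1)], variables=("A", "B"))
    with pytest.raises(ValueError):
        score_graph(pred, TRUTH)


def test_fscore_identity():
    r = ScoreReport.from_counts(3, 1, 2, "skeleton")
    assert r.fscore == pytest.approx(
        2 * r.precision * r.recall / (r.precision + r.recall)
    )


def test_edit_distance():
    a = _graph([("A", "B", 1), ("B", "C", 0)], ("A", "B", "C"))
    b = _graph([("A", "B", 1), ("A", "C", 2)], ("A", "B", "C"))
    assert summary_edit_distance(a, b) == 2
    assert summary_edit_distance(a, a) == 0


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------

def test_summary_graph_roundtrip(tmp_path):
    g = SummaryGraph(
        ("A", "B", "C"),
        [
            SummaryEdge("A", "B", 1, "directed", "+", 0.99),
            SummaryEdge("B", "C", 0, "undirected", "-", np.nan),
            SummaryEdge("A", "C", 2, "bidirected", "none", 0.97),
        ],
    )
    path = tmp_path / "graph.tsv"
    write_summary_graph(g, path)
    back = read_summary_graph(path)
    assert back.variables == g.variables
    assert back.to_frame().drop(columns="confidence").equals(
        g.to_frame().drop(columns="confidence")
    )


def test_summary_graph_malformed_header(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("#variables=A,B\nsource\ttarget\tlag_ts\n")
    with pytest.raises(ValueError, match="orientation"):
        read_summary_graph(path)
    path.write_text("source\ttarget\n")
    with pytest.raises(ValueError, match="#variables="):
        read_summary_graph(path)


def test_ground_truth_roundtrip(tmp_path):
    net = BenchmarkNetwork(
        3,
        [BenchmarkEdge("A", "B", 1, 0.4, "linear")],
        ["A", "B", "C"],
        latent_edges=[BenchmarkEdge("A", "C", 2, 1.0, "latent")],
    )
    path = tmp_path / "truth.tsv"
    write_ground_truth(net, path)
    back = read_ground_truth(path)
    assert back.edge_set() == net.edge_set()
    assert len(back.latent_edges) == 1


def test_stack_roundtrip(tmp_path):
    stack = (np.arange(2 * 8 * 9) % 255).reshape(2, 8, 9).astype(np.uint8)
    path = tmp_path / "stack.tif"
    write_stack(stack, path)
    assert np.array_equal(read_stack(path), stack)


def test_feature_table_roundtrip(tmp_path):
    table = pd.DataFrame({"frame": [0, 1], "area": [600.0, 610.0],
                          "apoptosis": ["No", "Yes"]})
    path = tmp_path / "features.csv"
    write_feature_table(table, path)
    assert read_feature_table(path).equals(table)
    (tmp_path / "bad.csv").write_text("a,b\n1,2\n")
    with pytest.raises(ValueError, match="frame"):
        read_feature_table(tmp_path / "bad.csv")
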