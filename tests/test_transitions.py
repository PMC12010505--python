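import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifkit.io_formats import CohortTable, LabelSeries, ValidationError
from motifkit.transitions import (bin_labels, cohort_matrix, edge_group_test,
                                  export_network, fit_binomial_glmm,
                                  to_probabilities, top_edges,
                                  transition_counts, transition_difference)


def _series(labels, m, fps=25.0):
    return LabelSeries("s", fps, labels, m)


def test_bin_labels_modal_and_partial_drop():
    # bin 0: 0 x3 (mode); bin 1: mode 2; 2 trailing frames dropped
    lab = [0, 0, 0, 1] + [2, 2, 1, 2] + [1, 1]
    out = bin_labels(_series(lab, 3), bin_frames=4)
    np.testing.assert_array_equal(out.labels, [0, 2])
    assert out.fps == pytest.approx(25.0 / 4)


def test_bin_labels_tie_earliest_occurring():
    # bin with 2 frames of label 1 then 2 of label 0: tie -> 1 (earliest)
    out = bin_labels(_series([1, 1, 0, 0], 2), bin_frames=4)
    np.testing.assert_array_equal(out.labels, [1])


def test_transition_counts_brute_force(rng):
    m = 5
    lab = rng.integers(0, m, 300)
    counts, usage = transition_counts(_series(lab, m), m)
    brute = np.zeros((m, m), dtype=int)
    for a, b in zip(lab[:-1], lab[1:]):
        brute[a, b] += 1
    np.testing.assert_array_equal(counts, brute)
    np.testing.assert_array_equal(usage, np.bincount(lab[:-1], minlength=m))
    np.testing.assert_array_equal(counts.sum(axis=1), usage)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.integers(0, 3), min_size=2, max_size=100))
def test_transition_counts_property(lab):
    counts, usage = transition_counts(_series(lab, 4), 4)
    assert counts.sum() == len(lab) - 1
    np.testing.assert_array_equal(counts.sum(axis=1), usage)


def test_dwell_inclusive_absorbing_diagonal_one():
    lab = [0, 0, 1, 1, 1]  # state 1 is absorbing in this sample
    counts, usage = transition_counts(_series(lab, 2), 2)
    tm = to_probabilities(counts, usage, "dwell_inclusive")
    np.testing.assert_allclose(tm.probabilities[1], [0.0, 1.0])
    np.testing.assert_allclose(tm.probabilities[0], [0.5, 0.5])


def test_switch_only_zero_diagonal_renormalized():
    counts = np.array([[6, 2, 2], [1, 8, 1], [0, 0, 0]])
    usage = counts.sum(axis=1)
    tm = to_probabilities(counts, usage, "switch_only")
    np.testing.assert_allclose(np.diag(tm.probabilities), 0.0)
    np.testing.assert_allclose(tm.probabilities[0], [0.0, 0.5, 0.5])
    np.testing.assert_allclose(tm.probabilities[1], [0.5, 0.0, 0.5])
    # unvisited motif keeps an all-zero row
    np.testing.assert_allclose(tm.probabilities[2], 0.0)


def test_to_probabilities_usage_mismatch():
    counts = np.array([[1, 0], [0, 1]])
    with pytest.raises(ValidationError, match="usage"):
        to_probabilities(counts, np.array([2, 1]), "dwell_inclusive")


def test_cohort_matrix_pools_counts():
    a = _series([0, 1, 0], 2)
    b = _series([1, 1, 0], 2)
    tm = cohort_matrix([a, b], 2)
    # pooled counts: a gives 0->1, 1->0; b gives 1->1, 1->0
    np.testing.assert_array_equal(tm.counts, [[0, 1], [2, 1]])
    np.testing.assert_allclose(tm.probabilities[1], [2 / 3, 1 / 3])
    assert tm.subjects == ["s", "s"]


def test_transition_difference_and_mode_guard():
    a = cohort_matrix([_series([0, 1, 0, 1], 2)], 2)
    b = cohort_matrix([_series([0, 0, 1, 1], 2)], 2)
    d = transition_difference(a, b)
    np.testing.assert_allclose(d, a.probabilities - b.probabilities)
    b_sw = cohort_matrix([_series([0, 0, 1, 1], 2)], 2, mode="switch_only")
    with pytest.raises(ValidationError, match="mode"):
        transition_difference(a, b_sw)


def test_top_edges_ceil_and_ties():
    # rows normalize to give off-diagonal probabilities
    # (0,1)=.5 (0,2)=.3 (1,2)=.3 (2,3)=.3 (3,0)=.1
    counts = np.array([[2, 5, 3, 0],
                       [0, 7, 3, 0],
                       [0, 0, 7, 3],
                       [1, 0, 0, 9]])
    tm = to_probabilities(counts, counts.sum(axis=1), "dwell_inclusive")
    # 5 nonzero off-diagonal candidates; ceil(0.2 * 5) = 1 -> keep (0, 1)
    top = top_edges(tm, quantile=0.2)
    assert len(top) == 1
    assert (top.iloc[0]["source"], top.iloc[0]["target"]) == (0, 1)
    # ceil(0.4 * 5) = 2, but rank-2 prob 0.3 is tied three ways -> keep 4
    top2 = top_edges(tm, quantile=0.4)
    assert len(top2) == 4
    assert set(zip(top2["source"], top2["target"])) == {
        (0, 1), (0, 2), (1, 2), (2, 3)}


def test_top_edges_deterministic_order():
    probs = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
    counts = (probs * 2).astype(int)
    tm = to_probabilities(counts, counts.sum(axis=1), "dwell_inclusive")
    top = top_edges(tm, quantile=1.0)
    pairs = list(zip(top["source"], top["target"]))
    assert pairs == sorted(pairs)  # equal probs -> lexicographic order


def test_glmm_recovers_known_effect(rng):
    # simulate binomial counts with a known log-odds shift of 1.0
    n = 30
    group = np.repeat([0.0, 1.0], n // 2)
    u = rng.normal(0, 0.5, n)
    eta = -2.0 + 1.0 * group + u
    trials = np.full(n, 2000.0)
    succ = rng.binomial(2000, 1 / (1 + np.exp(-eta)))
    X = np.column_stack([np.ones(n), group])
    fit = fit_binomial_glmm(succ, trials, X)
    assert fit["converged"]
    assert fit["beta"][1] == pytest.approx(1.0, abs=0.4)
    assert 0.1 < fit["sigma"] < 1.2
    assert fit["p"][1] < 1e-3


def test_glmm_null_effect_large_p(rng):
    n = 20
    group = np.repeat([0.0, 1.0], n // 2)
    succ = rng.binomial(500, 0.1, n).astype(float)
    X = np.column_stack([np.ones(n), group])
    fit = fit_binomial_glmm(succ, np.full(n, 500.0), X)
    assert fit["converged"]
    assert fit["p"][1] > 0.01


def _edge_cohort():
    rows = [("c0", "WT", "F", "g", 25.0), ("c1", "WT", "M", "g", 25.0),
            ("c2", "WT", "F", "g", 25.0), ("c3", "WT", "M", "g", 25.0),
            ("m0", "MUT", "F", "g", 25.0), ("m1", "MUT", "M", "g", 25.0),
            ("m2", "MUT", "F", "g", 25.0), ("m3", "MUT", "M", "g", 25.0)]
    return CohortTable(pd.DataFrame(rows, columns=[
        "subject_id", "genotype", "sex", "group", "session_minutes"]))


def test_edge_group_test_detects_enriched_edge(rng):
    cohort = _edge_cohort()
    m = 3
    per_subject = {}
    for sid in cohort.subject_ids:
        p01 = 0.4 if sid.startswith("m") else 0.1
        counts = np.zeros((m, m), dtype=int)
        usage = np.zeros(m, dtype=int)
        usage[0] = 900
        counts[0, 1] = rng.binomial(900, p01)
        counts[0, 0] = usage[0] - counts[0, 1]
        usage[1] = 600
        counts[1, 2] = rng.binomial(600, 0.2)
        counts[1, 1] = usage[1] - counts[1, 2]
        per_subject[sid] = (counts, usage)
    rep, skipped = edge_group_test(per_subject, cohort, reference="WT")
    e01 = rep[(rep.source == 0) & (rep.target == 1)].iloc[0]
    assert e01["significant"]
    assert e01["direction"] == "over"
    assert e01["log_odds_ratio"] > 0.5
    e12 = rep[(rep.source == 1) & (rep.target == 2)].iloc[0]
    assert not e12["significant"]
    # untouched edges with zero pooled counts are skipped, not tested
    assert (skipped.source == 2).any()
    assert rep["q"].between(0, 1).all()


def test_edge_group_test_skips_zero_edges():
    cohort = _edge_cohort()
    counts = np.array([[5, 0], [0, 5]])
    usage = np.array([5, 5])
    per_subject = {sid: (counts, usage) for sid in cohort.subject_ids}
    rep, skipped = edge_group_test(per_subject, cohort, reference="WT")
    tested = set(zip(rep["source"], rep["target"]))
    assert tested == {(0, 0), (1, 1)}
    assert set(zip(skipped["source"], skipped["target"])) == {(0, 1), (1, 0)}


def test_export_network_round_trip(tmp_path):
    import networkx as nx
    edges = pd.DataFrame({"source": [0, 1], "target": [1, 0],
                          "probability": [0.6, 0.3], "rank": [1, 2]})
    gml = tmp_path / "net.graphml"
    tsv = tmp_path / "edges.tsv"
    g = export_network(edges, {0: 100.0, 1: 50.0}, str(gml), str(tsv),
                       communities={0: "A", 1: "B"})
    assert gml.exists() and tsv.exists()
    back = nx.read_graphml(gml)
    assert back.nodes["0"]["community"] == "A"
    assert back.edges["0", "1"]["probability"] == pytest.approx(0.6)
    assert back.edges["0", "1"]["width"] == pytest.approx(1.0)
    tab = pd.read_csv(tsv, sep="\t")
    assert len(tab) == 2
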