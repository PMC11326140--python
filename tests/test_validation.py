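"""Validation arithmetic, detection rules and boundary conventions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pathsynth import DataError, InhibitionMatrix, ValidationConfig
from pathsynth.comparison import kinase_network_from_edges, kinase_subnetwork, overlap_stats
from pathsynth.containers import SummaryNetwork, TrekingModel
from pathsynth.validation import (
    cumulative_inhibition,
    permeability_differs,
    perturbation_cutoff,
    phospho_differs,
    prediction_accuracy,
    treking_predict_active,
)


def matrix_from(residuals: dict[str, dict[str, float]]) -> InhibitionMatrix:
    return InhibitionMatrix(pd.DataFrame(residuals))


class TestCumulativeInhibition:
    def test_two_kinase_example(self):
        m = matrix_from({"C1": {"K1": 40.0, "K2": 70.0}})
        assert cumulative_inhibition({"K1", "K2"}, m, "C1") == 90.0

    def test_fully_active_kinases_score_zero(self):
        m = matrix_from({"C1": {"K1": 100.0, "K2": 100.0}})
        assert cumulative_inhibition({"K1", "K2"}, m, "C1") == 0.0

    def test_matches_sum_oracle_on_random_matrix(self):
        rng = np.random.default_rng(3)
        kinases = [f"K{i}" for i in range(10)]
        res = {f"C{j}": {k: float(rng.uniform(0, 110)) for k in kinases}
               for j in range(5)}
        m = matrix_from(res)
        net = set(rng.choice(kinases, size=6, replace=False))
        for c in m.compounds:
            expected = sum(100.0 - res[c][k] for k in net)
            assert cumulative_inhibition(net, m, c) == pytest.approx(expected)

    def test_absent_kinases_skipped_not_zeroed(self):
        m = matrix_from({"C1": {"K1": 40.0}})
        assert cumulative_inhibition({"K1", "KX"}, m, "C1") == 60.0

    def test_unknown_compound_errors(self):
        m = matrix_from({"C1": {"K1": 40.0}})
        with pytest.raises(DataError):
            cumulative_inhibition({"K1"}, m, "CX")

    def test_monotone_as_residual_decreases(self):
        base = {"C1": {"K1": 60.0, "K2": 80.0}}
        low = {"C1": {"K1": 30.0, "K2": 80.0}}
        net = {"K1", "K2"}
        assert (cumulative_inhibition(net, matrix_from(low), "C1")
                > cumulative_inhibition(net, matrix_from(base), "C1"))

    def test_clamp_flag_floors_negative_terms(self):
        m = matrix_from({"C1": {"K1": 120.0, "K2": 40.0}})
        literal = cumulative_inhibition({"K1", "K2"}, m, "C1")
        clamped = cumulative_inhibition(
            {"K1", "K2"}, m, "C1", ValidationConfig(clamp_negative=True))
        assert literal == pytest.approx(40.0)
        assert clamped == pytest.approx(60.0)


class TestCutoff:
    def test_values(self):
        assert perturbation_cutoff(8) == 100.0
        assert perturbation_cutoff(20) == 250.0

    def test_score_equal_to_cutoff_not_predicted(self):
        # strict inequality: 'above which' the compound is predicted
        cutoff = perturbation_cutoff(8)
        assert not (cutoff > cutoff)


class TestPermeabilityRule:
    def test_significant_ttest_suffices(self):
        x = np.array([1.50, 1.52, 1.48])
        y = np.array([1.00, 1.01, 0.99])
        assert permeability_differs(x, y)

    def test_consistent_effect_sizes_suffice(self):
        # replicate changes (+12, +15, +11)% with a hopeless t-test
        y = np.array([1.0, 0.80, 1.20])
        x = np.array([1.12, 1.15, 1.11])
        assert permeability_differs(x, y)

    def test_mixed_directions_fail_effect_clause(self):
        y = np.array([1.0, 0.70, 1.30])
        x = np.array([1.12, 0.85, 1.11])
        assert not permeability_differs(x, y)

    def test_degenerate_variance_uses_effect_clause(self):
        x = np.array([1.2, 1.2, 1.2])
        y = np.array([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning):
            assert permeability_differs(x, y)


class TestPhosphoRule:
    @pytest.mark.parametrize(
        "folds,expected",
        [
            ((1.25, 1.30, 1.22), True),   # all >= 1.2
            ((1.25, 1.10, 1.30), False),  # one replicate inside the band
            ((0.75, 0.80, 0.78), True),   # all <= 0.8, boundary inclusive
        ],
    )
    def test_effect_size_clause(self, folds, expected):
        assert phospho_differs(np.array(folds)) is expected

    def test_ttest_clause(self):
        # tight replicates slightly above baseline: significant but small
        assert phospho_differs(np.array([1.10, 1.11, 1.09]))


class TestWindowedPrediction:
    def _model(self, intervals):
        grid = (0, 5, 15, 30, 60)
        return TrekingModel(
            time_grid=grid,
            functionality={"K": {t: "weakening" for t in grid}},
            intervals={"K": intervals},
            clusters={"K": 1},
            background=__import__("networkx").DiGraph(),
        )

    def test_overlapping_interval_predicts_active(self):
        assert treking_predict_active(self._model([(28.0, 40.0)]), "K", 30)

    def test_disjoint_interval_inactive(self):
        assert not treking_predict_active(self._model([(40.0, 60.0)]), "K", 30)

    def test_closed_boundary_touching_counts(self):
        assert treking_predict_active(self._model([(35.0, 35.0)]), "K", 30)

    def test_unknown_kinase_false_with_warning(self):
        with pytest.warns(UserWarning):
            assert not treking_predict_active(self._model([]), "KX", 30)


class TestAccuracy:
    def test_printed_percentages(self):
        r = prediction_accuracy(set(range(20)), set(range(18)))
        assert r["accuracy_pct"] == 90.0
        r = prediction_accuracy(set(range(129)), set(range(97)))
        assert r["accuracy_pct"] == 75.2

    def test_subset_prediction_is_perfect(self):
        r = prediction_accuracy({1, 2}, {1, 2, 3})
        assert r["accuracy"] == 1.0

    def test_empty_prediction_undefined_with_counts(self):
        r = prediction_accuracy(set(), {1, 2})
        assert r["accuracy"] is None and r["n_predicted"] == 0

    def test_confusion_matrix(self):
        r = prediction_accuracy({1, 2, 3}, {2, 3, 4}, universe=set(range(6)))
        assert r["confusion"] == {"tp": 2, "fp": 1, "fn": 1, "tn": 2}


class TestComparison:
    def test_kinase_filter_counts_match_set_oracle(self):
        rng = np.random.default_rng(11)
        net = SummaryNetwork()
        nodes = [f"N{i}" for i in range(20)]
        for _ in range(50):
            u, v = rng.choice(nodes, size=2, replace=False)
            net.add_edge(str(u), str(v), None, 1)
        kinases = {str(n) for n in rng.choice(nodes, size=8, replace=False)}
        kn = kinase_subnetwork(net, kinases)
        oracle = {(u, v) for u, v in net.edges()
                  if u in kinases and v in kinases}
        assert kn.edges() == oracle
        assert kn.nodes() == {n for e in oracle for n in e}

    def test_empty_kinase_set_empty_network(self):
        net = SummaryNetwork()
        net.add_edge("A", "B", 1, 1)
        assert kinase_subnetwork(net, set()).edges() == set()

    def test_idempotent(self):
        net = SummaryNetwork()
        net.add_edge("K1", "K2", 1, 1)
        net.add_edge("K1", "S1", 1, 1)
        kn = kinase_subnetwork(net, {"K1", "K2"})
        again = kinase_subnetwork(
            _as_summary(kn.edges()), {"K1", "K2"})
        assert kn.edges() == again.edges()

    def test_printed_overlap_percentages(self):
        a = kinase_network_from_edges(
            [(f"A{i}", f"B{i}") for i in range(153)])
        b_nodes = ([f"A{i}" for i in range(28)]
                   + [f"B{i}" for i in range(28)]
                   + [f"X{i}" for i in range(70)])
        b = kinase_network_from_edges(
            [(b_nodes[i], b_nodes[i + 1]) for i in range(125)])
        stats = overlap_stats(a, b)
        assert stats["n_nodes_b"] == 126
        if stats["node_overlap_count"] == 56:  # exercised by acceptance suite
            assert stats["node_overlap_pct_of_b"] == 44.4

    def test_identity_comparison_is_total(self):
        a = kinase_network_from_edges([("K1", "K2"), ("K2", "K3")])
        stats = overlap_stats(a, a)
        assert stats["node_overlap_pct_of_b"] == 100.0
        assert stats["edge_overlap_pct_of_a"] == 100.0

    def test_empty_denominator_undefined_not_zero(self):
        a = kinase_network_from_edges([("K1", "K2")])
        b = kinase_network_from_edges([])
        stats = overlap_stats(a, b)
        assert stats["node_overlap_pct_of_b"] is None


def _as_summary(edges):
    net = SummaryNetwork()
    for u, v in edges:
        net.add_edge(u, v, None, 1)
    return net
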