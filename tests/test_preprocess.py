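"""Normalization, paired t-tests, discretization and prize derivation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pathsynth import DataError
from pathsynth.containers import ACTIVATED, INACTIVE, INHIBITED, PhosphoTimeSeries
from pathsynth.preprocess import (
    compute_prizes,
    compute_significance,
    discretize_activity,
    normalize_blots,
    paired_ttest,
    preprocess_dataset,
)


class TestNormalizeBlots:
    def test_worked_example(self):
        ts = normalize_blots([[100, 300]], [[50, 75]], 0.0,
                             time_grid=(0, 5))
        # (300/75)/(100/50) = 2
        assert np.allclose(ts.values, [[1.0, 2.0]])

    def test_raw_equal_loading_gives_unity(self):
        raw = np.array([[3.0, 7.0, 11.0], [2.0, 9.0, 4.0]])
        ts = normalize_blots(raw, raw, time_grid=(0, 5, 15))
        assert np.all(ts.values == 1.0)

    def test_matches_spreadsheet_oracle(self):
        rng = np.random.default_rng(42)
        raw = rng.uniform(10, 100, size=(3, 9))
        loading = rng.uniform(10, 100, size=(3, 9))
        bg = 2.0
        ts = normalize_blots(raw, loading, bg,
                             time_grid=(0, 5, 15, 30, 60, 120, 180, 240, 360))
        # cell-by-cell recomputation, spreadsheet style
        for r in range(3):
            base = (raw[r, 0] - bg) / (loading[r, 0] - bg)
            for t in range(9):
                expected = ((raw[r, t] - bg) / (loading[r, t] - bg)) / base
                assert abs(ts.values[r, t] - expected) <= 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(10, 100, size=(3, 5))
        loading = rng.uniform(10, 100, size=(3, 5))
        a = normalize_blots(raw, loading, time_grid=(0, 5, 15, 30, 60))
        b = normalize_blots(raw * 7.5, loading, time_grid=(0, 5, 15, 30, 60))
        assert np.allclose(a.values, b.values)

    def test_nonpositive_signal_names_band(self):
        with pytest.raises(DataError, match="band"):
            normalize_blots([[10.0, 1.0]], [[5.0, 5.0]], background=2.0)


class TestPairedTTest:
    def test_worked_value(self):
        """d = (0.1, 0.2, 0.3): t = 3.4641, two-sided p ~ 0.0742."""
        x = np.array([1.1, 1.2, 1.3])
        y = np.array([1.0, 1.0, 1.0])
        p, flag = paired_ttest(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert abs(t - 3.4641) < 1e-4
        assert abs(p - 0.0742) < 5e-4
        assert flag is None

    def test_identical_vectors_give_p_one(self):
        p, flag = paired_ttest(np.ones(3), np.ones(3))
        assert p == 1.0 and flag == "zero-diff"

    def test_constant_nonzero_difference_gives_p_zero(self):
        p, flag = paired_ttest(np.array([2.0, 2.0, 2.0]), np.ones(3))
        assert p == 0.0 and flag == "zero-sd"

    def test_matches_scipy_oracle_on_random_triples(self):
        """Agreement with the reference implementation to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            x = rng.normal(1, 0.3, size=3)
            y = rng.normal(1, 0.3, size=3)
            p, flag = paired_ttest(x, y)
            ref = stats.ttest_rel(x, y).pvalue
            assert flag is None
            assert abs(p - ref) < 1e-10

    @given(st.lists(st.floats(0.1, 10), min_size=2, max_size=8),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_p_in_unit_interval(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.array(xs)
        y = x + rng.normal(0, 0.5, size=x.size)
        p, _ = paired_ttest(x, y)
        assert 0.0 <= p <= 1.0


class TestSignificanceAndStates:
    def test_flat_series_all_p_one(self):
        ts = PhosphoTimeSeries("X", (0, 5, 15), np.ones((3, 3)))
        sc = compute_significance(ts)
        assert np.all(sc.firstscores == 1.0) and np.all(sc.prevscores == 1.0)

    def test_score_vectors_have_t_minus_one_entries(self, small_study):
        for p in small_study.dataset.proteins():
            sc = compute_significance(small_study.dataset[p])
            assert sc.firstscores.size == len(small_study.cfg.time_grid) - 1
            assert sc.prevscores.size == sc.firstscores.size

    def test_step_profile_detected_in_most_seeds(self):
        """p(first) < 0.05 at all post-step times in >= 90% of 200 seeds."""
        ok = 0
        grid = (0, 5, 15, 30, 60)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            base = np.array([1, 1, 2, 2, 2], dtype=float)
            vals = base * rng.lognormal(
                -0.5 * np.log(1 + 0.05**2), np.sqrt(np.log(1 + 0.05**2)),
                size=(3, 5),
            )
            vals[:, 0] = 1.0
            sc = compute_significance(PhosphoTimeSeries("X", grid, vals))
            if np.all(sc.firstscores[1:] < 0.05):
                ok += 1
        assert ok >= 180

    def test_discretization_rules(self):
        grid = (0, 5, 15)
        up = PhosphoTimeSeries("U", grid, np.array(
            [[1, 1.8, 1.9], [1, 1.75, 1.85], [1, 1.85, 1.8]]))
        prof = discretize_activity(up, compute_significance(up))
        assert prof.states[0] == INACTIVE
        assert prof.states[1] == ACTIVATED

    def test_insignificant_stays_inactive(self):
        grid = (0, 5, 15)
        rng = np.random.default_rng(5)
        vals = np.abs(rng.normal(1, 0.6, size=(3, 3))) + 0.2
        vals[:, 0] = 1.0
        ts = PhosphoTimeSeries("N", grid, vals)
        sc = compute_significance(ts)
        prof = discretize_activity(ts, sc)
        for k in range(1, 3):
            if min(sc.firstscores[k - 1], sc.prevscores[k - 1]) > 0.05:
                assert prof.states[k] == INACTIVE

    def test_planted_inhibition_recovered_noiselessly(self, noiseless_study):
        truth = noiseless_study.truth
        signs = truth.cumulative_signs()
        inhibited = [p for p in truth.activation_times
                     if p != truth.source_node and signs[p] < 0]
        scores, profiles, _ = preprocess_dataset(noiseless_study.dataset)
        for p in inhibited:
            prof = profiles[p]
            t_on = truth.activation_times[p]
            for t, s in zip(prof.time_grid, prof.states):
                if t >= t_on:
                    assert s == INHIBITED

    def test_noiseless_first_change_equals_activation_time(self, noiseless_study):
        truth = noiseless_study.truth
        _, profiles, _ = preprocess_dataset(noiseless_study.dataset)
        for p, t_on in truth.activation_times.items():
            if p == truth.source_node:
                continue
            assert profiles[p].first_change() == t_on


class TestPrizes:
    def test_worked_values(self):
        from pathsynth.containers import SignificanceScores

        sc = SignificanceScores("A", [0.01, 0.5], [0.9, 0.7])
        assert compute_prizes({"A": sc})["A"] == pytest.approx(2.0)
        flat = SignificanceScores("B", [1.0, 1.0], [1.0, 1.0])
        assert compute_prizes({"B": flat})["B"] == 0.0

    def test_zero_p_capped(self):
        from pathsynth.containers import SignificanceScores

        sc = SignificanceScores("A", [0.0, 1.0], [1.0, 1.0])
        assert compute_prizes({"A": sc})["A"] == 16.0

    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=8),
           st.integers(0, 7))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_evidence(self, ps, idx):
        """Lowering any p-value never lowers the prize."""
        from pathsynth.containers import SignificanceScores

        first, prev = list(ps), list(reversed(ps))
        sc = SignificanceScores("A", first, prev)
        base = compute_prizes({"A": sc})["A"]
        first2 = list(first)
        first2[idx % len(first2)] = first2[idx % len(first2)] / 10
        lowered = compute_prizes(
            {"A": SignificanceScores("A", first2, prev)}
        )["A"]
        assert lowered >= base - 1e-12
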