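"""Temporal synthesis core: candidates, path validity, consolidation."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from pathsynth import DataError, PartialModel, SubNetwork
from pathsynth.containers import ACTIVATED, INACTIVE, INHIBITED, ActivityProfile
from pathsynth.synthesis import (
    brute_force_summary,
    candidate_events,
    is_valid_path,
    synthesize,
)

GRID = (0, 5, 15, 30, 60)


def chain_sub(*nodes):
    g = nx.Graph()
    for a, b in zip(nodes, nodes[1:]):
        g.add_edge(a, b)
    return SubNetwork(g, nodes[0])


def profile(name, changes):
    """changes: {time: 'activated'|'inhibited'}; inactive elsewhere."""
    states = tuple(changes.get(t, INACTIVE) for t in GRID)
    return ActivityProfile(name, GRID, states)


class TestCandidateEvents:
    def test_unconstrained_edge_gives_four(self):
        sub = chain_sub("S", "A")
        evs = candidate_events(sub, PartialModel())
        assert evs == {("S", "A", 1), ("S", "A", -1),
                       ("A", "S", 1), ("A", "S", -1)}

    def test_signed_prior_restricts_to_one(self):
        sub = chain_sub("A", "B")
        pm = PartialModel([("A", "B", 1)])
        assert candidate_events(sub, pm) == {("A", "B", 1)}

    def test_unsigned_prior_keeps_both_signs_one_direction(self):
        sub = chain_sub("A", "B")
        pm = PartialModel([("A", "B", None)])
        assert candidate_events(sub, pm) == {("A", "B", 1), ("A", "B", -1)}

    def test_bidirectional_prior_keeps_both_directions(self):
        sub = chain_sub("A", "B")
        pm = PartialModel([("A", "B", 1), ("B", "A", -1)])
        assert candidate_events(sub, pm) == {("A", "B", 1), ("B", "A", -1)}

    def test_out_of_network_prior_edges_dropped(self):
        sub = chain_sub("A", "B")
        pm = PartialModel([("A", "Z", 1)])
        assert len(candidate_events(sub, pm)) == 4


class TestPathValidity:
    def test_activation_explained_by_positive_edge(self):
        profs = {"A": profile("A", {5: ACTIVATED})}
        assert is_valid_path([("S", "A", 1)], profs, "S")

    def test_timing_violation_rejected(self):
        profs = {"A": profile("A", {15: ACTIVATED}),
                 "B": profile("B", {5: ACTIVATED})}
        assert not is_valid_path([("S", "A", 1), ("A", "B", 1)], profs, "S")

    def test_sign_mismatch_rejected(self):
        profs = {"A": profile("A", {5: ACTIVATED})}
        assert not is_valid_path([("S", "A", -1)], profs, "S")

    def test_inhibition_needs_negative_product(self):
        profs = {"A": profile("A", {5: ACTIVATED}),
                 "B": profile("B", {15: INHIBITED})}
        assert is_valid_path([("S", "A", 1), ("A", "B", -1)], profs, "S")
        assert not is_valid_path([("S", "A", 1), ("A", "B", 1)], profs, "S")

    def test_unmeasured_terminal_rejected(self):
        assert not is_valid_path([("S", "X", 1)], {}, "S")

    def test_wrong_start_raises(self):
        profs = {"A": profile("A", {5: ACTIVATED})}
        with pytest.raises(DataError):
            is_valid_path([("A", "S", 1)], profs, "S")


class TestSynthesize:
    def test_directed_signed_chain(self):
        sub = chain_sub("S", "A", "B")
        pm = PartialModel([("S", "A", 1), ("A", "B", 1)])
        profs = {"A": profile("A", {5: ACTIVATED}),
                 "B": profile("B", {15: ACTIVATED})}
        summary, windows = synthesize(sub, pm, profs, "S")
        assert summary.edges() == [("A", "B"), ("S", "A")]
        assert summary.signed_edges() == [("A", "B", 1), ("S", "A", 1)]
        assert windows.states("S", 0) == frozenset({ACTIVATED})
        assert windows.states("A", 5) == frozenset({ACTIVATED})

    def test_ambiguous_orientation_emitted_unsigned_both_ways(self):
        # A and B change simultaneously: both orientations of {A,B} are valid
        g = nx.Graph()
        g.add_edge("S", "A")
        g.add_edge("S", "B")
        g.add_edge("A", "B")
        sub = SubNetwork(g, "S")
        profs = {"A": profile("A", {5: ACTIVATED}),
                 "B": profile("B", {5: ACTIVATED})}
        summary, _ = synthesize(sub, PartialModel(), profs, "S")
        assert ("A", "B") in summary.edges() and ("B", "A") in summary.edges()
        signs = dict(((u, v), s) for u, v, s in summary.signed_edges())
        assert ("A", "B") not in signs and ("B", "A") not in signs

    def test_no_changing_node_raises(self):
        sub = chain_sub("S", "A")
        profs = {"A": profile("A", {})}
        with pytest.raises(DataError):
            synthesize(sub, PartialModel(), profs, "S")

    def test_unmeasured_windows_unconstrained(self):
        sub = chain_sub("S", "X", "A")
        profs = {"A": profile("A", {15: ACTIVATED})}
        _, windows = synthesize(sub, PartialModel(), profs, "S")
        assert windows.states("X", 5) == frozenset(
            {ACTIVATED, INHIBITED, INACTIVE})

    def test_removing_partial_model_never_removes_directed_edges(self):
        rng = np.random.default_rng(4)
        for trial in range(30):
            sub, pm, profs = _random_instance(rng, with_pm=True)
            try:
                with_pm, _ = synthesize(sub, pm, profs, "S",
                                        max_path_len=len(sub.nodes()) - 1)
                without, _ = synthesize(sub, PartialModel(), profs, "S",
                                        max_path_len=len(sub.nodes()) - 1)
            except DataError:
                continue
            assert set(with_pm.edges()) <= set(without.edges())


def _random_instance(rng, with_pm=False):
    from pathsynth.synthetic import generate_synthesis_instance

    sub, pm, profs = generate_synthesis_instance(rng)
    return sub, (pm if with_pm else PartialModel()), profs


class TestBruteForceOracle:
    def test_single_node_graph_empty(self):
        g = nx.Graph()
        g.add_node("S")
        sub = SubNetwork(g, "S")
        net = brute_force_summary(sub, PartialModel(), {}, "S")
        assert net.edges() == []

    def test_equals_synthesize_on_random_instances(self):
        """Pruned DFS and exhaustive enumeration agree edge-for-edge."""
        rng = np.random.default_rng(0)
        compared = 0
        for trial in range(100):
            sub, pm, profs = _random_instance(rng, with_pm=True)
            limit = len(sub.nodes()) - 1
            try:
                fast, _ = synthesize(sub, pm, profs, "S", max_path_len=limit)
            except DataError:
                continue
            slow = brute_force_summary(sub, pm, profs, "S", max_path_len=limit)
            assert fast == slow
            fast_paths = {e: fast.graph.edges[e]["n_paths"] for e in fast.graph.edges}
            slow_paths = {e: slow.graph.edges[e]["n_paths"] for e in slow.graph.edges}
            assert fast_paths == slow_paths
            compared += 1
        assert compared >= 60

    def test_noiseless_cascade_recovered(self, noiseless_study):
        """Every planted edge appears with correct direction; signed edges
        carry the planted sign."""
        from pathsynth import TemporalPathwayModel

        m = TemporalPathwayModel(
            noiseless_study.dataset,
            noiseless_study.interactome,
            noiseless_study.source,
            noiseless_study.partial_model,
        )
        res = m.fit(seed=0)
        rec = res.recovery(noiseless_study.truth)
        assert rec["recall"] == 1.0
        assert rec["sign_errors"] == 0


class TestSignedSparsity:
    def test_signed_fraction_nonincreasing_with_fewer_measured(self):
        """With sparser measurements, fewer summary edges can be signed."""
        rng = np.random.default_rng(8)
        fractions = {0.9: [], 0.4: []}
        for trial in range(100):
            sub, pm, profs_full = _random_instance(rng, with_pm=True)
            for keep in fractions:
                profs = {k: v for k, v in profs_full.items()
                         if rng.random() < keep}
                try:
                    s, _ = synthesize(sub, pm, profs, "S")
                except DataError:
                    continue
                if s.n_edges():
                    fractions[keep].append(
                        len(s.signed_edges()) / s.n_edges())
        assert np.mean(fractions[0.4]) <= np.mean(fractions[0.9]) + 0.05
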