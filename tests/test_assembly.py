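import numpy as np
import pytest

from tfdyn import (
    ACTIVATING,
    INHIBITING,
    Edge,
    InfluenceRanking,
    SignedNetwork,
    ValidationError,
    add_marker,
    assemble,
    max_over_time_scores,
    select_markers_data_driven,
    sign_edge,
)
from tfdyn.assembly import AssemblyError
from tfdyn.datatypes import ScoredNetwork


class TestSignEdge:
    def test_proportional_series_is_activating(self):
        src = np.array([1.0, 2.0, 3.0])
        assert sign_edge(src, 2 * src) == ACTIVATING

    def test_anticorrelated_series_is_inhibiting(self):
        src = np.array([1.0, 2.0, 3.0])
        assert sign_edge(src, -src + 10) == INHIBITING

    def test_constant_target_defaults_to_activating(self, caplog):
        assert sign_edge(np.array([1.0, 2, 3]), np.array([3.0, 3, 3])) == ACTIVATING

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            sign_edge(np.array([1.0, 2]), np.array([2.0, 1]))


def _scored(nodes, matrix, t, mode=ACTIVATING):
    return ScoredNetwork(t, nodes, np.asarray(matrix, float), mode)


class TestMaxOverTime:
    def test_takes_max_of_mode_matched_scores(self):
        nodes = ["a", "b"]
        act_nets = [_scored(nodes, [[0, s], [0.1, 0]], t)
                    for t, s in zip((0, 1, 2), (0.2, 0.7, 0.4))]
        inh_nets = [_scored(nodes, [[0, 0.9], [s, 0]], t, INHIBITING)
                    for t, s in zip((0, 1, 2), (0.3, 0.1, 0.6))]
        signs = {("a", "b"): ACTIVATING, ("b", "a"): INHIBITING}
        cands = max_over_time_scores(
            {ACTIVATING: act_nets, INHIBITING: inh_nets}, signs)
        by_pair = {(c.source, c.target): c for c in cands}
        assert by_pair[("a", "b")].score == pytest.approx(0.7)  # max over time
        # inhibiting pair reads the inhibiting-formula networks only
        assert by_pair[("b", "a")].score == pytest.approx(0.6)

    def test_single_time_point_is_identity(self):
        nodes = ["a", "b"]
        nets = {ACTIVATING: [_scored(nodes, [[0, 0.5], [0.3, 0]], 0)],
                INHIBITING: [_scored(nodes, [[0, 0.2], [0.4, 0]], 0, INHIBITING)]}
        signs = {("a", "b"): ACTIVATING, ("b", "a"): ACTIVATING}
        cands = max_over_time_scores(nets, signs)
        assert {(c.source, c.target): c.score for c in cands} == \
            {("a", "b"): 0.5, ("b", "a"): 0.3}

    def test_node_mismatch_rejected(self):
        nets = {ACTIVATING: [_scored(["a", "b"], np.zeros((2, 2)), 0),
                             _scored(["a", "c"], np.zeros((2, 2)), 1)],
                INHIBITING: [_scored(["a", "b"], np.zeros((2, 2)), 0, INHIBITING)]}
        with pytest.raises(ValidationError):
            max_over_time_scores(nets, {("a", "b"): ACTIVATING})


def _edge(s, t, sign=ACTIVATING, score=0.5):
    return Edge(s, t, sign, score)


class TestAssemble:
    def test_two_cycle_survives_dangling_source_removed(self):
        cands = [_edge("a", "b", score=0.9), _edge("b", "a", score=0.8),
                 _edge("c", "a", INHIBITING, 0.7)]
        net = assemble(cands, ["a", "b", "c"], n_a=2, n_i=1)
        assert net.nodes == ["a", "b"]
        assert {(e.source, e.target) for e in net.edges} == {("a", "b"), ("b", "a")}

    def test_chain_without_cycle_cascades_to_error(self):
        cands = [_edge("a", "b", score=0.9), _edge("b", "c", score=0.8)]
        with pytest.raises(AssemblyError, match="n_a"):
            assemble(cands, ["a", "b", "c"], n_a=2, n_i=1)

    def test_prune_is_fixed_point(self, sparse_dataset, small_config):
        from tfdyn.assembly import _prune
        from tfdyn.pipeline import run_network_construction
        ds = sparse_dataset
        build = run_network_construction(ds.snapshots, ds.series,
                                         ds.de_forward, small_config)
        nodes, edges = set(build.network.nodes), list(build.network.edges)
        nodes2, edges2 = _prune(nodes, edges, exempt=build.network.marker_nodes)
        assert nodes2 == nodes and sorted(edges2) == sorted(edges)

    def test_invariant_to_candidate_order(self):
        rng = np.random.default_rng(0)
        names = [f"n{i}" for i in range(6)]
        cands = []
        for s in names:
            for t in names:
                if s != t:
                    sign = ACTIVATING if rng.random() < 0.7 else INHIBITING
                    cands.append(Edge(s, t, sign, float(rng.uniform(0, 1))))
        net1 = assemble(cands, names, 8, 3)
        shuffled = list(cands)
        rng.shuffle(shuffled)
        net2 = assemble(shuffled, names, 8, 3)
        assert net1.nodes == net2.nodes
        assert net1.sorted_edges() == net2.sorted_edges()

    def test_every_surviving_node_has_activating_input(self, sparse_dataset,
                                                       small_config):
        from tfdyn.pipeline import run_network_construction
        ds = sparse_dataset
        net = run_network_construction(ds.snapshots, ds.series, ds.de_forward,
                                       small_config).network
        for node in net.nodes:
            assert net.incoming(node, ACTIVATING), node


class TestAddMarker:
    CANDS = [
        _edge("a", "m", score=0.9), _edge("b", "m", score=0.8),
        _edge("c", "m", score=0.7), _edge("d", "m", INHIBITING, 0.6),
        _edge("a", "b", score=0.5), _edge("b", "a", score=0.5),
        _edge("c", "a", score=0.4), _edge("d", "c", score=0.4),
        _edge("a", "d", score=0.4), _edge("m", "n2", score=0.9),
    ]
    BASE = SignedNetwork(
        ["a", "b", "c", "d"],
        [_edge("a", "b", score=0.5), _edge("b", "a", score=0.5),
         _edge("c", "a", score=0.4), _edge("d", "c", score=0.4),
         _edge("a", "d", score=0.4)],
    )

    def test_top_two_per_sign_injected(self):
        net = add_marker(self.BASE, "m", self.CANDS)
        incoming = {(e.source, e.sign) for e in net.incoming("m")}
        assert incoming == {("a", ACTIVATING), ("b", ACTIVATING),
                            ("d", INHIBITING)}  # only one inhibiting exists
        assert net.marker_nodes == {"m"}

    def test_existing_node_only_marked(self):
        net = add_marker(self.BASE, "a", self.CANDS)
        assert net.marker_nodes == {"a"}
        assert net.sorted_edges() == self.BASE.sorted_edges()

    def test_order_independent_for_two_markers(self):
        cands = self.CANDS + [_edge("a", "n2", score=0.3)]
        n1 = add_marker(add_marker(self.BASE, "m", cands), "n2", cands)
        n2 = add_marker(add_marker(self.BASE, "n2", cands), "m", cands)
        assert n1.sorted_edges() == n2.sorted_edges()
        assert n1.marker_nodes == n2.marker_nodes == {"m", "n2"}

    def test_marker_without_activating_candidate_rejected(self):
        with pytest.raises(AssemblyError):
            add_marker(self.BASE, "zz", [_edge("a", "zz", INHIBITING, 0.9)])


class TestSelectMarkers:
    def _ranking(self, scores, comp=(0.0, 2.0), direction="forward"):
        return InfluenceRanking(comp, direction, scores)

    def test_most_recurrent_forward_tf_first(self):
        rankings = [
            self._ranking({"x": 3.0, "y": 1.0, "z": 0.5}, (0, t))
            for t in (2.0, 3.0, 4.0)
        ] + [self._ranking({"q": 9.0}, (0, 2.0), "backward")]
        assert select_markers_data_driven(rankings, k=1) == ["x"]

    def test_ties_break_lexicographically(self):
        rankings = [self._ranking({"b": 1.0, "c": 1.0, "a": 1.0}, (0, 2.0)),
                    self._ranking({"c": 1.0, "a": 1.0, "b": 1.0}, (0, 3.0))]
        assert select_markers_data_driven(rankings, k=2) == ["a", "b"]

    def test_requires_forward_rankings(self):
        backward = [self._ranking({"a": 1.0}, (2.0, 0.0), "backward")]
        with pytest.raises(ValidationError):
            select_markers_data_driven(backward, k=1)


class TestRandomCandidateSets:
    def test_prune_fixed_point_and_determinism(self):
        """Assembly on random candidate sets is a deterministic fixed point."""
        from tfdyn.assembly import _prune
        rng = np.random.default_rng(42)
        names = [f"n{i}" for i in range(8)]
        for _ in range(200):
            cands = []
            for s in names:
                for t in names:
                    if s != t and rng.random() < 0.4:
                        sign = ACTIVATING if rng.random() < 0.6 else INHIBITING
                        cands.append(Edge(s, t, sign, float(rng.uniform(0, 1))))
            try:
                net = assemble(cands, names, 6, 2)
            except AssemblyError:
                continue
            nodes2, edges2 = _prune(set(net.nodes), list(net.edges))
            assert nodes2 == set(net.nodes)
            assert sorted(edges2) == sorted(net.edges)
            net2 = assemble(list(reversed(cands)), names, 6, 2)
            assert net2.sorted_edges() == net.sorted_edges()
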