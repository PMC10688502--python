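import pytest

from conftest import make_subnetwork, random_instance
from oracle import oracle_expansion

from sesn.expansion import (
    ExpansionConfig,
    ExpansionState,
    error_correction_step,
    expansion_step,
    init_seeds,
    neighbor_frontier,
    run_expansion,
    score_w,
    select_expansion_node,
)
from sesn.expression import SubNetworkSet
from sesn.io import PPINetwork
from sesn.weights import WeightModel


def make_state(K, K_i, removed=frozenset()):
    st = ExpansionState(K=list(K), K_set=set(K),
                        K_i=[set(k) for k in K_i], removed=set(removed))
    return st


def weights_for(subnets, score_initial=None):
    return WeightModel(alpha=(1,) * 8,
                       score_initial=dict(score_initial or {}),
                       wmatrix=[dict(s.weights) for s in subnets])


class TestInitSeeds:
    def test_one_distinct_seed_per_subnetwork(self):
        subs = SubNetworkSet([
            make_subnetwork(0, {("a", "b"): 1.0}),
            make_subnetwork(1, {("c", "d"): 1.0}),
            make_subnetwork(2, {("e", "f"): 1.0}),
        ])
        state = init_seeds(subs, ExpansionConfig(n=3, rng_seed=5))
        assert len(state.K) == 3
        assert len(set(state.K)) == 3
        for i in range(3):
            assert state.K_i[i] <= subs[i].nodes

    def test_exhausted_subnetwork_skipped(self):
        subs = SubNetworkSet([
            make_subnetwork(0, {}, extra_nodes={"a"}),
            make_subnetwork(1, {}, extra_nodes={"a"}),  # only candidate taken
        ])
        state = init_seeds(subs, ExpansionConfig(n=1, rng_seed=0))
        assert state.K == ["a"]
        assert state.K_i[1] == set()

    def test_seeded_rng_is_deterministic(self):
        subs = SubNetworkSet([
            make_subnetwork(0, {("a", "b"): 1.0, ("b", "c"): 0.5}),
            make_subnetwork(1, {("d", "e"): 1.0, ("e", "f"): 0.5}),
        ])
        cfg = ExpansionConfig(n=2, rng_seed=123)
        assert init_seeds(subs, cfg).K == init_seeds(subs, cfg).K

    def test_all_empty_is_error(self):
        subs = SubNetworkSet([make_subnetwork(0, {})])
        with pytest.raises(ValueError):
            init_seeds(subs, ExpansionConfig(n=1, rng_seed=0))


class TestFrontierAndScore:
    def test_frontier_on_path(self, path_graph):
        assert neighbor_frontier({"b"}, path_graph, {"b"}) == {"a", "c"}

    def test_full_set_has_empty_frontier(self, path_graph):
        nodes = path_graph.nodes
        assert neighbor_frontier(nodes, path_graph, nodes) == set()

    def test_score_sums_k_neighbors_only(self):
        sn = make_subnetwork(0, {("k1", "c"): 0.2, ("k2", "c"): 0.3,
                                 ("c", "x"): 0.9})
        state = make_state(["k1", "k2"], [{"k1", "k2"}])
        w = weights_for([sn])
        assert score_w("c", sn, state, w) == pytest.approx(0.5)

    def test_score_zero_without_k_neighbors(self):
        sn = make_subnetwork(0, {("c", "x"): 0.9})
        state = make_state(["k1"], [{"k1"}], )
        assert score_w("c", sn, make_state(["k1"], [{"k1"}]),
                       weights_for([sn])) == 0.0

    def test_score_is_linear_in_weights(self):
        base = {("k1", "c"): 0.2, ("k2", "c"): 0.3}
        sn1 = make_subnetwork(0, base)
        sn2 = make_subnetwork(0, {e: 2 * w for e, w in base.items()})
        state = make_state(["k1", "k2"], [{"k1", "k2"}])
        assert score_w("c", sn2, state, weights_for([sn2])) == pytest.approx(
            2 * score_w("c", sn1, state, weights_for([sn1])))


class TestSelection:
    def test_global_two_step_max(self):
        subs = SubNetworkSet([
            make_subnetwork(0, {("s0", "x"): 0.4}),
            make_subnetwork(1, {("s1", "y"): 0.7}),
        ])
        state = make_state(["s0", "s1"], [{"s0"}, {"s1"}])
        node, idx = select_expansion_node(state, subs, weights_for(subs))
        assert (node, idx) == ("y", 1)

    def test_empty_frontiers_return_none(self):
        subs = SubNetworkSet([make_subnetwork(0, {("a", "b"): 0.4})])
        state = make_state(["a", "b"], [{"a", "b"}])
        assert select_expansion_node(state, subs, weights_for(subs)) is None

    def test_tie_breaks_lexicographically(self):
        subs = SubNetworkSet([
            make_subnetwork(0, {("s0", "zz"): 0.5}),
            make_subnetwork(1, {("s1", "aa"): 0.5}),
        ])
        state = make_state(["s0", "s1"], [{"s0"}, {"s1"}])
        node, idx = select_expansion_node(state, subs, weights_for(subs))
        assert node == "aa"

    def test_expansion_step_updates_matching_subnets(self):
        subs = SubNetworkSet([
            make_subnetwork(0, {("s0", "c"): 0.9}),
            make_subnetwork(1, {("s1", "d"): 0.1}, extra_nodes={"c"}),
            make_subnetwork(2, {("s2", "e"): 0.1}),
        ])
        state = make_state(["s0", "s1", "s2"], [{"s0"}, {"s1"}, {"s2"}])
        assert expansion_step(state, subs, weights_for(subs))
        assert state.K[-1] == "c"
        assert "c" in state.K_i[0] and "c" in state.K_i[1]
        assert "c" not in state.K_i[2]


class TestErrorCorrection:
    def _setup(self):
        net = PPINetwork.from_edges([("a", "b"), ("b", "c")])
        subs = SubNetworkSet([make_subnetwork(0, {("a", "b"): 1.0,
                                                  ("b", "c"): 1.0})])
        return net, subs

    def test_swap_rule(self):
        net, subs = self._setup()
        w = weights_for(subs, {"a": 0.1, "b": 0.5, "c": 0.4})
        state = make_state(["a", "b"], [{"a", "b"}])
        assert error_correction_step(state, net, w, subs)
        assert state.K == ["b", "c"]
        assert state.removed == {"a"}

    def test_no_swap_when_max_not_above_min(self):
        net, subs = self._setup()
        w = weights_for(subs, {"a": 0.4, "b": 0.5, "c": 0.4})
        state = make_state(["a", "b"], [{"a", "b"}])
        assert not error_correction_step(state, net, w, subs)
        assert state.K == ["a", "b"]

    def test_readded_node_never_removed_again(self):
        # a was removed once, then re-added; it cannot be the removal victim
        net, subs = self._setup()
        w = weights_for(subs, {"a": 0.1, "b": 0.2, "c": 0.9})
        state = make_state(["a", "b"], [{"a", "b"}], removed={"a"})
        assert error_correction_step(state, net, w, subs)
        assert "a" in state.K            # protected by the one-removal ledger
        assert "b" not in state.K        # the weakest never-removed member goes
        assert state.removed == {"a", "b"}

    def test_empty_frontier_skips(self):
        net = PPINetwork.from_edges([("a", "b")])
        subs = SubNetworkSet([make_subnetwork(0, {("a", "b"): 1.0})])
        w = weights_for(subs, {"a": 0.1, "b": 0.5})
        state = make_state(["a", "b"], [{"a", "b"}])
        assert not error_correction_step(state, net, w, subs)


class TestRunExpansion:
    def test_n_equals_seed_count_returns_seeds(self):
        subs = SubNetworkSet([
            make_subnetwork(0, {("a", "b"): 1.0}),
            make_subnetwork(1, {("c", "d"): 1.0}),
        ])
        net = PPINetwork.from_edges([("a", "b"), ("c", "d")])
        cfg = ExpansionConfig(n=2, rng_seed=7)
        pred = run_expansion(net, subs, weights_for(subs), cfg)
        assert len(pred.ranking) == 2
        assert set(pred.seeds.values()) == set(pred.ranking)

    def test_unreachable_component_truncates(self):
        # the second component can never be reached by either mechanism
        net = PPINetwork.from_edges([("a", "b"), ("x", "y"), ("y", "z")])
        subs = SubNetworkSet([make_subnetwork(0, {("a", "b"): 1.0})])
        w = weights_for(subs, {v: 0.1 for v in net.nodes})
        pred = run_expansion(net, subs, w, ExpansionConfig(n=4, rng_seed=0))
        assert pred.truncated
        assert set(pred.ranking) == {"a", "b"}

    def test_k_is_monotone_and_exact_length(self):
        net, subnets, weights = random_instance(seed=901)
        n = max(2, len(net) // 3)
        pred = run_expansion(net, subnets, weights,
                             ExpansionConfig(n=n, rng_seed=3))
        if not pred.truncated:
            assert len(pred.ranking) == n
        assert len(set(pred.ranking)) == len(pred.ranking)

    def test_determinism(self):
        net, subnets, weights = random_instance(seed=77)
        cfg = ExpansionConfig(n_fraction=0.4, rng_seed=5)
        a = run_expansion(net, subnets, weights, cfg)
        b = run_expansion(net, subnets, weights, cfg)
        assert a.ranking == b.ranking

    def test_n_resolution_validation(self):
        cfg = ExpansionConfig(n=3, n_fraction=0.5)
        with pytest.raises(ValueError):
            cfg.resolve_n(10)
        assert ExpansionConfig(n_fraction=0.25).resolve_n(10) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_oracle(self, seed):
        net, subnets, weights = random_instance(seed=1000 + seed)
        n = max(2, len(net) // 2)
        pred = run_expansion(net, subnets, weights,
                             ExpansionConfig(n=n, rng_seed=seed))
        expect = oracle_expansion(net, subnets, weights, seed, n)
        assert pred.ranking == expect
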