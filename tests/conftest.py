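import numpy as np
import pytest

from sesn.expression import SubNetwork, SubNetworkSet
from sesn.io import AnnotationBundle, PPINetwork, RawExpression, SamplePlan
from sesn.synth import SyntheticConfig, generate


@pytest.fixture
def path_graph():
    """a - b - c - d path."""
    return PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def small_dataset():
    """A small deterministic synthetic dataset shared across tests."""
    cfg = SyntheticConfig(n_proteins=80, mean_degree=6.0, rng_seed=11)
    net, raw, bundle = generate(cfg)
    return cfg, net, raw, bundle


def make_subnetwork(index, edges_with_weights, extra_nodes=()):
    """Build a SubNetwork directly from {(u, v): w} for unit tests."""
    sn = SubNetwork(index=index)
    for (u, v), w in edges_with_weights.items():
        key = (u, v) if u <= v else (v, u)
        sn.weights[key] = w
        sn.nodes.update((u, v))
        sn.adjacency.setdefault(u, set()).add(v)
        sn.adjacency.setdefault(v, set()).add(u)
    sn.nodes.update(extra_nodes)
    return sn


def random_instance(seed, max_nodes=60, max_subnets=8):
    """A random small expansion instance: network, sub-networks, weights.

    Used by the oracle-equivalence harness.  Weights are arbitrary values
    in (0, 1]; sub-network membership is a random subset of nodes.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, max_nodes + 1))
    ids = [f"n{i:02d}" for i in range(n)]
    p_edge = min(1.0, 3.0 / n + 0.05)
    edges = [(ids[a], ids[b]) for a in range(n) for b in range(a + 1, n)
             if rng.random() < p_edge]
    net = PPINetwork.from_edges(edges, extra_nodes=ids)
    m = int(rng.integers(1, max_subnets + 1))
    subs = []
    for i in range(m):
        keep = {v for v in ids if rng.random() < 0.6}
        ew = {}
        for u, v in edges:
            if u in keep and v in keep and rng.random() < 0.8:
                ew[(u, v)] = float(rng.uniform(0.05, 1.0))
        subs.append(make_subnetwork(i, ew, extra_nodes={v for v in keep}))
    subnets = SubNetworkSet(subs)
    score_initial = {v: float(rng.uniform(0.0, 1.0)) for v in ids}
    from sesn.weights import WeightModel
    weights = WeightModel(alpha=(1,) * 8,
                          score_initial=score_initial,
                          wmatrix=[dict(s.weights) for s in subs])
    return net, subnets, weights
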