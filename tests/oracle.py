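"""From-scratch reference implementation of the seed-expansion loop.

Deliberately naive: every frontier and every candidate score is recomputed
from primitive dicts/sets each iteration, with no incremental state.  Used
to cross-check `sesn.expansion.run_expansion` element by element.
"""

import numpy as np


def oracle_expansion(net, subnets, weights, seed, n, use_correction=True):
    """Return the ranked list an exhaustive recomputation produces."""
    adj = {v: net.neighbors(v) for v in net.nodes}
    m = subnets.m
    sub_nodes = [set(s.nodes) for s in subnets]
    sub_adj = [{v: set(s.neighbors(v)) for v in s.nodes} for s in subnets]
    wm = [dict(weights.wmatrix[i]) for i in range(m)]
    si = dict(weights.score_initial)

    rng = np.random.default_rng(seed)
    K, K_i, removed, chosen = [], [set() for _ in range(m)], set(), set()
    for i in range(m):
        pool = sorted(sub_nodes[i] - chosen)
        if not pool:
            continue
        s = pool[rng.integers(len(pool))]
        chosen.add(s)
        K.append(s)
        K_i[i].add(s)

    while len(K) < n:
        k_set = set(K)
        # sub-network expansion: full recomputation
        best = None
        for i in range(m):
            frontier = set()
            for u in K_i[i]:
                frontier |= sub_adj[i].get(u, set())
            frontier -= k_set
            for cand in frontier:
                sc = 0.0
                for v in sub_adj[i].get(cand, set()):
                    if v in k_set:
                        key = (cand, v) if cand <= v else (v, cand)
                        sc += wm[i].get(key, 0.0)
                entry = (-sc, cand, i)
                if best is None or entry < best:
                    best = entry
        added = False
        if best is not None:
            node = best[1]
            K.append(node)
            for i in range(m):
                if node in sub_nodes[i]:
                    K_i[i].add(node)
            added = True
        if len(K) >= n:
            break
        corrected = False
        if use_correction:
            k_set = set(K)
            nei_k = set()
            for u in K:
                nei_k |= adj[u]
            nei_k -= k_set
            removable = [v for v in K if v not in removed]
            if nei_k and removable:
                mx = min(nei_k, key=lambda v: (-si[v], v))
                mn = min(removable, key=lambda v: (si[v], v))
                if si[mx] > si[mn]:
                    K.append(mx)
                    for i in range(m):
                        if mx in sub_nodes[i]:
                            K_i[i].add(mx)
                    corrected = True
                    if len(K) >= n:
                        break
                    K.remove(mn)
                    removed.add(mn)
                    for i in range(m):
                        K_i[i].discard(mn)
        if not added and not corrected:
            break
    return K[:n]
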