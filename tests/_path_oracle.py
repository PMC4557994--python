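"""Exhaustive-enumeration oracle for minimum-cost voxel paths.

Independent of the production Dijkstra route: enumerates every simple voxel
path between the two regions by depth-first search (with a cost bound for
tractability — any path whose partial cost already exceeds the best complete
path cannot be optimal, so pruning preserves exhaustiveness of the optimum).
Only usable on tiny grids.
"""

import itertools

import numpy as np


def _neighbors(shape):
    offs = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    nbrs = {}
    for vox in itertools.product(*[range(s) for s in shape]):
        out = []
        for o in offs:
            w = tuple(v + d for v, d in zip(vox, o))
            if all(0 <= w[k] < shape[k] for k in range(3)):
                out.append(w)
        nbrs[vox] = out
    return nbrs


def brute_force_min_cost(cost, labels, value_a, value_b, voxel_size=(1, 1, 1)):
    """Minimum cumulative cost between two labelled regions.

    Step cost u -> v is the physical step length times the mean of the two
    voxel costs; every voxel of region A is a zero-cost start. Returns inf
    when no path exists.
    """
    cost = np.asarray(cost, dtype=float)
    labels = np.asarray(labels)
    shape = cost.shape
    nbrs = _neighbors(shape)
    starts = list(zip(*np.nonzero(labels == value_a)))
    targets = {tuple(v) for v in zip(*np.nonzero(labels == value_b))}
    scale = np.asarray(voxel_size, dtype=float)

    best = [np.inf]

    def step_cost(u, v):
        d = (np.asarray(v) - np.asarray(u)) * scale
        return float(np.linalg.norm(d)) * (cost[u] + cost[v]) / 2.0

    def dfs(node, acc, visited):
        if acc >= best[0]:
            return
        if node in targets:
            best[0] = acc
            return
        for nxt in nbrs[node]:
            if nxt not in visited:
                dfs(nxt, acc + step_cost(node, nxt), visited | {nxt})

    for s in starts:
        dfs(s, 0.0, frozenset(starts))  # within-region travel is free
    return best[0]
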