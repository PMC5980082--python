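"""Independent test oracles: random additive trees and exhaustive
unrooted-topology enumeration.  Nothing here touches the package's own
tree code beyond plain data structures."""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def _dfs_side(edges, start, blocked_edge):
    """Leaves reachable from ``start`` without crossing ``blocked_edge``."""
    adj = {}
    for (u, v) in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen = {start}
    queue = deque([start])
    bu, bv = blocked_edge
    while queue:
        node = queue.popleft()
        for nb in adj.get(node, ()):
            if {node, nb} == {bu, bv}:
                continue
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return seen


def edges_to_bipartitions(edges, leaves):
    """Nontrivial bipartitions (as frozenset-of-two-frozensets) of an
    unrooted tree given as an undirected edge list."""
    leaves = frozenset(leaves)
    out = set()
    for (u, v) in edges:
        side = frozenset(x for x in _dfs_side(edges, u, (u, v)) if x in leaves)
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset({side, leaves - side}))
    return out


def all_unrooted_topologies(labels):
    """Every unrooted binary topology on ``labels`` (3 for n=4, 15 for n=5),
    each returned as (edge list, bipartition set)."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    counter = itertools.count()
    center = f"__i{next(counter)}"
    trees = [[(labels[0], center), (labels[1], center), (labels[2], center)]]
    for leaf in labels[3:]:
        nxt = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                mid = f"__i{next(counter)}"
                new_edges = edges[:k] + edges[k + 1:]
                new_edges += [(u, mid), (mid, v), (leaf, mid)]
                nxt.append(new_edges)
        trees = nxt
    return [(e, edges_to_bipartitions(e, labels)) for e in trees]


def four_point_consistent(D, labels, bipartitions):
    """Whether every bipartition satisfies the four-point condition on the
    additive matrix ``D`` (cross sums equal and >= within sums)."""
    idx = {lb: i for i, lb in enumerate(labels)}
    for bp in bipartitions:
        side_a, side_b = tuple(bp)
        for i, j in itertools.combinations(sorted(side_a), 2):
            for k, l in itertools.combinations(sorted(side_b), 2):
                within = D[idx[i], idx[j]] + D[idx[k], idx[l]]
                c1 = D[idx[i], idx[k]] + D[idx[j], idx[l]]
                c2 = D[idx[i], idx[l]] + D[idx[j], idx[k]]
                if not np.isclose(c1, c2):
                    return False
                if within > c1 + 1e-9:
                    return False
    return True


def topology_by_enumeration(D, labels):
    """Exhaustive oracle (n = 4 or 5): the unique topology whose every
    bipartition passes the four-point condition."""
    winners = [
        bps for _, bps in all_unrooted_topologies(labels)
        if four_point_consistent(D, labels, bps)
    ]
    assert len(winners) == 1, f"expected unique topology, got {len(winners)}"
    return winners[0]


def random_additive_tree(n, rng, min_len=0.1, max_len=1.0):
    """A random unrooted binary tree on n leaves with positive branch
    lengths; returns (labels, distance matrix, bipartition set)."""
    labels = [f"t{i}" for i in range(n)]
    counter = itertools.count()
    center = f"__i{next(counter)}"
    edges = {
        (labels[0], center): rng.uniform(min_len, max_len),
        (labels[1], center): rng.uniform(min_len, max_len),
        (labels[2], center): rng.uniform(min_len, max_len),
    }
    for leaf in labels[3:]:
        pick = list(edges)[int(rng.integers(len(edges)))]
        (u, v) = pick
        old = edges.pop(pick)
        mid = f"__i{next(counter)}"
        split = rng.uniform(0.25, 0.75)
        edges[(u, mid)] = old * split
        edges[(mid, v)] = old * (1 - split)
        edges[(leaf, mid)] = rng.uniform(min_len, max_len)

    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        queue = deque([src])
        while queue:
            node = queue.popleft()
            for nb, w in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    queue.append(nb)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    bps = edges_to_bipartitions(list(edges), labels)
    return labels, D, bps
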