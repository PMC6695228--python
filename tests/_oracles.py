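"""Independent brute-force oracles used to check the package's traversals.

Everything here works from a plain edge list with breadth-first searches
and explicit set arithmetic — no networkx, no shared code with the package
— so agreement between the two routes is meaningful.
"""

from __future__ import annotations

from collections import deque


def scoped_parent_adjacency(edges, scoping=("is_a", "part_of", "has_part"),
                            reinterpret_has_part=True):
    """node -> set of broader neighbours, from raw (s, rel, o) triples."""
    adj: dict[str, set[str]] = {}
    for s, rel, o in edges:
        if rel not in scoping:
            continue
        if rel == "has_part":
            if reinterpret_has_part:
                adj.setdefault(o, set()).add(s)   # part -> whole
            else:
                adj.setdefault(s, set()).add(o)   # stored direction
        else:
            adj.setdefault(s, set()).add(o)
    return adj


def bfs_reachable(adj, start):
    """All nodes reachable from start (start excluded); cycles tolerated."""
    seen: set[str] = set()
    queue = deque(adj.get(start, ()))
    while queue:
        node = queue.popleft()
        if node in seen:
            continue
        seen.add(node)
        queue.extend(adj.get(node, ()))
    seen.discard(start)
    return seen


def closure(edges, nodes, scoping=("is_a", "part_of", "has_part"),
            reinterpret_has_part=True):
    """node -> ancestor set for every node, by per-node BFS."""
    adj = scoped_parent_adjacency(edges, scoping, reinterpret_has_part)
    return {n: bfs_reachable(adj, n) for n in nodes}


def all_pairs(anc):
    """Ordered (descendant, ancestor) pairs from a closure, no self-pairs."""
    return {(d, a) for d, ancs in anc.items() for a in ancs if a != d}


def naive_pairs(edges, nodes):
    """Pairs from following every stored edge direction, label-blind."""
    adj: dict[str, set[str]] = {}
    for s, _, o in edges:
        adj.setdefault(s, set()).add(o)
    return {(d, a) for d in nodes for a in bfs_reachable(adj, d) if a != d}


def edge_problem_sets_oracle(edges, nodes, whole, part):
    """PA/PD for one has_part edge, from full forward+reverse closures."""
    anc = closure(edges, nodes)
    radj: dict[str, set[str]] = {}
    for n, parents in scoped_parent_adjacency(edges).items():
        for p in parents:
            radj.setdefault(p, set()).add(n)
    desc = {n: bfs_reachable(radj, n) for n in nodes}
    pa = (anc[part] | {part}) - (anc[whole] | {whole})
    pd_ = (desc[whole] | {whole}) - (desc[part] | {part})
    return pa, pd_


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up adjustment, written from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


def binom_tail_exact(k, n):
    """P(X >= k) for X ~ Binomial(n, 1/2) via exact integer combinatorics."""
    from math import comb

    return sum(comb(n, j) for j in range(k, n + 1)) / 2 ** n
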