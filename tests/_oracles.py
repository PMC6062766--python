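"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, closed forms)
and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# Cysteine architecture: exhaustive 6-subset search
# ---------------------------------------------------------------------------


def brute_force_core(mature: str, ranges, midpoints):
    """Best C1-C6 assignment by filtering all 6-subsets of cysteine positions.

    Scoring mirrors the documented rule (total deviation of non-fixed gaps
    from range midpoints, ties to the lexicographically smallest tuple) but
    is computed by plain enumeration.
    """
    cys = [i for i, aa in enumerate(mature) if aa == "C"]
    best = None
    for combo in itertools.combinations(cys, 6):
        gaps = [combo[i + 1] - combo[i] - 1 for i in range(5)]
        if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, ranges)):
            score = sum(
                abs(g - mid)
                for g, (lo, hi), mid in zip(gaps, ranges, midpoints)
                if lo != hi
            )
            key = (score, combo)
            if best is None or key < best:
                best = key
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Unrooted-topology enumeration and least-squares fitting
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All (2n-5)!! unrooted binary topologies on leaves 0..n-1 as edge lists.

    Internal nodes are numbered from n upward; built by inserting each new
    leaf into every edge of every smaller topology.
    """
    if n < 3:
        raise ValueError("need >= 3 leaves")
    tops: list[tuple[list[tuple[int, int]], int]] = [
        ([(0, n), (1, n), (2, n)], n + 1)
    ]
    for leaf in range(3, n):
        grown = []
        for edges, next_id in tops:
            for i, (a, b) in enumerate(edges):
                new_edges = (
                    edges[:i]
                    + edges[i + 1:]
                    + [(a, next_id), (b, next_id), (leaf, next_id)]
                )
                grown.append((new_edges, next_id + 1))
        tops = grown
    return [edges for edges, _ in tops]


def _leaf_paths(edges: list[tuple[int, int]], n: int) -> dict:
    """Map each leaf pair (i, j), i<j, to the set of edge indices on its path."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))
    paths = {}
    for i in range(n):
        # BFS from leaf i recording the edge path to every node
        seen = {i: ()}
        queue = [i]
        while queue:
            u = queue.pop()
            for v, idx in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + (idx,)
                    queue.append(v)
        for j in range(i + 1, n):
            paths[(i, j)] = seen[j]
    return paths


def topology_splits(edges: list[tuple[int, int]], n: int) -> frozenset:
    """Non-trivial leaf bipartitions of a topology, sides not containing leaf 0."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def leaves_beyond(a: int, b: int) -> frozenset:
        # leaves reachable from b without crossing edge (a, b)
        seen = {a, b}
        stack = [b]
        out = set()
        while stack:
            u = stack.pop()
            if u < n:
                out.add(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(out)

    splits = set()
    for a, b in edges:
        if a >= n and b >= n:  # internal edge
            side = leaves_beyond(a, b)
            if 2 <= len(side) <= n - 2:
                splits.add(side if 0 not in side else frozenset(range(n)) - side)
    return frozenset(splits)


def ls_best_topology(D: np.ndarray) -> tuple[frozenset, float]:
    """Exhaustive least-squares topology search over all unrooted topologies.

    Returns the split set of the topology minimising the unconstrained
    least-squares residual of branch lengths against the pairwise distances,
    together with that residual.
    """
    n = D.shape[0]
    d = np.array([D[i, j] for i, j in itertools.combinations(range(n), 2)])
    best = None
    for edges in enumerate_unrooted_topologies(n):
        paths = _leaf_paths(edges, n)
        A = np.zeros((len(d), len(edges)))
        for row, (i, j) in enumerate(itertools.combinations(range(n), 2)):
            for e in paths[(i, j)]:
                A[row, e] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(np.sum((A @ x - d) ** 2))
        key = (resid, topology_splits(edges, n))
        if best is None or key[0] < best[0]:
            best = key
    return best[1], best[0]


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, frozenset]:
    """Additive distance matrix from a random tree, plus its true split set.

    Topology is drawn by random leaf insertion; branch lengths are uniform
    on [0.1, 2.0] so no internal edge is degenerate.
    """
    edges = [(0, n), (1, n), (2, n)]
    next_id = n + 1
    for leaf in range(3, n):
        i = int(rng.integers(len(edges)))
        a, b = edges.pop(i)
        edges += [(a, next_id), (b, next_id), (leaf, next_id)]
        next_id += 1
    lengths = rng.uniform(0.1, 2.0, size=len(edges))
    paths = _leaf_paths(edges, n)
    D = np.zeros((n, n))
    for (i, j), path in paths.items():
        D[i, j] = D[j, i] = lengths[list(path)].sum()
    return D, topology_splits(edges, n)


# ---------------------------------------------------------------------------
# Mann-Whitney: full enumeration over arrangements
# ---------------------------------------------------------------------------


def enumerate_mw_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) group assignments.

    Tie-free data only.  The p-value is the null probability of a U at least
    as far from n*m/2 as the observed one.
    """
    pooled = np.sort(np.concatenate([x, y]))
    n, m = len(x), len(y)
    order = {v: r for r, v in enumerate(pooled)}  # 0-based ranks, tie-free

    def u_of(values) -> float:
        r = sum(order[v] + 1 for v in values)
        return r - n * (n + 1) / 2

    u_obs = u_of(x)
    center = n * m / 2
    dev = abs(u_obs - center)
    hits = 0
    total = 0
    for combo in itertools.combinations(pooled, n):
        total += 1
        if abs(u_of(combo) - center) >= dev - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Compact letter display: maximal-clique oracle
# ---------------------------------------------------------------------------


def clique_letter_columns(groups, significant_pairs) -> list[frozenset]:
    """All maximal cliques of the non-significance graph (valid letter columns)."""
    groups = list(groups)
    nonsig = {
        frozenset(p)
        for p in itertools.combinations(groups, 2)
        if frozenset(p) not in significant_pairs
    }

    def is_clique(sub) -> bool:
        return all(
            frozenset((a, b)) in nonsig for a, b in itertools.combinations(sub, 2)
        )

    cliques = []
    for r in range(len(groups), 0, -1):
        for sub in itertools.combinations(groups, r):
            s = frozenset(sub)
            if is_clique(sub) and not any(s < c for c in cliques):
                cliques.append(s)
    return cliques
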