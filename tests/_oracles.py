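"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: shortest paths by
exhaustive simple-path enumeration, search information by explicit
transition-probability products along the enumerated path, Mann-Whitney and
Spearman p-values by full enumeration of rank assignments.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def enumerate_simple_paths(weights: np.ndarray, source: int, target: int):
    """All simple paths source -> target with their total 1/w length."""
    n = weights.shape[0]
    out = []

    def dfs(node, visited, length, path):
        if node == target:
            out.append((length, tuple(path)))
            return
        for nxt in range(n):
            if weights[node, nxt] > 0 and nxt not in visited:
                dfs(
                    nxt,
                    visited | {nxt},
                    length + 1.0 / weights[node, nxt],
                    path + [nxt],
                )

    dfs(source, {source}, 0.0, [source])
    return out


def brute_shortest_path(weights: np.ndarray, source: int, target: int):
    """(min length, lexicographically smallest optimal path) or (inf, None)."""
    if source == target:
        return 0.0, (source,)
    paths = enumerate_simple_paths(weights, source, target)
    if not paths:
        return np.inf, None
    best = min(length for length, _ in paths)
    tol = 1e-12 * max(1.0, abs(best))
    optimal = sorted(p for length, p in paths if length <= best + tol)
    return best, optimal[0]


def brute_search_information(weights: np.ndarray, path, memory: bool) -> float:
    """-log2 of the walker's probability of following ``path`` exactly."""
    strength = weights.sum(axis=1)
    prob = 1.0
    for step, (u, v) in enumerate(zip(path[:-1], path[1:])):
        denom = strength[u]
        if memory and step > 0:
            denom -= weights[u, path[step - 1]]
        prob *= weights[u, v] / denom
    return -np.log2(prob)


def brute_mannwhitney_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    ranks = np.argsort(np.argsort(pooled)) + 1.0

    def u_stat(idx):
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2

    mean_u = a.size * b.size / 2
    obs = abs(u_stat(range(n_a)) - mean_u)
    count = total = 0
    for idx in combinations(range(n), n_a):
        count += abs(u_stat(idx) - mean_u) >= obs - 1e-12
        total += 1
    return count / total


def brute_spearman(x, y) -> tuple[float, float]:
    """Spearman rho (mid-ranks computed inline) + exact two-sided p."""

    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    count = total = 0
    for perm in permutations(range(len(rx))):
        count += abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= abs(rho) - 1e-12
        total += 1
    return float(rho), count / total


def random_connected_graph(rng: np.random.Generator, n: int,
                           density: float = 0.5) -> np.ndarray:
    """Random connected weighted graph: spanning tree + extra edges."""
    w = np.zeros((n, n))
    order = rng.permutation(n)
    for i in range(1, n):
        a, b = order[i], order[rng.integers(0, i)]
        w[a, b] = w[b, a] = rng.uniform(0.2, 3.0)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] == 0 and rng.uniform() < density:
                w[i, j] = w[j, i] = rng.uniform(0.2, 3.0)
    return w
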