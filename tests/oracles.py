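"""Independent reference implementations used only by the test suite.

These deliberately use different algorithms from the package (Floyd-Warshall
with path counting instead of Brandes; power iteration instead of a dense
eigendecomposition; the classical factorial Shapley formula instead of
per-coalition accumulation) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

TIE_TOL = 1e-12


def betweenness_oracle(adj: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Weighted betweenness via Floyd-Warshall shortest-path counting.

    Edge distance is 1/weight; disconnected pairs contribute nothing.
    """
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    count = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(count, 1.0)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j] > 0:
                dist[i, j] = 1.0 / adj[i, j]
                count[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            if i == k or not np.isfinite(dist[i, k]):
                continue
            for j in range(n):
                if j == i or j == k:
                    continue
                via = dist[i, k] + dist[k, j]
                if not np.isfinite(via):
                    continue
                if via < dist[i, j] - TIE_TOL:
                    dist[i, j] = via
                    count[i, j] = count[i, k] * count[k, j]
                elif abs(via - dist[i, j]) <= TIE_TOL:
                    count[i, j] += count[i, k] * count[k, j]
    bc = np.zeros(n)
    for v in range(n):
        total = 0.0
        for s in range(n):
            if s == v:
                continue
            for t in range(s + 1, n):
                if t == v or not np.isfinite(dist[s, t]) or count[s, t] == 0:
                    continue
                through = dist[s, v] + dist[v, t]
                if np.isfinite(through) and abs(through - dist[s, t]) <= TIE_TOL:
                    total += count[s, v] * count[v, t] / count[s, t]
        bc[v] = total
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def eigenvector_oracle(adj: np.ndarray, iterations: int = 20000,
                       tol: float = 1e-14) -> np.ndarray:
    """Dominant eigenvector by power iteration (unit Euclidean norm)."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    v = np.ones(n) / np.sqrt(n)
    # shift guarantees the dominant eigenvalue of (A + cI) is positive and
    # power iteration converges to the Perron vector
    shift = adj.sum(axis=1).max() + 1.0
    m = adj + shift * np.eye(n)
    for _ in range(iterations):
        w = m @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def shapley_oracle(value_fn, d: int) -> np.ndarray:
    """Classical Shapley formula: per-feature sum over 2^(d-1) subsets.

    ``value_fn(mask)`` maps a boolean inclusion mask of length d to v(S).
    """
    values = {}
    for bits in itertools.product([False, True], repeat=d):
        values[bits] = float(value_fn(np.array(bits)))
    phi = np.zeros(d)
    others = list(range(d))
    for i in range(d):
        rest = [j for j in others if j != i]
        for size in range(d):
            weight = (
                math.factorial(size) * math.factorial(d - size - 1)
                / math.factorial(d)
            )
            for subset in itertools.combinations(rest, size):
                mask = [False] * d
                for j in subset:
                    mask[j] = True
                without = tuple(mask)
                mask[i] = True
                with_i = tuple(mask)
                phi[i] += weight * (values[with_i] - values[without])
    return phi


def auc_oracle(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """One-vs-rest AUC as the Mann-Whitney U statistic (ties count 1/2)."""
    pos = np.asarray(scores)[np.asarray(is_positive, dtype=bool)]
    neg = np.asarray(scores)[~np.asarray(is_positive, dtype=bool)]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_connected_network(rng: np.random.Generator, n: int,
                             density: float = 0.6,
                             threshold: float = 0.3) -> np.ndarray:
    """Random symmetric weighted adjacency, connected by construction.

    A random spanning tree guarantees connectivity; extra edges appear with
    the given density.  Weights are uniform on [threshold, 1].
    """
    adj = np.zeros((n, n))
    order = rng.permutation(n)
    for k in range(1, n):
        a, b = order[k], order[rng.integers(0, k)]
        adj[a, b] = adj[b, a] = rng.uniform(threshold, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] == 0 and rng.random() < density:
                adj[i, j] = adj[j, i] = rng.uniform(threshold, 1.0)
    return adj
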