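"""Independent oracles used by the test suite.

These implementations deliberately share no code with the package: dense
sphere-grid search for the centroid objective, direct combinatorial
summation for the hypergeometric tail, Counter-based plug-in MI, and
exhaustive shortest-path enumeration for betweenness.
"""
from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


# --- centroid objective, brute force -------------------------------------

def sphere_grid(p: int, m: int) -> np.ndarray:
    """A dense set of unit vectors in R^p (p <= 3)."""
    if p == 1:
        return np.array([[1.0], [-1.0]])
    if p == 2:
        ang = np.linspace(0, 2 * np.pi, m, endpoint=False)
        return np.column_stack([np.cos(ang), np.sin(ang)])
    if p == 3:
        i = np.arange(m)
        phi = np.arccos(1 - 2 * (i + 0.5) / m)
        theta = np.pi * (1 + 5 ** 0.5) * i
        return np.column_stack([np.sin(phi) * np.cos(theta),
                                np.sin(phi) * np.sin(theta),
                                np.cos(phi)])
    raise ValueError("grid oracle supports p <= 3 only")


def brute_force_centroid_optimum(Xs, m2: int = 720, m3: int = 1500) -> float:
    """max over unit loadings of sum_{j<k} |cov(X_j a_j, X_k a_k)|.

    Three blocks, fully connected design, no l1 constraint.  Two blocks are
    searched on dense sphere grids; the third (largest) block is maximised
    in closed form: max_a |a.u| + |a.w| over the unit sphere equals
    max(||u+w||, ||u-w||).  The grid optimum is a lower bound on the true
    optimum, which is what the acceptance check needs.
    """
    Xs = [np.asarray(X, float) for X in Xs]
    Xs = [X - X.mean(axis=0) for X in Xs]
    n = Xs[0].shape[0]
    order = sorted(range(3), key=lambda j: -Xs[j].shape[1])
    j0, j1, j2 = order
    M01 = Xs[j0].T @ Xs[j1] / (n - 1)
    M02 = Xs[j0].T @ Xs[j2] / (n - 1)
    M12 = Xs[j1].T @ Xs[j2] / (n - 1)

    def grid(p):
        return sphere_grid(p, m2 if p == 2 else m3)

    G1 = grid(Xs[j1].shape[1])
    G2 = grid(Xs[j2].shape[1])
    U = G1 @ M01.T            # (m1, p0)
    W = G2 @ M02.T            # (m2, p0)
    cross = np.abs(G1 @ M12 @ G2.T)
    nu = (U ** 2).sum(axis=1)[:, None]
    nw = (W ** 2).sum(axis=1)[None, :]
    dot = U @ W.T
    plus = np.sqrt(np.maximum(nu + nw + 2 * dot, 0.0))
    minus = np.sqrt(np.maximum(nu + nw - 2 * dot, 0.0))
    return float((np.maximum(plus, minus) + cross).max())


# --- hypergeometric upper tail by direct summation ------------------------

def hypergeom_upper_tail(k: int, N: int, K: int, m: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, m), by direct combinatorial sum."""
    total = math.comb(N, m)
    acc = 0
    for i in range(max(k, 0, K + m - N), min(K, m) + 1):
        acc += math.comb(K, i) * math.comb(N - K, m - i)
    return acc / total


# --- plug-in mutual information from a joint table ------------------------

def mi_from_pairs(cx, cy) -> float:
    """Plug-in MI (nats) computed with Counters, no numpy table code shared."""
    n = len(cx)
    joint = Counter(zip(cx, cy))
    px = Counter(cx)
    py = Counter(cy)
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log(pab / ((px[a] / n) * (py[b] / n)))
    return max(0.0, total)


# --- betweenness by exhaustive shortest-path enumeration ------------------

def exhaustive_betweenness(nodes, edges) -> dict:
    """Normalised betweenness via explicit enumeration of all shortest paths."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        if s == t:
            return []
        paths, best = [], None
        frontier = [[s]]
        while frontier and best is None or (frontier and len(frontier[0]) <= best):
            nxt = []
            for path in frontier:
                for w in adj[path[-1]]:
                    if w in path:
                        continue
                    np_ = path + [w]
                    if w == t:
                        if best is None:
                            best = len(np_)
                        if len(np_) == best:
                            paths.append(np_)
                    else:
                        nxt.append(np_)
            frontier = [p for p in nxt if best is None or len(p) + 1 <= best]
        return paths

    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1
    return {v: s / norm for v, s in score.items()}
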