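"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (triple loops,
deque-based BFS, per-pair Pearson) and share no code with the package, so
they can arbitrate the vectorised implementations.
"""

from collections import deque

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def noise_image_40pct_zero():
    """Seeded 30x30x30 image with ~40% of voxels zeroed."""
    r = np.random.default_rng(424242)
    img = r.random((30, 30, 30)) + 0.05
    img[r.random((30, 30, 30)) < 0.4] = 0.0
    return img


@pytest.fixture(scope="session")
def twenty_cubes():
    """Twenty seeded random cubes as raw 27-vectors."""
    r = np.random.default_rng(777)
    return [r.random(27) for _ in range(20)]


# --------------------------------------------------------------------------
# graph oracles


def brute_degrees(adj):
    n = len(adj)
    return [sum(int(adj[i][j]) for j in range(n)) for i in range(n)]


def brute_clustering_per_node(adj):
    """Triangle counting by explicit neighbour-pair enumeration."""
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a]][nbrs[b]]:
                    links += 1
        out.append(2.0 * links / (k * (k - 1)))
    return out


def brute_shortest_paths_from(adj, source):
    n = len(adj)
    dist = [None] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u][v] and dist[v] is None:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_characteristic_path_length(adj):
    n = len(adj)
    total, count = 0, 0
    for s in range(n):
        dist = brute_shortest_paths_from(adj, s)
        for t in range(n):
            if t != s and dist[t] is not None:
                total += dist[t]
                count += 1
    return total / count if count else float("nan")


def brute_nodal_path_lengths(adj):
    n = len(adj)
    out = []
    for s in range(n):
        dist = brute_shortest_paths_from(adj, s)
        finite = [dist[t] for t in range(n) if t != s and dist[t] is not None]
        out.append(sum(finite) / len(finite) if finite else float("nan"))
    return out


def pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
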