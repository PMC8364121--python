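"""Global and regional graph-theory measures with small-world normalisation.

Measures follow the standard binary undirected conventions: degree, density,
Watts-Strogatz clustering coefficient C (nodes with fewer than two
neighbours contribute 0), and characteristic path length L as the mean
shortest-path distance over all ordered node pairs with a finite path
(disconnected pairs are excluded, keeping L defined for near-connected
networks).  C and L are normalised against degree-preserving randomised
reference networks (double-edge-swap null model), giving gamma = C/C_rand,
lambda = L/L_rand and the small-world coefficient sigma = gamma/lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GlobalNetworkMetrics",
    "node_degrees",
    "clustering_coefficients",
    "mean_clustering",
    "nodal_path_lengths",
    "characteristic_path_length",
    "degree_preserving_randomize",
    "normalized_small_world",
    "compute_global_metrics",
    "compute_regional_metrics",
]

GLOBAL_MEASURES = (
    "size",
    "degree",
    "density",
    "clustering",
    "path_length",
    "gamma",
    "lambda_",
    "sigma",
)


@dataclass
class GlobalNetworkMetrics:
    """Whole-network summary for one subject.

    ``degree`` is the mean node degree (the total edge count is reported
    separately as ``n_edges``); ``sigma == gamma / lambda_`` exactly.
    """

    size: int
    n_edges: int
    degree: float
    density: float
    clustering: float
    path_length: float
    gamma: float
    lambda_: float
    sigma: float
    n_reference: int
    reference_seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_adjacency(adj) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    if np.any(np.diagonal(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    return a.astype(np.int64)


def node_degrees(adj) -> np.ndarray:
    """Number of edges incident to each node."""
    return _validate_adjacency(adj).sum(axis=1)


def clustering_coefficients(adj) -> np.ndarray:
    """Per-node Watts-Strogatz clustering coefficient.

    Triangle counts come from the exact integer matrix product, so results
    match brute-force triple enumeration exactly.
    """
    a = _validate_adjacency(adj)
    k = a.sum(axis=1)
    triangles = np.diagonal(a @ a @ a) // 2
    pairs = k * (k - 1) // 2
    c = np.zeros(len(a), dtype=float)
    has = pairs > 0
    c[has] = triangles[has] / pairs[has]
    return c


def mean_clustering(adj) -> float:
    """Mean clustering coefficient C over all nodes."""
    return float(clustering_coefficients(adj).mean())


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def nodal_path_lengths(adj) -> np.ndarray:
    """Mean finite shortest-path distance from each node to all others.

    Nodes with no finite path to any other node get NaN.
    """
    a = _validate_adjacency(adj)
    d = _distance_matrix(a)
    np.fill_diagonal(d, np.inf)
    finite = np.isfinite(d)
    out = np.full(len(a), np.nan)
    counts = finite.sum(axis=1)
    rows = counts > 0
    out[rows] = np.where(finite, d, 0.0).sum(axis=1)[rows] / counts[rows]
    return out


def characteristic_path_length(adj) -> float:
    """Mean shortest-path length over ordered node pairs with a finite path.

    Returns NaN (with a warning) for a graph with no edges, where L is
    undefined.
    """
    a = _validate_adjacency(adj)
    if a.sum() == 0:
        warnings.warn("graph has no edges; path length is undefined", RuntimeWarning)
        return float("nan")
    d = _distance_matrix(a)
    np.fill_diagonal(d, np.inf)
    finite = np.isfinite(d)
    return float(d[finite].mean())


def degree_preserving_randomize(
    adj, n_swap_per_edge: int = 10, seed: int | None = None
) -> np.ndarray:
    """Randomise a graph by double-edge swaps, preserving every node degree.

    Each attempt picks two distinct edges (a, b), (c, d) and a random
    orientation and rewires them to (a, d), (c, b), rejecting swaps that
    would create a self-loop or a multi-edge.  ``n_swap_per_edge`` attempts
    are made per edge.  Graphs with no legal swap (e.g. complete graphs)
    are returned unchanged.  Deterministic given ``seed``.
    """
    a = _validate_adjacency(adj)
    iu, ju = np.nonzero(np.triu(a, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    n_edges = len(edges)
    if n_edges < 2:
        return a.copy()
    edge_set = {e for e in edges}
    rng = np.random.default_rng(seed)
    n_attempts = n_swap_per_edge * n_edges
    picks = rng.integers(0, n_edges, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a1, b1 = edges[e1]
        c1, d1 = edges[e2]
        if flip:
            c1, d1 = d1, c1
        # proposed new edges (a1, d1) and (c1, b1)
        if a1 == d1 or c1 == b1:
            continue
        new1 = (a1, d1) if a1 < d1 else (d1, a1)
        new2 = (c1, b1) if c1 < b1 else (b1, c1)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
    out = np.zeros_like(a)
    for u, v in edge_set:
        out[u, v] = 1
        out[v, u] = 1
    return out


def normalized_small_world(
    adj, n_reference: int = 5, seed: int | None = None, n_swap_per_edge: int = 10
) -> tuple[float, float, float]:
    """Normalise C and L against degree-preserving random references.

    gamma = C / mean(C over references), lambda = L / mean(L over
    references), sigma = gamma / lambda.  Reference seeds are derived from
    the master seed; an undefined L propagates as NaN.
    """
    if n_reference < 1:
        raise ValueError("n_reference must be at least 1")
    a = _validate_adjacency(adj)
    c = mean_clustering(a)
    length = characteristic_path_length(a)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reference) % (2**31)
    c_refs, l_refs = [], []
    for s in child_seeds:
        ref = degree_preserving_randomize(a, n_swap_per_edge=n_swap_per_edge, seed=int(s))
        c_refs.append(mean_clustering(ref))
        l_refs.append(characteristic_path_length(ref))
    with np.errstate(invalid="ignore", divide="ignore"):
        # zero reference clustering (very sparse graphs) propagates as NaN/inf
        gamma = c / np.mean(c_refs)
        lambda_ = length / np.mean(l_refs)
        sigma = gamma / lambda_
    return float(gamma), float(lambda_), float(sigma)


def compute_global_metrics(
    adj, n_reference: int = 5, seed: int | None = None
) -> GlobalNetworkMetrics:
    """Aggregate all global measures for one subject's network."""
    a = _validate_adjacency(adj)
    n = len(a)
    degrees = a.sum(axis=1)
    n_edges = int(degrees.sum()) // 2
    density = 2.0 * n_edges / (n * (n - 1)) if n > 1 else 0.0
    gamma, lambda_, sigma = normalized_small_world(a, n_reference=n_reference, seed=seed)
    return GlobalNetworkMetrics(
        size=n,
        n_edges=n_edges,
        degree=float(degrees.mean()),
        density=float(density),
        clustering=mean_clustering(a),
        path_length=characteristic_path_length(a),
        gamma=gamma,
        lambda_=lambda_,
        sigma=sigma,
        n_reference=n_reference,
        reference_seed=seed,
    )


def compute_regional_metrics(
    adj,
    node_labels: Sequence[int],
    node_volumes: Sequence[float],
    regions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Average nodal measures over the nodes of each atlas region.

    Returns one row per region with node_count and the unweighted means of
    degree, clustering, nodal path length and grey-matter volume.  Regions
    with no nodes carry NaN (missing, not zero).  Unlabelled nodes
    (label <= 0) are excluded; labelled node counts partition the labelled
    node set.
    """
    a = _validate_adjacency(adj)
    labels = np.asarray(node_labels)
    volumes = np.asarray(node_volumes, dtype=float)
    if len(labels) != len(a) or len(volumes) != len(a):
        raise ValueError("node_labels and node_volumes must align with the adjacency")
    nodal = pd.DataFrame(
        {
            "label": labels,
            "degree": node_degrees(a).astype(float),
            "clustering": clustering_coefficients(a),
            "path_length": nodal_path_lengths(a),
            "gm_volume": volumes,
        }
    )
    nodal = nodal[nodal["label"] > 0]
    grouped = nodal.groupby("label").agg(
        node_count=("degree", "size"),
        degree=("degree", "mean"),
        clustering=("clustering", "mean"),
        path_length=("path_length", "mean"),
        gm_volume=("gm_volume", "mean"),
    )
    if regions is None:
        regions = sorted(grouped.index.tolist())
    out = grouped.reindex(list(regions))
    out["node_count"] = out["node_count"].fillna(0).astype(int)
    out.index.name = "region"
    return out


def regional_metrics_from_mapping(
    regional: pd.DataFrame, region_names: Mapping[int, str] | None = None
) -> pd.DataFrame:
    """Attach region names to a regional metrics table."""
    out = regional.copy()
    if region_names is not None:
        out.insert(0, "region_name", [region_names.get(r, str(r)) for r in out.index])
    return out
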