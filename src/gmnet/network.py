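"""Single-subject grey-matter similarity networks.

A subject's grey-matter image is tiled into non-overlapping 3x3x3-voxel
cubes (6x6x6 mm^3 at 2 mm resolution).  Each cube containing grey matter
becomes a network node carrying its 27 raw intensities, its atlas label and
its grey-matter volume.  The connectivity between two nodes is the maximum
Pearson correlation of their intensity vectors over the discrete rotation
set (see :mod:`gmnet.rotations`), so that similar cortical folds are matched
regardless of local orientation.  The similarity matrix is binarised at a
subject-specific threshold calibrated by permutation so that the expected
proportion of spurious (chance) connections is held at ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .rotations import rotation_permutation_set

__all__ = [
    "Cube",
    "ThresholdResult",
    "partition_into_cubes",
    "max_rotated_correlation",
    "build_similarity_matrix",
    "estimate_binarization_threshold",
    "binarize",
    "CubeSimilarityNetwork",
]


@dataclass(frozen=True)
class Cube:
    """One network node: a 3x3x3 voxel block of the grey-matter image.

    ``origin`` is the 0-based voxel coordinate of the block's lowest corner
    (all components multiples of 3); ``values`` holds the 27 intensities in
    C raster order; ``label`` is the majority atlas region among the block's
    nonzero grey-matter voxels (0 when unlabelled); ``gm_volume`` is the sum
    of grey-matter intensity over the block.
    """

    index: int
    origin: tuple[int, int, int]
    values: np.ndarray
    label: int
    gm_volume: float


@dataclass
class ThresholdResult:
    """Permutation-calibrated binarisation threshold and its provenance.

    ``threshold`` is the (1 - alpha/M) empirical quantile of the null
    distribution of rotation-maximised correlations between
    within-cube-permuted cube pairs, where M is the number of distinct node
    pairs (a per-edge level corrected for multiple comparisons).  The null
    dialect -- independent permutation of the 27 intensities within each
    cube, destroying spatial pattern while preserving the intensity
    distribution -- is recorded here for provenance.
    """

    threshold: float
    alpha: float
    n_permutations: int
    n_pairs: int
    seed: int | None
    null_quantiles: dict[float, float]
    null_sample: np.ndarray = field(repr=False)
    null_model: str = "within-cube intensity permutation"


def _block_view(volume: np.ndarray) -> np.ndarray:
    """Reshape a 3-divisible volume into (n_blocks, 27) raster-ordered rows."""
    nx, ny, nz = (s // 3 for s in volume.shape)
    return (
        volume.reshape(nx, 3, ny, 3, nz, 3)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(nx * ny * nz, 27)
    )


def _pad_to_multiple_of_3(volume: np.ndarray) -> np.ndarray:
    pad = [(0, (-s) % 3) for s in volume.shape]
    if any(p[1] for p in pad):
        return np.pad(volume, pad, mode="constant")
    return volume


def partition_into_cubes(
    gm_image: np.ndarray,
    atlas_labels: np.ndarray | None = None,
    min_gm_fraction: float = 0.0,
) -> list[Cube]:
    """Tile the image into 3x3x3 cubes and keep those containing grey matter.

    A cube becomes a node iff it has at least one voxel with positive
    intensity and the fraction of its 27 voxels with positive intensity is
    at least ``min_gm_fraction``.  The cube label is the majority atlas
    label among its nonzero grey-matter voxels (background label 0 ignored),
    ties broken towards the smallest region id.  Cubes are returned in
    raster order of their grid position.
    """
    gm_image = np.asarray(gm_image)
    if gm_image.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {gm_image.shape}")
    if atlas_labels is not None:
        atlas_labels = np.asarray(atlas_labels)
        if atlas_labels.shape != gm_image.shape:
            raise ValueError(
                f"image shape {gm_image.shape} does not match "
                f"label shape {atlas_labels.shape}"
            )
    if not 0.0 <= min_gm_fraction <= 1.0:
        raise ValueError("min_gm_fraction must lie in [0, 1]")

    gm_image = _pad_to_multiple_of_3(gm_image)
    if atlas_labels is not None:
        atlas_labels = _pad_to_multiple_of_3(atlas_labels)

    blocks = _block_view(gm_image)
    label_blocks = _block_view(atlas_labels) if atlas_labels is not None else None

    nx, ny, nz = (s // 3 for s in gm_image.shape)
    grid = list(np.ndindex(nx, ny, nz))

    cubes: list[Cube] = []
    nonzero = blocks > 0
    fractions = nonzero.mean(axis=1)
    for b, (bi, bj, bk) in enumerate(grid):
        frac = fractions[b]
        if frac == 0.0 or frac < min_gm_fraction:
            continue
        label = 0
        if label_blocks is not None:
            labs = label_blocks[b][nonzero[b]]
            labs = labs[labs > 0]
            if labs.size:
                ids, counts = np.unique(labs, return_counts=True)
                label = int(ids[np.argmax(counts)])  # unique() sorts: ties -> smallest id
        cubes.append(
            Cube(
                index=len(cubes),
                origin=(3 * bi, 3 * bj, 3 * bk),
                values=blocks[b].astype(float),
                label=label,
                gm_volume=float(blocks[b].sum()),
            )
        )
    return cubes


def _cube_values(cube) -> np.ndarray:
    values = cube.values if isinstance(cube, Cube) else np.asarray(cube, dtype=float)
    if values.shape != (27,):
        raise ValueError(f"cube values must have length 27, got shape {values.shape}")
    return np.asarray(values, dtype=float)


def _unit_rows(values: np.ndarray) -> np.ndarray:
    """Centre rows and scale to unit norm; zero-variance rows become zero."""
    z = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, z / norms, 0.0)
    return z


def max_rotated_correlation(cube_a, cube_b, rotations: np.ndarray | None = None) -> float:
    """Maximum Pearson correlation of ``cube_b`` rotated against ``cube_a``.

    Returns 0.0 by convention when either cube has zero intensity variance
    (Pearson undefined), which guarantees exclusion at any positive
    threshold.  The result lies in [-1, 1].
    """
    if rotations is None:
        rotations = rotation_permutation_set()
    a = _cube_values(cube_a)
    b = _cube_values(cube_b)
    za = _unit_rows(a[None, :])[0]
    zb = _unit_rows(b[None, :])[0]
    if not za.any() or not zb.any():
        return 0.0
    dots = zb[rotations] @ za
    return float(np.clip(dots.max(), -1.0, 1.0))


def build_similarity_matrix(
    cubes: Sequence, rotations: np.ndarray | None = None
) -> np.ndarray:
    """All pairwise rotation-maximised correlations, self-connections zero.

    Symmetry is exact: because the rotation set is closed under inverse,
    entry (i, j) and entry (j, i) maximise the same set of correlations, and
    the elementwise maximum of the computed matrix with its transpose is
    taken to remove floating-point order effects.
    """
    if len(cubes) < 2:
        raise ValueError("at least 2 cubes are required to build a similarity matrix")
    if rotations is None:
        rotations = rotation_permutation_set()
    values = np.stack([_cube_values(c) for c in cubes])
    z = _unit_rows(values)
    sim = z @ z.T
    for perm in rotations:
        np.maximum(sim, z @ z[:, perm].T, out=sim)
    sim = np.maximum(sim, sim.T)
    np.clip(sim, -1.0, 1.0, out=sim)
    np.fill_diagonal(sim, 0.0)
    return sim


def _empirical_quantile(sample: np.ndarray, q: float) -> float:
    """Smallest order statistic at or above fraction ``q`` of the sample."""
    s = np.sort(sample)
    k = min(len(s) - 1, max(0, math.ceil(q * len(s)) - 1))
    return float(s[k])


def estimate_binarization_threshold(
    cubes: Sequence,
    rotations: np.ndarray | None = None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> ThresholdResult:
    """Calibrate the correlation threshold so spurious edges are held at alpha.

    The null distribution is built by repeatedly drawing a pair of distinct
    cubes, independently permuting the 27 intensities within each cube, and
    recording the rotation-maximised correlation.  The threshold is the
    (1 - alpha/M) empirical quantile of this null, M = n(n-1)/2 distinct
    node pairs, i.e. a per-edge level corrected for multiple comparisons.
    Deterministic given ``seed``.
    """
    n = len(cubes)
    if n < 2:
        raise ValueError("at least 2 cubes are required to calibrate a threshold")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    if rotations is None:
        rotations = rotation_permutation_set()

    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_permutations)
    j = (i + rng.integers(1, n, size=n_permutations)) % n  # distinct partner

    values = np.stack([_cube_values(c) for c in cubes])
    a = rng.permuted(values[i], axis=1)
    b = rng.permuted(values[j], axis=1)
    za = _unit_rows(a)
    zb = _unit_rows(b)

    null = np.einsum("ij,ij->i", za, zb)
    for perm in rotations:
        np.maximum(null, np.einsum("ij,ij->i", za, zb[:, perm]), out=null)
    np.clip(null, -1.0, 1.0, out=null)

    n_pairs = n * (n - 1) // 2
    q = 1.0 - alpha / n_pairs
    threshold = _empirical_quantile(null, q)
    if threshold <= 0.0:
        raise RuntimeError(
            "calibrated threshold is not positive; the null sample is degenerate"
        )
    quantiles = {p: _empirical_quantile(null, p) for p in (0.5, 0.9, 0.95, 0.99, 1.0)}
    return ThresholdResult(
        threshold=threshold,
        alpha=alpha,
        n_permutations=n_permutations,
        n_pairs=n_pairs,
        seed=seed,
        null_quantiles=quantiles,
        null_sample=null,
    )


def binarize(similarity: np.ndarray, threshold: float) -> np.ndarray:
    """Edges are pairs whose correlation strictly exceeds the threshold.

    The threshold must be positive, so only positive correlations can
    contribute edges.  Ties at the threshold are excluded.
    """
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    similarity = np.asarray(similarity)
    adj = (similarity > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


class CubeSimilarityNetwork(BaseEstimator):
    """Extract a single-subject grey-matter network from a 3D image.

    Parameters
    ----------
    min_gm_fraction : float, default 0.0
        Minimum fraction of a cube's 27 voxels with positive intensity for
        the cube to become a node (a cube always needs at least one).
    alpha : float, default 0.05
        Nominal risk of spurious connections after binarisation.
    n_permutations : int, default 1000
        Null-sample size for threshold calibration.
    random_state : int or None
        Seed for the permutation null.

    Attributes (after :meth:`fit`)
    ------------------------------
    cubes_ : list of Cube
    similarity_ : (n, n) ndarray of rotation-maximised correlations
    threshold_result_ : ThresholdResult
    threshold_ : float
    adjacency_ : (n, n) binary ndarray
    n_nodes_ : int
    """

    def __init__(
        self,
        min_gm_fraction: float = 0.0,
        alpha: float = 0.05,
        n_permutations: int = 1000,
        random_state: int | None = None,
    ):
        self.min_gm_fraction = min_gm_fraction
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, gm_image: np.ndarray, atlas_labels: np.ndarray | None = None):
        rotations = rotation_permutation_set()
        self.cubes_ = partition_into_cubes(
            gm_image, atlas_labels, min_gm_fraction=self.min_gm_fraction
        )
        if len(self.cubes_) < 2:
            raise ValueError(
                f"only {len(self.cubes_)} grey-matter cubes found; "
                "cannot build a network"
            )
        self.similarity_ = build_similarity_matrix(self.cubes_, rotations)
        self.threshold_result_ = estimate_binarization_threshold(
            self.cubes_,
            rotations,
            alpha=self.alpha,
            n_permutations=self.n_permutations,
            seed=self.random_state,
        )
        self.threshold_ = self.threshold_result_.threshold
        self.adjacency_ = binarize(self.similarity_, self.threshold_)
        self.n_nodes_ = len(self.cubes_)
        return self

    def fit_transform(
        self, gm_image: np.ndarray, atlas_labels: np.ndarray | None = None
    ) -> np.ndarray:
        """Fit and return the binary adjacency matrix."""
        return self.fit(gm_image, atlas_labels).adjacency_
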