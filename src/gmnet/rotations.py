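"""Discrete rotations of a 3x3x3 voxel cube.

The similarity between two cube nodes is the maximum Pearson correlation
over rotated versions of one cube, with rotation angles restricted to
multiples of 45 degrees about each grid axis.  On the discrete 3x3x3 grid a
45-degree rotation is realised by moving each voxel value to the grid point
nearest to its rotated centre; for multiples of 45 degrees this map is a
bijection (the ring of eight outer cells in each in-plane layer advances one
step), so every realised rotation is a permutation of the 27 raster-ordered
voxel slots.

The set exported by :func:`rotation_permutation_set` is the deduplicated
collection of all axis-rotation compositions ``Rx^i . Ry^j . Rz^k``
(i, j, k in 0..7), closed under inverse and under conjugation by the 24
exact right-angle rotations.  Inverse closure makes the rotation-maximised
correlation symmetric in its two arguments; conjugation closure makes the
extracted network invariant (up to node relabelling) under right-angle
rotation of the whole image.  The closure has exactly 432 members, a frozen
regression constant of this package.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

#: Number of permutations in the canonical rotation set (regression constant).
ROTATION_SET_SIZE = 432

# Voxel-centre offsets of a 3x3x3 block in C raster order: slot (i, j, k) of
# ``block.ravel(order="C")`` sits at offset (i-1, j-1, k-1).
_OFFSETS = np.array(list(product((-1.0, 0.0, 1.0), repeat=3)))


def _rotation_matrix(axis: int, k: int) -> np.ndarray:
    theta = k * np.pi / 4.0
    c, s = np.cos(theta), np.sin(theta)
    if axis == 0:
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == 1:
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _axis_permutation(axis: int, k: int) -> np.ndarray:
    """Nearest-grid-point realisation of a k*45 degree rotation about an axis.

    Returned in gather convention: ``rotated = values[perm]``.
    """
    rot = _rotation_matrix(axis, k)
    # Slot i of the rotated cube takes the value whose centre the inverse
    # rotation sends closest to slot i.
    back = _OFFSETS @ rot  # rot.T.T == rot; inverse rotation of each centre
    d2 = ((back[:, None, :] - _OFFSETS[None, :, :]) ** 2).sum(axis=2)
    perm = d2.argmin(axis=1)
    if len(set(perm.tolist())) != 27:  # pragma: no cover - structural guarantee
        raise RuntimeError(f"45-degree realisation is not a bijection (axis={axis}, k={k})")
    return perm


def _invert(perm: np.ndarray) -> np.ndarray:
    return np.argsort(perm)


@lru_cache(maxsize=1)
def _rotation_set_cached() -> np.ndarray:
    axis_perms = {(ax, k): _axis_permutation(ax, k) for ax in range(3) for k in range(8)}

    # All compositions Rx^i . Ry^j . Rz^k (apply x, then y, then z).
    composed: set[tuple[int, ...]] = set()
    for i, j, k in product(range(8), repeat=3):
        p = axis_perms[(0, i)][axis_perms[(1, j)]][axis_perms[(2, k)]]
        composed.add(tuple(p.tolist()))

    # Close under inverse.
    closed = set(composed)
    for t in composed:
        closed.add(tuple(_invert(np.array(t)).tolist()))

    # The 24 exact right-angle rotations (all multiples of 90 degrees).
    exact: set[tuple[int, ...]] = set()
    for i, j, k in product(range(4), repeat=3):
        p = axis_perms[(0, 2 * i % 8)][axis_perms[(1, 2 * j % 8)]][axis_perms[(2, 2 * k % 8)]]
        exact.add(tuple(p.tolist()))

    # Close under conjugation by the exact rotations (fixed point iteration).
    changed = True
    while changed:
        changed = False
        new: set[tuple[int, ...]] = set()
        for q in exact:
            qa = np.array(q)
            qi = _invert(qa)
            for t in closed:
                conj = tuple(qa[np.array(t)[qi]].tolist())
                if conj not in closed:
                    new.add(conj)
        if new:
            closed |= new
            changed = True

    out = np.array(sorted(closed), dtype=np.intp)
    if len(out) != ROTATION_SET_SIZE:  # pragma: no cover - frozen constant
        raise RuntimeError(f"rotation set size changed: {len(out)} != {ROTATION_SET_SIZE}")
    return out


def rotation_permutation_set() -> np.ndarray:
    """Return the canonical rotation permutations as an ``(R, 27)`` int array.

    The set contains the identity, is duplicate-free, closed under inverse,
    and closed under conjugation by exact 90-degree rotations.  The result is
    cached; callers must not mutate it.
    """
    return _rotation_set_cached()
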