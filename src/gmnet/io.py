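"""NIfTI, Matrix Market and TSV input/output plus isotropic resampling.

Coordinates are 0-based voxel indices throughout the package; world
coordinates appear only in NIfTI affines at the I/O boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from scipy.ndimage import map_coordinates

from .network import Cube, ThresholdResult

__all__ = [
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "write_adjacency",
    "read_adjacency",
    "write_node_table",
    "read_node_table",
    "write_threshold_result",
]


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Load a NIfTI volume: (data, voxel size in mm, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:
        raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"{path} is not a 3D volume (shape {data.shape})")
    return data, zooms, img.affine


def write_volume(path, data: np.ndarray, voxel_size_mm=2.0, affine=None) -> None:
    """Write a 3D array as NIfTI-1 with an isotropic (or given) affine."""
    data = np.asarray(data)
    if affine is None:
        if np.isscalar(voxel_size_mm):
            voxel_size_mm = (voxel_size_mm,) * 3
        affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def resample_isotropic(
    volume: np.ndarray,
    current_mm: float | Sequence[float],
    target_mm: float,
    method: str = "trilinear",
) -> np.ndarray:
    """Resample a volume to an isotropic grid of ``target_mm`` spacing.

    Voxel centres are aligned: output index ``i`` samples input coordinate
    ``(i + 0.5) * target / current - 0.5``.  ``method`` is "trilinear" for
    intensity images and "nearest" for label volumes; requesting trilinear
    interpolation of an integer label volume is an error.
    """
    volume = np.asarray(volume)
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    if method == "trilinear" and np.issubdtype(volume.dtype, np.integer):
        raise ValueError(
            "trilinear interpolation of an integer label volume is not allowed; "
            "use method='nearest'"
        )
    if np.isscalar(current_mm):
        current = (float(current_mm),) * 3
    else:
        current = tuple(float(c) for c in current_mm)
    if all(abs(c - target_mm) < 1e-12 for c in current):
        return volume.copy()
    out_shape = tuple(
        max(1, int(round(s * c / target_mm))) for s, c in zip(volume.shape, current)
    )
    grids = [
        (np.arange(n) + 0.5) * target_mm / c - 0.5 for n, c in zip(out_shape, current)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    order = 1 if method == "trilinear" else 0
    return map_coordinates(
        volume.astype(float), np.stack(coords), order=order, mode="nearest"
    ).astype(volume.dtype if method == "nearest" else float)


def write_adjacency(path, adjacency: np.ndarray) -> None:
    """Write a binary adjacency matrix in Matrix Market sparse format."""
    mmwrite(str(path), sparse.coo_matrix(np.asarray(adjacency)), field="integer")


def read_adjacency(path) -> np.ndarray:
    return np.asarray(mmread(str(path)).todense()).astype(np.int8)


def write_node_table(path, cubes: Sequence[Cube], header: str | None = None) -> None:
    """Node table TSV: node id, grid origin, atlas label, grey-matter volume."""
    df = pd.DataFrame(
        {
            "node": [c.index for c in cubes],
            "origin_x": [c.origin[0] for c in cubes],
            "origin_y": [c.origin[1] for c in cubes],
            "origin_z": [c.origin[2] for c in cubes],
            "label": [c.label for c in cubes],
            "gm_volume": [c.gm_volume for c in cubes],
        }
    )
    write_tsv(path, df, header)


def read_node_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_threshold_result(path, result: ThresholdResult) -> None:
    payload = {
        "threshold": result.threshold,
        "alpha": result.alpha,
        "n_permutations": result.n_permutations,
        "n_pairs": result.n_pairs,
        "seed": result.seed,
        "null_model": result.null_model,
        "null_quantiles": {str(k): v for k, v in result.null_quantiles.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_tsv(path, df: pd.DataFrame, header: str | None = None, index=False) -> None:
    """TSV writer supporting '#'-prefixed header comment lines."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
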