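"""Braak-stage composite ROIs for tau-PET SUVR.

Neurofibrillary tau pathology spreads in a stereotyped anatomical sequence
(Braak staging): stage I-II in the hippocampal formation, stage III-IV in
limbic/temporal cortex (fusiform, amygdala, cingulate, inferior and middle
temporal), stage V-VI in widespread neocortex.  Composite SUVR values over
these region groups, and a temporal meta-ROI covering stages I-IV, are the
volume-weighted averages of the member-region SUVRs, with weights taken
from the subject's own parcel volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "RoiDefinition",
    "composite_suvr",
    "default_braak_definitions",
    "load_roi_definitions",
    "region_volumes_from_labels",
    "BRAAK_STAGES",
]

BRAAK_STAGES = ("braak_1_2", "braak_3_4", "braak_5_6", "temporal_meta")


@dataclass(frozen=True)
class RoiDefinition:
    """A named composite ROI: a non-empty set of member atlas region ids."""

    name: str
    stage: str  # "I-II", "III-IV", "V-VI" or "meta"
    member_ids: tuple[int, ...]

    def __post_init__(self):
        if not self.member_ids:
            raise ValueError(f"ROI {self.name!r} has no member regions")


def composite_suvr(
    region_suvr: Mapping[int, float],
    region_volume: Mapping[int, float],
    roi: RoiDefinition,
) -> float:
    """Volume-weighted average SUVR over the ROI's member regions.

    Every member region must be present with positive volume; a missing
    region raises an error naming it.
    """
    num = 0.0
    den = 0.0
    for rid in roi.member_ids:
        if rid not in region_suvr:
            raise KeyError(f"region {rid} missing from region_suvr for ROI {roi.name!r}")
        if rid not in region_volume:
            raise KeyError(f"region {rid} missing from region_volume for ROI {roi.name!r}")
        vol = float(region_volume[rid])
        if vol <= 0:
            raise ValueError(f"region {rid} has non-positive volume in ROI {roi.name!r}")
        num += float(region_suvr[rid]) * vol
        den += vol
    return num / den


def _definitions_from_members(
    stage12: Sequence[int], stage34: Sequence[int], stage56: Sequence[int]
) -> list[RoiDefinition]:
    meta = tuple(stage12) + tuple(stage34)
    return [
        RoiDefinition("braak_1_2", "I-II", tuple(stage12)),
        RoiDefinition("braak_3_4", "III-IV", tuple(stage34)),
        RoiDefinition("braak_5_6", "V-VI", tuple(stage56)),
        RoiDefinition("temporal_meta", "meta", meta),
    ]


def default_braak_definitions(
    region_table: Mapping[str, int] | Sequence[int],
) -> list[RoiDefinition]:
    """Toy Braak staging for the synthetic atlas.

    Region ids (sorted) are split 20% / 30% / 50% into stages I-II, III-IV
    and V-VI, mimicking the relative extents of the hippocampal, limbic and
    neocortical stage groups; the temporal meta-ROI is the union of stages
    I-II and III-IV.  Accepts a name->id mapping or a plain id sequence.
    """
    if isinstance(region_table, Mapping):
        ids = sorted(int(v) for v in region_table.values())
    else:
        ids = sorted(int(v) for v in region_table)
    if len(ids) < 3:
        raise ValueError("need at least 3 regions for a Braak partition")
    n = len(ids)
    n12 = max(1, round(0.2 * n))
    n34 = max(1, round(0.3 * n))
    if n12 + n34 >= n:
        n12, n34 = 1, 1
    return _definitions_from_members(ids[:n12], ids[n12 : n12 + n34], ids[n12 + n34 :])


def load_roi_definitions(
    source, region_table: Mapping[str, int]
) -> list[RoiDefinition]:
    """Resolve named ROI definitions from a YAML config against a region table.

    The config maps stage keys (``braak_1_2``, ``braak_3_4``, ``braak_5_6``)
    to lists of region *names*; ids come from ``region_table``.  Unresolvable
    names raise an error listing them.  ``source`` may be a path or an
    already-parsed mapping.
    """
    if isinstance(source, Mapping):
        spec = dict(source)
    else:
        with open(source) as fh:
            spec = yaml.safe_load(fh)
    members: dict[str, list[int]] = {}
    for key in ("braak_1_2", "braak_3_4", "braak_5_6"):
        names = spec.get(key, [])
        missing = [n for n in names if n not in region_table]
        if missing:
            raise KeyError(
                f"ROI {key!r} names not found in region table: {', '.join(missing)}"
            )
        members[key] = [int(region_table[n]) for n in names]
    return _definitions_from_members(
        members["braak_1_2"], members["braak_3_4"], members["braak_5_6"]
    )


def bundled_braak_example() -> dict:
    """Parsed copy of the bundled synthetic Braak ROI example config."""
    with resources.files("gmnet.data").joinpath("braak_rois_synthetic.yaml").open() as fh:
        return yaml.safe_load(fh)


def region_volumes_from_labels(
    atlas_labels: np.ndarray, voxel_size_mm: float | Sequence[float]
) -> dict[int, float]:
    """Parcel volumes (voxel count x voxel volume) from a label image."""
    labels = np.asarray(atlas_labels)
    if np.isscalar(voxel_size_mm):
        voxvol = float(voxel_size_mm) ** 3
    else:
        voxvol = float(np.prod(voxel_size_mm))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return {int(i): float(c) * voxvol for i, c in zip(ids, counts)}
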