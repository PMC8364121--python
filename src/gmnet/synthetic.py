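"""Seeded synthetic cohorts for the grey-matter network pipeline.

The generator emulates the statistical structure the analysis assumes,
without any claim to realistic neuroanatomy:

* Each subject's grey-matter image is a tiling of 3x3x3-voxel blocks.  Every
  atlas region is assigned a 27-value texture *prototype* drawn once per
  cohort from a standard normal and shared across subjects, so blocks in
  regions sharing a prototype correlate strongly in intact images.
* Tau burden degrades the texture: each block is the mix
  ``(1 - m) * prototype + m * noise`` with mixing ``m = d / (1 + d)``
  (monotone, bounded by 1) driven by the subject's latent degradation
  ``d = base + slope * max(0, meta-ROI SUVR - control mean)``.  Higher tau
  therefore weakens within-region similarity and thins the extracted
  network.
* Per-region tau SUVR rises with disease stage (control, preclinical,
  prodromal, dementia), loading earlier Braak-stage regions more heavily.
* Cognition is generated with a direct tau effect plus an effect through
  the *analytic expectation* of network integrity (a decreasing function of
  degradation), so generation never runs the network extractor.

Two table-level simulators (:func:`simulate_association_table`,
:func:`simulate_mediation_table`) generate merged subject tables directly
for statistical calibration at sample sizes where image synthesis is
unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tau as tau_mod

__all__ = [
    "GROUPS",
    "CohortConfig",
    "SyntheticSubject",
    "generate_cohort",
    "generate_subject_image",
    "expected_integrity",
    "mixing_from_degradation",
    "simulate_association_table",
    "simulate_mediation_table",
    "write_cohort",
]

GROUPS = ("control", "preclinical", "prodromal", "dementia")


def _group_dict(control, preclinical, prodromal, dementia) -> dict[str, float]:
    return {
        "control": control,
        "preclinical": preclinical,
        "prodromal": prodromal,
        "dementia": dementia,
    }


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the toy scale the pipeline is exercised at: 30x30x30
    voxels at 2 mm (1000 cube nodes), 10 atlas regions sharing 6 texture
    prototypes, 25 subjects per diagnostic group, and meta-ROI SUVR means
    rising from 1.15 (amyloid-negative controls) to 2.4 (dementia), in the
    range typical of second-generation tau tracers.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: _group_dict(25, 25, 25, 25)
    )
    image_shape: tuple[int, int, int] = (30, 30, 30)
    voxel_size_mm: float = 2.0
    n_regions: int = 10
    n_prototypes: int = 6
    base_noise_sd: float = 1.0
    intensity_offset: float = 4.0
    base_degradation: float = 0.3
    degradation_slope: float = 0.2
    tau_group_means: dict[str, float] = field(
        default_factory=lambda: _group_dict(1.15, 1.35, 1.90, 2.40)
    )
    tau_sd: float = 0.20
    age_mean: dict[str, float] = field(
        default_factory=lambda: _group_dict(66.0, 72.0, 73.0, 72.0)
    )
    age_sd: dict[str, float] = field(
        default_factory=lambda: _group_dict(8.0, 7.0, 7.0, 8.0)
    )
    sex_female_prop: float = 0.5
    tiv_mean: float = 1450.0
    tiv_sd: float = 140.0
    cog_intercept: float = 29.0
    cog_direct: float = -2.5  # c'_sim: MMSE-like points per SUVR unit
    cog_mediator: float = 4.0  # b_sim: points per unit expected integrity
    cog_sd: float = 1.0
    memory_intercept: float = 9.0  # recall errors at zero tau/integrity
    memory_direct: float = 2.0
    memory_mediator: float = -3.0
    memory_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for g in GROUPS:
            if self.n_per_group.get(g, 0) < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")
        if any(s % 3 != 0 or s < 3 for s in self.image_shape):
            raise ValueError(
                f"image_shape {self.image_shape} must be divisible by 3 in each axis"
            )
        for name in ("base_noise_sd", "tau_sd", "tiv_sd", "cog_sd", "memory_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(self.age_sd[g] <= 0 for g in GROUPS):
            raise ValueError("age sds must be > 0")
        if self.n_regions < 1 or self.n_prototypes < 1:
            raise ValueError("n_regions and n_prototypes must be >= 1")
        if self.base_degradation < 0 or self.degradation_slope < 0:
            raise ValueError("degradation parameters must be >= 0")
        means = [self.tau_group_means[g] for g in GROUPS]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("tau_group_means must be non-decreasing across stages")

    # --- plain-text round trip -------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


@dataclass
class SyntheticSubject:
    """One simulated subject with its latent ground truth."""

    subject_id: str
    group: str
    gm_image: np.ndarray | None
    atlas_labels: np.ndarray | None
    region_suvr: dict[int, float]
    age: float
    sex: int  # 1 = female
    tiv: float
    cognition_global: float
    cognition_memory: float
    latent_degradation: float
    expected_integrity: float


def mixing_from_degradation(degradation: float) -> float:
    """Noise-mixing weight m = d / (1 + d): monotone, m(0) = 0, m < 1."""
    if degradation < 0:
        raise ValueError("degradation must be >= 0")
    return degradation / (1.0 + degradation)


def expected_integrity(degradation: float, noise_sd: float = 1.0) -> float:
    """Expected same-prototype cube correlation at a given degradation.

    For blocks ``(1 - m) p + m * noise`` sharing a unit-variance prototype
    ``p``, the population correlation is
    ``(1 - m)^2 / ((1 - m)^2 + m^2 sd^2)`` -- a smooth decreasing function
    of degradation used as the generative mediator for cognition.
    """
    m = mixing_from_degradation(degradation)
    s = (1.0 - m) ** 2
    return s / (s + (m * noise_sd) ** 2)


def _block_labels(shape: tuple[int, int, int], n_regions: int) -> np.ndarray:
    """Block-aligned atlas: contiguous slabs of the cube grid in raster order."""
    nb = tuple(s // 3 for s in shape)
    n_blocks = int(np.prod(nb))
    ranks = np.arange(n_blocks)
    block_region = 1 + (ranks * n_regions) // n_blocks
    labels = block_region.reshape(nb)
    return np.repeat(np.repeat(np.repeat(labels, 3, 0), 3, 1), 3, 2).astype(np.int16)


def generate_subject_image(
    shape: tuple[int, int, int],
    labels: np.ndarray,
    prototypes: dict[int, np.ndarray],
    degradation: float,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    intensity_offset: float = 4.0,
) -> np.ndarray:
    """Build one grey-matter image from region prototypes and degradation.

    Every 3x3x3 block is ``offset + (1 - m) * prototype(region) +
    m * N(0, noise_sd^2)`` with ``m = d / (1 + d)``, clipped to be
    non-negative.  Background blocks (label 0) stay zero.
    """
    if any(s % 3 != 0 for s in shape):
        raise ValueError(f"shape {shape} must be divisible by 3 in each axis")
    labels = np.asarray(labels)
    if labels.shape != tuple(shape):
        raise ValueError("labels shape must match image shape")
    m = mixing_from_degradation(degradation)  # validates degradation >= 0

    nb = tuple(s // 3 for s in shape)
    image = np.zeros(tuple(shape), dtype=float)
    for bi, bj, bk in np.ndindex(nb):
        sl = (
            slice(3 * bi, 3 * bi + 3),
            slice(3 * bj, 3 * bj + 3),
            slice(3 * bk, 3 * bk + 3),
        )
        block_labels = labels[sl]
        ids, counts = np.unique(block_labels[block_labels > 0], return_counts=True)
        if not ids.size:
            continue
        region = int(ids[np.argmax(counts)])
        proto = np.asarray(prototypes[region], dtype=float)
        noise = rng.normal(0.0, noise_sd, size=27)
        block = intensity_offset + (1.0 - m) * proto + m * noise
        image[sl] = block.reshape(3, 3, 3)
    np.clip(image, 0.0, None, out=image)
    return image


def _stage_loadings(n_regions: int) -> dict[int, float]:
    """Per-region tau loading: Braak I-IV regions 1.0, V-VI regions 0.8."""
    defs = tau_mod.default_braak_definitions(range(1, n_regions + 1))
    meta = next(d for d in defs if d.stage == "meta")
    loadings = {r: 0.8 for r in range(1, n_regions + 1)}
    for r in meta.member_ids:
        loadings[r] = 1.0
    return loadings


def generate_cohort(
    config: CohortConfig, include_images: bool = True
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate a full seeded cohort and its subject table.

    Deterministic given the config (all randomness flows from
    ``config.seed``).  With ``include_images=False`` the latent structure
    and table are identical in distribution but no images are synthesised.
    """
    rng = np.random.default_rng(config.seed)
    proto_library = rng.standard_normal((config.n_prototypes, 27))
    prototypes = {
        r: proto_library[(r - 1) % config.n_prototypes]
        for r in range(1, config.n_regions + 1)
    }
    labels = _block_labels(config.image_shape, config.n_regions)
    region_ids = list(range(1, config.n_regions + 1))
    loadings = _stage_loadings(config.n_regions)
    braak_defs = tau_mod.default_braak_definitions(region_ids)
    meta_def = next(d for d in braak_defs if d.name == "temporal_meta")
    region_volume = tau_mod.region_volumes_from_labels(labels, config.voxel_size_mm)
    control_mean = config.tau_group_means["control"]

    subjects: list[SyntheticSubject] = []
    rows: list[dict] = []
    sid = 0
    for group in GROUPS:
        for _ in range(config.n_per_group[group]):
            sid += 1
            tau_target = max(0.5, rng.normal(config.tau_group_means[group], config.tau_sd))
            region_suvr = {
                r: max(0.05, loadings[r] * tau_target + rng.normal(0.0, 0.05))
                for r in region_ids
            }
            meta_suvr = tau_mod.composite_suvr(region_suvr, region_volume, meta_def)
            degradation = config.base_degradation + config.degradation_slope * max(
                0.0, meta_suvr - control_mean
            )
            integrity = expected_integrity(degradation, config.base_noise_sd)

            image = None
            if include_images:
                image = generate_subject_image(
                    config.image_shape,
                    labels,
                    prototypes,
                    degradation,
                    rng,
                    noise_sd=config.base_noise_sd,
                    intensity_offset=config.intensity_offset,
                )

            age = rng.normal(config.age_mean[group], config.age_sd[group])
            sex = int(rng.random() < config.sex_female_prop)
            tiv = rng.normal(config.tiv_mean, config.tiv_sd)
            cog = (
                config.cog_intercept
                + config.cog_direct * meta_suvr
                + config.cog_mediator * integrity
                + rng.normal(0.0, config.cog_sd)
            )
            mem = (
                config.memory_intercept
                + config.memory_direct * meta_suvr
                + config.memory_mediator * integrity
                + rng.normal(0.0, config.memory_sd)
            )

            subject_id = f"sub-{sid:03d}"
            subjects.append(
                SyntheticSubject(
                    subject_id=subject_id,
                    group=group,
                    gm_image=image,
                    atlas_labels=labels if include_images else None,
                    region_suvr=region_suvr,
                    age=age,
                    sex=sex,
                    tiv=tiv,
                    cognition_global=cog,
                    cognition_memory=mem,
                    latent_degradation=degradation,
                    expected_integrity=integrity,
                )
            )
            row = {
                "subject_id": subject_id,
                "group": group,
                "age": age,
                "sex": sex,
                "tiv": tiv,
                "cognition_global": cog,
                "cognition_memory": mem,
                "latent_degradation": degradation,
                "expected_integrity": integrity,
            }
            for d in braak_defs:
                row[f"tau_{d.name}"] = tau_mod.composite_suvr(
                    region_suvr, region_volume, d
                )
            for r in region_ids:
                row[f"suvr_region_{r:02d}"] = region_suvr[r]
            rows.append(row)

    return subjects, pd.DataFrame(rows)


def simulate_association_table(
    n: int,
    effects: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Merged-table simulator for association calibration.

    Produces ``n`` subjects with standard-normal tau and covariates and the
    eight global network measures; each measure is
    ``effect * tau + N(0, 1)``, defaulting to pure noise (null cohort with
    tau independent of the network measures).
    """
    from .metrics import GLOBAL_MEASURES

    rng = np.random.default_rng(seed)
    effects = effects or {}
    tau = rng.standard_normal(n)
    table = pd.DataFrame(
        {
            "tau": tau,
            "age": rng.normal(70.0, 8.0, n),
            "sex": rng.integers(0, 2, n),
            "tiv": rng.normal(1450.0, 140.0, n),
        }
    )
    for measure in GLOBAL_MEASURES:
        table[measure] = effects.get(measure, 0.0) * tau + rng.standard_normal(n)
    return table


def simulate_mediation_table(
    n: int,
    a: float,
    b: float,
    c_prime: float,
    seed: int | None = None,
    mediator_sd: float = 1.0,
    outcome_sd: float = 1.0,
) -> pd.DataFrame:
    """Linear Gaussian mediation model with known paths.

    treatment ~ N(0,1); mediator = a*treatment + noise; outcome =
    c_prime*treatment + b*mediator + noise.  The analytic proportion
    mediated is a*b / (a*b + c_prime).
    """
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    m = a * t + rng.normal(0.0, mediator_sd, n)
    y = c_prime * t + b * m + rng.normal(0.0, outcome_sd, n)
    return pd.DataFrame({"treatment": t, "mediator": m, "outcome": y})


def write_cohort(subjects, table: pd.DataFrame, out_dir, config: CohortConfig) -> None:
    """Write a cohort to disk: NIfTI images/labels, subject TSV, config YAML."""
    from .io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "cohort_config.yaml")
    table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    for s in subjects:
        if s.gm_image is None:
            continue
        write_volume(out / f"{s.subject_id}_gm.nii", s.gm_image, config.voxel_size_mm)
        write_volume(
            out / f"{s.subject_id}_atlas.nii",
            s.atlas_labels.astype(np.int16),
            config.voxel_size_mm,
        )
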