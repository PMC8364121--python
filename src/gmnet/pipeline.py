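"""End-to-end orchestration: simulate -> networks -> metrics -> tau -> stats.

A :class:`PipelineConfig` fully determines a run; all randomness flows from
its seeds, so two runs with identical configs produce identical result
files.  Every output table carries the config hash and the stage seed in a
header comment, and subjects excluded along the way (too little grey
matter, empty networks) are recorded in ``exclusions.tsv``, never dropped
silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .metrics import compute_global_metrics, compute_regional_metrics
from .network import CubeSimilarityNetwork
from .stats import (
    filter_zscoreable_outcomes,
    mediation_analysis,
    run_association_suite,
    zscore_to_reference,
)
from .synthetic import CohortConfig, generate_cohort
from .tau import region_volumes_from_labels

logger = logging.getLogger("gmnet")

__all__ = ["PipelineConfig", "run_pipeline"]

HIGHER_ORDER = ("clustering", "path_length", "gamma", "lambda_", "sigma")
GLOBAL_OUTCOMES = ("size", "degree", "density") + HIGHER_ORDER


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    output_dir: str = "gmnet_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None  # read an existing cohort instead of simulating
    min_gm_fraction: float = 0.0
    alpha: float = 0.05
    n_permutations: int = 1000
    n_reference: int = 5
    network_seed: int = 100
    reference_seed: int = 200
    mediation_seed: int = 300
    n_boot: int = 1000
    regional: bool = True
    mediation: bool = True
    predictor: str = "tau_temporal_meta"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self._as_plain(), sort_keys=True))

    def _as_plain(self) -> dict:
        d = asdict(self)
        d["cohort"]["image_shape"] = list(self.cohort.image_shape)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        cohort = d.pop("cohort", {})
        if "image_shape" in cohort:
            cohort["image_shape"] = tuple(cohort["image_shape"])
        return cls(cohort=CohortConfig(**cohort), **d)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Path fields (output/input locations) are excluded so that the same
        analysis run into two directories is recognised as the same run.
        """
        plain = self._as_plain()
        plain.pop("output_dir", None)
        plain.pop("input_dir", None)
        canon = yaml.safe_dump(plain, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_cohort(input_dir: Path):
    """Read a previously written cohort directory (NIfTI + subjects.tsv)."""
    table = gio.read_tsv(input_dir / "subjects.tsv")
    images = {}
    for sid in table["subject_id"]:
        gm, zooms, _ = gio.read_volume(input_dir / f"{sid}_gm.nii")
        labels, _, _ = gio.read_volume(input_dir / f"{sid}_atlas.nii")
        images[sid] = (gm, labels.astype(int), zooms[0])
    return table, images


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the results directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"config_hash={chash}"
    config.to_yaml(out / "pipeline_config.yaml")

    # --- stage 1: cohort -------------------------------------------------
    if config.input_dir is not None:
        logger.info("loading cohort from %s", config.input_dir)
        table, images = _load_cohort(Path(config.input_dir))
        voxel_mm = config.cohort.voxel_size_mm
    else:
        logger.info("simulating cohort (seed=%d)", config.cohort.seed)
        subjects, table = generate_cohort(config.cohort)
        images = {
            s.subject_id: (s.gm_image, s.atlas_labels, config.cohort.voxel_size_mm)
            for s in subjects
        }
        voxel_mm = config.cohort.voxel_size_mm
    gio.write_tsv(out / "subjects.tsv", table, header=f"{header} seed={config.cohort.seed}")

    # --- stage 2+3: networks and metrics ---------------------------------
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    seed_seq = np.random.SeedSequence(config.network_seed)
    subject_seeds = seed_seq.generate_state(len(images)) % (2**31)
    ref_seeds = np.random.SeedSequence(config.reference_seed).generate_state(
        len(images)
    ) % (2**31)

    global_rows = []
    regional_rows = []
    exclusions = []
    region_vol_rows = {}
    for (sid, (gm, labels, _)), net_seed, ref_seed in zip(
        sorted(images.items()), subject_seeds, ref_seeds
    ):
        logger.info("subject %s: extracting network", sid)
        try:
            extractor = CubeSimilarityNetwork(
                min_gm_fraction=config.min_gm_fraction,
                alpha=config.alpha,
                n_permutations=config.n_permutations,
                random_state=int(net_seed),
            ).fit(gm, labels)
        except (ValueError, RuntimeError) as exc:
            logger.warning("subject %s excluded at network stage: %s", sid, exc)
            exclusions.append({"subject_id": sid, "stage": "network", "reason": str(exc)})
            continue
        if extractor.adjacency_.sum() == 0:
            logger.warning("subject %s excluded: empty network", sid)
            exclusions.append(
                {"subject_id": sid, "stage": "network", "reason": "no edges survive threshold"}
            )
            continue

        sdir = net_dir / sid
        sdir.mkdir(exist_ok=True)
        gio.write_adjacency(sdir / "adjacency.mtx", extractor.adjacency_)
        gio.write_node_table(
            sdir / "nodes.tsv", extractor.cubes_, header=f"{header} seed={net_seed}"
        )
        gio.write_threshold_result(sdir / "threshold.json", extractor.threshold_result_)

        gm_metrics = compute_global_metrics(
            extractor.adjacency_, n_reference=config.n_reference, seed=int(ref_seed)
        )
        global_rows.append({"subject_id": sid, **gm_metrics.to_dict()})
        if config.regional:
            node_labels = [c.label for c in extractor.cubes_]
            node_volumes = [c.gm_volume for c in extractor.cubes_]
            reg = compute_regional_metrics(
                extractor.adjacency_, node_labels, node_volumes
            ).reset_index()
            reg.insert(0, "subject_id", sid)
            regional_rows.append(reg)
        region_vol_rows[sid] = region_volumes_from_labels(labels, voxel_mm)

    if not global_rows:
        raise RuntimeError("pipeline failed: every subject was excluded at the network stage")
    global_df = pd.DataFrame(global_rows)
    gio.write_tsv(
        out / "metrics_global.tsv", global_df, header=f"{header} seed={config.network_seed}"
    )
    if config.regional and regional_rows:
        regional_df = pd.concat(regional_rows, ignore_index=True)
        gio.write_tsv(
            out / "metrics_regional.tsv",
            regional_df,
            header=f"{header} seed={config.network_seed}",
        )
    gio.write_tsv(out / "exclusions.tsv", pd.DataFrame(exclusions, columns=["subject_id", "stage", "reason"]), header=header)

    # --- stage 4: merge --------------------------------------------------
    merged = table.merge(global_df, on="subject_id", how="inner")
    gio.write_tsv(out / "merged_table.tsv", merged, header=header)

    # --- stage 5: associations -------------------------------------------
    control_mask = (merged["group"] == "control").to_numpy()
    reference_mask = control_mask if control_mask.sum() >= 2 else None

    def policy(outcome: str):
        base = ["age", "sex", "tiv"]
        return base + ["density"] if outcome in HIGHER_ORDER else base

    # outcomes with no variance in the reference group (e.g. every subject's
    # network keeping all nodes) cannot be z-scored; drop them with a warning
    outcomes, degenerate = filter_zscoreable_outcomes(
        merged, GLOBAL_OUTCOMES, reference_mask
    )
    for outcome in degenerate:
        logger.warning("outcome %s skipped: degenerate in reference group", outcome)

    results = run_association_suite(
        merged,
        outcomes=outcomes,
        predictor=config.predictor,
        covariate_policy=policy,
        adjust_method="fdr_bh",
        reference_mask=reference_mask,
    )
    assoc_df = pd.DataFrame([r.to_dict() for r in results])
    gio.write_tsv(out / "associations_global.tsv", assoc_df, header=header)

    regional_assoc_df = None
    if config.regional and regional_rows:
        regional_assoc_df = _regional_associations(
            merged, regional_df, config.predictor, header
        )
        if regional_assoc_df is not None:
            gio.write_tsv(out / "associations_regional.tsv", regional_assoc_df, header=header)

    # --- stage 6: mediation ----------------------------------------------
    mediation_payload = None
    if config.mediation:
        med_table = merged.copy()
        if reference_mask is not None:
            med_table["sigma_z"] = zscore_to_reference(
                med_table["sigma"].to_numpy(float), reference_mask
            )
        else:
            med_table["sigma_z"] = med_table["sigma"]
        mediation_payload = {}
        for outcome in ("cognition_global", "cognition_memory"):
            res = mediation_analysis(
                med_table,
                treatment=config.predictor,
                mediator="sigma_z",
                outcome=outcome,
                covariates=("age", "sex", "tiv"),
                n_boot=config.n_boot,
                seed=config.mediation_seed,
            )
            mediation_payload[outcome] = {
                "a": res.a,
                "b": res.b,
                "c": res.c,
                "c_prime": res.c_prime,
                "acme": res.acme,
                "prop_mediated": res.prop_mediated,
                "prop_flagged": res.prop_flagged,
                "ci": {k: list(v) for k, v in res.ci.items()},
                "n": res.n,
                "n_boot": res.n_boot,
                "seed": res.seed,
            }
        (out / "mediation.json").write_text(
            json.dumps({"config_hash": chash, **mediation_payload}, indent=2, sort_keys=True)
        )

    # --- manifest ---------------------------------------------------------
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config_hash": chash,
        "seeds": {
            "cohort": config.cohort.seed,
            "network": config.network_seed,
            "reference": config.reference_seed,
            "mediation": config.mediation_seed,
        },
        "n_subjects": int(len(table)),
        "n_analysed": int(len(global_df)),
        "n_excluded": int(len(exclusions)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline finished: %s", out)
    return out


def _regional_associations(
    merged: pd.DataFrame, regional_df: pd.DataFrame, predictor: str, header: str
) -> pd.DataFrame | None:
    """Per-region models, Bonferroni-corrected across regions per measure.

    Regional models are adjusted for age, sex, TIV and local grey-matter
    volume; clustering and path length additionally for local degree.
    """
    from .stats import adjust_pvalues, fit_linear_association

    rows = []
    for measure in ("degree", "clustering", "path_length"):
        per_region = []
        for region, sub in regional_df.groupby("region"):
            wide = pd.DataFrame(
                {
                    "subject_id": sub["subject_id"],
                    "regional_outcome": sub[measure],
                    "regional_degree": sub["degree"],
                    "regional_volume": sub["gm_volume"],
                }
            )
            data = merged.merge(wide, on="subject_id")
            covs = ["age", "sex", "tiv", "regional_volume"]
            if measure in ("clustering", "path_length"):
                covs.append("regional_degree")
            try:
                res = fit_linear_association(
                    data, "regional_outcome", predictor, covariates=covs
                )
            except ValueError:
                continue  # too few subjects or degenerate design for this region
            row = res.to_dict()
            row["outcome"] = measure
            row["region"] = region
            per_region.append(row)
        if per_region:
            adj = adjust_pvalues([r["p"] for r in per_region], method="bonferroni")
            for r, pa in zip(per_region, adj):
                r["p_adjusted"] = float(pa)
                r["adjust_method"] = "bonferroni"
            rows.extend(per_region)
    return pd.DataFrame(rows) if rows else None
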