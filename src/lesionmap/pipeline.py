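"""End-to-end orchestration: harmonize -> VLSM -> MLSM -> ROI -> cohort stats.

Every run writes a JSON report (validated against the shipped schema), a
per-subject flag table, NIfTI maps, an orthogonal-slice PNG of the ROI, and
a log with stage timings. Reports are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import io as io_mod
from .harmonization import harmonize_table
from .mask import LesionMask
from .multivariate import MlsmResult, MlsmSpec, run_mlsm
from .schema import validate
from .synthetic import SimConfig, generate_cohort
from .univariate import (
    Cluster,
    DesignSpec,
    clusters_from_mask,
    permutation_correct,
    voxelwise_glm,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate_to_disk"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    masks_dir: str
    behavior_csv: str
    out_dir: str
    design: DesignSpec = field(default_factory=DesignSpec)
    mlsm: MlsmSpec = field(default_factory=MlsmSpec)
    sim: SimConfig | None = None
    subset_column: str | None = None
    subset_value: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "masks_dir": self.masks_dir,
            "behavior_csv": self.behavior_csv,
            "out_dir": self.out_dir,
            "design": dataclasses.asdict(self.design),
            "mlsm": dataclasses.asdict(self.mlsm),
            "sim": None if self.sim is None else self.sim.to_dict(),
            "subset_column": self.subset_column,
            "subset_value": self.subset_value,
            "seed": self.seed,
        }
        d["design"]["covariates"] = list(self.design.covariates)
        d["mlsm"]["covariates"] = list(self.mlsm.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        design = dict(d.get("design", {}))
        if "covariates" in design:
            design["covariates"] = tuple(design["covariates"])
        mlsm = dict(d.get("mlsm", {}))
        if "covariates" in mlsm:
            mlsm["covariates"] = tuple(mlsm["covariates"])
        sim = d.get("sim")
        return cls(
            masks_dir=d["masks_dir"],
            behavior_csv=d["behavior_csv"],
            out_dir=d["out_dir"],
            design=DesignSpec(**design),
            mlsm=MlsmSpec(**mlsm),
            sim=None if sim is None else SimConfig.from_dict(sim),
            subset_column=d.get("subset_column"),
            subset_value=d.get("subset_value"),
            seed=d.get("seed", 0),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def simulate_to_disk(config: SimConfig, masks_dir: str | Path, behavior_csv: str | Path) -> None:
    """Generate a cohort and write masks, behavior CSV, ground truth, sidecar."""
    masks_dir = Path(masks_dir)
    masks_dir.mkdir(parents=True, exist_ok=True)
    masks, behavior, truth = generate_cohort(config)
    for sid, mask in zip(behavior["subject_id"], masks):
        io_mod.write_mask(mask, masks_dir / f"{sid}.nii.gz")
    io_mod.write_mask(truth.critical_mask, masks_dir / "ground_truth_critical.nii.gz")
    if truth.aos_mask is not None:
        io_mod.write_mask(truth.aos_mask, masks_dir / "ground_truth_aos.nii.gz")
    io_mod.write_behavior(behavior, behavior_csv)
    sidecar = Path(str(behavior_csv) + ".json")
    sidecar.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))


def _cluster_dict(c: Cluster) -> dict:
    return {
        "n_voxels": int(c.n_voxels),
        "volume_cm3": float(c.volume_cm3),
        "center_of_mass_mm": [float(v) for v in c.center_of_mass_mm],
        "peak_stat": float(c.peak_stat) if np.isfinite(c.peak_stat) else 0.0,
    }


def _effect_dict(e: cohort_mod.EffectEstimate) -> dict:
    return {
        "measure": e.measure,
        "point": float(e.point),
        "ci_low": float(e.ci_low),
        "ci_high": float(e.ci_high),
        "level": float(e.level),
    }


def _plot_roi(roi: LesionMask, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = roi.data
    if roi.n_voxels:
        centers = np.argwhere(data).mean(axis=0).astype(int)
    else:
        centers = np.array(data.shape) // 2
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, axis, idx in zip(axes, range(3), centers):
        ax.imshow(np.take(data, idx, axis=axis).T, origin="lower", cmap="gray")
        ax.set_title(f"axis {axis} slice {idx}")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)


def _stage(name: str, timings: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage name per contract
        raise PipelineError(name, str(exc)) from exc
    timings[name] = time.perf_counter() - t0
    log.info("stage %s finished in %.2fs", name, timings[name])
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain and return (and write) the report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("lesionmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}

    try:
        if config.sim is not None and not Path(config.behavior_csv).exists():
            _stage(
                "simulate",
                timings,
                simulate_to_disk,
                config.sim,
                config.masks_dir,
                config.behavior_csv,
            )

        behavior = _stage("load_behavior", timings, io_mod.read_behavior, config.behavior_csv)

        if config.subset_column is not None:
            keep = behavior[config.subset_column].astype(str) == str(config.subset_value)
            behavior = behavior.loc[keep].reset_index(drop=True)
            log.info("subset %s=%s keeps %d subjects", config.subset_column, config.subset_value, len(behavior))

        def _load_masks():
            masks_dir = Path(config.masks_dir)
            masks, ref = [], None
            for sid in behavior["subject_id"]:
                p = masks_dir / f"{sid}.nii.gz"
                if not p.exists():
                    p = masks_dir / f"{sid}.nii"
                m = io_mod.read_mask(p, reference=ref)
                ref = ref or m
                masks.append(m)
            return masks

        masks = _stage("load_masks", timings, _load_masks)

        if len(behavior) < config.design.min_lesioned + 2:
            raise PipelineError(
                "validate",
                f"cohort of {len(behavior)} subjects is below min_lesioned + 2",
            )

        harmonized = _stage("harmonize", timings, harmonize_table, behavior)

        statmap = _stage("vlsm_glm", timings, voxelwise_glm, masks, harmonized, config.design)
        perm = _stage("vlsm_permute", timings, permutation_correct, statmap, config.design)
        vlsm_clusters = clusters_from_mask(
            perm.significant, statmap.affine, statmap.stat, config.design.tail
        )
        io_mod.write_volume(statmap.stat, statmap.affine, out_dir / "vlsm_t.nii.gz")
        io_mod.write_volume(perm.fwer_p, statmap.affine, out_dir / "vlsm_fwer_p.nii.gz")
        io_mod.write_mask(LesionMask(statmap.inclusion, statmap.affine), out_dir / "vlsm_inclusion.nii.gz")
        io_mod.write_mask(LesionMask(perm.significant, statmap.affine), out_dir / "vlsm_cluster.nii.gz")

        mlsm_res: MlsmResult = _stage("mlsm", timings, run_mlsm, masks, harmonized, config.mlsm)
        io_mod.write_volume(mlsm_res.weight_map.weight, statmap.affine, out_dir / "mlsm_weight.nii.gz")
        io_mod.write_volume(mlsm_res.p_map, statmap.affine, out_dir / "mlsm_p.nii.gz")
        io_mod.write_mask(LesionMask(mlsm_res.significant, statmap.affine), out_dir / "mlsm_cluster.nii.gz")

        def _build_roi():
            affine = statmap.affine
            shape = statmap.stat.shape
            empty = LesionMask(np.zeros(shape, dtype=bool), affine)
            vlsm_mask = vlsm_clusters[0].to_mask(shape, affine) if vlsm_clusters else empty
            mlsm_mask = mlsm_res.clusters[0].to_mask(shape, affine) if mlsm_res.clusters else empty
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                roi = cohort_mod.intersect_rois(vlsm_mask, mlsm_mask)
                d = cohort_mod.dice(vlsm_mask, mlsm_mask)
            return roi, d

        roi, dice_vm = _stage("intersect_roi", timings, _build_roi)
        io_mod.write_mask(roi, out_dir / "lsm_roi.nii.gz")
        _plot_roi(roi, out_dir / "lsm_roi.png")

        def _cohort_stats():
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                roi_flags, dscs = cohort_mod.classify_roi_resection(masks, roi)
                deficit_flags, diffs = cohort_mod.classify_deficit(harmonized)
            table = cohort_mod.contingency(roi_flags, deficit_flags)
            result = {
                "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
                "n_roi_resections": int(roi_flags.sum()),
                "n_deficit": int(deficit_flags.sum()),
            }
            try:
                result["relative_risk"] = _effect_dict(cohort_mod.relative_risk(table))
                result["odds_ratio"] = _effect_dict(cohort_mod.odds_ratio(table))
            except ValueError:
                try:
                    result["relative_risk"] = _effect_dict(
                        cohort_mod.relative_risk(table, continuity_correction=True)
                    )
                    result["odds_ratio"] = _effect_dict(
                        cohort_mod.odds_ratio(table, continuity_correction=True)
                    )
                    result["effect_error"] = "zero cell; continuity correction applied"
                except ValueError as exc:
                    result["effect_error"] = str(exc)
            flags = pd.DataFrame(
                {
                    "subject_id": harmonized["subject_id"],
                    "dsc_roi": dscs,
                    "roi_resection": roi_flags.astype(int),
                    "severity_minus_self": diffs,
                    "deficit": deficit_flags.astype(int),
                }
            )
            flags.to_csv(out_dir / "subject_flags.csv", index=False)
            return result

        cohort_stats = _stage("cohort", timings, _cohort_stats)

        report = {
            "provenance": {
                "package_version": metadata.version("lesionmap"),
                "seed": config.seed,
                "config_sha256": config.sha256(),
                "versions": {
                    name: metadata.version(name)
                    for name in ("numpy", "scipy", "pandas", "nibabel", "scikit-learn")
                },
            },
            "n_subjects": int(len(behavior)),
            "vlsm": {
                "n_included_voxels": statmap.n_included,
                "n_excluded_rank": int(statmap.n_excluded_rank),
                "critical_t": float(perm.critical_t) if np.isfinite(perm.critical_t) else 0.0,
                "primary_threshold_t": float(perm.primary_threshold_t)
                if np.isfinite(perm.primary_threshold_t)
                else 0.0,
                "cluster_extent_critical": int(perm.cluster_extent_critical),
                "n_permutations": int(perm.n_permutations_used),
                "exhaustive": bool(perm.exhaustive),
                "clusters": [_cluster_dict(c) for c in vlsm_clusters],
            },
            "mlsm": {
                "n_included_voxels": int(mlsm_res.weight_map.inclusion.sum()),
                "n_permutations": int(config.mlsm.n_permutations),
                "n_subjects_zero_row": int(mlsm_res.n_subjects_zero_row),
                "clusters": [_cluster_dict(c) for c in mlsm_res.clusters],
            },
            "roi": {
                "n_voxels": int(roi.n_voxels),
                "volume_cm3": float(roi.volume_cm3),
                "dice_vlsm_mlsm": float(dice_vm),
            },
            "cohort": cohort_stats,
        }
        validate(report)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out_dir / "timings.json").write_text(
            json.dumps({k: round(v, 3) for k, v in timings.items()}, indent=2, sort_keys=True)
        )
        return report
    except PipelineError as exc:
        (out_dir / "FAILED").write_text(str(exc))
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
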