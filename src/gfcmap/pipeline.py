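"""End-to-end study orchestration.

Runs, from a single config: (optional) cohort simulation or ingestion of
existing files -> motion QC and subject exclusion -> per-subject GFC maps
-> voxel-wise group inference with FWE control and cluster extraction ->
cluster-mean clinical correlations -> single-region LOOCV SVM.  Every
intermediate is persisted (QC table, GFC NIfTIs, t/p maps, cluster TSV,
correlation TSV, classifier JSON) together with a run manifest holding the
config hash and the per-stage seeds; identical config + seed reproduce all
outputs bit-identically on one platform.

Per-stage seeds are derived from the global seed by hashing the stage name
(sha256), so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .cohort import CohortSpec, generate_cohort, spec_from_dict, spec_to_dict, write_cohort
from .classify import loocv_svm
from .clinical import correlate_clinical, correlations_to_frame, extract_cluster_means
from .gfc import build_gray_mask, compute_gfc, drop_constant_voxels
from .inference import (
    DEFAULT_COVARIATES,
    build_design,
    clusters_to_frame,
    extract_clusters,
    fit_voxelwise_glm,
    fwe_correct,
)
from .motion import apply_exclusion, compute_fd, read_motion_file

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_VARIABLES = [
    "TG", "CHOL", "HDL_C", "LDL_C", "HAMD17", "HAMA14", "YMRS",
    "RBANS_coding", "stroop_color",
]


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None  # CohortSpec fields; None -> ingest paths
    bold_dir: str | None = None
    gm_prob_path: str | None = None
    motion_dir: str | None = None
    subjects_path: str | None = None
    gm_threshold: float = 0.2
    z_order: str = "z_of_mean_r"
    mean_fd_limit: float = 0.2
    max_abs_translation: float = 2.0
    max_abs_rotation: float = 2.0
    fwe_method: str = "permutation_maxT"
    alpha: float = 0.05
    n_permutations: int = 1000
    connectivity: int = 26
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    correlation_variables: list[str] = field(
        default_factory=lambda: list(DEFAULT_CORRELATION_VARIABLES)
    )
    correlation_family: str = "all"
    classifier_grid: dict | None = None
    classifier_nested: bool = True
    resume: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.gm_threshold < 1):
            raise ValueError("gm_threshold must lie in [0, 1)")
        if self.z_order not in ("z_of_mean_r", "mean_of_z"):
            raise ValueError(f"unknown z_order {self.z_order!r}")
        if self.correlation_family not in ("all", "per_cluster"):
            raise ValueError("correlation_family must be 'all' or 'per_cluster'")
        if self.simulate is None:
            for name in ("bold_dir", "gm_prob_path", "motion_dir", "subjects_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when no simulate block is given")
                if not Path(p).exists():
                    raise ValueError(f"{name} path does not exist: {p}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    if "covariates" in raw:
        raw["covariates"] = tuple(raw["covariates"])
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256 of 'seed:stage', below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = yaml.safe_dump(_config_dict(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dict(cfg.__dict__)
    d["covariates"] = list(cfg.covariates)
    d.pop("resume", None)  # resume mode must not change the run's identity
    return d


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the consolidated report (also written
    to ``<out_dir>/report.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.resume and (out / "report.json").exists():
        previous = json.loads((out / "report.json").read_text())
        if previous.get("config_hash") == _config_hash(cfg):
            logger.info("resume: config hash matches, reusing persisted report")
            return previous
    report: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": {
            s: stage_seed(cfg.seed, s)
            for s in ("simulate", "group", "classify")
        },
    }

    # ---- stage: simulate or ingest -------------------------------------
    try:
        if cfg.simulate is not None:
            spec_fields = dict(cfg.simulate)
            spec_fields.setdefault("seed", stage_seed(cfg.seed, "simulate"))
            spec = spec_from_dict(spec_fields)
            volumes, gm_prob, traces, subjects, truth = generate_cohort(spec)
            write_cohort(out / "cohort", volumes, gm_prob, traces, subjects, truth)
            gm_affine = volumes[0].affine
            report["simulate"] = {"spec": spec_to_dict(spec)}
        else:
            volumes, gm_prob, gm_affine, traces, subjects = _ingest(cfg)
            truth = None
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/ingest' failed: {exc}") from exc

    # ---- stage: motion QC ----------------------------------------------
    try:
        fds = [compute_fd(t) for t in traces]
        kept, excluded, qc = apply_exclusion(
            fds, traces,
            mean_fd_limit=cfg.mean_fd_limit,
            max_abs_translation=cfg.max_abs_translation,
            max_abs_rotation=cfg.max_abs_rotation,
        )
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        mean_fd = {f.subject_id: f.mean_fd for f in fds}
        subjects = subjects[subjects["subject"].isin(kept)].copy()
        subjects["mean_fd"] = subjects["subject"].map(mean_fd)
        subjects = subjects.reset_index(drop=True)
        volumes = [v for v in volumes if v.subject_id in set(kept)]
        order = {s: i for i, s in enumerate(subjects["subject"])}
        volumes.sort(key=lambda v: order[v.subject_id])
        report["qc"] = {
            "n_kept": len(kept),
            "n_excluded": len(excluded),
            "excluded": excluded,
            "n_kept_patients": int((subjects["group"] == "patient").sum()),
            "n_kept_controls": int((subjects["group"] == "control").sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    # ---- stage: GFC maps ------------------------------------------------
    try:
        mask = build_gray_mask(gm_prob, cfg.gm_threshold, affine=gm_affine)
        mask = drop_constant_voxels(volumes[0], mask)
        maps_dir = out / "gfc"
        maps_dir.mkdir(exist_ok=True)
        rows = []
        for vs in volumes:
            m = compute_gfc(vs, mask, z_order=cfg.z_order)
            gio.save_gfc_map(m, maps_dir / f"{vs.subject_id}_gfc.nii.gz")
            rows.append(m.values)
        gfc_matrix = np.vstack(rows)
        report["gfc"] = {"n_mask_voxels": len(mask), "z_order": cfg.z_order}
    except Exception as exc:
        raise RuntimeError(f"stage 'gfc' failed: {exc}") from exc

    # ---- stage: group inference -----------------------------------------
    try:
        design, names = build_design(subjects, covariates=cfg.covariates)
        stat = fit_voxelwise_glm(gfc_matrix, design, group_col=1, column_names=names)
        fwe = fwe_correct(
            stat, gfc_matrix, design,
            method=cfg.fwe_method, alpha=cfg.alpha,
            n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, "group"),
        )
        clusters = extract_clusters(stat, fwe, mask, connectivity=cfg.connectivity)
        gio.save_stat_maps(stat, mask, out)
        cl_frame = clusters_to_frame(clusters)
        cl_frame.to_csv(out / "clusters.tsv", sep="\t", index=False)
        (out / "fwe.json").write_text(json.dumps({
            "method": fwe.method, "alpha": fwe.alpha,
            "n_permutations": fwe.n_permutations,
            "seed": fwe.seed, "threshold": fwe.threshold,
            "n_significant_voxels": int(fwe.significant.sum()),
        }, indent=2))
        report["group"] = {
            "dof": stat.dof,
            "fwe_threshold": fwe.threshold,
            "n_significant_voxels": int(fwe.significant.sum()),
            "clusters": cl_frame.to_dict(orient="records"),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'group' failed: {exc}") from exc

    # ---- stage: clinical correlations ------------------------------------
    try:
        if clusters:
            means = extract_cluster_means(
                gfc_matrix, list(subjects["subject"]), clusters, mask
            )
            means.to_csv(out / "cluster_means.tsv", sep="\t", index=False)
            variables = [
                v for v in cfg.correlation_variables if v in subjects.columns
            ]
            corrs = correlate_clinical(
                means, subjects, variables,
                group_filter="patient", family=cfg.correlation_family,
                alpha=0.05,
            )
            corr_frame = correlations_to_frame(corrs)
            corr_frame.to_csv(out / "correlations.tsv", sep="\t", index=False)
            patients = subjects[subjects["group"] == "patient"]
            for res in corrs:
                if not res.significant:
                    continue
                scatter = means.merge(
                    patients[["subject", res.variable]], on="subject", how="inner"
                )[["subject", res.cluster_id, res.variable]].dropna()
                scatter.to_csv(
                    out / f"scatter_{res.cluster_id}_{res.variable}.tsv",
                    sep="\t", index=False,
                )
            report["correlations"] = corr_frame.to_dict(orient="records")
        else:
            means = None
            report["correlations"] = []
    except Exception as exc:
        raise RuntimeError(f"stage 'correlate' failed: {exc}") from exc

    # ---- stage: classification -------------------------------------------
    try:
        report["classification"] = []
        if clusters and means is not None:
            labels = (subjects["group"] == "patient").to_numpy(dtype=int)
            for c in clusters:
                rep = loocv_svm(
                    means[c.cluster_id].to_numpy(),
                    labels,
                    region=c.cluster_id,
                    grid=cfg.classifier_grid,
                    nested=cfg.classifier_nested,
                    seed=stage_seed(cfg.seed, "classify"),
                )
                report["classification"].append(rep.to_dict())
                pd.DataFrame({
                    "subject": subjects["subject"],
                    "true": rep.true_labels,
                    "predicted": rep.predicted_labels,
                }).to_csv(out / f"predictions_{c.cluster_id}.tsv", sep="\t", index=False)
            (out / "classifier.json").write_text(
                json.dumps(report["classification"], indent=2)
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    if truth is not None:
        report["ground_truth_summary"] = {
            "n_hub_voxels": int(len(truth.hub_voxels)),
            "high_motion_ids": truth.high_motion_ids,
        }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _ingest(cfg: PipelineConfig):
    """Load an existing study from disk (bold dir, gm map, motion dir, table)."""
    subjects = pd.read_csv(cfg.subjects_path, sep="\t")
    gm_prob, gm_affine = gio.load_volume_3d(cfg.gm_prob_path)
    volumes, traces = [], []
    for sid in subjects["subject"]:
        volumes.append(gio.load_volume_series(Path(cfg.bold_dir) / f"{sid}.nii.gz", sid))
        traces.append(
            read_motion_file(Path(cfg.motion_dir) / f"rp_{sid}.txt", subject_id=sid)
        )
    return volumes, gm_prob, gm_affine, traces, subjects
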