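"""End-to-end orchestration: simulate -> maps -> group maps -> CPM -> change calls -> SVM.

One YAML config drives the whole chain. Artifacts live in a flat directory;
every stage writes a JSON sidecar recording its parameters, the master seed
and SHA-256 hashes of its inputs, and a manifest indexes everything. A stage
whose outputs already exist (with matching upstream hashes) is skipped, so
deleting one stage's outputs and rerunning regenerates that stage without
touching finished work. Reruns under the same config and seed are
bit-identical for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical_change, cpm, group_inference, regional_metrics, synthetic_cohort
from .imaging_io import (
    MetricMap,
    read_mask,
    read_parcellation,
    read_subject_table,
    read_volume,
    write_volume,
)
from .svm_classify import extract_cluster_features, leave_pair_out_cv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    cohort_dir: str | None = None          # defaults to <out_dir>/cohort
    design: synthetic_cohort.CohortDesign = field(default_factory=synthetic_cohort.CohortDesign)
    neighborhood: int = 27
    fwhm_mm: float = 4.0
    r_threshold: float = 0.25
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    n_perm: int = 200
    cpm_p_threshold: float = 0.01
    cpm_model: str = "negative"
    cpm_n_perm: int = 100
    alpha_reliability: float = 0.88
    score_name: str = "rbans_t"
    visit: str = "week12"
    svm_grid: dict = field(default_factory=lambda: {"C": [1.0, 10.0], "gamma": [0.1, 1.0]})
    seed: int = 0

    def validate(self) -> None:
        regional_metrics.RehoParams(neighborhood=self.neighborhood)
        regional_metrics.DcParams(r_threshold=self.r_threshold)
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if not 0 < self.voxel_p < 1 or not 0 < self.cluster_p < 1:
            raise ValueError("voxel_p and cluster_p must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.cpm_n_perm < 99:
            raise ValueError("cpm_n_perm must be >= 99")
        if not 0 < self.cpm_p_threshold < 1:
            raise ValueError("cpm_p_threshold must lie in (0, 1)")
        if self.cpm_model not in cpm.MODELS:
            raise ValueError(f"cpm_model must be one of {cpm.MODELS}")
        if not 0 < self.alpha_reliability <= 1:
            raise ValueError("alpha_reliability must lie in (0, 1]")
        if self.visit not in ("week12", "week24"):
            raise ValueError("visit must be week12 or week24")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        design_doc = doc.pop("design", {})
        if "grid_shape" in design_doc:
            design_doc["grid_shape"] = tuple(design_doc["grid_shape"])
        if "behavior_edges" in design_doc:
            design_doc["behavior_edges"] = tuple(tuple(e) for e in design_doc["behavior_edges"])
        cfg = cls(design=synthetic_cohort.CohortDesign(**design_doc), **doc)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_sidecar(path: Path, stage: str, params: dict, inputs: dict[str, str]) -> None:
    path.write_text(json.dumps(
        {"stage": stage, "params": params, "input_hashes": inputs}, indent=2, sort_keys=True
    ))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns the artifact manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_dir = Path(config.cohort_dir) if config.cohort_dir else out / "cohort"
    manifest: dict = {"stages": {}, "seed": config.seed}

    def run_stage(name, fn):
        t0 = time.monotonic()
        try:
            artifacts = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        dt = time.monotonic() - t0
        logger.info("stage %-10s done in %.1fs", name, dt)
        manifest["stages"][name] = {
            "artifacts": artifacts,
            "wall_seconds": round(dt, 3),
            "hashes": {k: _sha256(Path(v)) for k, v in artifacts.items()
                       if isinstance(v, str) and Path(v).is_file()},
        }
        return artifacts

    # ---- stage 1: cohort -------------------------------------------------
    def _simulate():
        if (cohort_dir / "subjects.tsv").exists():
            logger.info("cohort already present at %s; skipping simulation", cohort_dir)
        else:
            synthetic_cohort.write_cohort(config.design, cohort_dir)
        return {"cohort_dir": str(cohort_dir), "subjects": str(cohort_dir / "subjects.tsv")}

    cohort = run_stage("simulate", _simulate)
    records = read_subject_table(cohort["subjects"])
    mask = read_mask(cohort_dir / "mask.nii.gz")
    parc = read_parcellation(cohort_dir / "parcellation.nii.gz")
    voxel_size = (3.0, 3.0, 3.0)

    # ---- stage 2: per-subject metric maps --------------------------------
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)

    def _metrics():
        artifacts = {}
        reho_params = regional_metrics.RehoParams(neighborhood=config.neighborhood)
        dc_params = regional_metrics.DcParams(r_threshold=config.r_threshold)
        for rec in records:
            reho_path = maps_dir / f"{rec.subject_id}_reho.nii.gz"
            dc_path = maps_dir / f"{rec.subject_id}_dc.nii.gz"
            if reho_path.exists() and dc_path.exists():
                artifacts[f"{rec.subject_id}_reho"] = str(reho_path)
                artifacts[f"{rec.subject_id}_dc"] = str(dc_path)
                continue
            bold = read_volume(cohort_dir / f"{rec.subject_id}_bold.nii.gz",
                               subject_id=rec.subject_id)
            reho = regional_metrics.compute_reho(bold, mask, reho_params)
            reho = regional_metrics.normalize_map(reho, mask)
            reho = regional_metrics.smooth_map(reho, config.fwhm_mm, voxel_size)
            write_volume(reho, reho_path)
            dc = regional_metrics.compute_dc(bold, mask, dc_params)
            dc = regional_metrics.smooth_map(dc, config.fwhm_mm, voxel_size)
            write_volume(dc, dc_path)
            artifacts[f"{rec.subject_id}_reho"] = str(reho_path)
            artifacts[f"{rec.subject_id}_dc"] = str(dc_path)
        return artifacts

    run_stage("metrics", _metrics)

    def load_maps(kind: str) -> list[MetricMap]:
        return [read_volume(maps_dir / f"{rec.subject_id}_{kind}.nii.gz",
                            metric_kind="reho_normalized" if kind == "reho" else "dc",
                            mask=mask)
                for rec in records]

    groups = [rec.group for rec in records]
    covars = pd.DataFrame({
        "age": [rec.age for rec in records],
        "gender": [rec.gender for rec in records],
        "fd": [rec.fd for rec in records],
    })
    # drop covariates with missing or constant values (rank safety)
    covars = covars.loc[:, covars.notna().all() & (covars.nunique() > 1)]

    # ---- stage 3: group maps with permutation cluster correction ---------
    group_dir = out / "group"
    group_dir.mkdir(exist_ok=True)
    cluster_results: dict[str, group_inference.ClusterResult] = {}

    def _group():
        artifacts = {}
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        X, names = group_inference.design_matrix(groups, covars if len(covars.columns) else None)
        contrast = group_inference.group_contrast(names, "BD", "HC")
        for kind in ("reho", "dc"):
            maps = load_maps(kind)
            tmap, result = group_inference.cluster_correct(
                maps, X, contrast, voxel_p=config.voxel_p, cluster_p=config.cluster_p,
                n_perm=config.n_perm, rng=rng,
            )
            cluster_results[kind] = result
            tmap_path = group_dir / f"{kind}_bd_vs_hc_t.nii.gz"
            write_volume(tmap, tmap_path)
            table_path = group_dir / f"{kind}_bd_vs_hc_clusters.tsv"
            group_inference.cluster_table(result, config.cluster_p).to_csv(
                table_path, sep="\t", index=False)
            artifacts[f"{kind}_tmap"] = str(tmap_path)
            artifacts[f"{kind}_clusters"] = str(table_path)
        _write_sidecar(group_dir / "group.json", "group",
                       {"voxel_p": config.voxel_p, "cluster_p": config.cluster_p,
                        "n_perm": config.n_perm, "seed": config.seed},
                       {"subjects": _sha256(Path(cohort["subjects"]))})
        artifacts["sidecar"] = str(group_dir / "group.json")
        return artifacts

    run_stage("group", _group)

    # ---- stage 4: CPM on the patient group -------------------------------
    cpm_dir = out / "cpm"
    cpm_dir.mkdir(exist_ok=True)

    def _cpm():
        bd = [rec for rec in records if rec.group == "BD"]
        matrices = []
        behaviors = []
        for idx, rec in enumerate(bd):
            bold = read_volume(cohort_dir / f"{rec.subject_id}_bold.nii.gz",
                               subject_id=rec.subject_id)
            conn = cpm.build_connectivity(bold, parc)
            matrices.append(conn)
            rng_b = np.random.default_rng(np.random.SeedSequence([config.seed, 2, idx]))
            behaviors.append(synthetic_cohort.simulate_behavior(config.design, conn.values, rng_b))
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        p, result = cpm.permutation_p(matrices, behaviors, n_perm=config.cpm_n_perm,
                                      rng=rng, p_threshold=config.cpm_p_threshold,
                                      model=config.cpm_model)
        out_json = cpm_dir / "cpm_result.json"
        out_json.write_text(json.dumps({
            "model": config.cpm_model,
            "r_pred_obs": result.r_pred_obs,
            "p_perm": p,
            "n_subjects": len(bd),
            "n_empty_folds": result.n_empty_folds,
            "predicted": result.predicted.tolist(),
            "observed": result.observed.tolist(),
        }, indent=2))
        return {"cpm_result": str(out_json)}

    run_stage("cpm", _cpm)

    # ---- stage 5: improvement calls --------------------------------------
    change_dir = out / "change"
    change_dir.mkdir(exist_ok=True)
    calls_path = change_dir / "calls.tsv"

    def _change():
        bd_stats = synthetic_cohort.BASELINE_GROUP_STATS["BD"][config.score_name]
        hc_stats = synthetic_cohort.BASELINE_GROUP_STATS["HC"][config.score_name]
        criteria = clinical_change.make_criteria(
            sd_baseline=bd_stats[1], alpha=config.alpha_reliability,
            mean_clin=bd_stats[0], sd_clin=bd_stats[1],
            mean_norm=hc_stats[0], sd_norm=hc_stats[1],
        )
        bd = [rec for rec in records if rec.group == "BD"]
        calls, n_excluded = clinical_change.classify_improvement(
            bd, config.score_name, criteria, config.visit)
        pd.DataFrame([{
            "subject_id": c.subject_id, "visit": c.visit, "change": c.change_score,
            "followup": c.followup_score, "improved": int(c.improved),
            "rc_index": criteria.rc_index, "cutoff": criteria.cutoff,
        } for c in calls]).to_csv(calls_path, sep="\t", index=False)
        return {"calls": str(calls_path),
                "criteria": json.dumps({"rc_index": criteria.rc_index,
                                        "cutoff": criteria.cutoff,
                                        "n_excluded": n_excluded})}

    run_stage("change", _change)

    # ---- stage 6: SVM on cluster features --------------------------------
    svm_dir = out / "svm"
    svm_dir.mkdir(exist_ok=True)

    def _svm():
        calls = pd.read_csv(calls_path, sep="\t")
        if calls.empty or calls["improved"].nunique() < 2 or \
                calls["improved"].value_counts().min() < 2:
            return {"skipped": "improvement calls do not contain two usable classes"}
        usable_kinds = {k: r for k, r in cluster_results.items() if r.clusters}
        if not usable_kinds:
            return {"skipped": "no supra-threshold clusters to extract features from"}
        bd_ids = calls["subject_id"].tolist()
        id_index = {rec.subject_id: i for i, rec in enumerate(records)}
        maps_by_kind = {}
        for kind in usable_kinds:
            all_maps = load_maps(kind)
            maps_by_kind[kind] = [all_maps[id_index[s]] for s in bd_ids]
        labels = pd.Series(calls["improved"].to_numpy(), index=pd.Index(bd_ids, name="subject_id"))
        table = extract_cluster_features(
            maps_by_kind, usable_kinds, bd_ids, labels)
        report = leave_pair_out_cv(table, params_grid=config.svm_grid)
        report_path = svm_dir / "svm_report.json"
        report_path.write_text(json.dumps({
            "tp": report.tp, "fn": report.fn, "tn": report.tn, "fp": report.fp,
            "sensitivity": report.sensitivity, "specificity": report.specificity,
            "accuracy": report.accuracy, "best_params": report.best_params,
        }, indent=2))
        grid_path = svm_dir / "grid_surface.tsv"
        report.grid.to_csv(grid_path, sep="\t", index=False)
        return {"report": str(report_path), "grid": str(grid_path)}

    run_stage("svm", _svm)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
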