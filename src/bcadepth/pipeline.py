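"""End-to-end orchestration on phantom batches.

Mirrors the study protocol: train the voxel classifier on tumor/wall voxel
samples from training phantoms, then for each validation phantom segment
the candidate region, excise the predicted tumor, recompute wall thickness
and report the invasion depth.  Every case row carries the segmentation
Dice coefficient and the invasion depth computed twice — from the
ground-truth tumor mask (the "manual" analogue) and from the pipeline
segmentation — plus their absolute difference.

All randomness (phantom noise, voxel sampling, CV folds) derives from one
global seed through a seed sequence, so a config+seed pair reproduces the
report byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .classifier import (dice, hard_segment, probability_map, rfe_rank,
                         select_optimal, soft_boundary, train_svm)
from .depth import excise_cancer, invasion_depth
from .features import FeatureExtractor
from .io import Mask
from .phantom import PhantomSpec, make_phantom, sample_training_voxels
from .thickness import detect_candidate, geometry_from_regions, thickness_map

__all__ = ["PipelineConfig", "PipelineReport", "run_end_to_end"]

log = logging.getLogger("bcadepth")


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Round-trips unchanged through YAML (``to_yaml``/``from_yaml``).
    """

    seed: int = 0
    # phantom batch
    n_train_phantoms: int = 4
    n_cases: int = 10
    case_depths_mm: list = field(default_factory=lambda: [0.5, 1.0, 1.5, 2.0])
    phantom: dict = field(default_factory=dict)   # PhantomSpec overrides
    n_per_class: int = 300
    sample_margin_mm: float = 1.0
    # features
    wavelet: str = "haar"
    levels: int = 2
    lm_support: int = 49
    lm_sigma0: float = 1.0
    # classifier
    svm_c: float = 1.0
    use_rfe: bool = True
    rfe_step: int = 50
    folds: int = 5
    cv_grid: list | None = None
    hard_threshold: float = 0.5
    soft_lo: float = 0.1
    soft_hi: float = 0.9
    # thickness / depth
    solver_tol: float = 1e-6
    solver_max_iter: int = 10000
    step_mm: float = 0.25
    anomaly_k: float = 3.0
    candidate_source: str = "truth"   # "truth" | "detect"
    # bypass the classifier and use the ground-truth tumor mask as the
    # segmentation (pass-through check of the depth machinery)
    oracle_segmentation: bool = False

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineReport:
    table: pd.DataFrame
    summary: dict
    config: PipelineConfig
    model_info: dict

    def to_json(self) -> str:
        return json.dumps({
            "summary": self.summary,
            "cases": self.table.to_dict(orient="records"),
            "model": self.model_info,
            "config": asdict(self.config),
        }, indent=1)


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2 ** 31))


def _case_spec(cfg: PipelineConfig, depth: float, seed: int) -> PhantomSpec:
    overrides = dict(cfg.phantom)
    overrides.update(invasion_depth_mm=depth, seed=seed)
    return PhantomSpec(**overrides)


def _wall_geometry(truth):
    wall_domain = truth.wall_mask.bool() | truth.tumor_mask.bool()
    return geometry_from_regions(wall_domain, truth.lumen_mask.bool(),
                                 truth.wall_mask)


def _depth_from_cancer(cfg, geom, candidate: Mask, cancer: Mask) -> float:
    geom2 = excise_cancer(geom, cancer)
    tm = thickness_map(geom2, tol=cfg.solver_tol, max_iter=cfg.solver_max_iter,
                       step_mm=cfg.step_mm)
    rep = invasion_depth(tm, candidate, cancer)
    return rep.t_id_mm


def train_model(cfg: PipelineConfig, seq: np.random.SeedSequence,
                extractor: FeatureExtractor):
    """Train the (optionally RFE-selected) voxel classifier on
    ``cfg.n_train_phantoms`` phantoms; returns (model, info dict)."""
    frames, labels = [], []
    depths = cfg.case_depths_mm
    for i in range(cfg.n_train_phantoms):
        s_phantom, s_sample = _child_seed(seq.spawn(1)[0]), _child_seed(seq.spawn(1)[0])
        spec = _case_spec(cfg, depths[i % len(depths)], s_phantom)
        truth = make_phantom(spec)
        tum, wal = sample_training_voxels(truth, cfg.n_per_class,
                                          margin_mm=cfg.sample_margin_mm,
                                          seed=s_sample)
        vox = np.vstack([tum, wal])
        t0 = time.time()
        frames.append(extractor.extract(truth.volume, vox))
        log.info("train phantom %d: %d voxels featurized in %.1fs",
                 i, len(vox), time.time() - t0)
        labels.append(np.r_[np.ones(len(tum)), np.zeros(len(wal))])
    X = pd.concat(frames, axis=0)
    y = np.concatenate(labels).astype(int)

    info = {"n_train_voxels": int(len(y)), "n_features": int(X.shape[1])}
    if cfg.use_rfe:
        t0 = time.time()
        ranking = rfe_rank(X, y, step=cfg.rfe_step, C=cfg.svm_c)
        res = select_optimal(X, y, ranking, folds=cfg.folds, grid=cfg.cv_grid,
                             C=cfg.svm_c, seed=_child_seed(seq.spawn(1)[0]))
        log.info("RFE + CV selection in %.1fs: optimal N=%d (train acc %.4f, "
                 "AUC %.4f)", time.time() - t0, res.optimal_n, res.accuracy,
                 res.auc)
        info.update(optimal_n=int(res.optimal_n),
                    cv_grid=[int(g) for g in res.grid],
                    cv_accuracy=[float(a) for a in res.cv_accuracy_curve],
                    sensitivity=res.sensitivity, specificity=res.specificity,
                    accuracy=res.accuracy, auc=res.auc)
        return res.model, info
    model = train_svm(X, y, C=cfg.svm_c)
    return model, info


def run_end_to_end(cfg: PipelineConfig) -> PipelineReport:
    """Run train -> segment -> excise -> thickness -> depth on a phantom
    batch and tabulate per-case DSC and invasion depths."""
    seq = np.random.SeedSequence(cfg.seed)
    if cfg.oracle_segmentation:
        extractor = model = None
        model_info = {"oracle_segmentation": True}
    else:
        extractor = FeatureExtractor(wavelet=cfg.wavelet, levels=cfg.levels,
                                     lm_support=cfg.lm_support,
                                     sigma0=cfg.lm_sigma0)
        model, model_info = train_model(cfg, seq, extractor)
        cancer_cols = list(model.columns)

    rows = []
    for case in range(cfg.n_cases):
        s_case = _child_seed(seq.spawn(1)[0])
        depth_true = cfg.case_depths_mm[case % len(cfg.case_depths_mm)]
        spec = _case_spec(cfg, depth_true, s_case)
        truth = make_phantom(spec)
        geom = _wall_geometry(truth)

        if cfg.candidate_source == "detect":
            tm0 = thickness_map(geom, tol=cfg.solver_tol,
                                max_iter=cfg.solver_max_iter,
                                step_mm=cfg.step_mm, keep_paths=True)
            candidate = detect_candidate(tm0, geom, k=cfg.anomaly_k)
        elif cfg.candidate_source == "truth":
            candidate = truth.candidate_mask
        else:
            raise ValueError(f"unknown candidate_source {cfg.candidate_source!r}")

        vox = np.argwhere(candidate.bool())
        t0 = time.time()
        if cfg.oracle_segmentation:
            hard = truth.tumor_mask
            soft = Mask.from_bool(np.zeros_like(hard.bool()), hard)
        else:
            Xc = extractor.extract(truth.volume, vox)[cancer_cols]
            pm = probability_map(model, Xc, candidate)
            hard = hard_segment(pm, threshold=cfg.hard_threshold)
            soft = soft_boundary(pm, cfg.soft_lo, cfg.soft_hi)
        dsc = dice(hard, truth.tumor_mask)
        log.info("case %d: %d candidate voxels, DSC=%.3f (%.1fs)",
                 case, len(vox), dsc, time.time() - t0)

        t_id_manual = _depth_from_cancer(cfg, geom, candidate, truth.tumor_mask)
        if hard.bool().any():
            t_id_pipe = _depth_from_cancer(cfg, geom, candidate, hard)
        else:
            t_id_pipe = float("nan")
        rows.append({"case": case, "true_depth_mm": depth_true,
                     "dsc": dsc,
                     "t_id_manual_mm": t_id_manual,
                     "t_id_pipeline_mm": t_id_pipe,
                     "abs_diff_mm": abs(t_id_pipe - t_id_manual),
                     "n_soft_voxels": int(soft.bool().sum())})

    table = pd.DataFrame(rows)
    summary = {
        "mean_dsc": float(table["dsc"].mean()),
        "sd_dsc": float(table["dsc"].std(ddof=1)) if len(table) > 1 else 0.0,
        "mean_abs_tid_diff_mm": float(table["abs_diff_mm"].mean()),
        "sd_abs_tid_diff_mm": float(table["abs_diff_mm"].std(ddof=1))
        if len(table) > 1 else 0.0,
    }
    return PipelineReport(table, summary, cfg, model_info)
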