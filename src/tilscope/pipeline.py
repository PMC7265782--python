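"""End-to-end orchestration: slide -> FOV -> TIL map -> features, and the
cohort-level association/survival reports.

A single top-level seed deterministically derives one child seed per stage
via ``numpy.random.SeedSequence(seed).spawn`` (order: fov, segmentation,
spatial, association), so a full run is reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .errors import NoTissueError
from .fovdetect import crop_fov, identify_fov
from .lymphseg.model import load_checkpoint
from .omicsassoc import (
    lasso_cox_select,
    multivariate_risk_groups,
    mutation_test,
    spearman_screen,
    subtype_groups,
    univariate_cutoff_scan,
)
from .synthfix import RasterSlide
from .tilquant import compute_til_map, til_score, tile_fov
from .tilspatial.features import compute_feature_vector

logger = logging.getLogger(__name__)

STAGE_NAMES = ("fov", "segmentation", "spatial", "association")


@dataclass
class PipelineConfig:
    seed: int = 0
    downsample_factor: int = 16
    kmeans_k: int = 3
    patch_size: int = 200
    max_background: float = 0.8
    min_til_fraction: float = 0.1
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_conv_iter: int = 100
    ap_preference: str | float = "median"
    spearman_threshold: float = 0.3
    min_mutated: int = 10
    cutoff_lo: float = 20.0
    cutoff_hi: float = 80.0
    cutoff_step: float = 1.0
    verbosity: str = "info"

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(len(STAGE_NAMES))
        return {
            name: int(child.generate_state(1)[0])
            for name, child in zip(STAGE_NAMES, children)
        }

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def asdict(self):
        return dataclasses.asdict(self)


def _log_stage(out_dir, slide_id, stage, status, **extra):
    entry = {"slide": slide_id, "stage": stage, "status": status, **extra}
    logger.info("%s", entry)
    with open(os.path.join(out_dir, "pipeline.log.jsonl"), "a") as fh:
        fh.write(json.dumps(entry, default=str) + "\n")


def run_slide(slide_path, ckpt_path, config: PipelineConfig, out_dir,
              slide_id=None):
    """Run FOV -> TIL map -> spatial features for one slide.

    All intermediates are persisted in ``out_dir`` (FOV JSON, TIL map
    CSV/PNG, feature CSV) together with the resolved config; re-running
    with the same seed reproduces the outputs. Returns
    ``(FOVRegion, TILMap, SpatialFeatureVector)``.
    """
    os.makedirs(out_dir, exist_ok=True)
    slide_id = slide_id or os.path.splitext(os.path.basename(str(slide_path)))[0]
    seeds = config.stage_seeds()
    config.to_yaml(os.path.join(out_dir, "config_resolved.yaml"))
    cfg_dict = config.asdict()

    pixels = io.read_image(slide_path)
    slide = RasterSlide(pixels=pixels, downsample_factor=config.downsample_factor)
    try:
        fov = identify_fov(slide, k=config.kmeans_k, seed=seeds["fov"])
    except NoTissueError:
        _log_stage(out_dir, slide_id, "fov", "error", error="no tissue detected")
        raise
    io.write_fov(fov, os.path.join(out_dir, f"{slide_id}_fov.json"),
                 seed=config.seed, config=cfg_dict)
    _log_stage(out_dir, slide_id, "fov", "ok", bbox_full=fov.bbox_full)

    ckpt = load_checkpoint(ckpt_path)
    crop = crop_fov(slide, fov)
    grid, tissue_mask = tile_fov(
        crop, fov.cluster_model, patch_size=config.patch_size,
        max_background=config.max_background,
    )
    til_map = compute_til_map(ckpt, grid, crop, tissue_mask)
    io.write_til_map(
        til_map, os.path.join(out_dir, f"{slide_id}_tilmap"),
        seed=config.seed, config=cfg_dict,
    )
    score = til_score(til_map)
    _log_stage(out_dir, slide_id, "segmentation", "ok",
               K=grid.K, til_score=score.value)

    vec = compute_feature_vector(
        til_map,
        min_fraction=config.min_til_fraction,
        preference=config.ap_preference,
        damping=config.ap_damping,
        max_iter=config.ap_max_iter,
        conv_iter=config.ap_conv_iter,
        seed=seeds["spatial"],
    )
    io.write_feature_vectors(
        {slide_id: vec}, os.path.join(out_dir, f"{slide_id}_features.csv"),
        seed=config.seed, config=cfg_dict,
    )
    if vec.clustering is not None and vec.n_points:
        from .tilspatial.features import select_til_patches

        pts = select_til_patches(til_map, config.min_til_fraction).points
        io.write_clustering(
            pts, vec.clustering,
            os.path.join(out_dir, f"{slide_id}_clusters.csv"),
            seed=config.seed, config=cfg_dict,
        )
    _log_stage(out_dir, slide_id, "spatial", "ok", n_points=vec.n_points)
    return fov, til_map, vec


def run_cohort(features: pd.DataFrame, clinical: pd.DataFrame,
               expression: pd.DataFrame, mutation: pd.DataFrame,
               config: PipelineConfig, out_dir):
    """Per-subtype association and survival reports.

    ``features`` is patients x spatial features (must include ``til_pct``).
    Patients missing from any table are excluded with a log entry. Writes
    per-subtype CSVs and returns a nested dict of results.
    """
    os.makedirs(out_dir, exist_ok=True)
    seeds = config.stage_seeds()
    cfg_dict = config.asdict()
    config.to_yaml(os.path.join(out_dir, "config_resolved.yaml"))

    ids = features.index.intersection(clinical.index)
    dropped = sorted(
        set(features.index) ^ set(clinical.index)
    )
    if dropped:
        _log_stage(out_dir, "cohort", "id-check", "warn",
                   mismatched_ids=dropped[:20], n_mismatched=len(dropped))
    groups = subtype_groups(clinical.loc[ids])
    results: dict = {}
    for subtype, pids in groups.items():
        if not pids:
            _log_stage(out_dir, "cohort", subtype, "skipped", reason="empty subtype")
            continue
        sub = {}
        til = clinical.loc[pids, "til_score"]
        expr_cols = expression.columns.intersection(pids)
        if len(expr_cols) >= 3:
            screen = spearman_screen(
                til, expression[expr_cols], threshold=config.spearman_threshold
            )
            screen.to_csv(
                os.path.join(out_dir, f"{_slug(subtype)}_expression_screen.csv"),
                index=False,
            )
            sub["expression_screen"] = screen
        mut_cols = mutation.columns.intersection(pids)
        if len(mut_cols):
            mt = mutation_test(til, mutation[mut_cols], min_mutated=config.min_mutated)
            mt.to_csv(
                os.path.join(out_dir, f"{_slug(subtype)}_mutation_test.csv"),
                index=False,
            )
            sub["mutation_test"] = mt
        time = clinical.loc[pids, "time"]
        event = clinical.loc[pids, "event"]
        feats = features.loc[pids]
        scans = {}
        for col in feats.columns:
            strat = univariate_cutoff_scan(
                feats[col], time, event,
                lo=config.cutoff_lo, hi=config.cutoff_hi, step=config.cutoff_step,
            )
            scans[col] = strat
        pd.DataFrame(
            [
                {"feature": col, "best_percentile": s.cutoff_percentile,
                 "best_p": s.p, "chi2": s.statistic}
                for col, s in scans.items()
            ]
        ).to_csv(
            os.path.join(out_dir, f"{_slug(subtype)}_univariate_scan.csv"),
            index=False,
        )
        sub["univariate"] = scans
        if event.sum() > 0 and feats.shape[1] >= 2:
            sub["kmeans_groups"] = multivariate_risk_groups(
                feats, time, event, seed=seeds["association"]
            )
            lasso = lasso_cox_select(feats, time, event, seed=seeds["association"])
            lasso.selected_features.to_csv(
                os.path.join(out_dir, f"{_slug(subtype)}_lasso_selected.csv"),
                index=False,
            )
            sub["lasso"] = lasso
        results[subtype] = sub
        _log_stage(out_dir, "cohort", subtype, "ok", n=len(pids))
    return results


def _slug(subtype: str) -> str:
    return subtype.lower().replace("-", "_")
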