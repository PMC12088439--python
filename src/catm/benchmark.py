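"""The simulation benchmark: TM versus CATM on synthetic condensates.

Runs the full replication: simulate tomograms with known ground truth,
run exhaustive template matching with a CCC-threshold sweep, run CATM from
segmentation-grade centroids, and score both against the ground truth on
position alone and on position plus orientation.  All randomness derives
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evaluate import (match_particles, orientation_distribution,
                       precision_recall_f1)
from .localize import emulate_segmentation_centroids, matched_filter_localize
from .matching import ccc_threshold_sweep, nms_distance_cutoff, tm_search
from .orientation import RotationGrid
from .particles import ParticleSet
from .placement import CatmConfig, run_catm
from .simulate import ImagingModel, SimulationConfig, generate_benchmark
from .templates import ParticleShape, build_nucleosome_template


@dataclass
class TomogramResult:
    seed: int
    tm_sweep_position: pd.DataFrame
    tm_sweep_angular: pd.DataFrame
    tm_max_f1_position: float
    tm_max_f1_angular: float
    catm_f1_position: float
    catm_f1_angular: float
    tm_particles: ParticleSet
    catm_particles: ParticleSet
    gt_particles: ParticleSet
    log: dict = field(default_factory=dict)


@dataclass
class BenchmarkResult:
    per_tomogram: list[TomogramResult]

    def summary(self) -> dict:
        def mean(attr):
            return float(np.mean([getattr(t, attr) for t in self.per_tomogram]))

        return {
            "tm_max_f1_position": mean("tm_max_f1_position"),
            "tm_max_f1_angular": mean("tm_max_f1_angular"),
            "catm_f1_position": mean("catm_f1_position"),
            "catm_f1_angular": mean("catm_f1_angular"),
            "n_tomograms": len(self.per_tomogram),
        }

    def pooled(self, which: str = "catm") -> ParticleSet:
        key = {"catm": "catm_particles", "tm": "tm_particles",
               "gt": "gt_particles"}[which]
        return ParticleSet.concat([getattr(t, key) for t in self.per_tomogram])


def _imaging_model(cfg: PipelineConfig) -> ImagingModel:
    im = cfg.imaging
    return ImagingModel(im.tilt_min, im.tilt_max, im.ctf_defocus_um,
                        im.ctf_voltage_kv, im.ctf_cs_mm,
                        im.ctf_amplitude_contrast, im.snr,
                        im.noise_correlation_nm)


def run_benchmark_tomogram(seed: int, cfg: PipelineConfig | None = None
                           ) -> TomogramResult:
    """Simulate one tomogram and run both assignment pipelines on it."""
    cfg = cfg or PipelineConfig()
    imaging = _imaging_model(cfg)
    sim = SimulationConfig(
        box_size=(cfg.simulation.box_size_nm,) * 3,
        voxel_size=cfg.simulation.voxel_size_nm,
        n_nucleosomes=cfg.simulation.n_nucleosomes,
        n_dna=cfg.simulation.n_dna, imaging=imaging, seed=seed)
    tomogram, gt, _ = generate_benchmark(sim)
    shape = ParticleShape("nucleosome_disc", cfg.template.diameter_nm,
                          cfg.template.height_nm)
    template = build_nucleosome_template(shape, cfg.simulation.voxel_size_nm)
    gt_nuc = gt.particles.of_kind("nucleosome_disc")

    # --- exhaustive TM with threshold sweep
    tm_grid = RotationGrid(cfg.tm.angular_step_deg)
    cands = tm_search(tomogram, template, tm_grid, imaging,
                      score_floor=cfg.tm.threshold_sweep_start)
    tm_pred = nms_distance_cutoff(cands, cfg.tm.nms_cutoff_nm)
    thresholds = np.arange(cfg.tm.threshold_sweep_start,
                           cfg.tm.threshold_sweep_stop,
                           cfg.tm.threshold_sweep_step)
    sweep_pos = ccc_threshold_sweep(tm_pred, gt, thresholds,
                                    dist_tol=cfg.evaluation.dist_tol_nm)
    sweep_ang = ccc_threshold_sweep(tm_pred, gt, thresholds,
                                    dist_tol=cfg.evaluation.dist_tol_nm,
                                    ang_tol=cfg.evaluation.ang_tol_deg)
    best_thr = float(sweep_pos[sweep_pos.is_max_f1].iloc[0].threshold)
    tm_best = tm_pred.select(tm_pred.scores >= best_thr)

    # --- CATM from segmentation-grade centroids
    ss = np.random.SeedSequence(seed)
    rng_cent = np.random.default_rng(ss.spawn(3)[2])
    if cfg.catm.centroid_source == "segmentation":
        centroids = emulate_segmentation_centroids(
            gt_nuc.positions, cfg.simulation.box_size_nm, rng_cent,
            jitter_nm=cfg.catm.centroid_jitter_nm,
            miss_rate=cfg.catm.centroid_miss_rate,
            extra_rate=cfg.catm.centroid_extra_rate)
    elif cfg.catm.centroid_source == "matched_filter":
        centroids = matched_filter_localize(tomogram, template, imaging)
    else:
        raise ValueError(f"unknown centroid source {cfg.catm.centroid_source!r}")
    catm_cfg = CatmConfig(
        search_radius_nm=cfg.catm.search_radius_nm,
        angular_step=cfg.catm.angular_step_deg,
        retain_threshold=cfg.catm.retain_threshold,
        clash_tolerance_fraction=cfg.catm.clash_tolerance_fraction,
        lowpass_sigma_nm=cfg.catm.lowpass_sigma_nm,
        mask_threshold_fraction=cfg.template.mask_threshold_fraction,
        mask_dilation_voxels=cfg.catm.mask_dilation_voxels)
    catm_pred, log = run_catm(tomogram, template, centroids, imaging, catm_cfg)

    f1p = precision_recall_f1(match_particles(
        gt_nuc, catm_pred, cfg.evaluation.dist_tol_nm))[2]
    f1a = precision_recall_f1(match_particles(
        gt_nuc, catm_pred, cfg.evaluation.dist_tol_nm,
        ang_tol=cfg.evaluation.ang_tol_deg))[2]
    log.update({"seed": seed, "tm_best_threshold": best_thr,
                "config_hash": cfg.config_hash(),
                "n_gt_nucleosomes": len(gt_nuc)})
    return TomogramResult(
        seed=seed,
        tm_sweep_position=sweep_pos, tm_sweep_angular=sweep_ang,
        tm_max_f1_position=float(sweep_pos.f1.max()),
        tm_max_f1_angular=float(sweep_ang.f1.max()),
        catm_f1_position=float(f1p), catm_f1_angular=float(f1a),
        tm_particles=tm_best, catm_particles=catm_pred,
        gt_particles=gt_nuc, log=log)


def run_benchmark(seed: int = 1, cfg: PipelineConfig | None = None,
                  n_tomograms: int | None = None,
                  progress: bool = False) -> BenchmarkResult:
    """Run the benchmark over ``n_tomograms`` tomograms (seeds seed..seed+n-1)."""
    cfg = cfg or PipelineConfig()
    n = n_tomograms if n_tomograms is not None else cfg.n_tomograms
    results = []
    for i in range(n):
        r = run_benchmark_tomogram(seed + i, cfg)
        if progress:
            print(f"tomogram seed={seed + i}: "
                  f"TM F1 {r.tm_max_f1_position:.3f}/{r.tm_max_f1_angular:.3f}  "
                  f"CATM F1 {r.catm_f1_position:.3f}/{r.catm_f1_angular:.3f}")
        results.append(r)
    return BenchmarkResult(results)


def orientation_diagnostics(result: BenchmarkResult) -> dict:
    """Pooled angle-to-z diagnostics for CATM, TM and ground truth."""
    out = {}
    for which in ("catm", "tm", "gt"):
        parts = result.pooled(which)
        if len(parts):
            out[which] = orientation_distribution(parts)
    return out
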