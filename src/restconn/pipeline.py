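"""End-to-end runner: synthetic cohort -> denoise -> maps -> prediction.

``run_full_pipeline`` ties the stages into the two analyses the package
exists for:

1. ROI selection (baseline obese-vs-lean contrast with permutation
   cluster FDR) followed by leave-one-participant-out prediction of
   weight change from each selected ROI's connectivity feature.
2. Interaction-derived ROI followed by the leptin-per-kg-fat vs
   connectivity-change correlation in the obese group.

Everything is deterministic given ``RunConfig.rng_seed``; outputs are a
directory of TSV tables, NIfTI maps and JSON summaries plus a manifest
with a config hash and per-stage counts so the exclusion and censoring
cascade is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import denoise as dn
from . import group_maps as gm
from . import hormones as hm
from . import io as rio
from . import prediction as pred
from .synthetic import (SESSIONS, BoldRun, CohortSpec, ParticipantRecord,
                        generate_bold_run, generate_cohort)

__all__ = ["RunConfig", "run_full_pipeline"]

log = logging.getLogger("restconn")


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the study's values."""

    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    out_dir: str = "restconn_out"
    band: tuple[float, float] = (0.01, 0.1)
    z_global: float = 3.0
    fd_mm: float = 0.5
    motion_exclude_mm: float = 3.5
    motion_criterion: str = "peak_translation_mm"
    erode_iterations: int = 1
    smooth_fwhm_mm: float = 0.0
    voxel_p: float = 0.001
    cluster_q: float = 0.05
    interaction_extent: int = 50
    cluster_connectivity: int = 6
    n_perm_cluster: int = 1000
    n_perm: int = 10_000
    loocv_intercept: bool = True
    feature: str = "change"  # or "level" (T0 value)
    hormone_roi_source: str = "interaction"  # or "baseline"
    save_maps: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError("band low must be below band high")
        for name in ("z_global", "fd_mm", "voxel_p", "cluster_q",
                     "motion_exclude_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.feature not in ("change", "level"):
            raise ValueError("feature must be 'change' or 'level'")
        if self.hormone_roi_source not in ("interaction", "baseline"):
            raise ValueError("hormone_roi_source must be 'interaction' or 'baseline'")
        if self.rng_seed is None:
            raise ValueError("rng_seed is required")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        cohort_cfg = cfg.pop("cohort", {})
        if "coupling_T0" in cohort_cfg:
            cohort_cfg["coupling_T0"] = {
                g: dict(rois) for g, rois in cohort_cfg["coupling_T0"].items()}
        if "grid_shape" in cohort_cfg:
            cohort_cfg["grid_shape"] = tuple(cohort_cfg["grid_shape"])
        if "band" in cfg:
            cfg["band"] = tuple(cfg["band"])
        return cls(cohort=CohortSpec(**cohort_cfg), **cfg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["grid_shape"] = list(self.cohort.grid_shape)
        d["band"] = list(self.band)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _denoise_one(run: BoldRun, config: RunConfig) -> dn.CleanRun:
    flags = dn.detect_outlier_volumes(run, config.z_global, config.fd_mm)
    wm = dn.erode_mask(run.masks["wm"], config.erode_iterations, "wm")
    csf = dn.erode_mask(run.masks["csf"], config.erode_iterations, "csf")
    design = dn.build_nuisance_design(run.motion,
                                      run.data[wm].mean(axis=0),
                                      run.data[csf].mean(axis=0), flags)
    if config.smooth_fwhm_mm > 0:
        data = np.empty_like(run.data)
        for t in range(run.n_volumes):
            data[..., t] = dn.smooth_volume(run.data[..., t],
                                            config.smooth_fwhm_mm, run.affine)
        run = BoldRun(data=data, tr_s=run.tr_s, motion=run.motion,
                      affine=run.affine, masks=run.masks)
    return dn.denoise_run(run, design, config.band)


def _connectivity_map(clean: dn.CleanRun, seed_mask: np.ndarray,
                      participant: str, session: str) -> conn.ConnectivityMap:
    series = conn.seed_mean_timecourse(clean, seed_mask)
    return conn.seed_to_voxel_map(clean, series, participant, session)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run both analyses on a synthetic cohort; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.cohort
    affine = spec.affine

    # --- cohort and runs -------------------------------------------------
    records = generate_cohort(spec)
    log.info("generated %d participants (%d lean, %d obese)",
             len(records), spec.n_lean, spec.n_obese)

    zmaps, groups, sessions, map_ids = [], [], [], []
    censored_per_run = {}
    excluded = []
    included: list[ParticipantRecord] = []
    seed_masks = None
    for rec in records:
        runs = {s: generate_bold_run(rec, s, spec) for s in SESSIONS}
        summary = dn.motion_summary(runs["T0"].motion)
        summary8 = dn.motion_summary(runs["T8"].motion)
        peak = {k: max(summary[k], summary8[k]) for k in summary}
        if dn.flag_high_motion(peak, config.motion_exclude_mm,
                               config.motion_criterion):
            rec.excluded = True
            rec.exclusion_reason = (f"head motion "
                                    f"({peak[config.motion_criterion]:.2f} mm)")
            excluded.append(rec)
            log.info("excluding %s: %s", rec.id, rec.exclusion_reason)
            continue
        included.append(rec)
        if seed_masks is None:
            seed_masks = runs["T0"].masks
        for s in SESSIONS:
            clean = _denoise_one(runs[s], config)
            censored_per_run[f"{rec.id}_{s}"] = int((~clean.retained).sum())
            cmap = _connectivity_map(clean, runs[s].masks["seed"], rec.id, s)
            zmaps.append(cmap.zgrid)
            groups.append(rec.group)
            sessions.append(s)
            map_ids.append(rec.id)
    rio.write_phenotypes(records, out / "phenotypes.tsv")

    zmaps = np.asarray(zmaps)
    groups_arr = np.asarray(groups)
    sessions_arr = np.asarray(sessions)

    # --- group maps and ROI selection (baseline data only) ---------------
    contrasts = gm.fit_group_time_model(zmaps, groups_arr, sessions_arr)
    t0 = contrasts["group_T0"]
    t0_maps = zmaps[sessions_arr == "T0"]
    t0_groups = groups_arr[sessions_arr == "T0"]
    null_rng = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=(3,)))
    null_extents = gm.permutation_null_extents(
        t0_maps, t0_groups, config.n_perm_cluster, config.voxel_p,
        config.cluster_connectivity, null_rng)
    rois = gm.select_obesity_sensitive_rois(
        t0.stat_grid, t0.df, null_extents, config.voxel_p, config.cluster_q,
        config.cluster_connectivity)
    roi_masks = {}
    cluster_rows = []
    for roi in rois:
        prefix = "obese_gt_lean" if roi.sign == "positive" else "obese_lt_lean"
        name = f"{prefix}_{sum(1 for r in roi_masks if r.startswith(prefix)) + 1}"
        roi_masks[name] = roi.mask
        peak_mm = (affine @ np.r_[roi.cluster.peak_index, 1.0])[:3]
        cluster_rows.append({
            "roi": name, "sign": roi.sign, "extent": roi.cluster.extent,
            "peak_i": roi.cluster.peak_index[0],
            "peak_j": roi.cluster.peak_index[1],
            "peak_k": roi.cluster.peak_index[2],
            "peak_x_mm": float(peak_mm[0]), "peak_y_mm": float(peak_mm[1]),
            "peak_z_mm": float(peak_mm[2]),
            "peak_t": roi.cluster.peak_value, "p": roi.cluster.p_value,
            "q": roi.cluster.q_value})
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if config.save_maps:
        rio.write_nifti(t0.stat_grid, affine, out / "tmap_group_T0.nii.gz")
        for name, mask in roi_masks.items():
            rio.write_nifti(mask.astype(float), affine, out / f"roi_{name}.nii.gz")

    # --- ROI features and LOOCV prediction --------------------------------
    id_index = {rec.id: rec for rec in included}
    feature_rows = []
    features_by_roi = {}
    for name, mask in roi_masks.items():
        z_by_id_sess = {}
        for k, grid in enumerate(zmaps):
            z_by_id_sess[(map_ids[k], sessions_arr[k])] = float(grid[mask].mean())
        for (pid, sess), z in sorted(z_by_id_sess.items()):
            feature_rows.append(conn.ConnectivityFeature(z, name, pid, sess))
        vec = []
        for rec in included:
            z0 = z_by_id_sess[(rec.id, "T0")]
            z8 = z_by_id_sess[(rec.id, "T8")]
            vec.append(z8 - z0 if config.feature == "change" else z0)
        features_by_roi[name] = np.asarray(vec)
    rio.write_features(feature_rows, out / "features.tsv")

    prediction_results = pred.predict_weight_change_pipeline(
        features_by_roi, included, n_perm=config.n_perm,
        seed=config.rng_seed, intercept=config.loocv_intercept)
    for name, res in prediction_results.items():
        pd.DataFrame({
            "participant": res.participants,
            "observed_kg": res.observed, "predicted_kg": res.predicted,
            "fold_beta0": [f.beta0 for f in res.fits],
            "fold_beta_roi": [f.beta_roi for f in res.fits],
        }).to_csv(out / f"prediction_{name}.tsv", sep="\t", index=False)

    # --- interaction ROI and hormone correlation --------------------------
    interaction_roi = None
    if "interaction" in contrasts:
        inter = contrasts["interaction"]
        interaction_roi = gm.select_interaction_roi(
            inter.stat_grid, inter.df, config.voxel_p,
            config.interaction_extent, config.cluster_connectivity)
        if config.save_maps:
            rio.write_nifti(inter.stat_grid, affine, out / "tmap_interaction.nii.gz")
    hormone_summary = None
    hormone_mask = None
    if config.hormone_roi_source == "interaction" and interaction_roi is not None:
        hormone_mask, hormone_roi_name = interaction_roi.mask, "interaction"
    else:
        neg = [m for n, m in roi_masks.items() if "lt" in n]
        hormone_mask = neg[0] if neg else None
        hormone_roi_name = "baseline"
        if config.hormone_roi_source == "interaction":
            log.warning("no interaction cluster reached extent %d; "
                        "falling back to baseline ROI", config.interaction_extent)
    if hormone_mask is not None:
        y_by_id = {}
        for rec in included:
            if rec.group != "obese":
                continue
            z = {}
            for k, grid in enumerate(zmaps):
                if map_ids[k] == rec.id:
                    z[sessions_arr[k]] = float(grid[hormone_mask].mean())
            y_by_id[rec.id] = z["T8"] - z["T0"]
        x, y, ids = hm.hormone_dataset(included, y_by_id)
        if x.size >= 4:
            stats_rng = np.random.default_rng(
                np.random.SeedSequence(config.rng_seed, spawn_key=(4,)))
            hs = hm.hormone_connectivity_correlation(x, y, ids,
                                                     n_perm=config.n_perm,
                                                     seed=stats_rng)
            pd.DataFrame({"participant": hs.participants,
                          "leptin_per_fat_ngml_kg": hs.x,
                          "z_change": hs.y}).to_csv(
                out / "hormones.tsv", sep="\t", index=False)
            hormone_summary = {
                "roi_source": hormone_roi_name, "n": len(hs.participants),
                "rho": hs.rho, "p_parametric": hs.p_parametric,
                "perm_low": hs.perm_low, "perm_high": hs.perm_high,
                "n_perm": hs.n_perm}
    change_table = hm.change_tests(included)
    change_table.to_csv(out / "change_tests.tsv", sep="\t", index=False)

    # --- summary and manifest ---------------------------------------------
    summary = {
        "prediction": {
            name: {"r": res.r, "p_parametric": res.p_parametric,
                   "perm_low": res.perm_low, "perm_high": res.perm_high,
                   "n_perm": res.n_perm, "n": len(res.participants),
                   "detected": bool(res.detected)}
            for name, res in prediction_results.items()},
        "hormones": hormone_summary,
        "clusters": cluster_rows,
    }
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "enrolled": len(records),
        "included": len(included),
        "excluded": len(excluded),
        "exclusions": {r.id: r.exclusion_reason for r in excluded},
        "censored_volumes": censored_per_run,
        "n_clusters_baseline": len(cluster_rows),
        "interaction_roi_extent": (int(interaction_roi.cluster.extent)
                                   if interaction_roi is not None else 0),
    }
    rio.write_summary_json(summary, out / "summary.json")
    rio.write_summary_json(manifest, out / "manifest.json")
    return {"summary": summary, "manifest": manifest,
            "records": records, "roi_masks": roi_masks}
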