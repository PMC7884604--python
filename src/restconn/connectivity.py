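"""Seed-to-voxel correlation maps and scalar ROI connectivity features.

The seed-mean BOLD course is correlated with every voxel's course over
retained volumes; Pearson r is Fisher-transformed (z = atanh r) to give
approximately normal connectivity maps.  A scalar feature per ROI is the
unweighted mean of z over the ROI's voxels, the quantity regressed
against weight change downstream.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .denoise import CleanRun

__all__ = [
    "ConnectivityMap",
    "ConnectivityFeature",
    "seed_mean_timecourse",
    "seed_to_voxel_map",
    "roi_mean_z",
]

#: |r| is clipped here before atanh so maps stay finite (seed-internal
#: voxels correlate perfectly with their own mean)
R_CLIP = 1.0 - 1e-6


@dataclasses.dataclass
class ConnectivityMap:
    """Voxel-wise Fisher-z map for one participant and session."""

    zgrid: np.ndarray
    participant: str = ""
    session: str = ""
    seed: str = "seed"
    n_retained: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.zgrid)):
            raise ValueError("connectivity map contains non-finite values")


@dataclasses.dataclass(frozen=True)
class ConnectivityFeature:
    """ROI-mean Fisher z for one participant and session."""

    value: float
    roi: str
    participant: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("connectivity feature must be finite")


def seed_mean_timecourse(clean: CleanRun, seed: np.ndarray) -> np.ndarray:
    """Unweighted mean course over seed voxels, retained volumes only."""
    seed = np.asarray(seed, dtype=bool)
    if seed.shape != clean.residuals.shape[:3]:
        raise ValueError("seed mask shape does not match run")
    if not seed.any():
        raise ValueError("seed mask is empty")
    return clean.residuals[seed][:, clean.retained].mean(axis=0)


def seed_to_voxel_map(clean: CleanRun, seed_series: np.ndarray,
                      participant: str = "", session: str = "",
                      seed: str = "seed") -> ConnectivityMap:
    """Fisher-z map of voxel-wise Pearson correlation with the seed course."""
    n_ret = clean.n_retained
    if seed_series.shape != (n_ret,):
        raise ValueError("seed series length must equal retained volume count")
    if n_ret < 10:
        raise ValueError(f"only {n_ret} retained volumes; need at least 10")

    shape = clean.residuals.shape[:3]
    Y = clean.residuals.reshape(-1, clean.retained.size)[:, clean.retained]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sc = seed_series - seed_series.mean()
    seed_norm = np.linalg.norm(sc)
    if seed_norm == 0:
        raise ValueError("seed series has zero variance")
    vox_norm = np.linalg.norm(Yc, axis=1)
    dead = vox_norm == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance voxel(s) set to z = 0")
        vox_norm[dead] = 1.0
    r = (Yc @ sc) / (vox_norm * seed_norm)
    r[dead] = 0.0
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return ConnectivityMap(zgrid=z.reshape(shape), participant=participant,
                           session=session, seed=seed, n_retained=n_ret)


def roi_mean_z(cmap: ConnectivityMap, roi: np.ndarray,
               roi_id: str = "roi") -> ConnectivityFeature:
    """Unweighted mean of the Fisher-z map over the ROI's voxels."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != cmap.zgrid.shape:
        raise ValueError("ROI mask shape does not match map")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    return ConnectivityFeature(value=float(cmap.zgrid[roi].mean()), roi=roi_id,
                               participant=cmap.participant,
                               session=cmap.session)
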