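"""Nuisance removal: outlier censoring, confound regression, band-pass.

The cleaning contract follows the standard seed-connectivity recipe:

* per-volume outlier detection from the global-signal z-score and the
  framewise displacement (FD) of the rigid-body motion trace;
* a confound design of 18 motion-derived regressors (6 parameters plus
  first and second backward differences), mean eroded white-matter and
  CSF signals, linear and quadratic trends, and one indicator column per
  censored volume;
* confound regression and 0.01-0.1 Hz band-pass performed in a single
  least-squares fit restricted to retained volumes, with the band-stop
  realized by augmenting the design with a discrete cosine basis whose
  frequencies lie outside the pass band.

Residuals are exactly orthogonal to the fitted design over retained
volumes, and censored volumes never re-enter downstream correlations.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .synthetic import BoldRun

__all__ = [
    "NuisanceDesign",
    "CleanRun",
    "framewise_displacement",
    "detect_outlier_volumes",
    "build_nuisance_design",
    "erode_mask",
    "denoise_run",
    "smooth_volume",
    "motion_summary",
    "flag_high_motion",
]

#: rotation-to-mm conversion: arc length on a 50 mm sphere, the dominant
#: convention in the motion-scrubbing literature
ROTATION_RADIUS_MM = 50.0


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Per-volume head displacement in mm.

    Sum of absolute backward differences of the three translations plus
    ``ROTATION_RADIUS_MM`` times the absolute rotation differences; the
    first element is 0 (no predecessor).  Invariant to adding a constant
    offset to the trace.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute displacement")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return fd


def _global_signal_z(data: np.ndarray) -> np.ndarray:
    """Z-score of the linearly detrended volume-mean intensity series."""
    gm = data.mean(axis=(0, 1, 2))
    t = np.arange(gm.size, dtype=float)
    resid = gm - np.polyval(np.polyfit(t, gm, 1), t)
    sd = resid.std(ddof=1)
    if sd == 0:
        return np.zeros_like(resid)
    return resid / sd


def detect_outlier_volumes(run: BoldRun, z_thresh: float = 3.0,
                           fd_thresh_mm: float = 0.5) -> np.ndarray:
    """Flag volumes with |global-signal z| > z_thresh or FD >= fd_thresh_mm."""
    if run.n_volumes < 2:
        raise ValueError("run too short for outlier detection")
    z = _global_signal_z(run.data)
    fd = framewise_displacement(run.motion)
    return (np.abs(z) > z_thresh) | (fd >= fd_thresh_mm)


@dataclasses.dataclass
class NuisanceDesign:
    """T x K confound matrix with column labels and censor flags."""

    matrix: np.ndarray
    column_labels: list[str]
    censored: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.censored.size, len(self.column_labels)):
            raise ValueError("design matrix / labels / censor length mismatch")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass
class CleanRun:
    """Denoised residual grid with retained-volume flags and pass band."""

    residuals: np.ndarray
    retained: np.ndarray
    band: tuple[float, float]
    tr_s: float = 2.0
    affine: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def _backward_diff(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    out[1:] = np.diff(x, axis=0)
    return out


def build_nuisance_design(motion: np.ndarray, wm_series: np.ndarray,
                          csf_series: np.ndarray,
                          outlier_flags: np.ndarray) -> NuisanceDesign:
    """Assemble the confound matrix.

    Columns: 6 motion parameters, their first and second backward
    differences (first row padded with 0), WM and CSF mean series,
    linear and quadratic trends, and a one-hot column per flagged
    volume; K = 22 + number of outliers.
    """
    motion = np.asarray(motion, dtype=float)
    wm_series = np.asarray(wm_series, dtype=float)
    csf_series = np.asarray(csf_series, dtype=float)
    outlier_flags = np.asarray(outlier_flags, dtype=bool)
    T = motion.shape[0]
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    for name, s in (("wm_series", wm_series), ("csf_series", csf_series),
                    ("outlier_flags", outlier_flags)):
        if s.shape != (T,):
            raise ValueError(f"{name} length {s.shape} != number of volumes {T}")

    d1 = _backward_diff(motion)
    d2 = _backward_diff(d1)
    lin = np.linspace(-1.0, 1.0, T)
    cols = [motion, d1, d2,
            wm_series[:, None], csf_series[:, None],
            lin[:, None], (lin**2)[:, None]]
    labels = ([f"motion_{i}" for i in range(6)]
              + [f"motion_d1_{i}" for i in range(6)]
              + [f"motion_d2_{i}" for i in range(6)]
              + ["wm", "csf", "trend_linear", "trend_quadratic"])
    for idx in np.flatnonzero(outlier_flags):
        onehot = np.zeros((T, 1))
        onehot[idx] = 1.0
        cols.append(onehot)
        labels.append(f"outlier_{idx}")
    return NuisanceDesign(matrix=np.hstack(cols), column_labels=labels,
                          censored=outlier_flags.copy())


def erode_mask(mask: np.ndarray, iterations: int = 1,
               name: str = "mask") -> np.ndarray:
    """6-connected binary erosion, erroring if the mask empties."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"{name} is empty before erosion")
    if iterations == 0:
        return mask.copy()
    structure = ndimage.generate_binary_structure(3, 1)
    out = ndimage.binary_erosion(mask, structure=structure,
                                 iterations=iterations, border_value=0)
    if not out.any():
        raise ValueError(f"{name} eroded to empty after {iterations} iteration(s)")
    return out


def _dct_stopband_basis(T: int, tr_s: float,
                        band: tuple[float, float]) -> np.ndarray:
    """DCT-II columns whose frequencies lie outside the pass band.

    Regressing these out removes out-of-band power (band-stop by
    regression), which together with censoring-aware fitting implements
    the simultaneous filter-and-regress step.
    """
    low, high = band
    t = np.arange(T)
    j = np.arange(1, T)
    freqs = j / (2.0 * T * tr_s)
    keep = (freqs < low) | (freqs > high)
    j = j[keep]
    return np.cos(np.pi * np.outer(2 * t + 1, j) / (2.0 * T))


def denoise_run(run: BoldRun, design: NuisanceDesign,
                band: tuple[float, float] = (0.01, 0.1)) -> CleanRun:
    """Confound regression + band-pass in one fit over retained volumes.

    The design is augmented with an intercept and the out-of-band cosine
    basis; zero-variance columns on the retained rows (e.g. derivatives
    of a still trace, or indicators of censored volumes) are dropped
    with a warning.  Residuals at censored volumes are set to 0 and
    excluded by the ``retained`` flags.
    """
    if design.n_volumes != run.n_volumes:
        raise ValueError("design rows do not match run length")
    T = run.n_volumes
    retained = ~design.censored
    X = np.hstack([np.ones((T, 1)), design.matrix,
                   _dct_stopband_basis(T, run.tr_s, band)])
    labels = (["intercept"] + design.column_labels
              + [f"dct_{k}" for k in range(X.shape[1] - 1 - len(design.column_labels))])
    Xr = X[retained]
    sd = Xr.std(axis=0)
    keep = (sd > 0) | (np.arange(X.shape[1]) == 0)  # intercept is constant
    dropped = [labels[k] for k in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance design column(s): "
                      + ", ".join(dropped[:8]) + ("..." if len(dropped) > 8 else ""))
    Xr = Xr[:, keep]
    n_ret = int(retained.sum())
    if n_ret < Xr.shape[1] + 10:
        raise ValueError(f"under-determined fit: {n_ret} retained volumes "
                         f"for {Xr.shape[1]} regressors")

    Y = run.data.reshape(-1, T).T[retained]  # (n_ret, V)
    beta, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
    resid = Y - Xr @ beta

    out = np.zeros((T, Y.shape[1]))
    out[retained] = resid
    residuals = out.T.reshape(run.data.shape)
    return CleanRun(residuals=residuals, retained=retained, band=band,
                    tr_s=run.tr_s, affine=run.affine)


def smooth_volume(grid: np.ndarray, fwhm_mm: float = 8.0,
                  affine: np.ndarray | None = None) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in mm.

    Voxel spacing is taken from the affine's column norms; ``fwhm_mm=0``
    is the identity.  Total intensity of interior signal is conserved.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    grid = np.asarray(grid, dtype=float)
    if affine is None:
        spacing = np.ones(3)
    else:
        spacing = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    if np.any(spacing <= 0):
        raise ValueError("non-positive voxel spacing in affine")
    if fwhm_mm == 0:
        return grid.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spacing
    return ndimage.gaussian_filter(grid, sigma=sigma_vox, mode="nearest")


def motion_summary(motion: np.ndarray) -> dict[str, float]:
    """Participant-level motion summary: peak |translation|, peak/mean FD."""
    motion = np.asarray(motion, dtype=float)
    fd = framewise_displacement(motion)
    return {
        "peak_translation_mm": float(np.abs(motion[:, :3]).max()),
        "peak_fd_mm": float(fd.max()),
        "mean_fd_mm": float(fd.mean()),
    }


def flag_high_motion(summary: dict[str, float], threshold_mm: float = 3.5,
                     criterion: str = "peak_translation_mm") -> bool:
    """Participant exclusion rule: peak motion at or above ``threshold_mm``.

    Defaults to peak absolute translation; ``peak_fd_mm`` is available
    as an alternative criterion.
    """
    if criterion not in summary:
        raise ValueError(f"unknown motion criterion {criterion!r}")
    return summary[criterion] >= threshold_mm
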