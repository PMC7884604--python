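"""Synthetic cohort and BOLD-run generator with planted ground truth.

Emulates a two-group (lean / obese) longitudinal resting-state study:
each participant has phenotypes (weight, serum leptin, body fat, insulin)
at two sessions (T0, before a weight-loss intervention; T8, eight months
after), and one 4D BOLD run per session on a small voxel grid carrying a
seed region whose coupling to two target regions ("vstr", "dlpfc") is
planted at configurable Pearson correlations.

Planted effect structure
------------------------
* Baseline seed-vstr coupling is weaker in the obese group than in lean
  controls; seed-dlpfc coupling is stronger (hyper-connectivity).
* Over the T0 -> T8 interval the obese group's seed-vstr coupling rises
  by a per-participant Fisher-z increment ``dz``; weight change is
  ``offset + slope * dz + noise`` so the connectivity change carries
  real predictive information about weight change.
* The dlpfc coupling does not change and carries no weight information:
  a planted null feature.
* Serum leptin is tied to body fat mass through a per-session slope, and
  the leptin lost per kilogram of fat is additionally coupled to ``dz``
  so the hormone-connectivity correlation has a planted positive sign.

All randomness flows from ``CohortSpec.rng_seed`` through
``numpy.random.SeedSequence`` spawn keys, so cohorts and runs are
bit-reproducible and each participant/session has an independent stream.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np

__all__ = [
    "CohortSpec",
    "ParticipantRecord",
    "BoldRun",
    "generate_cohort",
    "generate_bold_run",
    "inject_motion_spike",
    "default_masks",
    "bandlimited_noise",
]

GROUPS = ("lean", "obese")
SESSIONS = ("T0", "T8")
ROI_NAMES = ("vstr", "dlpfc")

#: fractional mask centres (x, y, z) and cube edge lengths, scaled to the grid
_MASK_LAYOUT = {
    "seed": ((0.25, 0.45, 0.25), 3),
    "vstr": ((0.65, 0.45, 0.30), 4),
    "dlpfc": ((0.50, 0.78, 0.65), 3),
    "wm": ((0.20, 0.20, 0.75), 5),
    "csf": ((0.80, 0.20, 0.75), 5),
}


def _default_coupling_T0() -> dict:
    return {
        "lean": {"vstr": 0.50, "dlpfc": 0.15},
        "obese": {"vstr": 0.20, "dlpfc": 0.35},
    }


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the emulated study: 30 lean and 14 obese female
    participants, 304 volumes acquired at TR = 2 s with the first five
    discarded, 3 mm isotropic voxels on a 20x20x20 grid, obese mean
    weight 119 kg at T0 dropping to ~85 kg at T8, fat mass 62 -> 42 kg
    and leptin 70 -> 25 ng/ml.
    """

    n_lean: int = 30
    n_obese: int = 14
    n_volumes_acquired: int = 304
    n_discard: int = 5
    tr_s: float = 2.0
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.0
    #: target seed-to-ROI-voxel Pearson r per group and ROI at baseline
    coupling_T0: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=_default_coupling_T0
    )
    #: mean / sd of the obese group's planted seed-vstr Fisher-z increase
    coupling_change_mean_z: float = 0.36
    coupling_change_sd_z: float = 0.15
    #: session-to-session Fisher-z jitter for couplings that do not change
    coupling_jitter_sd_z: float = 0.05
    #: kg weight change per unit planted Fisher-z change (beta_ROI)
    coupling_change_slope: float = -25.0
    #: deterministic obese group weight-change offset, kg
    weight_change_offset_obese_kg: float = -25.0
    noise_sd_kg: float = 4.0
    lean_weight_change_sd_kg: float = 2.0
    #: ng/ml serum leptin per kg body fat, per session
    leptin_fat_slope: float = 1.1
    leptin_fat_slope_T8: float = 0.6
    leptin_noise_sd: float = 4.0
    #: extra leptin lost per kg fat per unit planted z-change (plants the
    #: positive hormone-connectivity correlation)
    hormone_link: float = 4.0
    #: sd of the measurement noise on extracted ROI-mean z features
    feature_noise_sd_z: float = 0.1
    spike_rate: float = 0.005
    #: this many participants (in enumeration order) receive a slow >3.5 mm
    #: translation drift and should be excluded by the motion criterion
    n_high_motion: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lean <= 0 or self.n_obese <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_discard < 0 or self.n_discard >= self.n_volumes_acquired:
            raise ValueError("n_discard must be in [0, n_volumes_acquired)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be three axes of at least 8 voxels")
        for group, rois in self.coupling_T0.items():
            for roi, r in rois.items():
                if not abs(r) < 1:
                    raise ValueError(f"|coupling| must be < 1 ({group}/{roi}: {r})")
        for name in ("noise_sd_kg", "leptin_noise_sd", "coupling_change_sd_z",
                     "coupling_jitter_sd_z", "feature_noise_sd_z",
                     "lean_weight_change_sd_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.spike_rate < 1:
            raise ValueError("spike_rate must be a probability")
        if not 0 <= self.n_high_motion <= self.n_lean + self.n_obese:
            raise ValueError("n_high_motion out of range")

    @property
    def n_volumes_retained(self) -> int:
        return self.n_volumes_acquired - self.n_discard

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


@dataclasses.dataclass
class ParticipantRecord:
    """Phenotypes for one participant.

    Lean controls carry leptin at T0 only and no body-fat measurements
    (the emulated study performed body-composition scans and follow-up
    blood sampling only for the surgical group).  ``planted`` carries the
    generator's ground truth (couplings per session, z-change, noisy ROI
    features) and is ``None`` for records read from disk.
    """

    id: str
    group: str
    height_m: float
    weight_T0_kg: float
    weight_T8_kg: float
    leptin_T0: float
    leptin_T8: float | None = None
    body_fat_T0_kg: float | None = None
    body_fat_T8_kg: float | None = None
    insulin_T0: float | None = None
    insulin_T8: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    planted: dict | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.weight_T0_kg <= 0 or self.weight_T8_kg <= 0:
            raise ValueError("weights must be positive")
        if self.group == "obese":
            for f in ("leptin_T8", "body_fat_T0_kg", "body_fat_T8_kg"):
                if getattr(self, f) is None:
                    raise ValueError(f"obese record {self.id} missing {f}")

    @property
    def index(self) -> int:
        return int(self.id.rsplit("-", 1)[1])

    def bmi(self, session: str) -> float:
        w = self.weight_T0_kg if session == "T0" else self.weight_T8_kg
        return w / self.height_m**2

    def body_fat_pct(self, session: str) -> float | None:
        fat = self.body_fat_T0_kg if session == "T0" else self.body_fat_T8_kg
        if fat is None:
            return None
        w = self.weight_T0_kg if session == "T0" else self.weight_T8_kg
        return 100.0 * fat / w


@dataclasses.dataclass
class BoldRun:
    """One session's 4D BOLD grid with motion trace and masks.

    ``data`` is (X, Y, Z, T); ``motion`` is (T, 6) with translations in mm
    followed by rotations in radians; ``masks`` holds boolean grids for
    "seed", the target ROIs, "wm" and "csf".
    """

    data: np.ndarray
    tr_s: float
    motion: np.ndarray
    affine: np.ndarray
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (X, Y, Z, T)")
        if self.motion.shape != (self.data.shape[3], 6):
            raise ValueError("motion trace must be (T, 6)")
        for name, mask in self.masks.items():
            if mask.shape != self.data.shape[:3]:
                raise ValueError(f"mask {name!r} shape mismatch")
            if not mask.any():
                raise ValueError(f"mask {name!r} is empty")
        if "seed" in self.masks:
            for roi in ROI_NAMES:
                if roi in self.masks and (self.masks["seed"] & self.masks[roi]).any():
                    raise ValueError(f"seed and {roi} masks overlap")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def default_masks(grid_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Disjoint cubic masks (seed, vstr, dlpfc, wm, csf) scaled to the grid."""
    masks = {}
    dims = np.asarray(grid_shape)
    for name, (frac, size) in _MASK_LAYOUT.items():
        centre = np.asarray(frac) * dims
        start = np.clip(np.round(centre - size / 2).astype(int), 0, dims - size)
        m = np.zeros(grid_shape, dtype=bool)
        m[start[0]:start[0] + size,
          start[1]:start[1] + size,
          start[2]:start[2] + size] = True
        masks[name] = m
    occupancy = sum(m.astype(int) for m in masks.values())
    if occupancy.max() > 1:
        raise ValueError("mask layout overlaps on this grid; use a larger grid")
    return masks


def bandlimited_noise(rng: np.random.Generator, n_series: int, n_volumes: int,
                      tr_s: float, low_hz: float = 0.01,
                      high_hz: float = 0.1) -> np.ndarray:
    """Unit-variance Gaussian noise with spectral support in [low, high] Hz.

    Signals confined to the analysis pass band survive band-stop nuisance
    regression, so planted correlations are preserved through denoising.
    """
    white = rng.standard_normal((n_series, n_volumes))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_volumes, tr_s)
    spec[:, ~((freqs >= low_hz) & (freqs <= high_hz))] = 0.0
    out = np.fft.irfft(spec, n=n_volumes, axis=1)
    sd = out.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("pass band contains no Fourier bins for this run length")
    return out / sd


def _cohort_rng(spec: CohortSpec, i: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(0, i)))


def _run_rng(spec: CohortSpec, i: int, session: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(1, i, SESSIONS.index(session))))


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Generate phenotype records with planted connectivity ground truth.

    Obese weight change is ``offset + slope * dz + N(0, noise_sd_kg)``
    where ``dz`` is the participant's planted seed-vstr Fisher-z change;
    leptin is tied to fat mass per session, with the leptin-per-kg-fat
    ratio additionally coupled to ``dz`` through ``hormone_link``.
    """
    records = []
    n_total = spec.n_lean + spec.n_obese
    for i in range(n_total):
        group = "lean" if i < spec.n_lean else "obese"
        rng = _cohort_rng(spec, i)
        high_motion = i < spec.n_high_motion

        # planted Fisher-z couplings per ROI and session
        z0 = {roi: math.atanh(spec.coupling_T0[group][roi]) for roi in ROI_NAMES}
        if group == "obese":
            dz_vstr = rng.normal(spec.coupling_change_mean_z,
                                 spec.coupling_change_sd_z)
        else:
            dz_vstr = rng.normal(0.0, spec.coupling_jitter_sd_z)
        dz_dlpfc = rng.normal(0.0, spec.coupling_jitter_sd_z)
        dz = {"vstr": dz_vstr, "dlpfc": dz_dlpfc}
        coupling = {
            roi: {"T0": math.tanh(z0[roi]), "T8": math.tanh(z0[roi] + dz[roi])}
            for roi in ROI_NAMES
        }
        # noisy ROI-mean z features, as a downstream feature extractor
        # would measure them from a finite run
        features = {
            roi: {s: z0[roi] + (dz[roi] if s == "T8" else 0.0)
                  + rng.normal(0.0, spec.feature_noise_sd_z)
                  for s in SESSIONS}
            for roi in ROI_NAMES
        }

        height = rng.normal(1.65, 0.06)
        if group == "lean":
            w0 = rng.normal(62.0, 6.0)
            dw = rng.normal(0.0, spec.lean_weight_change_sd_kg)
            record = ParticipantRecord(
                id=f"sub-{i:03d}", group=group, height_m=height,
                weight_T0_kg=w0, weight_T8_kg=w0 + dw,
                leptin_T0=max(0.5, rng.normal(9.0, 4.0)),
                insulin_T0=max(0.5, rng.normal(4.0, 2.0)),
            )
        else:
            w0 = rng.normal(119.0, 11.0)
            dw = (spec.weight_change_offset_obese_kg
                  + spec.coupling_change_slope * dz_vstr
                  + (rng.normal(0.0, spec.noise_sd_kg) if spec.noise_sd_kg else 0.0))
            fat0 = rng.normal(62.0, 9.0)
            fat_loss = rng.normal(20.0, 3.0)
            fat8 = max(5.0, fat0 - fat_loss)
            lep0 = max(0.5, spec.leptin_fat_slope * fat0
                       + rng.normal(0.0, spec.leptin_noise_sd))
            lep8 = max(0.5, spec.leptin_fat_slope_T8 * fat8
                       - spec.hormone_link * (dz_vstr - spec.coupling_change_mean_z)
                       * (fat0 - fat8)
                       + rng.normal(0.0, spec.leptin_noise_sd))
            record = ParticipantRecord(
                id=f"sub-{i:03d}", group=group, height_m=height,
                weight_T0_kg=w0, weight_T8_kg=max(40.0, w0 + dw),
                leptin_T0=lep0, leptin_T8=lep8,
                body_fat_T0_kg=fat0, body_fat_T8_kg=fat8,
                insulin_T0=max(0.5, rng.normal(28.0, 8.0)),
                insulin_T8=max(0.5, rng.normal(10.0, 3.0)),
            )
        record.planted = {
            "coupling": coupling,
            "delta_z": dz,
            "features": features,
            "high_motion": high_motion,
        }
        records.append(record)
    return records


def _motion_trace(rng: np.random.Generator, n_volumes: int,
                  high_motion: bool) -> np.ndarray:
    trans = np.cumsum(rng.normal(0.0, 0.01, (n_volumes, 3)), axis=0)
    rots = np.cumsum(rng.normal(0.0, 1e-4, (n_volumes, 3)), axis=0)
    if high_motion:
        # slow 4 mm excursion: excludes the participant (peak >= 3.5 mm)
        # without tripping the per-volume displacement censor
        t = np.arange(n_volumes)
        trans[:, 0] += 4.0 * np.sin(np.pi * t / n_volumes)
    return np.hstack([trans, rots])


def generate_bold_run(record: ParticipantRecord, session: str,
                      spec: CohortSpec) -> BoldRun:
    """Synthesize one session's 4D run realizing the record's planted coupling.

    Seed voxels share a band-limited latent course; each target-ROI voxel
    mixes that latent with band-limited voxel noise, calibrated so its
    expected Pearson correlation with the seed-mean course equals the
    planted per-voxel coupling.  Background voxels carry broadband noise,
    a slow linear drift and a shared global fluctuation; WM/CSF voxels
    share tissue-specific nuisance courses.
    """
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}")
    if record.planted is None:
        raise ValueError("record carries no planted ground truth")
    T = spec.n_volumes_retained
    shape = spec.grid_shape
    masks = default_masks(shape)
    rng = _run_rng(spec, record.index, session)

    latent = bandlimited_noise(rng, 1, T, spec.tr_s)[0]
    amplitude = 2.0
    data = np.empty(shape + (T,), dtype=np.float64)

    # background: white noise + per-voxel linear drift
    n_vox = int(np.prod(shape))
    noise = rng.standard_normal((n_vox, T))
    tline = np.linspace(-1.0, 1.0, T)
    slopes = rng.normal(0.0, 0.25, (n_vox, 1))
    data.reshape(n_vox, T)[:] = 1000.0 + noise + slopes * tline

    # shared global fluctuation on non-seed/non-ROI tissue only, so the
    # planted coupling calibration is exact for seed and ROI voxels
    signal_vox = masks["seed"].copy()
    for roi in ROI_NAMES:
        signal_vox |= masks[roi]
    # tails clipped so a clean run's global-signal z stays under the
    # censoring threshold by construction
    global_sig = 0.3 * np.clip(rng.standard_normal(T), -2.5, 2.5)
    data[~signal_vox] += global_sig

    # tissue nuisance courses
    for tissue in ("wm", "csf"):
        course = bandlimited_noise(rng, 1, T, spec.tr_s, 0.0, 0.05)[0]
        data[masks[tissue]] += 1.5 * course

    # seed: shared latent plus small band-limited voxel noise
    m_seed = int(masks["seed"].sum())
    seed_noise = bandlimited_noise(rng, m_seed, T, spec.tr_s)
    data[masks["seed"]] = 1000.0 + amplitude * (latent + 0.1 * seed_noise)

    # target ROIs: calibrated mixture so corr(voxel, seed mean) = planted r
    seed_mean_sd = math.sqrt(1.0 + 0.01 / m_seed)
    for roi in ROI_NAMES:
        r = record.planted["coupling"][roi][session]
        a = r * seed_mean_sd
        if not abs(a) < 1:
            raise ValueError(f"coupling {r} for {roi} not realizable")
        m_roi = int(masks[roi].sum())
        vox_noise = bandlimited_noise(rng, m_roi, T, spec.tr_s)
        data[masks[roi]] = 1000.0 + amplitude * (
            a * latent + math.sqrt(1.0 - a * a) * vox_noise)

    motion = _motion_trace(rng, T, record.planted.get("high_motion", False))
    run = BoldRun(data=data, tr_s=spec.tr_s, motion=motion,
                  affine=spec.affine, masks=masks)

    if spec.spike_rate > 0:
        spike_at = np.flatnonzero(rng.random(T) < spec.spike_rate)
        spike_at = spike_at[(spike_at > 0) & (spike_at < T - 1)]
        mags = rng.uniform(0.6, 1.2, spike_at.size)
        for idx, mag in zip(spike_at, mags):
            # out-and-back pulse: displacement does not accumulate, so
            # spontaneous spikes never trip the participant-level
            # peak-translation exclusion
            run = inject_motion_spike(run, int(idx), float(mag))
            run = inject_motion_spike(run, int(idx) + 1, -float(mag))
    return run


def inject_motion_spike(run: BoldRun, volume_index: int,
                        magnitude_mm: float) -> BoldRun:
    """Add a step displacement of ``magnitude_mm`` at ``volume_index``.

    The x-translation shifts by the magnitude from the given volume
    onward (one framewise-displacement excursion), and the same volume's
    intensities are disturbed proportionally.  ``magnitude_mm = 0``
    returns an identical copy.
    """
    if not 0 < volume_index < run.n_volumes:
        raise ValueError(f"volume_index {volume_index} out of range "
                         f"(1..{run.n_volumes - 1})")
    motion = run.motion.copy()
    data = run.data.copy()
    motion[volume_index:, 0] += magnitude_mm
    data[..., volume_index] += magnitude_mm
    return BoldRun(data=data, tr_s=run.tr_s, motion=motion,
                   affine=run.affine, masks=run.masks)
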