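"""Denoising contracts: FD, censoring, confound design, band-stop fit."""

import numpy as np
import pytest

from restconn import denoise as dn
from restconn.synthetic import bandlimited_noise, inject_motion_spike


def _still_trace(T: int) -> np.ndarray:
    return np.zeros((T, 6))


class TestFramewiseDisplacement:
    def test_constant_trace_is_zero(self):
        motion = np.tile([1.0, -2.0, 0.5, 0.01, 0.0, -0.02], (50, 1))
        assert np.allclose(dn.framewise_displacement(motion), 0.0)

    def test_translation_step(self):
        motion = _still_trace(10)
        motion[5:, :3] += [0.2, 0.2, 0.1]
        fd = dn.framewise_displacement(motion)
        assert fd[0] == 0.0
        assert fd[5] == pytest.approx(0.5)
        assert np.all(fd >= 0)

    def test_rotation_step_uses_50mm_arm(self):
        motion = _still_trace(10)
        motion[3:, 4] += 0.01
        assert dn.framewise_displacement(motion)[3] == pytest.approx(0.5)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        motion = rng.normal(size=(30, 6))
        shifted = motion + np.array([3.0, -1.0, 2.0, 0.1, 0.2, -0.1])
        assert np.allclose(dn.framewise_displacement(motion),
                           dn.framewise_displacement(shifted))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            dn.framewise_displacement(np.zeros((1, 6)))


class TestOutlierDetection:
    def test_clean_run_has_no_flags(self, still_run):
        assert dn.detect_outlier_volumes(still_run).sum() == 0

    def test_motion_spike_is_flagged(self, still_run):
        spiked = inject_motion_spike(still_run, 40, 1.2)
        flags = dn.detect_outlier_volumes(spiked)
        assert flags[40]

    def test_global_signal_spike_is_flagged(self, still_run):
        data = still_run.data.copy()
        gm = data.mean(axis=(0, 1, 2))
        t = np.arange(gm.size, dtype=float)
        resid = gm - np.polyval(np.polyfit(t, gm, 1), t)
        data[..., 100] += 4.0 * resid.std(ddof=1)
        run = type(still_run)(data=data, tr_s=still_run.tr_s,
                              motion=still_run.motion, affine=still_run.affine,
                              masks=still_run.masks)
        flags = dn.detect_outlier_volumes(run)
        assert flags[100]


class TestNuisanceDesign:
    def test_column_count_with_outliers(self):
        T = 40
        rng = np.random.default_rng(1)
        flags = np.zeros(T, bool)
        flags[[7, 21]] = True
        design = dn.build_nuisance_design(rng.normal(size=(T, 6)),
                                          rng.normal(size=T),
                                          rng.normal(size=T), flags)
        # 18 motion + wm + csf + 2 trends + 2 outlier indicators
        assert design.matrix.shape == (T, 24)
        assert design.column_labels.count("wm") == 1
        assert sum(l.startswith("motion") for l in design.column_labels) == 18

    def test_constant_motion_gives_zero_derivatives(self):
        T = 30
        design = dn.build_nuisance_design(np.ones((T, 6)), np.zeros(T),
                                          np.zeros(T), np.zeros(T, bool))
        d_cols = [k for k, l in enumerate(design.column_labels) if "_d" in l]
        assert len(d_cols) == 12
        assert np.allclose(design.matrix[:, d_cols], 0.0)

    def test_outlier_indicator_is_one_hot(self):
        T = 20
        flags = np.zeros(T, bool)
        flags[4] = True
        design = dn.build_nuisance_design(np.zeros((T, 6)), np.zeros(T),
                                          np.zeros(T), flags)
        col = design.matrix[:, design.column_labels.index("outlier_4")]
        assert col.sum() == 1.0 and col[4] == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            dn.build_nuisance_design(np.zeros((10, 6)), np.zeros(9),
                                     np.zeros(10), np.zeros(10, bool))


class TestErosion:
    def test_solid_cube_loses_its_shell(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[2:7, 2:7, 2:7] = True
        out = dn.erode_mask(mask, 1)
        expected = np.zeros_like(mask)
        expected[3:6, 3:6, 3:6] = True
        assert np.array_equal(out, expected)
        assert out.sum() == 27

    def test_single_voxel_erodes_to_empty(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError, match="eroded to empty"):
            dn.erode_mask(mask, 1)

    def test_zero_iterations_is_identity(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        assert np.array_equal(dn.erode_mask(mask, 0), mask)

    def test_anti_extensive(self):
        rng = np.random.default_rng(2)
        mask = rng.random((8, 8, 8)) < 0.6
        mask[3:6, 3:6, 3:6] = True  # solid core keeps the result nonempty
        out = dn.erode_mask(mask, 1)
        assert (out <= mask).all() and out.sum() < mask.sum()


@pytest.fixture(scope="module")
def denoised(still_run):
    run = still_run
    flags = dn.detect_outlier_volumes(run)
    wm = dn.erode_mask(run.masks["wm"], 1)
    csf = dn.erode_mask(run.masks["csf"], 1)
    design = dn.build_nuisance_design(run.motion, run.data[wm].mean(axis=0),
                                      run.data[csf].mean(axis=0), flags)
    return run, design, dn.denoise_run(run, design)


class TestDenoiseRun:
    def test_residuals_orthogonal_to_design(self, denoised):
        run, design, clean = denoised
        retained = clean.retained
        X = design.matrix[retained]
        keep = X.std(axis=0) > 0
        Xc = X[:, keep] - X[:, keep].mean(axis=0)
        rng = np.random.default_rng(3)
        vox = rng.choice(np.prod(run.data.shape[:3]), 200, replace=False)
        R = clean.residuals.reshape(-1, run.n_volumes)[vox][:, retained]
        Rc = R - R.mean(axis=1, keepdims=True)
        num = np.abs(Rc @ Xc)
        denom = np.outer(np.linalg.norm(Rc, axis=1),
                         np.linalg.norm(Xc, axis=0))
        assert (num / denom).max() < 1e-6

    def test_out_of_band_sinusoid_removed(self, still_run):
        run = still_run
        data = run.data.copy()
        t = np.arange(run.n_volumes) * run.tr_s
        data[3, 3, 3, :] = 1000.0 + 5.0 * np.sin(2 * np.pi * 0.2 * t)
        mod = type(run)(data=data, tr_s=run.tr_s, motion=run.motion,
                        affine=run.affine, masks=run.masks)
        design = dn.build_nuisance_design(
            run.motion, data[dn.erode_mask(run.masks["wm"])].mean(axis=0),
            data[dn.erode_mask(run.masks["csf"])].mean(axis=0),
            dn.detect_outlier_volumes(mod))
        clean = dn.denoise_run(mod, design)
        inp = data[3, 3, 3, clean.retained]
        out = clean.residuals[3, 3, 3, clean.retained]
        assert out.var() < 0.05 * inp.var()

    def test_design_column_voxel_fits_perfectly(self, denoised):
        run, design, _ = denoised
        data = run.data.copy()
        data[1, 1, 1, :] = design.matrix[:, 0]  # a motion regressor
        mod = type(run)(data=data, tr_s=run.tr_s, motion=run.motion,
                        affine=run.affine, masks=run.masks)
        clean = dn.denoise_run(mod, design)
        assert np.abs(clean.residuals[1, 1, 1, clean.retained]).max() < 1e-8

    def test_in_band_signal_survives(self, still_run):
        """A pass-band voxel orthogonal to the confounds keeps its shape.

        The probe lives in the filter's own in-band subspace (cosine
        modes with 0.01 < f < 0.1 Hz) and is orthogonalized against the
        nuisance columns — the contract's precondition — before
        insertion; the band-stop fit must then leave it intact."""
        run = still_run
        T = run.n_volumes
        rng = np.random.default_rng(4)
        t = np.arange(T)
        j = np.arange(1, T)
        freqs = j / (2.0 * T * run.tr_s)
        j = j[(freqs > 0.015) & (freqs < 0.09)]
        basis = np.cos(np.pi * np.outer(2 * t + 1, j) / (2.0 * T))
        sig = basis @ rng.normal(size=j.size)
        design = dn.build_nuisance_design(
            run.motion, run.data[dn.erode_mask(run.masks["wm"])].mean(axis=0),
            run.data[dn.erode_mask(run.masks["csf"])].mean(axis=0),
            dn.detect_outlier_volumes(run))
        # orthogonal to the design means orthogonal to everything the fit
        # can remove: confounds AND their in-band content (an in-band
        # probe correlated with in-band motion content is nuisance)
        X = np.column_stack([np.ones(T), design.matrix,
                             dn._dct_stopband_basis(T, run.tr_s, (0.01, 0.1))])
        sig = sig - X @ np.linalg.lstsq(X, sig, rcond=None)[0]
        data = run.data.copy()
        data[2, 2, 2, :] = 1000.0 + 5.0 * sig / sig.std()
        mod = type(run)(data=data, tr_s=run.tr_s, motion=run.motion,
                        affine=run.affine, masks=run.masks)
        clean = dn.denoise_run(mod, design)
        inp = data[2, 2, 2, clean.retained]
        out = clean.residuals[2, 2, 2, clean.retained]
        assert np.corrcoef(inp, out)[0, 1] > 0.95

    def test_broadband_noise_attenuated_out_of_band(self, denoised):
        """Residual power outside the pass band drops >= 20x on
        broadband-noise voxels."""
        run, design, clean = denoised
        retained = clean.retained
        freqs = np.fft.rfftfreq(run.n_volumes, run.tr_s)
        out_band = (freqs > 0.12) | ((freqs < 0.008) & (freqs > 0))
        vox = [(0, 0, 0), (5, 0, 9), (11, 11, 11)]
        for v in vox:
            inp = run.data[v][retained] - run.data[v][retained].mean()
            out = clean.residuals[v][retained]
            # compare power in out-of-band bins (retained-volume FFT is an
            # approximation; censored volumes are few in a still run)
            p_in = np.abs(np.fft.rfft(inp, n=run.n_volumes))[out_band] ** 2
            p_out = np.abs(np.fft.rfft(out, n=run.n_volumes))[out_band] ** 2
            assert p_out.sum() < p_in.sum() / 20

    def test_underdetermined_fit_raises(self, still_run):
        run = still_run
        flags = np.ones(run.n_volumes, bool)
        flags[:40] = False  # keep too few volumes
        design = dn.build_nuisance_design(run.motion,
                                          np.zeros(run.n_volumes),
                                          np.zeros(run.n_volumes), flags)
        with pytest.raises(ValueError, match="under-determined"):
            dn.denoise_run(run, design)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(5)
        grid = rng.normal(size=(8, 8, 8))
        assert np.array_equal(dn.smooth_volume(grid, 0.0), grid)

    def test_impulse_centre_weight_matches_discrete_kernel(self):
        """Closed-form oracle: the smoothed unit impulse equals the cube of
        the normalized 1D Gaussian centre weight."""
        fwhm, spacing = 8.0, 3.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / spacing
        radius = int(4 * sigma + 0.5)
        k = np.exp(-np.arange(-radius, radius + 1) ** 2 / (2 * sigma**2))
        w0 = k[radius] / k.sum()
        grid = np.zeros((15, 15, 15))
        grid[7, 7, 7] = 1.0
        affine = np.diag([spacing] * 3 + [1.0])
        out = dn.smooth_volume(grid, fwhm, affine)
        assert out[7, 7, 7] == pytest.approx(w0**3, rel=1e-6)
        assert out.sum() == pytest.approx(1.0, rel=1e-3)

    def test_constant_grid_unchanged(self):
        grid = np.full((10, 10, 10), 7.0)
        assert np.allclose(dn.smooth_volume(grid, 8.0, np.diag([3., 3, 3, 1])),
                           7.0)

    def test_negative_fwhm_raises(self):
        with pytest.raises(ValueError):
            dn.smooth_volume(np.zeros((4, 4, 4)), -1.0)
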