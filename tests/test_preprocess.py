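"""Preprocessing primitives: outliers, detrend, smooth, filter, regress,
register, resample."""

import numpy as np
import pytest

import phmri
from phmri import AffineTransform, PhmriSimConfig
from phmri.preprocess import (
    FWHM_TO_SIGMA,
    bandpass,
    build_nuisance_design,
    centred_affine,
    detect_motion_outliers,
    detrend,
    gaussian_smooth,
    nuisance_regress,
    register_affine,
    resample_trilinear,
)

from conftest import make_scan


class TestMotionOutliers:
    def test_constant_series_unflagged(self):
        scan = make_scan(np.full((4, 4, 2, 20), 100.0))
        flags = detect_motion_outliers(scan, threshold=5.0)
        assert not flags.any()

    def test_single_inflated_acquisition_flagged(self, rng):
        data = rng.normal(1000, 1.0, size=(5, 5, 3, 40))
        g_sd = data.mean(axis=(0, 1, 2)).std()
        data[..., 17] += 10 * g_sd
        scan = make_scan(data)
        flags = detect_motion_outliers(scan, threshold=5.0)
        assert flags[17] and flags.sum() == 1

    def test_detects_simulated_spikes(self, small_atlas):
        cfg = PhmriSimConfig(motion_spike_prob=0.02, drift_slope=0.0)
        scan, truth = phmri.simulate_phmri_subject(small_atlas, cfg, "vehicle", seed=31)
        injected = set(truth.spike_acquisitions)
        assert injected
        scan.outlier_flags = np.zeros(scan.n_acquisitions, dtype=bool)
        flags = detect_motion_outliers(scan, threshold=5.0)
        assert injected <= set(np.flatnonzero(flags))

    def test_empty_mask_errors(self):
        scan = make_scan(np.zeros((3, 3, 2, 15)), mask=np.zeros((3, 3, 2), bool))
        with pytest.raises(ValueError, match="mask"):
            detect_motion_outliers(scan)


class TestDetrend:
    def test_pure_line_removed(self):
        assert np.allclose(detrend(np.array([1.0, 2.0, 3.0])), 0.0)

    def test_full_period_cosine_preserved(self):
        n, k = 120, 4
        t = np.arange(n)
        # symmetric about the series midpoint -> exactly orthogonal to a line
        wave = np.cos(2 * np.pi * k * (t - (n - 1) / 2) / n)
        line = 3.0 + 0.05 * t
        out = detrend(wave + line)
        assert np.max(np.abs(out - wave)) < 1e-9

    def test_idempotent(self, rng):
        x = rng.standard_normal((10, 50))
        once = detrend(x)
        assert np.allclose(detrend(once), once, atol=1e-10)


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self, rng):
        v = rng.standard_normal((6, 6, 4))
        assert np.array_equal(gaussian_smooth(v, 0.0, (1, 1, 1)), v)

    def test_constant_volume_unchanged(self):
        v = np.full((8, 8, 6), 7.0)
        assert np.allclose(gaussian_smooth(v, 0.8, (0.3125, 0.3125, 0.3125)), 7.0)

    def test_impulse_profile_has_expected_sigma(self):
        vox = 0.3125
        sigma = 0.8 * FWHM_TO_SIGMA / vox  # voxel units
        v = np.zeros((31, 31, 31))
        v[15, 15, 15] = 1.0
        sm = gaussian_smooth(v, 0.8, (vox, vox, vox))
        prof = sm[:, 15, 15]
        # recover sigma from the log-curvature at the peak
        curv = np.log(prof[16]) - 2 * np.log(prof[15]) + np.log(prof[14])
        sigma_est = np.sqrt(-1.0 / curv)
        assert abs(sigma_est - sigma) / sigma < 0.02

    def test_mean_preserved_in_interior(self, rng):
        v = rng.standard_normal((20, 20, 20)) + 5.0
        sm = gaussian_smooth(v, 1.0, (1, 1, 1))
        assert abs(sm.mean() - v.mean()) / abs(v.mean()) < 1e-6

    def test_negative_fwhm_errors(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((4, 4, 4)), -1.0, (1, 1, 1))


class TestBandpass:
    def _ratio(self, freq, tr=1.0, n=1200):
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, tr)
        core = slice(n // 4, 3 * n // 4)  # avoid edge transients
        return y[core].std() / x[core].std()

    def test_passband_preserved(self):
        assert self._ratio(0.05) >= 0.9

    def test_low_stopband_suppressed(self):
        assert self._ratio(0.005) <= 0.1

    def test_high_stopband_suppressed(self):
        assert self._ratio(0.2) <= 0.1

    def test_dc_removed(self):
        y = bandpass(np.full(500, 42.0), 1.0)
        assert np.max(np.abs(y)) < 1e-6

    def test_above_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(100), tr_seconds=6.0, high_hz=0.1)


class TestNuisanceRegress:
    def _scan(self, rng, n_t=80):
        data = rng.normal(1000, 1, size=(4, 4, 2, n_t))
        wm = rng.standard_normal(n_t)
        csf = rng.standard_normal(n_t)
        motion = rng.standard_normal((n_t, 6)) * 1e-3
        return make_scan(data, motion_params=motion,
                         tissue_means={"white_matter": wm, "csf": csf})

    def test_perfect_regressor_removed(self, rng):
        scan = self._scan(rng)
        scan.data[2, 2, 1, :] = 500 + 3.0 * scan.tissue_means["white_matter"]
        resid = nuisance_regress(scan)
        assert np.max(np.abs(resid[2, 2, 1])) < 1e-8

    def test_residuals_orthogonal_to_design(self, rng):
        scan = self._scan(rng)
        scan.outlier_flags[10] = True
        X, _ = build_nuisance_design(scan)
        resid = nuisance_regress(scan)[scan.mask]
        dots = np.abs(X.T @ resid.T)
        scale = np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(resid, axis=1)[None, :]
        assert np.max(dots / scale) < 1e-6

    def test_flagged_spike_absorbed(self, rng):
        scan = self._scan(rng)
        scan.data[..., 25] += 500.0
        scan.outlier_flags[25] = True
        resid = nuisance_regress(scan)[scan.mask]
        # the indicator column zeroes that timepoint's residual exactly
        assert np.max(np.abs(resid[:, 25])) < 1e-8

    def test_collinear_column_dropped_with_warning(self, rng):
        scan = self._scan(rng)
        scan.tissue_means["csf"] = scan.tissue_means["white_matter"] * 2.0
        with pytest.warns(UserWarning, match="collinear"):
            X, names = build_nuisance_design(scan)
        assert "csf" not in names


_PHANTOM_SHAPE = (28, 28, 14)


def _phantom_func(w: np.ndarray) -> np.ndarray:
    """Continuous brain-like phantom: smooth ellipsoidal envelope with a
    fixed multi-cosine internal texture; evaluable at any world point."""
    centre = (np.asarray(_PHANTOM_SHAPE, dtype=float) - 1) / 2
    semi = 0.4 * np.asarray(_PHANTOM_SHAPE, dtype=float)
    u = (w - centre) / semi
    r2 = (u**2).sum(axis=-1)
    x, y, z = w[..., 0], w[..., 1], w[..., 2]
    texture = (np.cos(0.9 * x + 0.2) + np.cos(0.7 * y + 1.1)
               + np.cos(1.1 * z + 0.4) + np.cos(0.5 * (x + y) + 0.8))
    return np.exp(-r2) * (1.0 + 0.15 * texture)


def _phantom_pair(true: AffineTransform):
    """Sample reference and moving images of the same continuous object:
    the moving frame is related to the reference frame by ``true``."""
    grid = np.moveaxis(np.indices(_PHANTOM_SHAPE, dtype=float), 0, -1)
    ref = _phantom_func(grid)
    moving = _phantom_func(true.apply(grid.reshape(-1, 3)).reshape(grid.shape))
    return moving, ref


class TestRegisterAffine:
    def test_identity_recovered(self):
        moving, ref = _phantom_pair(AffineTransform.identity())
        T = register_affine(moving, ref)
        assert np.all(np.abs(T.decompose()["translation"]) < 0.1)

    def test_known_shift_recovered(self):
        true = AffineTransform.from_params(translation_mm=(2.0, 1.0, 0.0))
        moving, ref = _phantom_pair(true)
        T = register_affine(moving, ref)
        err = T.decompose()["translation"] - np.array([2.0, 1.0, 0.0])
        assert np.linalg.norm(err) < 0.5

    def test_known_scale_recovered(self):
        true = centred_affine(_PHANTOM_SHAPE, scale=(1.05, 1.05, 1.05))
        moving, ref = _phantom_pair(true)
        T = register_affine(moving, ref)
        assert np.all(np.abs(T.decompose()["scale"] - 1.05) < 0.01)


class TestResampleTrilinear:
    def test_identity_exact(self, rng):
        v = rng.standard_normal((6, 7, 8))
        out = resample_trilinear(v, AffineTransform.identity(), v.shape)
        assert np.allclose(out, v)

    def test_half_voxel_shift_exact_on_ramp(self):
        x = np.arange(10, dtype=float)
        v = np.broadcast_to(x[:, None, None], (10, 6, 6)).copy()
        T = AffineTransform.from_params(translation_mm=(0.5, 0.0, 0.0))
        out = resample_trilinear(v, T, v.shape)
        # trilinear interpolation is exact for an affine-in-space image
        interior = out[1:9]
        expect = np.broadcast_to((x - 0.5)[1:9, None, None], interior.shape)
        assert np.allclose(interior, expect)

    def test_out_of_field_is_missing_not_zero(self):
        v = np.ones((5, 5, 5))
        T = AffineTransform.from_params(translation_mm=(10.0, 0.0, 0.0))
        out = resample_trilinear(v, T, v.shape)
        assert np.isnan(out).all()

    def test_round_trip_within_interpolation_error(self):
        grid = np.moveaxis(np.indices(_PHANTOM_SHAPE, dtype=float), 0, -1)
        centre = (np.asarray(_PHANTOM_SHAPE, dtype=float) - 1) / 2
        u = (grid - centre) / (0.4 * np.asarray(_PHANTOM_SHAPE, dtype=float))
        x, y = grid[..., 0], grid[..., 1]
        v = np.exp(-(u**2).sum(axis=-1)) * (1 + 0.3 * np.cos(0.25 * x + 0.2)
                                            * np.cos(0.2 * y + 0.9))
        T = AffineTransform.from_params(
            translation_mm=(0.7, -0.4, 0.3), rotation_rad=(0.02, 0.0, 0.03),
            scale=(1.02, 0.98, 1.01),
        )
        fwd = resample_trilinear(v, T, v.shape)
        back = resample_trilinear(fwd, T.inverse(), v.shape)  # NaNs propagate
        ok = ~np.isnan(back)
        rng_v = v.max() - v.min()
        assert np.max(np.abs(back[ok] - v[ok])) < 0.05 * rng_v


def test_slice_timing_correct_identity_for_constant():
    data = np.full((4, 4, 6, 30), 3.0)
    out = phmri.preprocess.slice_timing_correct(data)
    assert np.allclose(out, 3.0)
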