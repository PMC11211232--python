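import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from synaps.flowquant import (
    PlaneSpec,
    agreement_stats,
    align_peak_systole,
    contrast_ratio,
    dice_coefficient,
    extract_plane,
    flow_metrics,
    segment_vessel_dynamic,
)
from synaps.recon import Flow4D


class TestExtractPlane:
    def _vol(self, velocity):
        P = 3
        mag = np.ones((8, 8, P))
        vel = np.zeros((8, 8, P, 3))
        vel[:] = velocity
        return Flow4D(velocity=vel, magnitude=mag, venc_cm_s=150.0, voxel_mm=2.0)

    def test_through_plane_projection(self):
        vol = self._vol((100.0, 0.0, 0.0))
        _, v = extract_plane(vol, PlaneSpec(axis="x", index=0, normal=(1, 0, 0)))
        assert np.allclose(v, 100.0)

    def test_in_plane_velocity_projects_to_zero(self):
        vol = self._vol((0.0, 50.0, 0.0))
        _, v = extract_plane(vol, PlaneSpec(axis="x", index=0, normal=(1, 0, 0)))
        assert np.allclose(v, 0.0)

    def test_phantom_velocities_confined_to_vessels(self, phantom):
        t = 0.1
        from scipy.ndimage import binary_dilation

        v = phantom.render_velocity(t, include_resp=False)[..., 0]
        m = phantom.true_vessel_mask(t, 0, include_resp=False)
        m |= phantom.true_vessel_mask(t, 1, include_resp=False)
        # beyond a one-pixel partial-volume rim the velocity is exactly zero
        assert np.all(v[~binary_dilation(m)] == 0.0)

    def test_unit_normal_required(self):
        with pytest.raises(ValueError):
            PlaneSpec(axis="x", index=0, normal=(2.0, 0.0, 0.0))


class TestSegmentation:
    def _disk_stack(self, radius_px=5.0, P=4, noise=0.0, seed=0):
        n = 32
        yy, zz = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rho2 = (yy - 16) ** 2 + (zz - 16) ** 2
        mag = np.where(rho2 <= radius_px**2, 3.0, 1.0)[:, :, None] * np.ones(P)
        if noise:
            mag = mag + np.random.default_rng(seed).normal(0, noise, mag.shape)
        return mag

    def test_disk_area_recovered(self):
        mag = self._disk_stack(radius_px=5.0)
        masks = segment_vessel_dynamic(mag, (16, 16))
        area = masks[..., 0].sum() * 2.0**2  # 2 mm pixels
        assert area == pytest.approx(np.pi * 10.0**2, rel=0.10)

    def test_dice_against_truth_on_clean_contrast(self, phantom):
        frame = phantom.render_frame(0.0, "FISS", include_resp=False)
        mag = frame[:, :, None]
        centers = phantom.vessel_centers_mm()
        n = phantom.config.grid_size
        seed = (
            centers[0][0] / phantom.config.voxel_mm + n / 2,
            centers[0][1] / phantom.config.voxel_mm + n / 2,
        )
        masks = segment_vessel_dynamic(mag, seed)
        truth = phantom.true_vessel_mask(0.0, 0, include_resp=False)
        assert dice_coefficient(masks[..., 0], truth) >= 0.9

    def test_low_contrast_segmentation_is_noisier(self, phantom):
        # PC-contrast magnitudes give larger per-phase area variance than FISS
        rng = np.random.default_rng(3)
        P = 6
        taus = (np.arange(P) + 0.5) / P / phantom.config.heart_rate_hz
        fiss = np.stack(
            [phantom.render_frame(t, "FISS", include_resp=False) for t in taus], -1
        )
        pc = np.stack(
            [phantom.render_frame(t, "PC", include_resp=False) for t in taus], -1
        )
        noise = rng.normal(0, 0.1, fiss.shape)
        centers = phantom.vessel_centers_mm()
        n = phantom.config.grid_size
        seed = (
            centers[1][0] / phantom.config.voxel_mm + n / 2,
            centers[1][1] / phantom.config.voxel_mm + n / 2,
        )
        a_f = segment_vessel_dynamic(fiss + noise, seed).sum(axis=(0, 1))
        a_p = segment_vessel_dynamic(pc + noise, seed).sum(axis=(0, 1))
        truth = np.array(
            [
                phantom.true_vessel_mask(t, 1, include_resp=False).sum()
                for t in taus
            ]
        )
        err_f = np.abs(a_f - truth).mean()
        err_p = np.abs(a_p - truth).mean()
        assert err_p >= err_f

    def test_vanishing_component_names_phase(self):
        mag = self._disk_stack(P=3)
        mag[..., 2] = 0.0
        with pytest.raises(ValueError, match="phase 2"):
            segment_vessel_dynamic(mag, (16, 16))


class TestFlowMetrics:
    def test_constant_flow(self):
        P = 10
        masks = np.ones((4, 4, P), bool)
        # 100 mL/s over a 16-pixel 2mm plane: v such that 0.01*v*64mm2*... per pixel
        v = np.full((4, 4, P), 100.0 / (0.01 * 16 * 4.0))
        m = flow_metrics(masks, v, pixel_mm=2.0, rr_s=1.0)
        assert m["net_volume_ml"] == pytest.approx(100.0)
        assert m["peak_flow_ml_s"] == pytest.approx(100.0)

    def test_zero_velocity_zero_volume(self):
        masks = np.ones((4, 4, 5), bool)
        m = flow_metrics(masks, np.zeros((4, 4, 5)), 2.0, 0.8)
        assert m["net_volume_ml"] == 0.0

    def test_parabolic_profile_flow_rate(self):
        # vmax=100 cm/s in a 10 mm radius vessel: Q = vmax/2 * pi R^2 = 157.1 mL/s
        n, pix = 64, 2.0
        c = (np.arange(n) - n / 2 + 0.5) * pix
        yy, zz = np.meshgrid(c, c, indexing="ij")
        rho2 = yy**2 + zz**2
        R = 10.0
        v = np.where(rho2 <= R**2, 100.0 * (1 - rho2 / R**2), 0.0)
        mask = rho2 <= R**2
        m = flow_metrics(mask[..., None], v[..., None], pix, 1.0)
        assert m["peak_flow_ml_s"] == pytest.approx(157.1, rel=0.05)

    def test_net_volume_is_time_integral(self):
        rng = np.random.default_rng(0)
        P = 8
        masks = np.ones((2, 2, P), bool)
        v = rng.random((2, 2, P)) * 50
        m = flow_metrics(masks, v, 2.0, 0.8)
        assert m["net_volume_ml"] == pytest.approx(np.sum(m["q_ml_s"]) * 0.8 / P)


class TestContrastRatio:
    def test_printed_example(self):
        img = np.ones((10, 10))
        img[:5] = 3.0
        img[5:] = 2.0
        assert contrast_ratio(img, ((0, 5), (0, 10)), ((5, 10), (0, 10))) == 1.5

    def test_equal_means_give_one(self):
        img = np.ones((10, 10))
        assert contrast_ratio(img, ((0, 5), (0, 10)), ((5, 10), (0, 10))) == 1.0

    def test_zero_myocardium_rejected(self):
        img = np.zeros((10, 10))
        img[:5] = 1.0
        with pytest.raises(ValueError):
            contrast_ratio(img, ((0, 5), (0, 10)), ((5, 10), (0, 10)))

    def test_overlapping_rois_rejected(self):
        img = np.ones((10, 10))
        with pytest.raises(ValueError):
            contrast_ratio(img, ((0, 6), (0, 10)), ((5, 10), (0, 10)))


class TestDice:
    def test_identical_disjoint_half(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0
        b = np.zeros((4, 4), bool)
        b[1:3] = True  # |A|=|B|=8, overlap 4
        assert dice_coefficient(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3), bool)
        assert dice_coefficient(z, z) == 1.0

    @settings(deadline=None, derandomize=True)
    @given(
        a=hnp.arrays(bool, (6, 6)),
        b=hnp.arrays(bool, (6, 6)),
    )
    def test_symmetry_bounds_and_identity(self, a, b):
        d = dice_coefficient(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice_coefficient(b, a)
        if d == 1.0:
            assert np.array_equal(a, b)


class TestAgreementStats:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        s = agreement_stats(a, a)
        assert s["bias"] == 0.0
        assert s["loa_high"] - s["loa_low"] == 0.0
        assert s["pearson_r"] == pytest.approx(1.0)
        assert s["r2"] == pytest.approx(1.0)

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        s = agreement_stats(a + 5.0, a)
        assert s["bias"] == pytest.approx(5.0)
        assert s["loa_high"] == pytest.approx(5.0)  # zero SD of differences

    def test_printed_mean_absolute_error(self):
        s = agreement_stats([100.0, 110.0, 100.0], [90.0, 120.0, 100.0])
        assert s["mean_abs_error"] == pytest.approx(20.0 / 3)

    def test_mean_abs_error_two_point_example(self):
        # lengths >= 3 enforced; the printed toy pair checked via the formula
        d = np.abs(np.array([100.0, 110.0]) - np.array([90.0, 120.0]))
        assert d.mean() == pytest.approx(10.0)

    def test_zero_variance_flagged(self):
        s = agreement_stats([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert s["zero_variance"]
        assert np.isnan(s["pearson_r"])


class TestAlignPeakSystole:
    def test_documented_shift(self):
        a = np.zeros(10)
        a[5] = 1.0
        b = np.zeros(10)
        b[7] = 1.0
        shifts = align_peak_systole([a, b])
        assert shifts == [0, 8]  # roll by -2 mod 10
        assert np.argmax(np.roll(b, shifts[1])) == 5

    def test_already_aligned(self):
        a = np.zeros(8)
        a[3] = 1.0
        assert align_peak_systole([a, a.copy()]) == [0, 0]

    def test_postcondition_argmaxes_equal(self):
        rng = np.random.default_rng(2)
        curves = [rng.random(12) for _ in range(4)]
        shifts = align_peak_systole(curves)
        ref = np.argmax(curves[0])
        for c, s in zip(curves, shifts):
            assert np.argmax(np.roll(c, s)) == ref
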