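import numpy as np
import pytest

from synaps.phantom import (
    DEFAULT_CONTRAST_TABLE,
    PhantomConfig,
    make_phantom,
    simulate_pt,
)


class TestConfigValidation:
    def test_vessel_radius_vs_fov(self):
        with pytest.raises(ValueError):
            make_phantom(PhantomConfig(vessel_radius_mm=40.0))

    def test_resp_amplitude_bound(self):
        with pytest.raises(ValueError):
            PhantomConfig(resp_amplitude_mm=(0.0, 0.0, 30.0))

    def test_positive_stroke_volume(self):
        with pytest.raises(ValueError):
            PhantomConfig(stroke_volume_ml=-1.0)


class TestRendering:
    def test_default_phantom_has_two_vessels_with_flow(self, phantom):
        v = phantom.render_velocity(0.1)
        assert (v[..., 0] > 0).any() and (v[..., 0] < 0).any()

    def test_determinism(self):
        a = make_phantom(PhantomConfig(seed=9)).render_frame(0.3, "FISS")
        b = make_phantom(PhantomConfig(seed=9)).render_frame(0.3, "FISS")
        assert np.array_equal(a, b)

    def test_zero_resp_amplitude_means_no_displacement(self):
        ph = make_phantom(PhantomConfig(resp_amplitude_mm=(0.0, 0.0, 0.0)))
        for t in (0.0, 1.3, 2.7):
            assert np.all(ph.respiratory_displacement(t) == 0.0)

    def test_blood_myocardium_ratio_by_contrast(self, phantom):
        fiss = phantom.render_frame(0.0, "FISS")
        pc = phantom.render_frame(0.0, "PC")
        blood_f, myo_f = DEFAULT_CONTRAST_TABLE["blood"][0], DEFAULT_CONTRAST_TABLE["myocardium"][0]
        assert blood_f / myo_f == pytest.approx(1.5)
        # rendered images honour the table: bright-blood ratio exceeds PC ratio
        mask = phantom.true_vessel_mask(0.0)
        assert fiss[mask].mean() > pc[mask].mean()

    def test_fat_suppressed_in_fiss(self, phantom):
        from synaps.phantom import _FAT_FRACTION, _TORSO_SEMI

        assert DEFAULT_CONTRAST_TABLE["fat"][0] == 0.0
        fiss = phantom.render_frame(0.0, "FISS", include_resp=False)
        pc = phantom.render_frame(0.0, "PC", include_resp=False)
        grid = phantom.config.grid
        ax = grid.axis_coords()
        yy, zz = np.meshgrid(ax, ax, indexing="ij")
        ty, tz = np.array(_TORSO_SEMI) * grid.fov_mm
        rho = (yy / ty) ** 2 + (zz / tz) ** 2
        # fat ring interior (away from partial-volume edges)
        ring = (rho < 0.98) & (rho > _FAT_FRACTION**2 * 1.04)
        assert np.all(fiss[ring] < 0.2)
        assert pc[ring].mean() > 2.0

    def test_cardiac_periodicity(self, phantom):
        T = 1.0 / phantom.config.heart_rate_hz
        Tr = 1.0 / phantom.config.resp_rate_hz
        # two times one cardiac period apart with equal r(t): lcm of periods
        t0, t1 = 0.3, 0.3 + 5 * T  # 5 cardiac periods = 5/1.2 s; resp differs
        a = phantom.render_frame(t0, "FISS", include_resp=False)
        b = phantom.render_frame(t1, "FISS", include_resp=False)
        assert np.allclose(a, b, atol=1e-12)

    def test_unknown_contrast_rejected(self, phantom):
        with pytest.raises(ValueError):
            phantom.render_frame(0.0, "T2")


class TestVelocityField:
    def test_parabolic_profile_on_axis_and_wall(self, phantom):
        t = 0.1  # during systole
        tau = phantom.cardiac_phase_fn(t)
        vmax = float(phantom.vmax_at(tau))
        assert vmax > 0
        v = phantom.render_velocity(t, include_resp=False)[..., 0]
        # voxel-averaged near-axis velocity: partial volume and the off-grid
        # vessel center cost a few percent of the analytic vmax
        assert v.max() == pytest.approx(vmax, rel=0.04)
        # beyond a one-pixel partial-volume rim the velocity is exactly zero
        from scipy.ndimage import binary_dilation

        m = phantom.true_vessel_mask(t, 0, include_resp=False)
        m |= phantom.true_vessel_mask(t, 1, include_resp=False)
        assert np.all(v[~binary_dilation(m)] == 0.0)

    def test_cross_section_mean_is_half_vmax(self, phantom):
        t = 0.1
        tau = phantom.cardiac_phase_fn(t)
        vmax = float(phantom.vmax_at(tau))
        v = phantom.render_velocity(t, include_resp=False)[..., 0]
        mask = phantom.true_vessel_mask(t, 0, include_resp=False)
        assert v[mask].mean() == pytest.approx(vmax / 2, rel=0.05)

    def test_per_beat_volume_equals_stroke_volume(self, phantom):
        # numeric quadrature of the rendered flow over one beat
        cfg = phantom.config
        T = 1.0 / cfg.heart_rate_hz
        n = 160
        vol = 0.0
        for t in (np.arange(n) + 0.5) * T / n:
            v = phantom.render_velocity(t, include_resp=False)[..., 0]
            vol += 0.01 * v[v > 0].sum() * cfg.voxel_mm**2 * (T / n)
        assert vol == pytest.approx(cfg.stroke_volume_ml, rel=0.02)


class TestPilotTone:
    def test_noiseless_rank_two(self, phantom):
        pt = simulate_pt(phantom, 12, 50.0, noise_sd=0.0, duration_s=20.0)
        rank = np.linalg.matrix_rank(pt.data, tol=1e-8 * np.abs(pt.data).max())
        assert rank <= 2

    def test_determinism(self, phantom):
        a = simulate_pt(phantom, 12, 50.0, 0.1, duration_s=15.0, seed=1)
        b = simulate_pt(phantom, 12, 50.0, 0.1, duration_s=15.0, seed=1)
        assert np.array_equal(a.data, b.data)

    def test_low_sampling_rate_rejected(self, phantom):
        with pytest.raises(ValueError):
            simulate_pt(phantom, 12, fs=2.0, noise_sd=0.0)

    def test_channel_count(self, phantom):
        pt = simulate_pt(phantom, 12, 50.0, 0.1, duration_s=12.0)
        assert pt.data.shape[0] == 12

    def test_cardiac_source_minima_at_beat_onsets(self, phantom):
        T = 1.0 / phantom.config.heart_rate_hz
        t = np.linspace(0, 5 * T, 5000)
        s = phantom.pt_cardiac_source(t)
        onsets = phantom.true_trigger_times(0.1, 5 * T - 0.1)
        for trig in onsets:
            i = np.argmin(np.abs(t - trig))
            lo, hi = max(i - 150, 0), min(i + 150, len(t))
            assert s[i] <= s[lo:hi].min() + 1e-9


class TestRespiratoryConsistency:
    def test_displacement_matches_c_times_r(self, phantom):
        # cross-correlate two rendered frames one displacement apart
        cfg = phantom.config
        t = 2.0  # r(t) = -cos(pi) = +1: full 8 mm displacement, 4 voxels
        d = phantom.respiratory_displacement(t)
        assert np.allclose(d, np.asarray(cfg.resp_amplitude_mm) * phantom.resp_curve_fn(t))
        # rendered frame with resp equals the resp-free frame shifted by d
        shift_vox = d[2] / cfg.voxel_mm
        if abs(shift_vox - round(shift_vox)) < 1e-9:
            a = phantom.render_frame(t, "FISS", include_resp=True)
            b = np.roll(
                phantom.render_frame(t, "FISS", include_resp=False),
                int(round(shift_vox)),
                axis=1,
            )
            interior = np.abs(a - b) < 1e-9
            assert interior.mean() > 0.99  # up to wrap-around at the edge
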