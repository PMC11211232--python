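import numpy as np
import pytest

from synaps.acquisition import RawAcquisition, make_coil_maps, simulate_scan
from synaps.operators import Grid, RadialNudft, ramp_density_compensation
from synaps.phantom import PhantomConfig, make_phantom
from synaps.recon import (
    Cine4D,
    Flow4D,
    ReconConfig,
    combine_synaps,
    decode_velocity,
    gridded_recon,
    kt_sparse_sense,
    normalize_raw,
)
from synaps.trajectory import (
    build_schedule,
    fiss_config,
    golden_angle_2d_directions,
    radial_offsets,
)
from synaps.acquisition import ENCODING_MATRIX, velocity_phase


def _toy_raw(img, grid, n_spokes=32, n_coils=3, seed=1):
    """Noiseless single-frame acquisition of a given image."""
    dirs = golden_angle_2d_directions(n_spokes, 1).reshape(-1, 3)
    kr = radial_offsets(2 * grid.size, grid.kmax)
    coils = make_coil_maps(n_coils, grid, seed=seed)
    op = RadialNudft(dirs, kr, grid, np.complex128)
    y = op.forward(coils.maps * img.ravel()[:, None])
    cfg = fiss_config(
        n_interleaves=1, fov_mm=grid.fov_mm, resolution_mm=grid.voxel_mm, mode="2d"
    )

    class _Sched:
        config = cfg
        directions = dirs
        timestamps = np.arange(n_spokes) * 0.01
        encoding_segment = np.full(n_spokes, -1)
        is_si = np.zeros(n_spokes, bool)

        def __len__(self):
            return n_spokes

    return RawAcquisition(samples=y, schedule=_Sched(), coil_maps=coils, grid=grid), op


@pytest.fixture(scope="module")
def smooth16():
    grid = Grid(16, 2.0, "2d")
    ax = grid.axis_coords()
    yy, zz = np.meshgrid(ax, ax, indexing="ij")
    img = np.exp(-((yy - 3) ** 2 + (zz + 2) ** 2) / 60.0) + 0.5 * np.exp(
        -((yy + 6) ** 2 + zz**2) / 30.0
    )
    return grid, img


class TestGriddedRecon:
    def test_point_object_peaks_at_center(self):
        grid = Grid(16, 2.0, "2d")
        img = np.zeros(grid.shape)
        img[8, 8] = 1.0
        raw, _ = _toy_raw(img, grid)
        rec = np.abs(gridded_recon(raw))
        assert np.unravel_index(rec.argmax(), rec.shape) == (8, 8)

    def test_linearity(self, smooth16):
        grid, img = smooth16
        raw, _ = _toy_raw(img, grid)
        a = gridded_recon(raw)
        b = gridded_recon(raw.copy_with(2.0 * raw.samples))
        assert np.allclose(b, 2.0 * a)

    def test_empty_bin_error_names_bin(self, smooth16):
        grid, img = smooth16
        raw, _ = _toy_raw(img, grid)
        bins = np.zeros(len(raw.schedule), int)  # phase 1 of 2 empty
        with pytest.raises(ValueError, match="1"):
            gridded_recon(raw, bins=bins, n_phases=2)

    def test_ramp_dcf_center_cap(self):
        kr = radial_offsets(8, 0.25)
        w = ramp_density_compensation(kr)
        dk = kr[1] - kr[0]
        assert w[kr == 0] == pytest.approx(dk / 2)


class TestNormalizeRaw:
    def test_unit_max_after_scaling(self, smooth16):
        grid, img = smooth16
        raw, _ = _toy_raw(img, grid)
        scaled, factor = normalize_raw(raw)
        assert factor > 0
        assert np.abs(gridded_recon(scaled)).max() == pytest.approx(1.0, abs=1e-6)

    def test_idempotent(self, smooth16):
        grid, img = smooth16
        raw, _ = _toy_raw(img, grid)
        scaled, _ = normalize_raw(raw)
        _, second = normalize_raw(scaled)
        assert second == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_rejected(self, smooth16):
        grid, img = smooth16
        raw, _ = _toy_raw(img, grid)
        with pytest.raises(ValueError):
            normalize_raw(raw.copy_with(np.zeros_like(raw.samples)))


class TestKtSparseSense:
    def test_lambda0_matches_cg_least_squares_oracle(self, smooth16):
        grid, img = smooth16
        raw, op = _toy_raw(img, grid)
        res = kt_sparse_sense(
            raw,
            np.zeros(len(raw.schedule), int),
            ReconConfig(0.0, 0.0, n_iterations=60, tolerance=1e-14),
            dtype=np.complex128,
        )
        # oracle: conjugate gradients on the explicit normal equations
        A = op.matrix()
        E = np.concatenate(
            [A * raw.coil_maps.maps[:, c][None, :] for c in range(raw.coil_maps.n_coils)]
        )
        y = np.concatenate(
            [raw.samples[:, :, c].ravel() for c in range(raw.coil_maps.n_coils)]
        )
        EhE, Ehy = E.conj().T @ E, E.conj().T @ y
        x = np.zeros_like(Ehy)
        r = Ehy.copy()
        p = r.copy()
        rs = np.vdot(r, r).real
        for _ in range(3000):
            Ap = EhE @ p
            alpha = rs / np.vdot(p, Ap).real
            x += alpha * p
            r -= alpha * Ap
            rs_new = np.vdot(r, r).real
            if rs_new < 1e-24 * np.vdot(Ehy, Ehy).real:
                break
            p = r + (rs_new / rs) * p
            rs = rs_new
        nrmse = np.linalg.norm(res.volumes[..., 0].ravel() - x) / np.linalg.norm(x)
        assert nrmse < 0.01

    def test_objective_trace_non_increasing(self, smooth16):
        grid, img = smooth16
        raw, _ = _toy_raw(img, grid)
        res = kt_sparse_sense(
            raw,
            np.zeros(len(raw.schedule), int),
            ReconConfig(0.01, 0.015, n_iterations=25),
        )
        tr = np.asarray(res.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * max(1.0, tr[0]))

    def test_kt_beats_gridded_on_undersampled_dynamic_phantom(self):
        cfg = PhantomConfig(seed=8, resp_amplitude_mm=(0.0, 0.0, 0.0))
        ph = make_phantom(cfg)
        sc = fiss_config(
            n_interleaves=10, tr_ms=50.0, fov_mm=cfg.grid.fov_mm,
            resolution_mm=cfg.voxel_mm, mode="2d",
        )
        sched = build_schedule(sc)
        raw = simulate_scan(ph, sched, noise_sd=0.0, n_coils=4, seed=8)
        P = 8
        tau = np.mod(sched.timestamps * cfg.heart_rate_hz, 1.0)
        bins = np.minimum((tau * P).astype(int), P - 1)
        raw, _ = normalize_raw(raw)
        res = kt_sparse_sense(raw, bins, ReconConfig(0.03, 0.015, n_iterations=30))
        grd = gridded_recon(raw, bins=bins, n_phases=P)
        # ground truth: bin-centre frames
        truth = np.stack(
            [
                ph.render_frame((p + 0.5) / P / cfg.heart_rate_hz, "FISS")
                for p in range(P)
            ],
            axis=-1,
        )

        def nrmse(x):
            x = np.abs(x)
            s = (x * truth).sum() / (x * x).sum()  # optimal scalar
            return np.linalg.norm(s * x - truth) / np.linalg.norm(truth)

        assert nrmse(res.volumes) < nrmse(grd)


class TestVelocityDecoding:
    def test_identical_segments_give_zero(self):
        seg = np.ones((4, 5, 5), complex)
        v, wrapped = decode_velocity(seg, 150.0)
        assert np.allclose(v, 0.0)
        assert not wrapped.any()

    def test_convention_example(self):
        # segment phases (pi/2)*(-1, 1, 1, -1) decode to (venc, 0, 0)
        phases = (np.pi / 2) * np.array([-1.0, 1.0, 1.0, -1.0])
        seg = np.exp(1j * phases)[:, None, None] * np.ones((4, 3, 3))
        v, wrapped = decode_velocity(seg, 150.0)
        assert np.allclose(v[..., 0], 150.0, atol=1e-9)
        assert np.allclose(v[..., 1:], 0.0, atol=1e-9)

    def test_encode_decode_roundtrip_random_velocities(self):
        rng = np.random.default_rng(0)
        n = 500
        # velocities with magnitude below venc (components within +/-venc)
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v_true = u * (rng.uniform(0, 0.999, n) * 150.0)[:, None]
        segs = np.stack(
            [np.exp(1j * velocity_phase(v_true, s, 150.0)) for s in range(4)]
        )
        v, wrapped = decode_velocity(segs, 150.0)
        assert np.abs(v - v_true).max() < 1e-6

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_velocity(np.ones((3, 4, 4)), 150.0)


class TestCombine:
    def _pair(self, P=4):
        mag = np.random.default_rng(0).random((8, 8, P))
        vel = np.random.default_rng(1).random((8, 8, P, 3))
        cine = Cine4D(magnitude=mag, voxel_mm=2.0, rr_s=0.8)
        flow = Flow4D(
            velocity=vel, magnitude=0.5 * mag, venc_cm_s=150.0, voxel_mm=2.0, rr_s=0.8
        )
        return cine, flow

    def test_magnitude_and_velocity_pass_through_bitwise(self):
        cine, flow = self._pair()
        out = combine_synaps(cine, flow)
        assert out.magnitude is cine.magnitude
        assert out.velocity is flow.velocity

    def test_phase_count_mismatch_rejected(self):
        cine, _ = self._pair(P=20)
        _, flow = self._pair(P=10)
        with pytest.raises(ValueError):
            combine_synaps(cine, flow)

    def test_native_and_synaps_share_velocity(self):
        cine, flow = self._pair()
        synaps = combine_synaps(cine, flow)
        assert synaps.velocity is flow.velocity  # only magnitude differs
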