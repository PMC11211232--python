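"""Multi-coil radial k-space simulation from the dynamic phantom.

The forward model is deliberately discrete: each readout encodes the
rasterized phantom frame frozen at its own timestamp through the same
NUDFT whose exact adjoint the reconstruction uses.  Velocity enters as a
voxelwise phase via the balanced 4-point scheme, and respiratory
displacement enters as a linear k-space phase (rigid translation), which
is precisely what the focused-navigation correction later removes.

Balanced 4-point convention: segment s imparts phase

    phi_s = (pi / (2*venc)) * (h_s . v),    h_s a row of H,

    H = [[-1,-1,-1], [1,1,-1], [1,-1,1], [-1,1,1]],   H^T H = 4 I,

so a paired-segment phase difference reaches pi at |v| = venc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import Grid, RadialNudft, spoke_matrix
from .phantom import DynamicPhantom, PilotToneRecord, simulate_pt
from .trajectory import ReadoutSchedule, radial_offsets

__all__ = [
    "ENCODING_MATRIX",
    "CoilMaps",
    "RawAcquisition",
    "make_coil_maps",
    "velocity_phase",
    "encode_readout",
    "simulate_scan",
]

#: balanced 4-point velocity-encoding matrix (segments x axes), H^T H = 4 I
ENCODING_MATRIX = np.array(
    [[-1, -1, -1], [1, 1, -1], [1, -1, 1], [-1, 1, 1]], dtype=float
)


@dataclass
class CoilMaps:
    """Per-coil complex sensitivities, flattened to (n_voxels, n_coils).

    Voxelwise sum of squared magnitudes is 1.
    """

    maps: np.ndarray
    grid: Grid

    @property
    def n_coils(self) -> int:
        return self.maps.shape[1]

    def validate(self):
        sos = np.sum(np.abs(self.maps) ** 2, axis=1)
        assert np.allclose(sos, 1.0, atol=1e-6)


def make_coil_maps(n_coils: int, grid: Grid, seed: int = 0) -> CoilMaps:
    """Smooth complex coil maps: Gaussian-lobe magnitudes centered outside
    the FOV perimeter, low-order polynomial phase, normalized so the
    voxelwise sum of squared magnitudes is 1."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    coords = grid.coords()  # (nvox, 3)
    fov = grid.fov_mm
    inplane = coords[:, 1:] if grid.mode == "2d" else coords
    rng = np.random.default_rng(seed)
    maps = np.empty((grid.n_voxels, n_coils), np.complex128)
    if n_coils == 1:
        maps[:, 0] = 1.0
        return CoilMaps(maps=maps, grid=grid)
    angles = 2 * np.pi * np.arange(n_coils) / n_coils
    width = 0.9 * fov
    for c, ang in enumerate(angles):
        if grid.mode == "2d":
            center = 0.6 * fov * np.array([np.cos(ang), np.sin(ang)])
        else:
            center = 0.6 * fov * np.array([0.0, np.cos(ang), np.sin(ang)])
        d2 = np.sum((inplane - center) ** 2, axis=1)
        mag = np.exp(-d2 / (2 * width**2))
        coef = rng.normal(scale=0.5, size=3)
        u = inplane / fov
        phase = coef[0] * u[:, -1] + coef[1] * u[:, -2] + coef[2] * u[:, -1] * u[:, -2]
        maps[:, c] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=1, keepdims=True))
    maps /= sos
    return CoilMaps(maps=maps, grid=grid)


@dataclass
class RawAcquisition:
    """Raw radial k-space of one sequence plus everything needed to use it."""

    samples: np.ndarray  # (R, N, C) complex
    schedule: ReadoutSchedule
    coil_maps: CoilMaps
    grid: Grid
    pt: PilotToneRecord = None
    truth: dict = None  # ground-truth block, simulated data only

    @property
    def kr(self) -> np.ndarray:
        return radial_offsets(self.samples.shape[1], self.grid.kmax)

    def validate(self):
        assert self.samples.shape[0] == len(self.schedule)

    def copy_with(self, samples) -> "RawAcquisition":
        return RawAcquisition(
            samples=samples,
            schedule=self.schedule,
            coil_maps=self.coil_maps,
            grid=self.grid,
            pt=self.pt,
            truth=self.truth,
        )


def velocity_phase(velocity, enc_segment, venc_cm_s: float) -> np.ndarray:
    """Voxelwise encoding phase (rad) of one segment for a velocity field
    with trailing axis (3,) in cm/s."""
    h = ENCODING_MATRIX[enc_segment]
    return (np.pi / (2.0 * venc_cm_s)) * (np.asarray(velocity) @ h)


def encode_readout(
    frame: np.ndarray,
    velocity: np.ndarray,
    enc_segment,
    coords: np.ndarray,
    coils: CoilMaps,
    shift_mm=(0.0, 0.0, 0.0),
    venc_cm_s: float = None,
) -> np.ndarray:
    """Encode one readout: samples (n_samples, n_coils).

    ``coords`` are the k-space sample coordinates (n_samples, 3) in
    cycles/mm along one spoke.  ``shift_mm`` applies the Fourier shift
    theorem phase exp(-2j*pi*k.shift).  ``enc_segment`` None/-1 disables
    velocity encoding (anatomical readout / SI projection).
    """
    grid = coils.grid
    coords = np.asarray(coords, float)
    kr_norm = np.linalg.norm(coords, axis=1)
    if np.max(kr_norm) > grid.kmax * (1 + 1e-9):
        raise ValueError("k-space coordinate outside the Nyquist band")
    img = np.asarray(frame, float).ravel().astype(np.complex128)
    if enc_segment is not None and enc_segment >= 0:
        if venc_cm_s is None:
            raise ValueError("venc_cm_s required for velocity encoding")
        if np.asarray(velocity).shape[:-1] != np.asarray(frame).shape:
            raise ValueError("frame and velocity must share one grid")
        phi = velocity_phase(velocity, int(enc_segment), venc_cm_s).ravel()
        img = img * np.exp(1j * phi)
    stack = coils.maps * img[:, None]  # (nvox, C)
    # direction and radial offsets from the spoke coordinates
    imax = int(np.argmax(kr_norm))
    direction = coords[imax] / kr_norm[imax]
    kr = coords @ direction
    A = spoke_matrix(direction, kr, grid.coords(), np.complex128)
    samples = A @ stack
    shift = np.asarray(shift_mm, float)
    samples *= np.exp(-2j * np.pi * (coords @ shift))[:, None]
    return samples


def simulate_scan(
    phantom: DynamicPhantom,
    schedule: ReadoutSchedule,
    noise_sd: float = 0.0,
    coil_maps: CoilMaps = None,
    n_coils: int = 4,
    pt: PilotToneRecord = None,
    seed: int = None,
) -> RawAcquisition:
    """Simulate one full sequence acquisition.

    Each readout encodes the phantom frame at its own timestamp (motion
    state frozen per readout); the respiratory shift is applied as a
    k-space phase; complex Gaussian noise is added; a PT record spanning
    the schedule is attached (or simulated if not supplied).
    """
    cfg = schedule.config
    grid = phantom.config.grid
    if coil_maps is None:
        coil_maps = make_coil_maps(n_coils, grid, seed=phantom.config.seed)
    seed = phantom.config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    contrast = cfg.name  # FISS or PC contrast mechanism
    kr = radial_offsets(cfg.samples_per_readout, cfg.kmax)
    coords_img = grid.coords()
    R = len(schedule)
    N = len(kr)
    C = coil_maps.n_coils
    samples = np.empty((R, N, C), np.complex128)

    frame_cache, vel_cache = {}, {}

    def frame_at(t):
        tau = float(phantom.cardiac_phase_fn(t))
        if tau not in frame_cache:
            frame_cache[tau] = phantom.render_frame(t, contrast, include_resp=False)
            if len(frame_cache) > 8:
                frame_cache.pop(next(iter(frame_cache)))
        return frame_cache[tau]

    def velocity_at(t):
        tau = float(phantom.cardiac_phase_fn(t))
        if tau not in vel_cache:
            vel_cache[tau] = phantom.render_velocity(t, include_resp=False)
            if len(vel_cache) > 8:
                vel_cache.pop(next(iter(vel_cache)))
        return vel_cache[tau]

    needs_venc = schedule.encoding_segment.max(initial=-1) >= 0
    venc = cfg.venc_cm_s if needs_venc else None

    for r in range(R):
        t = schedule.timestamps[r]
        img = frame_at(t).ravel().astype(np.complex128)
        seg = int(schedule.encoding_segment[r])
        if seg >= 0:
            phi = velocity_phase(velocity_at(t), seg, venc).ravel()
            img = img * np.exp(1j * phi)
        stack = coil_maps.maps * img[:, None]
        d = schedule.directions[r]
        A = spoke_matrix(d, kr, coords_img, np.complex128)
        y = A @ stack
        shift = phantom.respiratory_displacement(t)
        y *= np.exp(-2j * np.pi * kr * (d @ shift))[:, None]
        samples[r] = y
    if noise_sd > 0:
        noise = rng.standard_normal((R, N, C, 2))
        samples += noise_sd * (noise[..., 0] + 1j * noise[..., 1])
    if pt is None:
        duration = schedule.timestamps[-1] + cfg.tr_ms * 1e-3
        pt = simulate_pt(
            phantom, n_channels=12, fs=50.0, noise_sd=0.1, duration_s=duration
        )
    truth = {
        "c_true_mm": np.asarray(phantom.config.resp_amplitude_mm, float),
        "trigger_times_s": phantom.true_trigger_times(
            schedule.timestamps[0], schedule.timestamps[-1]
        ),
        "stroke_volume_ml": phantom.config.stroke_volume_ml,
        "vmax_peak_cm_s": phantom.vmax_peak_cm_s,
    }
    return RawAcquisition(
        samples=samples,
        schedule=schedule,
        coil_maps=coil_maps,
        grid=grid,
        pt=pt,
        truth=truth,
    )
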