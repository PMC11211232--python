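"""Dynamic digital torso phantom: beating heart, breathing, pulsatile flow,
and multi-channel pilot-tone (PT) signals.

The phantom stands in for a scanned subject and provides exact ground truth
for every downstream stage:

* anatomy — torso (muscle) with a fat ring, a myocardial shell with a blood
  pool, and two aorta-like vessels running along the through-plane axis;
* contrast — a tissue table maps each tissue to a (FISS, PC) signal pair:
  FISS is bright-blood and fat-suppressed, PC has low blood-to-myocardium
  contrast (the dichotomy the anatomical/flow combination exploits);
* cardiac cycle — vessel and blood-pool radii are modulated by a
  raised-cosine systolic pulse occupying the first ``systolic_fraction`` of
  the RR interval; the same pulse shapes the flow waveform;
* flow — a parabolic (Poiseuille) profile along each vessel axis whose
  per-beat volume integral equals ``stroke_volume_ml`` exactly;
* respiration — a rigid translation c_true * r(t) with
  r(t) = -cos(2*pi*f_resp*t), the bounded unitless curve the motion
  correction later re-scales;
* pilot tone — each channel is a seeded linear mixture of a cardiac source
  (smooth periodic dips whose minima mark beat onsets) and the respiratory
  curve, plus linear drift, a step offset at the inter-sequence gap, and
  Gaussian noise.

In 2D mode the image plane is (y, z) and flow is through-plane (v_x); in 3D
mode the vessels are cylinders along x.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .operators import Grid

__all__ = [
    "PhantomConfig",
    "DynamicPhantom",
    "PilotToneRecord",
    "DEFAULT_CONTRAST_TABLE",
    "make_phantom",
    "render_frame",
    "render_velocity",
    "simulate_pt",
]

#: tissue -> (FISS signal, PC signal).  FISS: bright blood (blood/myocardium
#: = 1.5) with inherent fat suppression.  PC: low blood contrast
#: (blood/myocardium = 0.7), fat not suppressed.
DEFAULT_CONTRAST_TABLE = {
    "background": (0.0, 0.0),
    "muscle": (1.0, 1.0),
    "fat": (0.0, 2.5),
    "myocardium": (2.0, 2.0),
    "blood": (3.0, 1.4),
}

CONTRAST_NAMES = ("FISS", "PC")

#: relative width (fraction of RR) of the cardiac pilot-tone dip
_PT_CARDIAC_DIP_WIDTH = 0.15


@dataclass(frozen=True)
class PhantomConfig:
    grid_size: int = 64
    voxel_mm: float = 2.0
    mode: str = "2d"  # "2d" single slice (y,z), "3d" small volume
    heart_rate_hz: float = 1.2
    resp_rate_hz: float = 0.25
    resp_amplitude_mm: tuple = (0.0, 0.0, 8.0)  # c_true, mm per axis (x,y,z)
    stroke_volume_ml: float = 30.0  # per beat, per vessel
    vessel_radius_mm: float = 10.0
    vessel_pulsatility: float = 0.08  # fractional radius modulation over the beat
    systolic_fraction: float = 0.35  # raised-cosine pulse occupies this RR fraction
    contrast_table: dict = field(default_factory=lambda: dict(DEFAULT_CONTRAST_TABLE))
    supersample: int = 4  # rasterization partial-volume factor
    freeze_cardiac_phase: float = None  # hold the heart at one phase (static studies)
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if np.max(np.abs(self.resp_amplitude_mm)) > 25.0:
            raise ValueError("resp_amplitude components must be within +/-25 mm")
        if self.stroke_volume_ml <= 0:
            raise ValueError("stroke_volume_ml must be > 0")
        if self.vessel_radius_mm >= self.grid_size * self.voxel_mm / 4:
            raise ValueError("vessel radius must be < FOV/4")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_size, self.voxel_mm, self.mode)


# Geometry layout as fractions of the FOV (vessel radius stays absolute so
# that flow areas are physical).  In-plane coordinates are (y, z).
_TORSO_SEMI = (0.45, 0.39)
_FAT_FRACTION = 0.92  # fat ring occupies the outer 8% of the torso ellipse
_HEART_CENTER = (-0.125, 0.0)
_HEART_OUTER = 0.16
_POOL_RADIUS = 0.09
_AAO_CENTER = (0.125, 0.11)
_DAO_CENTER = (0.125, -0.125)


@dataclass
class DynamicPhantom:
    """Time-parameterized phantom; construct with :func:`make_phantom`."""

    config: PhantomConfig
    vmax_peak_cm_s: float = None  # set in make_phantom

    # -- temporal parameterization -------------------------------------
    def cardiac_phase_fn(self, t) -> np.ndarray:
        """Cardiac phase in [0, 1), periodic with 1/heart_rate_hz."""
        t = np.asarray(t, float)
        if self.config.freeze_cardiac_phase is not None:
            return np.full(t.shape, self.config.freeze_cardiac_phase % 1.0)
        return np.mod(t * self.config.heart_rate_hz, 1.0)

    def resp_curve_fn(self, t) -> np.ndarray:
        """Unitless respiratory curve r(t) in [-1, 1]."""
        return -np.cos(2 * np.pi * self.config.resp_rate_hz * np.asarray(t, float))

    def systolic_pulse(self, tau) -> np.ndarray:
        """Raised-cosine pulse on [0, systolic_fraction), zero in diastole."""
        tau = np.mod(np.asarray(tau, float), 1.0)
        fs = self.config.systolic_fraction
        w = 0.5 * (1 - np.cos(2 * np.pi * tau / fs))
        return np.where(tau < fs, w, 0.0)

    def respiratory_displacement(self, t) -> np.ndarray:
        """Rigid displacement c_true * r(t), mm; shape (..., 3)."""
        r = self.resp_curve_fn(t)
        c = np.asarray(self.config.resp_amplitude_mm, float)
        return np.asarray(r)[..., None] * c

    # -- geometry --------------------------------------------------------
    def vessel_radius_at(self, tau) -> np.ndarray:
        r0 = self.config.vessel_radius_mm
        return r0 * (1 + self.config.vessel_pulsatility * self.systolic_pulse(tau))

    def vessel_centers_mm(self):
        fov = self.config.grid.fov_mm
        return (
            np.array(_AAO_CENTER) * fov,
            np.array(_DAO_CENTER) * fov,
        )

    def vmax_at(self, tau) -> np.ndarray:
        """On-axis (peak) velocity of the parabolic profile, cm/s."""
        return self.vmax_peak_cm_s * self.systolic_pulse(tau)

    def true_flow_curve(self, tau) -> np.ndarray:
        """Instantaneous flow rate per vessel, mL/s (positive forward)."""
        area_mm2 = np.pi * self.vessel_radius_at(tau) ** 2
        return 0.01 * (self.vmax_at(tau) / 2.0) * area_mm2

    def true_vessel_mask(self, t, vessel: int = 0, include_resp: bool = True):
        """Boolean in-plane mask of one vessel cross-section at time t."""
        cfg = self.config
        tau = self.cardiac_phase_fn(t)
        centers = self.vessel_centers_mm()
        c = np.asarray(centers[vessel], float)
        if include_resp:
            d = self.respiratory_displacement(t)
            c = c + d[..., 1:]
        ax = cfg.grid.axis_coords()
        yy, zz = np.meshgrid(ax, ax, indexing="ij")
        rad = self.vessel_radius_at(tau)
        return (yy - c[0]) ** 2 + (zz - c[1]) ** 2 <= rad**2

    # -- rendering -------------------------------------------------------
    def _inplane_points(self):
        """Supersample point coordinates whose s x s boxes are centered on
        the grid voxel centers (i - n/2) * voxel_mm."""
        cfg = self.config
        n = cfg.grid_size * cfg.supersample
        step = cfg.voxel_mm / cfg.supersample
        return (np.arange(n) - n / 2.0 + 0.5) * step - cfg.voxel_mm / 2.0

    def _tissue_image(self, t, values, include_resp: bool):
        """Rasterize tissue intensities at time t (supersampled, box-averaged)."""
        cfg = self.config
        tau = self.cardiac_phase_fn(t)
        fov = cfg.grid.fov_mm
        shift = np.zeros(3)
        if include_resp:
            shift = self.respiratory_displacement(t)
        c = self._inplane_points()
        s = cfg.supersample
        if cfg.mode == "2d":
            yy, zz = np.meshgrid(c - shift[1], c - shift[2], indexing="ij")
            xx = None
        else:
            xx, yy, zz = np.meshgrid(
                c - shift[0], c - shift[1], c - shift[2], indexing="ij"
            )

        img = np.full(yy.shape, values["background"], float)
        ty, tz = np.array(_TORSO_SEMI) * fov
        torso = (yy / ty) ** 2 + (zz / tz) ** 2
        if cfg.mode == "3d":
            torso = torso + (xx / (0.48 * fov)) ** 2
        img[torso <= 1.0] = values["muscle"]
        img[(torso <= 1.0) & (torso > _FAT_FRACTION**2)] = values["fat"]

        hc = np.array(_HEART_CENTER) * fov
        # blood-pool radius contracts during systole (ejection)
        pool_r = _POOL_RADIUS * fov * (1 - 0.10 * self.systolic_pulse(tau))
        heart = (yy - hc[0]) ** 2 + (zz - hc[1]) ** 2
        if cfg.mode == "3d":
            heart = heart + (xx / 1.3) ** 2
        outer = (_HEART_OUTER * fov) ** 2
        img[heart <= outer] = values["myocardium"]
        img[heart <= pool_r**2] = values["blood"]

        rad = self.vessel_radius_at(tau)
        for center in self.vessel_centers_mm():
            rho2 = (yy - center[0]) ** 2 + (zz - center[1]) ** 2
            img[rho2 <= rad**2] = values["blood"]

        # box-average the supersampled rasterization back to the grid
        if cfg.mode == "2d":
            n = cfg.grid_size
            return img.reshape(n, s, n, s).mean(axis=(1, 3))
        n = cfg.grid_size
        return img.reshape(n, s, n, s, n, s).mean(axis=(1, 3, 5))

    def render_frame(self, t: float, contrast: str, include_resp: bool = True):
        """Real-valued tissue image at time t for one contrast mechanism."""
        if contrast not in CONTRAST_NAMES:
            raise ValueError(f"unknown contrast {contrast!r}")
        idx = CONTRAST_NAMES.index(contrast)
        values = {k: v[idx] for k, v in self.config.contrast_table.items()}
        return self._tissue_image(t, values, include_resp)

    def render_velocity(self, t: float, include_resp: bool = True):
        """3-component velocity field (cm/s), shape grid.shape + (3,).

        Parabolic profile v(rho) = vmax(t) * (1 - (rho/R)^2) along the
        vessel axis (x); AAo flows +x, DAo flows -x; zero elsewhere.
        """
        cfg = self.config
        tau = self.cardiac_phase_fn(t)
        vmax = self.vmax_at(tau)
        rad = self.vessel_radius_at(tau)
        shift = np.zeros(3)
        if include_resp:
            shift = self.respiratory_displacement(t)
        c = self._inplane_points()
        s = cfg.supersample
        if cfg.mode == "2d":
            yy, zz = np.meshgrid(c - shift[1], c - shift[2], indexing="ij")
        else:
            _, yy, zz = np.meshgrid(
                c - shift[0], c - shift[1], c - shift[2], indexing="ij"
            )
        vx = np.zeros(yy.shape)
        for sign, center in zip((1.0, -1.0), self.vessel_centers_mm()):
            rho2 = (yy - center[0]) ** 2 + (zz - center[1]) ** 2
            inside = rho2 <= rad**2
            vx[inside] += sign * vmax * (1 - rho2[inside] / rad**2)
        n = cfg.grid_size
        if cfg.mode == "2d":
            vx = vx.reshape(n, s, n, s).mean(axis=(1, 3))
        else:
            vx = vx.reshape(n, s, n, s, n, s).mean(axis=(1, 3, 5))
        out = np.zeros(vx.shape + (3,))
        out[..., 0] = vx
        return out

    # -- pilot tone ------------------------------------------------------
    def pt_cardiac_source(self, t) -> np.ndarray:
        """Cardiac PT source: smooth periodic dips, minima at beat onsets."""
        tau = self.cardiac_phase_fn(t)
        dist = np.minimum(tau, 1.0 - tau)  # circular distance to beat onset
        sigma = _PT_CARDIAC_DIP_WIDTH
        return -np.exp(-(dist**2) / (2 * sigma**2))

    def true_trigger_times(self, t_start: float, t_end: float) -> np.ndarray:
        """Beat-onset times (cardiac phase 0) within [t_start, t_end]."""
        T = 1.0 / self.config.heart_rate_hz
        k0 = int(np.ceil(t_start / T))
        k1 = int(np.floor(t_end / T))
        return np.arange(k0, k1 + 1) * T


def make_phantom(config: PhantomConfig) -> DynamicPhantom:
    """Build the phantom and calibrate the flow waveform amplitude so that
    the per-beat flow-rate integral equals ``stroke_volume_ml`` exactly."""
    ph = DynamicPhantom(config=config, vmax_peak_cm_s=1.0)
    tau = (np.arange(4096) + 0.5) / 4096
    w = ph.systolic_pulse(tau)
    area_mm2 = np.pi * ph.vessel_radius_at(tau) ** 2
    T = 1.0 / config.heart_rate_hz
    # 0.01 converts cm/s * mm^2 to mL/s; mean velocity = vmax/2 (parabola)
    integral = 0.01 * 0.5 * np.mean(w * area_mm2) * T
    ph.vmax_peak_cm_s = config.stroke_volume_ml / integral
    return ph


def render_frame(
    phantom: DynamicPhantom, t: float, contrast: str, include_resp: bool = True
):
    return phantom.render_frame(t, contrast, include_resp)


def render_velocity(phantom: DynamicPhantom, t: float, include_resp: bool = True):
    return phantom.render_velocity(t, include_resp)


@dataclass
class PilotToneRecord:
    """Multi-channel PT matrix sampled at ``fs`` Hz from t = 0."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    gap_time_s: float = None  # inter-sequence interrupt, if any

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.fs


def simulate_pt(
    phantom: DynamicPhantom,
    n_channels: int,
    fs: float,
    noise_sd: float,
    drift_per_min: float = 0.0,
    duration_s: float = 60.0,
    gap_time_s: float = None,
    step_offset: float = 0.0,
    seed: int = None,
) -> PilotToneRecord:
    """Simulate the PT channel matrix over [0, duration_s].

    Each channel is a_c*s_cardiac(t) + a_r*s_resp(t) + linear drift + a step
    offset at the inter-sequence gap + Gaussian noise.  Sources are unit-
    standard-deviation so ``noise_sd`` is an inverse SNR (noise_sd = 0.1
    corresponds to SNR 10).
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if fs <= 2 * phantom.config.heart_rate_hz:
        raise ValueError("fs must exceed twice the cardiac frequency")
    seed = phantom.config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    s_card = phantom.pt_cardiac_source(t)
    s_resp = phantom.resp_curve_fn(t)

    def _unit(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    sources = np.stack([_unit(s_card), _unit(s_resp)])
    mixing = rng.normal(size=(n_channels, 2))
    mixing += 0.3 * np.sign(mixing)  # keep every channel informative
    data = mixing @ sources
    data += (drift_per_min / 60.0) * rng.normal(size=(n_channels, 1)) * t[None, :]
    if gap_time_s is not None and step_offset:
        data += step_offset * rng.normal(size=(n_channels, 1)) * (
            t[None, :] >= gap_time_s
        )
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    return PilotToneRecord(data=data, fs=fs, gap_time_s=gap_time_s)
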