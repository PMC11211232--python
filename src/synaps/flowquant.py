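"""Vessel-plane extraction, dynamic segmentation, flow metrics and
agreement statistics.

Flow-rate conventions: with velocity in cm/s and pixel areas in mm^2,
Q [mL/s] = 0.01 * sum_pixels v * pixel_area, and the net volume per beat is
sum_p Q_p * (RR / P).  Planes are labelled like the aortic measurement
planes of a clinical exam (AAo = ascending, DAo = descending aorta); their
normals are chosen so physiologic systolic flow is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "PlaneSpec",
    "FlowReport",
    "extract_plane",
    "segment_vessel_dynamic",
    "flow_metrics",
    "contrast_ratio",
    "dice_coefficient",
    "agreement_stats",
    "align_peak_systole",
]

#: segmentation threshold as a fraction of the seed-component median
#: intensity; 0.6 keeps partial-volume rim pixels out of the vessel mask at
#: 2 mm voxels while still flooding on low-contrast (PC) magnitudes
SEGMENTATION_TAU = 0.6


@dataclass(frozen=True)
class PlaneSpec:
    """Axis-aligned or oblique measurement plane.

    Axis-aligned: ``axis`` in {"x", "y", "z"} with ``index`` (nearest-slice
    extraction).  Oblique: ``point_mm`` + unit ``normal`` (trilinear
    sampling).  ``label`` identifies the vessel (AAo/DAo/other).
    """

    axis: str = None
    index: int = None
    point_mm: tuple = None
    normal: tuple = (1.0, 0.0, 0.0)
    label: str = "other"

    def __post_init__(self):
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("plane normal must be unit-norm")


def extract_plane(vol, plane: PlaneSpec):
    """Per-phase in-plane magnitude and through-plane velocity (cm/s).

    ``vol`` is a SyNAPS or flow volume object with ``magnitude`` (…, P) and
    ``velocity`` (…, P, 3).  For a 2D (single-slice) volume the slice
    itself is the plane and only the through-plane projection v·n applies.
    Returns (mag, v_through) each shaped (plane_shape + (P,)).
    """
    normal = np.asarray(plane.normal, float)
    mag = vol.magnitude
    vel = vol.velocity
    ndim = mag.ndim - 1  # spatial dims
    if ndim == 2:
        mag_p = mag
        vel_p = vel
    else:
        if plane.axis is None:
            return _extract_oblique(vol, plane)
        ax = "xyz".index(plane.axis)
        if not (0 <= plane.index < mag.shape[ax]):
            raise ValueError("plane outside volume")
        mag_p = np.take(mag, plane.index, axis=ax)
        vel_p = np.take(vel, plane.index, axis=ax)
    v_through = vel_p @ normal
    return mag_p, v_through


def _extract_oblique(vol, plane: PlaneSpec):
    """Trilinear sampling of an oblique plane through a 3D volume."""
    normal = np.asarray(plane.normal, float)
    point = np.asarray(plane.point_mm, float)
    n = vol.magnitude.shape[0]
    voxel = vol.voxel_mm
    # in-plane basis
    a = np.array([0.0, 0.0, 1.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    extent = (np.arange(n) - n / 2.0) * voxel
    uu, vv = np.meshgrid(extent, extent, indexing="ij")
    pts = point + uu[..., None] * e1 + vv[..., None] * e2  # (n, n, 3) mm
    idx = (pts / voxel + n / 2.0).transpose(2, 0, 1)  # voxel coordinates
    if idx.min() < -1 or idx.max() > n:
        raise ValueError("plane outside volume")
    P = vol.magnitude.shape[-1]
    mag = np.empty((n, n, P))
    vth = np.empty((n, n, P))
    for p in range(P):
        mag[..., p] = ndimage.map_coordinates(
            vol.magnitude[..., p], idx, order=1, mode="nearest"
        )
        comp = sum(
            normal[k]
            * ndimage.map_coordinates(
                vol.velocity[..., p, k], idx, order=1, mode="nearest"
            )
            for k in range(3)
        )
        vth[..., p] = comp
    return mag, vth


def segment_vessel_dynamic(mag: np.ndarray, seed_point) -> np.ndarray:
    """Threshold-and-track vessel segmentation per cardiac phase.

    The phase-0 seed component defines a blood-pool reference intensity;
    every phase is thresholded at ``SEGMENTATION_TAU`` times its median,
    keeping the connected component containing the seed, which is
    propagated between phases as the previous mask's centroid (a
    deterministic emulation of semi-automatic vessel tracing).

    ``mag`` has shape (ny, nx, P); returns boolean masks of the same shape.
    """
    mag = np.asarray(mag, float)
    P = mag.shape[-1]
    seed = tuple(int(round(s)) for s in seed_point)
    # bootstrap reference from a 3x3 patch, then refine from the component
    patch = mag[
        max(seed[0] - 1, 0) : seed[0] + 2, max(seed[1] - 1, 0) : seed[1] + 2, 0
    ]
    ref = np.median(patch)
    comp = _seeded_component(mag[..., 0], SEGMENTATION_TAU * ref, seed)
    if comp is None:
        raise ValueError("seed is not inside a bright component at phase 0")
    tau = SEGMENTATION_TAU * np.median(mag[..., 0][comp])
    masks = np.zeros(mag.shape, bool)
    for p in range(P):
        comp = _seeded_component(mag[..., p], tau, seed)
        if comp is None or not comp.any():
            raise ValueError(f"vessel component vanished at cardiac phase {p}")
        masks[..., p] = comp
        cy, cx = ndimage.center_of_mass(comp)
        seed = (int(round(cy)), int(round(cx)))
    return masks


def _seeded_component(img, tau, seed):
    fg = img >= tau
    if not fg[seed]:
        return None
    labels, _ = ndimage.label(fg)
    return labels == labels[seed]


def flow_metrics(
    masks: np.ndarray, vel: np.ndarray, pixel_mm: float, rr_s: float
) -> dict:
    """Area(t), Q(t), net volume and peak flow from per-phase masks and
    through-plane velocity (cm/s)."""
    masks = np.asarray(masks, bool)
    vel = np.asarray(vel, float)
    if masks.shape != vel.shape:
        raise ValueError("masks and velocity must share shape (ny, nx, P)")
    P = masks.shape[-1]
    pixel_area = pixel_mm**2
    area = masks.sum(axis=(0, 1)) * pixel_area  # mm^2
    q = 0.01 * np.array(
        [vel[..., p][masks[..., p]].sum() * pixel_area for p in range(P)]
    )  # mL/s
    return {
        "area_mm2": area,
        "q_ml_s": q,
        "net_volume_ml": float(q.sum() * rr_s / P),
        "peak_flow_ml_s": float(q.max()),
    }


def contrast_ratio(mag: np.ndarray, roi_blood, roi_myo) -> float:
    """Mean(blood ROI) / mean(myocardium ROI); ROIs are (start, stop)
    boxes per axis and must be disjoint and nonempty."""
    sl_b = tuple(slice(a, b) for a, b in roi_blood)
    sl_m = tuple(slice(a, b) for a, b in roi_myo)
    mag = np.asarray(mag, float)
    blood, myo = mag[sl_b], mag[sl_m]
    if blood.size == 0 or myo.size == 0:
        raise ValueError("empty ROI")
    in_b = np.zeros(mag.shape, bool)
    in_b[sl_b] = True
    in_m = np.zeros(mag.shape, bool)
    in_m[sl_m] = True
    if (in_b & in_m).any():
        raise ValueError("blood and myocardium ROIs overlap")
    denom = myo.mean()
    if denom == 0:
        raise ValueError("myocardium ROI mean is zero")
    return float(blood.mean() / denom)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A| + |B|); defined as 1 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def agreement_stats(series_a, series_b) -> dict:
    """Pairwise agreement between two matched series.

    Pearson r, linear regression (slope/intercept/r^2), Bland-Altman bias
    and 1.96-SD limits of agreement (sign convention a - b), mean absolute
    error, and a two-sided Wilcoxon signed-rank p value.  Any Bonferroni
    factor is applied at the reporting layer, not here.
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must be equal-length with n >= 3")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    out = {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "mean_abs_error": float(np.abs(d).mean()),
        "n": int(a.size),
    }
    if a.std() == 0 or b.std() == 0:
        out.update(pearson_r=np.nan, slope=np.nan, intercept=np.nan, r2=np.nan)
        out["zero_variance"] = True
    else:
        r = stats.pearsonr(a, b).statistic
        reg = stats.linregress(a, b)
        out.update(
            pearson_r=float(r),
            slope=float(reg.slope),
            intercept=float(reg.intercept),
            r2=float(reg.rvalue**2),
            zero_variance=False,
        )
    if np.allclose(d, 0):
        out["wilcoxon_p"] = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["wilcoxon_p"] = float(stats.wilcoxon(a, b).pvalue)
    return out


def align_peak_systole(curves) -> list:
    """Circular shifts aligning each flow curve's argmax to the first
    curve's argmax (ties broken by the earliest index).

    Returns the per-curve shift; apply with ``np.roll(curve, shift)``.
    """
    curves = [np.asarray(c, float) for c in curves]
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    ref = int(np.argmax(curves[0]))
    shifts = []
    for c in curves:
        shifts.append((ref - int(np.argmax(c))) % len(c))
    return shifts


@dataclass
class FlowReport:
    """Per-plane quantification plus pairwise agreement statistics."""

    label: str
    area_mm2: np.ndarray
    q_ml_s: np.ndarray
    net_volume_ml: float
    peak_flow_ml_s: float
    contrast_ratio: float = None
    stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "area_mm2": [float(v) for v in self.area_mm2],
            "q_ml_s": [float(v) for v in self.q_ml_s],
            "net_volume_ml": self.net_volume_ml,
            "peak_flow_ml_s": self.peak_flow_ml_s,
            "contrast_ratio": self.contrast_ratio,
            "stats": self.stats,
        }
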