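"""Focused-navigation (fNAV) respiratory motion correction.

The bulk translation of the heart is modeled as d(t) = c * r(t): the
unitless respiratory curve r(t) scaled by three per-axis coefficients in
millimeters.  The coefficients are found by minimizing an image-blur
metric — the entropy of the gradient image over a region of interest
containing the heart — of a density-compensated, cardiac-pooled adjoint
reconstruction of the phase-corrected bright-blood (FISS) data.  The same
fitted model is then applied to both sequences' k-space as a linear phase
(the exact inverse of a rigid translation), on the shared clock.

Optimizer: derivative-free coordinate search — a coarse grid (2 mm step)
per axis followed by golden-section refinement to 0.1 mm, two sweeps.
Axes to which the trajectory is blind (e.g. the through-plane axis of a
single-slice study, where k = 0) are detected and their coefficient fixed
at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import RawAcquisition
from .operators import RadialNudft, ramp_density_compensation

__all__ = [
    "MotionModel",
    "gradient_entropy",
    "entropy_of_gradient",
    "apply_respiratory_correction",
    "fit_fnav_coefficients",
    "default_heart_roi",
]

SEARCH_BOUND_MM = 25.0
COARSE_STEP_MM = 2.0
REFINE_TOL_MM = 0.1
N_SWEEPS = 2
GOLDEN = (np.sqrt(5) - 1) / 2


@dataclass
class MotionModel:
    """Rigid respiratory displacement d(t) = coeffs_mm * r(t)."""

    coeffs_mm: np.ndarray  # (3,)
    resp_times: np.ndarray  # (T,) seconds on the shared clock
    resp_values: np.ndarray  # (T,) unitless r
    entropy: float = None
    trace: list = field(default_factory=list)  # (coeffs, entropy) accepted steps
    roi: tuple = None

    def __post_init__(self):
        self.coeffs_mm = np.asarray(self.coeffs_mm, float)
        if np.max(np.abs(self.coeffs_mm)) > SEARCH_BOUND_MM + 1e-9:
            raise ValueError("coefficients exceed the search bound")

    def resp_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, float), self.resp_times, self.resp_values)

    def displacement_at(self, t) -> np.ndarray:
        """(..., 3) displacement in mm at the given times."""
        return self.resp_at(t)[..., None] * self.coeffs_mm


def entropy_of_gradient(g: np.ndarray) -> float:
    """Shannon entropy (natural log) of the normalized gradient magnitudes.

    Uniform g over N pixels gives ln N; a single nonzero pixel gives 0;
    an all-zero gradient returns +inf (maximally blurred sentinel).
    """
    g = np.abs(np.asarray(g, float)).ravel()
    total = g.sum()
    if total == 0:
        return np.inf
    p = g / total
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def gradient_entropy(image: np.ndarray, roi=None) -> float:
    """Entropy of the gradient-magnitude image over ``roi``.

    ``roi`` is a tuple of (start, stop) pairs per axis (None = full image).
    The gradient is evaluated on the ROI sub-image.
    """
    image = np.asarray(image, float)
    if roi is not None:
        sl = tuple(slice(a, b) for a, b in roi)
        image = image[sl]
    if image.size == 0:
        raise ValueError("empty ROI")
    grads = np.gradient(image)
    if image.ndim == 1:
        grads = [grads]
    g = np.sqrt(sum(gr**2 for gr in grads))
    return entropy_of_gradient(g)


def default_heart_roi(shape) -> tuple:
    """Central box of half the FOV per axis."""
    return tuple((n // 4, n // 4 + n // 2) for n in shape)


def correction_phase(raw: RawAcquisition, displacement: np.ndarray) -> np.ndarray:
    """Per-sample correction phase exp(+2j*pi*k.d(t)), shape (R, N)."""
    kr = raw.kr
    proj = np.einsum("rj,rj->r", raw.schedule.directions, displacement)
    return np.exp(2j * np.pi * np.outer(proj, kr))


def apply_respiratory_correction(
    raw: RawAcquisition, model: MotionModel
) -> RawAcquisition:
    """Multiply every readout by the inverse of the simulator's shift phase.

    The schedule, PT record and coil maps are shared (unchanged); the
    operation is exactly invertible (apply with -c to undo).
    """
    d = model.displacement_at(raw.schedule.timestamps)
    if d.shape[0] != len(raw.schedule):
        raise ValueError("displacement/schedule length mismatch")
    phase = correction_phase(raw, d)
    return raw.copy_with(raw.samples * phase[:, :, None])


def _pooled_magnitude(op, raw, dcf, phase):
    """Coil-combined magnitude of the pooled density-compensated adjoint."""
    y = raw.samples * phase[:, :, None]
    img = op.adjoint(y, weights=dcf)  # (nvox, C)
    combined = np.sum(np.conj(raw.coil_maps.maps) * img, axis=1)
    return np.abs(combined).reshape(raw.grid.shape)


def fit_fnav_coefficients(
    raw_fiss: RawAcquisition,
    r: np.ndarray = None,
    roi: tuple = None,
    bound_mm: float = SEARCH_BOUND_MM,
    coarse_step_mm: float = COARSE_STEP_MM,
    tol_mm: float = REFINE_TOL_MM,
    n_sweeps: int = N_SWEEPS,
    resp_times: np.ndarray = None,
) -> MotionModel:
    """Fit the three displacement coefficients on the FISS acquisition.

    ``r`` is the unitless respiratory curve sampled at the FISS readout
    times (or pass ``resp_times`` alongside a curve on its own time base).
    Returns the model with the achieved entropy and the accepted-step trace.
    """
    times = raw_fiss.schedule.timestamps
    if r is None:
        raise ValueError("a respiratory curve is required")
    r = np.asarray(r, float)
    if resp_times is None:
        if len(r) != len(times):
            raise ValueError("r must be sampled at the FISS readout times")
        resp_times = times
        r_ro = r
    else:
        r_ro = np.interp(times, resp_times, r)
    if roi is None:
        roi = default_heart_roi(raw_fiss.grid.shape)

    model_kwargs = dict(resp_times=resp_times, resp_values=r, roi=roi)
    if np.max(np.abs(r_ro)) < 1e-12:
        warnings.warn("degenerate (all-zero) respiratory curve: returning c = 0")
        m = MotionModel(coeffs_mm=np.zeros(3), **model_kwargs)
        m.entropy = np.nan
        return m

    op = RadialNudft(
        raw_fiss.schedule.directions, raw_fiss.kr, raw_fiss.grid, np.complex64
    )
    dcf = ramp_density_compensation(raw_fiss.kr)
    proj = raw_fiss.schedule.directions  # (R, 3)
    kr = raw_fiss.kr

    # axes the trajectory can see; others are fixed at zero
    visible = np.max(np.abs(proj), axis=0) > 1e-9

    cache = {}

    def objective(c):
        key = tuple(np.round(c, 6))
        if key not in cache:
            d = r_ro[:, None] * np.asarray(c, float)
            phase = np.exp(2j * np.pi * np.outer(np.einsum("rj,rj->r", proj, d), kr))
            img = _pooled_magnitude(op, raw_fiss, dcf, phase.astype(np.complex64))
            cache[key] = gradient_entropy(img, roi)
        return cache[key]

    c = np.zeros(3)
    best = objective(c)
    trace = [(c.copy(), best)]

    def golden_section(axis, lo, hi, c, f_best):
        x1 = hi - GOLDEN * (hi - lo)
        x2 = lo + GOLDEN * (hi - lo)
        cand = c.copy()
        cand[axis] = x1
        f1 = objective(cand)
        cand[axis] = x2
        f2 = objective(cand)
        while hi - lo > tol_mm:
            if f1 < f2:
                hi, x2, f2 = x2, x1, f1
                x1 = hi - GOLDEN * (hi - lo)
                cand[axis] = x1
                f1 = objective(cand)
            else:
                lo, x1, f1 = x1, x2, f2
                x2 = lo + GOLDEN * (hi - lo)
                cand[axis] = x2
                f2 = objective(cand)
        x = x1 if f1 < f2 else x2
        f = min(f1, f2)
        return (x, f) if f < f_best else (c[axis], f_best)

    for sweep in range(n_sweeps):
        for axis in range(3):
            if not visible[axis]:
                continue
            # coarse grid every sweep: the landscape along one axis changes
            # once the other axes have been corrected.  After the first
            # sweep the basin is known, so later sweeps re-grid locally.
            if sweep == 0:
                grid = np.arange(-bound_mm + 1, bound_mm, coarse_step_mm)
            else:
                grid = np.arange(
                    max(-bound_mm, c[axis] - 3 * coarse_step_mm),
                    min(bound_mm, c[axis] + 3 * coarse_step_mm) + 1e-9,
                    coarse_step_mm,
                )
            vals = []
            for g in grid:
                cand = c.copy()
                cand[axis] = g
                vals.append(objective(cand))
            i = int(np.argmin(vals))
            if vals[i] < best:
                c[axis], best = grid[i], vals[i]
            lo = max(-bound_mm, c[axis] - coarse_step_mm)
            hi = min(bound_mm, c[axis] + coarse_step_mm)
            x, f = golden_section(axis, lo, hi, c, best)
            if f < best:
                c[axis], best = x, f
                trace.append((c.copy(), best))
    op.free()
    m = MotionModel(coeffs_mm=c, **model_kwargs)
    m.entropy = best
    m.trace = trace
    return m
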