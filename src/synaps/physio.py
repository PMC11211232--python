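"""Cardiac and respiratory gating from the pilot-tone record.

One PT record spans both acquisitions on a shared clock, so triggers and
the respiratory curve are derived once and apply to both sequences'
schedules without re-estimation.

Cardiac path: PCA (<= 8 components) -> FastICA -> pick the component whose
spectral peak dominates the cardiac band (0.5-3.0 Hz, i.e. 30-180 bpm) ->
canonicalize polarity so the sharper extrema are the minima (triggers are
defined at local minima) -> zero-phase band-pass re-centered on the
component's own spectral peak (+/- 0.3 Hz).

Respiratory path: PCA -> pick the component with dominant power in the
respiratory band (0.05-0.7 Hz, 3-42 breaths/min) -> zero-phase low-pass at
its peak + 0.1 Hz -> per-sequence linear detrend -> remove the step offset
at the inter-sequence gap by matching medians in +/- 10 s windows ->
normalize to unit maximum absolute amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA, FastICA

__all__ = [
    "CARDIAC_BAND_HZ",
    "RESPIRATORY_BAND_HZ",
    "PhysioExtractionError",
    "PhysioRecord",
    "BinningConfig",
    "extract_cardiac_signal",
    "detect_triggers",
    "extract_respiratory_curve",
    "assign_cardiac_phase",
    "extract_physio",
]

CARDIAC_BAND_HZ = (0.5, 3.0)
RESPIRATORY_BAND_HZ = (0.05, 0.7)
#: half-width of the adaptive band-pass around the cardiac spectral peak
CARDIAC_HALFBAND_HZ = 0.3
#: margin added to the respiratory spectral peak for the low-pass cutoff
RESP_LOWPASS_MARGIN_HZ = 0.1
#: a spectral peak must exceed this multiple of the median PSD to count
PEAK_DOMINANCE = 10.0


class PhysioExtractionError(RuntimeError):
    """No component with an in-band spectral peak could be found."""


@dataclass(frozen=True)
class BinningConfig:
    n_phases: int = 20

    def __post_init__(self):
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")


@dataclass
class PhysioRecord:
    """Derived gating signals on the shared clock starting at t = 0."""

    cardiac_signal: np.ndarray
    trigger_times: np.ndarray
    resp_curve: np.ndarray  # unitless, max|r| = 1, at fs
    fs: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.cardiac_signal)) / self.fs

    def resp_at(self, t) -> np.ndarray:
        """Respiratory curve resampled at arbitrary times (linear interp)."""
        return np.interp(np.asarray(t, float), self.times, self.resp_curve)


def _welch(x, fs):
    nper = min(len(x), max(256, int(fs * 40)))
    return sps.welch(x, fs=fs, nperseg=nper)


def _band_peak(x, fs, band):
    """(peak_freq, dominance) of the PSD peak restricted to ``band``;
    dominance is peak/median over the full PSD."""
    f, p = _welch(x, fs)
    med = np.median(p[f > 0])
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel) or med <= 0:
        return None, 0.0
    i = np.argmax(p[sel])
    return f[sel][i], p[sel][i] / med


def _bandpass(x, fs, lo, hi):
    lo = max(lo, 1e-3)
    hi = min(hi, 0.49 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _lowpass(x, fs, cutoff):
    sos = sps.butter(4, min(cutoff, 0.49 * fs), btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _lowpass_padded(x, fs, cutoff, f0):
    """Zero-phase low-pass with padding extended to a few signal periods,
    which tames the edge transients on short sequence windows."""
    sos = sps.butter(4, min(cutoff, 0.49 * fs), btype="lowpass", fs=fs, output="sos")
    padlen = min(len(x) - 1, int(3.0 / max(f0, 1e-3) * fs))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def _extrema_sharpness(x, fs, f0):
    """Mean |second difference| at local minima and maxima of a lightly
    smoothed copy of x; used to canonicalize ICA polarity."""
    x = _lowpass(x, fs, 3.0 * f0)
    dist = max(1, int(0.5 * fs / f0))
    d2 = np.zeros_like(x)
    d2[1:-1] = x[:-2] - 2 * x[1:-1] + x[2:]
    mins, _ = sps.find_peaks(-x, distance=dist)
    maxs, _ = sps.find_peaks(x, distance=dist)
    sharp_min = np.abs(d2[mins]).mean() if len(mins) else 0.0
    sharp_max = np.abs(d2[maxs]).mean() if len(maxs) else 0.0
    return sharp_min, sharp_max


def extract_cardiac_signal(pt: np.ndarray, fs: float) -> np.ndarray:
    """Cardiac time series from the PT channel matrix (channel x time)."""
    pt = np.atleast_2d(np.asarray(pt, float))
    if pt.shape[0] < 2:
        raise ValueError("need at least 2 PT channels")
    if pt.shape[1] / fs < 10.0:
        raise ValueError("need at least 10 s of PT data")
    x = (pt - pt.mean(axis=1, keepdims=True)).T  # (T, C)
    n_comp = min(8, pt.shape[0])
    scores = PCA(n_components=n_comp, random_state=0).fit_transform(x)
    ica = FastICA(n_components=n_comp, random_state=0, max_iter=1000, tol=1e-4)
    with warnings.catch_warnings():
        # mixing separability, not full ICA convergence, is what matters here
        warnings.simplefilter("ignore")
        comps = ica.fit_transform(scores).T  # (n_comp, T)
    best, best_dom, best_f = None, 0.0, None
    for comp in comps:
        f0, dom = _band_peak(comp, fs, CARDIAC_BAND_HZ)
        if f0 is not None and dom > best_dom:
            best, best_dom, best_f = comp, dom, f0
    if best is None or best_dom < PEAK_DOMINANCE:
        raise PhysioExtractionError(
            "no ICA component with a dominant spectral peak in the cardiac band"
        )
    sharp_min, sharp_max = _extrema_sharpness(best, fs, best_f)
    if sharp_max > sharp_min:  # triggers live at minima: make minima the sharp side
        best = -best
    out = _bandpass(best, fs, best_f - CARDIAC_HALFBAND_HZ, best_f + CARDIAC_HALFBAND_HZ)
    return out / np.abs(out).max()


def detect_triggers(cardiac: np.ndarray, fs: float) -> np.ndarray:
    """Trigger times (s) at interior local minima of the cardiac signal,
    with refractory spacing >= 0.5 / f_peak."""
    cardiac = np.asarray(cardiac, float)
    if cardiac.size == 0:
        raise ValueError("empty cardiac series")
    if np.ptp(cardiac) == 0:
        warnings.warn("constant cardiac signal: no triggers detected")
        return np.array([])
    f0, _ = _band_peak(cardiac, fs, CARDIAC_BAND_HZ)
    if f0 is None or f0 <= 0:
        f0 = CARDIAC_BAND_HZ[0]
    dist = max(1, int(round(0.5 * fs / f0)))
    idx, _ = sps.find_peaks(-cardiac, distance=dist)
    return idx / fs


def extract_respiratory_curve(
    pt: np.ndarray, fs: float, gap_time: float = None
) -> np.ndarray:
    """Unitless respiratory curve r(t) spanning both acquisitions."""
    pt = np.atleast_2d(np.asarray(pt, float))
    x = (pt - pt.mean(axis=1, keepdims=True)).T
    n_comp = min(8, pt.shape[0])
    comps = PCA(n_components=n_comp, random_state=0).fit_transform(x).T
    best, best_dom, best_f = None, 0.0, None
    for comp in comps:
        f0, dom = _band_peak(comp, fs, RESPIRATORY_BAND_HZ)
        if f0 is not None and dom > best_dom:
            best, best_dom, best_f = comp, dom, f0
    if best is None or best_dom < PEAK_DOMINANCE:
        raise PhysioExtractionError(
            "no principal component with dominant respiratory-band power"
        )
    t = np.arange(len(best)) / fs
    if gap_time is None:
        segments = [np.ones(len(best), bool)]
    else:
        segments = [t < gap_time, t >= gap_time]
    # low-pass and detrend each sequence separately so the inter-sequence
    # step neither rings through the filter nor biases the trend fit; the
    # linear trend is estimated on a central span covering an integer
    # number of respiratory periods so the oscillation does not leak into it
    r = np.empty_like(best)
    for sel in segments:
        m = np.count_nonzero(sel)
        if m <= 1:
            r[sel] = best[sel]
            continue
        seg = _lowpass_padded(best[sel], fs, best_f + RESP_LOWPASS_MARGIN_HZ, best_f)
        ts = t[sel]
        span = m
        i0 = 0
        if best_f > 0:
            n_per = int(np.floor(m / fs * best_f))
            if n_per >= 1:
                span = int(round(n_per / best_f * fs))
                i0 = (m - span) // 2
        coef = np.polyfit(ts[i0 : i0 + span], seg[i0 : i0 + span], 1)
        r[sel] = seg - np.polyval(coef, ts)
    if gap_time is not None:
        # residual step: match medians around the gap.  The windows span an
        # integer number of respiratory periods (up to 10 s) so that the
        # oscillation itself does not bias the medians.
        win = 10.0
        if best_f > 0:
            win = max(1.0, np.floor(10.0 * best_f)) / best_f
        before = (t >= gap_time - win) & (t < gap_time)
        after = (t >= gap_time) & (t < gap_time + win)
        if np.any(before) and np.any(after):
            r[t >= gap_time] -= np.median(r[after]) - np.median(r[before])
    peak = np.abs(r).max()
    return r / peak if peak > 0 else r


def assign_cardiac_phase(
    t, triggers: np.ndarray, cfg: BinningConfig
) -> np.ndarray:
    """Phase index per timestamp; -1 flags readouts outside all RR intervals.

    Within [T_k, T_{k+1}): phase = floor((t - T_k)/(T_{k+1} - T_k) * P),
    clipped to P - 1.
    """
    triggers = np.asarray(triggers, float)
    if len(triggers) < 2:
        raise ValueError("need at least 2 triggers")
    t = np.atleast_1d(np.asarray(t, float))
    P = cfg.n_phases
    k = np.searchsorted(triggers, t, side="right") - 1
    valid = (k >= 0) & (k < len(triggers) - 1)
    phase = np.full(t.shape, -1, dtype=int)
    kv = k[valid]
    frac = (t[valid] - triggers[kv]) / (triggers[kv + 1] - triggers[kv])
    phase[valid] = np.minimum((frac * P).astype(int), P - 1)
    return phase


def extract_physio(
    pt, fs: float, gap_time: float = None, binning: BinningConfig = None
) -> PhysioRecord:
    """Run the full extraction: cardiac signal, triggers, respiratory curve."""
    data = pt.data if hasattr(pt, "data") else np.asarray(pt)
    if gap_time is None and hasattr(pt, "gap_time_s"):
        gap_time = pt.gap_time_s
    cardiac = extract_cardiac_signal(data, fs)
    triggers = detect_triggers(cardiac, fs)
    resp = extract_respiratory_curve(data, fs, gap_time)
    return PhysioRecord(
        cardiac_signal=cardiac, trigger_times=triggers, resp_curve=resp, fs=fs
    )
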