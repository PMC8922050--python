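"""Calcium-transient quantification: dF/F, ROIs, tSNR, FWHMs, statistics.

The relative fluorescence change of a trace ``F(t)`` is

    dF/F = (F - F0) / (F0 - Fd)

with ``F0`` the mean over a pre-stimulus baseline window (convention: 20
samples = 1 s at 20 frames/s) and ``Fd`` the camera's constant dark signal.
Values are reported in percent.

Functionally responding structures are located on an *activation map*, the
per-pixel variance of dF/F over time; ROIs are the top 2 percentile of
map values; contours for display are ``dilate(mask) XOR mask``.  The
temporal signal-to-noise ratio (tSNR) divides the peak dF/F (%) after
stimulus onset by the baseline noise (%), the standard deviation of the
baseline dF/F.  Transient decay time and spatial signal confinement are both
reported as full widths at half maximum (FWHM) with linear interpolation of
the half-maximum crossings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "TraceSet",
    "ActivationResult",
    "ROI",
    "TransientMetrics",
    "dff",
    "activation_map",
    "extract_roi",
    "roi_contour",
    "transient_metrics",
    "roi_timecourse",
    "fwhm_linear",
    "spatial_profile",
    "depth_profile",
    "signal_std_map",
    "depth_center_of_mass",
    "compare_paired",
]


class DegenerateBaseline(ValueError):
    """Raised when the baseline mean does not exceed the dark signal."""


@dataclass
class TraceSet:
    """A raw fluorescence trace with its derived dF/F time course.

    ``f`` raw counts; ``f0`` baseline mean (counts); ``fd`` dark signal
    (counts); ``dff_pct`` the dF/F trace in percent; ``dt_s`` frame interval;
    ``baseline`` the baseline sample indices.
    """

    f: np.ndarray
    f0: float
    fd: float
    dff_pct: np.ndarray
    dt_s: float
    baseline: np.ndarray

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.f.size) * self.dt_s


@dataclass
class ActivationResult:
    """Per-pixel variance of dF/F over time, with a validity mask."""

    map: np.ndarray
    valid: np.ndarray


@dataclass
class ROI:
    """A pixel/voxel mask with its extraction provenance."""

    mask: np.ndarray
    percentile: float
    label: str = "somatic"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class TransientMetrics:
    """Headline transient numbers: peak (%), noise (%), tSNR, decay FWHM (s)."""

    peak_pct: float
    noise_pct: float
    tsnr: float
    decay_s: float
    decay_field_limited: bool = False


def dff(
    f: np.ndarray,
    baseline: Sequence[int] | slice,
    fd: float,
    dt_s: float = 0.05,
) -> TraceSet:
    """Compute dF/F (%) of a raw trace against a pre-stimulus baseline window."""
    f = np.asarray(f, dtype=float)
    idx = np.arange(f.size)[baseline] if isinstance(baseline, slice) else np.asarray(baseline)
    if idx.size == 0:
        raise ValueError("baseline window is empty")
    f0 = float(f[idx].mean())
    if not f0 > fd:
        raise DegenerateBaseline(f"baseline mean {f0} does not exceed dark signal {fd}")
    rel = (f - f0) / (f0 - fd) * 100.0
    return TraceSet(f, f0, float(fd), rel, dt_s, idx)


def activation_map(
    series: np.ndarray,
    baseline: Sequence[int] | slice,
    fd: float,
) -> ActivationResult:
    """Variance over time of the per-pixel dF/F of a (t, ...) series.

    Population variance (divide by N): the map only ranks pixels.  Pixels
    whose baseline does not exceed the dark signal are flagged invalid and
    set to zero.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 frames for a variance map")
    idx = (
        np.arange(series.shape[0])[baseline]
        if isinstance(baseline, slice)
        else np.asarray(baseline)
    )
    f0 = series[idx].mean(axis=0)
    valid = f0 > fd
    denom = np.where(valid, f0 - fd, 1.0)
    rel = (series - f0) / denom * 100.0
    amap = rel.var(axis=0)
    amap = np.where(valid, amap, 0.0)
    return ActivationResult(amap, valid)


def extract_roi(
    amap: np.ndarray,
    percentile: float = 98.0,
    label: str = "somatic",
) -> ROI:
    """Mask of map values at or above the given percentile (default: top 2%).

    The threshold is the linear-interpolation percentile of the flattened
    map; ties at the threshold are all included.
    """
    amap = np.asarray(amap, dtype=float)
    if np.ptp(amap) == 0:
        raise ValueError("degenerate activation map: all values equal")
    thr = np.percentile(amap, percentile)
    return ROI(amap >= thr, percentile, label)


def roi_contour(roi: ROI | np.ndarray) -> np.ndarray:
    """Expanded outline ``dilate(mask) XOR mask`` (3x3 structuring element in 2D)."""
    mask = roi.mask if isinstance(roi, ROI) else np.asarray(roi, dtype=bool)
    struct = ndimage.generate_binary_structure(mask.ndim, mask.ndim)
    return ndimage.binary_dilation(mask, structure=struct) ^ mask


def _half_crossing(t: np.ndarray, y: np.ndarray, half: float, i_peak: int, direction: int) -> float | None:
    """Time of the first half-level crossing walking from the peak outward."""
    i = i_peak
    while 0 <= i + direction < y.size:
        j = i + direction
        if y[j] <= half:
            # linear interpolation between samples i and j
            if y[i] == y[j]:
                return t[j]
            frac = (y[i] - half) / (y[i] - y[j])
            return t[i] + frac * (t[j] - t[i])
        i = j
    return None


def fwhm_linear(
    y: np.ndarray,
    spacing: float = 1.0,
    baseline: float = 0.0,
) -> tuple[float, bool]:
    """FWHM of a 1D profile by linear interpolation of half-maximum crossings.

    ``baseline`` is the zero level; the half level is midway between baseline
    and the profile maximum.  Returns ``(width, field_limited)``: when the
    profile never drops below half maximum on one side, the width is measured
    to the field edge and flagged.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("profile too short for a FWHM")
    t = np.arange(y.size) * spacing
    i_peak = int(np.argmax(y))
    half = baseline + (y[i_peak] - baseline) / 2.0
    left = _half_crossing(t, y, half, i_peak, -1)
    right = _half_crossing(t, y, half, i_peak, +1)
    limited = left is None or right is None
    if left is None:
        left = t[0]
    if right is None:
        right = t[-1]
    return float(right - left), limited


def transient_metrics(
    ts: TraceSet,
    stim_onset_s: float | Sequence[float],
) -> TransientMetrics:
    """Peak (%), baseline noise (%), tSNR and decay FWHM (s) of a transient.

    The peak is the global maximum of dF/F from the first stimulus onset to
    the end of the trace; the noise is the sample standard deviation (ddof=1)
    of the baseline dF/F; tSNR = peak / noise.  The decay time is the FWHM of
    the transient around the peak, with the pre-stimulus baseline mean as the
    zero level, searched within the surrounding inter-stimulus interval.
    """
    onsets = np.atleast_1d(np.asarray(stim_onset_s, dtype=float))
    if ts.baseline.size < 2:
        raise ValueError("baseline window must hold at least 2 samples")
    i0 = int(np.ceil(onsets.min() / ts.dt_s))
    if i0 >= ts.dff_pct.size:
        raise ValueError("no post-stimulus segment in the trace")
    seg = ts.dff_pct[i0:]
    peak = float(seg.max())
    noise = float(ts.dff_pct[ts.baseline].std(ddof=1))
    if noise == 0:
        raise ZeroDivisionError("zero baseline variance: tSNR undefined")
    i_peak = i0 + int(np.argmax(seg))
    t_peak = i_peak * ts.dt_s
    later = onsets[onsets > t_peak + 1e-9]
    i_end = int(np.floor(later.min() / ts.dt_s)) if later.size else ts.dff_pct.size
    base_level = float(ts.dff_pct[ts.baseline].mean())
    window = ts.dff_pct[:i_end]
    t = np.arange(window.size) * ts.dt_s
    half = base_level + (window[i_peak] - base_level) / 2.0
    left = _half_crossing(t, window, half, i_peak, -1)
    right = _half_crossing(t, window, half, i_peak, +1)
    limited = left is None or right is None
    if left is None:
        left = t[0]
    if right is None:
        right = t[-1]
    return TransientMetrics(peak, noise, peak / noise, float(right - left), limited)


def roi_timecourse(
    series: np.ndarray,
    roi: ROI | np.ndarray,
    baseline: Sequence[int] | slice,
    fd: float,
    dt_s: float = 0.05,
) -> TraceSet:
    """dF/F of the ROI-mean raw intensity of a (t, ...) series."""
    series = np.asarray(series, dtype=float)
    mask = roi.mask if isinstance(roi, ROI) else np.asarray(roi, dtype=bool)
    if mask.shape != series.shape[1:]:
        raise ValueError("ROI mask does not match the series geometry")
    if not mask.any():
        raise ValueError("empty ROI mask")
    f = series[:, mask].mean(axis=1)
    return dff(f, baseline, fd, dt_s)


def spatial_profile(
    volume: np.ndarray,
    axis: str,
    *,
    through: tuple[int, ...] | None = None,
    pitch_um: float = 1.0,
    baseline: float = 0.0,
) -> tuple[np.ndarray, float, bool]:
    """1D intensity profile along ``axis`` ("z", "x" or "y") and its FWHM (um).

    ``volume`` has axes (z, x, y).  With ``through`` a (z, x, y) index tuple,
    the profile is the line through that point; without it, the profile is
    the maximum-intensity projection onto the axis.  Returns
    ``(profile, fwhm_um, field_limited)``.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must have axes (z, x, y)")
    ax = {"z": 0, "x": 1, "y": 2}[axis]
    if through is not None:
        sel = list(through)
        sel[ax] = slice(None)
        profile = volume[tuple(sel)]
    else:
        other = tuple(i for i in range(3) if i != ax)
        profile = volume.max(axis=other)
    if np.ptp(profile) == 0:
        raise ValueError("profile is degenerate along the requested axis")
    width, limited = fwhm_linear(profile, pitch_um, baseline)
    return profile, width, limited


def depth_profile(
    series: np.ndarray,
    roi: ROI | np.ndarray,
    baseline: Sequence[int] | slice,
    fd: float,
    z_um: np.ndarray,
    dt_s: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Depth-resolved dF/F of a lateral ROI and its time-summed depth curve.

    ``series`` has axes (t, z, x, y); the ROI is a lateral (x, y) mask applied
    at every depth.  Returns ``(depth_time, depth_curve, com_z_um)`` where
    ``depth_time[z, t]`` is the dF/F trace per depth, ``depth_curve`` its sum
    over time, and ``com_z_um`` the intensity-weighted centre-of-mass depth of
    the non-negative part of the curve.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must have axes (t, z, x, y)")
    mask = roi.mask if isinstance(roi, ROI) else np.asarray(roi, dtype=bool)
    z_um = np.asarray(z_um, dtype=float)
    rows = []
    for iz in range(series.shape[1]):
        ts = roi_timecourse(series[:, iz], mask, baseline, fd, dt_s)
        rows.append(ts.dff_pct)
    depth_time = np.stack(rows)
    depth_curve = depth_time.sum(axis=1)
    w = np.clip(depth_curve, 0.0, None)
    com = float((w * z_um).sum() / w.sum()) if w.sum() > 0 else float("nan")
    return depth_time, depth_curve, com


def signal_std_map(
    series: np.ndarray,
    baseline: Sequence[int] | slice,
    fd: float,
) -> ActivationResult:
    """Noise-corrected activation: std of the *signal* part of dF/F.

    The raw activation map mixes signal variance with a shot/read-noise
    variance floor that is present in every voxel and biases depth profiles
    toward the window centre.  The baseline window measures that floor, so
    ``sqrt(max(var_total - var_baseline, 0))`` estimates the standard
    deviation of the stimulus-evoked component alone.  Reported as std (not
    variance) so profiles scale linearly with signal amplitude.
    """
    series = np.asarray(series, dtype=float)
    idx = (
        np.arange(series.shape[0])[baseline]
        if isinstance(baseline, slice)
        else np.asarray(baseline)
    )
    res = activation_map(series, baseline, fd)
    f0 = series[idx].mean(axis=0)
    denom = np.where(res.valid, f0 - fd, 1.0)
    rel_base = (series[idx] - f0) / denom * 100.0
    var_base = rel_base.var(axis=0)
    sig = np.sqrt(np.clip(res.map - var_base, 0.0, None))
    return ActivationResult(np.where(res.valid, sig, 0.0), res.valid)


def depth_center_of_mass(
    profile: np.ndarray,
    z_um: np.ndarray,
    window_um: float = 12.0,
    max_iter: int = 30,
) -> float:
    """Centre-of-mass depth of an axial profile, iteratively windowed.

    A plain centre of mass over the full reconstructed range is skewed both
    by the residual noise floor and by truncation of the broad axial response
    at the window edges.  Iterative centroiding (standard in particle
    localization) removes the truncation skew: the CoM is recomputed over a
    window of half-width ``window_um`` centred on the running estimate, with
    the in-window minimum subtracted as the local floor, until it converges.
    """
    profile = np.asarray(profile, dtype=float)
    z_um = np.asarray(z_um, dtype=float)
    w = np.clip(profile, 0.0, None)
    if w.sum() == 0:
        return float("nan")
    com = float((w * z_um).sum() / w.sum())
    for _ in range(max_iter):
        sel = np.abs(z_um - com) <= window_um
        ww = np.clip(profile[sel] - profile[sel].min(), 0.0, None)
        if ww.sum() == 0:
            break
        new = float((ww * z_um[sel]).sum() / ww.sum())
        if abs(new - com) < 1e-3:
            com = new
            break
        com = new
    return com


def _median_iqr(x: np.ndarray) -> dict:
    return {
        "median": float(np.median(x)),
        "iqr": [float(np.percentile(x, 25)), float(np.percentile(x, 75))],
    }


def compare_paired(
    *conditions: Sequence[float],
    test: str = "wilcoxon",
) -> dict:
    """Paired nonparametric comparison with median [IQR] summaries.

    ``test="wilcoxon"`` (exactly 2 conditions): matched-pairs signed-rank
    test, exact null distribution for small samples.  ``test="friedman"``
    (>= 3 conditions): two-way analysis of variance by ranks.  Degenerate
    inputs (all differences zero / all ranks tied) return the null-extreme
    statistic with p = 1.
    """
    arrays = [np.asarray(c, dtype=float) for c in conditions]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("paired samples must have equal lengths")
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    out: dict = {"n": n, "test": test, "summaries": [_median_iqr(a) for a in arrays]}
    if test == "wilcoxon":
        if len(arrays) != 2:
            raise ValueError("wilcoxon compares exactly 2 conditions")
        d = arrays[0] - arrays[1]
        if np.all(d == 0):
            out.update(statistic=0.0, p_value=1.0)
            return out
        method = "exact" if n <= 25 else "auto"
        res = stats.wilcoxon(arrays[0], arrays[1], method=method)
        out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
        return out
    if test == "friedman":
        if len(arrays) < 3:
            raise ValueError("friedman requires at least 3 conditions")
        block = np.stack(arrays, axis=1)
        if np.all(np.ptp(block, axis=1) == 0):
            out.update(statistic=0.0, p_value=1.0)
            return out
        res = stats.friedmanchisquare(*arrays)
        out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
        return out
    raise ValueError(f"unknown test {test!r}")
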