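"""Kymograph construction, pointed-end tracking and depolymerization-rate fits.

The experimental procedure this automates: build a space-time image
(kymograph) by resampling each movie frame along the filament line, follow
the shrinking end down the kymograph, and fit a straight line to the end
trajectory.  The line's slope, divided by the subunit rise (~2.7 nm), is the
depolymerization rate in subunits/s.  Trajectories whose residuals indicate
a pause or a severing step are discarded with a reason rather than fitted
blindly, mirroring the manual exclusion applied to real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from typing import Literal

Side = Literal["left", "right"]


@dataclass
class Kymograph:
    """Space-time intensity image: rows = frames, columns = position."""

    intensity: np.ndarray
    pixel_size: float  # nm
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (time x position)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("kymograph intensities must be finite")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class EndTrack:
    """Per-frame end positions (nm) with per-frame quality flags."""

    times: np.ndarray
    position_nm: np.ndarray
    flagged: np.ndarray  # True where the end could not be detected reliably
    snr: np.ndarray


@dataclass
class DepolRateResult:
    """Result of fitting an end trajectory.

    ``slope`` is the signed end velocity in nm/s; ``rate`` is its magnitude
    converted to subunits/s.  ``discarded`` is set (with ``reason``) when the
    trajectory shows a pause/step inconsistent with a single constant rate.
    """

    slope: float  # nm/s, signed
    rate: float  # subunits/s, magnitude
    fit_residual: float  # nm RMS
    n_frames_used: int
    discarded: bool = False
    reason: str = ""


def build_kymograph(
    movie: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    width: int = 1,
    *,
    pixel_size: float,
    frame_interval: float,
    reduce: str = "max",
) -> Kymograph:
    """Resample each frame of ``movie`` along ``line`` to build a kymograph.

    ``line`` is ((x0, y0), (x1, y1)) in pixel coordinates; intensities are
    sampled at unit spacing along the line and reduced (max or mean) across
    ``width`` perpendicular offsets, emulating the ImageJ reslice operation.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] == 0:
        raise ValueError("movie must be a non-empty (frames, height, width) stack")
    if width < 1:
        raise ValueError("width must be >= 1")
    (x0, y0), (x1, y1) = line
    h, w = movie.shape[1:]
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError("line endpoint outside the image")
    length = float(np.hypot(x1 - x0, y1 - y0))
    n_samples = int(np.round(length)) + 1
    t = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + (x1 - x0) * t
    ys = y0 + (y1 - y0) * t
    # unit normal for perpendicular width offsets
    if length > 0:
        nx, ny = -(y1 - y0) / length, (x1 - x0) / length
    else:
        nx, ny = 0.0, 1.0
    offsets = np.arange(width) - (width - 1) / 2.0

    rows = np.empty((movie.shape[0], n_samples))
    stack = np.empty((width, n_samples))
    for k in range(movie.shape[0]):
        for j, d in enumerate(offsets):
            coords = np.vstack([ys + d * ny, xs + d * nx])
            stack[j] = ndimage.map_coordinates(movie[k], coords, order=1, mode="nearest")
        rows[k] = stack.max(axis=0) if reduce == "max" else stack.mean(axis=0)
    return Kymograph(intensity=rows, pixel_size=pixel_size, frame_interval=frame_interval)


def _row_threshold(row: np.ndarray, n_iter: int = 4) -> tuple[float, float, float, float]:
    """Isodata-style split of a row into filament plateau and background.

    Returns (threshold, plateau, background, background_sd).
    """
    thr = 0.5 * (row.min() + row.max())
    fg_med = bg_med = thr
    for _ in range(n_iter):
        fg = row[row > thr]
        bg = row[row <= thr]
        if len(fg) == 0 or len(bg) == 0:
            break
        fg_med = float(np.median(fg))
        bg_med = float(np.median(bg))
        thr = 0.5 * (fg_med + bg_med)
    bg = row[row <= thr]
    bg_sd = float(np.std(bg)) if len(bg) > 1 else 0.0
    return thr, fg_med, bg_med, bg_sd


def track_end(
    kymo: Kymograph,
    side: Side = "right",
    *,
    smooth_px: int = 3,
    snr_min: float = 4.0,
) -> EndTrack:
    """Track the filament end in each kymograph row by half-maximum crossing.

    Each row is median-smoothed, split into plateau/background levels, and
    the end is placed at the sub-pixel crossing of the half-maximum
    (plateau+background)/2 level on the requested side.  Rows failing an SNR
    check, or with no detectable filament, are flagged rather than fatal.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if kymo.n_frames < 5:
        raise ValueError("kymograph must have at least 5 frames")
    n_frames, n_px = kymo.intensity.shape
    pos = np.full(n_frames, np.nan)
    flagged = np.zeros(n_frames, dtype=bool)
    snr = np.zeros(n_frames)
    for k in range(n_frames):
        row = ndimage.median_filter(kymo.intensity[k], size=smooth_px, mode="nearest")
        thr, plateau, bg, bg_sd = _row_threshold(row)
        snr[k] = (plateau - bg) / bg_sd if bg_sd > 0 else np.inf
        above = np.flatnonzero(row >= thr)
        if len(above) < 2 or snr[k] < snr_min:
            flagged[k] = True
            continue
        if side == "right":
            j = above[-1]
            if j == n_px - 1:
                flagged[k] = True
                continue
            frac = (row[j] - thr) / (row[j] - row[j + 1])
            p = j + frac
        else:
            j = above[0]
            if j == 0:
                flagged[k] = True
                continue
            frac = (row[j] - thr) / (row[j] - row[j - 1])
            p = j - frac
        pos[k] = (p + 0.5) * kymo.pixel_size
    return EndTrack(times=kymo.times, position_nm=pos, flagged=flagged, snr=snr)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return float(slope), float(intercept), resid


def _two_segment_rms(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Best two-segment piecewise-linear fit: (rms, slope1, slope2, jump).

    ``jump`` is the fitted position discontinuity at the breakpoint (a
    severing event removes the tracked end segment, which appears as an
    instantaneous jump rather than a slope change).
    """
    n = len(t)
    best = (np.inf, 0.0, 0.0, 0.0)
    step = max(1, n // 60)
    for b in range(3, n - 2, step):
        s1, i1, r1 = _ols_line(t[:b], y[:b])
        s2, i2, r2 = _ols_line(t[b:], y[b:])
        rms = float(np.sqrt((np.sum(r1**2) + np.sum(r2**2)) / n))
        if rms < best[0]:
            tb = t[b]
            jump = abs((s2 * tb + i2) - (s1 * tb + i1))
            best = (rms, s1, s2, jump)
    return best


def _three_segment_rms(
    t: np.ndarray, y: np.ndarray, min_seg: int = 5, n_grid: int = 24
) -> tuple[float, float, float, float, float]:
    """Best three-segment fit: (rms, s1, s2, s3, middle duration)."""
    n = len(t)
    cands = np.unique(np.linspace(min_seg, n - min_seg, n_grid).astype(int))
    best = (np.inf, 0.0, 0.0, 0.0, 0.0)
    for i, b1 in enumerate(cands):
        for b2 in cands[i + 1 :]:
            if b2 - b1 < min_seg:
                continue
            s1, _, r1 = _ols_line(t[:b1], y[:b1])
            s2, _, r2 = _ols_line(t[b1:b2], y[b1:b2])
            s3, _, r3 = _ols_line(t[b2:], y[b2:])
            rms = float(
                np.sqrt((np.sum(r1**2) + np.sum(r2**2) + np.sum(r3**2)) / n)
            )
            if rms < best[0]:
                best = (rms, s1, s2, s3, float(t[b2 - 1] - t[b1]))
    return best


def fit_depolymerization_rate(
    end_positions_nm: np.ndarray,
    frame_interval: float,
    subunit_rise: float = 2.7,
    *,
    flags: np.ndarray | None = None,
    outlier_mad: float = 3.0,
    pause_rms_improvement: float = 0.4,
    pause_slope_ratio: float = 3.0,
    min_frames: int = 5,
) -> DepolRateResult:
    """Fit a robust line to an end trajectory and convert the slope to subunits/s.

    Ordinary least squares with one pass of MAD-based outlier rejection.  A
    two-segment piecewise fit is compared against the single line: when it
    reduces the RMS residual by more than ``pause_rms_improvement`` (default
    40%) and the two segment slopes differ more than ``pause_slope_ratio``
    fold, the trajectory is discarded as containing a pause or severing step.
    """
    y = np.asarray(end_positions_nm, dtype=float)
    t = np.arange(len(y)) * frame_interval
    keep = np.isfinite(y)
    if flags is not None:
        keep &= ~np.asarray(flags, dtype=bool)
    t, y = t[keep], y[keep]
    if len(y) < min_frames:
        raise ValueError(f"need at least {min_frames} unflagged frames, got {len(y)}")

    slope, intercept, resid = _ols_line(t, y)
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        inliers = np.abs(resid - np.median(resid)) <= outlier_mad * 1.4826 * mad
        if inliers.sum() >= min_frames and inliers.sum() < len(y):
            t, y = t[inliers], y[inliers]
            slope, intercept, resid = _ols_line(t, y)
    rms = float(np.sqrt(np.mean(resid**2)))

    # Pause/sever exclusion.  A severing event appears as a position jump
    # (two segments with an intercept discontinuity) or a gross slope break;
    # a transient pause as slope/flat/slope.  The segmented fit must cut the
    # residual substantially AND the implied displacement must exceed what
    # constant-rate Poisson shortening itself produces over the same window
    # (sd = sqrt(rise * |slope| * tau)) plus the residual noise — without
    # that guard, slow staircase-like trajectories would be discarded
    # wholesale, biasing slow conditions upward by survivorship.
    def _noise_scale(local_rms: float, tau: float) -> float:
        poisson_var = subunit_rise * abs(slope) * max(tau, 0.0)
        return float(np.sqrt(poisson_var + local_rms**2))

    discarded, reason = False, ""
    span = t[-1] - t[0]
    if len(y) >= 10:
        rms2, s1, s2, jump = _two_segment_rms(t, y)
        a, b = sorted([abs(s1), abs(s2)])
        ratio = b / max(a, 1e-12)
        step_nm = abs(s1 - s2) * span / 4.0
        scale = _noise_scale(rms2, span / 4.0)
        if rms2 < (1.0 - pause_rms_improvement) * rms and (
            jump > 7.0 * scale
            or (ratio > pause_slope_ratio and step_nm > 7.0 * scale)
        ):
            discarded, reason = True, "pause-or-sever"
    if not discarded and len(y) >= 20:
        rms3, s1, s2, s3, mid_dur = _three_segment_rms(t, y)
        outer = 0.5 * (abs(s1) + abs(s3))
        deficit_nm = outer * mid_dur  # displacement missed while paused
        if (
            rms3 < (1.0 - pause_rms_improvement) * rms
            and abs(s2) < outer / pause_slope_ratio
            and deficit_nm > 7.0 * _noise_scale(rms3, mid_dur)
        ):
            discarded, reason = True, "pause-or-sever"

    return DepolRateResult(
        slope=slope,
        rate=abs(slope) / subunit_rise,
        fit_residual=rms,
        n_frames_used=len(y),
        discarded=discarded,
        reason=reason,
    )


def estimate_rate_from_kymograph(
    kymo: Kymograph,
    side: Side = "right",
    subunit_rise: float = 2.7,
    **fit_kwargs,
) -> DepolRateResult:
    """Convenience pipeline: track the end, then fit the depolymerization rate."""
    track = track_end(kymo, side=side)
    return fit_depolymerization_rate(
        track.position_nm,
        kymo.frame_interval,
        subunit_rise,
        flags=track.flagged,
        **fit_kwargs,
    )
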