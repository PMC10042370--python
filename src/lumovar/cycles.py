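"""Cycle segmentation and the linear movement-pattern metrics.

A trial is divided into reaching cycles at the peaks of the sagittal
(flexion-extension) thorax orientation.  To exclude transients, only the final
40 of the 45 repetitions enter the analysis.  Metrics:

* CyclSD — temporal variability: sample SD of the cycle (peak-to-peak)
  durations, seconds;
* MeanSD — spatial variability: each cycle is time-normalized to 101 samples
  (0-100% phase) by cubic spline, cycles are aligned by cross-correlation, and
  the per-axis SD across cycles at each phase point is averaged over the 101
  points, degrees;
* amplitude — mean per-cycle maximum minus mean per-cycle minimum angle per
  axis, degrees;
* velocity — repetitions divided by the time span of the analyzed cycles,
  repetitions/second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

__all__ = [
    "CycleError",
    "CycleSet",
    "MovementMetrics",
    "detect_cycles",
    "select_analysis_cycles",
    "cycl_sd",
    "normalize_cycles",
    "align_cycles",
    "mean_sd",
    "amplitude",
    "velocity",
]

logger = logging.getLogger(__name__)

N_PHASE_POINTS = 101  # 0..100% of the movement cycle


class CycleError(ValueError):
    """Cycle segmentation or metric computation failed."""


@dataclass
class CycleSet:
    """Segmented, normalized and aligned cycles of one trial."""

    peak_indices: np.ndarray        # boundary sample indices (n_cycles + 1)
    durations: np.ndarray           # seconds per cycle (n_cycles)
    normalized_cycles: np.ndarray   # (n_cycles, 101, 3) degrees, unaligned
    aligned_cycles: np.ndarray      # (n_cycles, 101, 3) after alignment
    alignment_shifts: np.ndarray    # integer phase-sample shift per cycle


@dataclass
class MovementMetrics:
    """Per-trial movement-pattern metrics."""

    meansd_fe: float
    meansd_lb: float
    meansd_ar: float
    cyclsd: float
    amplitude_fe: float
    amplitude_lb: float
    amplitude_ar: float
    velocity: float
    lde: float = float("nan")
    lde_slope_per_sample: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _dominant_period(x: np.ndarray) -> int:
    """Lag of the first autocorrelation peak, in samples."""
    x = x - x.mean()
    if not np.any(x):
        raise CycleError("constant signal: no cycles to detect")
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    ac /= ac[0]
    pk, _ = find_peaks(ac, height=0.1)
    if pk.size == 0:
        raise CycleError("no dominant period found in autocorrelation")
    return int(pk[0])


def detect_cycles(
    thorax_sagittal: np.ndarray,
    expected_count: int | None = None,
    min_separation_frac: float = 0.5,
    prominence_frac: float = 0.25,
    min_peaks: int = 5,
    smooth_harmonics: float | None = 4.0,
    refine_window_frac: float = 0.03,
) -> np.ndarray:
    """Indices of the most-forward sagittal orientation, one per reaching cycle.

    Local maxima with minimum separation ``min_separation_frac`` times the
    dominant period (from the autocorrelation's first peak) and prominence at
    least ``prominence_frac`` times the signal's interquartile range.

    Peak candidates are located on a zero-phase low-pass-filtered copy
    (cutoff ``smooth_harmonics`` times the movement frequency) so that
    measurement noise on the flat portions of the movement cannot spawn
    spurious maxima; each candidate is then refined to the vertex of a
    quadratic fitted to the raw signal over ``+/-refine_window_frac`` of a
    period, which locates the most-forward sample without inheriting
    sample-level noise.  Set ``smooth_harmonics=None`` to detect directly on
    the raw signal with no refinement.
    """
    x = np.asarray(thorax_sagittal, dtype=float)
    period = _dominant_period(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise CycleError("degenerate signal: zero interquartile range")
    xs = x
    if smooth_harmonics is not None and period > 4:
        wn = min(0.99, 2.0 * smooth_harmonics / period)
        from scipy.signal import butter, filtfilt
        b, a = butter(2, wn)
        xs = filtfilt(b, a, x)
    peaks, _ = find_peaks(
        xs,
        distance=max(1, int(round(min_separation_frac * period))),
        prominence=prominence_frac * iqr,
    )
    if smooth_harmonics is not None:
        half = max(3, int(round(refine_window_frac * period)))
        refined = []
        for p in peaks:
            lo, hi = max(0, p - half), min(x.size, p + half + 1)
            idx = np.arange(lo, hi)
            c2, c1, _ = np.polyfit(idx, x[lo:hi], 2)
            vertex = -c1 / (2 * c2) if c2 < 0 else float(p)
            refined.append(int(round(np.clip(vertex, lo, hi - 1))))
        peaks = np.unique(refined)
    if peaks.size < min_peaks:
        raise CycleError(
            f"only {peaks.size} peaks found (need >= {min_peaks}): {peaks.tolist()}"
        )
    if expected_count is not None and peaks.size != expected_count:
        raise CycleError(
            f"found {peaks.size} peaks, expected {expected_count}: {peaks.tolist()}"
        )
    return peaks


def select_analysis_cycles(peaks: np.ndarray, n_cycles: int = 40) -> np.ndarray:
    """Boundaries of the final ``n_cycles`` inter-peak cycles (transients discarded).

    Returns ``n_cycles + 1`` peak indices; 45 detected peaks yield the final
    40 of the 44 peak-to-peak cycles.
    """
    peaks = np.asarray(peaks)
    if peaks.size < n_cycles + 1:
        raise CycleError(
            f"{peaks.size} peaks provide only {max(peaks.size - 1, 0)} cycles; "
            f"{n_cycles} required"
        )
    return peaks[-(n_cycles + 1):]


def cycl_sd(durations: np.ndarray) -> float:
    """Sample SD (n-1 denominator) of the cycle durations, seconds."""
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise CycleError("need at least 2 cycle durations")
    return float(np.std(durations, ddof=1))


def normalize_cycles(angles: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Time-normalize each cycle to 101 phase samples by cubic spline.

    ``angles`` is the (n, 3) trial series, ``boundaries`` the cycle boundary
    sample indices.  Endpoints are spline knots and therefore preserved
    exactly.
    """
    angles = np.asarray(angles, dtype=float)
    boundaries = np.asarray(boundaries)
    n_cycles = boundaries.size - 1
    if n_cycles < 1:
        raise CycleError("need at least one cycle")
    out = np.empty((n_cycles, N_PHASE_POINTS, 3))
    for c in range(n_cycles):
        lo, hi = int(boundaries[c]), int(boundaries[c + 1])
        seg = angles[lo:hi + 1]
        if seg.shape[0] < 4:
            raise CycleError(f"cycle {c} has {seg.shape[0]} samples; need >= 4")
        src = np.linspace(0.0, 1.0, seg.shape[0])
        dst = np.linspace(0.0, 1.0, N_PHASE_POINTS)
        for axis in range(3):
            out[c, :, axis] = CubicSpline(src, seg[:, axis])(dst)
    return out


def _roll_cycle(cycle: np.ndarray, shift: int) -> np.ndarray:
    """Circularly shift a 101-sample cycle on its 100 unique phase samples."""
    body = np.roll(cycle[:-1], shift, axis=0)
    return np.concatenate([body, body[:1]], axis=0)


def align_cycles(
    normalized_cycles: np.ndarray,
    max_shift: int = 10,
    n_passes: int = 2,
    channel: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Align cycles to the ensemble mean by circular cross-correlation.

    The integer phase shift (bounded to +/-``max_shift`` samples) maximizing
    the cross-correlation of each cycle's flexion-extension trace with the
    ensemble mean is found and applied to all three axes, preserving
    intersegmental coupling; a refinement pass repeats the search against the
    updated mean.  Returns the aligned cycles and the total shift per cycle.
    """
    cycles = np.asarray(normalized_cycles, dtype=float)
    if cycles.ndim != 3 or cycles.shape[1] != N_PHASE_POINTS:
        raise CycleError(f"expected (n, {N_PHASE_POINTS}, 3) cycles, got {cycles.shape}")
    if cycles.shape[0] < 2:
        raise CycleError("need at least 2 cycles to align")
    aligned = cycles.copy()
    total = np.zeros(cycles.shape[0], dtype=int)
    shifts_range = np.arange(-max_shift, max_shift + 1)
    for _ in range(n_passes):
        mean_fe = aligned[:, :-1, channel].mean(axis=0)
        for c in range(aligned.shape[0]):
            body = aligned[c, :-1, channel]
            scores = np.array([body @ np.roll(mean_fe, -s) for s in shifts_range])
            best = int(shifts_range[np.argmax(scores)])
            new_total = total[c] + best
            if abs(new_total) > max_shift:
                clamped = int(np.clip(new_total, -max_shift, max_shift))
                logger.info("cycle %d: shift %d clamped to %d", c, new_total, clamped)
                best = clamped - total[c]
                new_total = clamped
            if best:
                aligned[c] = _roll_cycle(aligned[c], best)
            total[c] = new_total
    return aligned, total


def mean_sd(aligned_cycles: np.ndarray) -> np.ndarray:
    """Per-axis MeanSD: SD (n-1) across cycles at each phase point, averaged.

    Returns a length-3 array (flexion-extension, lateral-bending,
    axial-rotation), degrees.
    """
    cycles = np.asarray(aligned_cycles, dtype=float)
    if cycles.shape[0] < 2:
        raise CycleError("need at least 2 cycles")
    return np.std(cycles, axis=0, ddof=1).mean(axis=0)


def amplitude(cycles: np.ndarray) -> np.ndarray:
    """Per-axis range of motion: mean per-cycle maximum minus mean minimum."""
    cycles = np.asarray(cycles, dtype=float)
    if cycles.ndim != 3 or cycles.shape[0] < 1:
        raise CycleError("need at least 1 cycle")
    return cycles.max(axis=1).mean(axis=0) - cycles.min(axis=1).mean(axis=0)


def velocity(n_repetitions: int, trial_duration: float) -> float:
    """Repetitions per second over the analyzed span."""
    if trial_duration <= 0:
        raise CycleError("trial duration must be positive")
    return n_repetitions / trial_duration
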