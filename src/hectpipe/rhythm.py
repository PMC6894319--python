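"""Spontaneous rhythm analysis: beat rate, variability, Poincaré, capture.

Beat-rate variability is quantified as the coefficient of variation
(COV = sample SD / mean) of the inter-beat intervals within a recording
window.  A Poincaré plot pairs each interval with the next; its principal
dispersions SD1 (perpendicular to the identity line, short-term
variability) and SD2 (along the identity line) summarise the scatter.

Pacing capture is judged 1:1 when nearly every stimulus produced a twitch
and every inter-beat interval is close to the pacing period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mechanics import DataError, ParameterError

__all__ = [
    "BeatSeries",
    "PoincareResult",
    "CaptureConfig",
    "CaptureResult",
    "beat_series",
    "poincare_pairs",
    "detect_capture",
]


class InsufficientDataError(DataError):
    """Too few beats for the requested statistic (recording excluded)."""


@dataclass(frozen=True)
class BeatSeries:
    """Beat times (twitch peaks) with interval statistics.

    ``mean_rate_hz`` is (n-1)/(t_last - t_first); ``cov`` is the sample
    (n-1 denominator) SD of the intervals over their mean.
    """

    beat_times_s: np.ndarray
    intervals_s: np.ndarray
    mean_rate_hz: float
    cov: float
    window_s: float


def beat_series(beat_times_s: np.ndarray, window_s: float) -> BeatSeries:
    """Interval statistics over a recording window.

    Requires at least 3 beats (2 intervals); fewer raises
    :class:`InsufficientDataError`, mirroring the exclusion of recordings
    without a usable spontaneous rhythm.
    """
    times = np.sort(np.asarray(beat_times_s, dtype=float))
    if times.size < 3:
        raise InsufficientDataError(f"need >= 3 beats, got {times.size}")
    intervals = np.diff(times)
    if np.any(intervals <= 0):
        raise DataError("beat times must be strictly increasing")
    mean_rate = (times.size - 1) / (times[-1] - times[0])
    mean_int = float(np.mean(intervals))
    cov = float(np.std(intervals, ddof=1) / mean_int)
    return BeatSeries(times, intervals, float(mean_rate), cov, float(window_s))


@dataclass(frozen=True)
class PoincareResult:
    """Consecutive-interval pairs and their principal dispersions."""

    pairs: np.ndarray  # (n-1, 2): (PP_n, PP_{n+1})
    sd1: float         # SD of (PP_{n+1} - PP_n)/sqrt(2), short-term
    sd2: float         # SD of (PP_{n+1} + PP_n)/sqrt(2), long-term


def poincare_pairs(series: BeatSeries) -> PoincareResult:
    """Poincaré pairs (PP_n, PP_{n+1}) with SD1/SD2 dispersions.

    Dispersion of the point cloud about the identity line indicates beat
    rate variability: constant rhythm collapses to a single point with
    SD1 = SD2 = 0.
    """
    pp = series.intervals_s
    if pp.size < 2:
        raise InsufficientDataError("need >= 2 intervals for a Poincaré plot")
    pairs = np.column_stack([pp[:-1], pp[1:]])
    diff = (pp[1:] - pp[:-1]) / math.sqrt(2.0)
    summ = (pp[1:] + pp[:-1]) / math.sqrt(2.0)
    return PoincareResult(
        pairs=pairs,
        sd1=float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0,
        sd2=float(np.std(summ, ddof=1)) if summ.size > 1 else 0.0,
    )


@dataclass(frozen=True)
class CaptureConfig:
    count_frac: float = 0.95   # min observed/expected beat count
    period_tol: float = 0.10   # max relative interval deviation from 1/f


@dataclass(frozen=True)
class CaptureResult:
    pace_freq_hz: float
    captured_1to1: bool
    observed_beats: int
    expected_beats: int
    max_rel_interval_dev: float


def detect_capture(
    series: BeatSeries, pace_freq_hz: float, cfg: CaptureConfig = CaptureConfig()
) -> CaptureResult:
    """Judge 1:1 pacing capture from the detected beat series.

    Capture holds iff the observed beat count reaches ``count_frac`` of
    the expected ``floor(window * f)`` AND every interval lies within
    ``period_tol`` of the pacing period.  A tissue beating once per two
    stimuli (2:1 response) fails on both counts.
    """
    if pace_freq_hz <= 0:
        raise ParameterError("pace_freq must be positive")
    expected = int(math.floor(series.window_s * pace_freq_hz))
    period = 1.0 / pace_freq_hz
    rel_dev = np.abs(series.intervals_s - period) / period
    max_dev = float(rel_dev.max()) if rel_dev.size else math.inf
    observed = int(series.beat_times_s.size)
    captured = observed >= cfg.count_frac * expected and max_dev <= cfg.period_tol
    return CaptureResult(pace_freq_hz, bool(captured), observed, expected, max_dev)
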