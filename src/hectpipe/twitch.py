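"""Twitch detection and per-twitch contractile metrics.

Given a force trace, this module finds individual twitches and computes
the standard engineered-heart-tissue contractility metrics:

* developed force (DF): peak force minus the local inter-twitch baseline;
* maximum contraction rate (+dF/dt) and maximum relaxation rate (-dF/dt);
* passive force: the inter-twitch baseline referenced to the fabrication
  zero (a diastolic tone proxy);
* twitch timing: time to peak (TTP) from onset, and RT50 / RT90, the
  times from peak to 50% and 90% relaxation.

Detection runs on a Savitzky-Golay-smoothed copy of the trace: peaks with
prominence above a configurable fraction of the signal range and a
minimum separation, with onset/end located where the smoothed trace
crosses baseline plus a small fraction of the twitch amplitude.
Derivatives come from a Savitzky-Golay smoothed differentiator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .mechanics import DataError, ForceTrace, TissueGeometry, developed_stress

__all__ = [
    "TwitchConfig",
    "Twitch",
    "TwitchSummary",
    "detect_twitches",
    "twitch_metrics",
    "analyze_trace",
    "summarize_recording",
    "fold_change_vs_control",
]

METRIC_NAMES = (
    "df_un",
    "dfdt_max_un_per_s",
    "dfdt_min_un_per_s",
    "passive_force_un",
    "ttp_s",
    "rt50_s",
    "rt90_s",
)


@dataclass(frozen=True)
class TwitchConfig:
    """Tunable twitch-detection parameters.

    Defaults suit 30-s recordings sampled at 100 Hz with beat rates up to
    ~3 Hz (hence the 0.3 s minimum peak separation).
    """

    smooth_window_s: float = 0.051       # Savitzky-Golay smoothing window
    sg_order: int = 2
    prominence_frac: float = 0.3         # of smoothed signal range
    min_period_s: float = 0.3
    onset_frac: float = 0.05             # of twitch amplitude
    baseline_percentile: float = 10.0    # of inter-twitch samples
    sg_deriv_window_s: float = 0.051     # derivative smoothing window
    flat_range_un: float = 1e-9          # below this signal range: no twitches


@dataclass
class TwitchSegment:
    """Index range of one detected twitch within a trace."""

    i_onset: int
    i_peak: int
    i_end: int


@dataclass
class Twitch:
    """Per-twitch metrics; ``dfdt_min`` is stored signed (negative)."""

    t_onset: float
    t_peak: float
    t_end: float
    df_un: float
    dfdt_max_un_per_s: float
    dfdt_min_un_per_s: float
    passive_force_un: float
    ttp_s: float
    rt50_s: float
    rt90_s: float


def _odd_window(window_s: float, fs: float, order: int) -> int:
    w = int(round(window_s * fs))
    w = max(w, order + 1)
    if w % 2 == 0:
        w += 1
    return w


def _smooth(force: np.ndarray, fs: float, cfg: TwitchConfig) -> np.ndarray:
    w = _odd_window(cfg.smooth_window_s, fs, cfg.sg_order)
    if w >= force.size:
        return force.copy()
    return savgol_filter(force, w, cfg.sg_order)


def detect_twitches(trace: ForceTrace, cfg: TwitchConfig = TwitchConfig()) -> list[TwitchSegment]:
    """Locate twitch segments (onset, peak, end) in a force trace.

    Returns an empty list when no peaks qualify (e.g. a flat trace); the
    segments are time-ordered and non-overlapping.
    """
    if trace.duration < 2.0:
        raise DataError("trace must be at least 2 s long")
    fs = trace.sampling_rate
    smoothed = _smooth(trace.force_un, fs, cfg)
    rng = float(smoothed.max() - smoothed.min())
    if rng <= cfg.flat_range_un:
        return []
    peaks, _ = find_peaks(
        smoothed,
        prominence=cfg.prominence_frac * rng,
        distance=max(int(round(cfg.min_period_s * fs)), 1),
    )
    if peaks.size == 0:
        return []

    baseline = float(np.percentile(smoothed, cfg.baseline_percentile))
    segments: list[TwitchSegment] = []
    for j, p in enumerate(peaks):
        amp = smoothed[p] - baseline
        thr = baseline + cfg.onset_frac * amp
        lo = peaks[j - 1] if j > 0 else 0
        hi = peaks[j + 1] if j + 1 < peaks.size else smoothed.size - 1
        below = np.flatnonzero(smoothed[lo:p] <= thr)
        i_onset = lo + below[-1] if below.size else lo
        below = np.flatnonzero(smoothed[p : hi + 1] <= thr)
        i_end = p + below[0] if below.size else hi
        segments.append(TwitchSegment(int(i_onset), int(p), int(i_end)))
    return segments


def _local_baseline(
    smoothed: np.ndarray,
    segments: list[TwitchSegment],
    idx: int,
    cfg: TwitchConfig,
) -> float:
    """Baseline from the inter-twitch windows flanking segment ``idx``."""
    seg = segments[idx]
    prev_end = segments[idx - 1].i_end if idx > 0 else 0
    next_onset = segments[idx + 1].i_onset if idx + 1 < len(segments) else smoothed.size
    flank = np.concatenate([smoothed[prev_end : seg.i_onset + 1], smoothed[seg.i_end : next_onset]])
    if flank.size == 0:
        flank = smoothed[[seg.i_onset, min(seg.i_end, smoothed.size - 1)]]
    return float(np.percentile(flank, cfg.baseline_percentile))


def twitch_metrics(
    trace: ForceTrace,
    segment: TwitchSegment,
    baseline: float,
    cfg: TwitchConfig = TwitchConfig(),
    _smoothed: Optional[np.ndarray] = None,
    _deriv: Optional[np.ndarray] = None,
) -> Twitch:
    """Compute metrics for one detected twitch.

    ``baseline`` is the local inter-twitch baseline (absolute force units,
    referenced to the fabrication zero); it doubles as the passive force.
    RT50/RT90 are NaN when the twitch does not relax to the corresponding
    threshold before the segment ends.
    """
    fs = trace.sampling_rate
    t = trace.time_s
    smoothed = _smooth(trace.force_un, fs, cfg) if _smoothed is None else _smoothed
    if _deriv is None:
        w = _odd_window(cfg.sg_deriv_window_s, fs, cfg.sg_order)
        if w >= trace.force_un.size:
            raise DataError("trace shorter than the derivative window")
        deriv = savgol_filter(trace.force_un, w, cfg.sg_order, deriv=1, delta=1.0 / fs)
    else:
        deriv = _deriv

    if segment.i_end - segment.i_onset < 3:
        raise DataError("segment shorter than the derivative window")

    i_peak = segment.i_peak
    df = float(smoothed[i_peak] - baseline)
    # the contraction-rate maximum can precede the onset-threshold crossing
    # (force rises fastest right at the foot of the twitch), so extend the
    # search back along the rising limb while the derivative stays positive
    i_rise = segment.i_onset
    floor = max(segment.i_onset - (i_peak - segment.i_onset), 0)
    while i_rise > floor and deriv[i_rise - 1] > 0:
        i_rise -= 1
    dfdt_max = float(np.max(deriv[i_rise : i_peak + 1]))
    dfdt_min = float(np.min(deriv[i_peak : segment.i_end + 1]))

    def first_crossing(level: float) -> float:
        post = smoothed[i_peak : segment.i_end + 1]
        below = np.flatnonzero(post <= level)
        if below.size == 0:
            return math.nan
        j = below[0]
        if j == 0:
            return 0.0
        # linear interpolation between the bracketing samples
        f0, f1 = post[j - 1], post[j]
        frac = (f0 - level) / (f0 - f1) if f1 != f0 else 1.0
        return (j - 1 + frac) / fs

    return Twitch(
        t_onset=float(t[segment.i_onset]),
        t_peak=float(t[i_peak]),
        t_end=float(t[segment.i_end]),
        df_un=df,
        dfdt_max_un_per_s=dfdt_max,
        dfdt_min_un_per_s=dfdt_min,
        passive_force_un=float(baseline),
        ttp_s=float(t[i_peak] - t[segment.i_onset]),
        rt50_s=first_crossing(baseline + 0.5 * df),
        rt90_s=first_crossing(baseline + 0.1 * df),
    )


@dataclass
class TwitchSummary:
    """Per-recording aggregate of twitch metrics.

    ``valid`` is False when no twitches were detected, mirroring the
    exclusion of tissues without detectable post deflection.
    """

    n_twitches: int
    valid: bool
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    developed_stress_un_per_mm2: Optional[float] = None
    metadata: dict = field(default_factory=dict)
    twitches: list = field(default_factory=list)


def analyze_trace(trace: ForceTrace, cfg: TwitchConfig = TwitchConfig()) -> list[Twitch]:
    """Detect twitches and compute metrics for each; skips twitches whose
    segment is too short for the derivative window."""
    fs = trace.sampling_rate
    segments = detect_twitches(trace, cfg)
    if not segments:
        return []
    smoothed = _smooth(trace.force_un, fs, cfg)
    w = _odd_window(cfg.sg_deriv_window_s, fs, cfg.sg_order)
    deriv = savgol_filter(trace.force_un, w, cfg.sg_order, deriv=1, delta=1.0 / fs)
    out = []
    for i, seg in enumerate(segments):
        baseline = _local_baseline(smoothed, segments, i, cfg)
        try:
            out.append(twitch_metrics(trace, seg, baseline, cfg, _smoothed=smoothed, _deriv=deriv))
        except DataError:
            continue
    return out


def summarize_recording(
    trace: ForceTrace,
    geometry: Optional[TissueGeometry] = None,
    cfg: TwitchConfig = TwitchConfig(),
) -> TwitchSummary:
    """Detection + metrics + aggregation for one recording.

    Developed stress is attached when a tissue geometry is given
    (mean DF over cross-sectional area).
    """
    twitches = analyze_trace(trace, cfg)
    if not twitches:
        return TwitchSummary(n_twitches=0, valid=False, metadata=dict(trace.metadata))
    means, sds = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(tw, name) for tw in twitches], dtype=float)
        vals = vals[np.isfinite(vals)]
        means[name] = float(np.mean(vals)) if vals.size else math.nan
        sds[name] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    ds = developed_stress(means["df_un"], geometry) if geometry is not None else None
    return TwitchSummary(
        n_twitches=len(twitches),
        valid=True,
        means=means,
        sds=sds,
        peak_times=np.array([tw.t_peak for tw in twitches]),
        developed_stress_un_per_mm2=ds,
        metadata=dict(trace.metadata),
        twitches=twitches,
    )


def fold_change_vs_control(
    values: pd.DataFrame,
    control_group: str = "control",
    value_col: str = "value",
) -> pd.DataFrame:
    """Normalize per-tissue metric values to the day-matched control mean.

    ``values`` needs columns ``group``, ``day`` and ``value_col``.  Each
    value is divided by the mean of the control group on the same day, so
    control means map to exactly 1.0.
    """
    out = values.copy()
    out["fold_change"] = np.nan
    for day, sub in values.groupby("day"):
        ctrl = sub.loc[sub["group"] == control_group, value_col]
        if ctrl.empty:
            raise DataError(f"no {control_group} values for day {day}")
        out.loc[sub.index, "fold_change"] = sub[value_col] / ctrl.mean()
    return out
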