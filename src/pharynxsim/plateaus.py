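"""Plateau detection, duration/shape measurement, and regime
classification of voltage traces.

A plateau is a maximal interval with V above a detection threshold
(default -30 mV, midway between rest near -65 mV and the plateau level
near +40 mV) lasting at least a minimum duration.  Threshold-crossing
times are refined by linear interpolation between samples, so durations
are not quantized to the output step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .integrator import SimulationTrace
from .stimulus import EventSchedule, IPSP

__all__ = ["PlateauSegment", "Regime", "RegimeThresholds", "detect_plateaus",
           "PlateauAccumulator", "mean_plateau_duration", "duration_stats",
           "classify_regime", "wedge_depth", "plateau_levels",
           "mark_commanded", "segments_to_dataframe"]


@dataclass(frozen=True)
class PlateauSegment:
    """One detected plateau.

    ``open_ended`` marks a segment still above threshold at the end of the
    trace; such segments have no meaningful duration and are excluded from
    duration statistics.  ``terminated_by_command`` is filled by
    :func:`mark_commanded` once a schedule is available.
    """

    t_on: float
    t_off: float
    V_peak: float
    open_ended: bool = False
    terminated_by_command: bool | None = None
    V_upper_level: float | None = None
    V_lower_level: float | None = None
    wedge_depth_mV: float | None = None

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


class Regime(str, enum.Enum):
    """Qualitative behavior of a trace under the feeding protocol."""

    QUIESCENT = "quiescent"
    LOW_AMPLITUDE = "low_amplitude"
    PHYSIOLOGICAL = "physiological"
    TWO_LEVEL = "two_level"
    UNENDING = "unending"
    FAILURE = "failure"  # solver failure in a sweep cell


@dataclass(frozen=True)
class RegimeThresholds:
    """Tunable constants of the regime classifier."""

    detect_mV: float = -30.0        # plateau detection threshold
    min_duration_ms: float = 5.0
    peak_mV: float = 20.0           # full-amplitude plateau criterion
    activity_mV: float = -55.0      # any excursion above this counts as activity
    unending_periods: float = 2.0   # open-ended span >= this many stimulus periods
    command_window_ms: float = 25.0 # t_off within this window after an IPSP
    band_dwell_ms: float = 50.0     # min dwell per voltage band (two-level)
    band_separation_mV: float = 20.0
    commanded_fraction: float = 0.5


class PlateauAccumulator:
    """Streaming threshold-crossing detector.

    Feed consecutive (times, V) chunks of one trace; crossings are
    interpolated linearly, and segments spanning chunk boundaries are
    stitched.  :meth:`finalize` returns the completed segment list.
    """

    def __init__(self, threshold: float = -30.0, min_duration: float = 5.0):
        self.threshold = threshold
        self.min_duration = min_duration
        self._segments: list[PlateauSegment] = []
        self._t_on: float | None = None
        self._v_peak: float = -np.inf
        self._prev_t: float | None = None
        self._prev_v: float | None = None
        self._t_end: float | None = None

    def _cross(self, t0, v0, t1, v1) -> float:
        # linear interpolation of the threshold crossing in (t0, t1]
        return t0 + (self.threshold - v0) / (v1 - v0) * (t1 - t0)

    def feed(self, times: np.ndarray, V: np.ndarray) -> None:
        thr = self.threshold
        times = np.asarray(times, dtype=float)
        V = np.asarray(V, dtype=float)
        if times.size == 0:
            return
        if self._prev_t is not None:
            times = np.concatenate(([self._prev_t], times))
            V = np.concatenate(([self._prev_v], V))
        elif V[0] >= thr:
            # trace starts above threshold
            self._t_on = times[0]
            self._v_peak = V[0]
        above = V >= thr
        flips = np.nonzero(np.diff(above.astype(np.int8)))[0]
        start = 0
        for i in flips:
            if above[i + 1]:  # upward crossing at interpolated time
                self._t_on = self._cross(times[i], V[i], times[i + 1], V[i + 1])
                self._v_peak = -np.inf
                start = i + 1
            else:             # downward crossing closes the open segment
                t_off = self._cross(times[i], V[i], times[i + 1], V[i + 1])
                self._v_peak = max(self._v_peak,
                                   float(V[start:i + 1].max(initial=-np.inf)))
                self._close(t_off)
                start = i + 1
        if self._t_on is not None and above[-1]:
            self._v_peak = max(self._v_peak,
                               float(V[start:].max(initial=-np.inf)))
        self._prev_t = float(times[-1])
        self._prev_v = float(V[-1])
        self._t_end = float(times[-1])

    def _close(self, t_off: float) -> None:
        if self._t_on is None:
            return
        if t_off - self._t_on >= self.min_duration:
            self._segments.append(PlateauSegment(
                t_on=float(self._t_on), t_off=float(t_off),
                V_peak=float(self._v_peak)))
        self._t_on = None
        self._v_peak = -np.inf

    def finalize(self) -> list[PlateauSegment]:
        segments = list(self._segments)
        if self._t_on is not None and self._t_end is not None:
            seg = PlateauSegment(t_on=float(self._t_on),
                                 t_off=float(self._t_end),
                                 V_peak=float(self._v_peak), open_ended=True)
            if seg.duration >= self.min_duration:
                segments.append(seg)
        return segments


def detect_plateaus(trace: SimulationTrace, threshold: float = -30.0,
                    min_duration: float = 5.0) -> list[PlateauSegment]:
    """Maximal intervals with V >= threshold lasting >= min_duration."""
    acc = PlateauAccumulator(threshold, min_duration)
    acc.feed(trace.times, trace.V)
    return acc.finalize()


def closed_durations(segments: Iterable[PlateauSegment]) -> np.ndarray:
    return np.array([s.duration for s in segments if not s.open_ended])


def duration_stats(segments: Iterable[PlateauSegment]):
    """(mean_ms, n, is_empty) over closed segments."""
    d = closed_durations(segments)
    if d.size == 0:
        return 0.0, 0, True
    return float(d.mean()), int(d.size), False


def mean_plateau_duration(segments: Iterable[PlateauSegment]) -> float:
    """Arithmetic mean duration of closed segments; 0.0 when empty
    (see :func:`duration_stats` for the explicit emptiness flag)."""
    return duration_stats(segments)[0]


def mark_commanded(segments: Sequence[PlateauSegment],
                   schedule: EventSchedule,
                   window_ms: float = 25.0) -> list[PlateauSegment]:
    """Flag segments whose termination falls within ``window_ms`` after a
    scheduled IPSP (commanded termination, as opposed to noise-truncated
    or spontaneous)."""
    ipsp_times = np.array([ev.t for ev in schedule.events if ev.kind == IPSP])
    out = []
    for seg in segments:
        if seg.open_ended:
            out.append(replace(seg, terminated_by_command=False))
            continue
        i = np.searchsorted(ipsp_times, seg.t_off, side="right") - 1
        cmd = i >= 0 and (seg.t_off - ipsp_times[i]) <= window_ms
        out.append(replace(seg, terminated_by_command=bool(cmd)))
    return out


def plateau_levels(trace: SimulationTrace, segment: PlateauSegment,
                   band_dwell_ms: float = 50.0,
                   band_separation_mV: float = 20.0,
                   bin_mV: float = 2.0):
    """Sustained voltage bands within one plateau segment.

    Builds a dwell-time histogram of V over the segment and finds local
    dwell maxima with at least ``band_dwell_ms`` of residence.  Returns
    ``(V_upper, V_lower)`` for a two-level plateau -- two bands at least
    ``band_separation_mV`` apart with the upper band occupied first -- or
    ``None`` when the segment has a single level.  Band voltages are
    dwell-weighted means within +/- 1.5 bins of the mode.
    """
    mask = (trace.times >= segment.t_on) & (trace.times <= segment.t_off)
    V = trace.V[mask]
    t = trace.times[mask]
    if V.size < 3:
        return None
    dt = trace.dt_out
    lo = np.floor(V.min() / bin_mV) * bin_mV
    hi = np.ceil(V.max() / bin_mV) * bin_mV + bin_mV
    edges = np.arange(lo, hi + bin_mV / 2, bin_mV)
    counts, _ = np.histogram(V, bins=edges)
    dwell = counts * dt
    # local dwell maxima with sufficient residence
    modes = []
    for i in range(len(dwell)):
        if dwell[i] < band_dwell_ms:
            continue
        left = dwell[i - 1] if i > 0 else -1
        right = dwell[i + 1] if i < len(dwell) - 1 else -1
        if dwell[i] >= left and dwell[i] >= right:
            modes.append(i)
    if len(modes) < 2:
        return None
    # merge adjacent-bin modes, then keep the two best-separated strong bands
    bands = []
    for i in modes:
        center = 0.5 * (edges[i] + edges[i + 1])
        sel = np.abs(V - center) <= 1.5 * bin_mV
        v_band = float(np.mean(V[sel]))
        t_band = float(np.median(t[sel]))
        bands.append((v_band, dwell[i], t_band))
    bands.sort(key=lambda b: b[0], reverse=True)
    upper = bands[0]
    lower_candidates = [b for b in bands[1:]
                       if upper[0] - b[0] >= band_separation_mV]
    if not lower_candidates:
        return None
    lower = max(lower_candidates, key=lambda b: b[1])
    if upper[2] >= lower[2]:
        return None  # upper band must be occupied before the lower one
    return upper[0], lower[0]


def wedge_depth(trace: SimulationTrace, segment: PlateauSegment,
                peak_window_ms: float = 50.0,
                search_window_ms: float = 150.0,
                recovery_tol_mV: float = 1.0) -> float:
    """Depth (mV) of the transient hyperpolarizing 'wedge' after the
    plateau's initial peak.

    The wedge is the dip between the initial local maximum (within the
    first ``peak_window_ms`` of the segment) and the subsequent local
    minimum from which V recovers.  A plateau that merely relaxes
    monotonically from its peak (the ultrafast shape, driven by slow
    L-type inactivation) has no recovery and scores 0.
    """
    mask = (trace.times >= segment.t_on) & (trace.times <= segment.t_off)
    V = trace.V[mask]
    t = trace.times[mask]
    if V.size < 3:
        return 0.0
    n_peak = max(1, int(np.searchsorted(t, t[0] + peak_window_ms)))
    i_peak = int(np.argmax(V[:n_peak]))
    v_peak = float(V[i_peak])
    end = np.searchsorted(t, min(t[i_peak] + search_window_ms, t[-1]))
    seg = V[i_peak:end]
    if seg.size < 3:
        return 0.0
    i_min = int(np.argmin(seg))
    v_min = float(seg[i_min])
    if i_min >= seg.size - 1:
        return 0.0
    recovery = float(seg[i_min:].max())
    if recovery - v_min < recovery_tol_mV:
        return 0.0  # no rebound: monotone relaxation, not a wedge
    return v_peak - v_min


def classify_regime(trace: SimulationTrace, schedule: EventSchedule,
                    thresholds: RegimeThresholds | None = None) -> Regime:
    """Classify the qualitative regime of a reference-protocol trace.

    Precedence: unending (an open-ended plateau spanning at least two
    stimulus periods) > two_level (any segment with two sustained bands)
    > physiological (full-amplitude plateaus, mostly commanded-terminated)
    > low_amplitude (activity that never reaches full amplitude) >
    quiescent.
    """
    th = thresholds or RegimeThresholds()
    segs = detect_plateaus(trace, th.detect_mV, th.min_duration_ms)
    segs = mark_commanded(segs, schedule, th.command_window_ms)

    epsp = [ev.t for ev in schedule.events if ev.kind == "EPSP"]
    period = float(np.median(np.diff(epsp))) if len(epsp) > 1 else 500.0

    for seg in segs:
        if seg.open_ended and seg.duration >= th.unending_periods * period:
            return Regime.UNENDING
    for seg in segs:
        if seg.open_ended:
            continue
        if plateau_levels(trace, seg, th.band_dwell_ms,
                          th.band_separation_mV) is not None:
            return Regime.TWO_LEVEL
    closed = [s for s in segs if not s.open_ended]
    if closed:
        peaks = np.array([s.V_peak for s in closed])
        commanded = np.array([bool(s.terminated_by_command) for s in closed])
        if (np.median(peaks) >= th.peak_mV
                and commanded.mean() >= th.commanded_fraction):
            return Regime.PHYSIOLOGICAL
    if float(trace.V.max()) < th.peak_mV and float(trace.V.max()) >= th.activity_mV:
        return Regime.LOW_AMPLITUDE
    if closed or segs:
        return Regime.LOW_AMPLITUDE
    return Regime.QUIESCENT


def segments_to_dataframe(segments: Sequence[PlateauSegment],
                          regime: Regime | None = None) -> pd.DataFrame:
    rows = []
    for s in segments:
        rows.append({
            "t_on_ms": s.t_on, "t_off_ms": s.t_off, "duration_ms": s.duration,
            "V_peak_mV": s.V_peak, "open_ended": s.open_ended,
            "terminated_by_command": s.terminated_by_command,
            "wedge_depth_mV": s.wedge_depth_mV,
            "regime": regime.value if regime is not None else None,
        })
    cols = ["t_on_ms", "t_off_ms", "duration_ms", "V_peak_mV", "open_ended",
            "terminated_by_command", "wedge_depth_mV", "regime"]
    return pd.DataFrame(rows, columns=cols)
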