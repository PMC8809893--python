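"""Pupil preprocessing and dilation-event detection.

Processing order: z-score the whole-session trace, smooth with a 500-ms
moving average (suppresses false-positive slope detections), estimate
slopes every 200 ms from consecutive bin averages, then define a dilation
event as the maximum pupil value between sequential positive
zero-crossings of the slope series.
"""
from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .core import DilationEvent, PupilTrace, SlopeSeries

logger = logging.getLogger("lcpupil")


def zscore_trace(trace: PupilTrace) -> PupilTrace:
    """Session-wide z-score with sample SD (n-1). Constant traces raise."""
    sd = float(np.std(trace.values, ddof=1))
    if sd == 0:
        raise ValueError("cannot z-score a constant trace")
    z = (trace.values - trace.values.mean()) / sd
    return replace(trace, values=z, units="z")


def smooth_trace(trace: PupilTrace, window: float = 0.5) -> PupilTrace:
    """Centered moving average; window rounded to an odd sample count.

    Edges use shrinking windows so constants pass through unchanged. A
    window shorter than one sample period returns the trace with a warning.
    """
    w = int(round(window * trace.rate))
    if w < 1:
        logger.warning("smoothing window %.3g s below one sample period; identity", window)
        return replace(trace, values=trace.values.copy())
    if w % 2 == 0:
        w += 1
    if w == 1:
        return replace(trace, values=trace.values.copy())
    kernel = np.ones(w)
    sums = np.convolve(trace.values, kernel, mode="same")
    counts = np.convolve(np.ones_like(trace.values), kernel, mode="same")
    return replace(trace, values=sums / counts)


def compute_slopes(trace: PupilTrace, step: float = 0.2) -> SlopeSeries:
    """Finite-difference slopes of consecutive ``step``-second bin averages."""
    per_bin = int(round(step * trace.rate))
    if per_bin < 1:
        raise ValueError("step must be at least one sample period")
    n_bins = trace.values.size // per_bin
    if n_bins < 2:
        raise ValueError("trace shorter than two slope steps")
    binned = trace.values[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    slopes = np.diff(binned) / step
    return SlopeSeries(slopes=slopes, step=step, t0=trace.t0)


def detect_dilation_events(trace: PupilTrace, slopes: SlopeSeries) -> list[DilationEvent]:
    """Dilation events between sequential positive zero-crossings of the slopes.

    A positive zero-crossing is a slope transition from <= 0 to > 0. For
    each consecutive crossing pair the event is the maximum trace value in
    between; its amplitude is that value (SD units for a z-scored trace).
    Spans containing NaNs are dropped.
    """
    s = slopes.slopes
    if s.size < 2:
        return []
    crossing = np.flatnonzero((s[:-1] <= 0) & (s[1:] > 0)) + 1
    times = slopes.times
    events: list[DilationEvent] = []
    for a, b in zip(crossing[:-1], crossing[1:]):
        ia = trace.index_at(times[a])
        ib = trace.index_at(times[b])
        if ib <= ia:
            continue
        span = trace.values[ia : ib + 1]
        if not np.all(np.isfinite(span)):
            continue
        k = int(np.argmax(span))
        t_ev = float(trace.t0 + (ia + k) / trace.rate)
        events.append(
            DilationEvent(
                time=t_ev,
                amplitude=float(span[k]),
                # grid rounding can land the max half a sample early
                rise_start=min(float(times[a]), t_ev),
            )
        )
    return events


def preprocess(trace: PupilTrace, smooth_window: float = 0.5, slope_step: float = 0.2):
    """z-score -> smooth -> slopes; returns (smoothed z trace, slope series)."""
    z = zscore_trace(trace)  # standardise so amplitudes are session SD units
    sm = smooth_trace(z, smooth_window)
    return sm, compute_slopes(sm, slope_step)


def percent_change(
    trace: PupilTrace, t_ref: float, baseline_window: float
) -> tuple[np.ndarray, float]:
    """Series of % changes from the mean over [t_ref - window, t_ref)."""
    i0 = trace.index_at(t_ref - baseline_window)
    i1 = trace.index_at(t_ref)
    if i1 <= i0:
        raise ValueError("baseline window contains no samples")
    b = float(trace.values[i0:i1].mean())
    if b == 0:
        raise ValueError("zero baseline; percent change undefined")
    return 100.0 * (trace.values - b) / b, b
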