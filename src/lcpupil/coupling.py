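"""Forward (cluster -> pupil) and reverse (dilation event -> spikes) coupling.

Forward: the peak pupil dilation following a spike cluster is the maximum
z-scored pupil value in a 6-s window from cluster onset; peaks grouped by
cluster size give the coupling curve whose linear slope (z-units per
spike) summarises the session.

Reverse: LC spikes are counted in a -4 to -2 s window before each pupil
dilation event; events binned every 0.3 SD of amplitude give the
spike-count distributions per event size.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CouplingCurve,
    DilationEvent,
    EventSpikeCount,
    PupilTrace,
    SlopeSeries,
    SpikeCluster,
    SpikeTrain,
    TriggeredResponse,
)


def triggered_peak(
    trace: PupilTrace,
    onset: float,
    window: float = 6.0,
    size: int = 1,
    peak_mode: str = "signed",
) -> TriggeredResponse:
    """Peak pupil value in [onset, onset + window].

    ``peak_mode`` "signed" takes the maximum z value (a dilation peak);
    "absolute" takes the value of largest magnitude. Responses whose window
    extends past the recording are flagged excluded.
    """
    if onset + window > trace.t_end or onset < trace.t0:
        return TriggeredResponse(onset, size, np.nan, np.nan, excluded=True)
    i0 = trace.index_at(onset)
    i1 = trace.index_at(onset + window)
    seg = trace.values[i0 : i1 + 1]
    if peak_mode == "signed":
        k = int(np.argmax(seg))
    elif peak_mode == "absolute":
        k = int(np.argmax(np.abs(seg)))
    else:
        raise ValueError(f"unknown peak_mode {peak_mode!r}")
    return TriggeredResponse(
        onset=onset,
        size=size,
        peak=float(seg[k]),
        latency=float((i0 + k) / trace.rate + trace.t0 - onset),
    )


def triggered_peaks(
    trace: PupilTrace,
    clusters: list[SpikeCluster],
    window: float = 6.0,
    peak_mode: str = "signed",
) -> list[TriggeredResponse]:
    """Cluster-triggered peaks for every cluster; excluded ones are dropped."""
    out = []
    for c in clusters:
        r = triggered_peak(trace, c.onset, window, size=c.size, peak_mode=peak_mode)
        if not r.excluded:
            out.append(r)
    return out


def coupling_curve(responses: list[TriggeredResponse], low_n: int = 5) -> CouplingCurve:
    """Group triggered peaks by cluster size: mean, SEM, occurrence per size."""
    if not responses:
        raise ValueError("no triggered responses")
    df = pd.DataFrame({"size": [r.size for r in responses],
                       "peak": [r.peak for r in responses]})
    g = df.groupby("size")["peak"]
    sizes = np.array(sorted(g.groups), dtype=int)
    mean = g.mean().loc[sizes].to_numpy()
    n = g.count().loc[sizes].to_numpy()
    sem = g.sem().loc[sizes].to_numpy()  # NaN for single-response sizes
    occurrence = n / n.sum()
    return CouplingCurve(
        sizes=sizes,
        mean_peak=mean,
        sem=sem,
        occurrence=occurrence,
        n=n,
        low_n_sizes=sizes[n < low_n],
    )


def fit_linear(curve: CouplingCurve) -> tuple[float, float]:
    """OLS of per-size mean peak on cluster size -> (slope, r2).

    Mirrors the session-level regression; sessions with fewer than 3
    distinct cluster sizes are not suitable for a linear fit and raise.
    """
    if curve.sizes.size < 3:
        raise ValueError("linear fit needs at least 3 distinct cluster sizes")
    res = stats.linregress(curve.sizes.astype(float), curve.mean_peak)
    curve.slope = float(res.slope)
    curve.r2 = float(res.rvalue**2)
    return curve.slope, curve.r2


def fit_linear_responses(
    responses: list[TriggeredResponse],
) -> tuple[float, float, float]:
    """OLS of individual peaks on cluster size -> (slope, stderr, r2).

    The per-response fit provides a well-determined standard error for the
    slope (the per-size mean fit has too few points for a stable SE).
    """
    sizes = np.array([r.size for r in responses], dtype=float)
    peaks = np.array([r.peak for r in responses], dtype=float)
    if np.unique(sizes).size < 3:
        raise ValueError("linear fit needs at least 3 distinct cluster sizes")
    res = stats.linregress(sizes, peaks)
    return float(res.slope), float(res.stderr), float(res.rvalue**2)


def spikes_before_event(
    train: SpikeTrain,
    event: DilationEvent,
    window: tuple[float, float] = (-4.0, -2.0),
) -> EventSpikeCount:
    """Spike count in the half-open pre-event window [t+lo, t+hi).

    With the default window, spikes from 4 s before the event up to (but
    not including) 2 s before are counted. Events whose window precedes the
    recording start are flagged excluded.
    """
    lo, hi = window
    t0, t1 = event.time + lo, event.time + hi
    if t0 < train.t_start:
        return EventSpikeCount(event, 0, _bin_index(event.amplitude), excluded=True)
    count = int(np.searchsorted(train.times, t1, side="left")
                - np.searchsorted(train.times, t0, side="left"))
    return EventSpikeCount(event, count, _bin_index(event.amplitude))


def _bin_index(amplitude: float, bin_width: float = 0.3, bin_max: float = 3.0) -> int | None:
    if 0.0 <= amplitude < bin_max:
        return int(amplitude // bin_width)
    return None


def event_spike_counts(
    train: SpikeTrain,
    events: list[DilationEvent],
    window: tuple[float, float] = (-4.0, -2.0),
) -> list[EventSpikeCount]:
    out = [spikes_before_event(train, ev, window) for ev in events]
    return [c for c in out if not c.excluded]


def bin_events(
    counts: list[EventSpikeCount], bin_width: float = 0.3, bin_max: float = 3.0
) -> tuple[pd.DataFrame, int]:
    """Per-0.3-SD-bin spike-count summary over [0, 3) SD.

    Returns (table, n_outside). Occurrence is the fraction of all events
    (including out-of-range ones, which are excluded from the bins but
    reported via ``n_outside``).
    """
    n_bins = int(round(bin_max / bin_width))
    total = len(counts)
    rows = []
    for b in range(n_bins):
        vals = [c.count for c in counts if c.bin_index == b]
        rows.append(
            {
                "bin": b,
                "amp_lo": b * bin_width,
                "amp_hi": (b + 1) * bin_width,
                "n_events": len(vals),
                "mean_count": float(np.mean(vals)) if vals else np.nan,
                "occurrence": len(vals) / total if total else np.nan,
            }
        )
    n_outside = sum(1 for c in counts if c.bin_index is None)
    return pd.DataFrame(rows), n_outside


def exclude_licking(
    clusters: list[SpikeCluster], licks: np.ndarray, halfwidth: float = 0.5
) -> list[SpikeCluster]:
    """Drop clusters whose onset falls within +/- halfwidth of any lick
    (closed interval). Licks must be sorted."""
    licks = np.asarray(licks, dtype=float)
    if licks.size == 0:
        return list(clusters)
    out = []
    for c in clusters:
        i = np.searchsorted(licks, c.onset)
        near = min(
            licks[i] - c.onset if i < licks.size else np.inf,
            c.onset - licks[i - 1] if i > 0 else np.inf,
        )
        if near > halfwidth:
            out.append(c)
    return out


def derivative_response(
    slopes: SlopeSeries, onset: float, window: float = 6.0
) -> float:
    """Peak of the pupil time-derivative in [onset, onset + window].

    Variant of the forward analysis using pupil slopes instead of diameter.
    """
    t = slopes.times
    mask = (t >= onset) & (t <= onset + window)
    if not mask.any():
        raise ValueError("window contains no slope estimates")
    return float(slopes.slopes[mask].max())
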