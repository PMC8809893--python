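"""End-to-end session analyses combining the individual stages.

``forward_analysis`` runs cluster -> triggered peak -> coupling curve ->
per-size ROC; ``reverse_analysis`` runs dilation-event detection ->
pre-event spike counts -> per-bin ROC. Both operate on one paired
recording (a spike train and a pupil trace).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    CouplingCurve,
    DilationEvent,
    EventSpikeCount,
    PupilTrace,
    ROCResult,
    SpikeCluster,
    SpikeTrain,
    TriggeredResponse,
    as_rng,
)
from .clustering import cluster_spikes, median_isi
from .coupling import (
    bin_events,
    coupling_curve,
    event_spike_counts,
    exclude_licking,
    fit_linear_responses,
    triggered_peaks,
)
from .observer import auc_by_cluster_size, auc_by_event_bin, spike_count_pool
from .pupil import detect_dilation_events, preprocess


@dataclass
class ForwardResult:
    clusters: list[SpikeCluster]
    responses: list[TriggeredResponse]
    curve: CouplingCurve
    slope: float
    slope_se: float
    r2: float
    roc: list[ROCResult]


@dataclass
class ReverseResult:
    events: list[DilationEvent]
    counts: list[EventSpikeCount]
    bins: pd.DataFrame
    n_outside: int
    roc: list[ROCResult]


def forward_analysis(
    train: SpikeTrain,
    trace: PupilTrace,
    config: AnalysisConfig | None = None,
    licks: np.ndarray | None = None,
    roc_baseline: str = "samples",
    roc_repeats: int | None = None,
) -> ForwardResult:
    """Cluster-triggered pupil analysis of one paired recording."""
    cfg = config or AnalysisConfig()
    rng = as_rng(cfg.seed)
    z, _ = preprocess(trace, cfg.smooth_window, cfg.slope_step)
    clusters = cluster_spikes(train, median_isi(train))
    if licks is not None and len(licks):
        clusters = exclude_licking(clusters, licks, cfg.lick_halfwidth)
    responses = triggered_peaks(z, clusters, cfg.peak_window)
    curve = coupling_curve(responses)
    if curve.sizes.size >= 3:
        slope, se, r2 = fit_linear_responses(responses)
        curve.slope, curve.r2 = slope, r2
    else:
        # too few distinct cluster sizes for a linear fit; session flagged
        slope = se = r2 = float("nan")
    n_rep = roc_repeats if roc_repeats is not None else cfg.n_boot
    roc = (
        auc_by_cluster_size(
            responses, z, n_repeats=n_rep, seed=rng,
            baseline=roc_baseline, window=cfg.peak_window,
        )
        if n_rep > 0
        else []
    )
    return ForwardResult(clusters, responses, curve, slope, se, r2, roc)


def reverse_analysis(
    train: SpikeTrain,
    trace: PupilTrace,
    config: AnalysisConfig | None = None,
    pool_size: int = 1000,
    roc_repeats: int | None = None,
) -> ReverseResult:
    """Dilation-event-triggered spike analysis of one paired recording."""
    cfg = config or AnalysisConfig()
    rng = as_rng(cfg.seed)
    z, slopes = preprocess(trace, cfg.smooth_window, cfg.slope_step)
    events = detect_dilation_events(z, slopes)
    counts = event_spike_counts(train, events, cfg.pre_event_window)
    bins, n_outside = bin_events(counts, cfg.event_bin, cfg.event_bin_max)
    pool = spike_count_pool(
        train, pool_size, cfg.pre_event_window, seed=rng
    )
    n_rep = roc_repeats if roc_repeats is not None else cfg.n_boot
    roc = (
        auc_by_event_bin(counts, pool, n_repeats=n_rep, seed=rng)
        if n_rep > 0
        else []
    )
    return ReverseResult(events, counts, bins, n_outside, roc)
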