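"""Ideal-observer ROC analysis of pupil-LC coupling.

The AUC here is the two-alternative probability that a randomly chosen
"signal" observation exceeds a randomly chosen "baseline" observation
(ties count one half) — the Mann-Whitney / concordance form of the area
under the ROC curve. Signals are peak pupil values for clusters of a given
size (forward) or pre-event spike counts for dilation events of a given
amplitude bin (reverse); baselines are number-matched random draws from
the session, repeated and averaged. The performance threshold d' = 1
corresponds to AUC = Phi(1/sqrt(2)) ~ 0.76 ("~0.75") for the
equal-variance Gaussian observer.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm, rankdata

from .core import (
    EventSpikeCount,
    PupilTrace,
    ROCResult,
    SpikeTrain,
    TriggeredResponse,
    as_rng,
)
from .coupling import triggered_peak


def auc(pos, neg) -> float:
    """P(pos > neg) + 0.5 P(pos = neg), computed from midranks.

    Exactly antisymmetric: auc(a, b) + auc(b, a) = 1.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both value lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _matched_baseline(
    trace: PupilTrace,
    n: int,
    rng: np.random.Generator,
    baseline: str,
    window: float,
) -> np.ndarray:
    if baseline == "samples":
        return rng.choice(trace.values, size=n, replace=True)
    if baseline == "matched_peaks":
        onsets = rng.uniform(trace.t0, trace.t_end - window, size=n)
        return np.array(
            [triggered_peak(trace, o, window).peak for o in onsets]
        )
    raise ValueError(f"unknown baseline {baseline!r}")


def roc_cluster(
    peaks_k,
    trace: PupilTrace,
    n_repeats: int = 100,
    seed: int | np.random.Generator | None = None,
    baseline: str = "samples",
    window: float = 6.0,
    condition_label: str = "",
) -> ROCResult:
    """AUC of cluster-triggered peaks against number-matched random draws.

    ``baseline`` "samples" draws single pupil samples uniformly from the
    session trace (randomly selected pupil diameters); "matched_peaks"
    draws window maxima at random onsets, the exchangeable construction
    whose null AUC is exactly 0.5. The AUC is averaged over ``n_repeats``
    baseline draws.
    """
    peaks_k = np.asarray(peaks_k, dtype=float)
    rng = as_rng(seed)
    aucs = np.array(
        [
            auc(peaks_k, _matched_baseline(trace, peaks_k.size, rng, baseline, window))
            for _ in range(n_repeats)
        ]
    )
    return ROCResult(
        condition_label=condition_label,
        auc=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if n_repeats > 1 else np.nan,
        n_pos=int(peaks_k.size),
        n_neg=int(peaks_k.size),
        n_repeats=n_repeats,
        low_n=peaks_k.size < 3,
    )


def roc_event(
    counts_b,
    pool,
    n_repeats: int = 100,
    seed: int | np.random.Generator | None = None,
    condition_label: str = "",
) -> ROCResult:
    """AUC of pre-event spike counts against number-matched draws from a
    pool of spike counts at randomly selected times."""
    counts_b = np.asarray(counts_b, dtype=float)
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("baseline pool is empty")
    rng = as_rng(seed)
    aucs = np.array(
        [
            auc(counts_b, rng.choice(pool, size=counts_b.size, replace=True))
            for _ in range(n_repeats)
        ]
    )
    return ROCResult(
        condition_label=condition_label,
        auc=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if n_repeats > 1 else np.nan,
        n_pos=int(counts_b.size),
        n_neg=int(counts_b.size),
        n_repeats=n_repeats,
        low_n=counts_b.size < 3,
    )


def spike_count_pool(
    train: SpikeTrain,
    n: int,
    window: tuple[float, float] = (-4.0, -2.0),
    t_range: tuple[float, float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Spike counts in the pre-window of ``n`` randomly selected times."""
    lo, hi = window
    t0 = (t_range[0] if t_range else train.t_start) - lo
    t1 = t_range[1] if t_range else train.t_end
    rng = as_rng(seed)
    times = rng.uniform(t0, t1, size=n)
    a = np.searchsorted(train.times, times + lo, side="left")
    b = np.searchsorted(train.times, times + hi, side="left")
    return (b - a).astype(int)


def dprime_to_auc(d: float) -> float:
    """Equal-variance Gaussian observer: AUC = Phi(d / sqrt(2))."""
    if not np.isfinite(d):
        raise ValueError("d' must be finite")
    return float(norm.cdf(d / math.sqrt(2.0)))


def auc_to_dprime(a: float) -> float:
    """Inverse of :func:`dprime_to_auc`."""
    if not 0.0 < a < 1.0:
        raise ValueError("AUC must be in (0, 1)")
    return float(math.sqrt(2.0) * norm.ppf(a))


def threshold_crossing(
    results: list[ROCResult], thr: float = 0.75
) -> ROCResult | None:
    """First condition (in the given order) whose AUC reaches ``thr``."""
    for r in results:
        if r.auc >= thr:
            return r
    return None


def auc_by_cluster_size(
    responses: list[TriggeredResponse],
    trace: PupilTrace,
    n_repeats: int = 100,
    seed: int | np.random.Generator | None = None,
    baseline: str = "samples",
    window: float = 6.0,
    min_n: int = 3,
) -> list[ROCResult]:
    """Per-cluster-size ROC results, ordered by size."""
    rng = as_rng(seed)
    by_size: dict[int, list[float]] = {}
    for r in responses:
        by_size.setdefault(r.size, []).append(r.peak)
    out = []
    for size in sorted(by_size):
        peaks = by_size[size]
        if len(peaks) < min_n:
            continue
        out.append(
            roc_cluster(
                peaks, trace, n_repeats, rng, baseline, window,
                condition_label=f"size={size}",
            )
        )
    return out


def auc_by_event_bin(
    counts: list[EventSpikeCount],
    pool: np.ndarray,
    n_repeats: int = 100,
    seed: int | np.random.Generator | None = None,
    min_n: int = 3,
) -> list[ROCResult]:
    """Per-amplitude-bin ROC results, ordered by bin index."""
    rng = as_rng(seed)
    by_bin: dict[int, list[int]] = {}
    for c in counts:
        if c.bin_index is not None:
            by_bin.setdefault(c.bin_index, []).append(c.count)
    out = []
    for b in sorted(by_bin):
        vals = by_bin[b]
        if len(vals) < min_n:
            continue
        out.append(roc_event(vals, pool, n_repeats, rng, condition_label=f"bin={b}"))
    return out
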