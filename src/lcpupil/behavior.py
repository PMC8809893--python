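"""Go/NoGo signal-detection metrics and their link to pupil-LC coupling.

Decision bias uses the SDT criterion c = -(z(H) + z(FA)) / 2 with rates
clamped to [1/(2n), 1 - 1/(2n)] before the normal quantile; lower bias
means more liberal licking.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .core import AnalysisConfig, BehaviorSummary, PupilTrace, SpikeCluster, TrialTable
from .coupling import exclude_licking, fit_linear_responses, triggered_peaks


def _clamped_z(rate: float, n: int) -> float:
    lo = 1.0 / (2 * n)
    return float(stats.norm.ppf(np.clip(rate, lo, 1.0 - lo)))


def summarize_behavior(trials: TrialTable) -> BehaviorSummary:
    """Hit rate, false-alarm rate, criterion bias and d' for one session."""
    df = trials.trials
    go = df[df.stim_present]
    nogo = df[~df.stim_present]
    if len(go) == 0 or len(nogo) == 0:
        raise ValueError("session needs at least one go and one nogo trial")
    hit_rate = float(go.response.mean())
    fa_rate = float(nogo.response.mean())
    zh = _clamped_z(hit_rate, len(go))
    zf = _clamped_z(fa_rate, len(nogo))
    return BehaviorSummary(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        bias=-(zh + zf) / 2.0,
        dprime=zh - zf,
        n_go=len(go),
        n_nogo=len(nogo),
    )


def correlate_slope_behavior(slopes, metric) -> tuple[float, float]:
    """Pearson correlation (and two-tailed t-test p) between per-session
    coupling slopes and a behavioral metric."""
    slopes = np.asarray(slopes, dtype=float)
    metric = np.asarray(metric, dtype=float)
    if slopes.size != metric.size or slopes.size < 3:
        raise ValueError("need >= 3 paired sessions")
    if not (np.all(np.isfinite(slopes)) and np.all(np.isfinite(metric))):
        raise ValueError("values must be finite")
    res = stats.pearsonr(slopes, metric)
    return float(res.statistic), float(res.pvalue)


def nonlick_slope(
    trace: PupilTrace,
    clusters: list[SpikeCluster],
    licks: np.ndarray,
    config: AnalysisConfig | None = None,
) -> tuple[float, float]:
    """Coupling slope recomputed from clusters outside licking periods.

    Clusters within +/- lick_halfwidth of any lick are excluded, then the
    per-response linear fit is repeated. Returns (slope, r2).
    """
    cfg = config or AnalysisConfig()
    kept = exclude_licking(clusters, licks, cfg.lick_halfwidth)
    if not kept:
        raise ValueError("no clusters survive lick exclusion")
    responses = triggered_peaks(trace, kept, cfg.peak_window)
    slope, _, r2 = fit_linear_responses(responses)
    return slope, r2


def session_qualifies(
    n_trials: int, r2: float, min_trials: int = 100, min_r2: float = 0.6
) -> bool:
    """Quality gate for slope-behavior correlations: enough trials and a
    coupling relation well described by a line."""
    return n_trials > min_trials and r2 > min_r2
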