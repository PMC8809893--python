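"""Resampling statistics for session comparisons.

Covers the bootstrap mean/CI of per-trial evoked responses, the
with-replacement permutation test between two sessions under identical
stimulation, across- vs within-session variability by pooled resampling,
waveform similarity, and the rank-sum test.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .core import PermutationResult, SessionPair, as_rng

logger = logging.getLogger("lcpupil")


def bootstrap_mean_ci(
    x,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Sample mean with a percentile bootstrap CI (default 100 resamples)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 2:
        logger.warning("n_boot=%d gives a degenerate CI", n_boot)
    rng = as_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(x.mean()), float(lo), float(hi)


def permutation_test(
    pair: SessionPair,
    n_iter: int = 1000,
    seed: int | np.random.Generator | None = None,
    with_replacement: bool = True,
) -> PermutationResult:
    """Resampling test for a session difference in mean evoked response.

    Trials from both sessions are pooled; each iteration re-draws
    pseudo-sessions of the original sizes (with replacement by default, the
    bootstrap-style null; ``with_replacement=False`` gives a strict
    permutation) and records the absolute difference of their means. The
    two-sided p is (1 + #{null >= observed}) / (n_iter + 1), so p is never 0.
    """
    x1, x2 = pair.responses_1, pair.responses_2
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both response lists must be non-empty")
    if n_iter < 100:
        logger.warning("n_iter=%d is low for a stable p value", n_iter)
    rng = as_rng(seed)
    observed = abs(float(x1.mean() - x2.mean()))
    pooled = np.concatenate([x1, x2])
    n1, n2 = x1.size, x2.size
    if with_replacement:
        m1 = pooled[rng.integers(0, pooled.size, size=(n_iter, n1))].mean(axis=1)
        m2 = pooled[rng.integers(0, pooled.size, size=(n_iter, n2))].mean(axis=1)
        null = np.abs(m1 - m2)
    else:
        null = np.empty(n_iter)
        for i in range(n_iter):
            perm = rng.permutation(pooled)
            null[i] = abs(perm[:n1].mean() - perm[n1:].mean())
    p = (1.0 + float(np.sum(null >= observed))) / (n_iter + 1.0)
    return PermutationResult(observed_diff=observed, null_diffs=null, p=p, n_iter=n_iter)


def across_session_sd(
    sessions: list[np.ndarray],
    n_rep: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Across-session variability by pooled resampling.

    Trials from all sessions are pooled; each repeat draws as many
    pseudo-sessions as real sessions (each with that session's trial count,
    with replacement) and takes the SD of the pseudo-session means; the SDs
    are averaged over repeats.
    """
    sessions = [np.asarray(s, dtype=float) for s in sessions]
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    rng = as_rng(seed)
    pooled = np.concatenate(sessions)
    sds = np.empty(n_rep)
    for r in range(n_rep):
        means = [
            pooled[rng.integers(0, pooled.size, size=s.size)].mean() for s in sessions
        ]
        sds[r] = np.std(means, ddof=1)
    return float(sds.mean())


def within_session_sd(
    sessions: list[np.ndarray],
    n_rep: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Within-session variability: bootstrap SD of each session's mean,
    averaged over sessions."""
    sessions = [np.asarray(s, dtype=float) for s in sessions]
    rng = as_rng(seed)
    out = []
    for s in sessions:
        idx = rng.integers(0, s.size, size=(n_rep, s.size))
        out.append(s[idx].mean(axis=1).std(ddof=1))
    return float(np.mean(out))


def within_outside_5pct(
    pair: SessionPair,
    n_iter: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[bool, bool]:
    """Flag sessions whose trial SD falls outside the central 95% of the
    pooled-resample null distribution of session SDs."""
    rng = as_rng(seed)
    pooled = np.concatenate([pair.responses_1, pair.responses_2])
    flags = []
    for x in (pair.responses_1, pair.responses_2):
        idx = rng.integers(0, pooled.size, size=(n_iter, x.size))
        null_sds = pooled[idx].std(axis=1, ddof=1)
        lo, hi = np.percentile(null_sds, [2.5, 97.5])
        obs = x.std(ddof=1)
        flags.append(bool(obs < lo or obs > hi))
    return flags[0], flags[1]


def waveform_similarity(w1, w2) -> float:
    """Pearson correlation between two equal-length waveforms."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.size != w2.size or w1.size < 3:
        raise ValueError("waveforms must be equal length >= 3")
    if np.std(w1) == 0 or np.std(w2) == 0:
        raise ValueError("waveforms must have nonzero variance")
    return float(stats.pearsonr(w1, w2).statistic)


def rank_sum_test(a, b) -> float:
    """Two-tailed Wilcoxon rank-sum p (exact for small untied samples,
    normal approximation with tie correction otherwise)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
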