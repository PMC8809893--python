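"""Grouping adjacent LC spikes into clusters by the unit's median ISI.

Two adjacent spikes join the same cluster when their interspike interval is
strictly shorter than the threshold (by default the unit's median ISI); ties
split. Single-spike clusters are valid. Cluster onset is the time of the
first spike and cluster size the spike count.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SpikeCluster, SpikeTrain


def median_isi(train: SpikeTrain) -> float:
    """Median interspike interval of the unit (needs >= 3 spikes)."""
    if train.n_spikes < 3:
        raise ValueError("median ISI needs at least 3 spikes (2 intervals)")
    return float(np.median(np.diff(train.times)))


def cluster_spikes(train: SpikeTrain, threshold: float) -> list[SpikeCluster]:
    """Left-to-right scan: a spike joins the current cluster iff its ISI to
    the previous spike is strictly below ``threshold``; otherwise it starts a
    new cluster. The clusters partition the train."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = train.times
    if t.size == 0:
        return []
    # cut at every ISI >= threshold
    cut = np.flatnonzero(np.diff(t) >= threshold) + 1
    return [SpikeCluster(member_times=seg) for seg in np.split(t, cut)]


def size_occurrence(clusters: list[SpikeCluster]) -> pd.Series:
    """Fraction of clusters per size (sums to 1), indexed by size."""
    sizes = pd.Series([c.size for c in clusters], dtype=int)
    return sizes.value_counts(normalize=True).sort_index()


def cluster_sensitivity(
    train: SpikeTrain, thresholds: list[float]
) -> pd.DataFrame:
    """Re-cluster at each threshold; tidy table of the size distributions.

    Columns: threshold, size, count, occurrence. Used to report robustness
    of the size distribution to the grouping window (0.1-0.5 s).
    """
    rows = []
    for thr in thresholds:
        clusters = cluster_spikes(train, thr)
        occ = size_occurrence(clusters)
        counts = pd.Series([c.size for c in clusters]).value_counts().sort_index()
        for size in occ.index:
            rows.append(
                {
                    "threshold": thr,
                    "size": int(size),
                    "count": int(counts.loc[size]),
                    "occurrence": float(occ.loc[size]),
                }
            )
    return pd.DataFrame(rows, columns=["threshold", "size", "count", "occurrence"])
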