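"""Delimited-text readers and writers for the pipeline's interchange files.

All files are comma-separated with a header row:

* spikes.csv       — unit_id, time_s
* pupil.csv        — time_s, diameter
* licks.csv        — time_s
* trials.csv       — trial_id, onset_s, stim_present, response, outcome
* stim_trials.csv  — onset_s, pulse_ms, n_pulses, freq_hz
* config.yaml      — AnalysisConfig keys
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AnalysisConfig, PupilTrace, SpikeTrain, StimTrialTable, TrialTable

logger = logging.getLogger("lcpupil")


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def read_spikes(path) -> list[SpikeTrain]:
    """Read a spikes.csv into one SpikeTrain per unit.

    Times are sorted (with a warning if the file was unsorted) and exact
    duplicate times within a unit are collapsed with a warning.
    """
    df = pd.read_csv(path)
    _require_columns(df, {"unit_id", "time_s"}, path)
    if not np.issubdtype(df["time_s"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric time_s column")
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            logger.warning("unit %s: unsorted spike times, sorting", unit_id)
            t = np.sort(t)
        uniq = np.unique(t)
        if uniq.size < t.size:
            logger.warning(
                "unit %s: collapsed %d duplicate spike times", unit_id, t.size - uniq.size
            )
            t = uniq
        trains.append(SpikeTrain(unit_id=str(unit_id), times=t))
    return trains


def write_spikes(trains: list[SpikeTrain], path) -> None:
    frames = [
        pd.DataFrame({"unit_id": tr.unit_id, "time_s": tr.times}) for tr in trains
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pupil(
    path, rate: float, units: str = "mm", max_gap: float = 1.0, max_missing: float = 0.2
) -> PupilTrace:
    """Read pupil.csv onto a regular grid at the declared rate.

    Timestamps jittered by less than half a sample period are snapped to the
    grid. Missing or NaN samples are linearly interpolated when the gap is at
    most ``max_gap`` seconds; longer gaps raise (use :func:`split_on_gaps` on
    the raw columns to analyse segments separately). More than
    ``max_missing`` fraction missing raises.
    """
    df = pd.read_csv(path)
    _require_columns(df, {"time_s", "diameter"}, path)
    t = df["time_s"].to_numpy(dtype=float)
    x = df["diameter"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    t0 = t[0]
    idx = np.round((t - t0) * rate).astype(int)
    if np.unique(idx).size < idx.size:
        raise ValueError(f"{path}: timestamps collide on the {rate} Hz grid")
    n = idx[-1] + 1
    grid = np.full(n, np.nan)
    grid[idx] = x
    missing = ~np.isfinite(grid)
    frac = missing.mean()
    if frac > max_missing:
        raise ValueError(f"{path}: {frac:.0%} samples missing (> {max_missing:.0%})")
    if missing.any():
        _check_gap_lengths(missing, rate, max_gap, path)
        good = np.flatnonzero(~missing)
        grid[missing] = np.interp(np.flatnonzero(missing), good, grid[good])
        logger.info("%s: interpolated %.2f%% of samples", path, 100 * frac)
    return PupilTrace(values=grid, rate=rate, t0=t0, units=units)


def _check_gap_lengths(missing: np.ndarray, rate: float, max_gap: float, path) -> None:
    # run-length encode the missing mask
    edges = np.diff(missing.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if missing[0]:
        starts = np.r_[0, starts]
    if missing[-1]:
        ends = np.r_[ends, missing.size]
    longest = (ends - starts).max() / rate
    if longest > max_gap:
        raise ValueError(
            f"{path}: gap of {longest:.2f} s exceeds max_gap={max_gap} s; "
            "split the recording at long gaps"
        )


def split_on_gaps(
    time_s: np.ndarray, diameter: np.ndarray, rate: float, max_gap: float = 1.0,
    units: str = "mm",
) -> list[PupilTrace]:
    """Split an irregular time/diameter series into regular traces at long gaps."""
    t = np.asarray(time_s, dtype=float)
    x = np.asarray(diameter, dtype=float)
    keep = np.isfinite(x)
    t, x = t[keep], x[keep]
    cuts = np.flatnonzero(np.diff(t) > max_gap) + 1
    traces = []
    for seg_t, seg_x in zip(np.split(t, cuts), np.split(x, cuts)):
        if seg_t.size < 2:
            continue
        idx = np.round((seg_t - seg_t[0]) * rate).astype(int)
        n = idx[-1] + 1
        grid = np.full(n, np.nan)
        grid[idx] = seg_x
        miss = ~np.isfinite(grid)
        if miss.any():
            good = np.flatnonzero(~miss)
            grid[miss] = np.interp(np.flatnonzero(miss), good, grid[good])
        traces.append(PupilTrace(values=grid, rate=rate, t0=seg_t[0], units=units))
    return traces


def write_pupil(trace: PupilTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "diameter": trace.values}).to_csv(
        path, index=False
    )


def read_licks(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, {"time_s"}, path)
    t = df["time_s"].to_numpy(dtype=float)
    return np.sort(t)


def write_licks(licks: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": np.asarray(licks, dtype=float)}).to_csv(path, index=False)


def read_trials(path, licks_path=None) -> TrialTable:
    df = pd.read_csv(path)
    _require_columns(df, {"trial_id", "stim_present", "response", "outcome"}, path)
    df["stim_present"] = df["stim_present"].astype(bool)
    df["response"] = df["response"].astype(bool)
    licks = read_licks(licks_path) if licks_path is not None else np.array([])
    return TrialTable(trials=df, lick_times=licks)


def write_trials(table: TrialTable, path, licks_path=None) -> None:
    table.trials.to_csv(path, index=False)
    if licks_path is not None:
        write_licks(table.lick_times, licks_path)


def read_stim_trials(path) -> StimTrialTable:
    df = pd.read_csv(path)
    return StimTrialTable(trials=df)


def write_stim_trials(table: StimTrialTable, path) -> None:
    table.trials.to_csv(path, index=False)


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML; absent keys take the defaults.

    Unknown keys raise (they are almost always typos of real knobs).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - AnalysisConfig.field_names()
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        return AnalysisConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid config value ({exc})") from exc


def save_config(cfg: AnalysisConfig, path) -> None:
    data = {
        "peak_window": cfg.peak_window,
        "smooth_window": cfg.smooth_window,
        "slope_step": cfg.slope_step,
        "pre_event_window": list(cfg.pre_event_window),
        "event_bin": cfg.event_bin,
        "event_bin_max": cfg.event_bin_max,
        "lick_halfwidth": cfg.lick_halfwidth,
        "n_boot": cfg.n_boot,
        "n_perm": cfg.n_perm,
        "auc_threshold": cfg.auc_threshold,
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(data))
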