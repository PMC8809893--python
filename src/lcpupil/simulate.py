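"""Synthetic paired LC-spike / pupil / behavior / stimulation data.

The generator emulates the statistical structure of awake paired
recordings: a bursty noradrenergic spike train whose cluster-size
occurrence decays geometrically, a pupil trace built as slow drift plus a
per-spike impulse response peaking ~3 s after the spike plus measurement
noise, a session-level coupling gain, and Go/NoGo behavioral sessions with
controllable hit and false-alarm rates. Ground-truth cluster memberships
and gains are returned so every downstream stage can be checked against
what was actually generated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, lfilter

from .core import (
    PupilTrace,
    SessionPair,
    SpikeCluster,
    SpikeTrain,
    StimTrialTable,
    TrialTable,
    as_rng,
)


@dataclass
class CouplingKernel:
    """Gamma-shaped pupil impulse response to a single LC spike.

    k(t) = amplitude * (t/peak_latency)^a * exp((peak_latency - t)/decay)
    with a = peak_latency/decay, so the unique maximum (= amplitude) sits at
    ``peak_latency`` and the tail decays with time constant ``decay``.
    Default peak latency 3 s lies inside the 2.5-4 s range of measured
    pupil responses to LC spiking.
    """

    peak_latency: float = 3.0
    decay: float = 1.0
    amplitude: float = 0.2  # z-units per spike

    def __post_init__(self) -> None:
        if self.peak_latency <= 0 or self.decay <= 0 or self.amplitude < 0:
            raise ValueError("kernel parameters must be positive")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a = self.peak_latency / self.decay
        out = np.zeros_like(t)
        pos = t > 0
        tp = t[pos] / self.peak_latency
        out[pos] = self.amplitude * tp**a * np.exp((self.peak_latency - t[pos]) / self.decay)
        return out

    def support(self) -> float:
        """Time past which the kernel is negligible (~1e-13 of amplitude)."""
        return self.peak_latency + 40.0 * self.decay

    def sample(self, rate_hz: float) -> np.ndarray:
        t = np.arange(1, int(np.ceil(self.support() * rate_hz))) / rate_hz
        return self(t)


@dataclass
class SimConfig:
    """Parameters of one simulated paired recording session."""

    duration: float = 1200.0
    cluster_rate: float = 0.08  # cluster onsets per second (Poisson)
    cluster_size_dist: float = 0.55  # geometric p; P(size=k) = p(1-p)^(k-1)
    intra_cluster_isi: float = 0.04
    kernel: CouplingKernel = field(default_factory=CouplingKernel)
    gain: float = 1.0
    noise_sd: float = 0.15
    drift_sd: float = 0.7
    drift_tau: float = 30.0
    rate_hz: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cluster_rate, self.noise_sd, self.drift_sd, self.intra_cluster_isi) < 0:
            raise ValueError("rates and SDs must be nonnegative")
        if self.drift_tau <= 0 or self.rate_hz <= 0:
            raise ValueError("drift_tau and rate_hz must be positive")
        if self.duration <= 10 * self.kernel.peak_latency:
            raise ValueError("duration must exceed 10x the kernel peak latency")
        if not (0 < self.cluster_size_dist <= 1):
            raise ValueError("cluster_size_dist must be in (0, 1]")
        if self.cluster_rate > 0:
            median_gap = math.log(2) / self.cluster_rate
            if self.intra_cluster_isi >= median_gap:
                raise ValueError(
                    "intra_cluster_isi >= median inter-cluster gap: clusters would merge"
                )


def generate_spike_train(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SpikeTrain, list[SpikeCluster]]:
    """Draw a bursty spike train and return it with its ground-truth clusters.

    Cluster onsets follow a homogeneous Poisson process at ``cluster_rate``;
    each cluster's spike count is geometric(``cluster_size_dist``) so the
    occurrence of cluster sizes decays monotonically; within-cluster ISIs are
    fixed at ``intra_cluster_isi``.
    """
    rng = as_rng(rng if rng is not None else [1, cfg.seed])
    if cfg.cluster_rate == 0:
        return (
            SpikeTrain("sim", np.array([]), t_start=0.0, t_end=cfg.duration),
            [],
        )
    n_onsets = rng.poisson(cfg.cluster_rate * cfg.duration)
    onsets = np.sort(rng.uniform(0.0, cfg.duration, n_onsets))
    sizes = rng.geometric(cfg.cluster_size_dist, n_onsets)
    clusters = []
    all_times = []
    for onset, size in zip(onsets, sizes):
        member = onset + cfg.intra_cluster_isi * np.arange(size)
        member = member[member <= cfg.duration]
        if member.size == 0:
            continue
        clusters.append(SpikeCluster(member_times=member))
        all_times.append(member)
    if all_times:
        times = np.unique(np.concatenate(all_times))
    else:
        times = np.array([])
    train = SpikeTrain("sim", times, t_start=0.0, t_end=cfg.duration)
    return train, clusters


def generate_pupil(
    spikes: SpikeTrain, cfg: SimConfig, rng: np.random.Generator | None = None
) -> PupilTrace:
    """Pupil trace = OU drift + gain * sum_i kernel(t - t_i) + white noise.

    Values are on a z-like scale (units flag "z"); nothing is re-normalised,
    so with gain 0, noise 0 and drift 0 the trace is identically zero, and a
    single spike reproduces the kernel exactly on the sample grid.
    """
    rng = as_rng(rng if rng is not None else [2, cfg.seed])
    n = int(round(cfg.duration * cfg.rate_hz))
    if spikes.times.size and (spikes.times[0] < 0 or spikes.times[-1] > cfg.duration):
        raise ValueError("spikes outside [0, duration]")
    dt = 1.0 / cfg.rate_hz

    signal = np.zeros(n)
    if cfg.gain != 0 and spikes.times.size:
        impulses = np.zeros(n)
        idx = np.clip(np.round(spikes.times * cfg.rate_hz).astype(int), 0, n - 1)
        np.add.at(impulses, idx, 1.0)
        kern = cfg.kernel.sample(cfg.rate_hz)
        conv = fftconvolve(impulses, kern)[: n - 1]
        signal[1:] = cfg.gain * conv  # kernel sampled from one step after the spike

    drift = np.zeros(n)
    if cfg.drift_sd > 0:
        # exact OU discretisation as an AR(1) filter, stationary start
        a = math.exp(-dt / cfg.drift_tau)
        innov = rng.normal(0.0, cfg.drift_sd * math.sqrt(1 - a * a), n)
        innov[0] = rng.normal(0.0, cfg.drift_sd)
        drift = lfilter([1.0], [1.0, -a], innov)

    noise = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
    return PupilTrace(values=drift + signal + noise, rate=cfg.rate_hz, units="z")


def generate_session(
    cfg: SimConfig,
) -> tuple[SpikeTrain, PupilTrace, list[SpikeCluster]]:
    """One paired recording: spike train, pupil trace, ground-truth clusters."""
    train, clusters = generate_spike_train(cfg)
    trace = generate_pupil(train, cfg)
    return train, trace, clusters


def make_stim_table(
    n_trials: int, iti: float = 15.0, t_first: float = 20.0,
    pulse_ms: float = 10.0, n_pulses: int = 4, freq_hz: float = 10.0,
) -> StimTrialTable:
    """Regular optical stimulation schedule (default four 10-ms pulses at 10 Hz)."""
    onsets = t_first + iti * np.arange(n_trials)
    return StimTrialTable(
        trials=pd.DataFrame(
            {
                "onset_s": onsets,
                "pulse_ms": pulse_ms,
                "n_pulses": n_pulses,
                "freq_hz": freq_hz,
            }
        )
    )


def _evoked_peaks(
    trace: PupilTrace, onsets: np.ndarray, baseline_window: float, response_window: float
) -> np.ndarray:
    peaks = []
    for onset in onsets:
        i0 = trace.index_at(onset - baseline_window)
        i1 = trace.index_at(onset)
        i2 = trace.index_at(onset + response_window)
        base = trace.values[i0:i1].mean()
        peaks.append(trace.values[i1 : i2 + 1].max() - base)
    return np.array(peaks)


def generate_session_pair(
    cfg_a: SimConfig,
    cfg_b: SimConfig,
    stim: StimTrialTable,
    baseline_window: float = 2.0,
    response_window: float = 6.0,
) -> SessionPair:
    """Two simulated sessions receiving the identical stimulation schedule.

    The configs may differ only in gain, noise/drift levels and seed; each
    stimulation trial injects ``n_pulses`` spikes at ``freq_hz`` into the
    spontaneous train before the pupil is generated. Returns the per-trial
    evoked peak pupil responses of both sessions.
    """
    base_a = replace(cfg_a, gain=0, noise_sd=0, drift_sd=0, seed=0)
    base_b = replace(cfg_b, gain=0, noise_sd=0, drift_sd=0, seed=0)
    if base_a != base_b:
        raise ValueError("session configs may differ only in gain, noise and seed")
    if stim.onsets.size and stim.onsets[-1] + response_window > cfg_a.duration:
        raise ValueError("stimulation schedule extends past the session duration")

    responses = []
    for cfg in (cfg_a, cfg_b):
        rng = as_rng([3, cfg.seed])
        train, _ = generate_spike_train(cfg, rng)
        stim_spikes = []
        for _, row in stim.trials.iterrows():
            stim_spikes.append(row.onset_s + np.arange(int(row.n_pulses)) / row.freq_hz)
        times = np.unique(np.concatenate([train.times, *stim_spikes]))
        full = SpikeTrain("sim", times, t_start=0.0, t_end=cfg.duration)
        trace = generate_pupil(full, cfg, rng)
        responses.append(
            _evoked_peaks(trace, stim.onsets, baseline_window, response_window)
        )
    return SessionPair(responses_1=responses[0], responses_2=responses[1])


def generate_behavior_session(
    hit_rate: float,
    fa_rate: float,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    p_go: float = 0.5,
    iti: float = 10.0,
) -> TrialTable:
    """Go/NoGo session with Bernoulli outcomes at the given hit/FA rates.

    Trials are laid out every ``iti`` seconds; every response (hit or false
    alarm) places a lick 0.5 s after trial onset.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = as_rng(seed)
    stim = rng.random(n_trials) < p_go
    p_resp = np.where(stim, hit_rate, fa_rate)
    resp = rng.random(n_trials) < p_resp
    outcome = np.where(
        stim, np.where(resp, "hit", "miss"), np.where(resp, "fa", "cr")
    )
    onsets = iti * np.arange(n_trials) + 2.0
    df = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "onset_s": onsets,
            "stim_present": stim,
            "response": resp,
            "outcome": outcome,
        }
    )
    licks = onsets[resp] + 0.5
    return TrialTable(trials=df, lick_times=licks)
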