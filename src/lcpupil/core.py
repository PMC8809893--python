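"""Domain types shared across the pupil-LC analysis pipeline.

Conventions: all times are seconds from session start; pupil traces are
regularly sampled with interval-start timestamps; diameters are either mm
(raw) or z (session z-scored / z-scale simulated) as flagged on the trace.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
import numpy as np
import pandas as pd


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SpikeTrain:
    """Ordered spike times of one unit within one session."""

    unit_id: str
    times: np.ndarray
    session_id: str = ""
    t_start: float = 0.0
    t_end: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.t_end is None:
            self.t_end = float(self.times[-1]) if self.times.size else self.t_start
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < self.t_start or self.times[-1] > self.t_end:
                raise ValueError("spike times outside [t_start, t_end]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.t_end - self.t_start)

    @property
    def rate(self) -> float:
        return self.n_spikes / self.duration if self.duration > 0 else np.nan


@dataclass
class PupilTrace:
    """Regularly sampled pupil diameter series.

    ``units`` is "mm" for raw diameters or "z" for z-scored (or z-scale
    simulated) values.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = "mm"
    session_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.values.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.units not in ("mm", "z"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + (self.values.size - 1) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample whose interval contains time t."""
        return int(np.clip(round((t - self.t0) * self.rate), 0, self.values.size - 1))

    def value_at(self, t: float) -> float:
        return float(self.values[self.index_at(t)])


@dataclass
class SpikeCluster:
    """A run of adjacent spikes; onset is the time of the first spike."""

    member_times: np.ndarray

    def __post_init__(self) -> None:
        self.member_times = np.asarray(self.member_times, dtype=float)
        if self.member_times.size < 1:
            raise ValueError("cluster needs at least one spike")

    @property
    def onset(self) -> float:
        return float(self.member_times[0])

    @property
    def size(self) -> int:
        return int(self.member_times.size)


@dataclass
class DilationEvent:
    """Local pupil maximum between consecutive positive slope zero-crossings."""

    time: float
    amplitude: float  # z value of the trace at the maximum
    rise_start: float  # preceding positive zero-crossing (<= time)

    def __post_init__(self) -> None:
        if self.rise_start > self.time:
            raise ValueError("rise_start must precede the event time")


@dataclass
class SlopeSeries:
    """Pupil slopes estimated from consecutive step-bin averages.

    slopes[k] is the finite difference between bin k+1 and bin k, assigned
    to the boundary time t0 + (k+1)*step.
    """

    slopes: np.ndarray
    step: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.step * (np.arange(self.slopes.size) + 1)


@dataclass
class TriggeredResponse:
    """Peak pupil value in a window following a spike-cluster onset."""

    onset: float
    size: int
    peak: float
    latency: float
    excluded: bool = False


@dataclass
class CouplingCurve:
    """Per-cluster-size summary of triggered pupil peaks."""

    sizes: np.ndarray
    mean_peak: np.ndarray
    sem: np.ndarray
    occurrence: np.ndarray  # fraction of clusters per size, sums to 1
    n: np.ndarray
    slope: float | None = None
    r2: float | None = None
    low_n_sizes: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "mean_peak": self.mean_peak,
                "sem": self.sem,
                "occurrence": self.occurrence,
                "n": self.n,
            }
        )


@dataclass
class EventSpikeCount:
    """Spike count in the pre-event window of one dilation event."""

    event: DilationEvent
    count: int
    bin_index: int | None  # floor(amplitude / 0.3) for amplitudes in [0, 3)
    excluded: bool = False


@dataclass
class ROCResult:
    """Ideal-observer discriminability of one condition vs a random baseline."""

    condition_label: str
    auc: float
    n_pos: int
    n_neg: int
    n_repeats: int
    auc_sd: float = np.nan
    low_n: bool = False


@dataclass
class SessionPair:
    """Per-trial evoked pupil responses from two sessions under identical stimulation."""

    responses_1: np.ndarray
    responses_2: np.ndarray
    label: str = ""
    baseline_1: float | None = None
    baseline_2: float | None = None

    def __post_init__(self) -> None:
        self.responses_1 = np.asarray(self.responses_1, dtype=float)
        self.responses_2 = np.asarray(self.responses_2, dtype=float)
        for b in (self.baseline_1, self.baseline_2):
            if b is not None and b <= 0:
                raise ValueError("baseline diameters must be positive")

    def baseline_matched(self, tol_mm: float = 0.05) -> bool:
        if self.baseline_1 is None or self.baseline_2 is None:
            raise ValueError("baselines not set")
        return abs(self.baseline_1 - self.baseline_2) <= tol_mm


@dataclass
class PermutationResult:
    observed_diff: float
    null_diffs: np.ndarray
    p: float
    n_iter: int


@dataclass
class BehaviorSummary:
    """Signal-detection summary of a Go/NoGo session."""

    hit_rate: float
    fa_rate: float
    bias: float
    dprime: float
    n_go: int
    n_nogo: int


@dataclass
class TrialTable:
    """Go/NoGo trial outcomes plus session lick times.

    ``trials`` columns: trial_id, onset_s, stim_present (bool),
    response (bool), outcome in {hit, miss, fa, cr}.
    """

    trials: pd.DataFrame
    lick_times: np.ndarray = field(default_factory=lambda: np.array([]))

    _VALID = {
        (True, True): "hit",
        (True, False): "miss",
        (False, True): "fa",
        (False, False): "cr",
    }

    def __post_init__(self) -> None:
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        required = {"trial_id", "stim_present", "response", "outcome"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        for _, row in self.trials.iterrows():
            expect = self._VALID[(bool(row.stim_present), bool(row.response))]
            if row.outcome != expect:
                raise ValueError(
                    f"trial {row.trial_id}: outcome {row.outcome!r} inconsistent "
                    f"with stim_present={row.stim_present}, response={row.response}"
                )


@dataclass
class StimTrialTable:
    """Optogenetic stimulation trials: onset_s, pulse_ms, n_pulses, freq_hz."""

    trials: pd.DataFrame
    min_iti: float = 10.0

    def __post_init__(self) -> None:
        required = {"onset_s", "pulse_ms", "n_pulses", "freq_hz"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"stim table missing columns: {sorted(missing)}")
        onsets = self.trials["onset_s"].to_numpy(dtype=float)
        if onsets.size > 1:
            gaps = np.diff(onsets)
            if np.any(gaps <= 0):
                raise ValueError("stimulation onsets must be increasing")
            if np.any(gaps < self.min_iti):
                raise ValueError(
                    f"stimulation trials closer than {self.min_iti} s would overlap"
                )

    @property
    def onsets(self) -> np.ndarray:
        return self.trials["onset_s"].to_numpy(dtype=float)


@dataclass
class EvokedResponse:
    """Baseline-subtracted peak pupil change after a stimulation trial."""

    onset: float
    baseline: float
    peak: float
    latency: float


@dataclass
class FiberModel:
    """Optical-fiber and tissue parameters for the excitable-volume estimate."""

    power_mw: float = 10.0
    radius_mm: float = 0.1  # 200 um core
    na: float = 0.39
    n_tissue: float = 1.4
    scatter_per_mm: float = 11.2
    threshold_mw_mm2: float = 2.5
    cone_full_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        vals = (
            self.power_mw,
            self.radius_mm,
            self.na,
            self.n_tissue,
            self.scatter_per_mm,
            self.threshold_mw_mm2,
            self.cone_full_angle_deg,
        )
        if any(v < 0 for v in vals):
            raise ValueError("fiber model parameters must be nonnegative")
        if self.na >= self.n_tissue:
            raise ValueError("NA must be below the tissue refractive index")


# Defaults below are the analysis constants used throughout: 6-s peak window,
# 500-ms smoothing, 200-ms slope steps, -4..-2 s pre-event spike window,
# 0.3-SD event bins up to 3 SD, +/-0.5 s lick exclusion, 100 bootstrap and
# 1000 permutation iterations, 0.75 AUC performance threshold (d' = 1).
@dataclass
class AnalysisConfig:
    peak_window: float = 6.0
    smooth_window: float = 0.5
    slope_step: float = 0.2
    pre_event_window: tuple[float, float] = (-4.0, -2.0)
    event_bin: float = 0.3
    event_bin_max: float = 3.0
    lick_halfwidth: float = 0.5
    n_boot: int = 100
    n_perm: int = 1000
    auc_threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        self.pre_event_window = tuple(self.pre_event_window)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        for name in ("peak_window", "smooth_window", "slope_step", "event_bin",
                     "event_bin_max", "lick_halfwidth", "auc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.pre_event_window
        if not (lo < hi < 0):
            raise ValueError("pre_event_window must satisfy lo < hi < 0")
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be >= 1")

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in fields(cls)}
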