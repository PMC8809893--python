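"""Evoked responses to optical LC stimulation and the excitable-volume model.

The excitable volume is the tissue cone under the fiber tip in which the
modeled irradiance exceeds the opsin activation threshold. Light spread
follows the geometric-plus-scattering transmission model

    I(z) = I(0) * rho^2 / ((S*z + 1) * (z + rho)^2),
    rho  = radius * sqrt((n/NA)^2 - 1),  I(0) = power / (pi * radius^2),

with S the tissue scattering coefficient. The threshold depth z* solves
I(z*) = threshold; the volume is the conical frustum from the fiber tip
radius to radius + z* tan(half-angle).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .core import EvokedResponse, FiberModel, PupilTrace, SessionPair, SpikeTrain, StimTrialTable

logger = logging.getLogger("lcpupil")


def evoked_pupil(
    trace: PupilTrace,
    onset: float,
    baseline_window: float = 2.0,
    response_window: float = 6.0,
) -> EvokedResponse:
    """Baseline-subtracted peak pupil response to one stimulation trial.

    Baseline is the mean over [onset - baseline_window, onset); the peak is
    the maximum over [onset, onset + response_window] minus baseline.
    """
    if onset - baseline_window < trace.t0 or onset + response_window > trace.t_end:
        raise ValueError("stimulation windows extend past the recording")
    i0 = trace.index_at(onset - baseline_window)
    i1 = trace.index_at(onset)
    i2 = trace.index_at(onset + response_window)
    baseline = float(trace.values[i0:i1].mean())
    seg = trace.values[i1 : i2 + 1]
    k = int(np.argmax(seg))
    return EvokedResponse(
        onset=onset,
        baseline=baseline,
        peak=float(seg[k] - baseline),
        latency=float(k / trace.rate),
    )


def evoked_pupil_responses(
    trace: PupilTrace,
    stim: StimTrialTable,
    baseline_window: float = 2.0,
    response_window: float = 6.0,
) -> list[EvokedResponse]:
    return [
        evoked_pupil(trace, o, baseline_window, response_window) for o in stim.onsets
    ]


def evoked_spikes(
    train: SpikeTrain, stim: StimTrialTable, tail: float = 0.05
) -> np.ndarray:
    """Spike count per stimulation trial, from the first pulse onset to the
    last pulse offset plus ``tail`` seconds."""
    counts = []
    for _, row in stim.trials.iterrows():
        t0 = float(row.onset_s)
        last_on = t0 + (int(row.n_pulses) - 1) / float(row.freq_hz) if row.n_pulses > 1 else t0
        t1 = last_on + float(row.pulse_ms) / 1000.0 + tail
        counts.append(
            int(
                np.searchsorted(train.times, t1, side="right")
                - np.searchsorted(train.times, t0, side="left")
            )
        )
    return np.array(counts, dtype=int)


def normalize_sessions(pair: SessionPair) -> SessionPair:
    """Divide both sessions' responses by the session-1 mean (maps it to 1)."""
    m1 = float(pair.responses_1.mean())
    if m1 == 0:
        raise ValueError("session-1 mean response is zero; cannot normalize")
    return replace(
        pair,
        responses_1=pair.responses_1 / m1,
        responses_2=pair.responses_2 / m1,
    )


@dataclass
class VolumeEstimate:
    z_star_mm: float
    volume_mm3: float
    surface_irradiance_mw_mm2: float


def irradiance(model: FiberModel, z) -> np.ndarray:
    """Modeled irradiance (mW/mm^2) at depth z (mm) below the fiber tip."""
    z = np.asarray(z, dtype=float)
    rho = model.radius_mm * math.sqrt((model.n_tissue / model.na) ** 2 - 1.0)
    i0 = model.power_mw / (math.pi * model.radius_mm**2)
    return i0 * rho**2 / ((model.scatter_per_mm * z + 1.0) * (z + rho) ** 2)


def excitable_volume(model: FiberModel, tol: float = 1e-6) -> VolumeEstimate:
    """Excitable tissue volume under the fiber tip.

    Finds the depth z* where the irradiance falls to the activation
    threshold (bisection to ``tol`` mm) and returns the volume of the
    conical frustum with the configured full cone angle.
    """
    i0 = model.power_mw / (math.pi * model.radius_mm**2)
    if model.threshold_mw_mm2 >= i0:
        logger.warning("threshold >= surface irradiance: excitable volume is zero")
        return VolumeEstimate(0.0, 0.0, i0)
    lo, hi = 0.0, 1.0
    while irradiance(model, hi) > model.threshold_mw_mm2:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("threshold depth did not bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if irradiance(model, mid) > model.threshold_mw_mm2:
            lo = mid
        else:
            hi = mid
    z_star = 0.5 * (lo + hi)
    r0 = model.radius_mm
    r1 = r0 + z_star * math.tan(math.radians(model.cone_full_angle_deg / 2.0))
    volume = math.pi * z_star / 3.0 * (r0**2 + r0 * r1 + r1**2)
    return VolumeEstimate(z_star_mm=z_star, volume_mm3=volume, surface_irradiance_mw_mm2=i0)
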