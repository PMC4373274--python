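"""Discrete-event model of asynchronous camera/stimulus frame pairing.

The camera computer and the stimulus/response computer run asynchronously.
The camera streams at the lower rate (30 Hz), so the compositor pairs each
camera frame C_i with the *most recently acquired* stimulus frame T_i — the
latest stimulus frame with a timestamp at or before the camera frame's.
The pairing lag therefore never reaches one stimulus/display refresh
period: with a 60 Hz stimulus source the worst case is just under
1000/60 = 16.7 ms.

A second, larger latency governs the closed visuomotor loop: a tablet
interaction occurring just after a camera exposure waits one full camera
frame period before it is captured, and per-frame processing must complete
within that same period, giving a worst-case interaction-to-display lag of
one camera period (33 ms at 30 Hz).  Both bounds sit below the ~50 ms it
takes proprioceptive or visual signals to reach primary sensory cortex, so
the feedback delay is treated as perceptually negligible.

Both quantities are computed here by brute-force phase-sweep simulation of
the two frame clocks, not by quoting the closed forms, so the model remains
honest for arbitrary rate combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import RealTimeConstraintError, ValidationError

__all__ = [
    "TimingModel",
    "PairingEvent",
    "pair_streams",
    "worst_case_pairing_lag",
    "worst_case_feedback_lag",
    "feedback_lag_negligible",
    "SENSORY_CONDUCTION_MS",
]

#: Approximate conduction time from peripheral receptors to primary sensory
#: cortex; the comparison point for "negligible" feedback latency.
SENSORY_CONDUCTION_MS = 50.0


@dataclass(frozen=True)
class TimingModel:
    """Clock rates and processing budget of the two video streams.

    Parameters
    ----------
    camera_rate_hz:
        Camera frame rate (default 30, NTSC camera).
    display_rate_hz:
        Refresh rate of the stimulus/VGA source paired against camera
        frames (default 60, the MRI projector).
    processing_budget_ms:
        Per-camera-frame segmentation+compositing time.  Must not exceed
        one camera frame period or the system is no longer real time.
    phase_offset_ms:
        Start time of the stimulus clock relative to the camera clock.
    """

    camera_rate_hz: float = 30.0
    display_rate_hz: float = 60.0
    processing_budget_ms: float = 0.0
    phase_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.camera_rate_hz <= 0 or self.display_rate_hz <= 0:
            raise ValidationError("frame rates must be > 0")
        if self.processing_budget_ms < 0:
            raise ValidationError("processing budget must be >= 0")

    @property
    def camera_period_ms(self) -> float:
        return 1000.0 / self.camera_rate_hz

    @property
    def display_period_ms(self) -> float:
        return 1000.0 / self.display_rate_hz


@dataclass(frozen=True)
class PairingEvent:
    """One camera frame and the stimulus frame composited with it."""

    camera_time_ms: float
    stimulus_time_ms: Optional[float]
    lag_ms: Optional[float]

    @property
    def paired(self) -> bool:
        return self.stimulus_time_ms is not None


def pair_streams(model: TimingModel, duration_ms: float) -> list[PairingEvent]:
    """Simulate frame pairing over ``[0, duration_ms)``.

    Camera frames tick at ``k / camera_rate``; stimulus frames at
    ``phase_offset + j / display_rate`` for j >= 0.  Each camera frame is
    paired with the latest stimulus frame at or before it (a simultaneous
    frame pairs with lag 0).  Camera frames preceding the first stimulus
    frame are returned unpaired (``stimulus_time_ms is None``).
    """
    if duration_ms <= 0:
        raise ValidationError("duration must be > 0")
    cam_t = np.arange(0.0, duration_ms, model.camera_period_ms)
    p = model.display_period_ms
    j = np.floor((cam_t - model.phase_offset_ms) / p)
    events: list[PairingEvent] = []
    for t, jj in zip(cam_t, j):
        if jj < 0:
            events.append(PairingEvent(float(t), None, None))
        else:
            ts = model.phase_offset_ms + jj * p
            events.append(PairingEvent(float(t), float(ts), float(t - ts)))
    return events


def worst_case_pairing_lag(
    model: TimingModel,
    duration_ms: float = 1000.0,
    n_phases: int = 4001,
) -> float:
    """Worst-case camera-to-stimulus pairing lag, in ms to one decimal.

    Sweeps ``n_phases`` stimulus phase offsets uniformly over one display
    period, simulates the pairing at each, and reports the supremum lag.
    The analytic supremum is one display period (approached, never
    attained); the sweep step is fine enough that rounding to 0.1 ms gives
    the analytic value.
    """
    if n_phases < 2:
        raise ValidationError("need at least 2 phases to sweep")
    p = model.display_period_ms
    cam_t = np.arange(0.0, duration_ms, model.camera_period_ms)
    phases = np.linspace(0.0, p, n_phases, endpoint=False)
    # lag[k, i] for phase k, camera frame i; unpaired frames excluded
    j = np.floor((cam_t[None, :] - phases[:, None]) / p)
    lag = cam_t[None, :] - (phases[:, None] + j * p)
    lag = np.where(j >= 0, lag, -np.inf)
    sup = float(lag.max())
    return round(sup, 1)


def worst_case_feedback_lag(model: TimingModel) -> int:
    """Worst-case tablet-interaction-to-display latency, nearest ms.

    An interaction just after a camera exposure waits one full camera
    period to be captured; processing must fit within that same period.

    Raises
    ------
    RealTimeConstraintError
        If the processing budget exceeds one camera frame period — the
        pipeline then no longer keeps up with the camera and the one-period
        bound does not hold.
    """
    period = model.camera_period_ms
    if model.processing_budget_ms > period + 1e-9:
        raise RealTimeConstraintError(
            f"processing budget {model.processing_budget_ms:.1f} ms exceeds the "
            f"camera frame period {period:.1f} ms: real-time constraint broken"
        )
    return int(round(period))


def feedback_lag_negligible(
    model: TimingModel, conduction_ms: float = SENSORY_CONDUCTION_MS
) -> bool:
    """Whether the worst-case feedback lag is below sensory conduction time."""
    return worst_case_feedback_lag(model) < conduction_ms
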