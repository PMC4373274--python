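"""Handwriting kinematics from stylus-tip force traces.

The stylus carries a force-sensing resistor at its tip, sampled every 25 ms
during task performance.  A zero ("null") reading means the stylus is off
the tablet surface, so contact structure is read directly off the trace:
a *contact episode* is a maximal run of consecutive samples with force
above a threshold (default 0, i.e. strictly positive readings).

Three per-trial performance parameters are derived:

* ``total_writing_time`` — first stylus contact to last lift-off, s;
* ``contact_time``       — total time the stylus touched the surface, s
  (number of above-threshold samples x sampling interval);
* ``mean_contact_force`` — mean force over above-threshold samples, in raw
  sensor units (the FSR readout is uncalibrated).

Participants lift the stylus once a paragraph is finished, so task
completion is indexed by the first sufficiently long terminal null-force
run (:func:`detect_trial_end`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import NoContactError, ValidationError

__all__ = [
    "CONDITIONS",
    "TASKS",
    "NOMINAL_DT_MS",
    "ForceTrace",
    "ContactEpisode",
    "KinematicsSummary",
    "detect_contact_episodes",
    "summarize_trial",
    "detect_trial_end",
    "force_histogram",
]

CONDITIONS = ("with_vfhp", "without_vfhp")
TASKS = ("grocery", "phone", "paragraph")
NOMINAL_DT_MS = 25.0


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled stylus force series for one trial.

    ``times_ms`` must be strictly increasing with spacing within
    ``spacing_tol_ms`` of the nominal 25 ms; forces are non-negative raw
    sensor units.
    """

    times_ms: np.ndarray
    force: np.ndarray
    participant: str = "p0"
    condition: str = "with_vfhp"
    task: str = "paragraph"
    trial: int = 1
    spacing_tol_ms: float = field(default=1.0, repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "force", f)
        if t.ndim != 1 or f.ndim != 1 or t.shape != f.shape or t.size == 0:
            raise ValidationError("times and force must be equal-length 1-D, non-empty")
        if t.size > 1:
            dt = np.diff(t)
            if (dt <= 0).any():
                raise ValidationError("times must be strictly increasing")
            if np.abs(dt - NOMINAL_DT_MS).max() > self.spacing_tol_ms:
                raise ValidationError(
                    f"sample spacing deviates from nominal {NOMINAL_DT_MS} ms "
                    f"by more than {self.spacing_tol_ms} ms"
                )
        if (f < 0).any():
            raise ValidationError("force readings must be non-negative")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be one of {TASKS}")

    @property
    def dt_ms(self) -> float:
        """Sampling interval; nominal if the trace has a single sample."""
        if self.times_ms.size < 2:
            return NOMINAL_DT_MS
        return float(np.median(np.diff(self.times_ms)))

    @property
    def duration_ms(self) -> float:
        return float(self.times_ms[-1] - self.times_ms[0] + self.dt_ms)

    def with_labels(self, **kwargs) -> "ForceTrace":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ContactEpisode:
    """Maximal run of above-threshold force samples."""

    start_ms: float
    end_ms: float
    mean_force: float
    n_samples: int

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class KinematicsSummary:
    """The three per-trial performance parameters (times in seconds)."""

    total_writing_time_s: float
    contact_time_s: float
    mean_contact_force: float
    n_episodes: int
    no_contact: bool

    def __post_init__(self) -> None:
        if not self.no_contact and not (
            0 <= self.contact_time_s <= self.total_writing_time_s + 1e-9
        ):
            raise ValidationError("contact time cannot exceed total writing time")


def detect_contact_episodes(
    trace: ForceTrace, threshold: float = 0.0
) -> list[ContactEpisode]:
    """Find maximal runs of samples with ``force > threshold``.

    Episode duration is run length x sampling interval: a run of n samples
    starting at time t spans ``[t, t + n*dt)``.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    above = trace.force > threshold
    if not above.any():
        return []
    dt = trace.dt_ms
    padded = np.diff(above.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive sample index
    episodes = []
    for i0, i1 in zip(starts, ends):
        episodes.append(
            ContactEpisode(
                start_ms=float(trace.times_ms[i0]),
                end_ms=float(trace.times_ms[i0] + (i1 - i0) * dt),
                mean_force=float(trace.force[i0:i1].mean()),
                n_samples=int(i1 - i0),
            )
        )
    return episodes


def summarize_trial(trace: ForceTrace, threshold: float = 0.0) -> KinematicsSummary:
    """Compute the three performance parameters for one trial.

    A trace with no above-threshold sample yields an explicit
    ``no_contact`` summary (all parameters zero) rather than silent zeros.
    """
    episodes = detect_contact_episodes(trace, threshold)
    if not episodes:
        return KinematicsSummary(0.0, 0.0, 0.0, 0, no_contact=True)
    above = trace.force > threshold
    contact_ms = sum(e.duration_ms for e in episodes)
    writing_ms = episodes[-1].end_ms - episodes[0].start_ms
    return KinematicsSummary(
        total_writing_time_s=writing_ms / 1000.0,
        contact_time_s=contact_ms / 1000.0,
        mean_contact_force=float(trace.force[above].mean()),
        n_episodes=len(episodes),
        no_contact=False,
    )


def detect_trial_end(
    trace: ForceTrace, lift_duration_ms: float = 1000.0, threshold: float = 0.0
) -> float:
    """Task-completion time: start of the terminal stylus lift.

    Returns the start time of the trailing null-force run if that run lasts
    at least ``lift_duration_ms`` (run length x dt); interior lifts shorter
    than the criterion are ignored.  Falls back to the last sample time when
    the trace does not end with a long enough lift.
    """
    if lift_duration_ms <= 0:
        raise ValidationError("lift duration must be > 0")
    above = trace.force > threshold
    if not above.any():
        raise NoContactError("trace has no contact at all; no trial to end")
    last_contact = int(np.flatnonzero(above)[-1])
    n_trailing = trace.force.size - last_contact - 1
    if n_trailing * trace.dt_ms >= lift_duration_ms:
        return float(trace.times_ms[last_contact + 1])
    return float(trace.times_ms[-1])


def force_histogram(
    trace: ForceTrace, bin_edges: Sequence[float]
) -> np.ndarray:
    """Histogram of *all* force samples (null readings included).

    Null-value frequency is the discriminating feature between feedback
    conditions, so zeros are counted, unlike the contact-only mean.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or (np.diff(edges) <= 0).any():
        raise ValidationError("bin edges must be 1-D and strictly increasing")
    counts, _ = np.histogram(trace.force, bins=edges)
    return counts
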