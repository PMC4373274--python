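"""File formats and run configuration.

Frames and masks travel as PNG (masks single-channel with values {0, 255});
force logs, trial summaries, lag tables and cohort tables as plain CSV;
run configuration as YAML.  Everything here is thin plumbing over the
analysis modules — readers validate, writers round-trip.

Force log schema (one row per sample)::

    time_ms, force, participant, condition, task, trial

Rows are grouped into one trace per (participant, condition, task, trial);
rows arriving out of time order within a trial are re-sorted by time (and
the re-sort is logged) rather than rejected.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError, ValidationError
from .kinematics import CONDITIONS, NOMINAL_DT_MS, TASKS, ForceTrace
from .segmentation import SkinRule, validate_frame
from .compositing import validate_mask

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_frame",
    "write_frame",
    "read_mask",
    "write_mask",
    "read_force_csv",
    "write_force_csv",
]

log = logging.getLogger("tablet_vfhp")

FORCE_COLUMNS = ["time_ms", "force", "participant", "condition", "task", "trial"]


@dataclass(frozen=True)
class RunConfig:
    """Validated defaults for every pipeline stage.

    Fields mirror the module parameters they feed: the skin rule
    thresholds, the kinematics contact threshold and lift criterion, the
    timing model rates, the statistics level and correction count, and the
    master seed.
    """

    r_min: int = 55
    g_min: int = 20
    b_min: int = 20
    chroma_min: int = 15
    rg_gap_min: int = 15
    contact_threshold: float = 0.0
    lift_duration_ms: float = 1000.0
    sampling_interval_ms: float = NOMINAL_DT_MS
    camera_rate_hz: float = 30.0
    display_rate_hz: float = 60.0
    processing_budget_ms: float = 0.0
    alpha: float = 0.05
    n_comparisons: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.skin_rule()  # range-checks the five thresholds
        if self.contact_threshold < 0:
            raise ConfigError("contact_threshold must be >= 0")
        if self.lift_duration_ms <= 0 or self.sampling_interval_ms <= 0:
            raise ConfigError("lift_duration_ms and sampling_interval_ms must be > 0")
        if self.camera_rate_hz <= 0 or self.display_rate_hz <= 0:
            raise ConfigError("frame rates must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_comparisons < 1:
            raise ConfigError("n_comparisons must be >= 1")

    def skin_rule(self) -> SkinRule:
        try:
            return SkinRule(
                r_min=self.r_min,
                g_min=self.g_min,
                b_min=self.b_min,
                chroma_min=self.chroma_min,
                rg_gap_min=self.rg_gap_min,
            )
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML run configuration; an empty file yields all defaults.

    Unknown keys raise :class:`ConfigError` naming the key; out-of-range
    values raise :class:`ConfigError` naming the field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except (TypeError, ValidationError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


def read_frame(path: Union[str, Path]) -> np.ndarray:
    """Read an image file as an H x W x 3 uint8 frame (alpha dropped)."""
    arr = iio.imread(path)
    if arr.ndim == 2:  # grayscale promoted to three identical channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return validate_frame(arr, str(path))


def write_frame(frame: np.ndarray, path: Union[str, Path]) -> None:
    iio.imwrite(path, validate_frame(frame))


def read_mask(path: Union[str, Path]) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel counts as 1."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return validate_mask((arr > 0).astype(np.uint8), str(path))


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write a {0, 1} mask as a single-channel PNG with values {0, 255}."""
    iio.imwrite(path, validate_mask(mask) * np.uint8(255))


def _trace_sort_key(trace: ForceTrace):
    return (trace.participant, trace.condition, trace.task, trace.trial)


def read_force_csv(path: Union[str, Path]) -> list[ForceTrace]:
    """Read a force log CSV into one :class:`ForceTrace` per trial.

    Rows are grouped by (participant, condition, task, trial); within each
    trial, out-of-order rows are re-sorted by time (logged).  Unknown
    condition/task labels and non-monotone-after-sort timestamps raise
    :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    missing = set(FORCE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"force CSV missing columns: {sorted(missing)}")
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unknown condition labels: {sorted(bad_cond)}")
    bad_task = set(df["task"].unique()) - set(TASKS)
    if bad_task:
        raise SchemaError(f"unknown task labels: {sorted(bad_task)}")
    traces = []
    for (participant, condition, task, trial), grp in df.groupby(
        ["participant", "condition", "task", "trial"], sort=True
    ):
        if not grp["time_ms"].is_monotonic_increasing:
            log.warning(
                "re-sorting %d out-of-order samples for trial %s/%s/%s/%s by time",
                len(grp), participant, condition, task, trial,
            )
            grp = grp.sort_values("time_ms")
        try:
            traces.append(
                ForceTrace(
                    times_ms=grp["time_ms"].to_numpy(dtype=float),
                    force=grp["force"].to_numpy(dtype=float),
                    participant=str(participant),
                    condition=str(condition),
                    task=str(task),
                    trial=int(trial),
                )
            )
        except ValidationError as exc:
            raise SchemaError(
                f"invalid trace for {participant}/{condition}/{task}/{trial}: {exc}"
            ) from exc
    return traces


def write_force_csv(traces: list[ForceTrace], path: Union[str, Path]) -> None:
    """Write traces to the canonical force log CSV (read round-trips)."""
    frames = []
    for tr in sorted(traces, key=_trace_sort_key):
        frames.append(
            pd.DataFrame(
                {
                    "time_ms": tr.times_ms,
                    "force": tr.force,
                    "participant": tr.participant,
                    "condition": tr.condition,
                    "task": tr.task,
                    "trial": tr.trial,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
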