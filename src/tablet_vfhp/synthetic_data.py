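"""Synthetic frames, force traces and cohorts with exact ground truth.

No camera, tablet or participant data ships with the package, so every
pipeline stage is exercised on generated inputs whose ground truth is known
by construction:

* :func:`render_scene` draws a hand (ellipse) holding a stylus (thick line
  segment) over a background palette.  Hand/stylus pixels are
  reject-sampled from a color box verified against the active skin rule,
  and background colors are (by default) verified to fail it, so the
  rendered geometry mask is the *exact* segmentation ground truth.  An
  adversarial palette inside the skin locus may be requested to
  demonstrate false positives.
* :func:`synthesize_trace` lays non-overlapping contact episodes onto a
  uniform 25 ms sample grid; above-zero force occurs exactly within
  episodes (optional additive noise is clipped at zero and default-off).
* :func:`synthesize_cohort` builds a balanced participant x condition x
  trial table of stylus contact times: grand mean + participant random
  effect + condition effect (added to the without-feedback condition) +
  trial (learning) effect + residual noise.  The default trial profile is
  mildly decreasing, emulating minor learning.

All generators are seed-deterministic: same spec + seed, identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinematics import CONDITIONS, NOMINAL_DT_MS, ForceTrace
from .segmentation import SkinRule

__all__ = [
    "HandScene",
    "SceneRender",
    "TraceSpec",
    "CohortSpec",
    "render_scene",
    "synthesize_trace",
    "synthesize_cohort",
    "DEFAULT_BACKGROUND_PALETTE",
]

# tablet surface / desk / stimulus-graphics colors; all fail the default rule
DEFAULT_BACKGROUND_PALETTE = (
    (40, 40, 40),     # dark gray tablet bezel
    (210, 210, 210),  # white screen region (zero chroma)
    (30, 60, 120),    # blue stimulus graphics (R not dominant)
    (0, 0, 0),        # black text
)

# skin/stylus color box: dominated red channel, warm chroma
DEFAULT_SKIN_LOW = (140, 60, 30)
DEFAULT_SKIN_HIGH = (210, 110, 80)


@dataclass(frozen=True)
class HandScene:
    """Geometry + colors of a synthetic hand-over-tablet camera frame."""

    height: int = 120
    width: int = 160
    # hand ellipse: center (row, col), semi-axes (row, col), rotation (rad)
    hand_center: tuple[float, float] = (70.0, 95.0)
    hand_axes: tuple[float, float] = (28.0, 18.0)
    hand_angle: float = 0.6
    # stylus segment: endpoints (row, col) and full width in px
    stylus_p0: tuple[float, float] = (60.0, 80.0)
    stylus_p1: tuple[float, float] = (25.0, 45.0)
    stylus_width: float = 5.0
    skin_low: tuple[int, int, int] = DEFAULT_SKIN_LOW
    skin_high: tuple[int, int, int] = DEFAULT_SKIN_HIGH
    background_palette: tuple[tuple[int, int, int], ...] = DEFAULT_BACKGROUND_PALETTE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("frame dimensions must be >= 1")
        for lo, hi in zip(self.skin_low, self.skin_high):
            if not (0 <= lo <= hi <= 255):
                raise ValidationError("skin color box must satisfy 0 <= low <= high <= 255")


@dataclass(frozen=True)
class SceneRender:
    """Rendered frame, exact ground-truth mask, and generation metadata."""

    frame: np.ndarray
    mask: np.ndarray
    clipped: bool       # geometry extended beyond the frame and was clipped
    separating: bool    # every background color fails the rule (exact recovery holds)


def _geometry_mask(scene: HandScene) -> tuple[np.ndarray, bool]:
    rr, cc = np.mgrid[0 : scene.height, 0 : scene.width].astype(float)
    cy, cx = scene.hand_center
    ay, ax = scene.hand_axes
    ct, st = np.cos(scene.hand_angle), np.sin(scene.hand_angle)
    u = (rr - cy) * ct + (cc - cx) * st
    v = -(rr - cy) * st + (cc - cx) * ct
    ellipse = (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
    p0 = np.asarray(scene.stylus_p0, dtype=float)
    p1 = np.asarray(scene.stylus_p1, dtype=float)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    pts = np.stack([rr - p0[0], cc - p0[1]], axis=-1)
    t = np.clip((pts @ seg) / seg_len2 if seg_len2 > 0 else 0.0, 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    dist = np.hypot(rr - closest[..., 0], cc - closest[..., 1])
    stylus = dist <= scene.stylus_width / 2.0
    mask = ellipse | stylus
    # clipped if the analytic geometry extends past the raster
    clipped = bool(
        cy - ay < 0
        or cy + ay > scene.height - 1
        or cx - ax < 0
        or cx + ax > scene.width - 1
        or min(p0[0], p1[0]) - scene.stylus_width / 2 < 0
        or max(p0[0], p1[0]) + scene.stylus_width / 2 > scene.height - 1
        or min(p0[1], p1[1]) - scene.stylus_width / 2 < 0
        or max(p0[1], p1[1]) + scene.stylus_width / 2 > scene.width - 1
    )
    return mask, clipped


def render_scene(scene: HandScene, rule: SkinRule = SkinRule()) -> SceneRender:
    """Render a scene and its exact ground-truth skin mask.

    Skin/stylus pixels are drawn uniformly from the scene's color box and
    reject-resampled until every one satisfies ``rule`` (the default box
    lies entirely inside the default rule, so resampling is rare).
    Background pixels take random palette colors.  ``separating`` in the
    result records whether every palette color fails the rule; only then is
    the mask guaranteed to be recovered exactly by segmentation.
    """
    rng = np.random.default_rng(scene.seed)
    mask, clipped = _geometry_mask(scene)
    n_skin = int(mask.sum())
    lo = np.asarray(scene.skin_low)
    hi = np.asarray(scene.skin_high)
    skin = rng.integers(lo, hi + 1, size=(n_skin, 3))
    for _ in range(64):
        bad = ~_rule_accepts(skin, rule)
        if not bad.any():
            break
        skin[bad] = rng.integers(lo, hi + 1, size=(int(bad.sum()), 3))
    else:
        raise ValidationError(
            "skin color box does not intersect the rule acceptance region"
        )
    palette = np.asarray(scene.background_palette, dtype=np.uint8)
    frame = palette[rng.integers(0, len(palette), size=mask.shape)]
    frame[mask] = skin.astype(np.uint8)
    separating = not _rule_accepts(palette.astype(int), rule).any()
    return SceneRender(
        frame=frame, mask=mask.astype(np.uint8), clipped=clipped, separating=separating
    )


def _rule_accepts(colors: np.ndarray, rule: SkinRule) -> np.ndarray:
    """Vector check of the skin rule on an (n, 3) integer color array."""
    r, g, b = colors[:, 0], colors[:, 1], colors[:, 2]
    mx, mn = colors.max(axis=1), colors.min(axis=1)
    return (
        (r > rule.r_min)
        & (g > rule.g_min)
        & (b > rule.b_min)
        & (mx - mn > rule.chroma_min)
        & (np.abs(r - g) > rule.rg_gap_min)
        & (r > g)
        & (r > b)
    )


@dataclass(frozen=True)
class TraceSpec:
    """Episode layout for a synthetic force trace.

    ``episodes`` are (start_ms, duration_ms, force) triples; they must be
    non-overlapping on the 25 ms sample grid and lie within the trial.
    """

    episodes: tuple[tuple[float, float, float], ...] = ((500.0, 1000.0, 10.0),)
    trial_duration_ms: float = 5000.0
    dt_ms: float = NOMINAL_DT_MS
    noise_amplitude: float = 0.0
    participant: str = "p0"
    condition: str = "with_vfhp"
    task: str = "paragraph"
    trial: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_duration_ms <= 0 or self.dt_ms <= 0:
            raise ValidationError("durations must be > 0")
        if self.noise_amplitude < 0:
            raise ValidationError("noise amplitude must be >= 0")
        eps = sorted(self.episodes)
        for start, dur, force in eps:
            if dur <= 0 or force <= 0 or start < 0:
                raise ValidationError("episodes need start >= 0, duration > 0, force > 0")
            if start + dur > self.trial_duration_ms:
                raise ValidationError("episode extends past trial duration")
        for (s0, d0, _), (s1, _, _) in zip(eps, eps[1:]):
            if s1 < s0 + d0:
                raise ValidationError("episodes overlap")


def synthesize_trace(spec: TraceSpec) -> ForceTrace:
    """Sample a force trace from an episode spec on a uniform grid.

    A sample at time t is in an episode iff ``start <= t < start + dur``;
    such samples read the episode's force level (plus optional noise,
    clipped below at zero), all others read exactly zero.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.trial_duration_ms, spec.dt_ms)
    f = np.zeros_like(t)
    for start, dur, force in spec.episodes:
        inside = (t >= start) & (t < start + dur)
        f[inside] = force
    if spec.noise_amplitude > 0:
        inside = f > 0
        f[inside] = np.clip(
            f[inside] + rng.normal(0.0, spec.noise_amplitude, size=int(inside.sum())),
            0.0,
            None,
        )
    return ForceTrace(
        times_ms=t,
        force=f,
        participant=spec.participant,
        condition=spec.condition,
        task=spec.task,
        trial=spec.trial,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a learning-design cohort (contact time, s).

    Defaults emulate the study conditions: nine participants, two feedback
    conditions, four trials, a 15 s condition effect added to the
    without-feedback condition, and a mildly decreasing trial (learning)
    profile.
    """

    n_participants: int = 9
    grand_mean_s: float = 60.0
    condition_effect_s: float = 15.0   # added to without_vfhp contact time
    trial_effects_s: tuple[float, ...] = (3.0, 1.5, 0.5, 0.0)
    sigma_participant_s: float = 10.0
    sigma_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("need at least 2 participants")
        if self.sigma_participant_s < 0 or self.sigma_s < 0:
            raise ValidationError("spreads must be >= 0")
        if len(self.trial_effects_s) < 2:
            raise ValidationError("need at least 2 trials")


def synthesize_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a balanced tidy cohort table of stylus contact times.

    Columns: ``participant``, ``condition``, ``trial`` (1-based),
    ``value`` (contact time, s).  Values are clipped below at zero (contact
    times are physical durations).
    """
    rng = np.random.default_rng(spec.seed)
    n_trials = len(spec.trial_effects_s)
    p_eff = rng.normal(0.0, spec.sigma_participant_s, size=spec.n_participants)
    rows = []
    for i in range(spec.n_participants):
        for condition in CONDITIONS:
            cond_eff = spec.condition_effect_s if condition == "without_vfhp" else 0.0
            for k in range(n_trials):
                value = (
                    spec.grand_mean_s
                    + p_eff[i]
                    + cond_eff
                    + spec.trial_effects_s[k]
                    + rng.normal(0.0, spec.sigma_s)
                )
                rows.append(
                    {
                        "participant": f"p{i:02d}",
                        "condition": condition,
                        "trial": k + 1,
                        "value": max(0.0, value),
                    }
                )
    return pd.DataFrame(rows)
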