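"""Behavioral statistics for the paired-condition and learning designs.

Two analysis paths are provided, matching how the two desktop experiments
were analyzed:

* **Paired-condition comparisons** (each participant measured once per
  feedback condition): a two-sided Wilcoxon signed-rank test with an exact
  null distribution for small samples (n <= 15 nonzero differences, the
  relevant regime for nine-participant cohorts) and a tie-corrected normal
  approximation beyond, plus Bonferroni correction across the three
  performance parameters.

* **Learning design** (condition x trial repeated measures): the classical
  balanced two-way repeated-measures ANOVA with participants as the random
  factor.  Each fixed effect is tested against its interaction with the
  participant factor (expected-mean-squares denominators):
  F_condition = MS_condition / MS_condition:participant, etc.  Unbalanced
  tables are refused — a general mixed model is out of scope.

Only significance categories were ever reported for the original cohorts
(p < 0.05, corrected), so the implementation is validated by enumeration
oracles and null/power simulation rather than against printed statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, UnbalancedDesignError, ValidationError

__all__ = [
    "PairedSample",
    "TestResult",
    "wilcoxon_signed_rank",
    "bonferroni",
    "mixed_anova",
    "condition_difference_summary",
    "simulate_null_type1",
]

EXACT_LIMIT = 15  # exact signed-rank null up to this many nonzero differences


@dataclass(frozen=True)
class PairedSample:
    """One participant's metric under both feedback conditions."""

    participant: str
    value_with: float
    value_without: float

    @property
    def difference(self) -> float:
        """with-VFHP minus without-VFHP."""
        return self.value_with - self.value_without


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    p_corrected: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")
        if self.p_corrected is not None and self.p_corrected < self.p_value - 1e-12:
            raise ValidationError("corrected p cannot be below raw p")


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank sum.

    ``ranks2`` are the tie-averaged ranks doubled to integers; ``w2`` the
    doubled positive-rank sum.  The null distribution of the doubled sum is
    built by dynamic-programming convolution (each rank enters the positive
    sum independently with probability 1/2), then the two-sided p is the
    null probability of a sum at least as far from the center as observed.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    center = total / 2.0
    dev = abs(w2 - center)
    support = np.arange(total + 1)
    tail = counts[np.abs(support - center) >= dev - 1e-9].sum()
    return min(1.0, float(tail / 2.0 ** len(ranks2)))


def wilcoxon_signed_rank(pairs: Sequence[PairedSample]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired condition values.

    Zero differences are discarded (classic convention); ties among the
    remaining absolute differences receive average ranks.  With n <= 15
    nonzero differences the p-value is exact (full enumeration of the 2^n
    sign assignments via convolution); beyond that a normal approximation
    with tie-corrected variance is used.  The reported statistic is W+, the
    positive-rank sum of (with minus without) differences.

    Raises
    ------
    DegenerateDataError
        If fewer than two nonzero differences remain.
    """
    d = np.asarray([p.difference for p in pairs], dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n < 2:
        raise DegenerateDataError(
            "need at least 2 nonzero paired differences for the signed-rank test"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        ranks2 = np.round(2.0 * ranks).astype(int)
        p = _signed_rank_exact_p(ranks2, 2.0 * w_plus)
        method = "wilcoxon-signed-rank-exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        if var <= 0:
            raise DegenerateDataError("zero variance in signed ranks")
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "wilcoxon-signed-rank-normal"
    return TestResult(statistic=w_plus, p_value=min(1.0, p), method=method, n=n)


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni correction: multiply each p by ``m``, cap at 1.

    ``m`` defaults to the number of p-values and must be at least that.
    """
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValidationError(f"m={m} smaller than number of p-values ({len(p)})")
    for pv in p:
        if not 0.0 <= pv <= 1.0:
            raise ValidationError(f"p-value {pv} outside [0, 1]")
    return [min(1.0, pv * m) for pv in p]


def _check_cohort(table: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "condition", "trial", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    return table


def _pivot_balanced(table: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    """Pivot a tidy cohort table to a (participant, condition, trial) cube."""
    table = _check_cohort(table)
    counts = table.groupby(["participant", "condition", "trial"]).size()
    participants = sorted(table["participant"].unique())
    conditions = sorted(table["condition"].unique())
    trials = sorted(table["trial"].unique())
    expected = len(participants) * len(conditions) * len(trials)
    if len(counts) != expected or (counts != 1).any():
        raise UnbalancedDesignError(
            "design is not a complete balanced participant x condition x trial "
            "grid with one observation per cell; fit a general mixed model "
            "instead (out of scope here)"
        )
    cube = (
        table.set_index(["participant", "condition", "trial"])["value"]
        .unstack(["condition", "trial"])
        .reindex(index=participants)
        .reindex(columns=pd.MultiIndex.from_product([conditions, trials]))
        .to_numpy()
        .reshape(len(participants), len(conditions), len(trials))
    )
    return cube, participants, conditions, trials


def _rm_anova_cube(x: np.ndarray) -> dict[str, tuple[float, int, float, int]]:
    """Sums of squares for a (..., s, a, b) repeated-measures cube.

    Supports an optional leading batch axis; returns, per effect,
    (SS, df, SS_error, df_error) with error terms given by the effect's
    interaction with the random participant factor.  Batched inputs return
    arrays in the SS slots.
    """
    *_, s, a, b = x.shape
    g = x.mean(axis=(-3, -2, -1), keepdims=True)
    m_s = x.mean(axis=(-2, -1), keepdims=True)
    m_a = x.mean(axis=(-3, -1), keepdims=True)
    m_b = x.mean(axis=(-3, -2), keepdims=True)
    m_sa = x.mean(axis=-1, keepdims=True)
    m_sb = x.mean(axis=-2, keepdims=True)
    m_ab = x.mean(axis=-3, keepdims=True)
    ss_a = s * b * ((m_a - g) ** 2).sum(axis=(-3, -2, -1))
    ss_b = s * a * ((m_b - g) ** 2).sum(axis=(-3, -2, -1))
    ss_ab = s * ((m_ab - m_a - m_b + g) ** 2).sum(axis=(-3, -2, -1))
    ss_as = b * ((m_sa - m_s - m_a + g) ** 2).sum(axis=(-3, -2, -1))
    ss_bs = a * ((m_sb - m_s - m_b + g) ** 2).sum(axis=(-3, -2, -1))
    resid = x - m_sa - m_sb - m_ab + m_s + m_a + m_b - g
    ss_abs = (resid**2).sum(axis=(-3, -2, -1))
    return {
        "condition": (ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        "trial": (ss_b, b - 1, ss_bs, (b - 1) * (s - 1)),
        "condition:trial": (ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (s - 1)),
    }


def mixed_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Balanced repeated-measures ANOVA with participants as random factor.

    Parameters
    ----------
    table:
        Tidy frame with columns ``participant``, ``condition``, ``trial``,
        ``value``; every participant x condition x trial cell present
        exactly once.

    Returns
    -------
    pandas.DataFrame
        One row per fixed effect (``condition``, ``trial``,
        ``condition:trial``) with sums of squares, degrees of freedom, the
        error term used, F and p.

    Raises
    ------
    UnbalancedDesignError
        For incomplete/unbalanced tables.
    DegenerateDataError
        If an error mean square is zero (e.g. all values identical).
    """
    cube, _, conditions, trials = _pivot_balanced(table)
    if len(conditions) < 2 or len(trials) < 2:
        raise ValidationError("need at least 2 conditions and 2 trials")
    rows = []
    for effect, (ss, df, ss_err, df_err) in _rm_anova_cube(cube).items():
        ms, ms_err = ss / df, ss_err / df_err
        if ms_err <= 0:
            raise DegenerateDataError(
                f"zero error mean square for effect '{effect}' "
                "(degenerate data, e.g. all values identical)"
            )
        f = ms / ms_err
        rows.append(
            {
                "effect": effect,
                "ss": float(ss),
                "df": df,
                "ms": float(ms),
                "error_term": f"{effect} x participant",
                "ss_error": float(ss_err),
                "df_error": df_err,
                "F": float(f),
                "p": float(sps.f.sf(f, df, df_err)),
            }
        )
    return pd.DataFrame(rows)


def condition_difference_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial distribution of condition differences in a cohort.

    For each trial, computes each participant's ``without_vfhp`` minus
    ``with_vfhp`` value and summarizes the distribution with box-plot
    statistics (median, quartiles, extremes).
    """
    cube, _, conditions, trials = _pivot_balanced(table)
    if sorted(conditions) != ["with_vfhp", "without_vfhp"]:
        raise ValidationError(
            f"conditions must be exactly {{'with_vfhp', 'without_vfhp'}}, got {conditions}"
        )
    i_with = conditions.index("with_vfhp")
    i_without = conditions.index("without_vfhp")
    diffs = cube[:, i_without, :] - cube[:, i_with, :]  # (participant, trial)
    rows = []
    for k, trial in enumerate(trials):
        d = diffs[:, k]
        rows.append(
            {
                "trial": trial,
                "n": d.size,
                "median": float(np.median(d)),
                "q1": float(np.quantile(d, 0.25)),
                "q3": float(np.quantile(d, 0.75)),
                "min": float(d.min()),
                "max": float(d.max()),
            }
        )
    return pd.DataFrame(rows)


def simulate_null_type1(
    n_participants: int = 9,
    n_trials: int = 4,
    n_reps: int = 10000,
    alpha: float = 0.05,
    sigma_participant: float = 10.0,
    sigma: float = 5.0,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the condition main effect under the null.

    Generates ``n_reps`` balanced cohorts with participant random effects
    but no condition or trial effects, runs the repeated-measures F test
    for the condition main effect on each (batched), and returns the
    rejection rate at level ``alpha``.  A correctly calibrated test gives a
    rate near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    s, a, b = n_participants, 2, n_trials
    x = rng.normal(0.0, sigma, size=(n_reps, s, a, b))
    x += rng.normal(0.0, sigma_participant, size=(n_reps, s, 1, 1))
    ss, df, ss_err, df_err = _rm_anova_cube(x)["condition"]
    f = (ss / df) / (ss_err / df_err)
    p = sps.f.sf(f, df, df_err)
    return float((p < alpha).mean())
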