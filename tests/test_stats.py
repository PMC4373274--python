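"""Behavioral statistics: Wilcoxon exact path, Bonferroni, balanced RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from helpers import enumerate_signed_rank_p
from tablet_vfhp.errors import (
    DegenerateDataError,
    UnbalancedDesignError,
    ValidationError,
)
from tablet_vfhp.stats import (
    PairedSample,
    bonferroni,
    condition_difference_summary,
    mixed_anova,
    simulate_null_type1,
    wilcoxon_signed_rank,
)
from tablet_vfhp.synthetic_data import CohortSpec, synthesize_cohort


def pairs_from_diffs(diffs):
    return [PairedSample(f"p{i}", float(d), 0.0) for i, d in enumerate(diffs)]


class TestWilcoxon:
    def test_one_sided_sweep_n6_gives_2_over_64(self):
        res = wilcoxon_signed_rank(pairs_from_diffs([1, 2, 3, 4, 5, 6]))
        assert res.p_value == pytest.approx(2 / 2**6)
        assert res.method == "wilcoxon-signed-rank-exact"
        assert res.n == 6

    def test_antisymmetric_differences_sit_at_the_null_center(self):
        res = wilcoxon_signed_rank(pairs_from_diffs([1.0, -1.0, 2.0, -2.0]))
        assert res.p_value == pytest.approx(1.0)

    def test_zeros_are_discarded(self):
        with_zeros = pairs_from_diffs([0.0, 0.0, 1, 2, 3, 4, 5, 6])
        res = wilcoxon_signed_rank(with_zeros)
        assert res.n == 6
        assert res.p_value == pytest.approx(2 / 2**6)

    def test_all_zero_differences_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(pairs_from_diffs([0.0, 0.0, 0.0]))

    def test_exact_p_equals_full_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(123)
        for n in range(2, 11):
            for _ in range(8):
                # small integer differences force ties and zero-free draws
                d = rng.integers(1, 5, size=n) * rng.choice([-1, 1], size=n)
                res = wilcoxon_signed_rank(pairs_from_diffs(d))
                assert res.p_value == pytest.approx(enumerate_signed_rank_p(d)), d

    def test_exact_p_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(5)
        for n in (6, 9, 12):
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(pairs_from_diffs(d))
            ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation_tracks_scipy(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.4, 1.0, size=40)
        res = wilcoxon_signed_rank(pairs_from_diffs(d))
        assert res.method == "wilcoxon-signed-rank-normal"
        ref = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestBonferroni:
    def test_definition_cap_and_identity(self):
        assert bonferroni([0.01], 3) == [pytest.approx(0.03)]
        assert bonferroni([0.5], 3) == [1.0]
        assert bonferroni([0.2], 1) == [pytest.approx(0.2)]

    def test_m_defaults_to_count_and_must_cover_it(self):
        assert bonferroni([0.01, 0.02]) == [pytest.approx(0.02), pytest.approx(0.04)]
        with pytest.raises(ValidationError):
            bonferroni([0.1, 0.2, 0.3], m=2)

    def test_monotone_and_order_preserving(self):
        p = [0.001, 0.01, 0.04, 0.2, 0.9]
        out = bonferroni(p, 5)
        assert out == sorted(out)
        assert all(a >= b for a, b in zip(out, p))


class TestMixedAnova:
    def test_agrees_with_pingouin_on_random_cohort(self):
        pingouin = pytest.importorskip("pingouin")
        df = synthesize_cohort(CohortSpec(seed=21))
        ours = mixed_anova(df).set_index("effect")
        ref = pingouin.rm_anova(
            data=df, dv="value", within=["condition", "trial"],
            subject="participant", detailed=True,
        ).set_index("Source")
        for effect, source in [
            ("condition", "condition"),
            ("trial", "trial"),
            ("condition:trial", "condition * trial"),
        ]:
            assert ours.loc[effect, "F"] == pytest.approx(ref.loc[source, "F"])
            assert ours.loc[effect, "p"] == pytest.approx(ref.loc[source, "p_unc"])

    def test_location_invariance(self):
        df = synthesize_cohort(CohortSpec(seed=9))
        shifted = df.assign(value=df["value"] + 1000.0)
        a = mixed_anova(df)
        b = mixed_anova(shifted)
        np.testing.assert_allclose(a["F"], b["F"])

    def test_unbalanced_table_refused(self):
        df = synthesize_cohort(CohortSpec(seed=2)).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            mixed_anova(df)

    def test_all_identical_values_are_degenerate(self):
        df = synthesize_cohort(
            CohortSpec(condition_effect_s=0.0, trial_effects_s=(0.0, 0.0, 0.0, 0.0),
                       sigma_participant_s=0.0, sigma_s=0.0)
        )
        with pytest.raises(DegenerateDataError):
            mixed_anova(df)

    def test_injected_condition_effect_detected_with_correct_sign(self):
        df = synthesize_cohort(CohortSpec(condition_effect_s=15.0, seed=13))
        table = mixed_anova(df).set_index("effect")
        assert table.loc["condition", "p"] < 0.05
        means = df.groupby("condition")["value"].mean()
        assert means["without_vfhp"] > means["with_vfhp"]

    def test_null_type1_rate_is_near_alpha_small_run(self):
        rate = simulate_null_type1(n_reps=1500, seed=17)
        assert 0.03 < rate < 0.07


class TestConditionDifferences:
    def test_identical_conditions_give_zero_differences(self):
        df = synthesize_cohort(CohortSpec(condition_effect_s=0.0, sigma_s=0.0, seed=4))
        out = condition_difference_summary(df)
        np.testing.assert_allclose(out["median"], 0.0, atol=1e-12)

    def test_constant_shift_appears_as_per_trial_median(self):
        df = synthesize_cohort(CohortSpec(condition_effect_s=15.0, sigma_s=0.0, seed=4))
        out = condition_difference_summary(df)
        np.testing.assert_allclose(out["median"], 15.0)
        np.testing.assert_allclose(out["q1"], 15.0)

    def test_medians_match_sort_based_oracle(self):
        df = synthesize_cohort(CohortSpec(seed=31))
        out = condition_difference_summary(df).set_index("trial")
        piv = df.pivot_table(index=["participant", "trial"], columns="condition",
                             values="value")
        for trial in out.index:
            d = (piv.xs(trial, level="trial")["without_vfhp"]
                 - piv.xs(trial, level="trial")["with_vfhp"]).to_numpy()
            d = np.sort(d)
            n = d.size
            median = d[n // 2] if n % 2 else (d[n // 2 - 1] + d[n // 2]) / 2
            assert out.loc[trial, "median"] == pytest.approx(median)

    def test_missing_cell_is_an_error(self):
        df = synthesize_cohort(CohortSpec(seed=1)).iloc[1:]
        with pytest.raises(UnbalancedDesignError):
            condition_difference_summary(df)
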