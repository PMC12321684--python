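import math

import numpy as np
import pytest

from rivalscore.scoring import score_session
from rivalscore.cohort_simulator import simulate_validation_cohort
from rivalscore.stats import (
    EffectSize,
    compare_dependent_correlations,
    dl_meta,
    group_compare,
    median_split_analysis,
    one_sample_t,
    pearson,
    variance_ratio,
)


class TestPearson:
    def test_identity_and_reflection(self):
        x = [1.0, 2.0, 4.0, 8.0]
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_independent_computation(self):
        x = [0.3, 1.7, 2.2, 3.9, 5.1, 0.4]
        y = [1.1, 0.2, 3.3, 2.8, 4.0, 0.9]
        r, n = pearson(x, y)
        xa, ya = np.asarray(x), np.asarray(y)
        expected = float(
            ((xa - xa.mean()) * (ya - ya.mean())).sum()
            / math.sqrt(((xa - xa.mean()) ** 2).sum() * ((ya - ya.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected, abs=1e-12)
        assert n == 6

    def test_pairwise_deletion_of_undefined(self):
        r, n = pearson([1.0, None, 2.0, 3.0, np.nan, 4.0], [1.0, 9.9, 2.0, 3.0, 1.0, 4.0])
        assert n == 4 and r == pytest.approx(1.0)

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError):
            pearson([1.0, None, 2.0], [1.0, 2.0, None])

    def test_zero_variance_undefined(self):
        assert pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == (None, 3)


class TestDependentCorrelationComparison:
    def test_equal_correlations_give_null(self):
        c = compare_dependent_correlations(0.4, 0.4, 0.3, n=50)
        assert c.z == 0.0 and c.p == pytest.approx(0.5)

    def test_fixture_matches_reference_formula(self):
        """Pinned against an independently coded Fisher-z / pooled-covariance
        implementation of the published test statistic."""
        c = compare_dependent_correlations(0.5, 0.3, 0.6, n=100)
        assert c.z == pytest.approx(2.467398410533247, abs=1e-10)

        def reference(r1, r2, r12, n):
            z1, z2 = np.arctanh(r1), np.arctanh(r2)
            rm2 = ((r1 + r2) / 2.0) ** 2
            cov = (r12 * (1 - 2 * rm2) - 0.5 * rm2 * (1 - 2 * rm2 - r12**2)) / (
                (1 - rm2) ** 2
            )
            return (z1 - z2) * math.sqrt((n - 3) / (2 - 2 * cov))

        assert c.z == pytest.approx(reference(0.5, 0.3, 0.6, 100), abs=1e-10)

    def test_antisymmetric_in_the_two_correlations(self):
        a = compare_dependent_correlations(0.5, 0.2, 0.4, 80)
        b = compare_dependent_correlations(0.2, 0.5, 0.4, 80)
        assert a.z == pytest.approx(-b.z, abs=1e-12)

    def test_two_tailed_doubles_one_tailed(self):
        one = compare_dependent_correlations(0.5, 0.3, 0.6, 100, tails="one")
        two = compare_dependent_correlations(0.5, 0.3, 0.6, 100, tails="two")
        assert two.p == pytest.approx(2 * one.p)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            compare_dependent_correlations(0.9, -0.9, 0.9, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(0.5, 0.3, 0.4, 9)


class TestVarianceRatio:
    def test_identity_and_doubling(self):
        assert variance_ratio(0.05, 0.05) == 1.0
        assert variance_ratio(0.04, 0.08) == pytest.approx(2.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio(0.0, 0.1)


class TestDLMeta:
    def test_homogeneous_studies(self):
        res = dl_meta([EffectSize(f"s{i}", 0.3, 50) for i in range(5)])
        assert res.pooled_r == pytest.approx(0.3)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.I2 == 0.0 and res.tau2 == 0.0

    def test_two_study_fixture_matches_reference(self):
        """Frozen from metafor::rma(method='DL') on the same Fisher-z inputs,
        and identical to the hand-computed moment estimator."""
        res = dl_meta([EffectSize("a", 0.2, 50), EffectSize("b", 0.4, 100)])
        assert res.pooled_r == pytest.approx(0.325702393338871, abs=1e-12)
        assert res.Q == pytest.approx(1.545122515828682, abs=1e-12)
        assert res.tau2 == pytest.approx(0.008609085575711, abs=1e-12)
        assert res.I2 == pytest.approx(35.2802130734, abs=1e-8)
        assert res.ci_low == pytest.approx(0.126376944331723, abs=1e-12)
        assert res.ci_high == pytest.approx(0.499747758981077, abs=1e-12)

    def test_pooled_r_invariant_to_study_order(self):
        studies = [EffectSize("a", 0.1, 40), EffectSize("b", 0.5, 90), EffectSize("c", 0.3, 60)]
        assert dl_meta(studies).pooled_r == pytest.approx(
            dl_meta(list(reversed(studies))).pooled_r, abs=1e-14
        )

    def test_ci_brackets_pooled_and_i2_clamped(self):
        res = dl_meta([EffectSize("a", 0.1, 40), EffectSize("b", 0.15, 500)])
        assert res.ci_low <= res.pooled_r <= res.ci_high
        assert 0.0 <= res.I2 <= 100.0 and res.tau2 >= 0.0

    def test_influence_exclusion_removes_outlier(self):
        studies = [EffectSize(f"s{i}", 0.2, 100) for i in range(6)]
        studies.append(EffectSize("outlier", 0.9, 100))
        res = dl_meta(studies, residual_threshold=2.0)
        assert res.excluded == ("outlier",)
        assert res.k == 6
        assert res.pooled_r == pytest.approx(0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dl_meta([EffectSize("a", 0.2, 50)])
        with pytest.raises(ValueError):
            EffectSize("a", 0.2, 3)
        with pytest.raises(ValueError):
            EffectSize("a", 1.0, 50)


class TestGroupCompare:
    def test_identical_groups_null(self):
        t, df, p, g = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and g == 0.0

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        a = [1.2, 2.3, 0.8, 1.9, 2.5, 1.1, 0.4]
        b = [2.0, 2.8, 3.1, 1.7, 2.2, 2.9, 3.3, 2.4]
        t, df, p, g = group_compare(a, b)
        ref = pg.ttest(np.array(a), np.array(b), correction=True)
        col = "p_val" if "p_val" in ref.columns else "p-val"
        assert t == pytest.approx(float(ref["T"].iloc[0]), abs=1e-10)
        assert df == pytest.approx(float(ref["dof"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref[col].iloc[0]), abs=1e-10)
        assert g == pytest.approx(
            float(pg.compute_effsize(np.array(a), np.array(b), eftype="hedges")),
            abs=1e-10,
        )

    def test_shift_flips_sign_only_when_order_reverses(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 3.0, 4.0, 5.0]
        t1, *_ = group_compare(a, b)
        t2, *_ = group_compare([v + 10 for v in a], b)
        assert t1 < 0 < t2

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 1.0], [1.0, 1.0])


class TestOneSampleT:
    def test_centered_sample_near_zero_t(self):
        t, df, p = one_sample_t([-0.1, 0.1, -0.2, 0.2])
        assert t == pytest.approx(0.0) and df == 3


class TestMedianSplit:
    @staticmethod
    def _cohort(seed=22):
        sessions, truth = simulate_validation_cohort(100, mixed_base=(0.05, 0.7), seed=seed)
        bundles = [score_session(s) for s in sessions]
        rng = np.random.default_rng(seed)
        vviq = [
            int(round(16 + 64 * float(np.clip(v + rng.normal(0, 0.05), 0, 1))))
            for v in truth["v"]
        ]
        return bundles, vviq

    def test_subset_sizes_sum_to_cohort(self):
        bundles, vviq = self._cohort()
        n_complete = sum(1 for b in bundles if b.original is not None)
        res = median_split_analysis(bundles, vviq)
        assert res.low.n + res.high.n == n_complete
        assert res.low.n > 0 and res.high.n > 0

    def test_low_nonmixed_subset_shows_larger_improvement_gap(self):
        """Where few non-mixed trials were recorded, the improved score gains
        more over the original score (majority of seeded replicates)."""
        wins = 0
        n_reps = 40
        for rep in range(n_reps):
            bundles, vviq = self._cohort(seed=4000 + rep)
            res = median_split_analysis(bundles, vviq)
            gap_low = res.low.r_improved - res.low.r_original
            gap_high = res.high.r_improved - res.high.r_original
            wins += gap_low > gap_high
        assert wins >= 0.8 * n_reps

    def test_constant_split_field_rejected(self):
        import dataclasses

        bundles, vviq = self._cohort()
        constant = [dataclasses.replace(b, n_nonmixed=20) for b in bundles]
        with pytest.raises(ValueError, match="degenerate"):
            median_split_analysis(constant, vviq)
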