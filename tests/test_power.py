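"""Noncentral chi-square power, sample-size solving, Bonferroni, one-sided Z."""

import numpy as np
import pytest
from scipy import stats

from mlmm_power import (
    PopulationParams,
    PowerRequest,
    TrialDesign,
    WeightVector,
    bonferroni_sample_size,
    chi2_power,
    composite_gamma_variance_unit,
    equal_weights,
    gamma_covariance_unit,
    noncentrality_per_participant,
    one_sided_z_power,
    optimal_weights_jc,
    power_at_n,
    required_noncentrality,
    required_noncentrality_one_sided,
    sample_size,
    unit_weight,
)

# closed-form oracle (z_{0.975} + z_{0.80})^2 for the df=1 two-sided test
LAMBDA_REQ_1 = (stats.norm.ppf(0.975) + stats.norm.ppf(0.80)) ** 2


class TestChi2Power:
    def test_null_power_equals_alpha(self):
        assert chi2_power(1, 0.0, 0.05) == pytest.approx(0.05)
        assert chi2_power(3, 0.0, 0.01) == pytest.approx(0.01)

    def test_df1_closed_form_identity(self):
        assert chi2_power(1, LAMBDA_REQ_1, 0.05) == pytest.approx(0.80, abs=1e-3)

    @pytest.mark.parametrize("df", [1, 2, 3, 5])
    def test_strictly_increasing_in_noncentrality(self, df):
        grid = [0.5, 1, 2, 5, 10, 20]
        powers = [chi2_power(df, lam, 0.05) for lam in grid]
        assert np.all(np.diff(powers) > 0)


class TestRequiredNoncentrality:
    def test_df1_matches_normal_quantile_identity(self):
        # the quantile identity ignores the far rejection tail (~1e-6 mass),
        # so agreement is to ~1e-5 in lambda, not machine precision
        assert required_noncentrality(1, 0.05, 0.80) == pytest.approx(
            LAMBDA_REQ_1, abs=1e-4
        )

    def test_df3_value(self):
        # literature value of the df=3 requirement at alpha=5%, power 80%
        assert required_noncentrality(3, 0.05, 0.80) == pytest.approx(10.903, abs=1e-2)

    @pytest.mark.parametrize("df,alpha,power", [(1, 0.05, 0.8), (3, 0.01, 0.9), (4, 0.1, 0.5)])
    def test_round_trip(self, df, alpha, power):
        lam = required_noncentrality(df, alpha, power)
        assert chi2_power(df, lam, alpha) == pytest.approx(power, abs=1e-9)

    def test_target_below_alpha_rejected(self):
        with pytest.raises(ValueError):
            required_noncentrality(1, 0.05, 0.04)


class TestNoncentrality:
    def test_weights_scale_invariance(self, mci_params, mci_effect, design2y):
        gc = gamma_covariance_unit(mci_params, design2y)
        g = mci_effect.gamma_for(mci_params)
        v = np.array([0.9, -0.1, 0.4])
        lam_a = noncentrality_per_participant(
            PowerRequest("JC", weights=WeightVector(v)), g, gc
        )
        lam_b = noncentrality_per_participant(
            PowerRequest("JC", weights=WeightVector(2 * v)), g, gc
        )
        assert lam_a == pytest.approx(lam_b, rel=1e-12)

    def test_optimal_jc_attains_joint_noncentrality(self, mci_params, mci_effect, design2y):
        """The Rayleigh quotient at w_JC* equals the full quadratic form."""
        gc = gamma_covariance_unit(mci_params, design2y)
        g = mci_effect.gamma_for(mci_params)
        lam_j = noncentrality_per_participant(PowerRequest("J"), g, gc)
        w = optimal_weights_jc(g, gc.sigma_gamma1)
        lam_jc = noncentrality_per_participant(PowerRequest("JC", weights=w), g, gc)
        assert lam_jc == pytest.approx(lam_j, rel=1e-12)

    def test_j1_all_statistics_agree(self, uni_params):
        d = TrialDesign(duration_years=3)
        gc = gamma_covariance_unit(uni_params, d)
        g = np.array([-0.02])
        w = WeightVector([1.0])
        comp = composite_gamma_variance_unit(w, uni_params, d)
        lams = [
            noncentrality_per_participant(PowerRequest("J"), g, gc),
            noncentrality_per_participant(PowerRequest("JC", weights=w), g, gc),
            noncentrality_per_participant(PowerRequest("C", weights=w), g, gc, comp),
        ]
        assert lams[0] == pytest.approx(lams[1], rel=1e-12)
        assert lams[0] == pytest.approx(lams[2], rel=1e-12)

    def test_orthogonal_weights_warn_and_zero(self, mci_params, design2y):
        gc = gamma_covariance_unit(mci_params, design2y)
        g = np.array([1.0, 0.0, 0.0])
        w = WeightVector([0.0, 1.0, 0.0])
        with pytest.warns(UserWarning, match="orthogonal"):
            lam = noncentrality_per_participant(PowerRequest("JC", weights=w), g, gc)
        assert lam == 0.0


class TestSampleSize:
    def test_ceiling_convention(self, mci_params, mci_effect, design2y):
        res = sample_size(PowerRequest("J"), mci_params, mci_effect, design2y)
        assert res.n_required == int(np.ceil(res.lambda_req / res.lambda1))
        # power is met at N and not at N-1 (up to the ceiling convention)
        p_at = power_at_n(
            PowerRequest("J"), mci_params, mci_effect, design2y, res.n_required
        )
        p_below = power_at_n(
            PowerRequest("J"), mci_params, mci_effect, design2y, res.n_required - 1
        )
        assert p_at >= design2y.target_power
        assert p_below < design2y.target_power

    def test_monotone_in_duration_effect_and_alpha(self, mci_params, mci_effect):
        from dataclasses import replace
        from mlmm_power import EffectSpec

        req = PowerRequest("J")
        base = TrialDesign(duration_years=2)
        n_by_duration = [
            sample_size(req, mci_params, mci_effect, base.with_duration(d)).n_required
            for d in (2, 3, 4, 5, 6)
        ]
        assert np.all(np.diff(n_by_duration) < 0)
        bigger_effect = EffectSpec(reduction_fraction=0.5)
        assert (
            sample_size(req, mci_params, bigger_effect, base).n_required
            < n_by_duration[0]
        )
        stricter = PowerRequest("J", alpha=0.01)
        assert (
            sample_size(stricter, mci_params, mci_effect, base).n_required
            > n_by_duration[0]
        )

    def test_undetectable_effect_raises(self, mci_params, design2y):
        from mlmm_power import EffectSpec

        effect = EffectSpec(mode="explicit", gamma_star=[0.0, 0.0, 0.01])
        w = WeightVector([1.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="undetectable"):
                sample_size(
                    PowerRequest("JC", weights=w), mci_params, effect, design2y
                )


class TestBonferroni:
    def test_maximum_of_component_sizes(self, mci_params, mci_effect, design2y):
        res = bonferroni_sample_size(mci_params, mci_effect, design2y)
        per = [r.n_required for r in res.per_component]
        assert res.n_required == max(per)
        assert len(per) == 3

    def test_j1_reduces_to_plain_composite_test(self, uni_params):
        from mlmm_power import EffectSpec

        d = TrialDesign(duration_years=3)
        effect = EffectSpec()
        res = bonferroni_sample_size(uni_params, effect, d)
        direct = sample_size(
            PowerRequest("C", weights=WeightVector([1.0])), uni_params, effect, d
        )
        assert res.n_required == direct.n_required

    def test_corrected_level_needs_more_subjects(self, mci_params, mci_effect, design2y):
        res = bonferroni_sample_size(mci_params, mci_effect, design2y)
        for comp, r in enumerate(res.per_component):
            w = unit_weight(3, comp)
            at_full_alpha = sample_size(
                PowerRequest("C", weights=w), mci_params, mci_effect, design2y
            )
            assert r.n_required > at_full_alpha.n_required


class TestOneSided:
    def test_one_sided_requirement_below_two_sided(self):
        assert required_noncentrality_one_sided(0.05, 0.80) < LAMBDA_REQ_1
        expected = (stats.norm.ppf(0.95) + stats.norm.ppf(0.80)) ** 2
        assert required_noncentrality_one_sided(0.05, 0.80) == pytest.approx(expected)

    def test_degenerate_half_half_requirement_is_zero(self):
        assert required_noncentrality_one_sided(0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_n_at_most_two_sided(self, mci_params, mci_effect, design2y):
        w = equal_weights(3)
        two = sample_size(
            PowerRequest("JC", weights=w), mci_params, mci_effect, design2y
        )
        one = sample_size(
            PowerRequest("JC", weights=w, sidedness="one_sided_z"),
            mci_params,
            mci_effect,
            design2y,
        )
        assert one.n_required <= two.n_required

    def test_sign_flip_leaves_power_magnitude(self, mci_params, design2y):
        from mlmm_power import EffectSpec

        w = equal_weights(3)
        req = PowerRequest("JC", weights=w, sidedness="one_sided_z")
        up = EffectSpec(mode="explicit", gamma_star=[0.02, 0.015, 0.014])
        down = EffectSpec(mode="explicit", gamma_star=[-0.02, -0.015, -0.014])
        p_up = power_at_n(req, mci_params, up, design2y, 5000)
        p_down = power_at_n(req, mci_params, down, design2y, 5000)
        assert p_up == pytest.approx(p_down, rel=1e-12)

    def test_joint_statistic_unsupported(self):
        with pytest.raises(ValueError, match="one-sided"):
            PowerRequest("J", sidedness="one_sided_z")


class TestPowerDominance:
    def test_df1_dominates_df3_at_equal_noncentrality(self):
        """Xi_JC at its optimum carries the joint noncentrality on one df,
        so its power curve lies above the joint test's everywhere."""
        for lam in np.linspace(0.0, 30.0, 61):
            assert chi2_power(1, lam, 0.05) >= chi2_power(3, lam, 0.05) - 1e-12

    def test_jc_dominates_c_for_random_weights(self, mci_params, mci_effect):
        rng = np.random.default_rng(5)
        base = TrialDesign(duration_years=2)
        g = mci_effect.gamma_for(mci_params)
        for dur in (2, 4, 6):
            d = base.with_duration(dur)
            gc = gamma_covariance_unit(mci_params, d)
            for _ in range(20):
                w = WeightVector(rng.standard_normal(3))
                lam_jc = noncentrality_per_participant(
                    PowerRequest("JC", weights=w), g, gc
                )
                comp = composite_gamma_variance_unit(w, mci_params, d)
                lam_c = noncentrality_per_participant(
                    PowerRequest("C", weights=w), g, gc, comp
                )
                assert lam_jc >= lam_c - 1e-12
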