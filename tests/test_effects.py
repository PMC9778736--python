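"""Random-effects and spike-recovery estimators."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from mpuncert import (
    DuplicateSet,
    SpikeSet,
    estimate_random_effects,
    estimate_systematic_effects,
    systematic_lambda_spec,
)


class TestRandomEffects:
    def test_halves_difference_variance(self):
        """Differences 0..4 over 5 pairs have sample variance 2.50, so Var(lambda_r) = 1.25."""
        pairs = [(3, 3), (4, 3), (5, 3), (6, 3), (7, 3)]
        re = estimate_random_effects(DuplicateSet(pairs, "PP"))
        assert re.var_lambda_r == pytest.approx(1.25, rel=1e-12)

    def test_identical_pairs_give_zero(self):
        re = estimate_random_effects(DuplicateSet([(4, 4), (7, 7), (0, 0)]))
        assert re.var_lambda_r == 0.0

    def test_hand_computed_three_pairs(self):
        """d = (-2, 0, 3): mean-subtracted variance 19/3, halved to 19/6."""
        re = estimate_random_effects(DuplicateSet([(0, 2), (1, 1), (3, 0)]))
        assert re.var_lambda_r == pytest.approx(19 / 6, rel=1e-12)

    def test_zero_center_variant(self):
        """Classical duplicate formula sum(d^2)/(2k) for the same three pairs."""
        re = estimate_random_effects(DuplicateSet([(0, 2), (1, 1), (3, 0)]), center="zero")
        assert re.var_lambda_r == pytest.approx((4 + 0 + 9) / 6, rel=1e-12)

    def test_zero_center_swap_invariant(self):
        pairs = [(0, 2), (1, 1), (3, 0)]
        swapped = [(b, a) for a, b in pairs]
        a = estimate_random_effects(DuplicateSet(pairs), center="zero")
        b = estimate_random_effects(DuplicateSet(swapped), center="zero")
        assert a.var_lambda_r == b.var_lambda_r

    @pytest.mark.parametrize("kappa", [2, 3, 10])
    def test_scale_equivariance(self, kappa):
        """Multiplying all counts by kappa scales the variance by kappa^2."""
        pairs = [(0, 2), (1, 1), (3, 0), (5, 2)]
        base = estimate_random_effects(DuplicateSet(pairs)).var_lambda_r
        scaled_pairs = [(kappa * a, kappa * b) for a, b in pairs]
        scaled = estimate_random_effects(DuplicateSet(scaled_pairs)).var_lambda_r
        assert scaled == pytest.approx(kappa**2 * base, rel=1e-12)

    @hyp_settings(derandomize=True, max_examples=50)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=2, max_size=20
        ),
        kappa=st.integers(1, 9),
    )
    def test_scale_equivariance_property(self, pairs, kappa):
        base = estimate_random_effects(DuplicateSet(pairs)).var_lambda_r
        scaled = estimate_random_effects(
            DuplicateSet([(kappa * a, kappa * b) for a, b in pairs])
        ).var_lambda_r
        assert scaled == pytest.approx(kappa**2 * base, rel=1e-9, abs=1e-12)

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nsufficient|at least 2"):
            estimate_random_effects(DuplicateSet([(1, 2)]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DuplicateSet([(1, -2), (0, 0)])

    def test_poisson_parameter_recovery(self):
        """For pure Poisson duplicates Var(d) = 2 lambda, so the estimator recovers lambda."""
        rng = np.random.default_rng(2024)
        lam = 4.0
        pairs = list(zip(rng.poisson(lam, 500), rng.poisson(lam, 500)))
        re = estimate_random_effects(DuplicateSet(pairs))
        assert re.var_lambda_r == pytest.approx(lam, rel=0.15)


class TestSystematicEffects:
    def test_printed_recovery_regime(self):
        """29 fours and 21 threes of 5 added: n_mean = 3.58 exactly, F = (5-3.58)/3.58."""
        recovered = [4] * 29 + [3] * 21
        se = estimate_systematic_effects(SpikeSet(recovered, 5, "PP"))
        assert se.mean_recovered == pytest.approx(3.58, rel=1e-12)
        assert se.correction_factor == pytest.approx((5 - 3.58) / 3.58, rel=1e-12)
        assert se.correction_factor == pytest.approx(0.39665, abs=5e-6)

    def test_full_recovery_needs_no_correction(self):
        se = estimate_systematic_effects(SpikeSet([5, 5, 5, 5], 5))
        assert se.correction_factor == 0.0
        assert se.var_recovered == 0.0

    def test_hand_computed_two_units(self):
        se = estimate_systematic_effects(SpikeSet([2, 3], 5))
        assert se.mean_recovered == 2.5
        assert se.var_recovered == pytest.approx(0.5)
        assert se.var_mean_recovered == pytest.approx(0.25)
        assert se.correction_factor == pytest.approx(1.0)

    def test_over_recovery_rejected(self):
        with pytest.raises(ValueError, match="invalid spike"):
            SpikeSet([6, 4], 5)

    def test_no_recovery_rejected(self):
        with pytest.raises(ValueError, match="[Nn]o particles recovered|undefined"):
            estimate_systematic_effects(SpikeSet([0, 0, 0], 5))

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            SpikeSet([4], 5)

    def test_binomial_parameter_recovery(self):
        """Binomial(5, 0.8) spikes: F estimates (1-R)/R = 0.25."""
        rng = np.random.default_rng(7)
        recovered = rng.binomial(5, 0.8, 500)
        se = estimate_systematic_effects(SpikeSet(recovered, 5))
        assert se.correction_factor == pytest.approx(0.25, rel=0.05)


class TestSystematicLambdaSpec:
    def _effects(self, n_bar, var_n, m, a=5):
        from mpuncert import SystematicEffects

        return SystematicEffects(
            mean_recovered=n_bar,
            var_recovered=var_n,
            var_mean_recovered=var_n / m,
            correction_factor=(a - n_bar) / n_bar,
            added_per_unit=a,
        )

    def test_zero_count_degenerates(self):
        spec = systematic_lambda_spec(0, self._effects(3.58, 0.143, 12))
        assert spec.expected_value == 0.0
        assert spec.variance == 0.0

    def test_delta_method_hand_computation(self):
        """C=10, A=5, n_mean=3.58, Var(n)=0.143, M=12: E = 3.9665, Var = 0.18137."""
        spec = systematic_lambda_spec(10, self._effects(3.58, 0.143, 12))
        assert spec.expected_value == pytest.approx(10 * (5 - 3.58) / 3.58, rel=1e-12)
        assert spec.expected_value == pytest.approx(3.9665, abs=5e-5)
        var_nbar = 0.143 / 12
        assert spec.variance == pytest.approx((10 * 5 / 3.58**2) ** 2 * var_nbar, rel=1e-12)
        assert spec.variance == pytest.approx(0.18137, abs=5e-5)

    def test_homogeneity_in_count(self):
        eff = self._effects(3.97, 0.0372, 36)
        one = systematic_lambda_spec(7, eff)
        two = systematic_lambda_spec(14, eff)
        assert two.expected_value == pytest.approx(2 * one.expected_value, rel=1e-12)
        assert two.variance == pytest.approx(4 * one.variance, rel=1e-12)

    @pytest.mark.parametrize(
        "c, n_bar, var_n, m",
        [(5, 3.97, 0.0372, 36), (10, 3.97, 0.0372, 36), (20, 4.5, 0.05, 48), (7, 4.0, 0.08, 100)],
    )
    def test_against_sampling_oracle(self, c, n_bar, var_n, m):
        """First-order Var(lambda_s) vs a 10^6-draw simulation of C (A/n* - 1), n* ~ Normal.

        Grid restricted to CV(n_mean) <~ 1.5 %, where the first-order
        propagation is exact to within Monte Carlo resolution.
        """
        eff = self._effects(n_bar, var_n, m)
        spec = systematic_lambda_spec(c, eff)
        rng = np.random.default_rng(c * 1000 + m)
        n_star = rng.normal(n_bar, np.sqrt(var_n / m), 1_000_000)
        sims = c * (5 / n_star - 1)
        centred = (sims - sims.mean()) ** 2
        mc_var = centred.mean()
        se_var = centred.std(ddof=1) / np.sqrt(sims.size)
        assert abs(spec.variance - mc_var) < 3 * se_var

    @pytest.mark.parametrize("c, n_bar, var_n, m", [(10, 3.58, 0.143, 12), (20, 4.2, 0.3, 24)])
    def test_truncation_error_follows_second_order_term(self, c, n_bar, var_n, m):
        """At larger CV(n_mean) the first-order formula undershoots by ~8 CV^2 relative.

        Var(1/X) for X ~ Normal(mu, sigma^2) expands as (sigma^2/mu^4)(1 + 8 sigma^2/mu^2 + ...),
        so the relative deficit of the first-order result is 8 CV^2.
        """
        eff = self._effects(n_bar, var_n, m)
        spec = systematic_lambda_spec(c, eff)
        tau2 = (var_n / m) / n_bar**2
        rng = np.random.default_rng(c * 77 + m)
        n_star = rng.normal(n_bar, np.sqrt(var_n / m), 2_000_000)
        mc_var = (c * (5 / n_star - 1)).var()
        rel_deficit = (mc_var - spec.variance) / spec.variance
        assert rel_deficit == pytest.approx(8 * tau2, rel=0.35)
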