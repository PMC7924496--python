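"""Quadrature of the limiting variance ratio and its empirical counterparts."""

import numpy as np
import pytest

from reci.exceptions import (
    ConfigurationError,
    NonIntegrableMechanismError,
    UndefinedRatioError,
)
from reci.inference import RECI, RunProtocol
from reci.pair import Direction
from reci.regressors import FamilySpec
from reci.simulate import MECHANISMS, TheoremPairConfig, generate_theorem_pair
from reci.theory import (
    MechanismRecord,
    causal_direction_mse_check,
    constant_variance_uniform_record,
    convergence_report,
    empirical_ratio,
    empirical_ratio_with_se,
    variance_ratio_limit,
    postulate_covariance,
)

NONLINEAR = ("quadratic-mix", "cubic-mix", "exp-norm", "sin-mix")


class TestVarianceRatioLimit:
    def test_linear_equality_case(self):
        assert variance_ratio_limit(constant_variance_uniform_record("linear")) == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_mix_closed_form(self):
        # phi'(c) = (1+2c)/2; integral of 4/(1+2c)^2 over [0,1] = 4 * 1/3
        val = variance_ratio_limit(constant_variance_uniform_record("quadratic-mix"))
        assert val == pytest.approx(4.0 / 3.0, rel=1e-8)

    @pytest.mark.parametrize("name", NONLINEAR)
    def test_postulate_records_respect_the_lower_bound(self, name):
        assert variance_ratio_limit(constant_variance_uniform_record(name)) >= 1.0 - 1e-9

    def test_quadrature_refinement_stabilizes(self):
        rec = constant_variance_uniform_record("sin-mix")
        grids = [501, 1001, 2001, 4001]
        vals = [variance_ratio_limit(rec, g) for g in grids]
        diffs = [abs(b - a) for a, b in zip(vals, vals[1:])]
        for earlier, later in zip(diffs, diffs[1:]):
            assert later <= earlier + 1e-12

    def test_divergent_mechanism_flagged(self):
        # slope vanishing like c at 0 makes 1/phi'^2 non-integrable
        rec = MechanismRecord(
            phi=lambda c: np.asarray(c, float) ** 2,
            phi_prime=lambda c: 2.0 * np.asarray(c, float),
            cond_var=lambda c: np.ones_like(np.asarray(c, float)),
            cause_density=lambda c: np.ones_like(np.asarray(c, float)),
        )
        with pytest.raises(NonIntegrableMechanismError):
            variance_ratio_limit(rec)


class TestPostulateCovariance:
    @pytest.mark.parametrize("name", NONLINEAR + ("linear",))
    def test_constant_variance_uniform_records_are_uncorrelated(self, name):
        assert abs(postulate_covariance(constant_variance_uniform_record(name))) < 1e-9

    def test_linear_mechanism_uncorrelated_with_any_profile(self):
        rec = MechanismRecord(
            phi=MECHANISMS["linear"].phi,
            phi_prime=MECHANISMS["linear"].phi_prime,
            cond_var=lambda c: 0.5 + np.asarray(c, float),
            cause_density=lambda c: np.ones_like(np.asarray(c, float)),
        )
        assert abs(postulate_covariance(rec)) < 1e-9

    def test_constructed_violation_is_strictly_positive(self):
        # Var[N|c] proportional to phi' couples slope and noise profile;
        # with uniform cause and integral(phi') = 1 the record still satisfies
        # the unit-variance convention, but the covariance is phi'-variance > 0
        mech = MECHANISMS["quadratic-mix"]
        rec = MechanismRecord(
            phi=mech.phi,
            phi_prime=mech.phi_prime,
            cond_var=mech.phi_prime,
            cause_density=lambda c: np.ones_like(np.asarray(c, float)),
        )
        rec.validate()
        assert postulate_covariance(rec) > 1e-3


class TestEmpiricalRatio:
    def test_deterministic_pair_has_undefined_ratio(self):
        pair, rec = generate_theorem_pair(
            TheoremPairConfig(phi="quadratic-mix", alpha=0.0, n_samples=5000, seed=1)
        )
        with pytest.raises(UndefinedRatioError):
            empirical_ratio(pair, 0.0, 50, record=rec)

    def test_linear_mechanism_ratio_near_one(self):
        # small-noise end of the grid: the finite-alpha rescaling bias
        # (1 + 2*sqrt(3)*alpha)^2 is ~7% here and shrinks linearly in alpha
        pair, rec = generate_theorem_pair(
            TheoremPairConfig(phi="linear", alpha=0.01, n_samples=200_000, seed=3)
        )
        ratio = empirical_ratio(pair, 0.01, 100, record=rec)
        assert 0.9 <= ratio <= 1.1

    def test_quadratic_mechanism_matches_quadrature(self):
        pair, rec = generate_theorem_pair(
            TheoremPairConfig(phi="quadratic-mix", alpha=0.02, n_samples=200_000, seed=4)
        )
        ratio = empirical_ratio(pair, 0.02, 100, record=rec)
        assert ratio == pytest.approx(4.0 / 3.0, rel=0.1)

    @pytest.mark.parametrize("name", ("linear",) + NONLINEAR)
    def test_small_noise_battery_agrees_with_quadrature(self, name):
        pair, rec = generate_theorem_pair(
            TheoremPairConfig(phi=name, alpha=0.01, n_samples=200_000, seed=7)
        )
        ratio = empirical_ratio(pair, 0.01, 100, record=rec)
        target = variance_ratio_limit(constant_variance_uniform_record(name))
        assert ratio == pytest.approx(target, rel=0.1)

    def test_bins_reduced_with_warning_on_tiny_samples(self):
        pair, rec = generate_theorem_pair(
            TheoremPairConfig(phi="quadratic-mix", alpha=0.1, n_samples=30, seed=5)
        )
        with pytest.warns(UserWarning, match="reducing bins"):
            empirical_ratio(pair, 0.1, 100, record=rec)


class TestCausalDirectionMse:
    @pytest.mark.parametrize("alpha", [0.05, 0.1, 0.2])
    def test_binned_conditional_variance_equals_alpha_squared(self, alpha):
        pair, _ = generate_theorem_pair(
            TheoremPairConfig(phi="quadratic-mix", alpha=alpha, n_samples=200_000, seed=6)
        )
        assert causal_direction_mse_check(pair, 100) == pytest.approx(alpha**2, rel=0.1)

    def test_zero_noise_gives_zero_up_to_the_binning_floor(self):
        pair, _ = generate_theorem_pair(
            TheoremPairConfig(phi="quadratic-mix", alpha=0.0, n_samples=20_000, seed=6)
        )
        # the within-bin variation of phi(C) bounds the estimate from below:
        # E[phi'^2] * w^2 / 12 with w the bin width, ~4e-5 at 50 bins
        assert causal_direction_mse_check(pair, 50) < 1e-4
        # refining the bins shrinks the floor quadratically
        assert causal_direction_mse_check(pair, 1000) < 1e-6

    def test_doubling_alpha_quadruples_the_estimate(self):
        small, _ = generate_theorem_pair(
            TheoremPairConfig(phi="cubic-mix", alpha=0.1, n_samples=200_000, seed=8)
        )
        big, _ = generate_theorem_pair(
            TheoremPairConfig(phi="cubic-mix", alpha=0.2, n_samples=200_000, seed=9)
        )
        r = causal_direction_mse_check(big, 100) / causal_direction_mse_check(small, 100)
        assert 3.6 <= r <= 4.4


class TestConvergenceReport:
    def test_linear_mechanism_equality_case(self):
        report = convergence_report(
            TheoremPairConfig(phi="linear", seed=1), alpha_grid=(0.05, 0.02, 0.01), n=100_000
        )
        assert report.limit_value == pytest.approx(1.0, abs=1e-9)
        # finite-alpha rescaling bias decays toward the limit of exactly 1
        ratios = list(report.empirical_ratios.values())
        assert ratios[0] > ratios[1] > ratios[2] > 0.9
        assert abs(ratios[-1] - 1.0) < 0.1
        assert report.bound_satisfied

    def test_nonlinear_ratios_approach_the_limit(self):
        hits = 0
        for seed in range(20):
            rep = convergence_report(
                TheoremPairConfig(phi="quadratic-mix", seed=seed),
                alpha_grid=(0.3, 0.02),
                n=50_000,
            )
            ratios = list(rep.empirical_ratios.values())
            target = rep.limit_value
            if abs(ratios[-1] - target) < abs(ratios[0] - target):
                hits += 1
        assert hits >= 16  # 80% of seeds

    def test_report_serializes_to_json_types(self):
        rep = convergence_report(
            TheoremPairConfig(phi="sin-mix", seed=2), alpha_grid=(0.05, 0.02), n=50_000
        )
        d = rep.to_dict()
        assert set(d) == {
            "mechanism", "limit_value", "postulate_cov",
            "empirical_ratios", "ratio_standard_errors", "bound_satisfied",
        }
        assert rep.bound_satisfied

    def test_increasing_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            convergence_report(TheoremPairConfig(), alpha_grid=(0.01, 0.05), n=1000)


class TestReciOnTheoremRegime:
    def test_polynomial_reci_recovers_direction_at_small_noise(self):
        hits = 0
        for seed in range(100):
            pair, _ = generate_theorem_pair(
                TheoremPairConfig(phi="quadratic-mix", alpha=0.1, n_samples=1000, seed=seed)
            )
            res = RECI(
                pair,
                candidates=[FamilySpec("POLY", order=3)],
                protocol=RunProtocol(n_runs=5, seed=seed),
            ).fit()
            hits += res.direction is Direction.X_CAUSES_Y
        assert hits >= 80
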