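"""Synthetic generators: monotone CDF mixtures, dependent-noise suites, and the
small-noise regime with renormalized conditional noise."""

import numpy as np
import pytest

from reci.exceptions import ConfigurationError, DegenerateInputError
from reci.pair import Direction
from reci.simulate import (
    MECHANISMS,
    CdfMixtureSpec,
    DependentPairConfig,
    TheoremPairConfig,
    cdf_mixture,
    generate_dependent_pair,
    generate_theorem_pair,
    random_cdf_mixture,
    rescale_interval,
    tilde_rescale,
)
from reci.theory import _equal_count_binned_variance


class TestCdfMixture:
    def test_single_component_value_at_its_mean(self):
        s = cdf_mixture(CdfMixtureSpec(betas=(1.0,), mus=(0.5,), sigmas=(0.1,)))
        assert s(np.array([0.5]))[0] == pytest.approx(0.5)

    def test_increasing_on_dense_grid(self, rng):
        # strictly increasing mathematically; in floats the component CDFs
        # saturate far from their means, so assert non-decreasing plus strict
        # growth over the whole interval
        for _ in range(10):
            s = cdf_mixture(random_cdf_mixture(rng))
            vals = s(np.linspace(0, 1, 1000))
            assert (np.diff(vals) >= 0).all()
            assert vals[-1] > vals[0]
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_strictly_increasing_at_moderate_spread(self):
        s = cdf_mixture(
            CdfMixtureSpec(betas=(0.4, 0.6), mus=(0.2, 0.8), sigmas=(0.1, 0.1))
        )
        vals = s(np.linspace(0, 1, 1000))
        assert (np.diff(vals) > 0).all()

    def test_symmetric_two_component_midpoint(self):
        s = cdf_mixture(
            CdfMixtureSpec(betas=(0.5, 0.5), mus=(0.3, 0.7), sigmas=(0.05, 0.05))
        )
        assert s(np.array([0.5]))[0] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(betas=(0.6, 0.6), mus=(0.2, 0.8), sigmas=(0.05, 0.05)),
            dict(betas=(1.0,), mus=(1.5,), sigmas=(0.05,)),
            dict(betas=(1.0,), mus=(0.5,), sigmas=(0.2,)),
            dict(betas=(1.0,), mus=(0.5,), sigmas=(0.0,)),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            CdfMixtureSpec(**bad)


class TestRescaling:
    def test_interval_endpoints(self):
        np.testing.assert_allclose(rescale_interval(np.array([0.0, 1.0]), -2, 2), [-2, 2])
        np.testing.assert_allclose(
            rescale_interval(np.array([0.0, 0.5, 1.0]), -2, 2), [-2, 0, 2]
        )

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            rescale_interval(np.array([1.0, 1.0]), 0, 1)

    def test_tilde_rescale_identity_at_zero_noise(self, rng):
        e = rng.uniform(size=20)
        np.testing.assert_array_equal(tilde_rescale(e, 0.0, -1.0, 1.0), e)

    def test_tilde_rescale_endpoint_mapping(self):
        a, nm, np_ = 0.3, -0.8, 1.2
        out = tilde_rescale(np.array([a * nm, 1 + a * np_]), a, nm, np_)
        np.testing.assert_allclose(out, [0.0, 1.0])

    def test_tilde_rescale_direct_substitution(self):
        np.testing.assert_allclose(
            tilde_rescale(np.array([2.0]), 1.0, -1.0, 1.0), [(2.0 + 1.0) / 3.0]
        )


class TestDependentPairs:
    def test_zero_noise_branch_is_deterministic(self):
        pair = generate_dependent_pair(
            DependentPairConfig(kind="invertible", alpha=0.0, n_samples=2000, seed=5)
        )
        # effect equals the mechanism image exactly: zero conditional variance
        np.testing.assert_array_equal(pair.y, pair.meta["effect_mean"])

    def test_cause_is_minmax_normalized(self):
        pair = generate_dependent_pair(DependentPairConfig(kind="noninvertible", seed=2))
        assert pair.x.min() == 0.0 and pair.x.max() == 1.0
        assert pair.truth is Direction.X_CAUSES_Y

    def test_noise_variance_scales_with_alpha(self):
        pair = generate_dependent_pair(
            DependentPairConfig(kind="linear", alpha=0.4, n_samples=10000, seed=3)
        )
        resid = pair.y - pair.x  # linear kind: phi is the identity
        assert resid.var() == pytest.approx(0.16, rel=0.1)

    def test_same_seed_is_bit_identical(self):
        cfg = DependentPairConfig(kind="invertible", alpha=0.2, n_samples=200, seed=11)
        a, b = generate_dependent_pair(cfg), generate_dependent_pair(cfg)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_linear_kind_produces_cause_noise_dependence(self):
        strong = 0
        for seed in range(100):
            pair = generate_dependent_pair(
                DependentPairConfig(kind="linear", alpha=0.5, n_samples=10000, seed=seed)
            )
            noise = pair.y - pair.x
            if abs(np.corrcoef(pair.x, noise)[0, 1]) > 0.1:
                strong += 1
        assert strong >= 30

    def test_invertible_kind_with_noise_is_nondeterministic(self):
        pair = generate_dependent_pair(
            DependentPairConfig(kind="invertible", alpha=0.5, n_samples=10000, seed=21)
        )
        var, _ = _equal_count_binned_variance(pair.x, pair.y, 50)
        assert var > 1e-4


class TestTheoremPairs:
    def test_constant_profile_gives_unit_conditional_variance(self):
        pair, rec = generate_theorem_pair(
            TheoremPairConfig(phi="quadratic-mix", alpha=1.0, n_samples=100_000, seed=1)
        )
        noise = pair.y - rec.mechanism.phi(pair.x)
        var, _ = _equal_count_binned_variance(pair.x, noise, 50)
        assert var == pytest.approx(1.0, rel=0.05)

    def test_nonconstant_profile_renormalizes_to_unit_expected_variance(self):
        pair, rec = generate_theorem_pair(
            TheoremPairConfig(
                phi="cubic-mix",
                alpha=1.0,
                n_samples=1_000_000,
                seed=2,
                cond_sd_profile=lambda c: 0.2 + c**2,
            )
        )
        noise = pair.y - rec.mechanism.phi(pair.x)
        var, _ = _equal_count_binned_variance(pair.x, noise, 100)
        assert var == pytest.approx(1.0, rel=0.02)

    def test_conditional_noise_means_are_zero(self):
        pair, rec = generate_theorem_pair(
            TheoremPairConfig(phi="quadratic-mix", alpha=1.0, n_samples=100_000, seed=3)
        )
        noise = pair.y - rec.mechanism.phi(pair.x)
        order = np.argsort(pair.x)
        for chunk in np.array_split(order, 20):
            m = noise[chunk].mean()
            se = noise[chunk].std(ddof=1) / np.sqrt(chunk.size)
            assert abs(m) < 3 * se + 1e-12

    def test_effect_support_within_stated_bounds(self):
        cfg = TheoremPairConfig(phi="sin-mix", alpha=0.3, n_samples=50_000, seed=4)
        pair, rec = generate_theorem_pair(cfg)
        assert pair.y.min() >= cfg.alpha * rec.n_minus - 1e-12
        assert pair.y.max() <= 1.0 + cfg.alpha * rec.n_plus + 1e-12

    def test_same_seed_is_bit_identical(self):
        cfg = TheoremPairConfig(phi="exp-norm", alpha=0.1, n_samples=500, seed=9)
        (a, _), (b, _) = generate_theorem_pair(cfg), generate_theorem_pair(cfg)
        np.testing.assert_array_equal(a.y, b.y)

    def test_zero_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_theorem_pair(
                TheoremPairConfig(cond_sd_profile=lambda c: np.zeros_like(c))
            )

    def test_mechanism_registry_contracts(self):
        grid = np.linspace(0, 1, 2001)
        for mech in MECHANISMS.values():
            assert mech.phi(np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-12)
            assert mech.phi(np.array([1.0]))[0] == pytest.approx(1.0, abs=1e-12)
            assert (mech.phi_prime(grid) > 0).all()
            # derivative consistency by central differences
            num = np.gradient(mech.phi(grid), grid)
            np.testing.assert_allclose(num[5:-5], mech.phi_prime(grid)[5:-5], rtol=5e-3)
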