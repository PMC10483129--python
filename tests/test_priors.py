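import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, multivariate_normal

from scdgd import GaussianMixture, SoftballPrior, mixture_weights

from conftest import random_gmm


class TestSoftball:
    def test_boundary_value_independent_of_sharpness(self):
        # at ||v|| == scale the mollifier contributes exactly -log 2
        for sharpness in (1.0, 5.0, 50.0):
            sb = SoftballPrior(3, scale=2.0, sharpness=sharpness)
            v = np.array([2.0, 0.0, 0.0])
            assert sb.log_prob(v) == pytest.approx(sb.log_norm - math.log(2))

    def test_log_norm_approaches_negative_log_ball_volume(self):
        # unit 2-ball has volume pi; the hard ball is the sharp limit
        sb = SoftballPrior(2, scale=1.0, sharpness=1000.0)
        assert sb.log_norm == pytest.approx(-math.log(math.pi), abs=1e-4)
        # at finite sharpness the normalizer absorbs the boundary correction
        soft = SoftballPrior(2, scale=1.0, sharpness=8.0)
        assert soft.log_norm == pytest.approx(
            -math.log(math.pi) - math.log(1 + math.pi**2 / (3 * 64)), abs=1e-3
        )

    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_density_normalizes_by_monte_carlo(self, dim):
        sb = SoftballPrior(dim, scale=1.0, sharpness=10.0)
        rng = np.random.default_rng(0)
        n = 10**6
        box = 2.0
        pts = rng.uniform(-box, box, size=(n, dim))
        integral = np.exp(sb.log_prob(pts)).mean() * (2 * box) ** dim
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_log_prob_decreasing_in_radius_and_finite(self):
        sb = SoftballPrior(2, scale=1.0, sharpness=3.0)
        radii = np.linspace(0, 10, 50)
        vals = np.array([sb.log_prob(np.array([r, 0.0])) for r in radii])
        assert np.all(np.isfinite(vals))
        assert np.all(np.diff(vals) < 0)

    def test_dimension_mismatch_raises(self):
        sb = SoftballPrior(3)
        with pytest.raises(ValueError, match="3"):
            sb.log_prob(np.ones(4))

    def test_sample_norms_and_mean(self):
        sb = SoftballPrior(3, scale=1.5)
        rng = np.random.default_rng(42)
        draws = sb.sample(10**5, rng)
        norms = np.linalg.norm(draws, axis=1)
        assert norms.max() <= 1.5
        tol = 3 * 1.5 / math.sqrt(10**5 * (3 + 2))
        assert np.all(np.abs(draws.mean(axis=0)) < tol)

    def test_sample_radial_law(self):
        # (||v||/scale)^m is uniform(0,1) for a uniform ball draw
        sb = SoftballPrior(4, scale=2.0)
        rng = np.random.default_rng(7)
        draws = sb.sample(10**5, rng)
        u = (np.linalg.norm(draws, axis=1) / 2.0) ** 4
        assert kstest(u, "uniform").statistic < 0.01

    def test_gradient_matches_finite_differences(self):
        sb = SoftballPrior(3, scale=1.2, sharpness=4.0)
        rng = np.random.default_rng(3)
        v = rng.standard_normal(3)
        g = sb.grad_log_prob(v)
        eps = 1e-6
        for d in range(3):
            vp, vm = v.copy(), v.copy()
            vp[d] += eps
            vm[d] -= eps
            fd = (sb.log_prob(vp) - sb.log_prob(vm)) / (2 * eps)
            assert g[d] == pytest.approx(fd, abs=1e-6)


class TestMixtureWeights:
    def test_equal_coefficients(self):
        np.testing.assert_allclose(mixture_weights(np.ones(3)), np.full(3, 1 / 3))

    def test_softmax_values(self):
        np.testing.assert_allclose(
            mixture_weights(np.array([0.0, math.log(3)])), [0.25, 0.75], atol=1e-12
        )

    def test_overflow_safety(self):
        w = mixture_weights(np.array([1000.0, 0.0]))
        assert np.all(np.isfinite(w))
        assert w[0] == pytest.approx(1.0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        coeffs=st.lists(
            st.floats(-50, 50), min_size=1, max_size=8
        ),
        shift=st.floats(-100, 100),
    )
    def test_simplex_and_shift_invariance(self, coeffs, shift):
        c = np.array(coeffs)
        w = mixture_weights(c)
        assert np.all(w > 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(mixture_weights(c + shift), w, atol=1e-9)


def brute_force_log_density(gmm, z):
    """Independent per-component summation with scipy densities."""
    w = mixture_weights(gmm.coeffs)
    dens = np.zeros(z.shape[0])
    for k in range(gmm.n_components):
        cov = np.diag(np.exp(-gmm.neg_log_var[k]))
        dens += w[k] * multivariate_normal.pdf(z, mean=gmm.means[k], cov=cov)
    return np.log(dens)


class TestGmmDensity:
    def test_standard_normal_at_mode(self):
        gmm = GaussianMixture(1, 1, rng=np.random.default_rng(0))
        gmm.means[:] = 0.0
        gmm.neg_log_var[:] = 0.0
        val = gmm.log_density(np.zeros((1, 1)))[0]
        assert val == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_symmetric_two_component(self):
        gmm = GaussianMixture(2, 1, rng=np.random.default_rng(0))
        gmm.means = np.array([[1.0], [-1.0]])
        gmm.neg_log_var[:] = 0.0
        gmm.coeffs[:] = 1.0
        # both terms equal the standard normal density at distance 1
        expected = -0.5 * math.log(2 * math.pi) - 0.5
        assert gmm.log_density(np.zeros((1, 1)))[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            gmm = random_gmm(rng, 3, 2)
            z = rng.standard_normal((10, 2)) * 2
            np.testing.assert_allclose(
                gmm.log_density(z), brute_force_log_density(gmm, z), atol=1e-10
            )

    def test_bounded_by_max_component_term(self, rng):
        gmm = random_gmm(rng, 4, 3)
        z = rng.standard_normal((20, 3))
        comp = gmm._component_log_densities(z)
        total = gmm.log_density(z)
        assert np.all(total >= comp.max(axis=1) - 1e-12)
        assert np.all(total <= comp.max(axis=1) + math.log(4) + 1e-12)

    def test_dimension_mismatch_raises(self, rng):
        gmm = random_gmm(rng, 2, 3)
        with pytest.raises(ValueError, match="dim"):
            gmm.log_density(np.zeros((5, 2)))


class TestResponsibilities:
    def test_rows_exponentiate_to_one(self, rng):
        gmm = random_gmm(rng, 5, 2)
        z = rng.standard_normal((50, 2)) * 3
        rows = np.exp(gmm.log_responsibilities(z)).sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-12)

    def test_equidistant_symmetric_case(self):
        gmm = GaussianMixture(4, 2, rng=np.random.default_rng(0))
        gmm.means = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        gmm.neg_log_var[:] = 0.0
        gmm.coeffs[:] = 0.0
        resp = np.exp(gmm.log_responsibilities(np.zeros((1, 2))))
        np.testing.assert_allclose(resp, 0.25, atol=1e-12)

    def test_matches_bayes_oracle(self, rng):
        gmm = random_gmm(rng, 3, 2)
        z = rng.standard_normal((15, 2))
        w = mixture_weights(gmm.coeffs)
        per_comp = np.stack(
            [
                w[k]
                * multivariate_normal.pdf(
                    z, mean=gmm.means[k], cov=np.diag(np.exp(-gmm.neg_log_var[k]))
                )
                for k in range(3)
            ],
            axis=1,
        )
        oracle = per_comp / per_comp.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            np.exp(gmm.log_responsibilities(z)), oracle, atol=1e-12
        )


class TestHardAssign:
    def test_single_component(self, rng):
        gmm = random_gmm(rng, 1, 2)
        assert np.all(gmm.hard_assign(rng.standard_normal((10, 2))) == 0)

    def test_point_at_component_mean(self):
        gmm = GaussianMixture(3, 2, rng=np.random.default_rng(0))
        gmm.means = np.array([[5.0, 0], [0, 5.0], [-5.0, 0]])
        gmm.neg_log_var[:] = 0.0
        gmm.coeffs[:] = 0.0
        assert gmm.hard_assign(gmm.means[1][None, :])[0] == 1

    def test_tie_goes_to_lowest_index(self):
        gmm = GaussianMixture(4, 1, rng=np.random.default_rng(0))
        gmm.means = np.array([[10.0], [1.0], [10.0], [-1.0]])
        gmm.neg_log_var[:] = 0.0
        gmm.coeffs[:] = 0.0
        # z = 0 is equidistant from components 1 and 3, both beat 0 and 2
        assert gmm.hard_assign(np.zeros((1, 1)))[0] == 1


class TestSampleLatent:
    def test_component_conditional_moments(self, rng):
        gmm = random_gmm(rng, 3, 2)
        draws = gmm.sample(10**5, component=1, rng=rng)
        sd = np.exp(-0.5 * gmm.neg_log_var[1])
        tol = 4 * sd / math.sqrt(10**5)
        assert np.all(np.abs(draws.mean(axis=0) - gmm.means[1]) < tol)
        np.testing.assert_allclose(
            draws.var(axis=0), np.exp(-gmm.neg_log_var[1]), rtol=0.05
        )

    def test_unconditional_component_frequencies(self, rng):
        gmm = random_gmm(rng, 3, 2)
        gmm.means *= 20  # separate enough to identify the generating component
        draws = gmm.sample(10**5, rng=rng)
        freq = np.bincount(gmm.hard_assign(draws), minlength=3) / 10**5
        w = gmm.weights()
        # multinomial 99% CI half-width
        hw = 2.58 * np.sqrt(w * (1 - w) / 10**5)
        assert np.all(np.abs(freq - w) < hw + 1e-3)

    def test_out_of_range_component_raises(self, rng):
        gmm = random_gmm(rng, 2, 2)
        with pytest.raises(ValueError, match="out of range"):
            gmm.sample(5, component=2, rng=rng)


class TestSupervisedDensity:
    def test_single_component_equals_mixture(self, rng):
        gmm = random_gmm(rng, 1, 2)
        z = rng.standard_normal((8, 2))
        np.testing.assert_allclose(
            gmm.supervised_log_density(z, np.zeros(8, dtype=int)),
            gmm.log_density(z),
            atol=1e-12,
        )

    def test_never_exceeds_mixture_density(self, rng):
        gmm = random_gmm(rng, 3, 2)
        z = rng.standard_normal((30, 2))
        labels = rng.integers(0, 3, size=30)
        assert np.all(
            gmm.supervised_log_density(z, labels) <= gmm.log_density(z) + 1e-12
        )

    def test_non_assigned_components_get_zero_gradient(self, rng):
        gmm = random_gmm(rng, 3, 2)
        gmm.zero_grad()
        z = rng.standard_normal((10, 2))
        labels = np.full(10, 1)
        gmm.supervised_log_density_backward(z, labels, np.ones(10))
        for k in (0, 2):
            np.testing.assert_array_equal(gmm.grad_means[k], 0.0)
            np.testing.assert_array_equal(gmm.grad_neg_log_var[k], 0.0)
        assert np.any(gmm.grad_means[1] != 0.0)

    def test_label_out_of_range_raises(self, rng):
        gmm = random_gmm(rng, 2, 2)
        with pytest.raises(ValueError, match="range"):
            gmm.supervised_log_density(np.zeros((1, 2)), np.array([2]))


class TestParamLogPrior:
    def test_alpha_one_kills_dirichlet_term(self, rng):
        gmm = random_gmm(rng, 3, 2)
        gmm.dirichlet_alpha = 1.0
        base = gmm.param_log_prior()
        gmm.coeffs = rng.standard_normal(3) * 5
        shifted = gmm.param_log_prior()
        # only the Dirichlet term depends on coeffs
        assert base == pytest.approx(shifted, abs=1e-10)

    def test_logvar_prior_maximized_at_mode(self, rng):
        gmm = random_gmm(rng, 2, 2)
        gmm.neg_log_var[:] = gmm.logvar_prior_mean
        at_mode = gmm.param_log_prior()
        gmm.neg_log_var += 0.3
        assert gmm.param_log_prior() < at_mode

    def test_additivity_of_terms(self, rng):
        gmm = random_gmm(rng, 3, 2)
        gmm.dirichlet_alpha = 2.0
        mean_term = float(np.sum(gmm.mean_prior.log_prob(gmm.means)))
        w = gmm.weights()
        dir_term = (2.0 - 1.0) * float(np.sum(np.log(w)))
        dev = gmm.neg_log_var - gmm.logvar_prior_mean
        var_term = -0.5 * float(np.sum(dev * dev))
        assert gmm.param_log_prior() == pytest.approx(
            mean_term + dir_term + var_term, abs=1e-10
        )
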