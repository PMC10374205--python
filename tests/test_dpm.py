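"""Dirichlet-process mixture sampler: conjugate updates, recovery, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dietclust.config import DPMConfig
from dietclust.dpm import (
    DPMState,
    FFQMatrix,
    fit_dpm,
    sample_allocations,
    stick_breaking_weights,
    update_components,
    update_concentration,
    update_sticks,
)


def make_state(weights, means, variances, alpha=1.0, n=0):
    weights = np.asarray(weights, float)
    means = np.atleast_2d(np.asarray(means, float))
    variances = np.atleast_2d(np.asarray(variances, float))
    return DPMState(
        sticks=np.zeros(len(weights) - 1),
        weights=weights,
        means=means,
        variances=variances,
        allocations=np.zeros(n, int),
        alpha=alpha,
    )


class TestStickBreaking:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ((0.5, 0.5, 0.5), (0.5, 0.25, 0.125, 0.125)),
            ((1.0, 0.3, 0.9), (1.0, 0.0, 0.0, 0.0)),
            ((0.2, 0.6), (0.2, 0.48, 0.32)),
        ],
    )
    def test_hand_arithmetic(self, v, expected):
        assert np.allclose(stick_breaking_weights(np.array(v)), expected, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            stick_breaking_weights(np.array([0.5, 1.2]))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_simplex_property(self, v):
        w = stick_breaking_weights(np.array(v))
        assert np.all(w >= 0)
        assert abs(w.sum() - 1.0) < 1e-12


class TestSampleAllocations:
    def test_well_separated_point(self, rng):
        state = make_state([0.5, 0.5], [[-5.0], [5.0]], [[1.0], [1.0]])
        _, probs = sample_allocations(np.array([[-5.0]]), state, rng)
        assert probs[0, 0] > 0.999

    def test_identical_components_give_weights(self, rng):
        w = np.array([0.2, 0.3, 0.5])
        state = make_state(w, [[1.0]] * 3, [[2.0]] * 3)
        _, probs = sample_allocations(rng.normal(size=(50, 1)), state, rng)
        assert np.allclose(probs, np.tile(w, (50, 1)), atol=1e-12)

    def test_midpoint_equal_densities(self, rng):
        """At the midpoint of two unit-variance components the densities are
        equal, so the allocation probability reduces to the weights."""
        state = make_state([0.3, 0.7], [[0.0], [1.0]], [[1.0], [1.0]])
        _, probs = sample_allocations(np.array([[0.5]]), state, rng)
        assert abs(probs[0, 0] - 0.3) < 1e-12

    def test_vanishing_densities_flagged_with_row(self, rng):
        state = make_state([0.5, 0.5], [[1e200], [-1e200]], [[1.0], [1.0]])
        with pytest.raises(FloatingPointError, match=r"row\(s\) \[1\]"):
            sample_allocations(np.array([[1e200], [0.0]]), state, rng)

    def test_row_permutation_permutes_probabilities(self, rng):
        X = rng.normal(size=(40, 2))
        state = make_state(
            [0.4, 0.6], [[0.0, 0.0], [1.0, -1.0]], [[1.0, 1.0], [0.5, 2.0]]
        )
        _, probs = sample_allocations(X, state, np.random.default_rng(0))
        perm = rng.permutation(40)
        _, probs_p = sample_allocations(X[perm], state, np.random.default_rng(0))
        assert np.allclose(probs_p, probs[perm], atol=0)


class TestUpdateSticks:
    def test_beta_posterior_mean(self):
        """All n observations in the first component, alpha = 1:
        v_1 ~ Beta(1+n, 1) with mean (n+1)/(n+2)."""
        rng = np.random.default_rng(0)
        n = 8
        z = np.zeros(n, int)
        draws = np.array([update_sticks(z, 1.0, 4, rng)[0] for _ in range(10000)])
        assert abs(draws.mean() - (n + 1) / (n + 2)) < 0.01

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(1)
        z = np.zeros(50, int)
        draws = np.array([update_sticks(z, 1.0, 5, rng) for _ in range(2000)])
        means = draws.mean(axis=0)
        assert means[0] > means[1:].max()

    def test_huge_alpha_dominates(self):
        rng = np.random.default_rng(2)
        v = update_sticks(np.zeros(10, int), 1e6, 8, rng)
        assert np.all(v[1:] < 0.01)
        w = stick_breaking_weights(v)
        # sticks concentrate near zero; leading weights nearly equal
        assert w[1:-1].std() / w[1:-1].mean() < 1.5


class TestUpdateComponents:
    def test_empty_component_draws_from_prior(self):
        """Empty components are drawn from the base distribution, so their
        mean draws center on m0."""
        rng = np.random.default_rng(3)
        cfg = DPMConfig(base_mean=2.0, base_scale=1.0)
        X = np.zeros((5, 1))
        z = np.zeros(5, int)
        means, _ = update_components(X, z, cfg, 10000, rng)
        empty = means[1:, 0]
        se = empty.std() / np.sqrt(len(empty))
        assert abs(empty.mean() - 2.0) < 3 * se

    def test_posterior_concentrates_on_sample_mean(self):
        rng = np.random.default_rng(4)
        cfg = DPMConfig(base_mean=0.0, base_scale=0.01)
        X = rng.normal(5.0, 1.0, size=(10000, 1))
        z = np.zeros(10000, int)
        means, _ = update_components(X, z, cfg, 2, rng)
        assert abs(means[0, 0] - X.mean()) < 0.05

    def test_single_observation_conjugate_mean(self):
        """n=1, kappa0=1, m0=0: posterior location of mu is x/2."""
        cfg = DPMConfig(base_mean=0.0, base_scale=1.0)
        X = np.array([[3.0]])
        z = np.zeros(1, int)
        draws = [
            update_components(X, z, cfg, 1, np.random.default_rng(s))[0][0, 0]
            for s in range(4000)
        ]
        draws = np.array(draws)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 1.5) < 3 * se


class TestUpdateConcentration:
    def test_gamma_posterior_mean(self):
        """v -> 0 and K-1 = 3 sticks with prior Gamma(2, 1): the update is
        Gamma(5, 1), mean 5."""
        rng = np.random.default_rng(5)
        v = np.full(3, 1e-14)
        draws = np.array(
            [update_concentration(v, (2.0, 1.0), rng) for _ in range(10000)]
        )
        assert abs(draws.mean() - 5.0) < 0.1

    def test_fixed_alpha_pass_through(self, rng):
        assert update_concentration(np.array([0.5]), (2.0, 1.0), rng, 3.7) == 3.7

    def test_stochastically_smaller_with_larger_sticks(self):
        rng = np.random.default_rng(6)
        small = np.array(
            [update_concentration(np.full(4, 0.05), (2.0, 1.0), rng) for _ in range(5000)]
        )
        large = np.array(
            [update_concentration(np.full(4, 0.9), (2.0, 1.0), rng) for _ in range(5000)]
        )
        assert large.mean() < small.mean()


class TestFitDPM:
    def test_two_well_separated_blobs(self):
        """Two N(-5,1)/N(+5,1) blobs of 100: exactly 2 occupied components in
        >= 95% of retained iterations; means recovered within 0.3."""
        g = np.random.default_rng(3)
        x = np.concatenate([g.normal(-5, 1, 100), g.normal(5, 1, 100)])[:, None]
        post = fit_dpm(x, DPMConfig(truncation_K=10, n_burnin=500, n_samples=2000, seed=3))
        assert (post.occupied_trace == 2).mean() >= 0.95
        occ = post.occupied_components
        means = np.sort(post.means[occ].ravel())
        assert abs(means[0] - (-5.0)) < 0.3
        assert abs(means[-1] - 5.0) < 0.3
        # truncation sanity: negligible posterior mass on the last component
        assert post.weights[-1] < 0.01

    def test_identical_observations_single_component(self):
        x = np.full((50, 2), 3.7)
        post = fit_dpm(x, DPMConfig(truncation_K=8, n_burnin=300, n_samples=1000, seed=0))
        assert post.occupied_count == 1
        occ = post.occupied_components
        assert np.allclose(post.means[occ], 3.7, atol=0.01)

    def test_seed_determinism(self, fast_dpm_config):
        g = np.random.default_rng(8)
        x = np.concatenate([g.normal(0, 1, 60), g.normal(6, 1, 60)])[:, None]
        a = fit_dpm(x, fast_dpm_config)
        b = fit_dpm(x, DPMConfig(truncation_K=8, n_burnin=200, n_samples=800, seed=7))
        assert np.array_equal(a.allocation_probs, b.allocation_probs)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.alpha_trace, b.alpha_trace)

    def test_finite_mixture_oracle(self):
        """With alpha fixed tiny and K at the true component count, posterior
        means agree with an EM Gaussian-mixture fit (well-separated case)."""
        from sklearn.mixture import GaussianMixture

        g = np.random.default_rng(9)
        x = np.concatenate([g.normal(-4, 1, 150), g.normal(4, 1, 150)])[:, None]
        post = fit_dpm(
            x,
            DPMConfig(
                truncation_K=2, n_burnin=400, n_samples=1500, fixed_alpha=0.01, seed=9
            ),
        )
        em = GaussianMixture(2, covariance_type="diag", n_init=3, random_state=0).fit(x)
        dpm_means = np.sort(post.means[post.occupied_components].ravel())
        em_means = np.sort(em.means_.ravel())
        assert np.allclose(dpm_means, em_means, atol=0.1)

    def test_nonfinite_data_rejected(self, fast_dpm_config):
        with pytest.raises(ValueError, match="finite"):
            fit_dpm(np.array([[1.0], [np.nan]]), fast_dpm_config)


class TestFFQMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match=">= 0"):
            FFQMatrix(np.array([[-1.0] * 12]))
        with pytest.raises(ValueError, match="group names"):
            FFQMatrix(np.ones((3, 4)))
        m = FFQMatrix(np.ones((3, 2)), ("a", "b"))
        assert m.n == 3 and m.d == 2
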