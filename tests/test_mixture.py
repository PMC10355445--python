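"""Mixture-CDF decomposition: empirical CDF, model CDF, fitting, fold change."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr

import origamiqc as oq
from origamiqc.mixture import MixtureFit, MixtureParams


def normal_map(seed, n=10_000, mu=0.0, sd=1.0, shape=(100, 100)):
    rng = np.random.default_rng(seed)
    return oq.HeightMap(rng.normal(mu, sd, n).reshape(shape), 1.0)


class TestEmpiricalCDF:
    def test_rank_over_n(self):
        arr = np.repeat([1.0, 2.0, 3.0], 40).reshape(40, 3, order="F")
        ecdf = oq.empirical_cdf(oq.HeightMap(arr, 1.0))
        assert list(ecdf.z_sorted) == [1.0, 2.0, 3.0]
        assert ecdf.F[1] == pytest.approx(2 / 3)
        assert ecdf.F[-1] == 1.0

    def test_ties_collapse_to_single_point(self):
        ecdf = oq.empirical_cdf(oq.HeightMap(np.full((10, 10), 5.0), 1.0))
        assert len(ecdf.z_sorted) == 1
        assert (ecdf.z_sorted[0], ecdf.F[0]) == (5.0, 1.0)

    def test_dkw_agreement_with_normal_cdf(self):
        # Dvoretzky-Kiefer-Wolfowitz: sup|F_n - Phi| < 0.02 fails with
        # probability 2*exp(-2*n*eps^2) ~ 7e-4 at n=10,000; seed fixed
        ecdf = oq.empirical_cdf(normal_map(seed=0))
        assert np.max(np.abs(ecdf.F - ndtr(ecdf.z_sorted))) < 0.02

    def test_refuses_tiny_maps(self):
        with pytest.raises(ValueError, match="refusing"):
            oq.empirical_cdf(oq.HeightMap(np.zeros((9, 9)), 1.0))

    def test_subsampling_is_seeded(self):
        hm = normal_map(seed=1, n=40_000, shape=(200, 200))
        a = oq.empirical_cdf(hm, max_points=5000, seed=3)
        b = oq.empirical_cdf(hm, max_points=5000, seed=3)
        assert np.array_equal(a.z_sorted, b.z_sorted)


class TestModelCDF:
    def test_single_component_symmetry(self):
        p = MixtureParams(1, 0, 0, 0, 0, 0, 1, 1, 1)
        assert oq.model_cdf(p, 0.0) == pytest.approx(0.5)

    def test_normalisation_at_infinity(self):
        p = MixtureParams(0.2, 0.3, 0.5, 0, 1, 2, 0.5, 0.5, 0.5)
        assert oq.model_cdf(p, np.inf) == pytest.approx(1.0)
        assert oq.model_cdf(p, -np.inf) == pytest.approx(0.0)

    def test_two_equal_components_cross_at_midpoint(self):
        # Phi(1) + Phi(-1) = 1, halved and summed -> 0.5 at z = 1
        p = MixtureParams(0.5, 0.5, 0.0, 0.0, 2.0, 2.0, 1.0, 1.0, 1.0)
        assert oq.model_cdf(p, 1.0) == pytest.approx(0.5)

    @given(st.integers(0, 10_000))
    def test_monotone_in_z_for_random_params(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet([1, 1, 1])
        mu = np.sort(rng.uniform(-5, 5, 3))
        sigma = rng.uniform(0.05, 3.0, 3)
        p = MixtureParams.from_components(raw, mu, sigma)
        z = np.linspace(-10, 10, 200)
        f = oq.model_cdf(p, z)
        assert np.all(np.diff(f) >= -1e-12)


class TestFitting:
    def test_recovers_known_fractions(self, separated_scene):
        spec, hm, truth = separated_scene
        fit = oq.fit_height_mixture(hm, n_restarts=3, seed=0)
        assert fit.converged
        assert np.allclose(fit.params.fractions, truth.pixel_fractions, atol=0.03)

    def test_fraction_constraints_always_hold(self, separated_scene):
        _, hm, _ = separated_scene
        fit = oq.fit_height_mixture(hm, n_restarts=2, seed=1)
        p = fit.params.fractions
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(fit.params.sigmas > 0)

    def test_single_population_limit(self):
        fit = oq.fit_height_mixture(normal_map(seed=5, sd=0.1), n_restarts=3, seed=0)
        assert fit.params.p_mica == pytest.approx(1.0, abs=0.02)

    def test_init_permutation_invariance(self, separated_scene):
        # from_components canonicalises the label order, so permuted
        # component triples produce the same starting point and fit
        _, hm, _ = separated_scene
        a = MixtureParams.from_components([0.6, 0.3, 0.1], [0.0, 1.0, 3.0],
                                          [0.2, 0.3, 0.4])
        b = MixtureParams.from_components([0.1, 0.6, 0.3], [3.0, 0.0, 1.0],
                                          [0.4, 0.2, 0.3])
        fit_a = oq.fit_height_mixture(hm, init=a, n_restarts=1, seed=0)
        fit_b = oq.fit_height_mixture(hm, init=b, n_restarts=1, seed=0)
        assert np.allclose(fit_a.params.fractions, fit_b.params.fractions)
        assert np.allclose(fit_a.params.means, fit_b.params.means)

    def test_degenerate_constant_map_refused(self):
        with pytest.raises(ValueError, match="degenerate"):
            oq.fit_height_mixture(oq.HeightMap(np.full((50, 50), 2.0), 1.0))

    def test_grid_search_oracle_two_component(self):
        # brute-force lattice search on a 2-component sample as an
        # independent check of the least-squares CDF fit
        rng = np.random.default_rng(11)
        n = 3000
        z = np.concatenate([rng.normal(0.0, 0.2, 1800), rng.normal(2.0, 0.4, 1200)])
        rng.shuffle(z)
        fit = oq.fit_height_mixture(oq.HeightMap(z.reshape(60, 50), 1.0),
                                    n_restarts=3, seed=0)
        zs = np.sort(z)
        F = np.arange(1, n + 1) / n
        best_p, best_sse = None, np.inf
        for p1 in np.arange(0.1, 0.95, 0.05):
            for m1 in np.arange(-0.4, 0.45, 0.2):
                for m2 in np.arange(1.6, 2.45, 0.2):
                    for s1 in (0.1, 0.2, 0.3):
                        for s2 in (0.3, 0.4, 0.5):
                            model = p1 * ndtr((zs - m1) / s1) \
                                + (1 - p1) * ndtr((zs - m2) / s2)
                            sse = np.sum((model - F) ** 2)
                            if sse < best_sse:
                                best_p, best_sse = (p1, m1, m2), sse
        # merge the 3 fitted components onto the 2 oracle means
        p_low = sum(pk for pk, mk in zip(fit.params.fractions, fit.params.means)
                    if abs(mk - best_p[1]) < abs(mk - best_p[2]))
        assert p_low == pytest.approx(best_p[0], abs=0.05)

    def test_mixture_fit_json_roundtrip(self, separated_scene):
        _, hm, _ = separated_scene
        fit = oq.fit_height_mixture(hm, n_restarts=1, seed=0)
        again = MixtureFit.from_json(fit.to_json())
        assert again.params == fit.params
        assert again.objective == fit.objective


class TestStapleReduction:
    @staticmethod
    def fit_with_p_staple(p_staple, p_mica=None):
        p_mica = (1 - p_staple) * 0.9 if p_mica is None else p_mica
        params = MixtureParams.from_components(
            [p_mica, p_staple, 1 - p_mica - p_staple], [0.0, 0.5, 2.0],
            [0.15, 0.3, 0.5])
        return MixtureFit(params=params, objective=0.0, n_pixels=10_000,
                          converged=True, n_restarts_used=1)

    def test_reported_fold_change(self):
        fold = oq.staple_reduction(self.fit_with_p_staple(0.62),
                                   self.fit_with_p_staple(0.29))
        assert fold == pytest.approx(2.138, abs=0.001)
        assert oq.round_sig(fold, 3) == 2.14

    def test_identity_and_halving(self):
        f = self.fit_with_p_staple(0.5)
        assert oq.staple_reduction(f, f) == 1.0
        assert oq.staple_reduction(self.fit_with_p_staple(0.50),
                                   self.fit_with_p_staple(0.25)) == pytest.approx(2.0)

    def test_zero_denominator_rejected(self):
        params = MixtureParams(0.9, 0.0, 0.1, 0.0, 0.5, 2.0, 0.15, 0.3, 0.5)
        empty_staple = MixtureFit(params=params, objective=0.0, n_pixels=10_000,
                                  converged=True, n_restarts_used=1)
        with pytest.raises(ValueError, match="zero"):
            oq.staple_reduction(self.fit_with_p_staple(0.5), empty_staple)

    def test_unconverged_fit_rejected(self):
        bad = self.fit_with_p_staple(0.5)
        bad.converged = False
        with pytest.raises(ValueError, match="converge"):
            oq.staple_reduction(bad, self.fit_with_p_staple(0.25))
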