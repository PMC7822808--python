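"""Duality-kernel backends, stationary density, Z and the MCMC sampler."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, special

import cwfdual as cw
from cwfdual.kernels import (
    I_series_2x2,
    Kummer1LocusKernel,
    NoMutationKernel,
    PIMQuadratureKernel,
    Series2x2Kernel,
    log_unnormalized_density,
    make_kernel,
    normalising_constant,
    sample_stationary,
)


def _counts_up_to(mtot, smax, min_entry=0):
    for c in itertools.product(range(min_entry, smax + 1), repeat=mtot):
        if 1 <= sum(c) <= smax:
            yield c


@pytest.fixture(scope="module")
def theta0_3allele():
    return cw.random_model(1, (3,), "no_mutation", seed=0)


class TestNoMutationKernel:

    def test_beta_product_small_values(self):
        spec = cw.random_model(1, (2,), "no_mutation", seed=0)
        kern = NoMutationKernel(spec)
        assert kern.k([2, 1]) == pytest.approx(0.5)  # G(2)G(1)/G(3)
        spec3 = cw.random_model(1, (4,), "no_mutation", seed=0)
        kern3 = NoMutationKernel(spec3)
        # all-ones vector: 1/(M-1)!
        assert kern3.k([1, 1, 1, 1]) == pytest.approx(1.0 / math.factorial(3))

    def test_coalescence_ratio_identity(self):
        """k(n - e_i)/k(n) = (n^(l)-1)/(n_i-1); at n = (3,2), i = 1 the
        ratio is (5-1)/(3-1) = 2."""
        spec = cw.random_model(1, (2,), "no_mutation", seed=0)
        kern = NoMutationKernel(spec)
        assert kern.k([2, 2]) / kern.k([3, 2]) == pytest.approx(2.0)
        assert kern.ratio([3, 2], [2, 2]) == pytest.approx(2.0)

    def test_zero_entry_rejected(self, theta0_3allele):
        spec = theta0_3allele
        kern = NoMutationKernel(spec)
        with pytest.raises(ValueError, match="zero entries"):
            kern.k([2, 0, 1])

    def test_exact_ratios_handle_boundary_counts(self, theta0_3allele):
        spec = theta0_3allele
        kern = NoMutationKernel(spec)
        # adding a lineage of a type currently absent: ratio 0
        assert kern.ratio([2, 0, 1], [2, 1, 1]) == 0.0
        # removing the last lineage of a type: ratio diverges
        assert kern.ratio([2, 1, 1], [2, 0, 1]) == math.inf
        # within the all-positive domain, matches log-space evaluation
        r = kern.ratio([2, 1, 1], [3, 1, 1])
        assert r == pytest.approx(math.exp(kern.log_k([3, 1, 1]) - kern.log_k([2, 1, 1])))

    def test_duality_F_zero_after_type_loss(self, theta0_3allele):
        spec = theta0_3allele
        kern = NoMutationKernel(spec)
        assert kern.duality_F(np.array([0.2, 0.3, 0.5]), np.array([1, 0, 2])) == 0.0


class TestPIMQuadrature:
    def test_k_at_zero_is_one(self, fig1_quad_kernel):
        assert fig1_quad_kernel.k([0, 0, 0, 0]) == 1.0

    def test_neutral_model_matches_dirichlet_moments(self):
        """With h = 0, J = 0 the kernel is a product of Dirichlet moments
        B(n + 2u)/B(2u)."""
        spec = cw.ModelSpec(M=(2, 2), h=None, J=None, pim_u=[[0.4, 0.7], [0.9, 0.2]])
        kern = PIMQuadratureKernel(spec)
        for n in _counts_up_to(4, 4):
            expect = 1.0
            for l in range(2):
                a = 2.0 * spec.pim_rates(l)
                nb = np.asarray(n)[spec.block_slice(l)]
                expect *= math.exp(
                    float(special.betaln(*(a + nb)) - special.betaln(*a))
                )
            assert kern.k(n) == pytest.approx(expect, rel=1e-9)

    def test_monotone_decreasing_in_each_count(self, fig1_quad_kernel):
        for n in [(0, 0, 0, 0), (1, 0, 1, 0), (2, 1, 1, 1)]:
            base = fig1_quad_kernel.k(n)
            for i in range(4):
                up = list(n)
                up[i] += 1
                assert fig1_quad_kernel.k(up) < base

    def test_cache_returns_bit_identical_values(self, fig1_quad_kernel):
        a = fig1_quad_kernel.k([2, 1, 0, 3])
        b = fig1_quad_kernel.k([2, 1, 0, 3])
        assert a == b

    def test_mc_path_for_three_allele_locus(self):
        """Dirichlet importance sampling agrees with the separable closed
        form on a neutral 3-allele model and reports a positive SE."""
        spec = cw.ModelSpec(M=(3,), h=None, J=None, pim_u=[[0.4, 0.6, 0.8]])
        kern = PIMQuadratureKernel(spec, mc_draws=100_000, seed=1)
        a = 2.0 * spec.pim_rates(0)
        n = np.array([2, 1, 0])
        expect = math.exp(
            float(
                np.sum(special.gammaln(a + n))
                - special.gammaln((a + n).sum())
                - np.sum(special.gammaln(a))
                + special.gammaln(a.sum())
            )
        )
        se = kern.se(n)
        assert se > 0
        assert abs(kern.k(n) - expect) <= 3 * max(se, 1e-12)


class TestKummer1Locus:
    def test_equal_h_reduces_to_beta_moments(self):
        spec = cw.ModelSpec(M=(2,), h=[0.5, 0.5], J=None, pim_u=[[0.5, 0.5]])
        kern = Kummer1LocusKernel(spec)
        # u1 = u2 = 0.5, h1 = h2: k(n) = B(n1+1, n2+1)/B(1,1)
        assert kern.k([1, 0]) == pytest.approx(0.5)
        assert kern.k([1, 1]) == pytest.approx(1.0 / 6.0)

    def test_matches_quadrature_on_random_parameters(self, one_locus_pim):
        kk = Kummer1LocusKernel(one_locus_pim)
        kq = PIMQuadratureKernel(one_locus_pim)
        for n in _counts_up_to(2, 6):
            assert kk.k(n) == pytest.approx(kq.k(n), rel=1e-8)

    def test_wrong_shape_rejected(self, fig1_coupled):
        with pytest.raises(ValueError, match="L = 1"):
            Kummer1LocusKernel(fig1_coupled)


class TestSeries2x2:
    def test_separable_case_is_product_of_betas(self):
        v = I_series_2x2(1.6, 1.6, 1.6, 1.6, 0.0, 0.0)
        expect = special.beta(1.6, 1.6) ** 2
        assert v == expect  # exact: single term, same Beta evaluations

    def test_matches_adaptive_quadrature_at_coupled_parameters(self):
        """I(1.6, 1.6, 1.6, 1.6) with J1 = J2 = 2 against dblquad."""

        def f(y, x):
            return (
                x**0.6
                * (1 - x) ** 0.6
                * y**0.6
                * (1 - y) ** 0.6
                * math.exp(2 * (2 * x * y + 2 * (1 - x) * (1 - y)))
            )

        quad, _ = integrate.dblquad(f, 0, 1, 0, 1, epsabs=1e-12, epsrel=1e-12)
        assert I_series_2x2(1.6, 1.6, 1.6, 1.6, 2.0, 2.0) == pytest.approx(
            quad, rel=1e-6
        )

    def test_reflection_symmetry(self):
        """x -> 1-x, y -> 1-y swaps (a1,a2),(b1,b2) and (J1,J2)."""
        a = I_series_2x2(1.3, 0.8, 2.1, 0.9, 1.5, 0.7)
        b = I_series_2x2(0.8, 1.3, 0.9, 2.1, 0.7, 1.5)
        assert a == pytest.approx(b, rel=1e-10)

    def test_kernel_matches_quadrature_backend(
        self, fig1_series_kernel, fig1_quad_kernel
    ):
        for n in _counts_up_to(4, 5):
            assert fig1_series_kernel.k(n) == pytest.approx(
                fig1_quad_kernel.k(n), rel=1e-8
            )

    def test_tightening_tolerance_is_stable(self, fig1_coupled):
        loose = Series2x2Kernel(fig1_coupled, tol=1e-8)
        tight = Series2x2Kernel(fig1_coupled, tol=1e-14)
        assert loose.k([2, 1, 1, 2]) == pytest.approx(tight.k([2, 1, 1, 2]), rel=1e-7)

    def test_wrong_coupling_shape_rejected(self):
        J = np.zeros((4, 4))
        J[0, 2] = J[2, 0] = 1.0
        J[0, 3] = J[3, 0] = 0.5  # off-diagonal coupling entry
        spec = cw.ModelSpec(M=(2, 2), h=None, J=J, pim_u=[[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValueError, match="diagonal coupling"):
            Series2x2Kernel(spec)


class TestMakeKernel:
    def test_auto_selects_by_model_shape(self, fig1_coupled, one_locus_pim):
        assert make_kernel(fig1_coupled).backend == "series_2x2"
        assert make_kernel(one_locus_pim).backend == "kummer_1locus"
        spec0 = cw.random_model(2, (2, 2), "no_mutation", seed=0)
        assert make_kernel(spec0).backend == "no_mutation"
        spec_g = cw.random_model(2, (2, 2), "pim_selection", seed=0)
        assert make_kernel(spec_g).backend == "pim_quadrature"

    def test_mixed_mutation_regime_rejected(self):
        spec = cw.ModelSpec(
            M=(2, 2),
            h=None,
            J=None,
            theta=[1.0, 0.0],
            P=[np.full((2, 2), 0.5), np.eye(2)],
        )
        with pytest.raises(ValueError, match="mixed"):
            make_kernel(spec)


class TestStationaryDensity:
    def test_uniform_dirichlet_gives_zero_log_density(self):
        spec = cw.ModelSpec(M=(2,), h=None, J=None, pim_u=[[0.5, 0.5]])
        assert log_unnormalized_density(spec, [0.37]) == pytest.approx(0.0)

    def test_coupled_model_term_by_term(self, fig1_coupled):
        """At xbar = (0.5, 0.5): log p + log Z = 0.6 * 4 log(1/2) + 2 V."""
        got = log_unnormalized_density(fig1_coupled, [0.5, 0.5])
        expect = (2 * 0.8 - 1) * 4 * math.log(0.5) + 2 * (2 * 0.25 + 2 * 0.25)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_label_swap_symmetry(self, fig1_coupled, rng):
        for _ in range(10):
            x, y = rng.uniform(0.05, 0.95, size=2)
            a = log_unnormalized_density(fig1_coupled, [x, y])
            b = log_unnormalized_density(fig1_coupled, [1 - x, 1 - y])
            assert a == pytest.approx(b, rel=1e-12)


class TestNormalisingConstant:
    def test_one_locus_kummer_formula(self, one_locus_pim):
        u = one_locus_pim.pim_rates(0)
        h1, h2 = one_locus_pim.h
        expect = (
            math.exp(2 * h2)
            * special.beta(2 * u[0], 2 * u[1])
            * float(special.hyp1f1(2 * u[0], 2 * u[0] + 2 * u[1], 2 * (h1 - h2)))
        )
        assert normalising_constant(one_locus_pim) == pytest.approx(expect, rel=1e-12)

    def test_equal_h_is_scaled_beta(self):
        spec = cw.ModelSpec(M=(2,), h=[0.5, 0.5], J=None, pim_u=[[0.4, 0.9]])
        expect = math.exp(1.0) * special.beta(0.8, 1.8)
        assert normalising_constant(spec) == pytest.approx(expect, rel=1e-12)

    def test_neutral_is_product_of_multivariate_betas(self):
        spec = cw.ModelSpec(M=(2, 3), h=None, J=None, pim_u=[[0.4, 0.7], [0.3, 0.5, 0.9]])
        expect = 1.0
        for l in range(2):
            a = 2.0 * spec.pim_rates(l)
            expect *= math.exp(
                float(np.sum(special.gammaln(a)) - special.gammaln(a.sum()))
            )
        got = normalising_constant(spec, method="mc", mc_draws=200_000, seed=3)
        assert got == pytest.approx(expect, rel=5e-3)

    def test_series_agrees_with_quadrature(self, fig1_coupled):
        zs = normalising_constant(fig1_coupled, method="series_2x2")
        zq = normalising_constant(fig1_coupled, method="quadrature")
        assert zs == pytest.approx(zq, rel=1e-6)


class TestStationarySampler:
    def test_neutral_draws_match_dirichlet_moments(self, fig1_independent):
        draws = sample_stationary(fig1_independent, 6000, seed=5)
        # Dirichlet(1.6, 1.6): mean 0.5, var = .25/(3.2+1)
        for col in (0, 2):
            m = draws[:, col].mean()
            se = draws[:, col].std(ddof=1) / math.sqrt(len(draws))
            # thinning leaves autocorrelation; allow 5 nominal SEs
            assert abs(m - 0.5) <= 5 * se
        var = draws[:, 0].var(ddof=1)
        assert var == pytest.approx(0.25 / 4.2, rel=0.15)

    def test_coupling_concentrates_corner_mass(self, fig1_coupled, fig1_independent):
        """Selection J = 2 moves stationary mass toward (0,0) and (1,1)."""

        def corner(d):
            both_low = (d[:, 0] < 0.25) & (d[:, 2] < 0.25)
            both_high = (d[:, 0] > 0.75) & (d[:, 2] > 0.75)
            return np.mean(both_low) + np.mean(both_high)

        d0 = sample_stationary(fig1_independent, 6000, seed=11)
        d2 = sample_stationary(fig1_coupled, 6000, seed=11)
        assert corner(d2) > corner(d0)

    def test_chains_reproducible_under_seed(self, fig1_coupled):
        a = sample_stationary(fig1_coupled, 500, seed=3)
        b = sample_stationary(fig1_coupled, 500, seed=3)
        assert np.array_equal(a, b)

    def test_moments_reproduce_kernel(self, fig1_coupled, fig1_series_kernel):
        """Empirical monomial means reproduce k(n) within 5 nominal SE for
        small n (thinning keeps some autocorrelation)."""
        draws = sample_stationary(fig1_coupled, 8000, seed=21)
        for n in [(1, 0, 0, 0), (1, 0, 1, 0), (2, 0, 0, 1)]:
            mono = np.prod(draws ** np.asarray(n), axis=1)
            se = mono.std(ddof=1) / math.sqrt(len(mono))
            assert abs(mono.mean() - fig1_series_kernel.k(n)) <= 5 * se
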