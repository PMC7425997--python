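import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import chisquare

from flexdegree.degree_models import (DegreeModel, Family, conditional_pmf,
                                      fixed_weight_normalizer, log_z_bounded,
                                      marginal_pmf, pmf_binomial, pmf_bounded,
                                      pmf_fixed, sample_degree)


def ztp_terms(x, kmax=300):
    K = np.arange(1, kmax + 1)
    return np.exp(K * np.log(x) - gammaln(K + 1.0))


class TestBoundedFamily:
    def test_closed_form_values(self):
        assert pmf_bounded(1, 1.0, 1.0) == pytest.approx(1 / (math.e - 1), rel=1e-12)
        assert pmf_bounded(3, 1.0, 2.0) == pytest.approx(8 / (6 * (math.e**2 - 1)), rel=1e-12)

    def test_vanishing_budget_limit_is_point_mass_at_one(self):
        assert pmf_bounded(1, 0.0, 5.0) == 1.0
        assert pmf_bounded(2, 0.0, 5.0) == 0.0
        assert pmf_bounded(1, 1e-12, 5.0) == pytest.approx(1.0, abs=1e-10)

    def test_matches_term_by_term_summation(self):
        # independent oracle: normalize the raw simplex-volume terms directly
        x = 2.0
        t = ztp_terms(x)
        for K in (1, 2, 3, 10):
            assert pmf_bounded(K, 1.0, x) == pytest.approx(t[K - 1] / t.sum(), rel=1e-10)

    @pytest.mark.parametrize("x", [0.1, 0.5, 1.0, 5.0, 20.0, 50.0])
    def test_normalizer_equals_expm1(self, x):
        assert log_z_bounded(x) == pytest.approx(math.log(math.expm1(x)), rel=1e-10)
        assert abs(math.log(ztp_terms(x).sum()) - log_z_bounded(x)) < 1e-10

    @pytest.mark.parametrize("x", [0.5, 1.0, 2.0, 5.0, 10.0, 50.0])
    def test_mode_matches_brute_force(self, x):
        K = np.arange(1, 200)
        brute = K[np.argmax(pmf_bounded(K, 1.0, x))]
        pmf = conditional_pmf(DegreeModel(Family.BOUNDED_VOLUME, alpha=1.0), x)
        assert pmf.support[np.argmax(pmf.probs)] == brute

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            pmf_bounded(1, -1.0, 2.0)
        with pytest.raises(ValueError):
            pmf_bounded(0, 1.0, 2.0)


class TestFixedFamily:
    def test_euclidean_value_against_direct_summation(self):
        # 1/Z_A with Z_A = sum_{K>=1} sqrt(K)/(K-1)! at x = 1
        K = np.arange(1, 200)
        Z = np.sum(np.sqrt(K) * np.exp(-gammaln(K)))
        assert pmf_fixed(1, 1.0, 1.0) == pytest.approx(1 / Z, rel=1e-9)
        assert pmf_fixed(1, 1.0, 1.0) == pytest.approx(0.2680, abs=5e-5)

    def test_manhattan_normalizer_is_closed_form(self):
        # Z_1(x) = sum K x^{K-1}/(K-1)! = (1 + x) e^x; at x=1 -> 2e
        assert pmf_fixed(2, 1.0, 1.0, "manhattan") == pytest.approx(2 / (2 * math.e), rel=1e-10)
        for x in (0.3, 1.0, 7.0, 40.0):
            lz, tail = fixed_weight_normalizer(x, "manhattan")
            assert lz == pytest.approx(math.log1p(x) + x, rel=1e-10)
            assert tail < 1e-12

    def test_point_mass_limit_and_unit_area_anchor(self):
        # A(1) = 1 in both norms, so the x -> 0 limit puts all mass on K = 1
        for norm in ("euclidean", "manhattan"):
            assert pmf_fixed(1, 0.0, 5.0, norm) == 1.0
            assert pmf_fixed(1, 1e-9, 5.0, norm) == pytest.approx(1.0, abs=1e-7)

    def test_truncation_bound_out_of_support(self):
        with pytest.raises(ValueError):
            pmf_fixed(51, 1.0, 10.0, K_max=50)


class TestBinomialFamily:
    def test_truncation_forces_the_only_outcome(self):
        assert pmf_binomial(1, 1, 0.3) == pytest.approx(1.0)
        assert pmf_binomial(4, 4, 1.0) == 1.0

    def test_value_against_wiring_enumeration(self):
        # enumerate all 2^4 wiring outcomes for N=4, q=1/2 and condition on K>=1
        from itertools import product
        hits = sum(1 for w in product([0, 1], repeat=4) if sum(w) == 2)
        total = sum(1 for w in product([0, 1], repeat=4) if sum(w) >= 1)
        assert pmf_binomial(2, 4, 0.5) == pytest.approx(hits / total, rel=1e-12)
        assert pmf_binomial(2, 4, 0.5) == pytest.approx(0.4, rel=1e-12)

    def test_support_and_domain(self):
        assert pmf_binomial(5, 4, 0.5) == 0.0
        with pytest.raises(ValueError):
            pmf_binomial(2, 4, 0.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(alpha=st.floats(0.01, 2.0), sbar=st.integers(1, 300),
       family=st.sampled_from([Family.BOUNDED_VOLUME, Family.FIXED_AREA,
                               Family.FIXED_AREA_1NORM]))
def test_conditional_pmfs_are_normalized(alpha, sbar, family):
    pmf = conditional_pmf(DegreeModel(family, alpha=alpha), float(sbar))
    assert 1 - 1e-9 <= pmf.probs.sum() <= 1 + 1e-9
    assert np.all(pmf.probs >= 0)


class TestMarginal:
    def test_constant_synapse_counts_reduce_to_conditional(self):
        model = DegreeModel(Family.BOUNDED_VOLUME, alpha=0.5)
        marg = marginal_pmf(model, [20, 20, 20])
        cond = conditional_pmf(model, 20.0, K_max=len(marg.probs))
        np.testing.assert_allclose(marg.probs, cond.probs, rtol=1e-12)

    def test_two_point_mixture_is_elementwise_average(self):
        model = DegreeModel(Family.BOUNDED_VOLUME, alpha=1.0)
        marg = marginal_pmf(model, [1, 2])
        expected = 0.5 * (1 / (math.e - 1) + 2 / (math.e**2 - 1))
        assert marg.prob(1) == pytest.approx(expected, rel=1e-9)
        assert marg.prob(1) == pytest.approx(0.4475, abs=5e-5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            marginal_pmf(DegreeModel(Family.BOUNDED_VOLUME, alpha=1.0), [])


class TestSampler:
    def test_empirical_frequencies_match_pmf(self, rng):
        model = DegreeModel(Family.BOUNDED_VOLUME, alpha=0.5)
        sbar, n = 10.0, 100_000
        draws = np.array([sample_degree(model, sbar, rng) for _ in range(n)])
        pmf = conditional_pmf(model, sbar)
        for K in range(1, 13):
            p = pmf.prob(K)
            obs = np.mean(draws == K)
            assert abs(obs - p) <= 4 * math.sqrt(p * (1 - p) / n) + 1e-12

    def test_degenerate_cases(self, rng):
        assert sample_degree(DegreeModel(Family.BINOMIAL, N=7, q=1.0), None, rng) == 7
        model = DegreeModel(Family.FIXED_AREA, alpha=0.0)
        assert sample_degree(model, 50.0, rng) == 1

    def test_chi_square_goodness_of_fit(self):
        # one seeded draw per family; pooled tail bins keep expected counts > 5
        cases = [
            (DegreeModel(Family.BOUNDED_VOLUME, alpha=0.25), 40.0),
            (DegreeModel(Family.FIXED_AREA, alpha=0.25), 40.0),
            (DegreeModel(Family.FIXED_AREA_1NORM, alpha=0.25), 40.0),
            (DegreeModel(Family.BINOMIAL, N=100, q=0.08), None),
        ]
        n = 20_000
        for i, (model, sbar) in enumerate(cases):
            rng = np.random.default_rng(1000 + i)
            draws = np.array([sample_degree(model, sbar, rng) for _ in range(n)])
            pmf = conditional_pmf(model, sbar)
            expected = pmf.probs * n
            keep = expected >= 5
            f_obs = np.array([np.sum(draws == k) for k in pmf.support[keep]])
            f_obs = np.append(f_obs, n - f_obs.sum())
            f_exp = np.append(expected[keep], max(n - expected[keep].sum(), 1e-9))
            stat, p = chisquare(f_obs, f_exp * (f_obs.sum() / f_exp.sum()))
            assert p > 0.01, f"{model.family}: chi-square p={p}"
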