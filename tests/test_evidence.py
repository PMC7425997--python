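import math

import numpy as np
import pytest
from scipy.special import gammaln

from conftest import make_records
from flexdegree.constraint_geometry import Norm
from flexdegree.degree_models import Family, fixed_weight_normalizer
from flexdegree.evidence import (EvidenceResult, fit_alpha_bounded, fit_alpha_fixed,
                                 fit_q_binomial, log_curvature_envelope,
                                 log_evidence_flat, log_evidence_jeffreys, log_odds,
                                 loglik_binomial, loglik_bounded, loglik_fixed,
                                 quadrature_evidence_oracle)
from flexdegree.synthetic_data import larva_like_config, generate_records


def synthetic(family, n, seed, **kw):
    return generate_records(larva_like_config(family=family, n_neurons=n, seed=seed, **kw))


class TestBoundedFit:
    def test_single_record_against_grid_search(self):
        recs = make_records([5], [10])
        fit = fit_alpha_bounded(recs)
        grid = np.linspace(1e-4, 2.0, 200_001)
        ll = [loglik_bounded(np.array([5.0]), np.array([10.0]), a) for a in grid]
        assert fit.point_estimate == pytest.approx(grid[int(np.argmax(ll))], abs=1e-5)
        assert fit.point_estimate == pytest.approx(0.4965, abs=1e-4)

    def test_all_degree_one_is_boundary_degenerate(self):
        fit = fit_alpha_bounded(make_records([1, 1, 1], [5, 9, 3]))
        assert fit.degenerate and fit.point_estimate == 0.0

    def test_large_rate_limit_recovers_poisson_mle(self):
        # truncation correction vanishes: alpha_hat -> sum K / sum S
        K = [40, 55, 61, 47]
        S = [100, 140, 150, 120]
        fit = fit_alpha_bounded(make_records(K, S))
        assert fit.point_estimate == pytest.approx(sum(K) / sum(S), rel=1e-6)


class TestFixedFit:
    def test_analytic_bracket_example(self):
        fit = fit_alpha_fixed(make_records([3, 5], [10, 20]))
        assert fit.bracket == (0.1, 0.2)
        assert 0.1 < fit.point_estimate < 0.2

    def test_single_degree_one_record_collapses_to_zero(self):
        fit = fit_alpha_fixed(make_records([1], [37]))
        assert fit.degenerate and fit.point_estimate == 0.0

    def test_parameter_recovery_at_known_alpha(self):
        recs = synthetic(Family.FIXED_AREA, 1000, seed=11, alpha=0.25)
        fit = fit_alpha_fixed(recs)
        assert 0.24 <= fit.point_estimate <= 0.26

    @pytest.mark.parametrize("norm", [Norm.EUCLIDEAN, Norm.MANHATTAN])
    def test_mle_maximizes_the_likelihood_locally(self, norm):
        recs = synthetic(Family.FIXED_AREA, 60, seed=5, alpha=0.3)
        K = np.array([r.degree for r in recs], float)
        S = np.array([r.total_synapses for r in recs], float)
        fit = fit_alpha_fixed(recs, norm)
        a = fit.point_estimate
        assert loglik_fixed(K, S, a, norm) >= loglik_fixed(K, S, a * 1.001, norm)
        assert loglik_fixed(K, S, a, norm) >= loglik_fixed(K, S, a * 0.999, norm)
        lo, hi = fit.bracket
        assert lo <= a <= hi

    def test_variance_interval_brackets_exact_curvature(self):
        for seed in range(30):
            recs = synthetic(Family.FIXED_AREA, 50, seed=seed, alpha=0.2)
            fit = fit_alpha_fixed(recs)
            assert fit.sigma2_lower <= fit.sigma2 <= fit.sigma2_upper


def test_normalizer_log_curvature_envelope_is_certified():
    # d^2 ln Z/dx^2 is non-positive and above the analytic envelope, both norms
    xs = np.concatenate([np.linspace(1e-3, 3, 80), np.geomspace(3, 500, 60)])
    for norm in (Norm.EUCLIDEAN, Norm.MANHATTAN):
        _, _, m1, v = fixed_weight_normalizer(xs, norm, with_moments=True)
        h = v / xs**2
        assert np.all(h <= 1e-12)
        assert np.all(h >= log_curvature_envelope(xs, norm) - 1e-12)
        # the MLE bracket rests on x < x * dlnZ/dx = m1 < 2x
        assert np.all(m1 > xs) and np.all(m1 < 2 * xs)


class TestBinomialFit:
    def test_against_grid_search_of_truncated_likelihood(self):
        recs = make_records([2] * 50, [10] * 50)
        fit = fit_q_binomial(recs, N=10)
        K = np.full(50, 2.0)
        grid = np.linspace(1e-4, 0.999, 100_001)
        ll = [loglik_binomial(K, 10, q) for q in grid]
        assert fit.point_estimate == pytest.approx(grid[int(np.argmax(ll))], abs=1e-4)
        assert fit.point_estimate == pytest.approx(0.16834, abs=2e-4)

    def test_saturated_and_untruncated_limits(self):
        assert fit_q_binomial(make_records([4, 4], [8, 8]), N=4).point_estimate == 1.0
        # large N with negligible truncation: q_hat -> mean K / N
        recs = make_records([30, 25, 35], [60, 50, 70])
        fit = fit_q_binomial(recs, N=300)
        assert fit.point_estimate == pytest.approx(30 / 300, rel=1e-3)

    def test_degrees_above_N_rejected(self):
        with pytest.raises(ValueError):
            fit_q_binomial(make_records([5], [10]), N=4)


class TestLaplaceEvidence:
    def test_flat_evidence_never_exceeds_gaussian_bound(self):
        for seed in range(5):
            recs = synthetic(Family.BOUNDED_VOLUME, 40, seed=seed, alpha=0.25)
            fit = fit_alpha_bounded(recs)
            ev = log_evidence_flat(fit, recs)
            assert ev.lower <= fit.max_loglik + 0.5 * math.log(2 * math.pi * fit.sigma2) + 1e-12

    def test_sharp_peak_limit(self):
        # theta_hat / sigma >> 1: evidence -> max_loglik + 0.5 ln(2 pi sigma^2)
        recs = synthetic(Family.BOUNDED_VOLUME, 2000, seed=1, alpha=0.5)
        fit = fit_alpha_bounded(recs)
        ev = log_evidence_flat(fit, recs)
        assert ev.lower == pytest.approx(
            fit.max_loglik + 0.5 * math.log(2 * math.pi * fit.sigma2), abs=1e-9)

    def test_flat_evidence_monotone_in_sigma2(self):
        from flexdegree.evidence import _log_flat_integral
        vals = [_log_flat_integral(0.3, s2, None) for s2 in np.geomspace(1e-6, 1.0, 40)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_jeffreys_evidence_monotone_in_sigma2_and_overflow_safe(self):
        from flexdegree.evidence import _log_jeffreys_integral
        vals = [_log_jeffreys_integral(0.3, s2) for s2 in np.geomspace(1e-8, 1.0, 40)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        huge_ratio = _log_jeffreys_integral(1.0, 1.0 / 4e6)  # theta^2/(4 s^2) = 1e6
        assert math.isfinite(huge_ratio)


class TestQuadratureOracle:
    def test_single_record_two_integrators_agree(self):
        # int_0^inf (4a)^2 / ((e^{4a} - 1) 2!) da, adaptive vs fine trapezoid
        recs = make_records([2], [4])
        oracle = quadrature_evidence_oracle(Family.BOUNDED_VOLUME, recs, "flat")
        a = np.linspace(1e-9, 30.0, 4_000_001)
        vals = (4 * a) ** 2 / (np.expm1(4 * a) * 2.0)
        trap = math.log(np.trapezoid(vals, a))
        assert oracle == pytest.approx(trap, abs=1e-6)

    @pytest.mark.parametrize("family,fitter", [
        (Family.BOUNDED_VOLUME, fit_alpha_bounded),
        (Family.BINOMIAL, None),
    ])
    def test_laplace_within_half_log_unit_of_oracle(self, family, fitter):
        recs = synthetic(family, 100, seed=2, alpha=0.25, N=300, q=0.05)
        if family is Family.BINOMIAL:
            fit = fit_q_binomial(recs, N=300)
            oracle = quadrature_evidence_oracle(family, recs, "flat", N=300)
        else:
            fit = fitter(recs)
            oracle = quadrature_evidence_oracle(family, recs, "flat")
        ev = log_evidence_flat(fit, recs)
        assert abs(ev.lower - oracle) < 0.5

    def test_jeffreys_closed_form_matches_oracle(self):
        recs = synthetic(Family.BOUNDED_VOLUME, 100, seed=3, alpha=0.25)
        fit = fit_alpha_bounded(recs)
        ev = log_evidence_jeffreys(fit, recs)
        oracle = quadrature_evidence_oracle(Family.BOUNDED_VOLUME, recs, "jeffreys")
        assert abs(ev.lower - oracle) < 0.5

    def test_laplace_gap_shrinks_with_sample_size(self):
        big = synthetic(Family.BOUNDED_VOLUME, 200, seed=4, alpha=0.25)
        gaps = {}
        for n in (20, 200):
            recs = big[:n]
            fit = fit_alpha_bounded(recs)
            ev = log_evidence_flat(fit, recs)
            gaps[n] = abs(ev.lower - quadrature_evidence_oracle(Family.BOUNDED_VOLUME, recs, "flat"))
        assert gaps[200] < gaps[20]

    def test_fixed_family_interval_brackets_oracle(self):
        recs = synthetic(Family.FIXED_AREA, 100, seed=6, alpha=0.25)
        fit = fit_alpha_fixed(recs)
        for prior, ev_fn, oracle in [
            ("flat", log_evidence_flat,
             quadrature_evidence_oracle(Family.FIXED_AREA, recs, "flat")),
            ("jeffreys", log_evidence_jeffreys,
             quadrature_evidence_oracle(Family.FIXED_AREA, recs, "jeffreys")),
        ]:
            ev = ev_fn(fit, recs)
            assert ev.lower <= oracle <= ev.upper, (prior, ev.log_evidence, oracle)

    def test_degenerate_boundary_dataset_still_yields_flat_evidence(self):
        recs = make_records([1, 1], [10, 12])
        fit = fit_alpha_bounded(recs)
        ev = log_evidence_flat(fit, recs)
        assert math.isfinite(ev.lower)
        with pytest.raises(ValueError):
            log_evidence_jeffreys(fit, recs)


class TestLogOdds:
    def test_identical_models_give_zero(self):
        e = EvidenceResult(Family.BOUNDED_VOLUME, "flat", -10.0, 5)
        assert log_odds(e, e).log_odds == 0.0

    def test_unit_log_odds_calibration(self):
        a = EvidenceResult(Family.FIXED_AREA, "flat", -9.0, 5)
        b = EvidenceResult(Family.BINOMIAL, "flat", -10.0, 5)
        L = log_odds(a, b).log_odds
        assert round(math.exp(L), 2) == 2.72
        c = EvidenceResult(Family.BINOMIAL, "flat", -19.0, 5)
        assert math.exp(log_odds(a, c).log_odds) == pytest.approx(22026.47, abs=0.005)

    def test_interval_antisymmetry(self):
        a = EvidenceResult(Family.FIXED_AREA, "flat", (-11.0, -10.5), 5)
        b = EvidenceResult(Family.BINOMIAL, "flat", -12.0, 5)
        ab, ba = log_odds(a, b), log_odds(b, a)
        assert ab.lower == -ba.upper and ab.upper == -ba.lower
        assert ab.lower <= ab.upper

    def test_mismatched_datasets_rejected(self):
        a = EvidenceResult(Family.FIXED_AREA, "flat", -1.0, 5)
        b = EvidenceResult(Family.BINOMIAL, "flat", -1.0, 6)
        with pytest.raises(ValueError):
            log_odds(a, b)
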