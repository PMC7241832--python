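"""Mixture likelihoods, NPML-EM fits and the null random-intercept model.

Likelihood values are checked against brute-force evaluation with
``scipy.stats.binom``; fits are checked against parameter recovery on
simulated data and against an exhaustive grid-search-plus-polish oracle on
tiny instances.
"""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import binom

from asemix.mixture_model import (
    FitControl,
    fit_npml_one,
    fit_npml_two,
    fit_null_one,
    loglik_mixture_one,
    loglik_mixture_two,
)
from asemix.phasing import GeneData, PhasedObservation
from asemix.simulator import SimulationConfig, simulate_gene, simulate_gene_paired


def _gene(obs_spec, paired=False):
    """Build GeneData from (ind, snp, major, total[, cond]) tuples."""
    obs = [
        PhasedObservation(
            individual_id=t[0], snp_id=t[1], major_count=t[2], total_count=t[3],
            major_is_ref=True, condition=t[4] if len(t) > 4 else None,
        )
        for t in obs_spec
    ]
    return GeneData(gene_id="g", observations=obs, paired=paired)


def _brute_loglik_one(pi, mu1, mu2, obs_spec):
    """Direct evaluation of the one-condition mixture likelihood."""
    by_ind = {}
    for ind, snp, m, y in obs_spec:
        by_ind.setdefault(ind, []).append((m, y))
    total = 0.0
    for obs in by_ind.values():
        comp = []
        for p in (expit(mu1), expit(mu2)):
            comp.append(np.prod([binom.pmf(m, y, p) for m, y in obs]))
        total += math.log(pi * comp[0] + (1 - pi) * comp[1])
    return total


def _brute_loglik_two(pi, mu1, b1, mu2, b2, obs_spec):
    by_ind = {}
    for ind, snp, m, y, cond in obs_spec:
        by_ind.setdefault(ind, []).append((m, y, cond))
    total = 0.0
    for obs in by_ind.values():
        comp = []
        for mu, b in ((mu1, b1), (mu2, b2)):
            prod = 1.0
            for m, y, cond in obs:
                p = expit(mu + (b if cond == "B" else 0.0))
                prod *= binom.pmf(m, y, p)
            comp.append(prod)
        total += math.log(pi * comp[0] + (1 - pi) * comp[1])
    return total


class TestLoglikOne:
    def test_single_component_closed_form(self):
        data = _gene([("i1", "s1", 5, 10)])
        assert loglik_mixture_one(1.0, 0.0, 3.0, data) == pytest.approx(
            math.log(0.24609375), abs=1e-12
        )

    def test_equal_mass_points_independent_of_pi(self):
        data = _gene([("i1", "s1", 7, 10), ("i2", "s1", 4, 12)])
        vals = {loglik_mixture_one(pi, 0.4, 0.4, data) for pi in (0.1, 0.5, 0.9)}
        assert max(vals) - min(vals) < 1e-12

    def test_matches_brute_force_on_toy_table(self):
        spec = [
            ("i1", "s1", 8, 10), ("i1", "s2", 6, 12),
            ("i2", "s1", 5, 10), ("i2", "s2", 7, 12),
        ]
        expected = _brute_loglik_one(0.4, 0.8, 0.0, spec)
        assert loglik_mixture_one(0.4, 0.8, 0.0, _gene(spec)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_nonfinite_parameters_raise(self):
        data = _gene([("i1", "s1", 5, 10)])
        with pytest.raises(ValueError):
            loglik_mixture_one(0.5, float("inf"), 0.0, data)


class TestLoglikTwo:
    def test_zero_condition_effect_reduces_to_pooled_one_condition(self):
        spec = [
            ("i1", "s1", 8, 10, "A"), ("i1", "s1", 6, 12, "B"),
            ("i2", "s1", 5, 10, "A"), ("i2", "s1", 9, 12, "B"),
        ]
        data = _gene(spec, paired=True)
        # pooling = dropping the condition label, record by record
        pooled = _gene([(i, f"{s}::{c}", m, y) for i, s, m, y, c in spec])
        lhs = loglik_mixture_two(0.4, 0.8, 0.0, 0.1, 0.0, data)
        rhs = loglik_mixture_one(0.4, 0.8, 0.1, pooled)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_single_component_closed_form(self):
        data = _gene(
            [("i1", "s1", 5, 10, "A"), ("i1", "s1", 5, 10, "B")], paired=True
        )
        assert loglik_mixture_two(1.0, 0.0, 0.0, 1.0, 1.0, data) == pytest.approx(
            2 * math.log(0.24609375), abs=1e-12
        )

    def test_matches_brute_force_on_toy_table(self):
        spec = [
            ("i1", "s1", 8, 10, "A"), ("i1", "s1", 5, 10, "B"),
            ("i2", "s1", 6, 10, "A"), ("i2", "s1", 6, 10, "B"),
        ]
        expected = _brute_loglik_two(0.5, 0.8, -0.3, 0.0, 0.0, spec)
        got = loglik_mixture_two(0.5, 0.8, -0.3, 0.0, 0.0, _gene(spec, paired=True))
        assert got == pytest.approx(expected, abs=1e-10)


def _het_hom_gene(rng, n=200, depth=500, n_snps=4, p_het=0.7, frac_het=0.5):
    """Direct Het/Hom mixture data with known major counts (no phasing)."""
    obs = []
    for i in range(n):
        p = p_het if i < frac_het * n else 0.5
        for j in range(n_snps):
            obs.append(
                (f"i{i:03d}", f"s{j}", int(rng.binomial(depth, p)), depth)
            )
    return _gene(obs)


class TestFitNpmlOne:
    def test_recovery_at_null(self):
        rng = np.random.default_rng(0)
        data = _het_hom_gene(rng, n=300, depth=300, n_snps=2, p_het=0.5)
        fit = fit_npml_one(data)
        assert expit(fit.mu1) == pytest.approx(0.5, abs=0.03)
        assert expit(fit.mu2) == pytest.approx(0.5, abs=0.03)

    def test_recovery_het_hom_mixture(self):
        rng = np.random.default_rng(1)
        data = _het_hom_gene(rng)
        fit = fit_npml_one(data)
        assert expit(fit.mu1) == pytest.approx(0.7, abs=0.02)
        assert expit(fit.mu2) == pytest.approx(0.5, abs=0.02)
        assert fit.pi == pytest.approx(0.5, abs=0.1)

    def test_loglik_self_consistent_and_dominates_grid(self):
        rng = np.random.default_rng(2)
        data = _het_hom_gene(rng, n=8, depth=40, n_snps=2)
        fit = fit_npml_one(data)
        assert fit.loglik == pytest.approx(
            loglik_mixture_one(fit.pi, fit.mu1, fit.mu2, data), abs=1e-8
        )
        for mu1 in np.linspace(-1.5, 1.5, 21):
            for mu2 in np.linspace(-1.5, 1.5, 21):
                for pi in np.linspace(0.05, 0.95, 11):
                    assert fit.loglik >= loglik_mixture_one(pi, mu1, mu2, data) - 1e-9

    def test_em_trace_monotone(self):
        rng = np.random.default_rng(3)
        data = _het_hom_gene(rng, n=30, depth=100, n_snps=2)
        fit = fit_npml_one(data)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_individual_permutation_invariance(self):
        rng = np.random.default_rng(4)
        data = _het_hom_gene(rng, n=20, depth=100, n_snps=2)
        perm = GeneData("g", list(reversed(data.observations)))
        f1, f2 = fit_npml_one(data), fit_npml_one(perm)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-9)
        assert (f1.pi, f1.mu1, f1.mu2) == pytest.approx((f2.pi, f2.mu1, f2.mu2))

    def test_labelling_convention(self):
        rng = np.random.default_rng(5)
        fit = fit_npml_one(_het_hom_gene(rng, n=50, depth=200))
        assert abs(fit.mu1) >= abs(fit.mu2)
        resp = fit.responsibilities
        assert np.all((resp >= 0) & (resp <= 1))
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            fit_npml_one(_gene([("i1", "s1", 5, 10)]))


class TestFitNpmlTwo:
    def _paired_gene(self, rng, p_a, p_b, n=200, depth=500, frac_het=0.5):
        obs = []
        for i in range(n):
            pa, pb = (p_a, p_b) if i < frac_het * n else (0.5, 0.5)
            obs.append((f"i{i:03d}", "s1", int(rng.binomial(depth, pa)), depth, "A"))
            obs.append((f"i{i:03d}", "s1", int(rng.binomial(depth, pb)), depth, "B"))
        return _gene(obs, paired=True)

    def test_no_effect_recovery(self):
        rng = np.random.default_rng(6)
        fit = fit_npml_two(self._paired_gene(rng, 0.7, 0.7))
        assert abs(fit.beta1) < 0.15
        assert abs(fit.beta2) < 0.15

    def test_condition_effect_recovery(self):
        rng = np.random.default_rng(7)
        fit = fit_npml_two(self._paired_gene(rng, 0.65, 0.7))
        assert fit.beta1 == pytest.approx(logit(0.7) - logit(0.65), abs=0.1)

    def test_fitted_loglik_dominates_coarse_grid(self):
        rng = np.random.default_rng(8)
        data = self._paired_gene(rng, 0.6, 0.75, n=10, depth=50)
        fit = fit_npml_two(data)
        assert fit.loglik == pytest.approx(
            loglik_mixture_two(fit.pi, fit.mu1, fit.beta1, fit.mu2, fit.beta2, data),
            abs=1e-8,
        )
        grid = np.linspace(-1.0, 1.0, 5)
        for mu1 in grid:
            for b1 in grid:
                for mu2 in grid:
                    for b2 in grid:
                        for pi in (0.25, 0.5, 0.75):
                            assert fit.loglik >= loglik_mixture_two(
                                pi, mu1, b1, mu2, b2, data
                            ) - 1e-9

    def test_labelling_by_condition_effect(self):
        rng = np.random.default_rng(9)
        fit = fit_npml_two(self._paired_gene(rng, 0.6, 0.75, n=50, depth=200))
        assert abs(fit.beta1) >= abs(fit.beta2)


class TestFitNullOne:
    def test_degenerate_symmetric_data(self):
        data = _gene([(f"i{k}", "s1", 10, 20) for k in range(5)])
        fit = fit_null_one(data)
        assert fit.mu == pytest.approx(0.0, abs=1e-9)
        assert fit.sigma == 0.0
        assert fit.loglik == pytest.approx(
            5 * binom.logpmf(10, 20, 0.5), abs=1e-9
        )

    def test_single_individual_sigma_zero_fallback(self):
        fit = fit_null_one(_gene([("i1", "s1", 15, 20)]))
        assert fit.sigma == 0.0
        assert fit.mu == pytest.approx(logit(0.75), abs=1e-9)
        assert fit.loglik == pytest.approx(binom.logpmf(15, 20, 0.75), abs=1e-9)

    def test_mu_recovery_from_logit_normal_data(self):
        rng = np.random.default_rng(10)
        gammas = rng.normal(0.4, 0.1, size=500)
        obs = [
            (f"i{k:03d}", "s1", int(rng.binomial(300, expit(g))), 300)
            for k, g in enumerate(gammas)
        ]
        fit = fit_null_one(_gene(obs))
        assert fit.mu == pytest.approx(0.4, abs=0.05)
        assert 0.0 < fit.sigma < 0.2

    def test_marginal_loglik_matches_direct_optimum(self):
        """The EM fit should match direct 2-parameter optimisation of the
        quadrature marginal likelihood."""
        rng = np.random.default_rng(11)
        gammas = rng.normal(0.2, 0.3, size=40)
        obs = [
            (f"i{k:02d}", "s1", int(rng.binomial(80, expit(g))), 80)
            for k, g in enumerate(gammas)
        ]
        data = _gene(obs)
        fit = fit_null_one(data)

        m = np.array([o[2] for o in obs], dtype=float)
        y = np.full(len(obs), 80.0)
        xk, wk = np.polynomial.hermite.hermgauss(61)

        def neg_marginal(theta):
            mu, log_sig = theta
            sig = math.exp(log_sig)
            nodes = mu + math.sqrt(2) * sig * xk
            p = expit(nodes)
            ll = 0.0
            for mi, yi in zip(m, y):
                vals = wk / math.sqrt(math.pi) * binom.pmf(mi, yi, p)
                ll += math.log(vals.sum())
            return -ll

        best = min(
            (
                minimize(neg_marginal, x0, method="Nelder-Mead")
                for x0 in ([0.2, math.log(0.3)], [0.0, math.log(0.1)])
            ),
            key=lambda r: r.fun,
        )
        assert fit.loglik == pytest.approx(-best.fun, abs=1e-4)
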