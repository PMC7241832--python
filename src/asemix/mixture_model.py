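"""Mixture likelihoods and NPML-EM fits for gene-level ASE models.

The population mixes individuals heterozygous ("Het") and homozygous
("Hom") at the unobserved regulatory SNP.  Writing ``M_ij`` for the
major-haplotype read count of individual *i* at SNP *j* (depth ``Y_ij``),
the one-condition likelihood is a two-component mixture

    L = prod_i [ pi * prod_j Binom(M_ij; Y_ij, expit(mu1))
                 + (1 - pi) * prod_j Binom(M_ij; Y_ij, expit(mu2)) ],

a nonparametric maximum-likelihood (two mass point) approximation to the
random-intercept distribution of a binomial GLMM ``logit(P_i) = gamma_i``.
The paired two-condition extension adds per-component condition effects
``beta_k`` on the logit scale.  Under the one-condition null the intercepts
share a common Normal(mu, sigma^2) distribution, integrated by adaptive
Gauss-Hermite quadrature.

All fits run EM with multiple starts; component 1 is by convention the one
deviating more from balanced expression (larger |mu| in one condition,
larger |beta| in two conditions), i.e. the Het component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit

from . import _kernels
from .phasing import GeneData

__all__ = [
    "FitControl",
    "MixtureFitOne",
    "MixtureFitTwo",
    "NullFitOne",
    "loglik_mixture_one",
    "loglik_mixture_two",
    "fit_npml_one",
    "fit_npml_two",
    "fit_null_one",
]


@dataclass(frozen=True)
class FitControl:
    """EM and quadrature settings shared by all fits.

    ``tol`` is the absolute log-likelihood change declaring convergence;
    ``n_starts`` counts EM initialisations (one pooled-proportion median
    split plus seeded random responsibility draws); ``n_quad`` is the number
    of Gauss-Hermite nodes for the null-model integral.
    """

    max_iter: int = 500
    tol: float = 1e-8
    n_starts: int = 5
    seed: int = 0
    n_quad: int = 25


@dataclass
class MixtureFitOne:
    """One-condition two-mass-point NPML fit."""

    pi: float
    mu1: float
    mu2: float
    loglik: float
    individuals: list[str]
    responsibilities: np.ndarray  # (N, 2): columns (Het, Hom)
    n_iter: int
    converged: bool
    n_starts: int
    loglik_trace: tuple[float, ...] = field(default_factory=tuple, repr=False)


@dataclass
class MixtureFitTwo:
    """Paired two-condition two-mass-point NPML fit."""

    pi: float
    mu1: float
    beta1: float
    mu2: float
    beta2: float
    loglik: float
    individuals: list[str]
    responsibilities: np.ndarray  # (N, 2): columns (Het, Hom)
    n_iter: int
    converged: bool
    n_starts: int
    clipped: bool = False
    loglik_trace: tuple[float, ...] = field(default_factory=tuple, repr=False)


@dataclass
class NullFitOne:
    """Common-mean random-intercept (null) fit."""

    mu: float
    sigma: float
    loglik: float
    quadrature_nodes: int
    converged: bool = True


def _individual_order(data: GeneData) -> list[str]:
    return data.individuals()


def one_condition_stats(data: GeneData):
    """Per-individual sufficient statistics (m_i, y_i) and the log binomial
    coefficient constant, individuals in sorted order."""
    inds = _individual_order(data)
    index = {ind: k for k, ind in enumerate(inds)}
    m = np.zeros(len(inds))
    y = np.zeros(len(inds))
    log_const = 0.0
    for obs in data.observations:
        k = index[obs.individual_id]
        m[k] += obs.major_count
        y[k] += obs.total_count
        log_const += (
            gammaln(obs.total_count + 1)
            - gammaln(obs.major_count + 1)
            - gammaln(obs.total_count - obs.major_count + 1)
        )
    return inds, m, y, log_const


def paired_stats(data: GeneData):
    """Per-individual, per-condition sufficient statistics for paired data.

    Conditions are coded by sorted label: the first is condition A
    (indicator 0), the second condition B (indicator 1).  The phasing
    reference does not alter this coding.
    """
    conditions = data.conditions()
    if len(conditions) != 2:
        raise ValueError(f"paired data requires two conditions, got {conditions}")
    cond_a, cond_b = conditions
    inds = _individual_order(data)
    index = {ind: k for k, ind in enumerate(inds)}
    mA = np.zeros(len(inds))
    yA = np.zeros(len(inds))
    mB = np.zeros(len(inds))
    yB = np.zeros(len(inds))
    log_const = 0.0
    for obs in data.observations:
        k = index[obs.individual_id]
        if obs.condition == cond_a:
            mA[k] += obs.major_count
            yA[k] += obs.total_count
        else:
            mB[k] += obs.major_count
            yB[k] += obs.total_count
        log_const += (
            gammaln(obs.total_count + 1)
            - gammaln(obs.major_count + 1)
            - gammaln(obs.total_count - obs.major_count + 1)
        )
    return inds, mA, yA, mB, yB, log_const, (cond_a, cond_b)


def _check_finite(*params: float) -> None:
    for p in params:
        if not math.isfinite(p):
            raise ValueError(f"non-finite parameter {p!r}")


def _log_mix_pair(log_pi, log_1mpi, l1, l2):
    a1 = log_pi + l1
    a2 = log_1mpi + l2
    hi = np.maximum(a1, a2)
    return hi + np.log(np.exp(a1 - hi) + np.exp(a2 - hi))


def loglik_mixture_one(
    pi: float, mu1: float, mu2: float, data: GeneData
) -> float:
    """Log of the one-condition mixture likelihood at given parameters.

    Computed in log space (per-individual log-sum-exp over the two
    components); includes the binomial coefficients, so values match
    direct evaluation with ``scipy.stats.binom``.
    """
    _check_finite(pi, mu1, mu2)
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    _, m, y, log_const = one_condition_stats(data)
    l1 = _kernels._binom_core(m, y, expit(mu1))
    l2 = _kernels._binom_core(m, y, expit(mu2))
    if pi == 0.0:
        per_ind = l2
    elif pi == 1.0:
        per_ind = l1
    else:
        per_ind = _log_mix_pair(math.log(pi), math.log1p(-pi), l1, l2)
    return float(per_ind.sum() + log_const)


def loglik_mixture_two(
    pi: float,
    mu1: float,
    beta1: float,
    mu2: float,
    beta2: float,
    data: GeneData,
) -> float:
    """Log of the paired two-condition mixture likelihood.

    Component k gives condition-A observations success probability
    ``expit(mu_k)`` and condition-B observations ``expit(mu_k + beta_k)``.
    With ``beta1 = beta2 = 0`` this reduces exactly to the one-condition
    likelihood on the pooled counts.
    """
    _check_finite(pi, mu1, beta1, mu2, beta2)
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    _, mA, yA, mB, yB, log_const, _ = paired_stats(data)
    l1 = _kernels._binom_core(mA, yA, expit(mu1)) + _kernels._binom_core(
        mB, yB, expit(mu1 + beta1)
    )
    l2 = _kernels._binom_core(mA, yA, expit(mu2)) + _kernels._binom_core(
        mB, yB, expit(mu2 + beta2)
    )
    if pi == 0.0:
        per_ind = l2
    elif pi == 1.0:
        per_ind = l1
    else:
        per_ind = _log_mix_pair(math.log(pi), math.log1p(-pi), l1, l2)
    return float(per_ind.sum() + log_const)


def fit_npml_one(
    data: GeneData, control: FitControl | None = None
) -> MixtureFitOne:
    """Fit the one-condition two-mass-point mixture by multi-start EM."""
    control = control or FitControl()
    inds, m, y, log_const = one_condition_stats(data)
    if len(inds) < 2:
        raise ValueError("mixture fit requires at least 2 individuals")
    rng = np.random.default_rng(control.seed)
    res = _kernels.em_mixture_one(
        m[None, :], y[None, :],
        n_starts=control.n_starts, max_iter=control.max_iter,
        tol=control.tol, rng=rng, keep_trace=True,
    )
    resp = np.column_stack([res.resp[0], 1.0 - res.resp[0]])
    trace = tuple(float(t[0]) + log_const for t in res.trace)
    return MixtureFitOne(
        pi=float(res.pi[0]),
        mu1=float(res.mu1[0]),
        mu2=float(res.mu2[0]),
        loglik=float(res.loglik[0]) + log_const,
        individuals=inds,
        responsibilities=resp,
        n_iter=int(res.n_iter[0]),
        converged=bool(res.converged[0]),
        n_starts=control.n_starts,
        loglik_trace=trace,
    )


def fit_npml_two(
    data: GeneData, control: FitControl | None = None
) -> MixtureFitTwo:
    """Fit the paired two-condition mixture by multi-start EM.

    The per-component M-step is a responsibility-weighted binomial logistic
    regression on the condition indicator; with a single binary covariate
    it reduces to weighted pooled proportions per condition.  Component
    proportions are clipped away from 0/1, which bounds |mu| and |beta|;
    a fit that hits the bound is flagged via ``clipped``.
    """
    control = control or FitControl()
    inds, mA, yA, mB, yB, log_const, _ = paired_stats(data)
    if len(inds) < 2:
        raise ValueError("mixture fit requires at least 2 individuals")
    rng = np.random.default_rng(control.seed)
    res = _kernels.em_mixture_two(
        mA[None, :], yA[None, :], mB[None, :], yB[None, :],
        n_starts=control.n_starts, max_iter=control.max_iter,
        tol=control.tol, rng=rng, keep_trace=True,
    )
    resp = np.column_stack([res.resp[0], 1.0 - res.resp[0]])
    trace = tuple(float(t[0]) + log_const for t in res.trace)
    return MixtureFitTwo(
        pi=float(res.pi[0]),
        mu1=float(res.mu1[0]),
        beta1=float(res.beta1[0]),
        mu2=float(res.mu2[0]),
        beta2=float(res.beta2[0]),
        loglik=float(res.loglik[0]) + log_const,
        individuals=inds,
        responsibilities=resp,
        n_iter=int(res.n_iter[0]),
        converged=bool(res.converged[0]),
        n_starts=control.n_starts,
        clipped=bool(res.clipped[0]),
        loglik_trace=trace,
    )


def fit_null_one(
    data: GeneData, control: FitControl | None = None
) -> NullFitOne:
    """Fit the null model: binomial GLMM with a common-mean random intercept.

    ``logit(P_i) = gamma_i`` with ``gamma_i ~ Normal(mu, sigma^2)``; the
    marginal likelihood integral is evaluated by adaptive Gauss-Hermite
    quadrature.  With a single individual (sigma unidentifiable) or whenever
    the boundary sigma = 0 attains the higher likelihood, the plain pooled
    binomial MLE is returned.  Non-convergence is flagged on the result
    rather than raised.
    """
    control = control or FitControl()
    _, m, y, log_const = one_condition_stats(data)
    res = _kernels.em_null_one(
        m[None, :], y[None, :],
        n_quad=control.n_quad, max_iter=control.max_iter, tol=control.tol,
    )
    return NullFitOne(
        mu=float(res.mu[0]),
        sigma=float(res.sigma[0]),
        loglik=float(res.loglik[0]) + log_const,
        quadrature_nodes=control.n_quad,
        converged=bool(res.converged[0]),
    )
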