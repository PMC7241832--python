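"""Vectorised EM cores operating on per-individual sufficient statistics.

Both mixture likelihoods and the null random-intercept model depend on the
data only through each individual's summed major-haplotype count and summed
depth (per condition, in the paired case), because every component assigns
one success probability to all of an individual's SNPs.  The kernels here
therefore take rectangular arrays whose axis 0 indexes independent datasets
— an observed gene stacked with its resampling replicates — and axis 1
indexes individuals.  Rows are dropped from the working set as they
converge, so stragglers do not multiply the cost of the whole batch.  This
batching is what keeps the resampling-calibrated tests (hundreds of EM fits
per gene) fast.

Log-likelihood values returned by these kernels omit the additive binomial
coefficient term ``sum log C(Y, M)``; it is identical for every model fitted
to the same dataset, so likelihood-ratio statistics are unaffected.  Callers
that need true log-likelihoods add the constant back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

_PROB_CLIP = 1e-6
_PI_CLIP = 1e-6
_SIGMA_FLOOR = 1e-6
# below this random-effect SD the marginal likelihood is indistinguishable
# from the sigma = 0 boundary fit, which is then adopted outright
_SIGMA_EXIT = 1e-3


def _binom_core(m, y, p):
    """``m log p + (y - m) log(1 - p)`` with broadcasting."""
    return m * np.log(p) + (y - m) * np.log1p(-p)


@dataclass
class MixtureOneResult:
    pi: np.ndarray          # (R,)
    mu1: np.ndarray         # (R,)
    mu2: np.ndarray         # (R,)
    loglik: np.ndarray      # (R,) without binomial-coefficient constant
    resp: np.ndarray        # (R, N) posterior prob of component 1 (Het)
    n_iter: np.ndarray      # (R,)
    converged: np.ndarray   # (R,) bool
    trace: list | None = None


@dataclass
class MixtureTwoResult:
    pi: np.ndarray
    mu1: np.ndarray
    beta1: np.ndarray
    mu2: np.ndarray
    beta2: np.ndarray
    loglik: np.ndarray
    resp: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray
    clipped: np.ndarray     # (R,) bool: a component proportion hit its bound
    trace: list | None = None


@dataclass
class NullOneResult:
    mu: np.ndarray
    sigma: np.ndarray
    loglik: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray


def _initial_responsibilities(m, y, n_starts, rng):
    """Median split on pooled proportions, then seeded random starts."""
    ratio = m / y
    med = np.median(ratio, axis=1, keepdims=True)
    starts = [np.where(ratio >= med, 0.9, 0.1)]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(0.05, 0.95, size=m.shape))
    return starts


def _em_two_component(stats, w0, m_step, component_loglik, max_iter, tol,
                      keep_trace=False):
    """Generic two-component EM with an active-set over batch rows.

    ``stats`` is a tuple of (R, N) arrays of sufficient statistics;
    ``m_step(w, stats)`` maps responsibilities to component parameters
    (a tuple of (r, 1) arrays, pi first); ``component_loglik(params, stats)``
    returns the per-individual log-likelihood under each component.
    Converged rows are frozen and removed from the working set.
    """
    R, N = w0.shape
    n_params = None
    out_params = None
    out_ll = np.full(R, -np.inf)
    out_w = np.zeros((R, N))
    out_iter = np.zeros(R, dtype=int)
    out_conv = np.zeros(R, dtype=bool)
    trace = [] if keep_trace else None

    active = np.arange(R)
    w = w0
    st = stats
    ll = np.full(R, -np.inf)
    for it in range(1, max_iter + 1):
        params = m_step(w, st)
        if out_params is None:
            n_params = len(params)
            out_params = [np.zeros(R) for _ in range(n_params)]
        pi = params[0]
        l1, l2 = component_loglik(params, st)
        a1 = np.log(pi) + l1
        a2 = np.log1p(-pi) + l2
        hi = np.maximum(a1, a2)
        log_mix = hi + np.log(np.exp(a1 - hi) + np.exp(a2 - hi))
        ll_new = log_mix.sum(axis=1)
        if keep_trace:
            trace.append(ll_new.copy())
        w = np.exp(a1 - log_mix)
        done = np.abs(ll_new - ll[active]) < tol
        ll[active] = ll_new
        if done.any() or it == max_iter:
            settle = done if it < max_iter else np.ones_like(done)
            rows = active[settle]
            for k in range(n_params):
                out_params[k][rows] = params[k][settle, 0]
            out_ll[rows] = ll_new[settle]
            out_w[rows] = w[settle]
            out_iter[rows] = it
            out_conv[rows] = done[settle]
            keep = ~settle
            if not keep.any():
                break
            active = active[keep]
            w = w[keep]
            st = tuple(s[keep] for s in st)
    return out_params, out_ll, out_w, out_iter, out_conv, trace


def _merge_best(best, cand, better):
    return tuple(
        np.where(better[:, None] if c_new.ndim == 2 else better, c_new, c_old)
        for c_new, c_old in zip(cand, best)
    )


def em_mixture_one(
    m: np.ndarray,
    y: np.ndarray,
    *,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
    rng: np.random.Generator | None = None,
    keep_trace: bool = False,
) -> MixtureOneResult:
    """Two-mass-point NPML fit of the one-condition mixture.

    E-step: responsibilities from the current (pi, mu1, mu2).  M-step:
    ``pi`` is the mean responsibility and each mass point the
    responsibility-weighted pooled binomial MLE on the logit scale.
    Component 1 is relabelled, if needed, to be the one whose mass point
    deviates more from logit(0.5) = 0.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    y = np.broadcast_to(np.asarray(y, dtype=float), m.shape).copy()
    rng = rng or np.random.default_rng(0)

    def m_step(w, st):
        mm, yy = st
        pi = np.clip(w.mean(axis=1, keepdims=True), _PI_CLIP, 1 - _PI_CLIP)
        w2 = 1.0 - w
        p1 = np.clip(
            (w * mm).sum(axis=1, keepdims=True)
            / (w * yy).sum(axis=1, keepdims=True),
            _PROB_CLIP, 1 - _PROB_CLIP,
        )
        p2 = np.clip(
            (w2 * mm).sum(axis=1, keepdims=True)
            / (w2 * yy).sum(axis=1, keepdims=True),
            _PROB_CLIP, 1 - _PROB_CLIP,
        )
        return pi, p1, p2

    def component_loglik(params, st):
        mm, yy = st
        _, p1, p2 = params
        return _binom_core(mm, yy, p1), _binom_core(mm, yy, p2)

    best = None
    best_trace = None
    for w0 in _initial_responsibilities(m, y, n_starts, rng):
        params, ll, w, n_iter, conv, trace = _em_two_component(
            (m, y), w0, m_step, component_loglik, max_iter, tol,
            keep_trace=keep_trace,
        )
        pi, p1, p2 = params
        cand = (pi, p1, p2, ll, w, n_iter, conv)
        if best is None:
            best = cand
            best_trace = trace
        else:
            better = ll > best[3]
            best = _merge_best(best, cand, better)
            if keep_trace and bool(better.all()):
                best_trace = trace
    pi, p1, p2, ll, w, n_iter, conv = best
    mu1 = logit(p1)
    mu2 = logit(p2)
    swap = np.abs(mu1) < np.abs(mu2)
    return MixtureOneResult(
        pi=np.where(swap, 1.0 - pi, pi),
        mu1=np.where(swap, mu2, mu1),
        mu2=np.where(swap, mu1, mu2),
        loglik=ll,
        resp=np.where(swap[:, None], 1.0 - w, w),
        n_iter=n_iter,
        converged=conv.astype(bool),
        trace=best_trace if keep_trace else None,
    )


def em_mixture_two(
    mA: np.ndarray,
    yA: np.ndarray,
    mB: np.ndarray,
    yB: np.ndarray,
    *,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
    rng: np.random.Generator | None = None,
    keep_trace: bool = False,
) -> MixtureTwoResult:
    """Two-mass-point NPML fit of the paired two-condition mixture.

    Each component k gives condition-A SNPs success probability
    ``expit(mu_k)`` and condition-B SNPs ``expit(mu_k + beta_k)``.  Because
    the condition indicator is binary, the responsibility-weighted logistic
    M-step is available in closed form: each component fits the weighted
    pooled proportion within each condition exactly.  Component 1 is
    relabelled to carry the larger |beta| (the differential component).
    """
    mA = np.atleast_2d(np.asarray(mA, dtype=float))
    mB = np.atleast_2d(np.asarray(mB, dtype=float))
    yA = np.broadcast_to(np.asarray(yA, dtype=float), mA.shape).copy()
    yB = np.broadcast_to(np.asarray(yB, dtype=float), mB.shape).copy()
    rng = rng or np.random.default_rng(0)

    def m_step(w, st):
        sA, tA, sB, tB = st
        pi = np.clip(w.mean(axis=1, keepdims=True), _PI_CLIP, 1 - _PI_CLIP)
        w2 = 1.0 - w

        def wprop(weight, mm, yy):
            return np.clip(
                (weight * mm).sum(axis=1, keepdims=True)
                / (weight * yy).sum(axis=1, keepdims=True),
                _PROB_CLIP, 1 - _PROB_CLIP,
            )

        return (
            pi,
            wprop(w, sA, tA), wprop(w, sB, tB),
            wprop(w2, sA, tA), wprop(w2, sB, tB),
        )

    def component_loglik(params, st):
        sA, tA, sB, tB = st
        _, pA1, pB1, pA2, pB2 = params
        l1 = _binom_core(sA, tA, pA1) + _binom_core(sB, tB, pB1)
        l2 = _binom_core(sA, tA, pA2) + _binom_core(sB, tB, pB2)
        return l1, l2

    best = None
    best_trace = None
    for w0 in _initial_responsibilities(mA + mB, yA + yB, n_starts, rng):
        params, ll, w, n_iter, conv, trace = _em_two_component(
            (mA, yA, mB, yB), w0, m_step, component_loglik, max_iter, tol,
            keep_trace=keep_trace,
        )
        pi, pA1, pB1, pA2, pB2 = params
        cand = (pi, pA1, pB1, pA2, pB2, ll, w, n_iter, conv)
        if best is None:
            best = cand
            best_trace = trace
        else:
            better = ll > best[5]
            best = _merge_best(best, cand, better)
            if keep_trace and bool(better.all()):
                best_trace = trace
    pi, pA1, pB1, pA2, pB2, ll, w, n_iter, conv = best
    mu1, beta1 = logit(pA1), logit(pB1) - logit(pA1)
    mu2, beta2 = logit(pA2), logit(pB2) - logit(pA2)
    swap = np.abs(beta1) < np.abs(beta2)
    clipped = np.zeros(ll.shape, dtype=bool)
    for p in (pA1, pB1, pA2, pB2):
        clipped |= (p <= _PROB_CLIP) | (p >= 1 - _PROB_CLIP)
    return MixtureTwoResult(
        pi=np.where(swap, 1.0 - pi, pi),
        mu1=np.where(swap, mu2, mu1),
        beta1=np.where(swap, beta2, beta1),
        mu2=np.where(swap, mu1, mu2),
        beta2=np.where(swap, beta1, beta2),
        loglik=ll,
        resp=np.where(swap[:, None], 1.0 - w, w),
        n_iter=n_iter,
        converged=conv.astype(bool),
        clipped=clipped,
        trace=best_trace if keep_trace else None,
    )


def _adaptive_gh_estep(m, y, mu, sigma, x, logw_base):
    """Adaptive Gauss-Hermite moments of the random intercept's posterior.

    For each (dataset, individual) cell the integrand — binomial likelihood
    times Normal(mu, sigma^2) prior — is maximised by damped Newton (it is
    strictly log-concave), nodes are centred at the mode with the Laplace
    scale, and posterior moments plus the log marginal likelihood follow by
    quadrature.  Returns (log_marginal_i, E[gamma_i], E[gamma_i^2]).
    """
    sig2 = sigma[:, None] ** 2
    g = np.broadcast_to(mu[:, None], m.shape).copy()
    for _ in range(40):
        p = expit(g)
        grad = m - y * p + (mu[:, None] - g) / sig2
        hess = -(y * p * (1 - p) + 1.0 / sig2)
        step = grad / hess
        np.clip(step, -3.0, 3.0, out=step)
        g -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(g)
    hess = -(y * p * (1 - p) + 1.0 / sig2)
    s = 1.0 / np.sqrt(-hess)

    gk = g[..., None] + np.sqrt(2.0) * s[..., None] * x          # (R, N, K)
    logp = -np.logaddexp(0.0, -gk)
    log1mp = -np.logaddexp(0.0, gk)
    logf = m[..., None] * logp + (y - m)[..., None] * log1mp
    logphi = (
        -0.5 * ((gk - mu[:, None, None]) / sigma[:, None, None]) ** 2
        - np.log(sigma)[:, None, None]
        - 0.5 * np.log(2.0 * np.pi)
    )
    logterm = logw_base + logf + logphi
    hi = logterm.max(axis=-1, keepdims=True)
    expterm = np.exp(logterm - hi)
    norm = expterm.sum(axis=-1)
    log_marg = hi[..., 0] + np.log(norm) + 0.5 * np.log(2.0) + np.log(s)
    omega = expterm / norm[..., None]
    Eg = (omega * gk).sum(axis=-1)
    Eg2 = (omega * gk**2).sum(axis=-1)
    return log_marg, Eg, Eg2


def em_null_one(
    m: np.ndarray,
    y: np.ndarray,
    *,
    n_quad: int = 25,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> NullOneResult:
    """Marginal ML fit of the null random-intercept model.

    Model: ``M_i ~ Binomial(Y_i, expit(gamma_i))`` with
    ``gamma_i ~ Normal(mu, sigma^2)`` — a common mean for every individual,
    no mixture.  Fitted by EM treating the intercepts as missing data, with
    an adaptive Gauss-Hermite E-step; the M-step sets mu and sigma to the
    mean and spread of the posterior intercepts.  Rows whose sigma shrinks
    to the boundary are settled on the plain-binomial (sigma = 0) fit, which
    is also evaluated for every row at the end and adopted wherever it
    attains the higher likelihood — covering the single-individual case
    where sigma is unidentifiable.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    y = np.broadcast_to(np.asarray(y, dtype=float), m.shape).copy()
    R, N = m.shape
    xk, wk = np.polynomial.hermite.hermgauss(n_quad)
    logw_base = np.log(wk) + xk**2

    p_pool = np.clip(m.sum(axis=1) / y.sum(axis=1), _PROB_CLIP, 1 - _PROB_CLIP)
    ll_sigma0 = _binom_core(m, y, p_pool[:, None]).sum(axis=1)

    out_mu = logit(p_pool).copy()
    out_sigma = np.zeros(R)
    out_ll = ll_sigma0.copy()
    out_iter = np.zeros(R, dtype=int)
    out_conv = np.ones(R, dtype=bool)
    if N < 2:
        return NullOneResult(out_mu, out_sigma, out_ll, out_iter, out_conv)

    active = np.arange(R)
    m_a, y_a = m, y
    mu = logit(p_pool)
    ratio = np.clip((m + 0.5) / (y + 1.0), _PROB_CLIP, 1 - _PROB_CLIP)
    sigma = np.clip(logit(ratio).std(axis=1), 0.05, 3.0)
    ll0_a = ll_sigma0
    ll = np.full(R, -np.inf)
    d_prev = np.full(R, np.inf)
    for it in range(1, max_iter + 1):
        log_marg, Eg, Eg2 = _adaptive_gh_estep(m_a, y_a, mu, sigma, xk, logw_base)
        ll_new = log_marg.sum(axis=1)
        d = np.abs(ll_new - ll)
        done = d < tol
        # When sigma shrinks towards the boundary, per-iteration gains decay
        # so slowly that the tolerance is unreachable; an Aitken projection of
        # the EM limit, ll + d * r / (1 - r) with rate r = d_t / d_{t-1},
        # settles such rows: either the projected limit is within tolerance
        # (effective convergence) or it cannot beat the exact sigma = 0 fit,
        # which is then adopted outright.
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.clip(d / d_prev, 0.0, 1.0 - 1e-12)
        gain = d * rate / (1.0 - rate)
        if it >= 4:
            done |= gain < tol
            done |= ll_new + gain <= ll0_a + 1e-9
        settle = done if it < max_iter else np.ones_like(done)
        if settle.any():
            rows = active[settle]
            use_em = ll_new[settle] > ll0_a[settle]
            out_mu[rows] = np.where(use_em, mu[settle], out_mu[rows])
            out_sigma[rows] = np.where(use_em, sigma[settle], 0.0)
            out_ll[rows] = np.where(use_em, ll_new[settle], ll0_a[settle])
            out_iter[rows] = it
            out_conv[rows] = done[settle]
            keep = ~settle
            if not keep.any():
                break
            active = active[keep]
            m_a, y_a = m_a[keep], y_a[keep]
            mu, sigma = mu[keep], sigma[keep]
            ll0_a = ll0_a[keep]
            ll_new = ll_new[keep]
            d = d[keep]
            Eg, Eg2 = Eg[keep], Eg2[keep]
        ll = ll_new
        d_prev = d
        mu = Eg.mean(axis=1)
        sig2 = Eg2.mean(axis=1) - mu**2
        sigma = np.sqrt(np.maximum(sig2, _SIGMA_FLOOR**2))
    return NullOneResult(
        mu=out_mu, sigma=out_sigma, loglik=out_ll, n_iter=out_iter,
        converged=out_conv,
    )


def lrt_one_batch(m, y, *, n_starts=5, max_iter=500, tol=1e-8, n_quad=25, rng=None):
    """One-condition LRT for a batch of datasets sharing a structure.

    Returns (lrt, mixture_fit, null_fit); negative raw statistics from
    imperfect optimisation are clamped at zero.
    """
    h1 = em_mixture_one(
        m, y, n_starts=n_starts, max_iter=max_iter, tol=tol, rng=rng
    )
    h0 = em_null_one(m, y, n_quad=n_quad, max_iter=max_iter, tol=tol)
    lrt = np.maximum(0.0, -2.0 * (h0.loglik - h1.loglik))
    return lrt, h1, h0


def lrt_two_batch(
    mA, yA, mB, yB, *, n_starts=5, max_iter=500, tol=1e-8, rng=None
):
    """Two-condition LRT batch: paired mixture vs pooled one-condition mixture."""
    h1 = em_mixture_two(
        mA, yA, mB, yB, n_starts=n_starts, max_iter=max_iter, tol=tol, rng=rng
    )
    mA2 = np.atleast_2d(np.asarray(mA, dtype=float))
    mB2 = np.atleast_2d(np.asarray(mB, dtype=float))
    yA2 = np.broadcast_to(np.asarray(yA, dtype=float), mA2.shape)
    yB2 = np.broadcast_to(np.asarray(yB, dtype=float), mB2.shape)
    h0 = em_mixture_one(
        mA2 + mB2, yA2 + yB2, n_starts=n_starts, max_iter=max_iter, tol=tol,
        rng=rng,
    )
    lrt = np.maximum(0.0, -2.0 * (h0.loglik - h1.loglik))
    return lrt, h1, h0
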