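"""Likelihood-ratio tests with resampling-calibrated p-values.

The gene-level statistic is ``LRT = -2 (logL_H0 - logL_H1)``.  Its null
distribution is nonstandard (the mixture null sits on the boundary of the
alternative), so significance is assessed by parametric resampling:

* one condition — major-haplotype counts are redrawn from
  ``Binomial(Y_ij, 0.5)`` (balanced expression);
* two conditions — counts are redrawn per individual from
  ``Binomial(Y_ij^c, p_hat_i0)`` where ``p_hat_i0`` is the
  posterior-weighted no-difference ASE level, keeping the pseudo-phasing
  bias of the observed statistic in the null.

In phase-unknown mode every replicate is pushed through the same
majority-voting (and, for paired data, reference-condition alignment) path
as the observed data, so the null carries the same phasing bias as the
statistic it calibrates.  The per-gene p-value is
``#(LRT_n >= LRT) / N_sim``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import _kernels
from .io_filters import AlleleCount
from .mixture_model import (
    FitControl,
    MixtureFitOne,
    MixtureFitTwo,
    NullFitOne,
    fit_npml_one,
    fit_npml_two,
    fit_null_one,
    one_condition_stats,
    paired_stats,
)
from .phasing import (
    GeneData,
    PhasedObservation,
    align_conditions,
    choose_reference_condition,
    phase_gene,
)

__all__ = [
    "AseTestResult",
    "NullAseEstimates",
    "lrt_one",
    "lrt_two",
    "resampling_pvalue_one",
    "resampling_pvalue_two",
    "estimate_null_ase",
    "bh_fdr",
    "enrichment_pvalue",
    "analyze_gene_one",
    "analyze_gene_two",
]


@dataclass
class AseTestResult:
    """Per-gene test outcome."""

    gene_id: str
    test_kind: str  # "one_condition" | "two_condition"
    lrt: float
    p_value: float
    n_sim: int
    fit_h1: MixtureFitOne | MixtureFitTwo
    fit_h0: NullFitOne | MixtureFitOne
    n_individuals: int
    n_snps: int
    seed: int
    q_value: float = float("nan")


@dataclass
class NullAseEstimates:
    """Per-individual no-difference ASE levels used by the paired bootstrap.

    ``p_hat`` is the pooled major-haplotype frequency across both conditions;
    ``p_hat_0 = 0.5 * post_hom + p_hat * post_het`` shrinks it towards 0.5
    in proportion to the posterior probability of being Hom, so resampled
    data represent "no condition difference" without inheriting the
    voting-induced inflation of Hom individuals.
    """

    individuals: list[str]
    p_hat: np.ndarray
    p_hat_0: np.ndarray
    post_het: np.ndarray
    post_hom: np.ndarray


def lrt_one(
    data: GeneData, control: FitControl | None = None
) -> tuple[float, MixtureFitOne, NullFitOne]:
    """One-condition LRT: two-mass-point mixture vs common-mean GLMM null.

    Negative raw statistics (possible when either optimiser stops in a
    local optimum) are clamped to zero with a warning.
    """
    control = control or FitControl()
    fit_h1 = fit_npml_one(data, control)
    fit_h0 = fit_null_one(data, control)
    raw = -2.0 * (fit_h0.loglik - fit_h1.loglik)
    if raw < -1e-6:
        warnings.warn(
            f"gene {data.gene_id!r}: raw LRT {raw:.3e} < 0 clamped to 0",
            stacklevel=2,
        )
    return max(0.0, raw), fit_h1, fit_h0


def _pooled_gene_data(data: GeneData) -> GeneData:
    """Drop condition labels, turning paired data into one-condition records.

    Each (individual, SNP, condition) observation is kept as its own record,
    so the one-condition likelihood of the pooled data equals the paired
    likelihood with both condition effects fixed at zero, binomial
    coefficients included.
    """
    pooled = [
        PhasedObservation(
            individual_id=obs.individual_id,
            snp_id=f"{obs.snp_id}::{obs.condition}",
            major_count=obs.major_count,
            total_count=obs.total_count,
            major_is_ref=obs.major_is_ref,
        )
        for obs in data.observations
    ]
    return GeneData(
        gene_id=data.gene_id,
        observations=pooled,
        phase_known=data.phase_known,
        paired=False,
    )


def lrt_two(
    data: GeneData, control: FitControl | None = None
) -> tuple[float, MixtureFitTwo, MixtureFitOne]:
    """Two-condition LRT: paired mixture vs one-condition mixture on pooled data.

    Under no condition difference the per-component condition effects vanish
    and the paired model reduces to the one-condition mixture applied to the
    condition-collapsed counts, which serves as H0.
    """
    control = control or FitControl()
    fit_h1 = fit_npml_two(data, control)
    fit_h0 = fit_npml_one(_pooled_gene_data(data), control)
    raw = -2.0 * (fit_h0.loglik - fit_h1.loglik)
    if raw < -1e-6:
        warnings.warn(
            f"gene {data.gene_id!r}: raw LRT {raw:.3e} < 0 clamped to 0",
            stacklevel=2,
        )
    return max(0.0, raw), fit_h1, fit_h0


def estimate_null_ase(data: GeneData, fit: MixtureFitTwo) -> NullAseEstimates:
    """Posterior-weighted no-difference ASE level per individual.

    The Hom component is the mixture component with the smaller |beta|
    (component 2 under the labelling convention).
    """
    inds, mA, yA, mB, yB, _, _ = paired_stats(data)
    if inds != fit.individuals:
        raise ValueError("fit and data describe different individuals")
    p_hat = (mA + mB) / (yA + yB)
    post_het = fit.responsibilities[:, 0]
    post_hom = fit.responsibilities[:, 1]
    p_hat_0 = 0.5 * post_hom + p_hat * post_het
    return NullAseEstimates(
        individuals=inds,
        p_hat=p_hat,
        p_hat_0=p_hat_0,
        post_het=post_het,
        post_hom=post_hom,
    )


def _one_condition_obs_arrays(data: GeneData):
    """Flat per-observation arrays, sorted by individual then SNP."""
    obs = sorted(data.observations, key=lambda o: (o.individual_id, o.snp_id))
    inds = data.individuals()
    index = {ind: k for k, ind in enumerate(inds)}
    ind_idx = np.array([index[o.individual_id] for o in obs], dtype=int)
    y = np.array([o.total_count for o in obs], dtype=float)
    starts = np.searchsorted(ind_idx, np.arange(len(inds)))
    return inds, ind_idx, y, starts


def _count_exceedances(batch_lrt, n_sim, lrt_obs, early_stop, chunk=50):
    """Count replicate LRTs at or above the observed one.

    With ``early_stop`` set, replicates are processed in chunks and the
    count stops once that many exceedances have accumulated — the p-value
    is then far above any interesting threshold and is estimated from the
    replicates processed so far.  ``early_stop=None`` (the default) keeps
    the exact single-batch computation.
    """
    if early_stop is None:
        return int(np.sum(batch_lrt(slice(None)) >= lrt_obs)), n_sim
    n_ge = n_done = 0
    for lo in range(0, n_sim, chunk):
        sl = slice(lo, min(lo + chunk, n_sim))
        n_ge += int(np.sum(batch_lrt(sl) >= lrt_obs))
        n_done = sl.stop
        if n_ge >= early_stop:
            break
    return n_ge, n_done


def resampling_pvalue_one(
    data: GeneData,
    n_sim: int,
    seed: int,
    control: FitControl | None = None,
    add_one: bool = False,
    early_stop: int | None = None,
) -> AseTestResult:
    """Resampling-calibrated p-value for one-condition ASE.

    Each replicate redraws a count from ``Binomial(Y_ij, 0.5)`` for every
    observation.  With unknown phase the draws are raw allele counts and are
    re-phased by per-SNP majority voting before fitting; with known phase a
    draw is the major-haplotype count directly.  ``add_one`` switches to the
    ``(# + 1) / (N_sim + 1)`` estimator that cannot return 0; ``early_stop``
    optionally truncates resampling once that many replicate statistics have
    reached the observed one (clearly non-significant genes finish early).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    control = control or FitControl()
    lrt_obs, fit_h1, fit_h0 = lrt_one(data, control)

    inds, ind_idx, y_obs, starts = _one_condition_obs_arrays(data)
    rng = np.random.default_rng(seed)
    draws = rng.binomial(y_obs.astype(int), 0.5, size=(n_sim, len(y_obs)))
    if data.phase_known:
        m_rep = draws.astype(float)
    else:
        m_rep = np.maximum(draws, y_obs[None, :] - draws).astype(float)
    m = np.add.reduceat(m_rep, starts, axis=1)
    y = np.add.reduceat(np.broadcast_to(y_obs, m_rep.shape), starts, axis=1)

    def batch_lrt(sl):
        lrt_rep, _, _ = _kernels.lrt_one_batch(
            m[sl], y[sl],
            n_starts=control.n_starts, max_iter=control.max_iter,
            tol=control.tol, n_quad=control.n_quad, rng=rng,
        )
        return lrt_rep

    n_ge, n_done = _count_exceedances(batch_lrt, n_sim, lrt_obs, early_stop)
    p = (n_ge + 1) / (n_done + 1) if add_one else n_ge / n_done
    return AseTestResult(
        gene_id=data.gene_id,
        test_kind="one_condition",
        lrt=lrt_obs,
        p_value=p,
        n_sim=n_done,
        fit_h1=fit_h1,
        fit_h0=fit_h0,
        n_individuals=len(inds),
        n_snps=len(data.snps()),
        seed=seed,
    )


def _paired_obs_arrays(data: GeneData):
    """Matched-pair arrays sorted by individual then SNP."""
    cond_a, cond_b = data.conditions()
    by_pair: dict[tuple[str, str], dict[str, PhasedObservation]] = {}
    for obs in data.observations:
        by_pair.setdefault((obs.individual_id, obs.snp_id), {})[obs.condition] = obs
    pairs = sorted(by_pair)
    inds = data.individuals()
    index = {ind: k for k, ind in enumerate(inds)}
    ind_idx = np.array([index[i] for i, _ in pairs], dtype=int)
    yA = np.array([by_pair[p][cond_a].total_count for p in pairs], dtype=float)
    yB = np.array([by_pair[p][cond_b].total_count for p in pairs], dtype=float)
    starts = np.searchsorted(ind_idx, np.arange(len(inds)))
    return inds, ind_idx, yA, yB, starts


def resampling_pvalue_two(
    data: GeneData,
    n_sim: int,
    seed: int,
    control: FitControl | None = None,
    add_one: bool = False,
    early_stop: int | None = None,
) -> AseTestResult:
    """Resampling-calibrated p-value for differential ASE between conditions.

    Replicates draw, per matched (individual, SNP, condition) observation, a
    count from ``Binomial(Y_ij^c, p_hat_i0)``.  With unknown phase each
    replicate re-chooses its reference condition by pooled major-allele
    proportion and is re-phased and aligned exactly as the observed data
    were; with known phase the drawn counts serve as major counts directly.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    control = control or FitControl()
    lrt_obs, fit_h1, fit_h0 = lrt_two(data, control)
    null_est = estimate_null_ase(data, fit_h1)

    inds, ind_idx, yA, yB, starts = _paired_obs_arrays(data)
    p0 = null_est.p_hat_0[ind_idx]
    rng = np.random.default_rng(seed)
    dA = rng.binomial(yA.astype(int), p0, size=(n_sim, len(yA))).astype(float)
    dB = rng.binomial(yB.astype(int), p0, size=(n_sim, len(yB))).astype(float)
    cond_a, cond_b = data.conditions()
    if data.phase_known:
        # repeat the whole-haplotype vote on the replicate's reference
        # condition: each draw is the count on the previously-major
        # haplotype, an individual whose reference-condition total falls
        # below half is flipped, and the other condition inherits the flip
        d_ref, y_ref = (dA, yA) if data.reference_condition == cond_a else (dB, yB)
        tot_ref = np.add.reduceat(d_ref, starts, axis=1)
        ytot_ref = np.add.reduceat(
            np.broadcast_to(y_ref, d_ref.shape), starts, axis=1
        )
        flip = (tot_ref < ytot_ref - tot_ref)[:, ind_idx]
        mA_rep = np.where(flip, yA[None, :] - dA, dA)
        mB_rep = np.where(flip, yB[None, :] - dB, dB)
    else:
        # re-vote: pick the replicate's reference condition, phase it per
        # SNP, and let the other condition inherit the assignment
        votedA = np.maximum(dA, yA[None, :] - dA)
        votedB = np.maximum(dB, yB[None, :] - dB)
        propA = votedA.sum(axis=1) / yA.sum()
        propB = votedB.sum(axis=1) / yB.sum()
        ref_is_a = (propA >= propB)[:, None]
        major_is_ref_a = dA >= yA[None, :] - dA  # ref cond A: keep drawn allele?
        major_is_ref_b = dB >= yB[None, :] - dB
        mA_rep = np.where(
            ref_is_a, votedA, np.where(major_is_ref_b, dA, yA[None, :] - dA)
        )
        mB_rep = np.where(
            ref_is_a, np.where(major_is_ref_a, dB, yB[None, :] - dB), votedB
        )
    mA = np.add.reduceat(mA_rep, starts, axis=1)
    mB = np.add.reduceat(mB_rep, starts, axis=1)
    yA_i = np.add.reduceat(np.broadcast_to(yA, mA_rep.shape), starts, axis=1)
    yB_i = np.add.reduceat(np.broadcast_to(yB, mB_rep.shape), starts, axis=1)

    def batch_lrt(sl):
        lrt_rep, _, _ = _kernels.lrt_two_batch(
            mA[sl], yA_i[sl], mB[sl], yB_i[sl],
            n_starts=control.n_starts, max_iter=control.max_iter,
            tol=control.tol, rng=rng,
        )
        return lrt_rep

    n_ge, n_done = _count_exceedances(batch_lrt, n_sim, lrt_obs, early_stop)
    p = (n_ge + 1) / (n_done + 1) if add_one else n_ge / n_done
    return AseTestResult(
        gene_id=data.gene_id,
        test_kind="two_condition",
        lrt=lrt_obs,
        p_value=p,
        n_sim=n_done,
        fit_h1=fit_h1,
        fit_h0=fit_h0,
        n_individuals=len(inds),
        n_snps=len(data.snps()),
        seed=seed,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_pvalue(
    n_hits_in_set: int,
    hit_set_size: int,
    background_overlap_labels: Sequence[bool],
    n_resample: int = 10_000,
    seed: int = 0,
) -> float:
    """Resampling enrichment p-value for overlap with an external gene set.

    ``p_observed = n_hits_in_set / hit_set_size``.  Each replicate samples
    ``hit_set_size`` genes without replacement from the labelled background
    and records the overlap proportion; the p-value is
    ``#(p_resampled >= p_observed) / n_resample``.
    """
    if hit_set_size <= 0:
        raise ValueError("hit_set_size must be positive")
    labels = np.asarray(background_overlap_labels, dtype=bool)
    k = hit_set_size
    if labels.size < k:
        warnings.warn(
            "background smaller than the hit set; sampling the whole "
            "background without replacement",
            stacklevel=2,
        )
        k = labels.size
    p_obs = n_hits_in_set / hit_set_size
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_resample):
        sample = rng.choice(labels.size, size=k, replace=False)
        if labels[sample].sum() / k >= p_obs:
            n_ge += 1
    return n_ge / n_resample


def analyze_gene_one(
    counts: Sequence[AlleleCount],
    phase_known: bool,
    n_sim: int,
    seed: int,
    control: FitControl | None = None,
    add_one: bool = False,
    early_stop: int | None = None,
) -> AseTestResult:
    """Phase one gene's counts and run the one-condition resampling test."""
    data = phase_gene(counts, phase_known=phase_known)
    return resampling_pvalue_one(
        data, n_sim, seed, control, add_one=add_one, early_stop=early_stop
    )


def analyze_gene_two(
    counts: Sequence[AlleleCount],
    phase_known: bool,
    n_sim: int,
    seed: int,
    control: FitControl | None = None,
    reference: str | None = None,
    add_one: bool = False,
    early_stop: int | None = None,
) -> AseTestResult:
    """Align one gene's paired counts and run the differential-ASE test."""
    if reference is None:
        reference = choose_reference_condition(counts)
    data = align_conditions(counts, reference, phase_known=phase_known)
    return resampling_pvalue_two(
        data, n_sim, seed, control, add_one=add_one, early_stop=early_stop
    )
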