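"""Truth-labelled synthetic allele-count data and rejection-rate experiments.

The generative model mirrors the study design the tests are built for: each
individual carries an unobserved regulatory SNP in Hardy-Weinberg
equilibrium whose heterozygotes ("Het") express the haplotype bearing the
expression-increasing allele at frequency ``P_i`` (logit-normal around the
population ASE level) while homozygotes ("Hom") are balanced at 0.5;
transcribed-SNP haplotypes follow a stationary first-order Markov chain
with fixed per-site minor allele frequency and adjacent-pair LD; read
counts at each heterozygous transcribed SNP are binomial at constant depth.
Counts are emitted in the same table format the readers consume, with the
major/minor identity hidden unless phase-known output is requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .inference import FitControl, analyze_gene_one, analyze_gene_two
from .io_filters import AlleleCount

__all__ = [
    "SimulationConfig",
    "SimulatedGene",
    "RejectionResult",
    "hwe_het_prob",
    "simulate_tsnp_haplotype",
    "simulate_individual_ase",
    "simulate_gene",
    "simulate_gene_paired",
    "run_rejection_experiment",
    "write_counts",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated gene.

    Defaults are the smallest design of the evaluation grid: N = 20
    individuals, 2 transcribed SNPs at depth 50, regulatory-SNP MAF 0.3,
    transcribed-SNP MAF 0.3 with adjacent-pair LD 0.8, logit-scale
    subject-effect SD 0.03, and a null ASE level (0.5 one-condition,
    0.7/0.7 paired).  ``ase`` is a single level for one-condition data or a
    pair ``(ase_a, ase_b)`` for paired data.
    """

    n_individuals: int = 20
    n_snps: int = 2
    depth: int = 50
    maf_rsnp: float = 0.3
    maf_tsnp: float = 0.3
    ld: float = 0.8
    ase: float | tuple[float, float] = 0.5
    re_sd: float = 0.03
    phase_known: bool = True
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1 or self.depth < 1:
            raise ValueError("n_individuals, n_snps and depth must be >= 1")
        for maf in (self.maf_rsnp, self.maf_tsnp):
            if not 0.0 < maf <= 0.5:
                raise ValueError(f"MAF must lie in (0, 0.5], got {maf}")
        if not 0.0 <= self.ld <= 1.0:
            raise ValueError(f"ld must lie in [0, 1], got {self.ld}")
        ase = self.ase
        if self.paired:
            if not (isinstance(ase, tuple) and len(ase) == 2):
                raise ValueError("paired mode requires ase = (ase_a, ase_b)")
        elif isinstance(ase, tuple):
            raise ValueError("one-condition mode requires a scalar ase")
        for a in ase if isinstance(ase, tuple) else (ase,):
            if not 0.5 <= a < 1.0:
                raise ValueError(f"ase must lie in [0.5, 1), got {a}")
        if self.re_sd < 0:
            raise ValueError("re_sd must be non-negative")


@dataclass
class IndividualTruth:
    rsnp_group: str                 # "Het" | "Hom"
    rsnp_genotype: int              # minor-allele count at the regulatory SNP
    true_p: float | tuple[float, float]
    true_major_haplotype: str       # "hap1" | "hap2"


@dataclass
class SimulatedGene:
    gene_id: str
    counts: list[AlleleCount]
    truth: dict[str, IndividualTruth]
    config: SimulationConfig


@dataclass
class RejectionResult:
    """Empirical rejection rate with an exact binomial confidence interval."""

    rate: float
    ci_low: float
    ci_high: float
    n_rejected: int
    n_genes: int
    alpha: float
    n_sim: int
    p_values: np.ndarray


def hwe_het_prob(maf: float) -> float:
    """Heterozygote fraction ``2 maf (1 - maf)`` under Hardy-Weinberg."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf must lie in [0, 1], got {maf}")
    return 2.0 * maf * (1.0 - maf)


def simulate_tsnp_haplotype(
    n_snps: int,
    maf: float,
    ld: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw haplotype allele vectors from a stationary Markov chain.

    Alleles are coded 1 for the minor allele.  The chain keeps the marginal
    minor-allele frequency at ``maf`` at every site and gives adjacent sites
    allelic correlation ``ld`` (with equal allele frequencies across sites
    the correlation coefficient and D' coincide, so either reading of an
    "LD coefficient" applies); sites at distance d correlate as ``ld**d``.
    Returns shape ``(n_snps,)`` or ``(size, n_snps)``.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    if not 0.0 <= ld <= 1.0:
        raise ValueError(f"ld must lie in [0, 1], got {ld}")
    # transition probabilities preserving the Bernoulli(maf) marginal with
    # lag-1 correlation ld
    p_stay_minor = maf + ld * (1.0 - maf)
    p_to_minor = maf * (1.0 - ld)
    if not (0.0 <= p_stay_minor <= 1.0 and 0.0 <= p_to_minor <= 1.0):
        raise ValueError(f"infeasible (maf={maf}, ld={ld}) pair")
    n_rows = 1 if size is None else size
    hap = np.empty((n_rows, n_snps), dtype=np.int8)
    u = rng.random((n_rows, n_snps))
    hap[:, 0] = u[:, 0] < maf
    for j in range(1, n_snps):
        p = np.where(hap[:, j - 1] == 1, p_stay_minor, p_to_minor)
        hap[:, j] = u[:, j] < p
    return hap[0] if size is None else hap


def simulate_individual_ase(
    ase: float, re_sd: float, rng: np.random.Generator
) -> float:
    """One individual's ASE level: logit-normal around the population level."""
    if re_sd == 0.0:
        return float(ase)
    return float(expit(rng.normal(logit(ase), re_sd)))


def _simulate_individuals(cfg: SimulationConfig, rng, conditions):
    """Common generative core for one- and two-condition genes.

    Per-individual draw order (fixed for reproducibility): regulatory-SNP
    alleles, two transcribed haplotypes, major-haplotype choice, ASE
    level(s), then per heterozygous SNP the binomial count(s).
    """
    ref_allele = rng.integers(0, 2, size=cfg.n_snps)  # seeded ref labelling
    snp_ids = [f"snp{j + 1:02d}" for j in range(cfg.n_snps)]
    ase_levels = cfg.ase if isinstance(cfg.ase, tuple) else (cfg.ase,)

    counts: list[AlleleCount] = []
    truth: dict[str, IndividualTruth] = {}
    for i in range(cfg.n_individuals):
        ind = f"ind{i + 1:04d}"
        rsnp_genotype = int((rng.random(2) < cfg.maf_rsnp).sum())
        group = "Het" if rsnp_genotype == 1 else "Hom"
        hap1 = simulate_tsnp_haplotype(cfg.n_snps, cfg.maf_tsnp, cfg.ld, rng)
        hap2 = simulate_tsnp_haplotype(cfg.n_snps, cfg.maf_tsnp, cfg.ld, rng)
        major_hap = "hap1" if rng.integers(0, 2) == 0 else "hap2"
        if group == "Het":
            p_true = tuple(
                simulate_individual_ase(a, cfg.re_sd, rng) for a in ase_levels
            )
        else:
            p_true = tuple(0.5 for _ in ase_levels)
        truth[ind] = IndividualTruth(
            rsnp_group=group,
            rsnp_genotype=rsnp_genotype,
            true_p=p_true if len(p_true) > 1 else p_true[0],
            true_major_haplotype=major_hap,
        )
        for j in range(cfg.n_snps):
            if hap1[j] == hap2[j]:
                continue  # homozygous transcribed SNP: uninformative
            ref_on_hap1 = hap1[j] == ref_allele[j]
            ref_hap = "hap1" if ref_on_hap1 else "hap2"
            for cond_label, p_cond in zip(conditions, p_true):
                m = int(rng.binomial(cfg.depth, p_cond))
                ref_count = m if ref_hap == major_hap else cfg.depth - m
                counts.append(
                    AlleleCount(
                        gene_id="__gene__",
                        individual_id=ind,
                        snp_id=snp_ids[j],
                        ref_count=ref_count,
                        total_count=cfg.depth,
                        condition=cond_label,
                        haplotype_of_ref=ref_hap if cfg.phase_known else None,
                    )
                )
    return counts, truth


def _with_gene_id(counts: list[AlleleCount], gene_id: str) -> list[AlleleCount]:
    return [
        AlleleCount(
            gene_id=gene_id,
            individual_id=c.individual_id,
            snp_id=c.snp_id,
            ref_count=c.ref_count,
            total_count=c.total_count,
            condition=c.condition,
            haplotype_of_ref=c.haplotype_of_ref,
        )
        for c in counts
    ]


def simulate_gene(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_id: str = "gene1",
) -> SimulatedGene:
    """Simulate one gene's one-condition allele counts.

    Major-haplotype counts are ``Binomial(depth, 0.5)`` for Hom individuals
    and ``Binomial(depth, P_i)`` for Het individuals; only heterozygous
    transcribed SNPs produce records, so individuals heterozygous at none
    contribute nothing.
    """
    if cfg.paired:
        raise ValueError("use simulate_gene_paired for paired configs")
    counts, truth = _simulate_individuals(cfg, rng, conditions=(None,))
    return SimulatedGene(
        gene_id=gene_id,
        counts=_with_gene_id(counts, gene_id),
        truth=truth,
        config=cfg,
    )


def simulate_gene_paired(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_id: str = "gene1",
) -> SimulatedGene:
    """Simulate one gene's paired two-condition allele counts.

    Both conditions share each individual's haplotypes, group label and
    major haplotype; Het individuals draw condition-specific levels
    ``P_i^A``, ``P_i^B`` and Hom individuals stay at 0.5 under both, so
    every heterozygous transcribed SNP yields one matched record per
    condition.
    """
    if not cfg.paired:
        raise ValueError("simulate_gene_paired requires a paired config")
    counts, truth = _simulate_individuals(cfg, rng, conditions=("A", "B"))
    return SimulatedGene(
        gene_id=gene_id,
        counts=_with_gene_id(counts, gene_id),
        truth=truth,
        config=cfg,
    )


def write_counts(sim_or_counts, stream: IO[str] | str) -> None:
    """Emit allele counts in the table format the readers accept."""
    counts = getattr(sim_or_counts, "counts", sim_or_counts)
    rows = [
        {
            "gene": c.gene_id,
            "id": c.individual_id,
            "snp": c.snp_id,
            "ref_count": c.ref_count,
            "total_count": c.total_count,
            **({"condition": c.condition} if c.condition is not None else {}),
            **(
                {"hap_of_ref": c.haplotype_of_ref}
                if c.haplotype_of_ref is not None
                else {}
            ),
        }
        for c in counts
    ]
    pd.DataFrame(rows).to_csv(stream, sep="\t", index=False)


def _clopper_pearson(k: int, n: int, level: float = 0.95):
    """Exact binomial confidence interval."""
    lo = 0.0 if k == 0 else float(beta_dist.ppf((1 - level) / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - (1 - level) / 2, k + 1, n - k))
    return lo, hi


def gene_seed(master_seed: int, replicate: int) -> int:
    """Stable per-gene resampling seed below 2**31."""
    state = np.random.SeedSequence((master_seed, replicate)).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def run_rejection_experiment(
    cfg: SimulationConfig,
    n_replicates: int,
    alpha: float = 0.01,
    n_sim: int = 250,
    seed: int | None = None,
    control: FitControl | None = None,
) -> RejectionResult:
    """Estimate the test's rejection rate under a simulation configuration.

    Simulates ``n_replicates`` independent genes from ``cfg``, runs the
    matching test (one- or two-condition, phase known or unknown) with
    ``n_sim`` resamples each, and reports the fraction of p-values at or
    below ``alpha`` with its exact binomial 95% interval.  Each replicate's
    random stream derives from ``(seed, replicate index)``, so results do
    not depend on evaluation order.
    """
    seed = cfg.seed if seed is None else seed
    simulate = simulate_gene_paired if cfg.paired else simulate_gene
    analyze = analyze_gene_two if cfg.paired else analyze_gene_one
    p_values = []
    skipped = 0
    for g in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, g, 0)))
        sim = simulate(cfg, rng, gene_id=f"gene{g + 1}")
        individuals = {c.individual_id for c in sim.counts}
        if len(individuals) < 2:
            skipped += 1
            continue
        res = analyze(
            sim.counts,
            phase_known=cfg.phase_known,
            n_sim=n_sim,
            seed=gene_seed(seed, g),
            control=control,
        )
        p_values.append(res.p_value)
    if skipped:
        warnings.warn(
            f"{skipped} replicate(s) produced <2 informative individuals "
            "and were skipped",
            stacklevel=2,
        )
    p = np.asarray(p_values)
    k = int(np.sum(p <= alpha))
    lo, hi = _clopper_pearson(k, len(p))
    return RejectionResult(
        rate=k / len(p),
        ci_low=lo,
        ci_high=hi,
        n_rejected=k,
        n_genes=len(p),
        alpha=alpha,
        n_sim=n_sim,
        p_values=p,
    )
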