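# Methods

## The problem and the model

Allele-specific expression (ASE) is detected from RNA-seq allele counts at
heterozygous transcribed SNPs (tSNPs). The cis-regulatory SNP (rSNP) whose
expression-increasing allele drives the imbalance is typically unobserved,
so a population sample is a mixture: individuals heterozygous at the rSNP
("Het") show imbalance, homozygous individuals ("Hom") are balanced. Three
consequences shape the design:

1. **Heterogeneity.** Counts for individual *i* at tSNP *j* on the major
   (more expressed) haplotype are modelled
   M_ij ~ Binomial(Y_ij, P_i) with logit(P_i) = gamma_i, and the
   random-effect distribution g(gamma) is approximated nonparametrically by
   two mass points mu_1 (Het) and mu_2 (Hom) with weights pi, 1-pi. Using
   the Hom group as an internal control (testing mu_1 = mu_2 rather than
   mu_1 = 0) absorbs phasing and alignment artefacts that push both
   components away from logit(0.5) = 0.
2. **Unknown phase.** The major haplotype is inferred by majority voting:
   per SNP (phase unknown) or per whole haplotype by summed reads (phase
   known). Voting folds the count distribution upwards — the estimated ASE
   of Hom individuals exceeds 0.5 — which is why the resampling null
   repeats the vote (below).
3. **Paired conditions.** With the same individuals measured under two
   conditions, each mixture component gains a logit-scale condition effect
   beta_k; the hypothesis of interest is beta_1 = beta_2. One condition —
   the one with the larger pooled major-allele proportion, chosen per gene
   — is phased first and the other inherits its allele-to-haplotype
   assignment, so "major" refers to the same physical haplotype under both
   conditions.

## Estimation

**Mixture fits (H1).** Two-mass-point NPML by EM. The E-step is the usual
posterior responsibility; the M-step has closed form: pi is the mean
responsibility and each mass point the responsibility-weighted pooled
binomial MLE (per condition, in the paired model — with a single binary
covariate the weighted logistic M-step reduces to weighted per-condition
proportions). Five starts are used: a median split on per-individual
pooled proportions plus four seeded random responsibility draws.
Convergence is an absolute log-likelihood change below 1e-8 (at most 500
iterations); component proportions are clipped to [1e-6, 1-1e-6], which
bounds |mu| and |beta| and flags separation in a component. Components are
labelled so that component 1 deviates more from balance (larger |mu|, or
larger |beta| in the paired model); permuting individuals or relabelling
components leaves the likelihood unchanged.

**One-condition null (H0).** A binomial GLMM with a common-mean Normal
random intercept, gamma_i ~ Normal(mu, sigma^2) — the conventional choice
for an unspecified "standard" mixed model; the resampling calibration
absorbs any misspecification. The marginal likelihood is maximised by EM
over the latent intercepts with an adaptive 25-node Gauss-Hermite E-step
(nodes centred at each individual's posterior mode with the Laplace scale;
the integrand is strictly log-concave so damped Newton finds the mode
reliably). Near the sigma = 0 boundary EM gains shrink sublinearly, so an
Aitken projection of the EM limit settles a dataset early: either the
projected limit is within tolerance (effective convergence) or it cannot
beat the exact sigma = 0 pooled-binomial fit, which is then returned. A
single informative individual always receives the sigma = 0 fallback
(sigma is unidentifiable there). Non-convergence is flagged, not raised.

**Paired null.** The paired mixture with beta_1 = beta_2 = 0 is exactly
the one-condition mixture applied to the condition-collapsed records
(labels dropped, observations kept separate), so H0 is fitted with the
same NPML-EM; the likelihood identity holds to floating precision,
binomial coefficients included.

All fits consume per-individual sufficient statistics (summed major counts
and depths, per condition), since each mixture component assigns one
success probability to all of an individual's SNPs. The EM kernels are
vectorised over batches of datasets — an observed gene stacked with its
resampling replicates — with converged rows dropped from the working set;
this is what makes resampling-calibrated testing of hundreds of simulated
genes tractable on one CPU.

## Testing

LRT = -2(logL_H0 - logL_H1), clamped at zero (optimisers can leave a
slightly negative raw value; the clamp applies identically to observed and
resampled statistics). The null law is nonstandard, so significance comes
from parametric resampling:

* one condition: per observation a count is drawn from Binomial(Y_ij, 0.5);
* two conditions: per (individual, SNP, condition) a count is drawn from
  Binomial(Y_ij^c, p_hat_i0), where p_hat_i0 = 0.5 * post_Hom,i +
  p_hat_i * post_Het,i shrinks the individual's pooled major-haplotype
  frequency towards 0.5 by its posterior probability of being Hom (taken
  from the H1 fit; Hom is the smaller-|beta| component). Without the
  shrinkage the voting-induced inflation of Hom individuals would leak a
  spurious signal into the null.

Replicates are processed exactly as the observed data: with unknown phase
they are re-voted per SNP (one condition) or the reference condition is
re-chosen, re-voted and the other condition re-aligned (paired); with
known phase the paired replicate repeats the whole-haplotype vote on its
reference condition and the inherited flip. The one exception, a
deliberate choice: one-condition phase-known replicates use the drawn
count directly as the major count. Re-voting them would fold the replicate
distribution at the individual level while the Binomial(Y, 0.5) draw
represents a haplotype already labelled, and the resulting test is
conservative rather than anticonservative (see below).

The p-value is #(LRT_n >= LRT) / N_sim, exactly as printed — it can be 0;
an optional (#+1)/(N_sim+1) estimator is available behind `add_one`, and
an optional `early_stop` truncates a gene's resampling once enough
replicate statistics have reached the observed one (the gene is then
clearly non-significant and the p-value is estimated from the replicates
processed). Both are off by default.
Gene-level p-values are adjusted by Benjamini-Hochberg (the field-default
FDR procedure). Overlap of a result set with an external gene list is
assessed by label resampling from the non-significant background, with an
exact hypergeometric tail as the test oracle.

### Null behaviour of the one-condition LRT

Majority voting folds null counts upwards, leaving them *under*-dispersed
relative to a binomial at the pooled mean. On such data the two-point NPML
collapses (mu_1 = mu_2 maximises the likelihood — verified by exhaustive
grid search on small instances) and the GLMM fits sigma = 0, so the LRT is
exactly zero for most null genes and the resampling p-value sits at 1.
The test is therefore valid but conservative under the null: its p-value
distribution is a large atom at 1 plus a thin uniform-ish tail, not
Uniform(0,1), and empirical type-I error at alpha = 0.01 lands at or below
the nominal level. Power is unaffected in kind: genuinely bimodal
alternatives separate the two mass points and produce large positive LRTs.
The paired LRT compares nested fits (the collapsed model is a special case
of the paired mixture), is positive generically, and its null p-values are
approximately uniform.

## Simulation framework

One gene at a time. Each individual draws an rSNP genotype under
Hardy-Weinberg equilibrium at the configured MAF; heterozygotes are "Het",
others "Hom". Two tSNP haplotypes come from a stationary first-order
Markov chain with per-site minor allele frequency 0.3 and adjacent-pair
allelic correlation 0.8 (with equal allele frequencies the correlation
equals D', so either reading of an "LD coefficient" applies; sites at
distance d correlate as 0.8^d — a constant all-pairs correlation of 0.8 is
infeasible for more than a few sites). Only tSNPs heterozygous in an
individual yield records. Het individuals draw their ASE level from a
logit-Normal around the population level (SD 0.03 on the logit scale);
Hom individuals sit at 0.5 under every condition. Major-haplotype counts
are Binomial(Y, P_i) at constant depth Y; paired genes share haplotypes,
group labels and the major haplotype across conditions. The emitted table
hides the major/minor identity: which allele is labelled "reference" is
randomised per SNP (seeded), and haplotype annotations appear only in
phase-known output. The rSNP genotype is drawn independently of the tSNP
haplotypes — ASE depends on the rSNP only through the group label.

What the generator does **not** emulate: mapping/reference bias, variable
depth across SNPs and individuals, overdispersed (beta-binomial) counts,
genotyping error, and LD between rSNP and tSNPs. Passing tests show the
estimator and its calibration behave as designed under the generative
model, not that real RNA-seq data meet these assumptions — WASP-style
bias correction upstream remains the user's responsibility.

## Default parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `min_minor_count` | 5 reads | drop observations with minor allele count below 5 |
| `min_total_count` | 20 reads | drop observations with depth below 20 |
| `min_minor_fraction` | 0.05 | drop observations with minor fraction below 5% |
| `min_individuals_per_gene` | 3 | genes need 3+ individuals |
| `min_matched_pairs` | 3 | paired genes need 3+ matched (individual, SNP) pairs |
| `n_sim` | 1000 (CLI) | resamples per gene; the acceptance runs use 250 |
| `tol` / `max_iter` | 1e-8 / 500 | EM convergence |
| `n_starts` | 5 | EM initialisations |
| `n_quad` | 25 | Gauss-Hermite nodes for the null GLMM |

Filters use strict "less than" for exclusion, so boundary observations
(minor = 5, depth = 20) are kept. The minor allele is defined per record
as the less-expressed allele (no population frequencies are assumed).

## Problem sizes used in checks

The rejection-rate checks simulate 400 null genes per design (N = 20,
2 tSNPs, depth 50, rSNP MAF 0.3) with 250 resamples per gene, and compare
the empirical rate at alpha = 0.01 against the nominal level through its
exact (Clopper-Pearson) 95% interval. Power-ordering checks use 200
simulated genes per cell at N = 50, ASE 0.6, with seeds shared across
cells so the comparison is paired. Parameter-recovery checks use N = 200
individuals at depth 500. These sizes are chosen to make Monte-Carlo error
small relative to the effects being checked while keeping the whole suite
runnable on a laptop CPU.

## Numerical and design choices

* Per-SNP and whole-haplotype voting ties break deterministically towards
  the reference allele / the haplotype carrying the reference allele at
  the first SNP in sorted order; reference-condition ties break to the
  first label in sorted order. Reproducibility over elegance.
* The condition indicator is coded 0/1 by sorted condition label,
  independent of which condition is the phasing reference (the reference
  affects phase assignment only; the LRT is invariant to the coding).
* Per-gene random streams derive from (master seed, gene id), so
  multi-gene runs are reproducible and independent of evaluation order;
  every CLI run writes a JSON provenance record (seed, configuration,
  per-gene diagnostics).
* Mass-point count is fixed at 2 — the Het/Hom biology — with no model
  selection over the number of components; covariates beyond the condition
  indicator and beta-binomial overdispersion are out of scope.
* Degenerate inputs: single-individual genes get the sigma = 0 null fit;
  mixture fits require 2+ individuals; empty post-filter datasets abort
  the CLI with a non-zero exit.

## Known limitations

* The one-condition null LRT is degenerate at zero for most balanced
  genes (see above): p-values are conservative, not uniform.
* The paired bootstrap draws from estimated p_hat_i0, so its null is
  calibrated only up to estimation error in the posterior weights —
  adequate at the simulated scales, but small-N genes inherit extra
  conservatism.
* Pseudo-phasing errors at low depth bias both components upwards; the
  internal-control design removes most but not all of this from the test.
* Unpaired two-group designs and cell-type-resolved ASE are out of scope.
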