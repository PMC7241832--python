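"""Major-haplotype inference ("majority voting") and cross-condition alignment.

The regulatory SNP driving allelic imbalance is unobserved, so each
individual's more highly expressed ("major") haplotype must be inferred
from the counts themselves.  With known phase the haplotype with the larger
summed read count across SNPs is declared major; with unknown phase each
SNP votes independently (the allele with more reads is placed on the major
haplotype).  In paired two-condition designs one condition is phased first
and the other inherits its allele-to-haplotype assignment so that "major"
means the same physical haplotype under both conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_filters import AlleleCount

__all__ = [
    "PhasedObservation",
    "GeneData",
    "pseudo_phase_individual",
    "phase_known_major",
    "choose_reference_condition",
    "align_conditions",
    "phase_gene",
]


@dataclass(frozen=True)
class PhasedObservation:
    """One observation expressed on the inferred major haplotype.

    ``major_count`` is the read count of the allele placed on the major
    haplotype; ``major_is_ref`` records whether that allele was the genomic
    reference allele.
    """

    individual_id: str
    snp_id: str
    major_count: int
    total_count: int
    major_is_ref: bool
    condition: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.major_count <= self.total_count:
            raise ValueError("major_count outside [0, total_count]")


@dataclass
class GeneData:
    """Phased observations for one gene, the unit the likelihoods consume."""

    gene_id: str
    observations: list[PhasedObservation]
    phase_known: bool = False
    paired: bool = False
    reference_condition: str | None = None

    def individuals(self) -> list[str]:
        return sorted({o.individual_id for o in self.observations})

    def snps(self) -> list[str]:
        return sorted({o.snp_id for o in self.observations})

    def conditions(self) -> list[str]:
        return sorted({o.condition for o in self.observations if o.condition})


def _check_single_individual(counts: Sequence[AlleleCount]) -> str:
    if not counts:
        raise ValueError("no observations supplied")
    ids = {c.individual_id for c in counts}
    if len(ids) != 1:
        raise ValueError(f"expected a single individual, got {sorted(ids)}")
    return next(iter(ids))


def pseudo_phase_individual(
    counts: Sequence[AlleleCount],
) -> list[PhasedObservation]:
    """Phase-unknown majority voting for one individual x gene.

    Each SNP independently places its higher-count allele on the major
    haplotype.  Ties go to the reference allele, so results are
    deterministic.
    """
    _check_single_individual(counts)
    out = []
    for c in counts:
        major_is_ref = c.ref_count >= c.alt_count
        out.append(
            PhasedObservation(
                individual_id=c.individual_id,
                snp_id=c.snp_id,
                major_count=max(c.ref_count, c.alt_count),
                total_count=c.total_count,
                major_is_ref=major_is_ref,
                condition=c.condition,
            )
        )
    return out


def phase_known_major(
    counts: Sequence[AlleleCount],
) -> list[PhasedObservation]:
    """Phase-known majority voting for one individual x gene.

    The two haplotypes' total read counts are obtained by summing each
    haplotype's allele counts over SNPs; the haplotype with the larger total
    is major, and per SNP the count of the allele residing on it is
    reported.  A tied vote goes to the haplotype carrying the reference
    allele at the lexicographically first SNP.
    """
    _check_single_individual(counts)
    if any(c.haplotype_of_ref is None for c in counts):
        raise ValueError("phase_known_major requires haplotype_of_ref on every record")
    hap1_total = sum(
        c.ref_count if c.haplotype_of_ref == "hap1" else c.alt_count
        for c in counts
    )
    hap2_total = sum(
        c.ref_count if c.haplotype_of_ref == "hap2" else c.alt_count
        for c in counts
    )
    if hap1_total > hap2_total:
        major_hap = "hap1"
    elif hap2_total > hap1_total:
        major_hap = "hap2"
    else:
        first = min(counts, key=lambda c: c.snp_id)
        major_hap = first.haplotype_of_ref
    out = []
    for c in counts:
        on_major_is_ref = c.haplotype_of_ref == major_hap
        out.append(
            PhasedObservation(
                individual_id=c.individual_id,
                snp_id=c.snp_id,
                major_count=c.ref_count if on_major_is_ref else c.alt_count,
                total_count=c.total_count,
                major_is_ref=on_major_is_ref,
                condition=c.condition,
            )
        )
    return out


def _group_by_individual(
    counts: Iterable[AlleleCount],
) -> dict[str, list[AlleleCount]]:
    groups: dict[str, list[AlleleCount]] = {}
    for c in counts:
        groups.setdefault(c.individual_id, []).append(c)
    return groups


def choose_reference_condition(counts: Sequence[AlleleCount]) -> str:
    """Pick the condition with the larger pooled allelic-imbalance effect.

    Each condition is pseudo-phased independently and its pooled
    major-allele proportion ``sum_ij M_ij / sum_ij Y_ij`` computed; the
    condition with the larger proportion becomes the phasing reference
    (ties break to the first label in sorted order).
    """
    conditions = sorted({c.condition for c in counts if c.condition is not None})
    if len(conditions) != 2:
        raise ValueError(f"expected two conditions, got {conditions}")
    props = {}
    for cond in conditions:
        sub = [c for c in counts if c.condition == cond]
        if not sub:
            raise ValueError(f"condition {cond!r} has no observations")
        major = sum(max(c.ref_count, c.alt_count) for c in sub)
        total = sum(c.total_count for c in sub)
        props[cond] = major / total
    if props[conditions[0]] >= props[conditions[1]]:
        return conditions[0]
    return conditions[1]


def align_conditions(
    counts: Sequence[AlleleCount],
    reference: str,
    phase_known: bool = False,
) -> GeneData:
    """Phase the reference condition and propagate its assignment.

    The reference condition is phased per individual (whole-haplotype vote
    if ``phase_known``, per-SNP vote otherwise); the identical
    allele-to-major-haplotype assignment is then applied to the matched
    observation in the other condition, so ``major_is_ref`` agrees across
    conditions for every matched (individual, SNP) pair.  Observations
    present under only one condition are dropped with a warning.
    """
    conditions = sorted({c.condition for c in counts if c.condition is not None})
    if reference not in conditions or len(conditions) != 2:
        raise ValueError(
            f"reference {reference!r} not among two condition labels {conditions}"
        )
    other = conditions[0] if conditions[1] == reference else conditions[1]
    gene_id = counts[0].gene_id

    by_pair: dict[tuple[str, str], dict[str, AlleleCount]] = {}
    for c in counts:
        by_pair.setdefault((c.individual_id, c.snp_id), {})[c.condition] = c
    unmatched = [k for k, v in by_pair.items() if len(v) != 2]
    if unmatched:
        warnings.warn(
            f"gene {gene_id!r}: dropping {len(unmatched)} observation(s) "
            f"present under only one condition",
            stacklevel=2,
        )
        for k in unmatched:
            del by_pair[k]
    if not by_pair:
        raise ValueError(f"gene {gene_id!r}: no matched observations to align")

    ref_counts = [v[reference] for v in by_pair.values()]
    observations: list[PhasedObservation] = []
    for ind, recs in _group_by_individual(ref_counts).items():
        phased = phase_known_major(recs) if phase_known else pseudo_phase_individual(recs)
        for obs in phased:
            observations.append(obs)
            partner = by_pair[(ind, obs.snp_id)][other]
            major = partner.ref_count if obs.major_is_ref else partner.alt_count
            observations.append(
                PhasedObservation(
                    individual_id=ind,
                    snp_id=obs.snp_id,
                    major_count=major,
                    total_count=partner.total_count,
                    major_is_ref=obs.major_is_ref,
                    condition=other,
                )
            )
    return GeneData(
        gene_id=gene_id,
        observations=observations,
        phase_known=phase_known,
        paired=True,
        reference_condition=reference,
    )


def phase_gene(
    counts: Sequence[AlleleCount], phase_known: bool = False
) -> GeneData:
    """Phase all individuals of one gene for one-condition analysis."""
    if not counts:
        raise ValueError("no observations supplied")
    gene_id = counts[0].gene_id
    observations: list[PhasedObservation] = []
    for recs in _group_by_individual(counts).values():
        phased = phase_known_major(recs) if phase_known else pseudo_phase_individual(recs)
        observations.extend(phased)
    return GeneData(
        gene_id=gene_id,
        observations=observations,
        phase_known=phase_known,
        paired=False,
    )
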