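"""Reading, validation and filtering of allele-specific count tables.

The unit record is one individual x transcribed SNP (x condition): the
reference-allele read count ``X`` and the total read count ``Y`` at a
heterozygous exonic SNP, as produced by an allele-aware counter downstream
of WASP-style filtering.  This module does not touch alignments; it only
consumes delimited text tables and applies the SNP-, individual- and
gene-level count filters used before model fitting.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import pandas as pd

__all__ = [
    "AlleleCount",
    "FilterConfig",
    "read_allele_counts",
    "filter_snp_observations",
    "filter_genes",
    "write_results",
    "RESULT_COLUMNS",
]


@dataclass(frozen=True)
class AlleleCount:
    """One allele-specific count observation.

    Parameters
    ----------
    gene_id, individual_id, snp_id
        Identifiers; ``(gene_id, individual_id, snp_id, condition)`` must be
        unique within a dataset.
    ref_count
        Reads carrying the genomic reference allele (``X``).
    total_count
        Total reads overlapping the SNP (``Y``); ``0 <= X <= Y`` and ``Y > 0``.
    condition
        Optional condition label (exactly two distinct values in paired mode).
    haplotype_of_ref
        Optional phase annotation: which haplotype (``"hap1"``/``"hap2"``)
        carries the reference allele.  Either present on every record of a
        gene or on none.
    """

    gene_id: str
    individual_id: str
    snp_id: str
    ref_count: int
    total_count: int
    condition: str | None = None
    haplotype_of_ref: str | None = None

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ValueError(
                f"total_count must be positive, got {self.total_count}"
            )
        if not 0 <= self.ref_count <= self.total_count:
            raise ValueError(
                f"ref_count {self.ref_count} outside [0, {self.total_count}]"
            )
        if self.haplotype_of_ref is not None and self.haplotype_of_ref not in (
            "hap1",
            "hap2",
        ):
            raise ValueError(
                f"haplotype_of_ref must be 'hap1' or 'hap2', got "
                f"{self.haplotype_of_ref!r}"
            )

    @property
    def alt_count(self) -> int:
        return self.total_count - self.ref_count

    @property
    def minor_count(self) -> int:
        """Count of the less-expressed allele at this SNP in this individual."""
        return min(self.ref_count, self.alt_count)


@dataclass(frozen=True)
class FilterConfig:
    """Count-filter thresholds.

    Defaults reproduce the filters used for real-data analyses: an
    observation is dropped when the minor allele count is below 5, the total
    count below 20, or the minor count below 5% of the total; genes must be
    observed in at least 3 individuals, and in paired designs must retain at
    least 3 matched (individual, SNP) pairs.
    """

    min_minor_count: int = 5
    min_total_count: int = 20
    min_minor_fraction: float = 0.05
    min_individuals_per_gene: int = 3
    min_matched_pairs: int = 3

    def __post_init__(self) -> None:
        if min(self.min_minor_count, self.min_total_count,
               self.min_individuals_per_gene, self.min_matched_pairs) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_minor_fraction <= 0.5:
            raise ValueError("min_minor_fraction must lie in [0, 0.5]")


_COLUMN_ALIASES = {
    "gene": "gene_id",
    "gene_id": "gene_id",
    "id": "individual_id",
    "individual": "individual_id",
    "individual_id": "individual_id",
    "snp": "snp_id",
    "snp_id": "snp_id",
    "ref_count": "ref_count",
    "total_count": "total_count",
    "condition": "condition",
    "hap_of_ref": "haplotype_of_ref",
    "haplotype_of_ref": "haplotype_of_ref",
}


def read_allele_counts(
    stream: IO[str] | str,
    has_condition: bool = False,
    has_phase: bool = False,
) -> list[AlleleCount]:
    """Read a delimited allele-count table into validated records.

    ``stream`` may be a path or an open text handle.  TSV and CSV are both
    accepted (delimiter sniffed from the header).  A header naming at least
    gene, individual, snp, ref_count and total_count columns is required.
    Rows violating the count invariants (``X > Y`` or ``Y <= 0``) are
    rejected, and the offending 1-based data row numbers reported in a
    warning.  Duplicate keys and mixed phase annotation within a gene raise
    ``ValueError``.
    """
    if isinstance(stream, str):
        with open(stream, "r") as fh:
            text = fh.read()
    else:
        text = stream.read()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - defensive
        raise ValueError(f"malformed table: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns=_COLUMN_ALIASES)

    required = ["gene_id", "individual_id", "snp_id", "ref_count", "total_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if has_condition and "condition" not in df.columns:
        raise ValueError("has_condition=True but no condition column found")
    if has_phase and "haplotype_of_ref" not in df.columns:
        raise ValueError("has_phase=True but no haplotype column found")

    records: list[AlleleCount] = []
    rejected: list[int] = []
    seen: set[tuple] = set()
    phase_by_gene: dict[str, bool] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            ref = int(rec["ref_count"])
            tot = int(rec["total_count"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"row {row_no}: malformed numeric field "
                f"(ref_count={rec['ref_count']!r}, "
                f"total_count={rec['total_count']!r})"
            ) from exc
        condition = None
        if has_condition:
            condition = str(rec["condition"])
        hap = None
        if has_phase:
            raw = rec["haplotype_of_ref"]
            hap = None if pd.isna(raw) else str(raw)
        gene = str(rec["gene_id"])
        has_hap = hap is not None
        if gene in phase_by_gene and phase_by_gene[gene] != has_hap:
            raise ValueError(
                f"row {row_no}: mixed phase annotation within gene {gene!r}"
            )
        phase_by_gene[gene] = has_hap
        key = (gene, str(rec["individual_id"]), str(rec["snp_id"]), condition)
        if key in seen:
            raise ValueError(f"row {row_no}: duplicate record key {key}")
        seen.add(key)
        try:
            records.append(
                AlleleCount(
                    gene_id=gene,
                    individual_id=str(rec["individual_id"]),
                    snp_id=str(rec["snp_id"]),
                    ref_count=ref,
                    total_count=tot,
                    condition=condition,
                    haplotype_of_ref=hap,
                )
            )
        except ValueError:
            rejected.append(row_no)
    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} row(s) violating count invariants: "
            f"rows {rejected}",
            stacklevel=2,
        )
    return records


def filter_snp_observations(
    counts: Iterable[AlleleCount], cfg: FilterConfig | None = None
) -> list[AlleleCount]:
    """Apply per-observation count filters.

    An observation is *excluded* when its minor allele count is strictly
    below ``min_minor_count``, its total count strictly below
    ``min_total_count``, or its minor count strictly below
    ``min_minor_fraction`` of the total.  Homozygous-looking observations
    (minor count 0) are removed by the first rule under defaults.
    """
    cfg = cfg or FilterConfig()
    kept = []
    for rec in counts:
        minor = rec.minor_count
        if minor < cfg.min_minor_count:
            continue
        if rec.total_count < cfg.min_total_count:
            continue
        if minor < cfg.min_minor_fraction * rec.total_count:
            continue
        kept.append(rec)
    return kept


def filter_genes(
    counts: Iterable[AlleleCount],
    cfg: FilterConfig | None = None,
    paired: bool = False,
) -> list[AlleleCount]:
    """Apply gene-level filters after SNP-level filtering.

    One-condition mode keeps genes observed in at least
    ``min_individuals_per_gene`` distinct individuals.  Paired mode
    additionally requires at least ``min_matched_pairs`` (individual, SNP)
    pairs with counts under both conditions, and drops unmatched
    observations within retained genes.
    """
    cfg = cfg or FilterConfig()
    counts = list(counts)
    by_gene: dict[str, list[AlleleCount]] = {}
    for rec in counts:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    kept: list[AlleleCount] = []
    for rec_list in by_gene.values():
        individuals = {r.individual_id for r in rec_list}
        if len(individuals) < cfg.min_individuals_per_gene:
            continue
        if not paired:
            kept.extend(rec_list)
            continue
        conditions = sorted({r.condition for r in rec_list if r.condition is not None})
        if len(conditions) != 2:
            raise ValueError(
                f"paired filtering requires exactly two condition labels, "
                f"got {conditions} for gene {rec_list[0].gene_id!r}"
            )
        pair_conditions: dict[tuple[str, str], set] = {}
        for r in rec_list:
            pair_conditions.setdefault(
                (r.individual_id, r.snp_id), set()
            ).add(r.condition)
        matched = {k for k, v in pair_conditions.items() if len(v) == 2}
        if len(matched) < cfg.min_matched_pairs:
            continue
        kept.extend(
            r for r in rec_list if (r.individual_id, r.snp_id) in matched
        )
    # preserve input ordering
    kept_set = {id(r) for r in kept}
    return [r for r in counts if id(r) in kept_set]


RESULT_COLUMNS = [
    "gene",
    "n_individuals",
    "n_snps",
    "lrt",
    "p_value",
    "n_sim",
    "q_value",
    "pi",
    "mu1",
    "mu2",
    "beta1",
    "beta2",
]


def write_results(results: Sequence, stream: IO[str] | str) -> None:
    """Write per-gene test results as a delimited table.

    Columns follow :data:`RESULT_COLUMNS`; rows are sorted by q-value then
    gene id.  Floats are printed with 6 significant digits, which
    round-trips through :func:`pandas.read_csv` at the documented precision.
    """
    rows = []
    for res in results:
        fit = res.fit_h1
        rows.append(
            {
                "gene": res.gene_id,
                "n_individuals": res.n_individuals,
                "n_snps": res.n_snps,
                "lrt": res.lrt,
                "p_value": res.p_value,
                "n_sim": res.n_sim,
                "q_value": res.q_value,
                "pi": fit.pi,
                "mu1": fit.mu1,
                "mu2": fit.mu2,
                "beta1": getattr(fit, "beta1", float("nan")),
                "beta2": getattr(fit, "beta2", float("nan")),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df = df.sort_values(["q_value", "gene"], kind="stable")
    try:
        df.to_csv(stream, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise OSError(f"failed writing results to {stream!r}: {exc}") from exc
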