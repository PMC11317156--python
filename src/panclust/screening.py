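"""Genome screening filters and multi-split bin bookkeeping.

Implements the default quality/size screens applied to recovered genomes:
the viral quality filter (viral/host gene ratio, completeness and quality
tiers from a CheckV-style summary), the organism-specific genome-size
filter (150 kb prokaryotic, 2 Mb eukaryotic defaults), generalized
multi-split partitioning of bins from concatenated multi-sample assemblies
(contigs carry a ``Sample__`` prefix), and the unbinned-contig feedback set
for iterative binning.  All threshold comparisons are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

QUALITY_TIERS = ("complete", "high", "medium", "low", "not-determined")
PASSING_TIERS = frozenset({"complete", "high", "medium"})
GENOME_SIZE_DEFAULTS = {"prokaryotic": 150_000, "eukaryotic": 2_000_000}
SAMPLE_DELIMITER = "__"


@dataclass(frozen=True)
class ViralQualityRecord:
    genome_id: str
    n_viral_genes: int
    n_host_genes: int
    completeness_pct: float
    quality_tier: str
    miuvig_tier: str

    def __post_init__(self):
        if self.n_viral_genes < 0 or self.n_host_genes < 0:
            raise ValueError(f"{self.genome_id}: negative gene counts")
        for tier in (self.quality_tier, self.miuvig_tier):
            if tier not in QUALITY_TIERS:
                raise ValueError(
                    f"{self.genome_id}: unknown quality tier {tier!r}"
                )


@dataclass(frozen=True)
class FilterResult:
    genome_id: str
    passed: bool
    reasons: tuple[str, ...]  # every failed clause, empty when passed


def viral_quality_filter(
    records: Iterable[ViralQualityRecord],
    min_gene_ratio: float = 5.0,
    min_completeness: float = 50.0,
) -> list[FilterResult]:
    """Default viral genome filter.

    Pass requires all of: viral genes >= ``min_gene_ratio`` x host genes,
    completeness >= ``min_completeness``%, and both the quality tier and
    the MIUViG tier in {medium, high, complete}.  Failed clauses are all
    reported.
    """
    results = []
    for rec in records:
        reasons = []
        if rec.n_viral_genes < min_gene_ratio * rec.n_host_genes:
            reasons.append(
                f"viral/host gene ratio: {rec.n_viral_genes} < "
                f"{min_gene_ratio} x {rec.n_host_genes}"
            )
        if rec.completeness_pct < min_completeness:
            reasons.append(
                f"completeness {rec.completeness_pct}% < {min_completeness}%"
            )
        if rec.quality_tier not in PASSING_TIERS:
            reasons.append(f"quality tier {rec.quality_tier!r}")
        if rec.miuvig_tier not in PASSING_TIERS:
            reasons.append(f"MIUViG tier {rec.miuvig_tier!r}")
        results.append(
            FilterResult(rec.genome_id, passed=not reasons, reasons=tuple(reasons))
        )
    return results


def genome_size_filter(
    bin_sizes: Mapping[str, int],
    organism_type: str,
    threshold_bp: int | None = None,
) -> dict[str, int]:
    """Retain bins whose size is at least the organism-type threshold.

    Defaults: 150 000 bp (prokaryotic), 2 000 000 bp (eukaryotic); other
    organism types require an explicit ``threshold_bp``.  The boundary is
    inclusive.
    """
    if threshold_bp is None:
        if organism_type not in GENOME_SIZE_DEFAULTS:
            raise ValueError(
                f"no default size threshold for organism type {organism_type!r}; "
                "pass threshold_bp explicitly"
            )
        threshold_bp = GENOME_SIZE_DEFAULTS[organism_type]
    return {b: s for b, s in bin_sizes.items() if s >= threshold_bp}


def split_sample(contig_id: str) -> tuple[str, str]:
    """Split ``Sample__contig`` at the first double-underscore delimiter."""
    if SAMPLE_DELIMITER not in contig_id:
        raise ValueError(
            f"contig {contig_id!r} lacks the {SAMPLE_DELIMITER!r} sample delimiter"
        )
    sample, rest = contig_id.split(SAMPLE_DELIMITER, 1)
    return sample, rest


def multisplit_partition(
    bin_to_contigs: Mapping[str, Sequence[str]],
    contig_sizes: Mapping[str, int] | None = None,
    algorithm: str = "METABAT2",
    organism_code: str = "P",
    iteration: int = 1,
    size_threshold_bp: int | None = None,
) -> dict[str, list[str]]:
    """Partition multi-sample bins by each contig's sample of origin.

    Each bin from a concatenated multi-sample assembly is split into one
    bin per contributing sample.  Output bin ids follow the MAG naming
    scheme ``[SampleID]__[Algorithm]__<code>.[Iteration]__[Name]`` (code P
    for prokaryotic, E for eukaryotic).  When ``contig_sizes`` and
    ``size_threshold_bp`` are given, per-sample bins below the threshold
    are dropped (inclusive boundary).
    """
    out: dict[str, list[str]] = {}
    for bin_name, contigs in bin_to_contigs.items():
        per_sample: dict[str, list[str]] = {}
        for contig in contigs:
            sample, _ = split_sample(contig)
            per_sample.setdefault(sample, []).append(contig)
        for sample, members in per_sample.items():
            new_id = (
                f"{sample}{SAMPLE_DELIMITER}{algorithm}{SAMPLE_DELIMITER}"
                f"{organism_code}.{iteration}{SAMPLE_DELIMITER}{bin_name}"
            )
            out[new_id] = list(members)
    if contig_sizes is not None and size_threshold_bp is not None:
        out = {
            bin_id: members
            for bin_id, members in out.items()
            if sum(contig_sizes[c] for c in members) >= size_threshold_bp
        }
    return out


def unbinned_feedback(
    all_contigs: Iterable[str], passing_bins: Mapping[str, Sequence[str]]
) -> set[str]:
    """Contigs not captured by any passing bin, for the next binning round.

    Contigs of bins that failed the quality/size filters (and hence are
    absent from ``passing_bins``) are returned along with never-binned
    contigs.
    """
    binned = {c for contigs in passing_bins.values() for c in contigs}
    return set(all_contigs) - binned
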