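"""Biosynthetic gene cluster (BGC) identifiers, novelty and prevalence.

BGCs get structured identifiers ``[id_genome]|[id_contig]|[id_region]`` and
their genes ``[id_bgc]_[position] | [start]:[end] ([strand])``.  The novelty
score of a BGC is the fraction of its genes with no homology to the MIBiG
reference, flagging candidate novel chemistry (scores above 0.85 are
conventionally reported as high novelty).  Prevalence tables tally BGC
protein-cluster members per genome and BGC nucleotide-cluster members per
sample; booleanized tables yield Jaccard distances for ordination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.spatial.distance import pdist, squareform

HIGH_NOVELTY_THRESHOLD = 0.85


@dataclass(frozen=True)
class BGCGene:
    gene_id: str
    start: int
    end: int
    strand: str
    mibig_hit: bool = False
    vfdb_hit: bool = False

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid 1-based interval {self.start}:{self.end} for {self.gene_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class BGCRecord:
    bgc_id: str
    genes: tuple[BGCGene, ...]
    on_contig_edge: bool = False
    length_bp: int = 0
    protocluster_type: str = ""


def make_bgc_identifiers(
    genome_id: str,
    contig_id: str,
    region_id: str,
    gene_intervals: Sequence[tuple[int, int, str]],
) -> tuple[str, list[str]]:
    """Structured identifiers for a BGC and its genes.

    ``gene_intervals`` are 1-based inclusive ``(start, end, strand)``
    tuples sorted by position.  The BGC id is
    ``genome|contig|region`` and gene ids follow
    ``<bgc_id>_<position> | <start>:<end> (<strand>)`` with positions
    numbered from 1.
    """
    for part in (genome_id, contig_id, region_id):
        if "|" in part:
            raise ValueError(f"identifier component {part!r} contains '|'")
        if not part:
            raise ValueError("empty identifier component")
    starts = [start for start, _, _ in gene_intervals]
    if starts != sorted(starts):
        raise ValueError("gene intervals must be sorted by start position")
    bgc_id = f"{genome_id}|{contig_id}|{region_id}"
    gene_ids = [
        f"{bgc_id}_{index} | {start}:{end} ({strand})"
        for index, (start, end, strand) in enumerate(gene_intervals, start=1)
    ]
    return bgc_id, gene_ids


def build_bgc_record(
    genome_id: str,
    contig_id: str,
    region_id: str,
    gene_intervals: Sequence[tuple[int, int, str]],
    mibig_hits: Sequence[bool] | None = None,
    vfdb_hits: Sequence[bool] | None = None,
    on_contig_edge: bool = False,
    protocluster_type: str = "",
) -> BGCRecord:
    bgc_id, gene_ids = make_bgc_identifiers(
        genome_id, contig_id, region_id, gene_intervals
    )
    n = len(gene_intervals)
    mibig_hits = list(mibig_hits) if mibig_hits is not None else [False] * n
    vfdb_hits = list(vfdb_hits) if vfdb_hits is not None else [False] * n
    genes = tuple(
        BGCGene(
            gene_id=gid,
            start=start,
            end=end,
            strand=strand,
            mibig_hit=mh,
            vfdb_hit=vh,
        )
        for gid, (start, end, strand), mh, vh in zip(
            gene_ids, gene_intervals, mibig_hits, vfdb_hits
        )
    )
    length_bp = max((g.end for g in genes), default=0)
    return BGCRecord(
        bgc_id=bgc_id,
        genes=genes,
        on_contig_edge=on_contig_edge,
        length_bp=length_bp,
        protocluster_type=protocluster_type,
    )


def novelty_score(bgc: BGCRecord) -> float:
    """Fraction of the BGC's genes with no MIBiG homology, in [0, 1]."""
    if not bgc.genes:
        raise ValueError(f"{bgc.bgc_id}: novelty undefined for an empty gene list")
    no_hit = sum(1 for gene in bgc.genes if not gene.mibig_hit)
    return no_hit / len(bgc.genes)


def bgc_prevalence(
    protein_cluster_members: Mapping[str, Sequence[str]],
    nucleotide_cluster_members: Mapping[str, Sequence[str]],
    protein_to_genome: Mapping[str, str],
    bgc_to_sample: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prevalence tables for BGC protein clusters and nucleotide clusters.

    Returns ``(genome x protein-cluster counts, sample x nucleotide-cluster
    counts)``.  Every protein member must map to a genome and every
    nucleotide member (a BGC id) to a sample.
    """

    def tally(members: Mapping[str, Sequence[str]], mapping: Mapping[str, str], what):
        counts: Counter = Counter()
        rows = set()
        for cluster, ids in members.items():
            for member in ids:
                if member not in mapping:
                    raise ValueError(f"{what} member {member!r} is unmapped")
                counts[(mapping[member], cluster)] += 1
                rows.add(mapping[member])
        table = pd.DataFrame(
            0, index=sorted(rows), columns=sorted(members), dtype=int
        )
        for (row, cluster), n in counts.items():
            table.loc[row, cluster] = n
        return table

    protein_table = tally(protein_cluster_members, protein_to_genome, "protein")
    nucleotide_table = tally(nucleotide_cluster_members, bgc_to_sample, "nucleotide")
    return protein_table, nucleotide_table


def jaccard_distance(prevalence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between the rows of a prevalence table.

    The table is booleanized (count > 0) first; d(x, y) = 1 - |x&y|/|x|y|.
    Rows with an empty union are at distance 0 (avoids NaN in downstream
    ordination).
    """
    boolean = (prevalence > 0).to_numpy(dtype=bool)
    if boolean.shape[0] < 2:
        return pd.DataFrame(
            0.0, index=prevalence.index, columns=prevalence.index
        )
    condensed = pdist(boolean, metric="jaccard")  # 0/0 defined as 0
    return pd.DataFrame(
        squareform(condensed), index=prevalence.index, columns=prevalence.index
    )
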