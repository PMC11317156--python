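"""Pangenome protein clustering and prevalence analytics.

Proteins are pooled per species-level cluster (SLC) and clustered
independently within each SLC into SLC-specific protein clusters (SSPC,
labelled ``<SLC>_SSPC-<j>``).  Genome x SSPC copy-count prevalence tables
drive the core/singleton logic; marker genes are SSPCs core in exactly one
SLC with no homology to any other SLC's representatives.  Consensus
annotations and consensus lineages summarize member-level metadata at the
cluster level, and Fisher's exact test supports case/control enrichment of
cluster presence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from panclust.backends import ClusteringBackend, GreedyKmerBackend

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class ProteinClusterSSPC:
    label: str
    slc_label: str
    representative_id: str
    member_protein_ids: tuple[str, ...]

    def __post_init__(self):
        if self.representative_id not in self.member_protein_ids:
            raise ValueError(
                f"{self.label}: representative {self.representative_id!r} is "
                "not a member"
            )


def cluster_proteins_within_slc(
    proteins: Mapping[str, Mapping[str, str]],
    slc_assignment: Mapping[str, str],
    identity: float = 0.5,
    coverage: float = 0.8,
    backend: ClusteringBackend | None = None,
) -> list[ProteinClusterSSPC]:
    """Cluster each SLC's pooled proteome into SSPCs.

    Parameters
    ----------
    proteins:
        genome_id -> {protein_id -> sequence}; protein ids must be globally
        unique.
    slc_assignment:
        genome_id -> SLC label; every genome with proteins must be assigned.

    Clustering is independent per SLC.  Within an SLC, clusters are numbered
    1..C by decreasing size, ties broken by lexicographically smallest
    representative id.
    """
    if backend is None:
        backend = GreedyKmerBackend()
    unassigned = sorted(set(proteins) - set(slc_assignment))
    if unassigned:
        raise ValueError(f"genomes without SLC assignment: {unassigned[:3]}")

    pooled: dict[str, dict[str, str]] = {}
    for genome_id, prots in proteins.items():
        slc = slc_assignment[genome_id]
        pooled.setdefault(slc, {}).update(prots)

    sspcs: list[ProteinClusterSSPC] = []
    for slc in sorted(pooled):
        member_to_rep = backend.cluster(pooled[slc], identity, coverage)
        groups: dict[str, list[str]] = {}
        for member, rep in member_to_rep.items():
            groups.setdefault(rep, []).append(member)
        ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        for j, (rep, members) in enumerate(ordered, start=1):
            sspcs.append(
                ProteinClusterSSPC(
                    label=f"{slc}_SSPC-{j}",
                    slc_label=slc,
                    representative_id=rep,
                    member_protein_ids=tuple(sorted(members)),
                )
            )
    return sspcs


def prevalence_table(
    sspcs: Sequence[ProteinClusterSSPC],
    protein_to_genome: Mapping[str, str],
    slc_label: str,
    genomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genome x SSPC copy-count matrix for one SLC.

    ``genomes`` fixes the row set (genomes of the SLC); by default the rows
    are the genomes observed among members.  Column sums equal cluster
    member counts.
    """
    slc_sspcs = [c for c in sspcs if c.slc_label == slc_label]
    counts: dict[tuple[str, str], int] = Counter()
    observed_genomes = set(genomes or ())
    for cluster in slc_sspcs:
        for protein_id in cluster.member_protein_ids:
            if protein_id not in protein_to_genome:
                raise ValueError(f"protein {protein_id!r} has no genome mapping")
            genome = protein_to_genome[protein_id]
            counts[(genome, cluster.label)] += 1
            observed_genomes.add(genome)
    table = pd.DataFrame(
        0,
        index=sorted(observed_genomes),
        columns=[c.label for c in slc_sspcs],
        dtype=int,
    )
    for (genome, label), n in counts.items():
        table.loc[genome, label] = n
    return table


def core_and_singleton(
    table: pd.DataFrame, core_fraction: float = 1.0
) -> tuple[list[str], list[str]]:
    """Core and singleton SSPCs of one prevalence table.

    Core: present (count >= 1) in at least ``core_fraction`` of the SLC's
    genomes.  Singleton: present in exactly one genome.
    """
    if table.empty:
        raise ValueError("empty prevalence table")
    if not 0.0 < core_fraction <= 1.0:
        raise ValueError(f"core_fraction must be in (0, 1], got {core_fraction}")
    presence = (table >= 1).sum(axis=0)
    n_genomes = table.shape[0]
    # tiny tolerance so fractions like 2/3 on 3 genomes behave exactly
    core = sorted(presence.index[presence >= core_fraction * n_genomes - 1e-9])
    singleton = sorted(presence.index[presence == 1])
    return core, singleton


def marker_genes(
    tables: Mapping[str, pd.DataFrame],
    representative_sequences: Mapping[str, str],
    identity: float = 0.5,
    core_fraction: float = 1.0,
    backend: GreedyKmerBackend | None = None,
) -> dict[str, list[str]]:
    """Cross-pangenome marker SSPCs.

    A marker is an SSPC that is core within its own SLC and whose
    representative has no match at or above ``identity`` to the
    representative of any SSPC of any other SLC.

    Parameters
    ----------
    tables:
        SLC label -> prevalence table.
    representative_sequences:
        SSPC label -> representative protein sequence, covering every column
        of every table.
    """
    if backend is None:
        backend = GreedyKmerBackend()
    missing = {
        label
        for table in tables.values()
        for label in table.columns
        if label not in representative_sequences
    }
    if missing:
        raise ValueError(f"missing representative sequences: {sorted(missing)[:3]}")

    markers: dict[str, list[str]] = {}
    for slc, table in sorted(tables.items()):
        core, _ = core_and_singleton(table, core_fraction)
        other_reps = [
            (other_label, representative_sequences[col])
            for other_label, other_table in tables.items()
            if other_label != slc
            for col in other_table.columns
        ]
        slc_markers = []
        for label in core:
            seq = representative_sequences[label]
            if any(
                backend.identity(seq, other_seq) >= identity
                for _, other_seq in other_reps
            ):
                continue
            slc_markers.append(label)
        markers[slc] = slc_markers
    return markers


def consensus_annotation(
    member_annotations: Mapping[str, Mapping[str, str]],
    members: Sequence[str],
    databases: Sequence[str] | None = None,
) -> dict[str, tuple[str, float]]:
    """Consensus (term, support) per annotation database for one cluster.

    The consensus is the most frequent non-empty term among members (ties
    broken lexicographically); support is its frequency over the member
    count.  A database with no annotated member yields ``("", 0.0)``.
    """
    if databases is None:
        databases = sorted(
            {db for pid in members for db in member_annotations.get(pid, {})}
        )
    out: dict[str, tuple[str, float]] = {}
    for db in databases:
        votes = Counter(
            term
            for pid in members
            if (term := member_annotations.get(pid, {}).get(db, ""))
        )
        if not votes:
            out[db] = ("", 0.0)
            continue
        best = min(votes, key=lambda t: (-votes[t], t))
        out[db] = (best, votes[best] / len(members))
    return out


@dataclass(frozen=True)
class Lineage:
    """Seven-rank taxonomic lineage; empty ranks only at the tail."""

    ranks: tuple[str, ...]

    def __post_init__(self):
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} ranks, got {len(self.ranks)}")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a semicolon lineage string like ``d__Bacteria;p__...;s__``."""
        parts = [p.strip() for p in text.split(";")]
        values = []
        for i, prefix in enumerate(_RANK_PREFIXES):
            if i < len(parts):
                part = parts[i]
                values.append(part[len(prefix):] if part.startswith(prefix) else part)
            else:
                values.append("")
        return cls(tuple(values))

    def truncate(self, depth: int) -> "Lineage":
        return Lineage(self.ranks[:depth] + ("",) * (len(RANKS) - depth))

    def to_string(self) -> str:
        return ";".join(p + v for p, v in zip(_RANK_PREFIXES, self.ranks))


def consensus_lineage(
    lineages: Sequence[Lineage],
    weights: Sequence[float] | None = None,
    agreement_threshold: float = 0.5,
) -> Lineage:
    """Weighted consensus lineage of an SLC's member genomes.

    Per rank from domain downward: take the weighted modal value among
    non-empty votes (ties broken lexicographically); if its weight fraction
    among non-empty votes is below ``agreement_threshold``, or all votes
    are empty, truncate at that rank (and all lower ranks).
    """
    if not lineages:
        raise ValueError("empty cluster: no lineages to summarize")
    if weights is None:
        weights = [1.0] * len(lineages)
    if len(weights) != len(lineages):
        raise ValueError("weights and lineages differ in length")
    consensus: list[str] = []
    for rank_index in range(len(RANKS)):
        votes: dict[str, float] = {}
        for lineage, weight in zip(lineages, weights):
            value = lineage.ranks[rank_index]
            if value:
                votes[value] = votes.get(value, 0.0) + weight
        if not votes:
            break
        total = sum(votes.values())
        best = min(votes, key=lambda v: (-votes[v], v))
        if votes[best] / total < agreement_threshold:
            break
        consensus.append(best)
    return Lineage(tuple(consensus) + ("",) * (len(RANKS) - len(consensus)))


def enrichment_test(a: int, b: int, c: int, d: int, sided: str = "one") -> float:
    """Fisher's exact p-value for the 2x2 table [[a, b], [c, d]].

    ``sided="two"`` uses the minimum-likelihood convention (the sum of all
    tables with point probability at most the observed one).  ``sided="one"``
    takes the tail in the direction of the observed deviation from
    independence: the lower tail on ``a`` when a is at or below its
    expectation under the margins, the upper tail otherwise.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    if a + b + c + d == 0 or min(a + b, c + d, a + c, b + d) < 0:
        raise ValueError("degenerate table")
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise ValueError("all-zero margin")
    table = [[a, b], [c, d]]
    if sided == "two":
        return float(fisher_exact(table, alternative="two-sided").pvalue)
    if sided != "one":
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    expected_a = (a + b) * (a + c) / (a + b + c + d)
    alternative = "less" if a <= expected_a else "greater"
    return float(fisher_exact(table, alternative=alternative).pvalue)
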