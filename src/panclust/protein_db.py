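"""Non-redundant protein database construction and stepwise clustering tiers.

Implements the construction logic of clustered microeukaryotic protein
databases of the MicroEuk100/90/50 kind: sequences are normalized (stop
characters stripped, uppercased), length-filtered, dereplicated by md5
content hash with source-database priority, then clustered stepwise at
decreasing identity thresholds so that each tier clusters the
representatives of the previous one.  Representation and compression
statistics summarize how well each tier covers the source organisms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from panclust.backends import ClusteringBackend, GreedyKmerBackend

# IUPAC amino-acid codes, extended (B/Z/J ambiguity, U/O rare, X unknown).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO")
MIN_LENGTH_AA = 11  # shorter sequences invite greedy over-clustering


class MalformedSequenceError(ValueError):
    """Raised for empty sequences or characters outside the amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    hash_id: str
    sequence: str
    source_organism: str
    source_database: str
    priority_rank: int

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDatabase:
    """Dereplicated protein records keyed by content hash.

    ``organisms`` records every organism whose proteome contained each hash,
    including organisms whose copy arrived after the first (dropped as a
    duplicate record but still counted as represented).
    """

    records: dict[str, ProteinRecord] = field(default_factory=dict)
    organisms: dict[str, set[str]] = field(default_factory=dict)
    priority_order: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def hashes_of_organism(self, organism: str) -> set[str]:
        return {h for h, orgs in self.organisms.items() if organism in orgs}


@dataclass
class ClusteredTier:
    tier_label: str
    representatives: set[str]
    member_to_rep: dict[str, str]
    identity_threshold: float
    coverage_threshold: float


def normalize_and_hash(raw_sequence: str) -> tuple[str, str] | None:
    """Normalize an amino-acid sequence and compute its md5 identifier.

    All ``*`` (stop) characters are removed and the sequence uppercased, so
    two proteins differing only by a stop codon or by case hash identically.
    Returns ``None`` (rejected) when the normalized sequence is shorter than
    11 residues; raises :class:`MalformedSequenceError` for empty input or
    characters outside the IUPAC amino-acid alphabet.
    """
    if not raw_sequence:
        raise MalformedSequenceError("empty sequence")
    upper = raw_sequence.upper()
    bad = set(upper) - AMINO_ACIDS - {"*"}
    if bad:
        raise MalformedSequenceError(
            f"non-amino-acid characters {sorted(bad)} in sequence"
        )
    normalized = upper.replace("*", "")
    if len(normalized) < MIN_LENGTH_AA:
        return None
    hash_id = hashlib.md5(normalized.encode("utf-8")).hexdigest()
    return normalized, hash_id


def build_nonredundant(
    source_sets: Sequence[tuple[str, Iterable[tuple[str, str]]]],
) -> SequenceDatabase:
    """Build a non-redundant database from prioritized sources.

    Parameters
    ----------
    source_sets:
        ``(database_name, proteins)`` pairs in priority order (first =
        highest priority); ``proteins`` yields ``(source_organism,
        raw_sequence)`` pairs.  The first occurrence of a hash wins; later
        duplicates are dropped but their organisms are still recorded as
        represented.  Sequences rejected by the length filter are skipped.
    """
    names = [name for name, _ in source_sets]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate database names in {names}")
    db = SequenceDatabase(priority_order=list(names))
    for rank, (database_name, proteins) in enumerate(source_sets, start=1):
        for organism, raw_seq in proteins:
            normalized = normalize_and_hash(raw_seq)
            if normalized is None:
                continue
            sequence, hash_id = normalized
            if hash_id not in db.records:
                db.records[hash_id] = ProteinRecord(
                    hash_id=hash_id,
                    sequence=sequence,
                    source_organism=organism,
                    source_database=database_name,
                    priority_rank=rank,
                )
                db.organisms[hash_id] = set()
            db.organisms[hash_id].add(organism)
    return db


def stepwise_cluster(
    db: SequenceDatabase,
    thresholds: Sequence[tuple[float, float]],
    backend: ClusteringBackend | None = None,
) -> list[ClusteredTier]:
    """Cluster the database stepwise at decreasing identity thresholds.

    Tier 0 (label ``"100"``) is the full non-redundant database; tier k
    clusters the representatives of tier k-1, so member maps compose
    transitively (see :func:`resolve_representative`).

    ``thresholds`` is a list of ``(identity, coverage)`` fractions ordered by
    strictly decreasing identity; tier labels are the identity percentages
    (0.9 -> ``"90"``).
    """
    identities = [ident for ident, _ in thresholds]
    if any(b >= a for a, b in zip(identities, identities[1:])):
        raise ValueError(f"identity thresholds must strictly decrease: {identities}")
    if backend is None:
        backend = GreedyKmerBackend()

    all_hashes = set(db.records)
    tiers = [
        ClusteredTier(
            tier_label="100",
            representatives=set(all_hashes),
            member_to_rep={h: h for h in all_hashes},
            identity_threshold=1.0,
            coverage_threshold=1.0,
        )
    ]
    for identity, coverage in thresholds:
        parent_reps = tiers[-1].representatives
        sequences = {h: db.records[h].sequence for h in parent_reps}
        member_to_rep = backend.cluster(sequences, identity, coverage)
        label = f"{identity * 100:g}"
        tiers.append(
            ClusteredTier(
                tier_label=label,
                representatives=set(member_to_rep.values()),
                member_to_rep=member_to_rep,
                identity_threshold=identity,
                coverage_threshold=coverage,
            )
        )
    return tiers


def resolve_representative(tiers: Sequence[ClusteredTier], hash_id: str) -> str:
    """Resolve an original record to its representative in the last tier."""
    rep = hash_id
    for tier in tiers:
        if rep in tier.member_to_rep:
            rep = tier.member_to_rep[rep]
    return rep


def organism_tier_counts(
    db: SequenceDatabase, tiers: Sequence[ClusteredTier]
) -> dict[str, int]:
    """Number of organisms represented in each tier.

    An organism is represented in a tier when at least one of its proteins
    is a cluster representative of that tier.
    """
    organism_hashes: dict[str, set[str]] = {}
    for hash_id, orgs in db.organisms.items():
        for org in orgs:
            organism_hashes.setdefault(org, set()).add(hash_id)
    counts: dict[str, int] = {}
    for tier in tiers:
        counts[tier.tier_label] = sum(
            1 for hashes in organism_hashes.values() if hashes & tier.representatives
        )
    return counts


def representation_stats(
    tier_organism_counts: Mapping[str, int], denominator: int
) -> dict[str, float]:
    """Per-tier organism representation as percentages of ``denominator``."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    for tier, count in tier_organism_counts.items():
        if count < 0:
            raise ValueError(f"negative count for tier {tier!r}")
    return {
        tier: 100.0 * count / denominator
        for tier, count in tier_organism_counts.items()
    }


def compression_ratio(n_tier: int, n_parent: int) -> float:
    """Fraction of the parent tier removed by clustering: 1 - n_tier/n_parent."""
    if n_parent <= 0:
        raise ValueError(f"parent count must be positive, got {n_parent}")
    if not 0 < n_tier <= n_parent:
        raise ValueError(
            f"tier count must be in (0, parent], got {n_tier} of {n_parent}"
        )
    return 1.0 - n_tier / n_parent
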