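"""Sequence-clustering backends.

External workflows typically delegate large-scale sequence clustering to
dedicated tools (MMseqs2, DeepClust) and consume their member->representative
tables.  This module defines the clustering contract those tables satisfy and
ships a desk-scale greedy incremental backend so the whole pipeline runs
self-contained.

The contract: a backend is any object with a method ::

    cluster(sequences: Mapping[str, str], identity: float, coverage: float)
        -> dict[str, str]

returning a member -> representative map over exactly the input keys, where
every representative maps to itself.
"""

from __future__ import annotations

from typing import Mapping, Protocol


class ClusteringBackend(Protocol):
    def cluster(
        self, sequences: Mapping[str, str], identity: float, coverage: float
    ) -> dict[str, str]: ...


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


class GreedyKmerBackend:
    """Greedy incremental clustering with a k-mer identity estimate.

    Sequences are visited longest-first; each sequence joins the first
    existing representative whose estimated identity and length coverage
    meet the thresholds, otherwise it founds a new cluster.  Identity is
    estimated from shared-k-mer containment C (shared k-mers over the
    smaller k-mer set) corrected to the per-site scale as C**(1/k), the
    standard relation between k-mer survival and per-site identity.

    Parameters
    ----------
    k:
        k-mer size; 5 is a reasonable default for amino-acid sequences.
    """

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        self.k = k

    def identity(self, seq_a: str, seq_b: str) -> float:
        """Estimated per-site identity between two sequences, in [0, 1]."""
        if not seq_a or not seq_b:
            raise ValueError("cannot estimate identity of an empty sequence")
        if seq_a == seq_b:
            return 1.0
        ka, kb = _kmer_set(seq_a, self.k), _kmer_set(seq_b, self.k)
        containment = len(ka & kb) / min(len(ka), len(kb))
        return containment ** (1.0 / self.k)

    def coverage(self, seq_a: str, seq_b: str) -> float:
        """Length coverage of the shorter sequence over the longer."""
        la, lb = len(seq_a), len(seq_b)
        return min(la, lb) / max(la, lb)

    def cluster(
        self, sequences: Mapping[str, str], identity: float, coverage: float
    ) -> dict[str, str]:
        if not 0.0 < identity <= 1.0:
            raise ValueError(f"identity must be in (0, 1], got {identity}")
        if not 0.0 < coverage <= 1.0:
            raise ValueError(f"coverage must be in (0, 1], got {coverage}")
        # longest-first, id as deterministic tie-break
        order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
        representatives: list[str] = []
        member_to_rep: dict[str, str] = {}
        for seq_id in order:
            seq = sequences[seq_id]
            for rep in representatives:
                rep_seq = sequences[rep]
                if self.coverage(seq, rep_seq) < coverage:
                    continue
                if self.identity(seq, rep_seq) >= identity:
                    member_to_rep[seq_id] = rep
                    break
            else:
                representatives.append(seq_id)
                member_to_rep[seq_id] = seq_id
        return member_to_rep


class PrecomputedBackend:
    """Clustering 'backend' that replays an externally computed assignment.

    Accepts a member -> representative map (e.g. parsed from an MMseqs2
    cluster TSV) and returns it restricted to the requested sequences,
    ignoring the identity/coverage arguments.
    """

    def __init__(self, member_to_rep: Mapping[str, str]):
        self._assignment = dict(member_to_rep)

    def cluster(
        self, sequences: Mapping[str, str], identity: float, coverage: float
    ) -> dict[str, str]:
        missing = set(sequences) - set(self._assignment)
        if missing:
            raise ValueError(
                f"precomputed assignment lacks {len(missing)} sequences, "
                f"e.g. {sorted(missing)[:3]}"
            )
        out = {s: self._assignment[s] for s in sequences}
        for member, rep in out.items():
            if rep not in sequences:
                raise ValueError(
                    f"representative {rep!r} of {member!r} is not among the inputs"
                )
        return out
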