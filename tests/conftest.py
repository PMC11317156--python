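"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from panclust.backends import GreedyKmerBackend

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def backend() -> GreedyKmerBackend:
    return GreedyKmerBackend(k=5)


def hamming_identity(seq_a: str, seq_b: str) -> float:
    """Exact global alignment identity for equal-length, substitution-only
    sequences (no indels): 1 - hamming / length."""
    assert len(seq_a) == len(seq_b)
    mismatches = sum(a != b for a, b in zip(seq_a, seq_b))
    return 1.0 - mismatches / len(seq_a)


def greedy_oracle(
    sequences: dict[str, str], identity: float, identity_fn=hamming_identity
) -> dict[str, str]:
    """Re-implementation of the greedy assignment rule with an exact
    identity oracle, used to cross-check the k-mer backend."""
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    reps: list[str] = []
    out: dict[str, str] = {}
    for sid in order:
        for rep in reps:
            if identity_fn(sequences[sid], sequences[rep]) >= identity:
                out[sid] = rep
                break
        else:
            reps.append(sid)
            out[sid] = sid
    return out


def partition_of(member_to_rep: dict[str, str]) -> set[frozenset[str]]:
    groups: dict[str, set[str]] = {}
    for member, rep in member_to_rep.items():
        groups.setdefault(rep, set()).add(member)
    return {frozenset(g) for g in groups.values()}


def mutate_protein(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Substitution-only protein mutation at a per-site rate."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for ch in sequence:
        if rng.random() < rate:
            choices = alphabet.replace(ch, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def random_protein(rng: np.random.Generator, length: int = 240) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(alphabet[i] for i in rng.integers(0, 20, size=length))
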