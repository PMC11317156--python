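"""Species-level genome clustering on a thresholded ANI graph.

Genomes are nodes, pairwise average nucleotide identity (ANI) values are
weighted edges; connected components of the graph restricted to edges at or
above a threshold (default >= 95% ANI, the standard species boundary) are
the species-level clusters (SLC).  Prokaryotic, eukaryotic and viral
genomes are clustered separately and labelled PSLC-k / ESLC-k / VSLC-k.

ANI edges can be supplied from any external tool (skani/FastANI-style TSV)
or estimated desk-scale with the built-in MinHash bottom-sketch backend and
the Mash distance closed form D = -(1/k) ln(2J / (1 + J)), ANI% = 100(1-D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np


class OrganismType(str, Enum):
    prokaryotic = "prokaryotic"
    eukaryotic = "eukaryotic"
    viral = "viral"


SLC_PREFIX = {
    OrganismType.prokaryotic: "PSLC",
    OrganismType.eukaryotic: "ESLC",
    OrganismType.viral: "VSLC",
}


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    organism_type: OrganismType
    sample_id: str = ""
    size_bp: int = 0
    sequence: str | None = None

    def __post_init__(self):
        if self.sequence is not None and self.size_bp:
            if len(self.sequence) != self.size_bp:
                raise ValueError(
                    f"{self.genome_id}: size_bp {self.size_bp} != sequence "
                    f"length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class ANIEdge:
    """Unordered ANI edge; endpoints are stored sorted and self-edges rejected."""

    genome_a: str
    genome_b: str
    ani_percent: float
    aligned_fraction: float = 1.0

    def __post_init__(self):
        if self.genome_a == self.genome_b:
            raise ValueError(f"self-edge on {self.genome_a}")
        if not 0.0 <= self.ani_percent <= 100.0:
            raise ValueError(f"ANI must be in [0, 100], got {self.ani_percent}")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError(
                f"aligned fraction must be in [0, 1], got {self.aligned_fraction}"
            )
        if self.genome_a > self.genome_b:
            a, b = self.genome_a, self.genome_b
            object.__setattr__(self, "genome_a", b)
            object.__setattr__(self, "genome_b", a)


@dataclass
class GenomeSketch:
    k: int
    sketch_size: int
    seed: int
    min_hashes: np.ndarray  # sorted uint64

    def __post_init__(self):
        if len(self.min_hashes) > self.sketch_size:
            raise ValueError("sketch holds more hashes than sketch_size")


# ---------------------------------------------------------------------------
# MinHash bottom-sketch ANI backend
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int8)
for _base, _c in zip(b"ACGT", range(4)):
    _CODE[_base] = _c
    _CODE[_base + 32] = _c  # lowercase


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: a fast, well-mixed 64-bit hash (wraps mod 2^64)."""
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return x ^ (x >> np.uint64(31))


def _canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    n_kmers = len(codes) - k + 1
    if n_kmers <= 0:
        raise ValueError(f"sequence length {len(codes)} < k={k}")
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    win = win[ok].astype(np.uint64)
    if win.size == 0:
        return np.empty(0, dtype=np.uint64)
    shifts = (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(
        np.uint64
    )
    fwd = (win << shifts).sum(axis=1, dtype=np.uint64)
    # reverse complement: complement code is 3 - code, order reversed
    rc_win = (np.uint64(3) - win)[:, ::-1]
    rev = (rc_win << shifts).sum(axis=1, dtype=np.uint64)
    return np.minimum(fwd, rev)


def sketch_genome(
    sequence: str, k: int = 21, sketch_size: int = 1000, seed: int = 0
) -> GenomeSketch:
    """Bottom sketch of hashed canonical k-mers of a nucleotide sequence.

    Canonical k-mer = lexicographic minimum of the k-mer and its reverse
    complement, so a sequence and its reverse complement sketch identically.
    k-mers containing non-ACGT characters are skipped.  Deterministic given
    ``seed``.
    """
    if k < 1 or k % 2 == 0 or k > 31:
        raise ValueError(f"k must be odd and in [1, 31], got {k}")
    kmers = _canonical_kmer_codes(sequence, k)
    hashed = np.unique(_splitmix64(kmers ^ _splitmix64(np.uint64(seed))))
    return GenomeSketch(
        k=k, sketch_size=sketch_size, seed=seed, min_hashes=hashed[:sketch_size]
    )


def estimate_ani(sketch_a: GenomeSketch, sketch_b: GenomeSketch) -> float:
    """Mash-style ANI estimate (percent) from two bottom sketches.

    Jaccard is estimated on the merged bottom sketch (the ``sketch_size``
    smallest hashes of the union); the Mash distance
    D = -(1/k) ln(2J / (1 + J)) converts it to ANI% = 100 (1 - D),
    clamped to [0, 100], with J = 0 mapping to ANI 0 by convention.
    """
    if (sketch_a.k, sketch_a.sketch_size, sketch_a.seed) != (
        sketch_b.k,
        sketch_b.sketch_size,
        sketch_b.seed,
    ):
        raise ValueError("sketches built with different parameters")
    jaccard = sketch_jaccard(sketch_a, sketch_b)
    if jaccard == 0.0:
        return 0.0
    distance = -math.log(2.0 * jaccard / (1.0 + jaccard)) / sketch_a.k
    return max(0.0, min(100.0, 100.0 * (1.0 - distance)))


def estimate_ani_edge(
    genome_a: str,
    genome_b: str,
    sketch_a: GenomeSketch,
    sketch_b: GenomeSketch,
) -> ANIEdge:
    """ANI edge between two genomes from their sketches.

    The built-in backend cannot measure alignment fraction, so edges carry
    aligned_fraction = 1 (i.e. the aligned-fraction filter is disabled).
    """
    return ANIEdge(
        genome_a, genome_b, ani_percent=estimate_ani(sketch_a, sketch_b)
    )


def sketch_jaccard(sketch_a: GenomeSketch, sketch_b: GenomeSketch) -> float:
    """Merged-bottom-sketch Jaccard estimate (the J used by estimate_ani_edge)."""
    union = np.union1d(sketch_a.min_hashes, sketch_b.min_hashes)
    merged = union[: sketch_a.sketch_size]
    shared = np.intersect1d(
        np.intersect1d(merged, sketch_a.min_hashes), sketch_b.min_hashes
    )
    return shared.size / merged.size if merged.size else 0.0


def pairwise_ani(
    genomes: Sequence[GenomeRecord],
    k: int = 21,
    sketch_size: int = 1000,
    seed: int = 0,
) -> list[ANIEdge]:
    """All-pairs ANI edges (within organism type) from the built-in backend."""
    sketches = {
        g.genome_id: sketch_genome(g.sequence, k, sketch_size, seed)
        for g in genomes
        if g.sequence is not None
    }
    edges = []
    ordered = sorted(sketches)
    types = {g.genome_id: g.organism_type for g in genomes}
    for i, ga in enumerate(ordered):
        for gb in ordered[i + 1 :]:
            if types[ga] != types[gb]:
                continue
            edges.append(estimate_ani_edge(ga, gb, sketches[ga], sketches[gb]))
    return edges


# ---------------------------------------------------------------------------
# SLC assignment
# ---------------------------------------------------------------------------


@dataclass
class SLCAssignment:
    """Genome -> species-level-cluster labels plus the filtered ANI graph."""

    labels: dict[str, str]
    graph: nx.Graph = field(default_factory=nx.Graph, repr=False)

    def __getitem__(self, genome_id: str) -> str:
        return self.labels[genome_id]

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for genome, label in self.labels.items():
            out.setdefault(label, []).append(genome)
        return {label: sorted(members) for label, members in out.items()}


def build_ani_graph(
    edges: Iterable[ANIEdge],
    genomes: Sequence[GenomeRecord],
    ani_threshold: float = 95.0,
    min_aligned_fraction: float = 0.0,
) -> nx.Graph:
    """ANI graph over all genomes with sub-threshold edges removed."""
    if not 0.0 < ani_threshold <= 100.0:
        raise ValueError(f"ANI threshold must be in (0, 100], got {ani_threshold}")
    by_id = {g.genome_id: g for g in genomes}
    graph = nx.Graph()
    for genome in genomes:
        graph.add_node(genome.genome_id, organism_type=genome.organism_type.value)
    for edge in edges:
        for endpoint in (edge.genome_a, edge.genome_b):
            if endpoint not in by_id:
                raise ValueError(f"edge endpoint {endpoint!r} not among genomes")
        if by_id[edge.genome_a].organism_type != by_id[edge.genome_b].organism_type:
            raise ValueError(
                f"edge {edge.genome_a}--{edge.genome_b} crosses organism types"
            )
        if edge.ani_percent < ani_threshold:
            continue
        if edge.aligned_fraction < min_aligned_fraction:
            continue
        graph.add_edge(
            edge.genome_a,
            edge.genome_b,
            ani=edge.ani_percent,
            aligned_fraction=edge.aligned_fraction,
        )
    return graph


def assign_slcs(
    edges: Iterable[ANIEdge],
    genomes: Sequence[GenomeRecord],
    ani_threshold: float = 95.0,
    min_aligned_fraction: float = 0.0,
) -> SLCAssignment:
    """Species-level clusters = connected components of the thresholded graph.

    Components are computed per organism type and numbered 1..C by
    decreasing size, ties broken by the lexicographically smallest member
    genome id; singletons get their own labels.  The assignment is a
    partition and is invariant to edge order.
    """
    graph = build_ani_graph(edges, genomes, ani_threshold, min_aligned_fraction)
    labels: dict[str, str] = {}
    for organism_type in OrganismType:
        nodes = [
            g.genome_id for g in genomes if g.organism_type == organism_type
        ]
        if not nodes:
            continue
        sub = graph.subgraph(nodes)
        components = sorted(
            (sorted(c) for c in nx.connected_components(sub)),
            key=lambda c: (-len(c), c[0]),
        )
        prefix = SLC_PREFIX[organism_type]
        for idx, component in enumerate(components, start=1):
            for genome_id in component:
                labels[genome_id] = f"{prefix}-{idx}"
    return SLCAssignment(labels=labels, graph=graph)


def feature_compression_ratio(n_features: int, n_clusters: int) -> float:
    """FCR = 1 - n_clusters / n_features: redundancy of a feature set."""
    if n_features < 1:
        raise ValueError(f"need at least one feature, got {n_features}")
    if not 1 <= n_clusters <= n_features:
        raise ValueError(
            f"cluster count must be in [1, n_features], got {n_clusters} of "
            f"{n_features}"
        )
    return 1.0 - n_clusters / n_features


@dataclass
class ClusteringReport:
    assignment: SLCAssignment
    fcr: float


def local_clustering(
    genomes: Sequence[GenomeRecord],
    edges: Iterable[ANIEdge],
    mode: str = "global",
    ani_threshold: float = 95.0,
    min_aligned_fraction: float = 0.0,
) -> dict[str, ClusteringReport]:
    """Global (inter-sample) or local (intra-sample) clustering with FCRs.

    Global mode clusters all genomes together and reports one FCR under the
    key ``"global"``; local mode restricts edges to same-sample pairs and
    reports one assignment and FCR per sample.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    edges = list(edges)
    if mode == "global":
        assignment = assign_slcs(edges, genomes, ani_threshold, min_aligned_fraction)
        n_clusters = len(set(assignment.labels.values()))
        return {
            "global": ClusteringReport(
                assignment, feature_compression_ratio(len(genomes), n_clusters)
            )
        }
    missing = [g.genome_id for g in genomes if not g.sample_id]
    if missing:
        raise ValueError(f"local mode requires sample ids; missing for {missing[:3]}")
    sample_of = {g.genome_id: g.sample_id for g in genomes}
    reports: dict[str, ClusteringReport] = {}
    for sample in sorted({g.sample_id for g in genomes}):
        sample_genomes = [g for g in genomes if g.sample_id == sample]
        sample_edges = [
            e
            for e in edges
            if sample_of.get(e.genome_a) == sample
            and sample_of.get(e.genome_b) == sample
        ]
        assignment = assign_slcs(
            sample_edges, sample_genomes, ani_threshold, min_aligned_fraction
        )
        n_clusters = len(set(assignment.labels.values()))
        reports[sample] = ClusteringReport(
            assignment, feature_compression_ratio(len(sample_genomes), n_clusters)
        )
    return reports
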