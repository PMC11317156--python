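"""Synthetic data generators and bundled worked-example tables.

Every input the analysis modules consume can be generated here with planted
ground truth: genomes with a known species structure (substitution-only
mutation from per-species ancestors, so expected ANI ~ 100 (1 - divergence)),
proteomes with planted gene families (shared families homologous across
species, one private core family per species for marker-gene tests) and a
synthetic KO/module universe, and compositional count tables drawn from a
known sparse precision matrix for network-recovery tests.

The module also embeds two published worked-example tables of the clustered
microeukaryotic protein database releases: the MicroEuk100/90/50 source
organism summary (sequence counts, per-source organism counts, totals) and
the per-genome CDS counts of eight re-analysed marine eukaryotic genomes
under four database versions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from panclust.genome_clustering import GenomeRecord, OrganismType

NUCLEOTIDES = np.array(list("ACGT"))
AMINO_ACIDS20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-structure genome/proteome generator."""

    seed: int = 0
    n_species: int = 3
    genomes_per_species: int = 4
    genome_length_bp: int = 50_000
    within_species_divergence: float = 0.02
    between_species_divergence: float = 0.30
    gene_families: int = 5
    samples: int = 4

    def __post_init__(self):
        for name in (
            "n_species",
            "genomes_per_species",
            "genome_length_bp",
            "gene_families",
            "samples",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("within_species_divergence", "between_species_divergence"):
            value = getattr(self, name)
            if not 0.0 <= value < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {value}")
        if self.within_species_divergence >= self.between_species_divergence:
            raise ValueError(
                "within-species divergence must be below between-species divergence"
            )


def _mutate(sequence: np.ndarray, rate: float, alphabet: np.ndarray, rng) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different symbol."""
    out = sequence.copy()
    hits = np.nonzero(rng.random(len(sequence)) < rate)[0]
    if hits.size:
        # draw a strictly different symbol at each hit site
        offsets = rng.integers(1, len(alphabet), size=hits.size)
        current = np.searchsorted(alphabet, sequence[hits])
        out[hits] = alphabet[(current + offsets) % len(alphabet)]
    return out


def simulate_genomes(
    spec: FixtureSpec, organism_type: OrganismType = OrganismType.prokaryotic
) -> tuple[list[GenomeRecord], dict[str, int]]:
    """Genomes with planted species structure.

    One ancestor per species (each derived from a common root at the
    between-species rate); members substitute i.i.d. at the within-species
    rate, so the expected ANI between two members of one species is about
    100 (1 - 2 x within_species_divergence).  Genome ids carry a
    ``S<k>__`` sample prefix (round-robin over samples).  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    root = rng.choice(NUCLEOTIDES, size=spec.genome_length_bp)
    genomes: list[GenomeRecord] = []
    species_of: dict[str, int] = {}
    counter = 0
    for s in range(spec.n_species):
        ancestor = _mutate(root, spec.between_species_divergence, NUCLEOTIDES, rng)
        for g in range(spec.genomes_per_species):
            member = _mutate(
                ancestor, spec.within_species_divergence, NUCLEOTIDES, rng
            )
            sample = f"S{counter % spec.samples + 1}"
            genome_id = f"{sample}__sp{s + 1}.g{g + 1}"
            sequence = "".join(member)
            genomes.append(
                GenomeRecord(
                    genome_id=genome_id,
                    organism_type=organism_type,
                    sample_id=sample,
                    size_bp=len(sequence),
                    sequence=sequence,
                )
            )
            species_of[genome_id] = s
            counter += 1
    return genomes, species_of


def simulate_proteome(
    genomes: Sequence[GenomeRecord],
    species_of: Mapping[str, int],
    spec: FixtureSpec,
    protein_length_aa: int = 240,
    protein_divergence: float | None = None,
) -> tuple[dict[str, dict[str, str]], dict[str, tuple[int, str]], dict[str, str]]:
    """Proteomes with planted families and a synthetic KO map.

    Per species: ``spec.gene_families`` shared families (one ancestor per
    family, common to all species, so they are homologous across species)
    plus one private core family (an independent random sequence per
    species, absent elsewhere) for marker-gene tests.  Every genome carries
    one copy of each family of its species.

    Returns ``(proteins, family_of, ko_of)`` where ``proteins`` maps genome
    -> {protein_id -> sequence}, ``family_of`` maps protein_id ->
    (species, family name), and ``ko_of`` maps protein_id to a synthetic
    KO from the bundled module universe.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if protein_divergence is None:
        protein_divergence = spec.within_species_divergence
    shared_ancestors = [
        rng.choice(AMINO_ACIDS20, size=protein_length_aa)
        for _ in range(spec.gene_families)
    ]
    n_species = max(species_of.values()) + 1
    private_ancestors = [
        rng.choice(AMINO_ACIDS20, size=protein_length_aa) for _ in range(n_species)
    ]
    kos = synthetic_ko_universe()
    proteins: dict[str, dict[str, str]] = {}
    family_of: dict[str, tuple[int, str]] = {}
    ko_of: dict[str, str] = {}
    for genome in genomes:
        species = species_of[genome.genome_id]
        prots: dict[str, str] = {}
        for f, ancestor in enumerate(shared_ancestors):
            pid = f"{genome.genome_id}|fam{f + 1}"
            prots[pid] = "".join(
                _mutate(ancestor, protein_divergence, AMINO_ACIDS20, rng)
            )
            family_of[pid] = (species, f"fam{f + 1}")
            ko_of[pid] = kos[f % len(kos)]
        pid = f"{genome.genome_id}|private"
        prots[pid] = "".join(
            _mutate(private_ancestors[species], protein_divergence, AMINO_ACIDS20, rng)
        )
        family_of[pid] = (species, "private")
        ko_of[pid] = kos[(spec.gene_families + species) % len(kos)]
        proteins[genome.genome_id] = prots
    return proteins, family_of, ko_of


# -- compositional counts ----------------------------------------------------


def paired_precision(
    n_nodes: int = 10, n_edges: int = 5, partial_correlation: float = 0.9
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Precision matrix with disjoint positively-coupled pairs.

    Edge (2i, 2i+1) couples a pair with the given positive partial
    correlation (latent correlation equals partial correlation in this
    disjoint design).  Returns the precision matrix and the planted edges.
    """
    if n_edges * 2 > n_nodes:
        raise ValueError("disjoint pairs need n_nodes >= 2 * n_edges")
    if not 0.0 < partial_correlation < 1.0:
        raise ValueError("partial correlation must be in (0, 1)")
    precision = np.eye(n_nodes)
    rho = partial_correlation
    diag = 1.0 / (1.0 - rho**2)
    off = -rho / (1.0 - rho**2)
    edges = set()
    for i in range(n_edges):
        a, b = 2 * i, 2 * i + 1
        precision[a, a] = precision[b, b] = diag
        precision[a, b] = precision[b, a] = off
        edges.add((a, b))
    return precision, edges


def chain_precision(n_nodes: int = 3, strength: float = 0.4) -> np.ndarray:
    """Tridiagonal precision: a chain X1 - X2 - ... with zero long-range partials."""
    precision = np.eye(n_nodes)
    for i in range(n_nodes - 1):
        precision[i, i + 1] = precision[i + 1, i] = -strength
    if np.linalg.eigvalsh(precision).min() <= 0:
        raise ValueError(f"chain strength {strength} is not positive definite")
    return precision


def simulate_counts(
    n_samples: int,
    precision_matrix: np.ndarray,
    seed: int = 0,
    depth: int = 100_000,
) -> tuple[pd.DataFrame, set[tuple[int, int]]]:
    """Compositional counts from a latent Gaussian with known precision.

    Latent log-abundances are multivariate normal with covariance equal to
    the inverse precision; each sample's exponentiated abundances are
    closed to relative abundances and multinomially sampled to ``depth``
    integer counts.  True edges are the pairs with negative off-diagonal
    precision (positive partial correlation).
    """
    precision = np.asarray(precision_matrix, dtype=float)
    if not np.allclose(precision, precision.T):
        raise ValueError("precision matrix must be symmetric")
    eigenvalues = np.linalg.eigvalsh(precision)
    if eigenvalues.min() <= 0:
        raise ValueError("precision matrix must be positive definite")
    p = precision.shape[0]
    covariance = np.linalg.inv(precision)
    rng = np.random.default_rng(seed)
    latent = rng.multivariate_normal(np.zeros(p), covariance, size=n_samples)
    abundances = np.exp(latent)
    counts = np.vstack(
        [rng.multinomial(depth, row / row.sum()) for row in abundances]
    )
    table = pd.DataFrame(
        counts,
        index=[f"sample_{i + 1}" for i in range(n_samples)],
        columns=[f"SLC-{j + 1}" for j in range(p)],
    )
    true_edges = {
        (i, j) for i in range(p) for j in range(i + 1, p) if precision[i, j] < 0
    }
    return table, true_edges


def planted_block_graph(
    n_blocks: int = 3,
    block_size: int = 4,
    within_weight: float = 1.0,
    across_weight: float = 0.05,
) -> tuple[nx.Graph, dict[str, int]]:
    """Weighted graph with planted communities for consensus-detection tests."""
    graph = nx.Graph()
    truth: dict[str, int] = {}
    nodes = []
    for b in range(n_blocks):
        for i in range(block_size):
            node = f"n{b * block_size + i + 1:02d}"
            graph.add_node(node)
            truth[node] = b
            nodes.append(node)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            weight = within_weight if truth[a] == truth[b] else across_weight
            if weight > 0:
                graph.add_edge(a, b, weight=weight)
    return graph, truth


# -- synthetic KO / module universe ------------------------------------------


def synthetic_ko_universe() -> list[str]:
    """Twenty synthetic KO identifiers used by the bundled module set."""
    return [f"K{i:05d}" for i in range(1, 21)]


SYNTHETIC_MODULE_DEFINITIONS: dict[str, str] = {
    "M00001": "K00001 K00002 K00003",
    "M00002": "K00004,K00005 K00006",
    "M00003": "(K00007+K00008),K00009 K00010",
    "M00004": "K00011+K00012 K00013-K00014",
    "M00005": "K00015 -- K00016",
    "M00006": "K00017,(K00018+K00019) K00020",
}


# -- bundled worked-example tables -------------------------------------------

# Published summary of the MicroEuk100/90/50 clustered protein database
# releases: per-source organism counts per tier, sequence counts, and the
# organism totals used as representation denominators (52 495 including the
# NCBI nr protists/fungi padding, 4 278 excluding it).
_MICROEUK_TIERS = ["MicroEuk100", "MicroEuk90", "MicroEuk50", "MicroEuk100.eukaryota_odb10"]
_MICROEUK_SOURCE_ORGANISMS = {
    "MycoCosm": (2503, 2503, 2503, 2500),
    "PhycoCosm": (174, 174, 174, 173),
    "EnsemblProtists": (233, 227, 227, 212),
    "MMETSP": (578, 578, 578, 570),
    "TARA_SAGv1": (8, 8, 8, 8),
    "EukProt": (366, 355, 348, 310),
    "EukZoo": (27, 25, 22, 18),
    "TARA_SMAGv1": (389, 389, 389, 388),
    "NR_Protists-Fungi": (48217, 11279, 4364, 1523),
}
_MICROEUK_SEQUENCES = (79_920_431, 51_767_730, 29_898_853, 713_072)
_MICROEUK_TOTAL_INCLUDING_NR = (52_495, 15_538, 8_613, 5_702)
_MICROEUK_TOTAL_EXCLUDING_NR = (4_278, 4_259, 4_249, 4_179)

# Per-genome CDS counts of eight re-analysed marine eukaryotic genomes
# modeled against four protein database versions.
_CDS_COLUMNS = ["MicroEuk_v2", "MicroEuk50", "MicroEuk90", "MicroEuk100"]
_CDS_COUNTS = {
    "ERR2002407__METABAT2__E.1__bin.2": (15655, 16478, 16755, 17098),
    "ERR2002416__METABAT2__E.1__bin.1": (17176, 18258, 18518, 18932),
    "ERR2002419__METABAT2__E.1__bin.2": (17127, 18192, 18459, 18843),
    "SRR17458614__METABAT2__E.1__bin.2": (11475, 12196, 12249, 12384),
    "SRR17458615__METABAT2__E.1__bin.2": (11434, 12169, 12229, 12362),
    "SRR17458630__METABAT2__E.1__bin.3": (19827, 21130, 21344, 21647),
    "SRR17458638__METABAT2__E.1__bin.3": (21006, 23208, 23336, 23612),
    "SRR17458638__METABAT2__E.1__bin.2": (15008, 15548, 15691, 16025),
}


def microeuk_summary() -> dict[str, pd.Series | pd.DataFrame]:
    """Bundled MicroEuk100/90/50 database summary (worked-example input).

    Keys: ``source_organisms`` (source x tier organism counts),
    ``sequences`` (sequence count per tier), ``total_including_nr`` and
    ``total_excluding_nr`` (organism totals per tier).
    """
    sources = pd.DataFrame(
        _MICROEUK_SOURCE_ORGANISMS, index=_MICROEUK_TIERS
    ).T
    return {
        "source_organisms": sources,
        "sequences": pd.Series(_MICROEUK_SEQUENCES, index=_MICROEUK_TIERS),
        "total_including_nr": pd.Series(
            _MICROEUK_TOTAL_INCLUDING_NR, index=_MICROEUK_TIERS
        ),
        "total_excluding_nr": pd.Series(
            _MICROEUK_TOTAL_EXCLUDING_NR, index=_MICROEUK_TIERS
        ),
    }


def cds_recovery_counts() -> pd.DataFrame:
    """Bundled per-genome CDS counts under four database versions."""
    return pd.DataFrame(_CDS_COUNTS, index=_CDS_COLUMNS).T


def mean_gene_gain_percent(cds_counts: pd.DataFrame | None = None) -> pd.Series:
    """Mean percent CDS increase of each database tier over the v2 baseline.

    Per genome the increase is 100 (CDS_tier - CDS_v2) / CDS_v2; the
    reported value is the mean across genomes.
    """
    if cds_counts is None:
        cds_counts = cds_recovery_counts()
    baseline = cds_counts["MicroEuk_v2"]
    tiers = [c for c in cds_counts.columns if c != "MicroEuk_v2"]
    gains = {
        tier: float((100.0 * (cds_counts[tier] - baseline) / baseline).mean())
        for tier in tiers
    }
    return pd.Series(gains)
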