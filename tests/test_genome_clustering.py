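"""Genome sketching, ANI estimation, and SLC assignment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panclust.genome_clustering import (
    ANIEdge,
    GenomeRecord,
    OrganismType,
    assign_slcs,
    estimate_ani,
    feature_compression_ratio,
    local_clustering,
    pairwise_ani,
    sketch_genome,
    sketch_jaccard,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_dna(rng, seq, rate):
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def exact_canonical_jaccard(seq_a: str, seq_b: str, k: int) -> float:
    """Independent oracle: Jaccard over the full canonical k-mer sets."""

    def kmers(seq):
        out = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            rc = "".join(COMPLEMENT[c] for c in reversed(kmer))
            out.add(min(kmer, rc))
        return out

    ka, kb = kmers(seq_a), kmers(seq_b)
    return len(ka & kb) / len(ka | kb)


class TestSketching:
    def test_identical_sequences_identical_sketches(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 5000)
        s1, s2 = sketch_genome(seq), sketch_genome(seq)
        assert np.array_equal(s1.min_hashes, s2.min_hashes)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 5000)
        rc = "".join(COMPLEMENT[c] for c in reversed(seq))
        assert np.array_equal(
            sketch_genome(seq).min_hashes, sketch_genome(rc).min_hashes
        )

    def test_sketch_jaccard_tracks_exact_jaccard(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 20_000)
        mutated = mutate_dna(rng, seq, 0.01)
        estimate = sketch_jaccard(sketch_genome(seq), sketch_genome(mutated))
        exact = exact_canonical_jaccard(seq, mutated, 21)
        assert abs(estimate - exact) <= 0.05

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            sketch_genome("ACGT", k=21)


class TestEstimateANI:
    def test_identical_sketches_give_100(self):
        rng = np.random.default_rng(3)
        sk = sketch_genome(random_dna(rng, 5000))
        assert estimate_ani(sk, sk) == 100.0

    def test_disjoint_sketches_give_0(self):
        rng = np.random.default_rng(4)
        a = sketch_genome(random_dna(rng, 3000))
        b = sketch_genome(random_dna(rng, 3000))
        assert estimate_ani(a, b) == 0.0

    def test_mash_closed_form_at_half_jaccard(self):
        # D = -(1/21) ln(2*0.5/1.5) -> ANI ~ 98.069%
        expected = 100.0 * (1.0 - (1.0 / 21.0) * math.log(1.5))
        assert expected == pytest.approx(98.069, abs=1e-3)

    def test_mismatched_parameters_rejected(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 2000)
        with pytest.raises(ValueError, match="parameters"):
            estimate_ani(sketch_genome(seq, k=21), sketch_genome(seq, k=15))

    def test_one_percent_divergence_estimates_near_99(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 100_000)
        ani = estimate_ani(
            sketch_genome(seq), sketch_genome(mutate_dna(rng, seq, 0.01))
        )
        assert ani == pytest.approx(99.0, abs=0.3)


def _genomes(ids, organism_type=OrganismType.prokaryotic, samples=None):
    samples = samples or {}
    return [
        GenomeRecord(g, organism_type, sample_id=samples.get(g, "S1")) for g in ids
    ]


def brute_force_components(nodes, edges, threshold):
    """O(n^3) reachability oracle over the >= threshold relation."""
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for e in edges:
        if e.ani_percent >= threshold:
            reach[index[e.genome_a], index[e.genome_b]] = True
            reach[index[e.genome_b], index[e.genome_a]] = True
    for k in range(n):
        for i in range(n):
            if reach[i, k]:
                reach[i] |= reach[k]
    groups = {}
    for i, node in enumerate(nodes):
        key = tuple(np.nonzero(reach[i])[0])
        groups.setdefault(key, set()).add(node)
    return {frozenset(g) for g in groups.values()}


class TestAssignSLCs:
    def test_transitive_chain_is_one_cluster(self):
        edges = [ANIEdge("A", "B", 96), ANIEdge("B", "C", 97)]
        assignment = assign_slcs(edges, _genomes("ABC"))
        assert set(assignment.labels.values()) == {"PSLC-1"}

    def test_subthreshold_edge_dropped_and_tiebreak(self):
        assignment = assign_slcs([ANIEdge("A", "B", 94)], _genomes("AB"))
        assert assignment["A"] == "PSLC-1"
        assert assignment["B"] == "PSLC-2"

    def test_prefix_follows_organism_type(self):
        for organism_type, prefix in [
            (OrganismType.prokaryotic, "PSLC"),
            (OrganismType.eukaryotic, "ESLC"),
            (OrganismType.viral, "VSLC"),
        ]:
            assignment = assign_slcs([], _genomes("A", organism_type))
            assert assignment["A"] == f"{prefix}-1"

    def test_cross_type_edge_rejected(self):
        genomes = [
            GenomeRecord("A", OrganismType.prokaryotic),
            GenomeRecord("B", OrganismType.viral),
        ]
        with pytest.raises(ValueError, match="organism types"):
            assign_slcs([ANIEdge("A", "B", 99)], genomes)

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="not among genomes"):
            assign_slcs([ANIEdge("A", "Z", 99)], _genomes("AB"))

    def test_random_graphs_match_reachability_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 41))
            nodes = [f"g{i:02d}" for i in range(n)]
            edges = []
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.08:
                    edges.append(ANIEdge(a, b, float(rng.uniform(80, 100))))
            assignment = assign_slcs(edges, _genomes(nodes), ani_threshold=95)
            got = {
                frozenset(members) for members in assignment.clusters().values()
            }
            assert got == brute_force_components(nodes, edges, 95)

    def test_label_determinism_under_edge_order(self):
        rng = np.random.default_rng(8)
        nodes = [f"g{i}" for i in range(12)]
        edges = [
            ANIEdge(a, b, float(rng.uniform(90, 100)))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.3
        ]
        base = assign_slcs(edges, _genomes(nodes)).labels
        shuffled = list(edges)
        rng.shuffle(shuffled)
        assert assign_slcs(shuffled, _genomes(nodes)).labels == base

    @given(threshold_pair=st.tuples(
        st.floats(min_value=80, max_value=99), st.floats(min_value=0.1, max_value=10)
    ))
    @settings(max_examples=25, deadline=None)
    def test_raising_threshold_never_merges(self, threshold_pair):
        low, delta = threshold_pair
        rng = np.random.default_rng(9)
        nodes = [f"g{i}" for i in range(15)]
        edges = [
            ANIEdge(a, b, float(rng.uniform(80, 100)))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.2
        ]
        n_low = len(set(assign_slcs(edges, _genomes(nodes), low).labels.values()))
        n_high = len(
            set(assign_slcs(edges, _genomes(nodes), min(100, low + delta)).labels.values())
        )
        assert n_high >= n_low

    def test_aligned_fraction_filter(self):
        edges = [ANIEdge("A", "B", 99, aligned_fraction=0.1)]
        assignment = assign_slcs(edges, _genomes("AB"), min_aligned_fraction=0.5)
        assert assignment["A"] != assignment["B"]


class TestFCRAndLocalClustering:
    @pytest.mark.parametrize(
        "features,clusters,expected",
        [(10, 10, 0.0), (10, 4, 0.6), (33, 17, 1 - 17 / 33)],
    )
    def test_fcr_values(self, features, clusters, expected):
        assert feature_compression_ratio(features, clusters) == pytest.approx(expected)

    def test_fcr_domain_errors(self):
        with pytest.raises(ValueError):
            feature_compression_ratio(4, 5)
        with pytest.raises(ValueError):
            feature_compression_ratio(4, 0)

    def test_single_sample_local_equals_global(self):
        edges = [ANIEdge("A", "B", 99)]
        genomes = _genomes("ABC")
        global_report = local_clustering(genomes, edges, "global")["global"]
        local_report = local_clustering(genomes, edges, "local")["S1"]
        assert global_report.assignment.labels == local_report.assignment.labels
        assert global_report.fcr == local_report.fcr

    def test_local_requires_sample_ids(self):
        genomes = [GenomeRecord("A", OrganismType.prokaryotic, sample_id="")]
        with pytest.raises(ValueError, match="sample"):
            local_clustering(genomes, [], "local")

    def test_planted_species_local_fcr_at_most_global(self):
        # 3 species x 4 samples, one genome per (species, sample); global
        # clustering collapses each species, per-sample clustering cannot
        samples = {}
        genomes = []
        edges = []
        for s in range(3):
            members = [f"sp{s}.{i}" for i in range(4)]
            for i, g in enumerate(members):
                samples[g] = f"S{i}"
            edges += [
                ANIEdge(a, b, 98.0) for a, b in itertools.combinations(members, 2)
            ]
            genomes += members
        records = _genomes(genomes, samples=samples)
        global_fcr = local_clustering(records, edges, "global")["global"].fcr
        locals_ = local_clustering(records, edges, "local")
        assert global_fcr == pytest.approx(1 - 3 / 12)
        for report in locals_.values():
            assert report.fcr <= global_fcr

    def test_pairwise_ani_separates_planted_species(self):
        from panclust.synthetic import FixtureSpec, simulate_genomes

        spec = FixtureSpec(seed=11, genome_length_bp=20_000)
        genomes, species_of = simulate_genomes(spec)
        edges = pairwise_ani(genomes, sketch_size=500)
        assignment = assign_slcs(edges, genomes, ani_threshold=95)
        # same label iff same planted species
        for a in genomes:
            for b in genomes:
                same_label = assignment[a.genome_id] == assignment[b.genome_id]
                same_species = species_of[a.genome_id] == species_of[b.genome_id]
                assert same_label == same_species
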