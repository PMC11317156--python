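"""SSPC clustering, prevalence analytics, consensus summaries, enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from panclust import pangenome
from panclust.pangenome import (
    Lineage,
    cluster_proteins_within_slc,
    consensus_annotation,
    consensus_lineage,
    core_and_singleton,
    enrichment_test,
    marker_genes,
    prevalence_table,
)

from conftest import mutate_protein, random_protein


def _planted_slc(rng, n_genomes=4, n_families=5, divergence=0.02, slc="PSLC-1"):
    ancestors = [random_protein(rng, 240) for _ in range(n_families)]
    proteins = {}
    truth = {}
    for g in range(n_genomes):
        genome = f"{slc}.g{g}"
        prots = {}
        for f, anc in enumerate(ancestors):
            pid = f"{genome}|f{f}"
            prots[pid] = mutate_protein(rng, anc, divergence)
            truth[pid] = f
        proteins[genome] = prots
    assignment = {g: slc for g in proteins}
    return proteins, assignment, truth


class TestClusterProteinsWithinSLC:
    def test_planted_families_recovered(self):
        rng = np.random.default_rng(0)
        proteins, assignment, truth = _planted_slc(rng)
        sspcs = cluster_proteins_within_slc(proteins, assignment, identity=0.9)
        assert len(sspcs) == 5
        for cluster in sspcs:
            families = {truth[p] for p in cluster.member_protein_ids}
            assert len(families) == 1  # no family split across clusters

    def test_labels_scoped_per_slc_and_independent(self):
        rng = np.random.default_rng(1)
        seqs = {f"p{i}": random_protein(rng, 100) for i in range(3)}
        proteins = {
            "g1": {f"g1|{k}": v for k, v in seqs.items()},
            "g2": {f"g2|{k}": v for k, v in seqs.items()},
        }
        assignment = {"g1": "PSLC-1", "g2": "PSLC-2"}
        sspcs = cluster_proteins_within_slc(proteins, assignment, identity=0.9)
        by_slc = {}
        for c in sspcs:
            by_slc.setdefault(c.slc_label, []).append(c)
        assert len(by_slc["PSLC-1"]) == len(by_slc["PSLC-2"]) == 3
        assert all(c.label.startswith(f"{c.slc_label}_SSPC-") for c in sspcs)

    def test_identical_sequences_one_sspc(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        proteins = {"g1": {"a": seq, "b": seq}, "g2": {"c": seq}}
        assignment = {"g1": "PSLC-1", "g2": "PSLC-1"}
        sspcs = cluster_proteins_within_slc(proteins, assignment)
        assert len(sspcs) == 1
        assert set(sspcs[0].member_protein_ids) == {"a", "b", "c"}

    def test_unassigned_genome_rejected(self):
        with pytest.raises(ValueError, match="without SLC"):
            cluster_proteins_within_slc({"g1": {"p": "MKT" * 10}}, {})


class TestPrevalence:
    def test_counts_and_conservation(self):
        rng = np.random.default_rng(2)
        proteins, assignment, _ = _planted_slc(rng, n_genomes=3, n_families=4)
        sspcs = cluster_proteins_within_slc(proteins, assignment, identity=0.9)
        protein_to_genome = {
            pid: genome for genome, prots in proteins.items() for pid in prots
        }
        table = prevalence_table(sspcs, protein_to_genome, "PSLC-1")
        total_proteins = sum(len(p) for p in proteins.values())
        assert int(table.to_numpy().sum()) == total_proteins
        for cluster in sspcs:
            assert table[cluster.label].sum() == len(cluster.member_protein_ids)

    def test_core_and_singleton_boundaries(self):
        table = pd.DataFrame(
            {"c1": [1, 1, 1, 1], "c2": [2, 1, 1, 0], "c3": [0, 0, 1, 0]},
            index=list("abcd"),
        )
        core, singleton = core_and_singleton(table, core_fraction=1.0)
        assert core == ["c1"]
        assert singleton == ["c3"]
        core75, _ = core_and_singleton(table, core_fraction=0.75)
        assert core75 == ["c1", "c2"]

    def test_single_genome_slc_every_sspc_core_and_singleton(self):
        table = pd.DataFrame({"c1": [1], "c2": [3]}, index=["g"])
        core, singleton = core_and_singleton(table)
        assert core == singleton == ["c1", "c2"]

    def test_random_table_matches_column_scan(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            rng.integers(0, 3, size=(20, 50)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"c{j}" for j in range(50)],
        )
        for fraction in (1.0, 0.5, 0.25):
            core, singleton = core_and_singleton(table, fraction)
            for col in table.columns:
                present = int((table[col] >= 1).sum())
                assert (col in core) == (present >= fraction * 20 - 1e-9)
                assert (col in singleton) == (present == 1)

    def test_lower_core_fraction_never_shrinks_core(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.integers(0, 2, size=(10, 30)))
        table.columns = [f"c{j}" for j in range(30)]
        previous = set()
        for fraction in (1.0, 0.75, 0.5, 0.25):
            core, _ = core_and_singleton(table, fraction)
            assert previous <= set(core)
            previous = set(core)


class TestMarkerGenes:
    def test_planted_private_families_are_markers(self):
        # 3 SLCs share 2 families; each has 1 private core family
        rng = np.random.default_rng(5)
        shared = [random_protein(rng, 200) for _ in range(2)]
        tables = {}
        reps = {}
        for s in range(3):
            slc = f"PSLC-{s + 1}"
            columns = {}
            for f, anc in enumerate(shared):
                label = f"{slc}_SSPC-{f + 1}"
                reps[label] = mutate_protein(rng, anc, 0.02)
                columns[label] = [1, 1, 1]
            private_label = f"{slc}_SSPC-3"
            reps[private_label] = random_protein(rng, 200)
            columns[private_label] = [1, 1, 1]
            tables[slc] = pd.DataFrame(columns, index=[f"{slc}.g{i}" for i in range(3)])
        markers = marker_genes(tables, reps, identity=0.5)
        for s in range(3):
            assert markers[f"PSLC-{s + 1}"] == [f"PSLC-{s + 1}_SSPC-3"]

    def test_disjoint_sequence_space_all_core_are_markers(self):
        rng = np.random.default_rng(6)
        tables = {}
        reps = {}
        for s in range(2):
            slc = f"PSLC-{s + 1}"
            labels = [f"{slc}_SSPC-{j}" for j in (1, 2)]
            for label in labels:
                reps[label] = random_protein(rng, 150)
            tables[slc] = pd.DataFrame(
                {label: [1, 1] for label in labels}, index=[f"{slc}.g{i}" for i in range(2)]
            )
        markers = marker_genes(tables, reps, identity=0.5)
        for slc, table in tables.items():
            assert markers[slc] == sorted(table.columns)

    def test_cross_slc_match_excluded(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
        tables = {
            "PSLC-1": pd.DataFrame({"PSLC-1_SSPC-1": [1]}, index=["g1"]),
            "PSLC-2": pd.DataFrame({"PSLC-2_SSPC-1": [1]}, index=["g2"]),
        }
        reps = {"PSLC-1_SSPC-1": seq, "PSLC-2_SSPC-1": seq}
        markers = marker_genes(tables, reps, identity=0.5)
        assert markers == {"PSLC-1": [], "PSLC-2": []}


class TestConsensusAnnotation:
    def test_majority_vote(self):
        annotations = {
            "A": {"ko": "K00001"},
            "B": {"ko": "K00001"},
            "C": {"ko": "K00002"},
        }
        result = consensus_annotation(annotations, ["A", "B", "C"])
        assert result["ko"] == ("K00001", pytest.approx(2 / 3))

    def test_all_unannotated(self):
        result = consensus_annotation({}, ["A", "B"], databases=["pfam"])
        assert result["pfam"] == ("", 0.0)

    def test_tie_breaks_lexicographically(self):
        annotations = {"A": {"ko": "K2"}, "B": {"ko": "K1"}}
        result = consensus_annotation(annotations, ["A", "B"])
        assert result["ko"] == ("K1", 0.5)

    def test_unanimous_support_is_one(self):
        annotations = {m: {"pfam": "PF18697.4"} for m in "ABCD"}
        result = consensus_annotation(annotations, list("ABCD"))
        assert result["pfam"] == ("PF18697.4", 1.0)


class TestConsensusLineage:
    L1 = Lineage.from_string("d__B;p__P1;c__C1;o__O1;f__F1;g__G1;s__S1")

    def test_identical_lineages_unchanged(self):
        assert consensus_lineage([self.L1] * 3) == self.L1

    def test_genus_majority_and_truncation(self):
        other = Lineage.from_string("d__B;p__P1;c__C1;o__O1;f__F1;g__G2;s__S2")
        votes = [self.L1, self.L1, other]
        kept = consensus_lineage(votes, agreement_threshold=0.5)
        assert kept.ranks[5] == "G1"
        truncated = consensus_lineage(votes, agreement_threshold=0.7)
        assert truncated.ranks[5] == ""
        assert truncated.ranks[6] == ""
        assert truncated.ranks[4] == "F1"

    def test_incomplete_lineage_votes_among_nonempty(self):
        missing_species = Lineage.from_string("d__B;p__P1;c__C1;o__O1;f__F1;g__G1;s__")
        result = consensus_lineage([self.L1, self.L1, missing_species])
        assert result.ranks[6] == "S1"  # decided among the 2 non-empty votes

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            consensus_lineage([])


def fisher_oracle(a, b, c, d, sided):
    """Exhaustive hypergeometric enumeration over tables with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {
        k: comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)
        for k in range(lo, hi + 1)
    }
    if sided == "two":
        cutoff = probs[a] * (1 + 1e-9)
        return sum(p for p in probs.values() if p <= cutoff)
    expected = row1 * col1 / n
    if a <= expected:
        return sum(p for k, p in probs.items() if k <= a)
    return sum(p for k, p in probs.items() if k >= a)


class TestEnrichment:
    def test_viral_pangenome_case_control_table(self):
        # 0/65 case vs 6/65 control presence of a protein cluster
        p = enrichment_test(0, 65, 6, 59, sided="one")
        oracle = comb(65, 6) / comb(130, 6)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p == pytest.approx(0.01385, abs=5e-6)

    def test_balanced_table_p_one(self):
        assert enrichment_test(5, 5, 5, 5, sided="two") == pytest.approx(1.0)

    def test_perfect_association_single_tail_term(self):
        p = enrichment_test(10, 0, 0, 10, sided="one")
        assert p == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(0, 0, 0, 0)
        with pytest.raises(ValueError):
            enrichment_test(-1, 2, 3, 4)

    def test_small_margin_tables_match_enumeration_oracle(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 and c + d == 0:
                continue
            if a + c == 0 and b + d == 0:
                continue
            for sided in ("one", "two"):
                got = enrichment_test(a, b, c, d, sided)
                assert got == pytest.approx(
                    fisher_oracle(a, b, c, d, sided), rel=1e-8, abs=1e-12
                ), (a, b, c, d, sided)
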