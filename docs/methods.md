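# Methods

This note documents the models and procedures implemented in `panclust`,
the parameters that matter, the numerical conventions, and what the
synthetic fixtures do and do not demonstrate.

## Protein database construction

Sequences are normalized before hashing: every `*` character (terminal or
internal stop) is removed and the sequence uppercased, so two gene calls
that differ only in a stop codon or case produce the same md5 hash. The
hash is md5 over the UTF-8 bytes of the normalized sequence (lowercase hex
digest), which is deterministic across platforms. Sequences shorter than
11 residues after normalization are rejected — very short peptides invite
greedy over-clustering downstream. The length filter is strict at the
boundary: 10 aa is rejected, 11 aa kept.

Sources are added in priority order; the first occurrence of a hash wins
and fixes the record's source database and organism, while organisms whose
copies arrive later are still recorded as represented. Within one source,
file order breaks ties, so builds are deterministic.

Stepwise clustering tiers: tier 0 is the full non-redundant set; tier k
clusters the *representatives* of tier k−1 (e.g. 90% identity then 50%
identity, both at 80% coverage), and member→representative maps compose
transitively so any record resolves to its final representative. An
organism counts as represented in a tier when at least one of its proteins
is a cluster representative there; representation percentages are
100 × count / denominator at full precision, and compression is
1 − N_tier/N_parent.

## Clustering backends

Production workflows delegate sequence clustering to MMseqs2-class tools;
the package defines the backend contract (a member→representative map over
the inputs) and accepts precomputed assignments (`PrecomputedBackend`).
The built-in `GreedyKmerBackend` is a desk-scale stand-in: sequences are
visited longest-first and join the first representative that meets the
identity and length-coverage thresholds. Identity is estimated from
shared-k-mer containment C (shared k-mers over the smaller k-mer set,
k = 5 for proteins) corrected to the per-site scale as C^(1/k) — the
standard k-mer-survival relation, under which 5% per-site divergence maps
to ≈ 0.95 rather than the raw containment ≈ 0.77. On the package's
substitution-only fixtures this estimate tracks exact alignment identity
closely, and the test suite verifies that greedy clustering under the
backend reproduces greedy clustering under an exact-identity oracle.
The estimate is unreliable for remote homology (below ~40% identity) and
for sequences with many repeats; that regime is what the external tools
are for.

## Genome clustering and FCR

The ANI graph has genomes as nodes and ANI percentages as weighted edges.
Edges below the ANI threshold (default 95%, the conventional species
boundary) or below the minimum aligned fraction are removed *before*
component formation. Species-level clusters are the connected components,
computed separately per organism type, labelled `PSLC-`/`ESLC-`/`VSLC-`
and numbered by decreasing size with ties broken by the lexicographically
smallest member id — the numbering is a package convention chosen for
determinism. Feature compression ratios are FCR = 1 − clusters/features;
"global" clusters all genomes, "local" restricts edges to same-sample
pairs and reports one FCR per sample.

The built-in ANI estimator is a MinHash bottom sketch (canonical k-mers,
k = 21, sketch size 1000, SplitMix64 hashing seeded explicitly) with the
Mash distance D = −(1/k)·ln(2J/(1+J)) and ANI% = 100(1−D), J estimated on
the merged bottom sketch. J = 0 maps to ANI 0 by convention and values are
clamped to [0, 100]. The estimator cannot measure alignment fraction, so
its edges carry aligned_fraction = 1 (the filter is effectively disabled);
precomputed edge tables from alignment-based tools should be preferred
when aligned-fraction filtering matters.

## Pangenome analytics

Proteins are pooled per SLC and clustered independently; SSPC labels are
`<SLC>_SSPC-<j>` numbered by decreasing cluster size. Default SSPC
thresholds are 0.5 identity and 0.8 coverage, mirroring common
linclust-style defaults; both are configurable. Prevalence tables are
genome × SSPC copy counts; core SSPCs are present in at least
`core_fraction` of genomes (default 1.0), singletons in exactly one.
Marker genes are SSPCs core in their own SLC whose representative has no
match at or above the identity threshold to any representative of any
other SLC — a representative-vs-representative reading of "not detected in
any other pangenome"; member-level cross-matching would be stricter and is
not implemented.

Consensus annotations take the most frequent non-empty term per database
among cluster members (ties broken lexicographically), with support =
frequency / member count. Consensus lineages vote per rank from domain
downward among non-empty votes; when the winning weight fraction falls
below the agreement threshold (default 0.5, strict majority) the lineage
is truncated from that rank down.

Enrichment uses Fisher's exact test (scipy). The two-sided p-value follows
the minimum-likelihood convention; the one-sided value takes the tail in
the direction of the observed deviation from independence (lower tail on
the first cell when it is at or below its expectation under the margins).
The test suite checks both against exhaustive hypergeometric enumeration.

## KEGG modules, MCR, and PGFCs

The module grammar follows KEGG conventions: spaces separate reaction
steps at the top level, commas separate alternatives (OR), `+` joins
complex subunits (AND), `-` marks the following unit optional, parentheses
group, and a bare `--` is an undefined step. Parsing canonicalizes
associativity (OR-in-OR and AND-in-AND flatten), so serialization is a
fixpoint and reparses to an identical tree. Spaces are step separators
only; a space inside parentheses is a parse error.

MCR = satisfied steps / total steps. Optional components are ignored in
evaluation. Undefined (`--`) steps count as unsatisfied — the conservative
choice among unsatisfied / satisfied / excluded-from-denominator, so a
module with undefined steps can never reach completion on KO evidence
alone; this is stated here because other tools differ.

PGFC cells sum a sample's SSPC counts over one (SLC, module) pair, where
an SSPC contributes when its consensus KO appears in the module
definition. A KO present in several modules contributes its full counts to
each such column — amalgamations must be unpackable to their constituent
SSPCs, and splitting would break integer counts. The companion MCR cell
evaluates the module on the KOs with nonzero count for that SLC in that
sample. Filtering keeps a column when at least `min_sample_fraction` of
samples pass both the count and the MCR thresholds (defaults: min_mcr 0.5,
min_sample_fraction 0.5).

## BGC analytics

Identifiers follow `genome|contig|region` for BGCs and
`<bgc>_<position> | <start>:<end> (<strand>)` for genes (1-based inclusive
coordinates, positions numbered from 1 along the cluster). The novelty
score is the fraction of a BGC's genes with no MIBiG homology; all genes
are counted, including those on contig edges. Scores above 0.85 are
flagged as high novelty in reports. Prevalence tables count BGC
protein-cluster members per genome and nucleotide-cluster members per
sample. Jaccard distances are computed on booleanized tables; rows with an
empty union are assigned distance 0 to avoid NaN propagation into
ordination. antiSMASH GenBank parsing is out of scope — the module
consumes tabular BGC descriptions.

## Screening filters

The viral filter passes a genome when viral genes ≥ 5 × host genes,
completeness ≥ 50%, and both the quality tier and MIUViG tier are medium,
high, or complete; every failed clause is reported. Genome-size defaults
are 150 000 bp (prokaryotic) and 2 000 000 bp (eukaryotic); viral genomes
have no size default and require an explicit threshold. All comparisons
are inclusive at the boundary. Multi-split partitioning splits each bin of
a concatenated multi-sample assembly by the contig's sample of origin —
the sample prefix ends at the *first* `__` — and names per-sample bins
`[Sample]__[Algorithm]__<P|E>.[Iteration]__[Name]`. Unbinned feedback
returns the contigs not captured by any passing bin, including contigs of
bins that failed the filters. Orchestrating the iterative binning itself
(running binners per round) is out of scope; only the bookkeeping contract
is implemented.

## Compositional networks

Counts are CLR-transformed per sample (log(x + pseudocount) minus the row
mean of logs; default pseudocount 1 for integer counts). Covariance is
estimated with the Schäfer–Strimmer shrinkage estimator: empirical
correlations are shrunk toward zero with the analytic intensity
λ* = Σ Var̂(r_ij) / Σ r_ij² (clamped to [0, 1]) while variances are kept,
i.e. the covariance is shrunk toward its diagonal, guaranteeing an
invertible estimate at small n. Partial correlations are
−P_ij/√(P_ii·P_jj) from the precision matrix P.

Ensembling bootstraps the samples with replacement (default
N_draws = 100): edge mean weights average the draws and support is the
fraction of draws with a strictly positive weight. Bootstrap-over-samples
is the standard reading of ensemble association networks; mean aggregation
is the default and the quantities are exposed separately so other
aggregations can be applied downstream. The positive subgraph keeps edges
with mean weight strictly > 0 and support ≥ 0.5 by default; the support
threshold suppresses sign-unstable edges and is exposed as a flag.

Consensus communities run weighted Leiden (RB-configuration modularity)
once per seed (default N_seeds = 100) and return the medoid partition —
the run with maximal mean adjusted Rand agreement with all other runs —
plus the co-membership fractions. The medoid is preferred over
thresholding co-membership because it is always a valid partition.
Community ids are renumbered by decreasing size. Connectivity rankings sum
incident positive edge weights, descending, ties lexicographic.

## Synthetic fixtures

Generators are seed-deterministic (NumPy `default_rng`); identical specs
give byte-identical outputs. Genomes use a substitution-only mutation
model (no indels), which keeps the ANI↔divergence relation analytic
(expected ANI ≈ 100(1 − d)) but does not emulate rearrangements, repeats,
or fragmented assemblies — recovery results on fixtures therefore bound
the idealized regime, not metagenome-assembled reality. Proteomes plant
shared families (homologous across species) and one private core family
per species, so marker-gene logic has known ground truth, and a bundled
universe of 20 synthetic KOs and 6 module definitions covering every
grammar operator makes the KEGG layer testable without the licensed KEGG
database.

Compositional counts are drawn from a latent multivariate normal with
covariance equal to the inverse of a planted sparse precision matrix,
exponentiated, closed, and multinomially sampled (default depth 100 000
reads/sample). The canonical network fixture plants 5 disjoint
positively-coupled pairs among 10 features with partial correlation 0.9.
That strength is deliberate: at this small dimension the CLR closure
subtracts a common term that drives weakly-coupled pairs' partial
correlations negative, so only tightly co-occurring pairs (the regime of
obligate syntrophy or virus–host coupling) are recoverable with stable
sign — a documented limitation of compositional partial-correlation
analysis at low feature counts, not of the estimator implementation.

## Problem sizes

Tests and the acceptance script run desk-scale configurations chosen as
representative defaults: 100 random ANI graphs of up to 40 genomes for
the partition oracle, all 2×2 tables with margins ≤ 12 for the exact-test
oracle, 100 samples × 10 features × 100 bootstrap draws for edge
recovery, and a 3-block, 12-node graph × 100 seeds for consensus
communities.

## Known limitations

- The built-in k-mer identity proxy and MinHash ANI are estimators;
  alignment-based tools remain authoritative at scale and for divergent
  or repeat-rich sequences.
- Marker-gene detection compares cluster representatives only.
- The module grammar does not support nested space-separated sub-steps
  inside parentheses (rare in real KEGG definitions).
- Negative associations are deliberately excluded from community analysis;
  only the positive subgraph is clustered.
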