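# panclust

Desk-scale analytics for genome-resolved multi-omics: from dereplicated
protein databases and species-level genome clusters to pangenome prevalence
tables, KEGG module completion, biosynthetic gene cluster novelty, and
compositional co-occurrence networks.

## Who this is for

Microbiome researchers who recover prokaryotic, eukaryotic and viral
genomes from metagenomes and need the computational layer that turns those
genomes into comparable units: **species-level clusters** (SLC) from an
average-nucleotide-identity graph, **SLC-specific protein clusters** (SSPC)
as the unit of pangenome analysis, and amalgamated functional features for
downstream statistics. Heavy sequence comparison (skani/FastANI, MMseqs2,
antiSMASH, CheckV) is expected to run externally at scale — this package
consumes their tabular outputs — but every step also has a built-in
desk-scale backend so the whole pipeline runs self-contained on synthetic
or small real data.

## What it computes

- **Protein database construction** (`panclust.protein_db`) — UniRef-style
  dereplication: strip stop characters, uppercase, reject sequences
  < 11 aa, key by md5 content hash, first-priority source wins; stepwise
  clustering tiers (e.g. 100 → 90% → 50% identity at 80% coverage);
  per-tier organism representation percentages and compression ratios
  1 − N_tier/N_parent.
- **Genome clustering** (`panclust.genome_clustering`) — ANI graph with
  edges filtered at a threshold (default ≥ 95%, the species boundary);
  connected components become `PSLC-k` / `ESLC-k` / `VSLC-k` labels;
  feature compression ratios FCR = 1 − clusters/features, globally or per
  sample; built-in MinHash bottom-sketch ANI via the Mash distance
  D = −(1/k)·ln(2J/(1+J)).
- **Pangenome analytics** (`panclust.pangenome`) — SSPCs per SLC,
  genome × SSPC copy-count prevalence tables, core/singleton calls,
  cross-pangenome marker genes, consensus annotations and consensus
  lineages, Fisher exact enrichment tests.
- **KEGG modules and PGFCs** (`panclust.kegg`) — a parser for KEGG-style
  module definitions (spaces = steps, commas = OR, `+` = complex,
  `-` = optional, `--` = undefined step), module completion ratios
  MCR = satisfied steps / total steps, and PhyloGenomic Functional
  Category tables that amalgamate SSPC counts per (SLC, module) with
  MCR-based low-prevalence filtering.
- **BGC analytics** (`panclust.bgc`) — structured identifiers
  `genome|contig|region` and `bgc_1 | start:end (strand)`, novelty score =
  fraction of genes with no MIBiG homology, prevalence tables and Jaccard
  distances.
- **Screening filters** (`panclust.screening`) — the default viral filter
  (viral genes ≥ 5 × host genes, completeness ≥ 50%, medium-or-better
  quality tiers), genome-size filters (150 kb prokaryotic / 2 Mb
  eukaryotic), multi-split bin partitioning by `Sample__` contig prefixes,
  and unbinned-contig feedback for iterative binning.
- **Compositional networks** (`panclust.networks`) — CLR transform,
  Schäfer–Strimmer shrinkage partial correlations, bootstrap ensemble
  networks (N_draws = 100), positive sign-stable subgraphs, consensus
  Leiden communities (N_seeds = 100), weighted-degree rankings.
- **Synthetic fixtures** (`panclust.synthetic`) — seed-deterministic
  generators for genomes with planted species, proteomes with planted gene
  families and a bundled KO/module universe, and compositional counts from
  a known sparse precision matrix, plus embedded published
  worked-example tables.

## Worked example

```python
from panclust import protein_db, kegg
from panclust.genome_clustering import (
    ANIEdge, GenomeRecord, OrganismType, assign_slcs, feature_compression_ratio,
)

db = protein_db.build_nonredundant([
    ("isolates", [("org1", "MSKTASDFLKJHGQWERTYIPASDGHWMKL*"),
                  ("org2", "msktasdflkjhgqwertyipasdghwmkl")]),
    ("nr",       [("org3", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")]),
])
print(f"{len(db)} non-redundant records")

genomes = [GenomeRecord(g, OrganismType.viral) for g in ("v1", "v2", "v3", "v4")]
edges = [ANIEdge("v1", "v2", 97.2), ANIEdge("v2", "v3", 96.1), ANIEdge("v3", "v4", 93.0)]
slcs = assign_slcs(edges, genomes, ani_threshold=95)
print(slcs.labels)
print(f"FCR = {feature_compression_ratio(4, len(set(slcs.labels.values()))):.2f}")

module = kegg.parse_module_definition("M00001", "(K00001+K00002),K00003 K00004-K00005")
print(f"MCR = {kegg.module_completion_ratio(module, {'K00003', 'K00004'}):.1f}")
```

prints

```
2 non-redundant records
{'v1': 'VSLC-1', 'v2': 'VSLC-1', 'v3': 'VSLC-1', 'v4': 'VSLC-2'}
FCR = 0.50
MCR = 1.0
```

The two stop/case variants of the first protein hash identically and
collapse to one record. The 93% edge falls below the 95% species
threshold, so v4 becomes its own singleton viral cluster and four genomes
compress to two clusters (FCR 0.50). In the module, step one is satisfied
through the `K00003` alternative and step two through `K00004` with
`K00005` optional, so the module is complete.

A command-line interface mirrors the library
(`panclust derep|cluster|pangenome|pgfc|bgc|screen|network|fixtures`, see
`panclust --help`).

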