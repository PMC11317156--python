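"""File I/O helpers: FASTA, manifest/edge TSVs, and graph JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from panclust.genome_clustering import ANIEdge, GenomeRecord, OrganismType


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(record_id, sequence)`` from a FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_genome_manifest(path: str | Path) -> list[GenomeRecord]:
    """Genome manifest TSV: genome_id, organism_type, sample_id[, size_bp]."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in table.iterrows():
        records.append(
            GenomeRecord(
                genome_id=row["genome_id"],
                organism_type=OrganismType(row["organism_type"]),
                sample_id=row.get("sample_id", ""),
                size_bp=int(row["size_bp"]) if row.get("size_bp") else 0,
            )
        )
    return records


def read_ani_edges(path: str | Path) -> list[ANIEdge]:
    """ANI edge TSV: genome_a, genome_b, ani_percent[, aligned_fraction]."""
    table = pd.read_csv(path, sep="\t")
    edges = []
    for _, row in table.iterrows():
        edges.append(
            ANIEdge(
                genome_a=str(row["genome_a"]),
                genome_b=str(row["genome_b"]),
                ani_percent=float(row["ani_percent"]),
                aligned_fraction=float(row.get("aligned_fraction", 1.0)),
            )
        )
    return edges


def write_tsv(path: str | Path, table: pd.DataFrame, index_label: str | None = None) -> None:
    table.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def write_graph_json(path: str | Path, graph: nx.Graph) -> None:
    """Serialize a graph as JSON node-link data."""
    data = nx.node_link_data(graph, edges="links")
    Path(path).write_text(json.dumps(data, indent=2, default=str))


def read_graph_json(path: str | Path) -> nx.Graph:
    data = json.loads(Path(path).read_text())
    return nx.node_link_graph(data, edges="links")
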