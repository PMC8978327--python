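"""Readers and writers for the pipeline's on-disk formats.

Formats: tab-separated expression matrices (transcripts x stages, one
normalized unit per file), FASTA sequence sets, GMT gene-set collections,
interaction tables (TSV), and network exports in SIF or GraphML for
Cytoscape-style downstream viewing.  All writers are deterministic — same
input, byte-identical file — and every reader/writer pair round-trips
losslessly modulo the declared ordering normalization (networks and
interaction tables are written in lexicographic order).

Conventions: tab-separated UTF-8 without quoting, '.' decimal separator;
positions 0-based half-open; sequences canonicalized to uppercase RNA
(T -> U) on input.
"""

from __future__ import annotations

import io
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .cerna_assembly import CeRNATriplet
from .matrix import ExpressionMatrix
from .target_prediction import Interaction, InteractionTable, _canon

NETWORK_FORMATS = ("SIF", "GraphML")


# -- expression matrices ----------------------------------------------------

def read_expression_tsv(path, expected_unit: str = "RPM") -> ExpressionMatrix:
    """Load a transcripts x stages TSV; first column transcript id.

    Rejects duplicate ids (listing offenders), missing values (no
    imputation) and negative or non-numeric cells (naming row and column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript ids in {path}: {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric value at transcript {bad!r}, stage {col!r} in {path}")
    if df.isna().any().any():
        bad_col = df.columns[df.isna().any()][0]
        bad_row = df.index[df[bad_col].isna()][0]
        raise ValueError(f"missing value at transcript {bad_row!r}, stage {bad_col!r} in {path}")
    df.index = df.index.astype(str)
    df.index.name = "transcript"
    return ExpressionMatrix(df.astype(float), unit=expected_unit)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "transcript"
    df.to_csv(path, sep="\t", float_format="%.10g")


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA to {id: sequence}, normalized to uppercase RNA (T -> U)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        sequences[record.id] = _canon(str(record.seq), f"sequence {record.id!r}")
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    """Write sequences in id order, wrapped at ``width`` columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq_id in sorted(sequences):
            seq = sequences[seq_id]
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# -- GMT gene sets ----------------------------------------------------------

def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT to ({term: gene set}, {term: description}).

    Each line: term, description, then members; genes repeated within one
    term count once (set semantics).
    """
    annotations: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno} in {path}: "
                                 f"expected term, description and >=1 member")
            term, desc, *genes = fields
            if term in annotations:
                raise ValueError(f"duplicate term {term!r} at GMT line {lineno} in {path}")
            annotations[term] = {g for g in genes if g}
            descriptions[term] = desc
    return annotations, descriptions


# -- interaction tables -----------------------------------------------------

_INTERACTION_COLUMNS = ("mirna_id", "target_id", "target_kind", "sources", "site_count")


def read_interactions_tsv(path) -> InteractionTable:
    """Load miRNA->target edges; duplicate rows merge (site counts sum)."""
    table = InteractionTable()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(_INTERACTION_COLUMNS):
            raise ValueError(f"malformed interaction header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"malformed interaction line {lineno} in {path}")
            mirna, target, kind, sources, count = fields
            table.add(Interaction(mirna, target, kind,
                                  tuple(sources.split(",")), int(count)))
    return table


def write_interactions_tsv(table: InteractionTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_INTERACTION_COLUMNS) + "\n")
        for row in table:  # already lexicographically sorted
            fh.write(f"{row.mirna_id}\t{row.target_id}\t{row.target_kind}\t"
                     f"{','.join(row.sources)}\t{row.site_count}\n")


# -- network export ---------------------------------------------------------

def _node_attributes(triplets: list[CeRNATriplet]) -> dict[str, dict[str, str]]:
    nodes: dict[str, dict[str, str]] = {}
    for t in sorted(triplets, key=lambda t: (t.circ_id, t.mirna_id, t.mrna_id)):
        circ_dir, mirna_dir, mrna_dir = (
            ("down", "up", "down") if t.scheme == "circ_down_mir_up_mrna_down"
            else ("up", "down", "up")
        )
        nodes[t.circ_id] = {"layer": "circRNA", "direction": circ_dir, "group": t.group}
        nodes[t.mirna_id] = {"layer": "miRNA", "direction": mirna_dir, "group": t.group}
        nodes[t.mrna_id] = {"layer": "mRNA", "direction": mrna_dir, "group": t.group}
    return nodes


def network_edges(triplets: list[CeRNATriplet]) -> list[tuple[str, str, str]]:
    """Sorted, de-duplicated (source, relation, target) edges of a network.

    circRNA --sponges--> miRNA; miRNA --targets--> mRNA.
    """
    edges = {(t.circ_id, "sponges", t.mirna_id) for t in triplets}
    edges |= {(t.mirna_id, "targets", t.mrna_id) for t in triplets}
    return sorted(edges)


def triplets_to_graph(triplets: list[CeRNATriplet]) -> nx.DiGraph:
    """Directed graph with layer/direction/group node attributes."""
    graph = nx.DiGraph()
    nodes = _node_attributes(triplets)
    for node in sorted(nodes):
        graph.add_node(node, **nodes[node])
    for source, relation, target in network_edges(triplets):
        graph.add_edge(source, target, relation=relation)
    return graph


def write_network(triplets: list[CeRNATriplet], path, fmt: str = "SIF") -> None:
    """Export a triplet network as SIF or GraphML, deterministically ordered."""
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; expected one of {NETWORK_FORMATS}")
    if fmt == "SIF":
        with open(path, "w", encoding="utf-8") as fh:
            for source, relation, target in network_edges(triplets):
                fh.write(f"{source}\t{relation}\t{target}\n")
    else:
        graph = triplets_to_graph(triplets)
        buffer = io.BytesIO()
        nx.write_graphml(graph, buffer, named_key_ids=True)
        Path(path).write_bytes(buffer.getvalue())


def read_sif(path) -> list[tuple[str, str, str]]:
    """SIF back to sorted (source, relation, target) edges."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"malformed SIF line {lineno} in {path}")
            edges.append(tuple(fields))
    return sorted(edges)


def read_graphml_network(path) -> nx.DiGraph:
    return nx.read_graphml(path)
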