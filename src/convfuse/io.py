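"""Readers and writers for the standard formats the pipeline touches.

FASTA (protein sequences, via Biopython), Newick (trees, via dendropy;
numeric internal-node labels are branch supports on the edge above that
node, the convention of common ML tree tools), and tab-separated tables
(genome gene orders, presence/absence and habitat matrices).  All TSVs have
a header row, UTF-8 encoding and "." decimals.
"""

from __future__ import annotations

import io as _io
import os
from typing import Optional, Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    GeneLocus,
    GenomeTable,
    HabitatMatrix,
    PresenceAbsenceMatrix,
    ProteinRecord,
)

PathLike = Union[str, os.PathLike]

GENOME_TABLE_COLUMNS = ["genome", "contig", "rank", "strand", "ortholog", "protein_id"]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read protein records; headers must be unique, sequences are uppercased.

    The description may carry ``key=value`` tokens (``species=...``,
    ``architecture=A-B``) written by :func:`write_fasta`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        species = ""
        architecture = None
        for token in rec.description.split()[1:]:
            if token.startswith("species="):
                species = token[len("species="):]
            elif token.startswith("architecture="):
                architecture = token[len("architecture="):].split("-")
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                species_id=species,
                architecture=architecture,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: PathLike) -> None:
    seqs = []
    for r in records:
        desc = []
        if r.species_id:
            desc.append(f"species={r.species_id}")
        if r.architecture:
            desc.append("architecture=" + "-".join(r.architecture))
        seqs.append(
            SeqRecord(Seq(r.sequence), id=r.id, description=" ".join(desc))
        )
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick


def read_newick(source: Union[PathLike, str], *, data: Optional[str] = None) -> dendropy.Tree:
    """Read a Newick tree; internal-node labels are kept (supports).

    Branch supports live on ``node.label`` of internal nodes and refer to the
    edge above that node; use :func:`edge_support` to retrieve them as
    integers.  ``data`` may be given instead of a path.
    """
    if data is None:
        with open(source) as fh:
            data = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"Newick parse error: {exc}") from exc
    _validate_tree(tree)
    return tree


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    for node in tree.preorder_node_iter():
        sup = edge_support(node)
        if sup is not None and not (0 <= sup <= 100):
            raise ValueError(f"support {sup} outside [0, 100]")


def write_newick(tree: dendropy.Tree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree))


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def edge_support(node: dendropy.Node) -> Optional[int]:
    """Support of the edge above ``node`` (numeric internal label), if any."""
    if node.is_leaf() or node.label is None:
        return None
    try:
        return int(round(float(node.label)))
    except (TypeError, ValueError):
        return None  # non-numeric labels are clade names, not supports


def set_edge_support(node: dendropy.Node, support: Optional[int]) -> None:
    node.label = None if support is None else str(int(support))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Genome tables


def read_genome_table(path: PathLike) -> list[GenomeTable]:
    """Read an ordered gene-annotation TSV into one GenomeTable per genome.

    Rank consecutiveness per contig is the semantic content (gene order) and
    is enforced by :class:`GenomeTable`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(GENOME_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genome table missing column(s): {sorted(missing)}")
    if df.isna().any().any():
        raise ValueError("genome table has missing values (ragged rows?)")
    tables = []
    for genome_id, group in df.groupby("genome", sort=True):
        loci = [
            GeneLocus(
                genome_id=str(genome_id),
                contig_id=row.contig,
                rank=int(row.rank),
                strand=row.strand.replace("−", "-"),
                ortholog=row.ortholog,
                protein_id=row.protein_id,
            )
            for row in group.itertuples()
        ]
        tables.append(GenomeTable(genome_id=str(genome_id), loci=loci))
    return tables


def write_genome_table(tables: list[GenomeTable], path: PathLike) -> None:
    rows = []
    for table in tables:
        for l in table.loci:
            rows.append(
                (l.genome_id, l.contig_id, l.rank, l.strand, l.ortholog, l.protein_id)
            )
    df = pd.DataFrame(rows, columns=GENOME_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices


def read_matrix(
    path: PathLike, kind: str
) -> Union[PresenceAbsenceMatrix, HabitatMatrix]:
    """Read a species × labels TSV as a typed matrix.

    ``kind`` is ``"presence"`` (entries coerced to {0,1}, anything else is an
    error) or ``"habitat"`` (nonnegative finite floats).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.isna().any().any():
        raise ValueError(f"matrix {path} has missing entries")
    if kind == "presence":
        return PresenceAbsenceMatrix(df)
    if kind == "habitat":
        return HabitatMatrix(df)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(
    matrix: Union[PresenceAbsenceMatrix, HabitatMatrix], path: PathLike
) -> None:
    matrix.df.to_csv(path, sep="\t")
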