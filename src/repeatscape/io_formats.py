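"""Readers and writers for the external formats the pipeline touches.

All intervals are stored 0-based half-open in memory.  RepeatMasker ``.out``
tables and GFF3 use 1-based inclusive coordinates on disk; the conversion
happens here, at the boundary, and nowhere else.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "RepeatHit",
    "GeneRecord",
    "GenomeIndex",
    "PhyloTree",
    "LibraryRecord",
    "read_repeat_annotation",
    "write_repeat_annotation",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_genome_index",
    "write_genome_index",
    "read_library_fasta",
    "write_library_fasta",
    "read_tree",
    "tree_from_newick",
    "write_table",
]

_VALID_STRANDS = {"+", "-", "?"}
_DNA_OK = set("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class RepeatHit:
    """One annotated repeat interval on a genome sequence."""

    seq_id: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    divergence_pct: float
    score: float
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if not (0.0 <= self.divergence_pct <= 100.0):
            raise ValueError(f"divergence_pct out of [0, 100]: {self.divergence_pct}")
        if self.score < 0:
            raise ValueError(f"negative score: {self.score}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.repeat_class:
            self.repeat_class = "Unknown"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneRecord:
    """Full span of one gene feature."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "?"
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for gene {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeIndex:
    """Sequence name -> length map for one assembly."""

    genome_id: str
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")

    @property
    def assembly_size(self) -> int:
        return sum(self.lengths.values())

    def validate_intervals(self, items: Iterable) -> None:
        """Check that every item's interval fits inside its sequence."""
        for it in items:
            length = self.lengths.get(it.seq_id)
            if length is None:
                raise ValueError(f"unknown sequence {it.seq_id!r} in {self.genome_id}")
            if it.end > length:
                raise ValueError(
                    f"interval [{it.start}, {it.end}) exceeds length {length} "
                    f"of {it.seq_id}"
                )


@dataclass
class PhyloTree:
    """Rooted tree with uniquely labeled tips and nonnegative branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = []
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("tree has unlabeled tips")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree edge without branch length")
            if edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self._labels = labels

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


class LibraryRecord(NamedTuple):
    """One repeat consensus sequence from a library FASTA."""

    name: str
    class_string: str
    sequence: str


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect
# ---------------------------------------------------------------------------

_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query         matching"
    "  repeat            position in repeat\n"
    "score   div. del. ins.  sequence  begin  end      (left)    repeat"
    "    class/family      begin  end  (left)   ID\n"
    "\n"
)


def read_repeat_annotation(
    path, genome_id: Optional[str] = None, index: Optional[GenomeIndex] = None
) -> tuple[list[RepeatHit], str]:
    """Parse a RepeatMasker ``.out`` table into :class:`RepeatHit` records.

    The file layout is 3 header lines followed by whitespace-delimited records.
    Query coordinates are 1-based inclusive on disk and converted to 0-based
    half-open; orientation ``C`` becomes strand ``-``.  Records flagged with a
    trailing ``*`` (overlap flag) are retained.  Returns ``(hits, genome_id)``
    where ``genome_id`` defaults to the file's stem.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if lineno <= 3:
                continue  # fixed 3-line header
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 11 fields, got {len(fields)}"
                )
            try:
                score = float(fields[0])
                div = float(fields[1])
                seq_id = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                orient = fields[8]
                rep_name = fields[9]
                rep_class = fields[10]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if begin > end:
                raise ParseError(
                    f"{path}:{lineno}: query begin {begin} > end {end}"
                )
            if orient == "+":
                strand = "+"
            elif orient in ("C", "c"):
                strand = "-"
            else:
                raise ParseError(f"{path}:{lineno}: unknown orientation {orient!r}")
            try:
                hits.append(
                    RepeatHit(
                        seq_id=seq_id,
                        start=begin - 1,
                        end=end,
                        strand=strand,
                        repeat_name=rep_name,
                        repeat_class=rep_class or "Unknown",
                        divergence_pct=div,
                        score=score,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if index is not None:
        index.validate_intervals(hits)
    return hits, gid


def write_repeat_annotation(hits: Iterable[RepeatHit], path) -> None:
    """Write hits back to the ``.out`` dialect (1-based inclusive, C for -)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, h in enumerate(hits, start=1):
            orient = "+" if h.strand == "+" else "C"
            rep_len = h.end - h.start
            fh.write(
                f"{h.score:>7g} {h.divergence_pct:>5.1f}  0.0  0.0  "
                f"{h.seq_id} {h.start + 1} {h.end} (0) {orient} "
                f"{h.repeat_name} {h.repeat_class} 1 {rep_len} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene features
# ---------------------------------------------------------------------------


def read_gene_annotation(path, index: Optional[GenomeIndex] = None) -> list[GeneRecord]:
    """Parse ``gene`` features from a GFF3 file.

    Only rows whose type column is ``gene`` are retained; coordinates are
    converted from 1-based inclusive to 0-based half-open.  The ``ID``
    attribute becomes ``gene_id`` (missing ID is an error, as is a duplicate);
    an optional ``family`` attribute becomes ``family_id``.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            try:
                start = int(cols[3]) - 1
                end = int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
            attrs = _parse_gff_attributes(cols[8])
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            strand = cols[6] if cols[6] in _VALID_STRANDS else "?"
            try:
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        seq_id=cols[0],
                        start=start,
                        end=end,
                        strand=strand,
                        family_id=attrs.get("family"),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if index is not None:
        index.validate_intervals(genes)
    return genes


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, value = chunk.split("=", 1)
            attrs[key] = value
    return attrs


def write_gene_annotation(genes: Iterable[GeneRecord], path, source="repeatscape") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.family_id is not None:
                attrs += f";family={g.family_id}"
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{g.seq_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Genome index (.fai-style two-column TSV)
# ---------------------------------------------------------------------------


def read_genome_index(path, genome_id: Optional[str] = None) -> GenomeIndex:
    """Read a seq-name/length table (first two columns of a ``.fai`` work)."""
    path = Path(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected name and length")
            try:
                lengths[cols[0]] = int(cols[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {cols[1]!r}") from exc
    return GenomeIndex(genome_id or path.stem, lengths)


def write_genome_index(index: GenomeIndex, path) -> None:
    with open(path, "w") as fh:
        for name, length in index.lengths.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Repeat library FASTA (Name#Class/Family headers)
# ---------------------------------------------------------------------------


def read_library_fasta(path) -> list[LibraryRecord]:
    """Read a repeat library; headers follow the ``Name#Class/Family`` convention.

    A header without ``#`` gets class ``Unknown``.  Non-ACGTN symbols trigger a
    warning but the sequence is kept verbatim.
    """
    records: list[LibraryRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "#" in header:
            name, class_string = header.split("#", 1)
        else:
            name, class_string = header, "Unknown"
        seq = str(rec.seq).upper()
        if set(seq) - _DNA_OK:
            warnings.warn(
                f"library sequence {name} contains non-ACGTN symbols; kept as-is",
                stacklevel=2,
            )
        records.append(LibraryRecord(name, class_string or "Unknown", seq))
    return records


def write_library_fasta(records: Iterable[LibraryRecord], path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=f"{r.name}#{r.class_string}", description="")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Trees and tables
# ---------------------------------------------------------------------------


def read_tree(path) -> PhyloTree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return PhyloTree(tree)


def tree_from_newick(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return PhyloTree(tree)


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write a TSV with a fixed float format so reruns are byte-identical."""
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")
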