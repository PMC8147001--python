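"""Alignment and tree I/O plus ordered multi-locus concatenation.

The pipeline consumes per-locus orthologous protein alignments (aligned
FASTA, one file per locus, taxon names shared across loci), a time-calibrated
species tree (Newick, node ages in millions of years) and a taxon-to-clade
table (TSV).  This module reads and writes those formats and builds the
ordered concatenated super-alignment ("supermatrix") with recorded partition
ranges.

Coordinates are 0-based, half-open throughout.  Taxon names are taken from
FASTA headers up to the first whitespace and matched across loci by exact
string equality — silent fuzzy matches are worse than hard errors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    AlphabetError,
    ConcatenationError,
    DuplicateTaxonError,
    TimeTreeError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AMINO_ACIDS + GAP + UNKNOWN)


def _validate_residues(residues: str, taxon: str) -> str:
    residues = residues.upper()
    for pos, ch in enumerate(residues):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"illegal residue {ch!r} at position {pos} in sequence {taxon!r}"
            )
    return residues


@dataclass
class SequenceRecord:
    """One protein sequence: taxon name, residue string, source locus."""

    taxon: str
    residues: str
    locus: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"empty sequence for taxon {self.taxon!r}")
        self.residues = _validate_residues(self.residues, self.taxon)


@dataclass
class LocusAlignment:
    """One locus' orthologous aligned protein sequences keyed by taxon."""

    locus: str
    members: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.members.values()}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"locus {self.locus!r}: unequal sequence lengths {sorted(lengths)}"
            )
        self.members = {
            t: _validate_residues(s, t) for t, s in self.members.items()
        }

    @property
    def length(self) -> int:
        return len(next(iter(self.members.values()))) if self.members else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.members)


@dataclass
class ConcatenatedAlignment:
    """Ordered multi-locus super-alignment with per-locus partition ranges.

    ``partitions`` maps each locus (in concatenation order) to its half-open
    column range ``[start, end)``; ranges are contiguous and cover the full
    alignment.
    """

    order: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def partition_range(self, locus: str) -> tuple[int, int]:
        for name, start, end in self.partitions:
            if name == locus:
                return start, end
        raise KeyError(locus)


class TimeTree:
    """Rooted species tree with node ages in MYA (leaves at age 0).

    Wraps a dendropy tree; ``mrca_age(a, b)`` is the pipeline's source of
    pairwise divergence times.
    """

    def __init__(self, tree: dendropy.Tree, ages: dict[int, float]):
        self._tree = tree
        self._ages = ages  # id(node) -> age in MYA

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaves(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def root_age(self) -> float:
        return self._ages[id(self._tree.seed_node)]

    def node_age(self, node: dendropy.Node) -> float:
        return self._ages[id(node)]

    def mrca_age(self, a: str, b: str) -> float:
        if a == b:
            if a not in self.leaves:
                raise TimeTreeError(f"unknown taxon {a!r}")
            return 0.0
        taxa = self._tree.taxon_namespace
        labels = {t.label for t in taxa}
        for name in (a, b):
            if name not in labels:
                raise TimeTreeError(f"unknown taxon {name!r}")
        mrca = self._tree.mrca(taxa=[t for t in taxa if t.label in (a, b)])
        return self._ages[id(mrca)]


def read_fasta(path, locus: str = "", aligned: bool = True) -> LocusAlignment:
    """Read a FASTA file into a :class:`LocusAlignment`.

    Taxon names are parsed from headers up to the first whitespace.  With
    ``aligned=True`` (default) unequal sequence lengths raise
    :class:`AlignmentFormatError`.
    """
    members: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = rec.id
        if taxon in members:
            raise DuplicateTaxonError(f"duplicate taxon {taxon!r} in {path}")
        members[taxon] = _validate_residues(str(rec.seq), taxon)
    if not members:
        raise AlignmentFormatError(f"no sequences in {path}")
    if aligned and len({len(s) for s in members.values()}) > 1:
        raise AlignmentFormatError(f"{path}: sequences have unequal lengths")
    return LocusAlignment(locus=locus or str(path), members=members)


def write_fasta(aln: LocusAlignment | ConcatenatedAlignment, path) -> None:
    rows = aln.members if isinstance(aln, LocusAlignment) else aln.rows
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate(
    loci: list[LocusAlignment],
    order: list[str] | None = None,
    missing_policy: str = "drop_taxon",
) -> ConcatenatedAlignment:
    """Join per-locus alignments column-wise in a fixed locus order.

    ``missing_policy='drop_taxon'`` (default) keeps only taxa present in
    every listed locus — the convention used when a subunit lacking
    annotation in some species is included, forcing those species out.
    ``'gap_fill'`` keeps the union of taxa, filling absent loci with gap
    columns.
    """
    if missing_policy not in ("drop_taxon", "gap_fill"):
        raise ConcatenationError(f"unknown missing_policy {missing_policy!r}")
    by_name = {a.locus: a for a in loci}
    if order is None:
        order = [a.locus for a in loci]
    missing = [name for name in order if name not in by_name]
    if missing:
        raise ConcatenationError(f"order names unknown loci: {missing}")
    chosen = [by_name[name] for name in order]

    if missing_policy == "drop_taxon":
        taxa: list[str] = [
            t for t in chosen[0].taxa if all(t in a.members for a in chosen)
        ]
        if not taxa:
            raise ConcatenationError(
                "no taxon is present in every locus (drop_taxon policy)"
            )
    else:
        seen: dict[str, None] = {}
        for a in chosen:
            for t in a.taxa:
                seen.setdefault(t)
        taxa = list(seen)

    partitions: list[tuple[str, int, int]] = []
    start = 0
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    for a in chosen:
        end = start + a.length
        partitions.append((a.locus, start, end))
        for t in taxa:
            pieces[t].append(a.members.get(t, GAP * a.length))
        start = end
    rows = {t: "".join(p) for t, p in pieces.items()}
    return ConcatenatedAlignment(order=list(order), rows=rows, partitions=partitions)


def read_timetree(
    source, dialect: str = "branch_lengths", rel_tol: float = 1e-6
) -> TimeTree:
    """Read a Newick species tree and resolve internal node ages in MYA.

    ``dialect='branch_lengths'`` (default): the tree is ultrametric and ages
    are read off as root-to-leaf depth minus node depth; deviation of any
    leaf depth beyond ``rel_tol`` × root age raises :class:`TimeTreeError`.
    ``dialect='node_labels'``: internal node labels carry the ages directly.
    """
    if dialect not in ("branch_lengths", "node_labels"):
        raise TimeTreeError(f"unknown time-tree dialect {dialect!r}")
    if isinstance(source, str) and (
        ";" in source or source.lstrip().startswith(("(", "["))
    ):
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(source), schema="newick")
    tree.is_rooted = True  # a time tree is rooted by construction

    ages: dict[int, float] = {}
    if dialect == "node_labels":
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                ages[id(node)] = 0.0
            else:
                if node.label is None:
                    raise TimeTreeError(
                        "internal node without an age label (node_labels dialect)"
                    )
                try:
                    ages[id(node)] = float(node.label)
                except ValueError as exc:
                    raise TimeTreeError(
                        f"non-numeric internal node label {node.label!r}"
                    ) from exc
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                if ages[id(node)] < ages[id(child)] - 1e-12:
                    raise TimeTreeError(
                        "node ages not monotone: a parent is younger than a child"
                    )
    else:
        # age of node = max depth below it; ultrametricity checked on leaves
        depth: dict[int, float] = {id(tree.seed_node): 0.0}
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                if child.edge.length is None:
                    raise TimeTreeError("branch without a length")
                depth[id(child)] = depth[id(node)] + child.edge.length
        root_age = max(depth[id(lf)] for lf in tree.leaf_node_iter())
        tol = rel_tol * root_age if root_age > 0 else rel_tol
        for lf in tree.leaf_node_iter():
            if abs(depth[id(lf)] - root_age) > tol:
                raise TimeTreeError(
                    f"tree not ultrametric: leaf {lf.taxon.label!r} at depth "
                    f"{depth[id(lf)]:.6g} vs root age {root_age:.6g}"
                )
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                ages[id(node)] = 0.0
            else:
                ages[id(node)] = root_age - depth[id(node)]
    return TimeTree(tree, ages)


def write_newick(tree: TimeTree | dendropy.Tree | str, path) -> None:
    if isinstance(tree, TimeTree):
        tree = tree.dendropy_tree
    if isinstance(tree, dendropy.Tree):
        text = tree.as_string(schema="newick", suppress_rooting=True)
    else:
        text = tree if tree.endswith("\n") else tree + "\n"
    with open(path, "w") as fh:
        fh.write(text)


@dataclass
class CladeMap:
    """Assignment of each taxon to exactly one clade label."""

    assignment: dict[str, str] = field(default_factory=dict)

    def clade_of(self, taxon: str) -> str:
        return self.assignment[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.assignment

    @property
    def clades(self) -> list[str]:
        out: dict[str, None] = {}
        for c in self.assignment.values():
            out.setdefault(c)
        return list(out)


def read_clademap(path) -> CladeMap:
    """Read a two-column TSV (taxon <tab> clade). Duplicate taxa are errors."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            taxon, clade = parts
            if taxon in assignment:
                raise DuplicateTaxonError(
                    f"{path}:{lineno}: duplicate taxon {taxon!r}"
                )
            assignment[taxon] = clade
    return CladeMap(assignment)


def write_clademap(clades: CladeMap, path) -> None:
    with open(path, "w") as fh:
        for taxon, clade in clades.assignment.items():
            fh.write(f"{taxon}\t{clade}\n")


def write_tsv(df, path) -> None:
    """Write a pandas DataFrame as TSV without the index (stable ordering)."""
    df.to_csv(path, sep="\t", index=False)


def fasta_string(aln: LocusAlignment | ConcatenatedAlignment) -> str:
    """Render an alignment as FASTA text (used for determinism checks)."""
    rows = aln.members if isinstance(aln, LocusAlignment) else aln.rows
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in rows.items()
    ]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
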