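"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open.  Anything emitted to or
read from GFF3 is converted at the boundary to the format's 1-based
inclusive convention.  Intron phase is defined as the number of CDS
nucleotides 5' of the boundary, modulo 3.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    DuplicateIdError,
    EmptySequenceError,
    GeneModelError,
    NewickParseError,
    UnrootedTreeError,
)

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")
_DNA_ALPHABET = set("ACGTN-")


@dataclass
class SeqRecord:
    """A named sequence, either protein or DNA.

    Residues are stored uppercase; ``had_lowercase`` records whether the
    source contained lowercase characters (soft-masking and the like).
    """

    id: str
    seq: str
    moltype: str = "protein"  # {"protein", "dna"}
    description: str = ""
    had_lowercase: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise EmptySequenceError(f"record {self.id!r} has an empty sequence")
        if self.seq != self.seq.upper():
            self.had_lowercase = True
            self.seq = self.seq.upper()
        alphabet = _DNA_ALPHABET if self.moltype == "dna" else _PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for {self.moltype}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def guess_moltype(seq: str) -> str:
    """DNA if the sequence uses only nucleotide characters, else protein."""
    return "dna" if set(seq.upper()) <= _DNA_ALPHABET else "protein"


def read_fasta(path, moltype: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Duplicate ids and empty sequences are rejected.  Lowercase residues
    are uppercased and flagged on the record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise EmptySequenceError(f"record {rec.id!r} in {path} has an empty sequence")
        mt = moltype or guess_moltype(seq)
        records.append(
            SeqRecord(id=rec.id, seq=seq, moltype=mt, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A genomic locus: ordered coding exons on a strand.

    ``exons`` are (start, end) 0-based half-open genomic intervals,
    ordered 5'->3' on the coding strand (decreasing genomic coordinate
    for minus-strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise GeneModelError(f"{self.gene_id}: empty or inverted exon ({s},{e})")
        by_pos = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_pos, by_pos[1:]):
            if s2 < e1:
                raise GeneModelError(f"{self.gene_id}: overlapping exons")
        expected = by_pos if self.strand == "+" else by_pos[::-1]
        if list(self.exons) != expected:
            raise GeneModelError(
                f"{self.gene_id}: exons not ordered 5'->3' on the coding strand"
            )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end), 0-based half-open, strand-agnostic."""
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


def read_gff_gene_models(path) -> list[GeneModel]:
    """Parse a GFF3 file into gene models.

    CDS features (grouped by their ``Parent``, falling back to the gene
    ID) define the coding exons.  GFF3 coordinates are 1-based inclusive
    and converted on the way in.  A CDS length not divisible by 3 marks
    the model incomplete with a warning rather than failing.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise GeneModelError(f"{path}: could not parse GFF3: {exc}") from exc

    cds_by_parent: dict[str, list[tuple[str, int, int, str]]] = {}
    parent_gene: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype in ("mRNA", "transcript"):
            parent = feat.attributes.get("Parent", [feat.id])[0]
            parent_gene[feat.id] = parent
        elif feat.featuretype == "CDS":
            parent = feat.attributes.get("Parent", [feat.id])[0]
            cds_by_parent.setdefault(parent, []).append(
                (feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
    models = []
    for parent, rows in cds_by_parent.items():
        chroms = {r[0] for r in rows}
        strands = {r[3] for r in rows}
        if len(chroms) > 1 or len(strands) > 1:
            raise GeneModelError(f"{parent}: CDS segments span chromosomes/strands")
        strand = strands.pop()
        exons = sorted((s, e) for _, s, e, _ in rows)
        if strand == "-":
            exons = exons[::-1]
        gene_id = parent_gene.get(parent, parent)
        complete = sum(e - s for s, e in exons) % 3 == 0
        if not complete:
            warnings.warn(f"{gene_id}: CDS length not divisible by 3; model marked incomplete")
        models.append(
            GeneModel(gene_id=gene_id, chrom=chroms.pop(), strand=strand,
                      exons=exons, complete=complete)
        )
    models.sort(key=lambda m: (m.chrom, m.span))
    return models


def write_gff_gene_models(models: Iterable[GeneModel], path) -> None:
    """Emit gene/mRNA/CDS features, converting to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(
                f"{m.chrom}\topsinkit\tgene\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            mrna = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\topsinkit\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={mrna};Parent={m.gene_id}\n"
            )
            phase = 0
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\topsinkit\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )
                phase = (3 - ((e - s) - phase) % 3) % 3


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a rooted tree with optional length and (SH-aLRT, UFboot) support."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support  # tuple (sh_alrt, ufboot) or None
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        for c in children or []:
            self.add_child(c)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def copy(self) -> "TreeNode":
        dup = TreeNode(self.name, self.length, self.support)
        for c in self.children:
            dup.add_child(c.copy())
        return dup

    def __repr__(self) -> str:
        return f"<TreeNode {self.name or '(internal)'} k={len(self.children)}>"


@dataclass
class Tree:
    """A rooted tree; leaf labels are unique."""

    root: TreeNode

    def __post_init__(self) -> None:
        names = self.root.leaf_names()
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NewickParseError(f"duplicate leaf labels: {dup}")

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def require_rooted_binary(self, what: str = "tree") -> None:
        if len(self.root.children) > 2:
            raise UnrootedTreeError(
                f"{what} has a multifurcating root; a rooted binary tree is required"
            )

    def copy(self) -> "Tree":
        return Tree(self.root.copy())


_SUPPORT_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*$")


def _parse_support(label: str | None):
    """Parse an 'SH-aLRT/UFboot' compound internal label, if that is what it is."""
    if not label:
        return None, label
    m = _SUPPORT_RE.match(label)
    if m:
        sh, uf = float(m.group(1)), float(m.group(2))
        if 0 <= sh <= 100 and 0 <= uf <= 100:
            return (sh, uf), None
    try:
        v = float(label)
    except ValueError:
        return None, label
    if 0 <= v <= 100:
        return (v, v), None
    return None, label


def _from_dendropy(node: dendropy.Node) -> TreeNode:
    if node.is_leaf():
        name = node.taxon.label if node.taxon else node.label
        return TreeNode(name=name, length=node.edge.length)
    label = node.label
    support, name = _parse_support(label)
    out = TreeNode(name=name, length=node.edge.length, support=support)
    for child in node.child_nodes():
        out.add_child(_from_dendropy(child))
    return out


def parse_newick(text: str) -> Tree:
    """Parse a Newick string, interpreting compound internal labels
    ``sh-alrt/ufboot`` as support pairs."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    return Tree(_from_dendropy(dtree.seed_node))


def read_newick(path) -> Tree:
    return parse_newick(Path(path).read_text())


def _format_node(node: TreeNode) -> str:
    if node.is_leaf:
        label = node.name or ""
    else:
        inner = ",".join(_format_node(c) for c in node.children)
        if node.support is not None:
            sh, uf = node.support
            label = f"({inner}){sh:g}/{uf:g}"
        else:
            label = f"({inner}){node.name or ''}"
    if node.length is not None:
        label += f":{node.length:g}"
    return label


def to_newick(tree: Tree) -> str:
    return _format_node(tree.root) + ";"


def write_newick(tree: Tree, path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

PROV_OBSERVED = "observed"
PROV_GENOMIC_ZERO = "genomic_zero"
PROV_MISSING = "transcriptomic_missing"


@dataclass
class CountTable:
    """Per-species gene counts per opsin subclade, with cell provenance.

    On disk, a cell is a non-negative integer or ``NA``.  ``NA`` means no
    transcriptomic evidence (unknown, excluded from parsimony); a literal
    0 means genomic evidence of absence (a true zero).
    """

    counts: pd.DataFrame      # int, species x clades
    provenance: pd.DataFrame  # str, same shape

    def __post_init__(self) -> None:
        if self.counts.shape != self.provenance.shape:
            raise ValueError("counts and provenance shapes differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        counts = pd.DataFrame(0, index=raw.index, columns=raw.columns, dtype=int)
        prov = pd.DataFrame(PROV_OBSERVED, index=raw.index, columns=raw.columns)
        for sp in raw.index:
            for cl in raw.columns:
                cell = raw.loc[sp, cl].strip()
                if cell in ("", "NA", "na", "?"):
                    prov.loc[sp, cl] = PROV_MISSING
                else:
                    v = int(cell)
                    counts.loc[sp, cl] = v
                    prov.loc[sp, cl] = PROV_GENOMIC_ZERO if v == 0 else PROV_OBSERVED
        return cls(counts=counts, provenance=prov)

    def to_tsv(self, path) -> None:
        out = self.counts.astype(object).copy()
        mask = self.provenance == PROV_MISSING
        out[mask] = "NA"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CdsExtract:
    cds: str
    protein: str
    left_flank: str
    right_flank: str
    left_truncated: bool = False
    right_truncated: bool = False
    pseudogene_candidate: bool = False


def extract_cds_and_flanks(
    genome: dict[str, str] | str | Path,
    model: GeneModel,
    flank_len: int = 2000,
) -> CdsExtract:
    """Splice a gene model's CDS out of a genome and grab its flanks.

    The CDS is returned in coding orientation (minus-strand models are
    reverse-complemented); flanks are in genomic orientation and
    truncated (with a flag) at contig edges.  An internal stop codon
    marks the extract a pseudogene candidate with a warning.
    """
    if not isinstance(genome, dict):
        genome = {r.id: r.seq for r in read_fasta(genome, moltype="dna")}
    if model.chrom not in genome:
        raise GeneModelError(f"{model.gene_id}: chromosome {model.chrom!r} not in genome")
    chrom_seq = genome[model.chrom]
    lo, hi = model.span
    if lo < 0 or hi > len(chrom_seq):
        raise GeneModelError(f"{model.gene_id}: coordinates outside {model.chrom!r}")

    pieces = []
    for s, e in model.exons:
        piece = chrom_seq[s:e]
        pieces.append(revcomp(piece) if model.strand == "-" else piece)
    cds = "".join(pieces)

    flank_start = max(0, lo - flank_len)
    left = chrom_seq[flank_start:lo]
    right = chrom_seq[hi:hi + flank_len]

    protein = ""
    pseudo = False
    if len(cds) % 3 == 0 and cds:
        aa = str(Seq(cds).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            warnings.warn(f"{model.gene_id}: internal stop codon; pseudogene candidate")
            pseudo = True
        protein = aa
    return CdsExtract(
        cds=cds,
        protein=protein,
        left_flank=left,
        right_flank=right,
        left_truncated=len(left) < flank_len,
        right_truncated=len(right) < flank_len,
        pseudogene_candidate=pseudo,
    )
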