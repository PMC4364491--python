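"""Sequence, alignment and tree I/O.

Protein-only: the pipeline works on amino-acid sequences (the 20 standard
residues, ``X`` for unknown, and ``-`` for alignment gaps). Lower-case input
is normalised to upper case; ``*`` (stop) is rejected. FASTA and Clustal
parsing is delegated to Biopython; Newick reading to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import AlignIO, SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(STANDARD_AA + "X")
ALIGNED_ALPHABET = frozenset(STANDARD_AA + "X-")


class ParseError(ValueError):
    """Malformed sequence or alignment input; message locates the problem."""


@dataclass(frozen=True)
class MHCSequence:
    """A named protein sequence with optional species/lineage annotations."""

    id: str
    sequence: str
    species: str | None = None
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    @property
    def lineage(self) -> str | None:
        return self.annotations.get("lineage")


def _validate_residues(seq_id: str, seq: str, *, aligned: bool) -> None:
    allowed = ALIGNED_ALPHABET if aligned else ALPHABET
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise ParseError(
                f"record {seq_id!r}: illegal residue {ch!r} at position {i + 1}"
                + (" (gaps only allowed in alignment mode)" if ch == "-" else "")
            )


@dataclass(frozen=True)
class AlignedSet:
    """An ordered multiple alignment; all members share one width."""

    members: tuple[MHCSequence, ...]
    width: int

    @classmethod
    def from_sequences(cls, seqs: Iterable[MHCSequence]) -> "AlignedSet":
        members = tuple(seqs)
        widths = {len(s) for s in members}
        if len(widths) > 1:
            by_len: dict[int, list[str]] = {}
            for s in members:
                by_len.setdefault(len(s), []).append(s.id)
            raise ParseError(f"ragged alignment; lengths by id: {by_len}")
        width = widths.pop() if widths else 0
        if members and width == 0:
            raise ParseError("alignment width must be > 0")
        ids = [s.id for s in members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate ids in alignment: {dupes}")
        return cls(members=members, width=width)

    def __len__(self) -> int:
        return len(self.members)

    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def column(self, index: int) -> str:
        """Residues of 1-based column ``index`` across members, in order."""
        if not 1 <= index <= self.width:
            raise IndexError(f"column {index} outside 1..{self.width}")
        return "".join(m.sequence[index - 1] for m in self.members)


def _records_to_sequences(records, *, aligned: bool) -> list[MHCSequence]:
    out: list[MHCSequence] = []
    seen: set[str] = set()
    for rec in records:
        desc = rec.description or ""
        remainder = desc.split(None, 1)[1] if len(desc.split(None, 1)) > 1 else ""
        seq = str(rec.seq).upper()
        _validate_residues(rec.id, seq, aligned=aligned)
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        ann = {"description": remainder} if remainder else {}
        out.append(MHCSequence(id=rec.id, sequence=seq, annotations=ann))
    return out


def read_fasta(path: str | Path, *, aligned: bool = False) -> list[MHCSequence]:
    """Read a FASTA file into a list of :class:`MHCSequence`.

    The header token before the first whitespace becomes the id; any
    remainder is kept under the ``description`` annotation. With
    ``aligned=True`` gap characters are retained, otherwise they are an
    error (mode contract: unaligned input must be gap-free).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _records_to_sequences(SeqIO.parse(str(path), "fasta"), aligned=aligned)


def write_fasta(seqs: Iterable[MHCSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            desc = s.annotations.get("description", "")
            header = f">{s.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


def read_alignment(path: str | Path, dialect: str = "fasta") -> AlignedSet:
    """Read a multiple alignment (``fasta`` or ``clustal`` dialect)."""
    if dialect not in ("fasta", "clustal"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        aln = AlignIO.read(str(path), dialect)
    except ValueError as exc:
        # Biopython raises on ragged/unparseable input; try to name offenders.
        if dialect == "fasta":
            seqs = read_fasta(path, aligned=True)
            return AlignedSet.from_sequences(seqs)  # raises with ids listed
        raise ParseError(f"{path}: {exc}") from exc
    return AlignedSet.from_sequences(_records_to_sequences(aln, aligned=True))


def write_alignment(aligned: AlignedSet, path: str | Path) -> None:
    write_fasta(aligned.members, path)


# ---------------------------------------------------------------------------
# Newick

_NEWICK_RESERVED = set("();:,[]' \t\n")


def _quote_label(label: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree, path: str | Path | None = None, *, include_support: bool = True) -> str:
    """Serialise a :class:`mhclin.phylogeny.PhyloTree` to Newick.

    Support values (percentages) are written as internal node labels when
    ``include_support`` is set. Returns the Newick string; writes it to
    ``path`` when given.
    """
    if len(tree.leaf_names()) < 2:
        raise ValueError("tree must have at least 2 leaves")

    def render(node) -> str:
        if not node.children:
            label = _quote_label(node.name)
        else:
            inner = ",".join(render(c) for c in node.children)
            sup = ""
            if include_support and node.support is not None:
                sup = format(node.support, "g")
            label = f"({inner}){sup}"
        if node.length is not None:
            label += f":{node.length:.10g}"
        return label

    root = tree.root
    inner = ",".join(render(c) for c in root.children)
    sup = ""
    if include_support and root.support is not None:
        sup = format(root.support, "g")
    text = f"({inner}){sup};"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path):
    """Parse Newick text (or a file path) into a PhyloTree via dendropy."""
    import dendropy

    from .phylogeny import Node, PhyloTree

    text = str(source)
    if isinstance(source, Path):
        text = source.read_text()
    elif "(" not in text:  # no tree syntax: must be a path
        text = Path(text).read_text()
    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            node = Node(name=dnode.taxon.label if dnode.taxon else (dnode.label or ""))
        else:
            node = Node(name="")
            if dnode.label is not None:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    pass
            for ch in dnode.child_nodes():
                node.add_child(convert(ch))
        edge = dnode.edge.length
        node.length = float(edge) if edge is not None else None
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return PhyloTree(root=root)
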