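"""Placement of query sequences into HLA-A2 mature-chain coordinates.

The published analyses rest on hand-curated alignments against HLA-A2; here
a deterministic affine-gap global alignment (Needleman–Wunsch, BLOSUM62,
open −10 / extend −1) stands in for that curation, and every downstream
operation takes the resulting position map as input so an externally
curated alignment can be substituted. Coordinates are 1-based closed
intervals in mature-chain numbering (Y7, C36, ... style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .reference import DomainBoundaries
from .seqio import MHCSequence


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap parameters. ``open_score`` is charged for the first gap
    residue and ``extend_score`` for each subsequent one; end gaps are
    penalised unless ``semiglobal`` is set (fragments)."""

    matrix: str = "BLOSUM62"
    open_score: float = -10.0
    extend_score: float = -1.0
    semiglobal: bool = False

    def __post_init__(self) -> None:
        if self.open_score >= 0 or self.extend_score >= 0:
            raise ValueError("gap penalties must be negative")
        if self.open_score > self.extend_score:
            raise ValueError("gap open must be <= gap extend")


@dataclass(frozen=True)
class PairwiseAlignment:
    query_row: str
    reference_row: str
    score: float
    parameters: AlignParams

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.reference_row):
            raise ValueError("alignment rows must have equal length")
        for q, r in zip(self.query_row, self.reference_row):
            if q == "-" and r == "-":
                raise ValueError("gap-over-gap column in alignment")

    @property
    def query(self) -> str:
        return self.query_row.replace("-", "")

    @property
    def reference(self) -> str:
        return self.reference_row.replace("-", "")


@lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.open_score
    aligner.extend_gap_score = params.extend_score
    aligner.mode = "global"
    if params.semiglobal:
        aligner.end_gap_score = 0.0
    return aligner


def global_align(
    query: MHCSequence | str,
    reference: MHCSequence | str,
    params: AlignParams | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``reference``.

    The score is the maximum over all global alignments under the affine
    gap model; the reported traceback is the first in Biopython's
    deterministic enumeration order, so repeated runs agree.
    """
    params = params or AlignParams()
    q = query.sequence if isinstance(query, MHCSequence) else str(query).upper()
    r = reference.sequence if isinstance(reference, MHCSequence) else str(reference).upper()
    if not q or not r:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(params).align(q, r)[0]
    return PairwiseAlignment(
        query_row=str(aln[0]),
        reference_row=str(aln[1]),
        score=float(aln.score),
        parameters=params,
    )


@dataclass(frozen=True)
class PositionMap:
    """Monotone correspondence query index -> reference mature position."""

    pairs: tuple[tuple[int, int], ...]
    reference_length: int

    def __post_init__(self) -> None:
        prev_q = prev_r = 0
        for q, r in self.pairs:
            if q <= prev_q or r <= prev_r:
                raise ValueError("position map must be strictly monotone")
            prev_q, prev_r = q, r

    @property
    def coverage(self) -> float:
        """Fraction of reference positions mapped."""
        if self.reference_length == 0:
            return 0.0
        return len(self.pairs) / self.reference_length

    def span_coverage(self, lo: int, hi: int) -> float:
        """Fraction of reference positions in [lo, hi] that are mapped."""
        n = sum(1 for _, r in self.pairs if lo <= r <= hi)
        return n / (hi - lo + 1)

    @property
    def query_to_ref(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def ref_to_query(self) -> dict[int, int]:
        return {r: q for q, r in self.pairs}

    def residue_at(self, query: MHCSequence | str, ref_pos: int) -> str | None:
        """Query residue mapped to reference position, or None if unmapped."""
        q = self.ref_to_query.get(ref_pos)
        if q is None:
            return None
        seq = query.sequence if isinstance(query, MHCSequence) else query
        return seq[q - 1]


def map_to_reference(alignment: PairwiseAlignment) -> PositionMap:
    """One (query, reference) index pair per aligned residue-over-residue
    column; monotone by construction."""
    pairs = []
    qi = ri = 0
    for q, r in zip(alignment.query_row, alignment.reference_row):
        if q != "-":
            qi += 1
        if r != "-":
            ri += 1
        if q != "-" and r != "-":
            pairs.append((qi, ri))
    return PositionMap(pairs=tuple(pairs), reference_length=ri)


def map_query(
    query: MHCSequence | str,
    reference: MHCSequence | str,
    params: AlignParams | None = None,
) -> PositionMap:
    """Convenience: align and map in one step."""
    return map_to_reference(global_align(query, reference, params))


@dataclass(frozen=True)
class DomainSegment:
    sequence: str
    start: int  # 1-based query coordinates; (0, -1) when empty
    end: int

    @property
    def empty(self) -> bool:
        return self.end < self.start


_EMPTY = DomainSegment("", 1, 0)


@dataclass(frozen=True)
class DomainPartition:
    """Query partitioned into α1/α2/α3 plus unassigned flanks.

    Internal unmapped residues are attributed to the preceding populated
    domain, so prefix + α1 + α2 + α3 + suffix always reconstructs the
    query. ``fragment`` flags maps covering < 20% of the reference
    α1–α3 span.
    """

    alpha1: DomainSegment
    alpha2: DomainSegment
    alpha3: DomainSegment
    unassigned_prefix: DomainSegment
    unassigned_suffix: DomainSegment
    fragment: bool = False
    span_coverage: float = field(default=0.0)

    def reconstruct(self) -> str:
        return "".join(
            seg.sequence
            for seg in (
                self.unassigned_prefix,
                self.alpha1,
                self.alpha2,
                self.alpha3,
                self.unassigned_suffix,
            )
        )


def split_domains(
    query: MHCSequence | str,
    pmap: PositionMap,
    boundaries: DomainBoundaries,
    fragment_threshold: float = 0.2,
) -> DomainPartition:
    """Assign each mapped query residue to the domain of its reference
    position; unmapped internal residues go to the nearest preceding
    populated domain."""
    seq = query.sequence if isinstance(query, MHCSequence) else str(query)
    if not pmap.pairs:
        raise ValueError("cannot split domains with an empty position map")
    intervals = boundaries.as_dict()
    order = ["alpha1", "alpha2", "alpha3"]
    mapped_q: dict[str, list[int]] = {d: [] for d in order}
    for qpos, rpos in pmap.pairs:
        for d in order:
            lo, hi = intervals[d]
            if lo <= rpos <= hi:
                mapped_q[d].append(qpos)
                break
    q_first = pmap.pairs[0][0]
    q_last = pmap.pairs[-1][0]
    populated = [d for d in order if mapped_q[d]]
    segments: dict[str, DomainSegment] = {d: _EMPTY for d in order}
    if populated:
        starts = {populated[0]: q_first}
        for prev, nxt in zip(populated, populated[1:]):
            starts[nxt] = min(mapped_q[nxt])
        for i, d in enumerate(populated):
            end = (
                starts[populated[i + 1]] - 1
                if i + 1 < len(populated)
                else q_last
            )
            start = starts[d]
            segments[d] = DomainSegment(seq[start - 1 : end], start, end)
    span_lo = intervals["alpha1"][0]
    span_hi = intervals["alpha3"][1]
    cov = pmap.span_coverage(span_lo, span_hi)
    return DomainPartition(
        alpha1=segments["alpha1"],
        alpha2=segments["alpha2"],
        alpha3=segments["alpha3"],
        unassigned_prefix=DomainSegment(seq[: q_first - 1], 1, q_first - 1),
        unassigned_suffix=DomainSegment(seq[q_last:], q_last + 1, len(seq)),
        fragment=cov < fragment_threshold,
        span_coverage=cov,
    )


def project_to_reference_frame(
    query: MHCSequence | str,
    pmap: PositionMap,
    width: int,
) -> str:
    """Render the query as a gapped row of ``width`` reference columns:
    the mapped residue at each reference position, ``-`` elsewhere.
    Query insertions relative to the reference are dropped; this is the
    representation used to join queries with reference-frame exemplar
    alignments."""
    seq = query.sequence if isinstance(query, MHCSequence) else str(query)
    row = ["-"] * width
    for qpos, rpos in pmap.pairs:
        if 1 <= rpos <= width:
            row[rpos - 1] = seq[qpos - 1]
    return "".join(row)
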