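"""Peptide-binding-groove feature statistics.

Implements the sequence-level checks used to characterise teleost MHC
class I molecules against the HLA-A2 groove: anchor-residue scoring at the
eight peptide-terminus positions, conservation of the 37 A–F pocket
positions across an aligned set, cysteine geometry (the α1 C36/C67 pair of
the U/P lineages, the S-lineage C6–9/C48/C100 pattern, and the canonical
α2/α3 disulfide pairs), the N86 glycosylation sequon, and Kyte–Doolittle
domain hydropathy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .align import PositionMap
from .reference import AnchorTable, HydropathyScale, PocketTable
from .seqio import AlignedSet, MHCSequence

_MISSING = set("-X")


def _seq_str(query) -> str:
    return query.sequence if isinstance(query, MHCSequence) else str(query).upper()


# ---------------------------------------------------------------------------
# Anchors


@dataclass(frozen=True)
class AnchorOutcome:
    position: int
    outcome: str  # "match" | "mismatch" | "unmapped"
    observed: str | None
    accepted: frozenset[str]


@dataclass(frozen=True)
class AnchorReport:
    outcomes: tuple[AnchorOutcome, ...]

    @property
    def n_matched(self) -> int:
        return sum(1 for o in self.outcomes if o.outcome == "match")

    @property
    def mismatches(self) -> dict[int, str]:
        return {
            o.position: o.observed
            for o in self.outcomes
            if o.outcome == "mismatch"
        }

    def observed_at(self, position: int) -> str | None:
        for o in self.outcomes:
            if o.position == position:
                return o.observed
        return None


def score_anchors(
    query: MHCSequence | str, pmap: PositionMap, anchors: AnchorTable
) -> AnchorReport:
    """Count anchor positions where the mapped query residue is accepted.

    Unmapped positions are reported distinctly and count as non-matches.
    """
    seq = _seq_str(query)
    outcomes = []
    for pos in anchors.positions:
        accepted = anchors.entries[pos]
        qidx = pmap.ref_to_query.get(pos)
        if qidx is None:
            outcomes.append(AnchorOutcome(pos, "unmapped", None, accepted))
            continue
        res = seq[qidx - 1]
        outcome = "match" if res in accepted else "mismatch"
        outcomes.append(AnchorOutcome(pos, outcome, res, accepted))
    return AnchorReport(outcomes=tuple(outcomes))


# ---------------------------------------------------------------------------
# Pocket conservation


@dataclass(frozen=True)
class PositionConservation:
    position: int
    pocket: str
    frequencies: dict[str, int]
    modal_residue: str | None
    conservation: float
    category: str  # "complete" | "high" | "below"
    n_missing: int


@dataclass(frozen=True)
class ConservationProfile:
    """Per-pocket-position conservation over an aligned sequence set.

    Two summary statistics are always reported because published
    "percent conserved" figures can mean either: the share of positions
    whose non-missing residues are all identical (position level), and
    the share of all non-missing sequence-by-position cells equal to their
    column's modal residue (cell level).
    """

    per_position: tuple[PositionConservation, ...]
    unalignable: tuple[int, ...]
    n_sequences: int

    @property
    def position_level_complete(self) -> float:
        evaluated = [p for p in self.per_position]
        if not evaluated:
            raise ValueError("no alignable pocket positions")
        return sum(p.category == "complete" for p in evaluated) / len(evaluated)

    @property
    def cell_level_identity(self) -> float:
        modal = sum(p.frequencies[p.modal_residue] for p in self.per_position)
        total = sum(sum(p.frequencies.values()) for p in self.per_position)
        if total == 0:
            raise ValueError("no non-missing cells at pocket positions")
        return modal / total


def _category(conservation: float) -> str:
    # Category bands follow the published colour scheme: black = complete
    # (100%), grey = 90-99.7%, everything else below.
    if conservation == 1.0:
        return "complete"
    if 0.90 <= conservation <= 0.997:
        return "high"
    return "below"


def pocket_conservation(
    aligned: AlignedSet,
    column_to_reference: PositionMap,
    pockets: PocketTable,
) -> ConservationProfile:
    """Residue conservation at the 37 pocket positions of an aligned set.

    ``column_to_reference`` maps 1-based alignment columns to reference
    positions (build it with :func:`column_map_from_member` when the
    reference is itself a member of the alignment). Gap/X cells are
    excluded per position; a pocket position with no mapped column is
    reported as unalignable (the "ellipse" case) and excluded from the
    summary denominators. Ties for the modal residue break alphabetically.
    """
    if len(aligned) < 1:
        raise ValueError("need at least one sequence")
    ref_to_col = column_to_reference.ref_to_query
    per_position = []
    unalignable = []
    for pos in pockets.positions:
        col = ref_to_col.get(pos)
        if col is None or not (1 <= col <= aligned.width):
            unalignable.append(pos)
            continue
        residues = [r for r in aligned.column(col) if r not in _MISSING]
        n_missing = len(aligned) - len(residues)
        if not residues:
            unalignable.append(pos)
            continue
        freq = Counter(residues)
        top = max(freq.values())
        modal = min(r for r, c in freq.items() if c == top)
        conservation = freq[modal] / len(residues)
        per_position.append(
            PositionConservation(
                position=pos,
                pocket=pockets.pocket_label[pos],
                frequencies=dict(sorted(freq.items())),
                modal_residue=modal,
                conservation=conservation,
                category=_category(conservation),
                n_missing=n_missing,
            )
        )
    return ConservationProfile(
        per_position=tuple(per_position),
        unalignable=tuple(unalignable),
        n_sequences=len(aligned),
    )


def column_map_from_member(aligned: AlignedSet, member_id: str) -> PositionMap:
    """Column -> reference-position map derived from a member of the
    alignment that *is* the reference (its ungapped index is the reference
    numbering)."""
    for m in aligned.members:
        if m.id == member_id:
            pairs = []
            ref = 0
            for col, ch in enumerate(m.sequence, start=1):
                if ch != "-":
                    ref += 1
                    pairs.append((col, ref))
            return PositionMap(pairs=tuple(pairs), reference_length=ref)
    raise KeyError(f"member {member_id!r} not in alignment")


# ---------------------------------------------------------------------------
# Hydropathy


@dataclass(frozen=True)
class HydropathyResult:
    mean: float
    n_residues: int
    n_excluded: int


def hydropathy(sequence: str | MHCSequence, scale: HydropathyScale) -> HydropathyResult:
    """Arithmetic mean of per-residue hydropathy values (GRAVY-style);
    gaps and X are excluded from both numerator and denominator."""
    seq = _seq_str(sequence)
    included = [scale[c] for c in seq if c in scale]
    excluded = len(seq) - len(included)
    if not included:
        raise ValueError("no scoreable residues for hydropathy")
    return HydropathyResult(
        mean=sum(included) / len(included),
        n_residues=len(included),
        n_excluded=excluded,
    )


def groove_hydropathy(
    query: MHCSequence | str,
    pmap: PositionMap,
    scale: HydropathyScale,
    span: tuple[int, int] = (1, 182),
) -> HydropathyResult:
    """Hydropathy of the query stretch mapping into the peptide-binding
    domains (reference ``span``, default α1+α2 = 1–182). The window runs
    from the first to the last query residue mapped inside the span, so
    query insertions within it are included — the score describes the
    query protein, not the reference."""
    seq = _seq_str(query)
    qpos = [q for q, r in pmap.pairs if span[0] <= r <= span[1]]
    if not qpos:
        raise ValueError("query has no residues mapped inside the span")
    return hydropathy(seq[min(qpos) - 1 : max(qpos)], scale)


# ---------------------------------------------------------------------------
# Cysteine geometry


@dataclass(frozen=True)
class CysteinePair:
    label: str
    positions: tuple[int, ...]

    @property
    def spacing(self) -> int:
        """Position difference |p2 - p1| (C36/C67 -> 31)."""
        return abs(self.positions[-1] - self.positions[0])

    @property
    def intervening(self) -> int:
        """Residues strictly between the pair (C36/C67 -> 30). Both
        conventions are reported because published spacing ranges do not
        state which was counted."""
        return max(self.spacing - 1, 0)


@dataclass(frozen=True)
class CysteineGeometry:
    mapped_positions: tuple[int, ...]
    flags: tuple[CysteinePair, ...]

    def has_flag(self, label: str) -> bool:
        return any(f.label == label for f in self.flags)


_CANONICAL_PAIRS = {"canonical_a2": (101, 164), "canonical_a3": (203, 259)}


def cysteine_geometry(
    query: MHCSequence | str,
    pmap: PositionMap,
    tolerance: int = 3,
) -> CysteineGeometry:
    """Locate mapped cysteines in reference coordinates and flag the
    lineage-diagnostic patterns:

    * ``UP_alpha1`` — the C36 + C67 pair of U/P lineage α1 domains;
    * ``S_alpha1`` — cysteine(s) at 6–9 and/or 48 (S lineage);
    * ``S_alpha2`` — the extra α2 cysteine at 100 (cavefish S);
    * ``canonical_a2`` / ``canonical_a3`` — the conserved disulfide pairs
      near 101/164 and 203/259 (± ``tolerance``).
    """
    seq = _seq_str(query)
    cys = tuple(
        sorted(r for q, r in pmap.pairs if seq[q - 1] == "C")
    )
    flags: list[CysteinePair] = []
    cys_set = set(cys)
    if 36 in cys_set and 67 in cys_set:
        flags.append(CysteinePair("UP_alpha1", (36, 67)))
    s_alpha1 = tuple(p for p in cys if 6 <= p <= 9 or p == 48)
    if s_alpha1:
        flags.append(CysteinePair("S_alpha1", s_alpha1))
    if 100 in cys_set:
        flags.append(CysteinePair("S_alpha2", (100,)))
    for label, (a, b) in _CANONICAL_PAIRS.items():
        hits_a = [p for p in cys if abs(p - a) <= tolerance]
        hits_b = [p for p in cys if abs(p - b) <= tolerance]
        if hits_a and hits_b:
            flags.append(CysteinePair(label, (hits_a[0], hits_b[0])))
    return CysteineGeometry(mapped_positions=cys, flags=tuple(flags))


# ---------------------------------------------------------------------------
# N86 sequon


@dataclass(frozen=True)
class SequonResult:
    status: bool | None  # None = undetermined (position 86 unmapped)
    residue_at_86: str | None
    motif: str | None


def sequon_at_86(query: MHCSequence | str, pmap: PositionMap) -> SequonResult:
    """N-linked glycosylation sequon check at reference position 86:
    true iff the mapped residue is N and the query continues N-X-[S/T]
    with X != P in query coordinates."""
    seq = _seq_str(query)
    qidx = pmap.ref_to_query.get(86)
    if qidx is None:
        return SequonResult(status=None, residue_at_86=None, motif=None)
    res = seq[qidx - 1]
    motif = seq[qidx - 1 : qidx + 2]
    if res != "N" or len(motif) < 3:
        return SequonResult(status=False, residue_at_86=res, motif=motif or None)
    ok = motif[1] != "P" and motif[2] in "ST"
    return SequonResult(status=ok, residue_at_86=res, motif=motif)
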