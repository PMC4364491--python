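"""Lineage classification: phylogenetic placement plus motif evidence.

A query is placed in a joint Neighbor-Joining tree with all labeled
exemplars of the reference bundle (after projection into HLA-A2
coordinates); its primary call is the lineage of the smallest exemplar
clade containing it, computed on the unrooted tree's bipartitions with
clades read relative to the non-teleost outgroup exemplars. When that
clade mixes lineages the call falls back to the nearest exemplar by
p-distance. Motif evidence (anchors, Y171, cysteine patterns) never
overrides the tree — agreement sets confidence high, conflict sets it low
with both signals reported.

Z sub-lineages: Z1 requires the groove check (>= 7 of 8 anchors with F
accepted at 171); otherwise the nearer of the Z2/Z3 exemplar clusters is
taken, ties broken by lexicographic exemplar id at low confidence.

α1 domain lineages (I–IX) are assigned for U-lineage queries with
sufficient α1 coverage by the same smallest-pure-clade rule on a joint
tree of α1 exemplars, with bootstrap support on the enclosing clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (
    AlignParams,
    PositionMap,
    global_align,
    map_to_reference,
    project_to_reference_frame,
)
from .groove import (
    AnchorReport,
    CysteineGeometry,
    cysteine_geometry,
    groove_hydropathy,
    score_anchors,
    sequon_at_86,
)
from .phylogeny import PhyloTree, bootstrap, neighbor_joining, p_distance
from .reference import ReferenceBundle
from .seqio import AlignedSet, MHCSequence

QUERY_TAG = "__query__"


@dataclass(frozen=True)
class ClassifyParams:
    coverage_threshold: float = 0.2
    boot: int = 100  # bootstrap replicates for placement supports; 0 = off
    seed: int = 0
    alpha1_min_positions: int = 60
    align: AlignParams = field(default_factory=AlignParams)
    motif_agreement_threshold: float = 0.6


@dataclass(frozen=True)
class LineageCall:
    id: str
    lineage: str  # U | Z | L | S | P | unknown
    sub_lineage: str | None  # Z1/Z2/Z3, only when lineage == "Z"
    alpha1_lineage: str | None  # I..IX, "unassigned", or None (not attempted)
    confidence: str  # "high" | "low"
    evidence: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sub_lineage is not None and self.lineage != "Z":
            raise ValueError("sub_lineage only valid for Z lineage calls")


def _joint_tree(
    rows: list[MHCSequence], boot: int, seed: int
) -> tuple[PhyloTree, "object"]:
    aligned = AlignedSet.from_sequences(rows)
    dm = p_distance(aligned)
    if boot > 0:
        tree = bootstrap(aligned, boot, seed)
    else:
        tree = neighbor_joining(dm)
    return tree, dm


def _smallest_enclosing(
    tree: PhyloTree,
    query_id: str,
    labels: dict[str, str],
    outgroup_ids: set[str],
) -> tuple[frozenset[str] | None, set[str]]:
    """Smallest outgroup-free clade containing the query and >= 1 exemplar.

    Returns (clade, lineages of its exemplars); (None, {}) when the query
    only attaches basal to every labeled clade.
    """
    for clade in tree.clades_excluding(outgroup_ids):
        if query_id not in clade:
            continue
        members = clade - {query_id}
        found = {labels[m] for m in members if m in labels}
        if found:
            return clade, found
    return None, set()


def _nearest(dm, query_id: str, candidate_ids: list[str]) -> tuple[str, float]:
    best = min(candidate_ids, key=lambda c: (dm.get(query_id, c), c))
    return best, dm.get(query_id, best)


def _motif_score(query, pmap: PositionMap, rules) -> float | None:
    if not rules:
        return None
    seq = query.sequence if isinstance(query, MHCSequence) else str(query)
    total = satisfied = 0.0
    for rule in rules:
        total += rule.weight
        for pos in rule.positions:
            res = pmap.residue_at(seq, pos)
            if res is not None and res in rule.residues:
                satisfied += rule.weight
                break
    return satisfied / total if total else None


def call_z_sublineage(
    query: MHCSequence,
    pmap: PositionMap,
    bundle: ReferenceBundle,
    dm,
    query_id: str,
) -> tuple[str, str]:
    """Z sub-lineage: Z1 on the groove check (>= 7/8 anchors, F accepted at
    171), else nearest of the Z2/Z3 exemplars; returns (sub_lineage,
    confidence)."""
    z_anchors = bundle.anchors.with_residue(171, "F")
    report = score_anchors(query, pmap, z_anchors)
    if report.n_matched >= 7:
        return "Z1", "high"
    z2 = [e.id for e in bundle.profiles["Z2"].exemplars]
    z3 = [e.id for e in bundle.profiles["Z3"].exemplars]
    n2, d2 = _nearest(dm, query_id, z2)
    n3, d3 = _nearest(dm, query_id, z3)
    if d2 == d3:
        # deterministic tie-break: lexicographically smallest exemplar id
        sub = "Z2" if min(n2, n3) == n2 else "Z3"
        return sub, "low"
    return ("Z2", "high") if d2 < d3 else ("Z3", "high")


def assign_alpha1_lineage(
    alpha1_row: str,
    bundle: ReferenceBundle,
    params: ClassifyParams,
) -> tuple[str, float | None]:
    """Place an α1-domain query (reference-frame row, width = α1 span)
    among the labeled α1 exemplars; returns (label or "unassigned",
    bootstrap support of the enclosing clade or None)."""
    width = bundle.boundaries.alpha1[1] - bundle.boundaries.alpha1[0] + 1
    mapped = sum(1 for c in alpha1_row if c not in "-X")
    if mapped < params.alpha1_min_positions:
        return "unassigned", None
    rows = [MHCSequence(id=QUERY_TAG, sequence=alpha1_row)]
    labels: dict[str, str] = {}
    out_ids: set[str] = set()
    for ex in bundle.alpha1_exemplars:
        seq = ex.sequence[:width]
        rows.append(MHCSequence(id=ex.id, sequence=seq))
        if ex.lineage == "OUT":
            out_ids.add(ex.id)
        else:
            labels[ex.id] = ex.lineage
    tree, _dm = _joint_tree(rows, params.boot, params.seed)
    clade, found = _smallest_enclosing(tree, QUERY_TAG, labels, out_ids)
    if clade is None or len(found) != 1:
        return "unassigned", None
    node = None
    all_leaves = frozenset(tree.leaf_names())
    side = clade if min(all_leaves) not in clade else all_leaves - clade
    node = tree.bipartitions().get(side)
    support = node.support if node is not None else None
    return next(iter(found)), support


def classify(
    query: MHCSequence,
    bundle: ReferenceBundle,
    params: ClassifyParams | None = None,
) -> LineageCall:
    """Classify one query sequence against the reference bundle.

    Deterministic given (query, bundle, params): the only randomness is
    the bootstrap, which is seeded from ``params.seed``.
    """
    params = params or ClassifyParams()
    aln = global_align(query, bundle.hla_a2, params.align)
    pmap = map_to_reference(aln)
    span = bundle.boundaries.span
    coverage = pmap.span_coverage(*span)
    evidence: dict = {"span_coverage": round(coverage, 4)}
    warnings: list[str] = []

    if coverage < params.coverage_threshold:
        return LineageCall(
            id=query.id,
            lineage="unknown",
            sub_lineage=None,
            alpha1_lineage=None,
            confidence="low",
            evidence=evidence,
            warnings=("fragment: coverage below threshold",),
        )

    anchor_report: AnchorReport = score_anchors(query, pmap, bundle.anchors)
    cys: CysteineGeometry = cysteine_geometry(query, pmap)
    sequon = sequon_at_86(query, pmap)
    evidence["n_anchors"] = anchor_report.n_matched
    evidence["y171"] = anchor_report.observed_at(171)
    evidence["cysteine_flags"] = tuple(f.label for f in cys.flags)
    evidence["n86_sequon"] = sequon.status
    try:
        evidence["hydropathy_a1a2"] = round(
            groove_hydropathy(query, pmap, bundle.hydropathy).mean, 4
        )
    except ValueError:
        evidence["hydropathy_a1a2"] = None

    # joint placement tree: query + all lineage exemplars + outgroup
    width = span[1]
    query_row = project_to_reference_frame(query, pmap, width)
    rows = [MHCSequence(id=QUERY_TAG, sequence=query_row)]
    labels: dict[str, str] = {}
    for ex in bundle.exemplars:
        rows.append(MHCSequence(id=ex.id, sequence=ex.sequence[:width]))
        labels[ex.id] = ex.lineage
    out_ids = set()
    for ex in bundle.outgroup:
        rows.append(MHCSequence(id=ex.id, sequence=ex.sequence[:width]))
        out_ids.add(ex.id)
    tree, dm = _joint_tree(rows, params.boot, params.seed)

    clade, found = _smallest_enclosing(tree, QUERY_TAG, labels, out_ids)
    nearest_id, nearest_d = _nearest(dm, QUERY_TAG, list(labels))
    evidence["nearest_exemplar"] = nearest_id
    evidence["nearest_distance"] = round(nearest_d, 4)
    confidence = "high"

    if clade is None:
        # basal to every labeled clade: not forced into a lineage
        return LineageCall(
            id=query.id,
            lineage="unknown",
            sub_lineage=None,
            alpha1_lineage=None,
            confidence="low",
            evidence=evidence,
            warnings=("basal placement: no enclosing exemplar clade",),
        )
    if len(found) == 1:
        sub = next(iter(found))
    else:
        sub = labels[nearest_id]
        confidence = "low"
        warnings.append(
            f"mixed enclosing clade {sorted(found)}; fell back to nearest exemplar"
        )
    if params.boot > 0:
        all_leaves = frozenset(tree.leaf_names())
        side = clade if min(all_leaves) not in clade else all_leaves - clade
        node = tree.bipartitions().get(side)
        evidence["clade_support"] = node.support if node is not None else None
    lineage = "Z" if sub.startswith("Z") else sub

    # motif evidence for the called (sub-)lineage
    motif = _motif_score(query, pmap, bundle.profiles[sub].motif_rules)
    evidence["motif_score"] = None if motif is None else round(motif, 3)
    if motif is not None and motif < params.motif_agreement_threshold:
        confidence = "low"
        warnings.append(
            f"motif evidence conflicts with tree placement ({sub}: {motif:.2f})"
        )

    sub_lineage = None
    if lineage == "Z":
        sub_lineage, z_conf = call_z_sublineage(query, pmap, bundle, dm, QUERY_TAG)
        if z_conf == "low":
            confidence = "low"
        if sub in ("Z2", "Z3") and sub_lineage != sub:
            warnings.append(
                f"tree placement ({sub}) and groove check ({sub_lineage}) disagree"
            )

    alpha1_lineage = None
    if lineage == "U":
        a1_lo, a1_hi = bundle.boundaries.alpha1
        alpha1_row = query_row[a1_lo - 1 : a1_hi]
        alpha1_lineage, a1_support = assign_alpha1_lineage(alpha1_row, bundle, params)
        evidence["alpha1_support"] = a1_support

    return LineageCall(
        id=query.id,
        lineage=lineage,
        sub_lineage=sub_lineage,
        alpha1_lineage=alpha1_lineage,
        confidence=confidence,
        evidence=evidence,
        warnings=tuple(warnings),
    )
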