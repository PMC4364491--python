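"""Fixed reference tables the analysis is expressed against.

Everything is stored as editable text files in a *bundle* directory (the
builtin bundle ships with the package): the HLA-A2 mature-chain reference
sequence, the eight peptide-terminus anchor positions, the 37 pocket
positions of the A–F binding-groove pockets, the Kyte–Doolittle hydropathy
scale, the α1/α2/α3 domain boundaries, per-lineage motif rules, and
labeled exemplar sequences used as phylogenetic references. A bundle is
versioned and checksummed so every report is attributable to one bundle.

The builtin exemplars are synthetic (generated from the HLA-A2 backbone
with lineage motif constraints enforced; see :mod:`mhclin.simulate`); real
curated alignments can be swapped in by pointing at another bundle
directory with the same file layout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seqio import MHCSequence, read_fasta

#: The eight classical peptide-terminus anchor positions (HLA-A2 mature
#: numbering) and their accepted residues; position 84 accepts Y or R
#: (mammalian vs bird/amphibian/fish usage).
CANONICAL_ANCHORS: dict[int, frozenset[str]] = {
    7: frozenset("Y"),
    59: frozenset("Y"),
    84: frozenset("YR"),
    143: frozenset("T"),
    146: frozenset("K"),
    147: frozenset("W"),
    159: frozenset("Y"),
    171: frozenset("Y"),
}

LINEAGES = ("U", "Z1", "Z2", "Z3", "L", "S", "P")
ALPHA1_LINEAGES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")
OUTGROUP_LABEL = "OUT"


class BundleValidationError(ValueError):
    """A reference bundle failed an invariant check at load time."""


@dataclass(frozen=True)
class AnchorTable:
    entries: dict[int, frozenset[str]]

    def __post_init__(self) -> None:
        if dict(self.entries) != CANONICAL_ANCHORS:
            raise BundleValidationError(
                "anchor table must contain exactly the eight classical "
                "anchor positions with their accepted residues"
            )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))

    def with_residue(self, position: int, extra: str) -> "AnchorTable":
        """A copy accepting one extra residue at ``position`` (used for the
        Z-lineage Y171F groove check). Bypasses the canonical-set check."""
        entries = dict(self.entries)
        entries[position] = entries[position] | frozenset(extra)
        obj = object.__new__(AnchorTable)
        object.__setattr__(obj, "entries", entries)
        return obj


@dataclass(frozen=True)
class PocketTable:
    """The 37 HLA-A2 positions contributing to the six A–F pockets."""

    positions: tuple[int, ...]
    pocket_label: dict[int, str]

    def __post_init__(self) -> None:
        if len(self.positions) != 37:
            raise BundleValidationError(
                f"pocket table must have 37 positions, got {len(self.positions)}"
            )
        if list(self.positions) != sorted(set(self.positions)):
            raise BundleValidationError("pocket positions must be strictly increasing")
        if not all(1 <= p <= 182 for p in self.positions):
            raise BundleValidationError("pocket positions must lie in 1..182")
        missing = [p for p in CANONICAL_ANCHORS if p not in set(self.positions)]
        if missing:
            raise BundleValidationError(
                f"anchor positions missing from pocket table: {missing}"
            )


@dataclass(frozen=True)
class HydropathyScale:
    values: dict[str, float]

    def __post_init__(self) -> None:
        from .seqio import STANDARD_AA

        missing = sorted(set(STANDARD_AA) - set(self.values))
        if missing:
            raise BundleValidationError(f"hydropathy scale missing residues: {missing}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.values


@dataclass(frozen=True)
class DomainBoundaries:
    """α domain intervals, 1-based closed, mature-chain numbering."""

    alpha1: tuple[int, int] = (1, 90)
    alpha2: tuple[int, int] = (91, 182)
    alpha3: tuple[int, int] = (183, 274)

    def __post_init__(self) -> None:
        a1, a2, a3 = self.alpha1, self.alpha2, self.alpha3
        ok = a1[0] <= a1[1] and a2[0] <= a2[1] and a3[0] <= a3[1]
        contiguous = a2[0] == a1[1] + 1 and a3[0] == a2[1] + 1
        if not (ok and contiguous):
            raise BundleValidationError(
                "domain boundaries must be ordered, disjoint and contiguous"
            )

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"alpha1": self.alpha1, "alpha2": self.alpha2, "alpha3": self.alpha3}

    def domain_of(self, position: int) -> str | None:
        for name, (lo, hi) in self.as_dict().items():
            if lo <= position <= hi:
                return name
        return None

    @property
    def span(self) -> tuple[int, int]:
        return (self.alpha1[0], self.alpha3[1])


@dataclass(frozen=True)
class MotifRule:
    """Accept if any of ``positions`` carries a residue from ``residues``."""

    positions: tuple[int, ...]
    residues: frozenset[str]
    weight: float = 1.0


@dataclass(frozen=True)
class LineageProfile:
    lineage: str
    motif_rules: tuple[MotifRule, ...]
    exemplars: tuple[MHCSequence, ...]

    def __post_init__(self) -> None:
        if not self.exemplars:
            raise BundleValidationError(f"lineage {self.lineage}: no exemplars")


def _rule_covers(rules, positions: set[int], residue: str) -> bool:
    return any(
        set(r.positions) & positions and residue in r.residues for r in rules
    )


@dataclass(frozen=True)
class ReferenceBundle:
    version: str
    checksum: str
    anchors: AnchorTable
    pockets: PocketTable
    hydropathy: HydropathyScale
    boundaries: DomainBoundaries
    profiles: dict[str, LineageProfile]
    alpha1_exemplars: tuple[MHCSequence, ...]
    hla_a2: MHCSequence
    outgroup: tuple[MHCSequence, ...]

    def __post_init__(self) -> None:
        missing = [lin for lin in LINEAGES if lin not in self.profiles]
        if missing:
            raise BundleValidationError(f"missing lineage profiles: {missing}")
        z1 = self.profiles["Z1"].motif_rules
        if not _rule_covers(z1, {171}, "F"):
            raise BundleValidationError("Z1 motif rules must accept F at 171")
        p = self.profiles["P"].motif_rules
        if not (_rule_covers(p, {36}, "C") and _rule_covers(p, {67}, "C")):
            raise BundleValidationError("P motif rules must require C36 and C67")
        s = self.profiles["S"].motif_rules
        if not (
            _rule_covers(s, set(range(6, 10)), "C") and _rule_covers(s, {48}, "C")
        ):
            raise BundleValidationError("S motif rules must require C6-9 and C48")
        a1_lineages = {e.lineage for e in self.alpha1_exemplars}
        if not set(ALPHA1_LINEAGES) <= a1_lineages:
            raise BundleValidationError(
                f"alpha1 exemplars missing lineages: "
                f"{sorted(set(ALPHA1_LINEAGES) - a1_lineages)}"
            )
        if not self.outgroup:
            raise BundleValidationError("bundle must include outgroup exemplars")

    @property
    def exemplars(self) -> tuple[MHCSequence, ...]:
        out: list[MHCSequence] = []
        for lin in LINEAGES:
            out.extend(self.profiles[lin].exemplars)
        return tuple(out)

    def exemplar_lineage(self, seq_id: str) -> str | None:
        for lin, prof in self.profiles.items():
            if any(e.id == seq_id for e in prof.exemplars):
                return lin
        return None


def _bundle_dir(path: str | Path | None) -> Path:
    if path is not None:
        return Path(path)
    return Path(resources.files("mhclin") / "data" / "bundle")


def _read_table(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _parse_positions(text: str) -> tuple[int, ...]:
    if "-" in text and not text.lstrip("-").isdigit():
        lo, hi = text.split("-")
        return tuple(range(int(lo), int(hi) + 1))
    return (int(text),)


def bundle_checksum(directory: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(directory.iterdir()):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


def load_reference_bundle(path: str | Path | None = None) -> ReferenceBundle:
    """Load and validate a reference bundle (builtin when ``path`` is None).

    All structural invariants (8 anchors, 37 pockets, motif requirements,
    exemplar coverage) are verified here; a violated invariant raises
    :class:`BundleValidationError`.
    """
    d = _bundle_dir(path)
    if not d.is_dir():
        raise FileNotFoundError(f"bundle directory not found: {d}")
    manifest = json.loads((d / "manifest.json").read_text())

    anchors = AnchorTable(
        entries={
            int(pos): frozenset(res.replace(",", ""))
            for pos, res in _read_table(d / "anchors.tsv")
        }
    )
    pocket_rows = _read_table(d / "pockets.tsv")
    pockets = PocketTable(
        positions=tuple(int(p) for p, _ in pocket_rows),
        pocket_label={int(p): lab for p, lab in pocket_rows},
    )
    hydropathy = HydropathyScale(
        values={res: float(v) for res, v in _read_table(d / "hydropathy_kd.tsv")}
    )
    dom = {name: (int(lo), int(hi)) for name, lo, hi in _read_table(d / "domains.tsv")}
    boundaries = DomainBoundaries(
        alpha1=dom["alpha1"], alpha2=dom["alpha2"], alpha3=dom["alpha3"]
    )

    (hla_a2,) = read_fasta(d / "hla_a2_mature.fasta")

    motif_rules: dict[str, list[MotifRule]] = {lin: [] for lin in LINEAGES}
    for lineage, positions, residues, weight in _read_table(d / "lineage_motifs.tsv"):
        motif_rules.setdefault(lineage, []).append(
            MotifRule(
                positions=_parse_positions(positions),
                residues=frozenset(residues.replace(",", "")),
                weight=float(weight),
            )
        )

    def tagged(seqs):
        out = []
        for s in seqs:
            desc = s.annotations.get("description", "")
            tags = dict(
                kv.split("=", 1) for kv in desc.split() if "=" in kv
            )
            out.append(
                MHCSequence(
                    id=s.id,
                    sequence=s.sequence,
                    species=tags.get("species"),
                    annotations={**s.annotations, **tags},
                )
            )
        return out

    lineage_seqs = tagged(read_fasta(d / "exemplars_lineage.synthetic.fasta", aligned=True))
    alpha1_seqs = tagged(read_fasta(d / "exemplars_alpha1.synthetic.fasta", aligned=True))

    profiles: dict[str, LineageProfile] = {}
    for lin in LINEAGES:
        exemplars = tuple(s for s in lineage_seqs if s.lineage == lin)
        profiles[lin] = LineageProfile(
            lineage=lin,
            motif_rules=tuple(motif_rules.get(lin, ())),
            exemplars=exemplars,
        )
    outgroup = tuple(s for s in lineage_seqs if s.lineage == OUTGROUP_LABEL)

    return ReferenceBundle(
        version=str(manifest["version"]),
        checksum=bundle_checksum(d),
        anchors=anchors,
        pockets=pockets,
        hydropathy=hydropathy,
        boundaries=boundaries,
        profiles=profiles,
        alpha1_exemplars=tuple(alpha1_seqs),
        hla_a2=hla_a2,
        outgroup=outgroup,
    )
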