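"""Regenerate the builtin reference bundle.

Writes the static reference tables (anchors, pockets, Kyte–Doolittle
scale, domain boundaries, lineage motif rules, the HLA-A2 mature-chain
sequence) and deterministically generates the synthetic lineage and α1
exemplar sets from the HLA-A2 backbone with each lineage's motif
constraints enforced. Running it twice produces byte-identical output.

Usage: python scripts/build_bundle.py [--out src/mhclin/data/bundle]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
import sys

sys.path.insert(0, str(ROOT / "src"))

from mhclin.seqio import MHCSequence, write_fasta  # noqa: E402
from mhclin.simulate import hydrophobic_pool, mutate_sequence  # noqa: E402

SEED = 20140801 % (2**31)

# Mature-chain HLA-A*02:01 (AAA76608.2), positions 1-274 (alpha1-alpha3).
HLA_A2_MATURE = (
    "GSHSMRYFFTSVSRPGRGEPRFIAVGYVDDTQFVRFDSDAASQRMEPRAPWIEQEGPEYW"
    "DGETRKVKAHSQTHRVDLGTLRGYYNQSEAGSHTVQRMYGCDVGSDWRFLRGYHQYAYDG"
    "KDYIALKEDLRSWTAADMAAQTTKHKWEAAHVAEQLRAYLEGTCVEWLRRYLENGKETLQ"
    "RTDAPKTHMTHHAVSDHEATLRCWALSFYPAEITLTWQRDGEDQTQDTELVETRPAGDGT"
    "FQKWAAVVVPSGQEQRYTCHVQHEGLPKPLTLRW"
)
assert len(HLA_A2_MATURE) == 274

ANCHORS = {7: "Y", 59: "Y", 84: "Y,R", 143: "T", 146: "K", 147: "W", 159: "Y", 171: "Y"}

# 37 pocket positions with primary pocket labels (A-F), compiled from the
# classical HLA-A2 pocket definitions.
POCKETS = {
    "A": [7, 59, 63, 66, 99, 159, 163, 171],
    "B": [9, 24, 25, 33, 34, 45, 60, 67, 70],
    "C": [73, 74, 97],
    "D": [114, 155, 156, 160],
    "E": [147, 152],
    "F": [77, 80, 81, 84, 95, 116, 123, 124, 133, 143, 146],
}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DOMAINS = {"alpha1": (1, 90), "alpha2": (91, 182), "alpha3": (183, 274)}

MOTIF_RULES = [
    # lineage, positions, residues, weight
    *(("U", str(p), ANCHORS[p], "1") for p in sorted(ANCHORS)),
    *(
        ("Z1", str(p), "F" if p == 171 else ANCHORS[p], "2" if p == 171 else "1")
        for p in sorted(ANCHORS)
    ),
    ("P", "36", "C", "1"),
    ("P", "67", "C", "1"),
    ("S", "6-9", "C", "1"),
    ("S", "48", "C", "1"),
]

ANCHOR_POS = set(ANCHORS)
CANONICAL_CYS = {101, 164, 203, 259}
SEQUON = {86, 87, 88}
POCKET_POS = {p for plist in POCKETS.values() for p in plist}

# Per-lineage founder recipe: backbone substitution rate, positions held
# fixed during divergence, residues forced afterwards, replacement pool.
RECIPES = {
    "U": dict(
        rate=0.30,
        fixed=ANCHOR_POS | CANONICAL_CYS | SEQUON | {36, 67},
        force={36: "C", 67: "C"},
    ),
    "Z1": dict(
        rate=0.30,
        fixed=ANCHOR_POS | CANONICAL_CYS | SEQUON | POCKET_POS,
        force={171: "F"},
    ),
    "Z2": dict(
        rate=0.45,
        fixed={7, 59, 84} | CANONICAL_CYS,
        force={143: "G", 146: "S", 147: "L", 159: "N", 171: "A"},
    ),
    "Z3": dict(
        rate=0.45,
        fixed={7, 59} | CANONICAL_CYS,
        force={84: "G", 143: "N", 146: "T", 147: "V", 159: "D", 171: "S"},
    ),
    "L": dict(
        rate=0.35,
        fixed=CANONICAL_CYS,
        force={7: "L", 59: "V", 84: "L", 143: "A", 146: "I", 147: "F", 159: "L", 171: "V"},
        pool=hydrophobic_pool(0.32),
    ),
    "S": dict(
        rate=0.40,
        fixed=CANONICAL_CYS,
        force={9: "C", 48: "C", 100: "C",
               7: "S", 59: "G", 84: "N", 143: "S", 146: "D", 147: "R", 159: "T", 171: "E"},
    ),
    "P": dict(
        rate=0.40,
        fixed=CANONICAL_CYS,
        force={36: "C", 67: "C",
               7: "G", 59: "D", 84: "Q", 143: "E", 146: "N", 147: "S", 159: "H", 171: "T"},
    ),
    "OUT": dict(
        rate=0.15,
        fixed=ANCHOR_POS | CANONICAL_CYS | SEQUON,
        force={},
    ),
}

N_EXEMPLARS = 3
EXEMPLAR_RATE = 0.08
ALPHA1_LINEAGES = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX"]
ALPHA1_FOUNDER_RATE = 0.35
ALPHA1_EXEMPLAR_RATE = 0.05


def force(seq: str, assignments: dict[int, str]) -> str:
    chars = list(seq)
    for pos, res in assignments.items():
        chars[pos - 1] = res
    return "".join(chars)


def build_lineage_exemplars() -> list[MHCSequence]:
    out = []
    for li, (lineage, recipe) in enumerate(RECIPES.items()):
        rng = np.random.default_rng(np.random.SeedSequence([SEED, 1, li]))
        founder, _ = mutate_sequence(
            HLA_A2_MATURE,
            recipe["rate"],
            rng,
            frozenset(recipe["fixed"]),
            recipe.get("pool"),
        )
        founder = force(founder, recipe["force"])
        fixed = frozenset(recipe["fixed"] | set(recipe["force"]))
        for k in range(N_EXEMPLARS):
            seq, _ = mutate_sequence(founder, EXEMPLAR_RATE, rng, fixed)
            out.append(
                MHCSequence(
                    id=f"{lineage}_ex{k + 1}",
                    sequence=seq,
                    annotations={"description": f"lineage={lineage} synthetic=true"},
                )
            )
    return out


def build_alpha1_exemplars() -> list[MHCSequence]:
    backbone = HLA_A2_MATURE[:90]
    fixed = frozenset({7, 59, 84, 86, 87, 88, 36, 67})
    out = []
    for li, lineage in enumerate(ALPHA1_LINEAGES):
        rng = np.random.default_rng(np.random.SeedSequence([SEED, 2, li]))
        founder, _ = mutate_sequence(backbone, ALPHA1_FOUNDER_RATE, rng, fixed)
        for k in range(N_EXEMPLARS):
            seq, _ = mutate_sequence(founder, ALPHA1_EXEMPLAR_RATE, rng, fixed)
            out.append(
                MHCSequence(
                    id=f"A1_{lineage}_ex{k + 1}",
                    sequence=seq,
                    annotations={"description": f"lineage={lineage} synthetic=true"},
                )
            )
    # alpha1 outgroup: the OUT founder's alpha1 domain
    rng = np.random.default_rng(np.random.SeedSequence([SEED, 2, 99]))
    for k in range(2):
        seq, _ = mutate_sequence(backbone, 0.15, rng, fixed)
        out.append(
            MHCSequence(
                id=f"A1_OUT_ex{k + 1}",
                sequence=seq,
                annotations={"description": "lineage=OUT synthetic=true"},
            )
        )
    return out


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default=str(ROOT / "src" / "mhclin" / "data" / "bundle"))
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    (out / "manifest.json").write_text(
        json.dumps(
            {
                "name": "mhclin-builtin",
                "version": "1.0.0",
                "synthetic_exemplars": True,
                "generator_seed": SEED,
            },
            indent=2,
        )
        + "\n"
    )
    (out / "anchors.tsv").write_text(
        "# HLA-A2 mature position\taccepted residues\n"
        + "".join(f"{p}\t{r}\n" for p, r in sorted(ANCHORS.items()))
    )
    pocket_rows = sorted(
        (p, label) for label, plist in POCKETS.items() for p in plist
    )
    (out / "pockets.tsv").write_text(
        "# HLA-A2 mature position\tprimary pocket\n"
        + "".join(f"{p}\t{label}\n" for p, label in pocket_rows)
    )
    (out / "hydropathy_kd.tsv").write_text(
        "# residue\tKyte-Doolittle hydropathy\n"
        + "".join(f"{aa}\t{v}\n" for aa, v in sorted(KYTE_DOOLITTLE.items()))
    )
    (out / "domains.tsv").write_text(
        "# domain\tstart\tend (mature numbering, 1-based closed)\n"
        + "".join(f"{d}\t{lo}\t{hi}\n" for d, (lo, hi) in DOMAINS.items())
    )
    (out / "lineage_motifs.tsv").write_text(
        "# lineage\tpositions\tresidues\tweight\n"
        + "".join("\t".join(row) + "\n" for row in MOTIF_RULES)
    )
    write_fasta(
        [
            MHCSequence(
                id="HLA-A2",
                sequence=HLA_A2_MATURE,
                annotations={
                    "description": "species=human accession=AAA76608.2 mature=1-274"
                },
            )
        ],
        out / "hla_a2_mature.fasta",
    )
    write_fasta(build_lineage_exemplars(), out / "exemplars_lineage.synthetic.fasta")
    write_fasta(build_alpha1_exemplars(), out / "exemplars_alpha1.synthetic.fasta")
    print(f"bundle written to {out}")


if __name__ == "__main__":
    main()
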