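"""Lineage-structured synthetic protein families with known ground truth.

The generator emulates the structure the real teleost MHC class I data
shows: a handful of deeply divergent founder sequences (one per lineage),
hard-conserved motif positions (peptide anchors, lineage cysteines, the
N86 sequon) on otherwise free backbones, and within-family variation from
independent Bernoulli point substitutions at a configurable per-site rate.
Replacement residues are drawn uniformly from the 19 alternatives unless a
weighted pool is supplied (e.g. a hydrophobic-biased pool for L-lineage
founders). Indels are off by default; when enabled they avoid fixed and
pocket positions so conservation statistics stay interpretable.

All randomness flows from a single integer seed; identical configs give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import STANDARD_AA, AlignedSet, MHCSequence


@dataclass(frozen=True)
class SimulationConfig:
    founders: Mapping[str, MHCSequence]
    fixed_positions: Mapping[str, frozenset[int]]  # per founder label, 1-based
    per_site_rate: float
    n_per_family: int
    seed: int
    indel_rate: float = 0.0
    indel_excluded: frozenset[int] = frozenset()
    replacement_pool: Mapping[str, float] | None = None  # residue -> weight

    def __post_init__(self) -> None:
        if not 0 <= self.per_site_rate <= 1:
            raise ValueError("per_site_rate must lie in [0, 1]")
        if not 0 <= self.indel_rate <= 1:
            raise ValueError("indel_rate must lie in [0, 1]")
        if self.n_per_family < 1:
            raise ValueError("n_per_family must be >= 1")
        for label, fixed in self.fixed_positions.items():
            founder = self.founders[label]
            bad = [p for p in fixed if not 1 <= p <= len(founder)]
            if bad:
                raise ValueError(f"fixed positions outside founder {label}: {bad}")


def _pool_arrays(pool: Mapping[str, float] | None):
    if pool is None:
        residues = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)
        weights = np.ones(len(residues))
    else:
        residues = np.frombuffer("".join(pool).encode(), dtype=np.uint8)
        weights = np.array(list(pool.values()), dtype=float)
    return residues, weights / weights.sum()


def mutate_sequence(
    sequence: str,
    rate: float,
    rng: np.random.Generator,
    fixed_positions: frozenset[int] = frozenset(),
    replacement_pool: Mapping[str, float] | None = None,
) -> tuple[str, list[int]]:
    """Bernoulli point substitutions at free sites; returns the mutated
    sequence and the 1-based positions changed. The replacement residue is
    drawn from the pool excluding the current residue (so every recorded
    substitution is a real change)."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    free = np.array(
        [i for i in range(len(arr)) if (i + 1) not in fixed_positions], dtype=int
    )
    if free.size == 0:
        if rate >= 1:
            raise ValueError("per-site rate 1 with zero free sites")
        return sequence, []
    hits = free[rng.random(free.size) < rate]
    residues, probs = _pool_arrays(replacement_pool)
    changed = []
    for i in hits:
        current = arr[i]
        mask = residues != current
        sub_res, sub_p = residues[mask], probs[mask]
        if sub_res.size == 0:
            continue
        arr[i] = rng.choice(sub_res, p=sub_p / sub_p.sum())
        changed.append(i + 1)
    return arr.tobytes().decode(), changed


def simulate_family(
    config: SimulationConfig,
) -> tuple[list[MHCSequence], pd.DataFrame]:
    """Simulate ``n_per_family`` members per founder.

    Returns the labeled sequences plus a truth table with one row per
    simulated sequence: id, founder label, substitution count and the
    mutated positions (semicolon-joined, 1-based founder coordinates).
    """
    rng = np.random.default_rng(config.seed)
    out: list[MHCSequence] = []
    rows = []
    for label in config.founders:  # insertion order: deterministic
        founder = config.founders[label]
        fixed = frozenset(config.fixed_positions.get(label, frozenset()))
        for k in range(config.n_per_family):
            seq, changed = mutate_sequence(
                founder.sequence,
                config.per_site_rate,
                rng,
                fixed,
                config.replacement_pool,
            )
            if config.indel_rate > 0:
                seq = _apply_indels(seq, config, fixed, rng)
            sid = f"{label}_sim{k:03d}"
            out.append(
                MHCSequence(id=sid, sequence=seq, annotations={"lineage": label})
            )
            rows.append(
                {
                    "id": sid,
                    "founder": label,
                    "n_substitutions": len(changed),
                    "positions": ";".join(map(str, changed)),
                }
            )
    return out, pd.DataFrame(rows)


def _apply_indels(
    seq: str,
    config: SimulationConfig,
    fixed: frozenset[int],
    rng: np.random.Generator,
) -> str:
    protected = fixed | config.indel_excluded
    chars = list(seq)
    # iterate from the end so earlier coordinates stay valid
    for i in range(len(chars), 0, -1):
        if i in protected:
            continue
        u = rng.random()
        if u < config.indel_rate / 2:
            del chars[i - 1]
        elif u < config.indel_rate:
            extra = STANDARD_AA[int(rng.integers(len(STANDARD_AA)))]
            chars.insert(i - 1, extra)
    return "".join(chars)


def hydrophobic_pool(bias: float = 0.32) -> dict[str, float]:
    """Replacement pool mixing a uniform draw over all 20 residues with a
    draw over strongly hydrophobic residues (A, V, I, L, M, F) with
    probability ``bias`` — used to simulate families whose binding domains
    are unusually hydrophobic (the L-lineage pattern)."""
    pool = {aa: (1 - bias) / 20 for aa in STANDARD_AA}
    hydro = "AVILMF"
    for aa in hydro:
        pool[aa] += bias / len(hydro)
    return pool


def lineage_fixed_positions(bundle, lineage: str) -> frozenset[int]:
    """Positions held invariant when simulating members of ``lineage``:
    the canonical α2/α3 cysteines, the lineage's motif-rule positions,
    anchors + N86 sequon for the groove-bearing lineages (U, Z1), and the
    full 37-pocket set for Z1 (whose hallmark is pocket conservation)."""
    fixed = {101, 164, 203, 259}
    for rule in bundle.profiles[lineage].motif_rules:
        fixed |= set(rule.positions)
    if lineage in ("U", "Z1"):
        fixed |= set(bundle.anchors.positions) | {86, 87, 88}
    if lineage == "Z1":
        fixed |= set(bundle.pockets.positions)
    return frozenset(fixed)


def simulate_star_alignment(
    n_seqs: int,
    n_cols: int,
    splits: Sequence[tuple[Sequence[str], float]] | None = None,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> AlignedSet:
    """Alignment whose columns support declared bipartitions in declared
    proportions; remaining columns are constant.

    ``splits`` is a list of ``(group_ids, fraction)`` pairs: for a
    diagnostic column of a split, members of the group carry K and all
    others E. Column blocks are laid out deterministically (no sampling);
    ``seed`` only shuffles column order so resampling tests are not
    block-structured.
    """
    if n_seqs < 4:
        raise ValueError("need at least 4 sequences")
    if ids is None:
        ids = [f"s{i + 1}" for i in range(n_seqs)]
    if len(ids) != n_seqs:
        raise ValueError("ids length must equal n_seqs")
    splits = splits or []
    counts = [int(round(frac * n_cols)) for _, frac in splits]
    if sum(counts) > n_cols:
        raise ValueError("split fractions exceed 1")
    columns: list[str] = []
    for (group, _), count in zip(splits, counts):
        group_set = set(group)
        unknown = group_set - set(ids)
        if unknown:
            raise ValueError(f"unknown split members: {sorted(unknown)}")
        col = "".join("K" if i in group_set else "E" for i in ids)
        columns.extend([col] * count)
    columns.extend(["G" * n_seqs] * (n_cols - sum(counts)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(columns))
    columns = [columns[i] for i in order]
    members = [
        MHCSequence(id=ids[i], sequence="".join(col[i] for col in columns))
        for i in range(n_seqs)
    ]
    return AlignedSet.from_sequences(members)
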