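"""Binding-groove feature statistics: anchors, pockets, cysteines, sequon,
hydropathy."""

import numpy as np
import pytest

from conftest import make_aligned
from mhclin.align import PositionMap, global_align, map_to_reference
from mhclin.groove import (
    column_map_from_member,
    cysteine_geometry,
    groove_hydropathy,
    hydropathy,
    pocket_conservation,
    score_anchors,
    sequon_at_86,
)
from mhclin.seqio import AlignedSet, MHCSequence


def _self_map(seq: str) -> PositionMap:
    return PositionMap(
        pairs=tuple((i, i) for i in range(1, len(seq) + 1)),
        reference_length=len(seq),
    )


class TestAnchors:
    def test_hla_matches_all_eight(self, bundle, hla):
        pmap = map_to_reference(global_align(hla, hla))
        report = score_anchors(hla, pmap, bundle.anchors)
        assert report.n_matched == 8

    def test_y171f_variant_scores_seven(self, bundle, hla):
        seq = hla.sequence[:170] + "F" + hla.sequence[171:]
        report = score_anchors(seq, _self_map(seq), bundle.anchors)
        assert report.n_matched == 7
        assert report.mismatches == {171: "F"}

    def test_z_acceptance_admits_f171(self, bundle, hla):
        seq = hla.sequence[:170] + "F" + hla.sequence[171:]
        z_anchors = bundle.anchors.with_residue(171, "F")
        assert score_anchors(seq, _self_map(seq), z_anchors).n_matched == 8

    def test_empty_map_all_unmapped(self, bundle, hla):
        empty = PositionMap(pairs=(), reference_length=274)
        report = score_anchors(hla, empty, bundle.anchors)
        assert report.n_matched == 0
        assert all(o.outcome == "unmapped" for o in report.outcomes)

    def test_invariant_under_sequence_renaming(self, bundle, hla):
        pmap = map_to_reference(global_align(hla, hla))
        a = score_anchors(hla, pmap, bundle.anchors)
        renamed = MHCSequence(id="other", sequence=hla.sequence)
        b = score_anchors(renamed, pmap, bundle.anchors)
        assert a.n_matched == b.n_matched


def _groove_alignment(bundle, n: int, deviant: tuple[int, int] | None = None):
    """n copies of the HLA groove (width 182), optionally one deviant cell
    (sequence index, pocket position)."""
    base = bundle.hla_a2.sequence[:182]
    rows = {}
    for i in range(n):
        seq = base
        if deviant and deviant[0] == i:
            pos = deviant[1]
            res = "A" if base[pos - 1] != "A" else "G"
            seq = base[: pos - 1] + res + base[pos:]
        rows[f"s{i:02d}"] = seq
    aligned = make_aligned(rows)
    cmap = PositionMap(
        pairs=tuple((i, i) for i in range(1, 183)), reference_length=182
    )
    return aligned, cmap


class TestPocketConservation:
    def test_identical_sequences_fully_conserved(self, bundle):
        aligned, cmap = _groove_alignment(bundle, 5)
        prof = pocket_conservation(aligned, cmap, bundle.pockets)
        assert prof.position_level_complete == 1.0
        assert prof.cell_level_identity == 1.0

    def test_single_deviant_cell_statistics(self, bundle):
        pos = bundle.pockets.positions[0]
        aligned, cmap = _groove_alignment(bundle, 31, deviant=(3, pos))
        prof = pocket_conservation(aligned, cmap, bundle.pockets)
        assert prof.cell_level_identity == pytest.approx(1146 / 1147)
        assert prof.position_level_complete == pytest.approx(36 / 37)

    def test_all_positions_divergent(self, bundle):
        base = bundle.hla_a2.sequence[:182]
        other = "".join(
            ("A" if c != "A" else "G") if (i + 1) in bundle.pockets.positions else c
            for i, c in enumerate(base)
        )
        aligned = make_aligned({"a": base, "b": other})
        cmap = PositionMap(
            pairs=tuple((i, i) for i in range(1, 183)), reference_length=182
        )
        prof = pocket_conservation(aligned, cmap, bundle.pockets)
        assert prof.position_level_complete == 0.0

    def test_missing_cells_excluded_from_denominator(self, bundle):
        pos = bundle.pockets.positions[5]
        aligned, cmap = _groove_alignment(bundle, 4)
        rows = {m.id: m.sequence for m in aligned.members}
        s = rows["s00"]
        rows["s00"] = s[: pos - 1] + "-" + s[pos:]
        prof = pocket_conservation(make_aligned(rows), cmap, bundle.pockets)
        by_pos = {p.position: p for p in prof.per_position}
        assert by_pos[pos].n_missing == 1
        assert by_pos[pos].conservation == 1.0  # 3/3 non-missing identical

    def test_unalignable_position_reported(self, bundle):
        aligned, cmap = _groove_alignment(bundle, 3)
        drop = bundle.pockets.positions[10]
        pairs = tuple(p for p in cmap.pairs if p[1] != drop)
        cmap2 = PositionMap(pairs=pairs, reference_length=182)
        prof = pocket_conservation(aligned, cmap2, bundle.pockets)
        assert drop in prof.unalignable
        assert len(prof.per_position) == 36

    def test_permutation_invariance(self, bundle):
        pos = bundle.pockets.positions[2]
        aligned, cmap = _groove_alignment(bundle, 8, deviant=(1, pos))
        rows = {m.id: m.sequence for m in aligned.members}
        shuffled = make_aligned(dict(reversed(list(rows.items()))))
        a = pocket_conservation(aligned, cmap, bundle.pockets)
        b = pocket_conservation(shuffled, cmap, bundle.pockets)
        assert a.cell_level_identity == b.cell_level_identity
        assert a.position_level_complete == b.position_level_complete

    def test_complete_implies_cell_identity_one(self, bundle):
        aligned, cmap = _groove_alignment(bundle, 6)
        prof = pocket_conservation(aligned, cmap, bundle.pockets)
        if prof.position_level_complete == 1.0:
            assert prof.cell_level_identity == 1.0

    def test_column_map_from_member(self, bundle):
        base = bundle.hla_a2.sequence[:50]
        aligned = make_aligned({"HLA-A2": base[:10] + "-" + base[10:], "x": base + "A"})
        cmap = column_map_from_member(aligned, "HLA-A2")
        assert cmap.ref_to_query[10] == 10
        assert cmap.ref_to_query[11] == 12  # shifted past the gap column


class TestHydropathy:
    def test_constant_sequence(self, bundle):
        assert hydropathy("IIII", bundle.hydropathy).mean == pytest.approx(4.5)

    def test_two_residue_average(self, bundle):
        assert hydropathy("RK", bundle.hydropathy).mean == pytest.approx(-4.2)

    def test_gaps_and_x_excluded(self, bundle):
        res = hydropathy("I-X-I", bundle.hydropathy)
        assert res.mean == pytest.approx(4.5)
        assert res.n_residues == 2 and res.n_excluded == 3

    def test_all_excluded_raises(self, bundle):
        with pytest.raises(ValueError):
            hydropathy("--XX", bundle.hydropathy)

    def test_hla_groove_value(self, bundle, hla):
        """The HLA-A2 α1+α2 mean under the shipped scale is the published
        reference point (≈ −0.902)."""
        pmap = map_to_reference(global_align(hla, hla))
        res = groove_hydropathy(hla, pmap, bundle.hydropathy)
        assert res.n_residues == 182
        assert res.mean == pytest.approx(-0.902, abs=5e-4)

    def test_concatenation_is_length_weighted_mean(self, bundle):
        rng = np.random.default_rng(8)
        from conftest import random_protein

        a = random_protein(rng, 30)
        b = random_protein(rng, 70)
        ha = hydropathy(a, bundle.hydropathy)
        hb = hydropathy(b, bundle.hydropathy)
        hab = hydropathy(a + b, bundle.hydropathy)
        expected = (ha.mean * 30 + hb.mean * 70) / 100
        assert hab.mean == pytest.approx(expected)


class TestCysteines:
    def test_up_alpha1_pair(self):
        seq = "A" * 35 + "C" + "A" * 30 + "C" + "A" * 20
        geom = cysteine_geometry(seq, _self_map(seq))
        assert geom.has_flag("UP_alpha1")
        (pair,) = [f for f in geom.flags if f.label == "UP_alpha1"]
        assert pair.spacing == 31 and pair.intervening == 30

    def test_s_alpha1_pattern(self):
        seq = "A" * 8 + "C" + "A" * 38 + "C" + "A" * 20
        geom = cysteine_geometry(seq, _self_map(seq))
        assert geom.has_flag("S_alpha1")
        assert not geom.has_flag("UP_alpha1")

    def test_cysteine_free_alpha1(self):
        seq = "A" * 90
        geom = cysteine_geometry(seq, _self_map(seq))
        assert geom.flags == ()

    def test_hla_canonical_pairs(self, hla):
        pmap = map_to_reference(global_align(hla, hla))
        geom = cysteine_geometry(hla, pmap)
        assert geom.has_flag("canonical_a2")
        assert geom.has_flag("canonical_a3")
        assert set(geom.mapped_positions) == {101, 164, 203, 259}

    def test_canonical_pair_spacing_range(self, hla):
        """The α2 and α3 disulfide pairs sit 55–63 positions apart, far
        wider than the α1 C36/C67 spacing of ~31."""
        pmap = map_to_reference(global_align(hla, hla))
        geom = cysteine_geometry(hla, pmap)
        for label in ("canonical_a2", "canonical_a3"):
            (pair,) = [f for f in geom.flags if f.label == label]
            assert 55 <= pair.spacing <= 63


class TestSequon:
    def test_hla_sequon_true(self, hla):
        pmap = map_to_reference(global_align(hla, hla))
        res = sequon_at_86(hla, pmap)
        assert res.status is True and res.motif == "NQS"

    def test_proline_breaks_sequon(self, hla):
        seq = hla.sequence[:86] + "P" + hla.sequence[87:]
        res = sequon_at_86(seq, _self_map(seq))
        assert res.status is False

    def test_non_asparagine(self, hla):
        seq = hla.sequence[:85] + "Q" + hla.sequence[86:]
        res = sequon_at_86(seq, _self_map(seq))
        assert res.status is False and res.residue_at_86 == "Q"

    def test_unmapped_is_undetermined(self, hla):
        pmap = PositionMap(pairs=((1, 1),), reference_length=274)
        assert sequon_at_86(hla, pmap).status is None
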