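"""Pocket-position conservation of a simulated Z1-style alignment.

Z1 molecules keep nearly all 37 pocket positions identical across species;
the generator reproduces that pattern (pockets fixed, everything else free
at 10% per site). Both summary statistics are printed: the share of
positions that are completely conserved, and the share of all residue
cells matching their column consensus.
"""

from mhclin import load_reference_bundle, pocket_conservation
from mhclin.align import PositionMap
from mhclin.seqio import AlignedSet, MHCSequence
from mhclin.simulate import SimulationConfig, lineage_fixed_positions, simulate_family

bundle = load_reference_bundle()
config = SimulationConfig(
    founders={"Z1": bundle.profiles["Z1"].exemplars[0]},
    fixed_positions={"Z1": lineage_fixed_positions(bundle, "Z1")},
    per_site_rate=0.1,
    n_per_family=31,
    seed=9,
)
seqs, _ = simulate_family(config)
groove = AlignedSet.from_sequences(
    [MHCSequence(id=s.id, sequence=s.sequence[:182]) for s in seqs]
)
cmap = PositionMap(pairs=tuple((i, i) for i in range(1, 183)), reference_length=182)
profile = pocket_conservation(groove, cmap, bundle.pockets)

print(f"{len(groove)} sequences, 37 pocket positions")
print(f"position-level completely conserved: {profile.position_level_complete:.1%}")
print(f"cell-level identity to consensus:    {profile.cell_level_identity:.1%}")
for p in profile.per_position[:5]:
    print(f"  pos {p.position:>3} (pocket {p.pocket}): {p.modal_residue} "
          f"{p.conservation:.0%} [{p.category}]")
# with pockets held fixed by the generator both statistics are 100%;
# free positions elsewhere in the groove do not enter the pocket table
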