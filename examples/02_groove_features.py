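"""Score binding-groove features for each teleost lineage exemplar.

For one exemplar per lineage: anchor matches out of 8, the residue at
position 171 (F is the Z hallmark), cysteine pattern flags, the N86
glycosylation sequon, and the mean Kyte-Doolittle hydropathy of the
peptide-binding domains (alpha1+alpha2). Classical grooves score 8/8
anchors; L is the most hydrophobic; S and P carry their diagnostic extra
cysteines.
"""

from mhclin import (
    cysteine_geometry,
    global_align,
    groove_hydropathy,
    load_reference_bundle,
    map_to_reference,
    score_anchors,
    sequon_at_86,
)

bundle = load_reference_bundle()
print(f"{'id':10} {'anchors':>7} {'171':>4} {'N86':>5} {'gravy':>7}  cysteine flags")
for lin in ("U", "Z1", "Z2", "Z3", "L", "S", "P"):
    ex = bundle.profiles[lin].exemplars[0]
    pmap = map_to_reference(global_align(ex, bundle.hla_a2))
    anchors = score_anchors(ex, pmap, bundle.anchors)
    cys = cysteine_geometry(ex, pmap)
    seq86 = sequon_at_86(ex, pmap)
    gravy = groove_hydropathy(ex, pmap, bundle.hydropathy).mean
    flags = ",".join(f.label for f in cys.flags) or "-"
    print(f"{ex.id:10} {anchors.n_matched:>5}/8 {anchors.observed_at(171) or '-':>4} "
          f"{str(seq86.status):>5} {gravy:>7.3f}  {flags}")
# the HLA-A2 groove itself scores 8/8 with gravy -0.902:
hla = bundle.hla_a2
pmap = map_to_reference(global_align(hla, hla))
print(f"{'HLA-A2':10} {score_anchors(hla, pmap, bundle.anchors).n_matched:>5}/8 "
      f"{'Y':>4} {'True':>5} {groove_hydropathy(hla, pmap, bundle.hydropathy).mean:>7.3f}")
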