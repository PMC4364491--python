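"""Map a query protein onto HLA-A2 mature-chain coordinates.

Aligns a teleost-style query (here: a bundled U-lineage exemplar) against
the HLA-A2 reference, prints where the eight anchor positions land in the
query, and splits the query into its alpha1/alpha2/alpha3 domains.
"""

from mhclin import global_align, load_reference_bundle, map_to_reference, split_domains

bundle = load_reference_bundle()
query = bundle.profiles["U"].exemplars[0]

alignment = global_align(query, bundle.hla_a2)
pmap = map_to_reference(alignment)
print(f"query {query.id}: alignment score {alignment.score:.0f}, "
      f"reference coverage {pmap.coverage:.2f}")

# anchor positions in query coordinates: these are the residues that pin
# the two ends of a bound peptide in classical class I molecules
for ref_pos in bundle.anchors.positions:
    q = pmap.ref_to_query.get(ref_pos)
    res = query.sequence[q - 1] if q else "-"
    print(f"  HLA-A2 position {ref_pos:>3} -> query {q or '-':>3} ({res})")

part = split_domains(query, pmap, bundle.boundaries)
for name in ("alpha1", "alpha2", "alpha3"):
    seg = getattr(part, name)
    print(f"{name}: query {seg.start}-{seg.end} ({len(seg.sequence)} aa)")
# a full-length query maps ~1:1, so each domain covers its reference span
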