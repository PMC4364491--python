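# Methods

## Coordinate system and reference

All residue numbering is 1-based on the mature HLA-A2 chain (signal
peptide removed), the convention in which the groove landmarks are cited
(Y7, C36, N86, Y171 …). The bundled reference is the mature A*02:01
ectodomain, positions 1–274, with domains α1 = 1–90, α2 = 91–182,
α3 = 183–274 (standard class I convention; the boundaries are a bundle
parameter). The sequence was checked programmatically for the expected
landmarks: all eight anchors, the N86-Q-S sequon, cysteines at
101/164/203/259, and a Kyte–Doolittle mean of −0.9022 over positions
1–182.

Queries are placed into these coordinates by affine-gap global alignment
(BLOSUM62; gap open −10, extend −1, Biopython's aligner as the engine;
end gaps penalised, with a semi-global option for fragments). Published
analyses of this kind rest on hand-curated alignments; the deterministic
automatic alignment replaces that step, and every downstream operation
takes the position map or alignment as an argument so a curated alignment
can be substituted. Indel-rich regions (the positions a curated alignment
would mark unalignable) are where automatic and manual placements can
disagree; the conservation profile reports such pocket positions as
`unalignable` and excludes them from summary denominators.

## Groove feature definitions

* **Anchors.** Eight positions with accepted residues {7:Y, 59:Y, 84:Y/R,
  143:T, 146:K, 147:W, 159:Y, 171:Y}. Unmapped positions count as
  non-matches but are reported distinctly. The Z-groove variant of the
  check accepts F at 171.
* **Pocket conservation.** The 37 positions forming the six A–F pockets
  are shipped as an editable table. The published source for the list is
  graphical, and the classical pocket definitions enumerate 39 positions;
  two peripheral A-pocket positions (5, 167) were omitted to keep the
  documented count of 37. Every operation takes the table as a parameter
  so an alternative list can be swapped in. Two summaries are always
  reported because "percent conserved" is ambiguous: *position-level*
  (fraction of alignable pocket positions whose non-missing residues are
  all identical) and *cell-level* (fraction of non-missing sequence ×
  position cells equal to the column's modal residue; modal ties break
  alphabetically). Category bands follow the published colour scheme:
  complete = 1.0, high = 0.90–0.997, below otherwise.
* **Cysteine geometry.** Diagnostic flags: `UP_alpha1` (C36 + C67, the
  U/P-lineage α1 pair, spacing 31 by position difference / 30 intervening
  residues — both conventions are reported because published spacing
  ranges do not state which was counted), `S_alpha1` (C at 6–9 and/or
  48), `S_alpha2` (C100), and the canonical α2/α3 disulfides near 101/164
  and 203/259 (±3 tolerance).
* **N86 sequon.** N-X-[S/T] with X ≠ P, evaluated in query coordinates;
  the raw residue at 86 is also reported. Position 86 unmapped yields
  "undetermined" rather than false.
* **Hydropathy.** Kyte–Doolittle values (shipped as data; the scale is a
  parameter), arithmetic mean over the query stretch from the first to
  the last residue mapped inside reference 1–182, so query insertions
  within the groove are included — the score describes the query protein.
  Gaps and X are excluded from numerator and denominator.

## Phylogenetics

p-distance with pairwise deletion: a site is comparable for a pair iff
both residues are standard amino acids; distance = differing/comparable;
a pair with zero comparable sites is an error naming the pair.
Neighbor-Joining follows Saitou–Nei (Q-minimisation, three-point branch
lengths, matrix reduction, trifurcating root for n ≥ 3; n = 2 is
represented as two half-length branches so the single edge has the full
distance). Determinism: Q is evaluated on the upper triangle only and
ties take the lowest (row, column) pair in the working order. Negative
branch lengths are clamped to zero with the deficit moved to the sister
branch (path lengths through the join are preserved); raw values are kept
in a diagnostic field. On additive inputs no clamping occurs and the
generating tree is reproduced to ≈ 1e-15 path error (measured in the
tests and acceptance script).

Bootstrap is Felsenstein column resampling: replicate *r* draws its
columns from an independent substream seeded by (seed, *r*), the tree is
rebuilt per replicate, and each internal edge of the full-data tree gets
the percentage of valid replicates containing the same bipartition
(canonicalised as the split side not containing the lexicographically
smallest leaf, so rooting cannot change it). Replicates in which some
pair loses all comparable sites are discarded and counted; > 5% discards
raises a warning on the tree. Input rows are sorted by id before
distance computation so supports are exactly invariant to the leaf order
of the input alignment. Display rooting at a declared outgroup is a
rebuild from the undirected edge set and never changes bipartitions.

## Reference bundle and exemplars

The bundle is a directory of text tables and FASTA files with a manifest
version; a SHA-256 over its contents is recorded in every pipeline report
so results are attributable to a bundle. The builtin exemplars are
**synthetic**: lineage founders are generated from the HLA-A2 backbone by
seeded Bernoulli substitution (rates 0.30–0.45 per lineage, chosen to
reproduce the deep inter-lineage divergence of the real families) with
each lineage's motif constraints enforced afterwards — U: all anchors +
C36/C67 + N86; Z1: anchors with Y171F and all 37 pocket positions held;
Z2/Z3: most anchors deliberately broken (3 and 2 retained); L: anchors
removed and a hydrophobic-biased replacement pool so the groove mean sits
near the elevated level described for that lineage; S: anchors removed,
C9/C48/C100 added; P: anchors removed, C36/C67 added — plus a
classical-type outgroup at low divergence. Three exemplars per lineage at
8% within-family divergence; nine α1-domain founders (I–IX) at 35%
backbone divergence with three exemplars each at 5%.
`scripts/build_bundle.py` regenerates the bundle byte-identically.

What the synthetic bundle does *not* emulate: real site-rate
heterogeneity, indels (the P lineage's deletion around position 59 is not
modelled), recombination between domains, and real within-lineage
phylogenetic substructure. Tests passing on this bundle therefore
demonstrate the correctness of the machinery (mapping, statistics, tree
building, placement logic), not the field accuracy of calls on real
data — for that, a curated bundle of real exemplars should be swapped in.

## Classification rules

Coverage below 20% of the reference 1–274 span → `unknown` with a
fragment flag. Otherwise the query is projected onto the reference frame
(query insertions dropped for tree purposes) and joined with all
exemplars plus the outgroup; p-distance + NJ; the call is the lineage of
the smallest outgroup-free clade containing the query and at least one
exemplar. A mixed clade falls back to the nearest exemplar at low
confidence; a query that only groups with the outgroup is reported
`unknown` (basal) rather than forced. Motif evidence is secondary: a
weighted motif score below 0.6 for the called lineage lowers confidence
and both signals are reported, never silently overridden. Z sub-lineage:
Z1 iff ≥ 7/8 anchors with F accepted at 171, else nearest of Z2/Z3 by
p-distance (exact ties break to the lexicographically smallest exemplar
id at low confidence). α1 lineages are attempted for U calls with ≥ 60
mapped α1 positions, by the same smallest-pure-clade rule on the α1
exemplar tree; mixed or basal placements are `unassigned`. Lineage IX is
retained but should be treated as provisional — it is the least settled
of the α1 groups.

Bootstrap for classification defaults to 100 replicates (supports on the
placement tree); 1000 is the report-grade setting. Recovery measurements
in the tests and acceptance script run with bootstrap off, since supports
do not enter the call itself.

## Problem sizes and defaults

The acceptance script measures: NJ reconstruction on 100 random additive
matrices with 4–12 taxa; p-distance against a naive recount on 1,000
random 50-residue pairs; bootstrap with 1,000 replicates on a fully
diagnostic 4 × 200 alignment; lineage recovery on 100 simulated queries
(five lineages × 20, per-site rate 0.1 — the within-family divergence at
which real lineage members are still unambiguous); α1 recovery on 100
queries from four founders at ~30% mutual p-distance with 5% family
noise. These sizes make the whole script run in seconds while keeping
binomial noise on the recovery rates below the asserted margins.

## Known limitations

* Automatic alignment can misplace indel-rich stretches relative to a
  structural curation; supply curated alignments for publication-grade
  conservation figures.
* The classifier does not call classical vs non-classical status
  (requires polymorphism and expression data) and does not model
  sequences basal to all exemplar clades beyond reporting them unknown.
* p-distance saturates for deep divergences; it is used here because it
  is the convention for these analyses, not because it is optimal.
* The 37-position pocket table is a reconstruction from the classical
  structural literature and is deliberately replaceable.
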