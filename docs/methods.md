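# Methods

This note documents the model behind `mgrna`, the choices made where the
procedure was genuinely open, and what the synthetic fixtures do and do
not establish about real crystallographic data.

## Coordinate model and symmetry

Structures are read with gemmi (PDB and mmCIF) into a flat atom list.
Hydrogens are discarded everywhere — all environment sums are defined over
non-hydrogen atoms.  Alternate conformers are reduced to the
highest-occupancy one (ties broken alphabetically by altloc).  Ribose
atom names are normalized to the prime convention (`O2*` → `O2'`) and
legacy phosphate names to `OP1`/`OP2`.  Author chain ids and residue
numbers are used throughout.

The neighbor search applies every space-group operator (looked up by
Hermann–Mauguin symbol) in fractional coordinates, takes the
nearest-image lattice translation plus its 26 surrounding cells, and
reports each contact with its operator index and lattice shift so that
physically distinct symmetry copies of one residue are distinguishable
downstream.  A structure without a usable cell degrades to
asymmetric-unit-only queries with a logged warning.  The search is
validated in the test suite against a brute-force oracle that explicitly
materializes all symmetry copies in a 5×5×5 block of cells.

Dataset selection keeps structures with at least three common
ribonucleotides (A/G/C/U) covalently linked by phosphodiester bonds and
at least one Mg²⁺ ion, and an X-ray experiment record when metadata is
present.  "Covalently linked" is operationalized as O3′(i)–P(i+1)
distance ≤ 2.0 Å, a generous single-bond cutoff; no cutoff is canonical
and this one is configurable.  Ribosome/non-ribosome tagging matches the
substring "ribosom" case-insensitively in title/keyword metadata and can
be overridden with an explicit id list.

## Inner sphere

Only O and N are ligand candidates.  Ideal bond lengths are
d(Mg–O) = 2.08 Å and d(Mg–N) = 2.20 Å.  Step 1 accepts everything within
d_ideal + 0.5 Å unconditionally; the chemical rules are deliberately not
applied here, so a mis-modeled amino-nitrogen contact at short range
surfaces later as a benchmark-filter rejection rather than being silently
dropped.  Step 2 (only when step 1 found fewer than six ligands) scans
(d_ideal + 0.5, d_ideal + 1.0] in ascending distance order and accepts a
candidate only if

1. it is not a second oxygen of a phosphate group that already
   contributes an accepted oxygen — phosphate identity follows the
   covalently bonded P atom (found within 1.9 Å), so OP1/OP2 and O5′
   belong to their own residue's phosphate and O3′ to the 3′ neighbor's;
2. a nucleobase nitrogen is one of the six –N= atoms
   (A-N1/N3/N7, G-N3/N7, C-N3);
3. its angle at the ion with *every* already-accepted ligand exceeds 50°.

Because the angle rule makes the outcome order-dependent and no canonical
order exists, candidates are processed in ascending distance (ties broken
by chain, residue number, atom name), which makes the result independent
of file atom order.  Step-1 ligands are never revisited.  CN is the total
accepted count, uncapped: CN > 6 almost always indicates a modeling error
and such sites are flagged rather than truncated.  The whole acceptance
procedure is checked against an exhaustive oracle that enumerates all
candidate subsets and keeps the unique rule-consistent one.

Geometric isomerism for sites with 2–4 phosphate oxygens: *trans* (2 or
4 O_ph) or *mer* (3 O_ph) whenever some O_ph pair subtends more than 135°
at the ion, otherwise *cis*/*fac*.

## Quality scores

Bond valences use the exponential form V(d) = exp((r₀ − d)/b) with the
standard Mg parameters r₀(Mg–O) = 1.693 Å, r₀(Mg–N) = 1.85 Å,
b = 0.37 Å.  The parameters sit in the run configuration so a tabulated
distance–valence relation can be dropped in without code changes.

- **Q_v** = 1 − |ΣV_i − 2|/2, clamped to [0, 1] (the clamp matters for
  grossly over-bonded sites, ΣV > 4).
- **Q_s** = 1 − |Σ V_i·**u**_i| / ΣV_i, where **u**_i is the unit vector
  from the ion to ligand i.  The vector sum has magnitude 0 for a
  perfectly symmetric ligand set, so the score is 1 at the octahedral
  ideal, 1 − 1/5 = 0.8 for a five-vertex site with equal valences and 0
  for a single ligand; it is defined as a complement so that, like the
  other two scores, larger is better.
- **Q_e** compares the ion's B-factor B_m and occupancy O_m with its
  environment: B_e = ΣV_iB_i/ΣV_i and O_e = ΣV_iO_i/ΣV_i over all
  non-hydrogen atoms within 4 Å (symmetry mates included), weighted by
  the same valence form evaluated at each neighbor's distance (non-O/N
  neighbors use the oxygen parameterization; the weighting only needs a
  smooth distance decay).  With full occupancies
  Q_e = min(B_m, B_e)/max(B_m, B_e); with partial occupancy
  Q_e = min(O_m, O_e) · min(r, 1/r) where r = (B_m/O_m)/(B_e/O_e).
  An empty 4 Å environment scores 0 with a warning.

Q_v and Q_s are invariant under rigid motion of the site; all three lie
in [0, 1] by construction.

## Outer sphere

Hydrogen bonds are detected geometrically: an RNA O/N atom within
2.4–3.5 Å (heavy-atom distance) of an inner-sphere water, with
Mg–O_w–acceptor angle ≥ 90° so that only the hemisphere of the water
pointing away from the ion can donate/accept.  The original workflow
delegated this to dot-based contact programs; the self-contained
criterion here is deliberately simple, with all three numbers
configurable — its calibration surface is the set of published
representative sites checked in the acceptance tests.  Only direct
water→RNA bonds define the outer sphere; second-shell water networks are
not traversed.  Atoms that are inner-sphere ligands of the same ion are
excluded.

Bonds aggregate into moieties — P_out (OP1/OP2/P), R_out (O2′/O4′),
B_out (base atoms) — counted once per (kind, residue, symmetry copy).
The bridging oxygens O3′/O5′ belong to the ribose unless their covalently
connected phosphate already contributes to the inner or outer sphere of
the same ion, in which case they fold into that phosphate's moiety.  The
contribution check uses the definite assignments (OP1/OP2/P and inner
phosphates) only; a phosphate "contributing" solely through bridging
oxygens would require a fixed-point iteration for no observed benefit.
A moiety that itself coordinates the ion in the inner sphere is dropped
from the outer sphere.

## Classification and type names

Classes, in precedence order: (i) another metal within 4 Å; (ii) any
non-RNA, non-water inner ligand (modified nucleotides count as non-RNA);
(iii) RNA-inner; (iv) RNA-outer (water-only inner sphere with at least
one moiety).  Sites with water in both spheres are not RNA-bound and stay
unclassified.

Inner type names concatenate an isomer prefix (when ≥ 2 O_ph), the O_ph
count and the other ligand-class tokens in the fixed order
O_r, O_b, N_b, joined by `•` with multiplicity prefixes
(`cis-2O_ph•N_b`).  The most populous branch — exactly one O_ph and
nothing else — is subdivided by the outer-phosphate count, encoded as a
suffix `(+nP_out)` (omitted at n = 0) so the primary name stays
comparable across branches.  Outer names use (#P_out, #R_out, #B_out)
the same way.  `parse_type_name` is the exact inverse and every emitted
name is round-trip tested.

## Motifs

Thirteen predicates over classified sites.  Sequence conventions:
*distant* = different chains (or different symmetry copies) or more than
seven residues apart; *consecutive* = residues i, i+1 of one chain;
*downstream* = higher residue number in the same chain.  Notable
decisions:

- The 10-member-ring family reports four variants (2 consecutive O_ph;
  3 consecutive; ring + extra O_ph separated by one residue, in both
  *fac* and *mer*; 4 O_ph forming two disjoint rings).
- G-phosphate / U-phosphate accept any base oxygen of guanine / uracil
  respectively.
- The purine-N7 seat requires both inner nitrogens to be purine N7 and
  3–4 outer phosphates, each downstream of (at least) one of the purine
  residues in its own chain.
- The G•G site has three variants (2P_out•2B_out with phosphates at n
  and n−1 of the lower guanine; 2B_out; P_out•2B_out with a distant
  phosphate).
- Overlapping hits are all reported; the queries are independent and no
  suppression hierarchy exists.  Motif screening runs on classified
  sites; censuses are taken over benchmark-accepted sites.

Previously described but rarely recurring arrangements (sheared G–A
pairs, A-rich bulge, three-helix junction) are intentionally not
implemented.

## Normalized interaction frequencies

F_atom(X) = p(Mg–X)/p(X), with p(Mg–X) the share of Mg–X interactions
among all counted interactions of the benchmark set (one per coordination
bond for the inner sphere, one per water–atom hydrogen bond for the
outer) and p(X) the share of type-X atoms in the background census.  The
background defaults to all ligand-capable identities (O_ph/O_r/O_b/N_b
atoms of RNA residues) in the full dataset, which is what the
normalization requires; a switch to "all RNA atoms" exists because the
denominator convention is not uniquely determined by the definition.
Both numerator and denominator are shares, so F_atom is invariant to
duplicating structures — redundancy in the dataset does not bias it.
Identities observed with zero background are flagged as infinite rather
than silently dropped.

## Synthetic fixtures

The generator plants sites with analytically known truth: ligand anchors
on exact octahedral vertices (pentagonal bipyramid for CN 7) at the ideal
distances, outer-sphere acceptors extended radially beyond inner waters
(so the angle criterion is met by construction), and residue fragments
with correct atom names, plausible bond lengths and deterministic
orientation.  Every file carries a three-nucleotide covalently linked
carrier chain placed ~30 Å away so dataset criteria hold, and a P1 cell
large enough (60 Å) that periodic images are inert — except in the
dedicated symmetry fixture (24 Å cell) where one inner water exists only
as a lattice translation of a stored atom.  A realizability check rejects
recipes that produce cross-fragment clashes or stray O/N atoms inside the
inner-shell search radius before anything is written.

Noise controls: radial distance jitter (Gaussian σ per planted ligand),
B-factor ranges and ion occupancy.  The battery (52 recipes, cycled to
any requested n) covers all four classes, 25 site types, all 13 motifs,
CN 0–7, all three step-2 rules, a symmetry-completed octahedron and a
partial-occupancy ion.  With the same seed the generator is
byte-deterministic.

What the fixtures do *not* emulate: real refinement artifacts beyond
B/occupancy/distance perturbation, stereochemically complete nucleotides,
correlated coordinate error, crowded binding pockets, or electron
density.  Perfect recovery on the battery therefore demonstrates that the
implementation applies its own rules exactly — not that the rules
themselves are optimal for noisy experimental data.  The published
representative sites exercised in the acceptance tests are the bridge to
real data; they require fetching the structures from the PDB at run time.

## Numerical choices and degenerate inputs

- Threshold comparisons are inclusive (Q ≥ threshold passes), and the
  135°/50°/90° angle rules are strict/inclusive exactly as stated in
  their definitions (> 135°, > 50°, ≥ 90°).
- CN = 0 sites score Q_v = Q_s = 0 (they fail the benchmark's CN
  criterion regardless); empty 4 Å environments score Q_e = 0.
- B-factor ratios define 0/0 as 1 (two zero-B atoms agree perfectly) and
  x/0 as 0.
- Ties in candidate ordering break by (distance, chain, residue number,
  atom name, symmetry id), making all outputs independent of atom input
  order.
- Contacts at distance < 10⁻⁶ Å are treated as the query atom itself and
  excluded.
- Problem sizes in the acceptance script (100-fixture battery, 100 oracle
  trials, 52 jittered fixtures) keep a full from-scratch run around two
  seconds while covering the catalogue twice; they are the package's
  default verification workload, not a statistical claim.

## Known limitations

- The bond-valence parameterization is the standard exponential form;
  site scores can differ in the second decimal from implementations using
  tabulated distance–valence relations.
- Hydrogen-bond detection is heavy-atom geometric; it cannot distinguish
  donor from acceptor and will disagree with dot-surface contact programs
  near the distance/angle boundaries.
- Only A/G/C/U are treated as RNA; modified nucleotides route a site into
  the non-RNA-inner class rather than contributing typed ligands.
- NMR/cryo-EM models, anisotropic B-factors and electron density are out
  of scope.
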