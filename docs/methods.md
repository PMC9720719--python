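# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage. Units are Å for distances and fractions in [0, 1]
for occupancies unless stated otherwise.

## Coordinate model and numbering

A structure is a flat atom table (serial, name, element, residue number,
residue name, subunit 1–4, xyz) sorted by (subunit, residue, serial).
Deposited PDB files are parsed with gemmi; only chains named in an
explicit chain→subunit map are kept (deposited chain IDs vary between
entries, so the mapping is user configuration, never inferred).
Alternate locations other than ''/'A' are dropped for a deterministic
atom set; insertion codes are rejected outright because silently
accepting them risks off-by-one residue numbering in every downstream
selection; HETATM records (waters, lipids, ions) are dropped by default.
Hydrogens are kept on read — contact analysis and pore profiling filter
them by element, since both are defined over heavy atoms.

All analyses assume canonical residue numbering (human RyR2 isoform 1).
Porcine depositions run one residue higher, so `apply_numbering_offset`
with offset 1 maps e.g. deposited G4865 to canonical G4864. Residue
regions (S4–S5 linker 4746–4766, U-motif 4167–4184, S6 helix 4839–4889,
gate window 4859–4869) and the modeled construct ranges
(4099–4206 ∪ 4485–4963, minus the disordered segments 4524–4556 and
4672–4694, and additionally residue 4523 for the open-state construct)
are unions of closed integer intervals; set arithmetic on them drives
extraction, counting (531/subunit closed, 530 open) and gap-adjacency
flags.

Writing uses a fixed-column PDB v3.3 formatter, one chain (A–D) per
subunit with TER records regenerated per subunit; read→write→read is
byte-stable on the atom table at the PDB's 3-decimal coordinate
precision.

## Superposition and chimera construction

Rigid-body fits are least-squares (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`, which enforces a
proper rotation) over atoms paired by canonical residue number and atom
name on the intersection of the two models — the systems compared are
the same protein, so sequence alignment is unnecessary and residues
missing on either side simply drop out of the pairing. The default atom
set is alpha-carbons (robust to sidechain noise); `atom_selection=None`
pairs every shared atom, which the synthetic models (no CA atoms) use.

Interactive aligners iteratively discard far pairs before refitting,
which lowers the reported RMSD; an optional prune-and-refit mode
reproduces this (drop pairs more than 2 SD above the mean post-fit
deviation, refit, at most 5 cycles, never below 3 pairs). Whole-model
RMSDs from such tools are therefore treated as approximate anchors, and
both full-pair and pruned values can be reported.

Substitution excises the target scope (whole subunit or residue
segment) from the acceptor and splices in the transformed donor atoms;
atoms outside the scope are bit-identical to the acceptor and serials
are renumbered. Splices are not geometrically regularised — downstream
relaxation (minimisation/MD) is assumed, as is standard when a segment
is transplanted between conformers — so the quality gates are an
automated clash scan (all heavy-atom pairs from different residues
closer than 1.0 Å; the KD-tree search equals the all-pairs result) and
backbone C–N bond lengths across the splice junctions. Point mutations
are not built; a recipe can carry a mutation label as metadata only, and
histidine protonation variants (HIE/HID) are likewise metadata: they
have no heavy-atom consequence for any analysis here.

## Pore-radius profile

The pore radius at axial position z is max over in-plane probe centres
of (3-D distance to the nearest atom centre minus that atom's van der
Waals radius), clamped at zero. Established probe-sphere tools solve
the same geometric problem with a randomised walk; here the per-slab
maximisation is deterministic — a 0.5 Å coarse grid around the previous
slab's centre (half-width max(2, previous radius + 1) Å) followed by
Nelder–Mead refinement (xatol 1e-3) — so profiles are exactly
reproducible without a random seed and agree with an exhaustive 0.05 Å
grid oracle to well under 0.1 Å on tube-like pores. Slabs step 0.25 Å
by default, anchored at the gate z when the gate-anchored pipeline is
used, and the profile extends in both directions until the radius
exceeds the cutoff (10 Å default; 12 Å where an open vestibule crosses
10 Å). Two caveats follow from the definition: the mathematical maximum
over an unbounded plane lies in free space outside the channel, so the
seeded local search (not a global one) is the correct reading; and the
walk terminates off the channel ends where the radius blows past the
cutoff.

vdW radii are Bondi (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80), with
1.70 Å for unlisted elements; probe-sphere tools ship slightly
different tables, so absolute radii may differ from other software by
~0.1–0.2 Å and published pore radii are treated as approximate anchors.
The channel axis is the laboratory z axis (membrane normal in the
standard setup); no principal-axis auto-detection. Luminal orientation
is declared per input (+1 = positive z luminal) rather than inferred.

The gate is located as the z-centroid of the gate residue's sidechain
heavy atoms on all four subunits (default residue 4867); the profile is
shifted so the gate sits at z = 0 and flipped if needed. The state call
reports both the radius at the sample nearest z = 0 and the local
minimum within 2 Å of it (a constriction can sit a fraction of a step
off the anchored origin); classification uses the former against a
1.5 Å threshold — the midpoint between the closed (≈0.6–0.85 Å) and
open (≈2–3.7 Å) gate-radius clusters — with the boundary value itself
called open, a documented convention.

## Trajectory statistics

Trajectories are ordered frames over a fixed topology (nominally
1 frame/ns, 1000 frames). RMSD time series fit every frame to frame 1
over the selection before evaluating RMSD on that selection; entry 0 is
exactly 0. The equilibrated average structure takes the last N frames
(N = 100 in the standard protocol), fits each to the first retained
frame to remove global translation/rotation, and averages coordinates
arithmetically; flexible regions can look distorted in such an average
and are left as-is (no B-factor masking), because the average serves
comparison of well-ordered elements.

Substructure RMSD between two tetramers extracts a residue region from
all four subunits of both models — the gate geometry is defined only by
the assembled tetramer, so all four subunits stay in every comparison —
then, for each of the 16 (model subunit, reference subunit) pairings,
superposes that pair and evaluates the whole four-subunit RMSD under
the resulting transform, corresponding the remaining subunits by the
same cyclic offset (the tetramer's four-fold arrangement); the minimum
over pairings is returned ("best aligned pair of chains"). The default
RMSD atom set is alpha-carbons, exposed as a flag; no pruning is
applied, so values from pruning aligners are qualitative anchors
(closed-like linker regions ≲1 Å from a closed reference, open-like
≳3 Å).

## Contact occupancy

A residue pair is in contact in a frame when any heavy-atom pair
between the two residues is within the cutoff (3.0 Å default — close to
the mean hydrogen-bond donor–acceptor distance in protein secondary
structure; the boundary is inclusive, and any heavy-atom pair counts,
polar or not). Percent occupancy is the number of frames in the
analysis window (default: last 100) containing the contact, over the
window size. The KD-tree search is an acceleration only; tests pin its
output to the O(n²) all-pairs result. Granularity is residue–residue:
atom contacts are collapsed to one record per residue pair per frame,
with the minimum atom distance retained.

Exclusions: same-residue pairs always; same-subunit pairs with
|Δresidue| ≤ 2 by default (backbone neighbours contact trivially;
configurable); and, when a scope region is given, same-subunit pairs
with both members inside the scope (a linker's self-contacts are not
interface contacts — contacts between the same element on *adjacent*
subunits still count). Records at ≥30% occupancy (inclusive) are the
high-percent-occupancy set; the threshold is a parameter.

Summaries tally records per residue in three modes — source-residue
(the scope-side residue), partner-residue, and interface (inter-subunit
records only, both residues credited) — pooled across the four subunits
of the systems in one pool. The standard pools are the three
closed-outcome systems (4C, 1C3O, 1C3O-HID), the three open-outcome
systems (4O, 1C3O-open-S4S5L, 1C3O-open-S4S5L-HID), and the two
H4762P-mutant systems, as configuration; mixing pools in one summary is
an error. The appear-at-least-N filter (N = 3 for the interface
comparison) keeps a residue when *any* pool reaches N, which is how the
closed and open summaries remain directly comparable.

## Mutation proximity

Distance from a mutation to the interaction sites is pure sequence
distance min |residue − site| — the criterion is "within k residues",
not spatial adjacency. Sites are the union of both partners of every
high-occupancy inter-subunit record in the designated pool. The
within-k fraction counts each mutation once, with ≤ k inclusive; the
inclusive convention is a documented choice, as the printed fractions
cannot disambiguate it without the original supplementary tables.
Catalogue entries are deduplicated with labels merged. Mutations within
a window (default 5) of a modeled-range gap boundary are flagged,
because their true sequence neighbourhood is partly absent from the
model and the proximity score may undercount.

## Synthetic benchmark generators

The toy channel is four C4-symmetric pseudo-helical subunits: each
residue is a ring of carbon atoms at the lumen wall radius (8 Å
default), stacked along z, with one gate residue per subunit whose ring
is pulled in to the gate centre radius. Atoms are cell-centred within
each 90° sector at a uniform ≥1.3 Å arc spacing, so seam gaps between
subunits equal the in-arc spacing and no inter-residue atom pair comes
closer than ~1.18 Å — the generator's output is clash-free at the 1.0 Å
default scan threshold by construction. Because the centre of a
complete ring is a local maximum of the inscribed-probe radius, the
pore radius at the gate is exactly (gate centre radius − vdW radius)
regardless of ring density, while the 1.70 Å vdW spheres seal the
inter-atom gaps against probe leakage. The presets place the gate at
2.44 Å (closed, → 0.74 Å gate radius) and 5.10 Å (open, → 3.40 Å),
matching the centres of the two observed gate-radius clusters. The
toys are geometric objects, not chemically valid polypeptides — no
backbone, no sidechain chemistry, no membrane — so passing tests
demonstrate correctness of the geometric and statistical machinery, not
force-field realism.

Synthetic trajectories add i.i.d. Gaussian coordinate jitter per frame
(σ = 0.1 Å default; real trajectories have correlated, anisotropic
fluctuations, which these do not emulate) and can pin designated atom
pairs at a contact distance in a Bernoulli(p) subset of frames and an
apart distance otherwise, giving pairs with known expected occupancy
and binomial spread. Synthetic mutation catalogues place a chosen
number of entries within k of a site set and the rest strictly beyond,
optionally with exact per-entry distances so mixed criteria (e.g. 32 of
49 within 3 *and* 36 of 49 within 5) are realised simultaneously. Every
generator is exactly reproducible from its spec and seed; one RNG
stream per spec, no global state.

## Problem sizes and determinism

The default test and acceptance runs use toy channels of ~1000 atoms,
trajectory windows of 100 frames, 100–500 random seeds for the
statistical recoveries, and brute-force oracles on ≤2000-atom slabs —
sizes chosen so every oracle comparison is exhaustive and exact while
the whole suite stays interactive. All randomness flows from explicit
seeds; the pore profiler and all structural operations are fully
deterministic.

## Known limitations

- The pore profiler assumes a roughly z-aligned, singly connected pore;
  branched or strongly tilted channels would need an axis definition
  this package deliberately does not auto-detect.
- Pore radii depend on the vdW table; cross-software comparisons should
  expect ~0.1–0.2 Å systematic offsets.
- Whole-model RMSD against values from pruning aligners is comparable
  only qualitatively unless the prune mode and its parameters match.
- Contact analysis is distance-only: no donor–acceptor angles, no
  energy weighting, no salt-bridge typing.
- Sequence-proximity scoring ignores 3-D distance; a mutation far in
  sequence but close in space scores as far.
- The modeled-range bookkeeping honours whatever the input contains; the
  disordered segments are not modeled, only accounted for.
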