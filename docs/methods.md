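# Methods

This note documents the models, conventions and numerical choices behind
`qtykit`, in the package's own terms.

## The QTY substitution model

The QTY code is a fixed four-pair map — L→Q, I→T, V→T, F→Y — applied
only inside annotated transmembrane (TM) segments.  The restriction to
TM segments is a modelling decision, not an implementation shortcut:
the rationale of the code is to neutralize the lipid-facing hydrophobic
belt while leaving soluble domains intact, and the near-invariance of
molecular weight and isoelectric point depends on the soluble domains
not being rewritten.  Two summary statistics follow directly:

- TM variation % = 100 × (substituted positions) / (summed TM-segment
  length),
- overall variation % = 100 × (substituted positions) / (full sequence
  length).

With substitutions confined to TM segments, TM variation ≥ overall
variation always.  Whether a published "TM variation" counts all
annotated TM residues or only helix-core residues is ambiguous in
general; this package counts **all residues of the annotated segments**
and records that convention in its outputs.  Percentages are carried at
full precision and rounded to two decimals only for display.

The map is a mathematical function (one target per source), idempotent
(Q, T, Y are not sources), and charge-preserving (no source or target is
ionizable at physiological pH except the added tyrosines, whose side
chain titrates near pKa 10).  Custom maps may be passed explicitly, but
no reverse map is shipped.

TM segments are an input (UniProt TRANSMEM convention, 1-based
inclusive); the package deliberately contains no TM-prediction
algorithm.  Non-standard residue letters are rejected in strict mode and
preserved verbatim — never silently coerced — in lenient mode, where
they are excluded from substitution and cause mass/pI calculations to
fail loudly.

## Molecular weight and isoelectric point

Masses are **average residue masses** (free amino acid = residue +
water, water = 18.01524 Da), matching the convention of common web
calculators that report two-decimal Da values.  Molecular weight is the
residue-mass sum plus one water; it is additive up to that water term,
and per-substitution deltas reduce to free-amino-acid differences
because the water cancels: L→Q +14.97, I→T −12.05, V→T +1.97, F→Y
+16.00 Da.

Net charge uses the Henderson–Hasselbalch sum over ionizable groups:
positive groups (N-terminus, K, R, H) contribute `1/(1+10^(pH−pKa))`,
negative groups (C-terminus, D, E, C, Y) contribute
`−1/(1+10^(pKa−pH))`.  The default pKa set is the Bjellqvist/Expasy
family (N-term 7.5, C-term 3.55, D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98,
K 10.0, R 12.0) **without** Expasy's charged-neighbour context rules,
which are not needed at the precision the package asserts; the EMBOSS
set is available by name.  The charge curve is strictly decreasing in
pH, so the isoelectric point is the unique root, found by bisection on
[0, 14] to 1e-4 pH; the residual charge at the reported pI is below
1e-3.  Agreement with the Expasy web tool is expected at roughly ±0.1
pH on ordinary sequences (the context rules and pKa revisions account
for the difference) and is not asserted by any test.

Hydropathy profiles are sliding-window arithmetic means on the
Kyte–Doolittle scale, default window 19 (the classic TM-detection
width); the window must be odd and no longer than the sequence.

## Structures, pairing, and the trimming rule

PDB and mmCIF files are parsed with gemmi into a minimal uniform model.
Deterministic reductions applied on read: first model of multi-model
files; one conformer per atom name (highest occupancy, ties favouring
altloc 'A'); hydrogens dropped (cryo-EM depositions lack them; all
downstream geometry is heavy-atom).  Residues are keyed by (chain,
author number, insertion code).  Author numbering is the pairing key
because experimental depositions of the proteins this pipeline targets
carry UniProt-consistent author numbering; predicted models numbered
from 1 are handled either by a constant per-chain offset or by the
"align" pairing policy, which global-aligns the one-letter sequences
with the four QTY pairs scored as matches, so a native structure pairs
site-by-site with its analog.

The trimming rule for RMSD is implemented *as* the pairing: residues
present in only one model — unresolved loops in an experimental map,
disordered termini in a prediction — simply drop out of the
correspondence.  No coordinates are modified.  Protomer extraction cuts
one chain out of a multimer and lets each hetero residue (cofactor,
ligand) travel with the chain owning its nearest polymer atom.

## Superposition

Kabsch's closed-form SVD solution, with the standard determinant
correction: if the optimal orthogonal matrix is a reflection, the sign
of the smallest singular vector is flipped, so the reported rotation is
always proper (det = +1) and a chiral set keeps a positive RMSD against
its mirror image.  Degenerate (e.g. collinear) inputs still return a
minimizer, but the rotation is then non-unique.  The implementation is
seedless and deterministic.

Model-level superposition is **CA-only by default** (an all-atom option
matches atoms by name within paired residues).  Published RMSDs for
structure pairs rarely state their atom selection or outlier handling,
so refinement is explicit and off by default: with `cycles > 0`, pairs
farther than `cutoff` (default 2.0 Å) from the current fit are rejected
and the fit repeated, and **both** the all-pair and the refined RMSD are
reported so an external value can be bracketed.  Refinement stops early
when no pair exceeds the cutoff and errors rather than continuing below
3 pairs.

## Solvent-accessible surface area

Shrake–Rupley point sampling: each heavy atom carries `n_points`
(default 960) sample points on its expanded sphere (van der Waals
radius + probe, probe default 1.4 Å); a point is accessible iff outside
every neighbour's expanded sphere; the atom's area is the accessible
fraction of the expanded sphere's area.  Three deterministic choices:

- sample points lie on a golden-section spiral, not a random cloud, so
  areas are bit-reproducible and `n_points` is the only accuracy knob
  (960 points put an isolated sphere within 0.5% of 4π(r+probe)²);
- all geometry is computed in a canonical principal-axes frame derived
  from the coordinates (axes ordered by variance, signs fixed by the
  third central moment, right-handed), which makes areas invariant
  under rigid motion of the input to machine precision; perfectly
  symmetric inputs fall back to an arbitrary but deterministic frame;
- radii come from a named Bondi-style heavy-atom set frozen in the
  module; unknown elements are an error unless an explicit fallback
  radius is requested.

The hydrophobic surface fraction divides the SASA of residues in a
configurable hydrophobic set by the total SASA.  The default set is
exactly {L, I, V, F, M, W, A} — the lipid-facing residue inventory of
TM helices; proline, sometimes listed with the hydrophobic class, is
excluded from the default.  Hydrophobicity is a residue-class property
here, not an atom-class one.  No absolute threshold defines a
"significant" reduction; the package asserts only the direction of the
change (QTY renaming on fixed coordinates strictly lowers the
fraction), which is a property-level statement.

## Binding-site geometry

Contacts are polymer residues with any heavy atom within a cutoff
(default 4.0 Å) of a ligand selection, recorded with their minimum
heavy-atom distance, the selection's own residues excluded.
Inter-cofactor separations are reported under a named convention —
minimum heavy-atom distance (default) or centroid distance — because
published single-number separations often leave the convention
unstated.  Pocket conservation between a native and an analog model
maps the analog's contact set through the residue pairing and reports
the Jaccard index of the two sets plus a kept / lost / gained table;
the Jaccard score is a descriptive convenience of this package, not a
published statistic, and is labelled as such in reports.  Analog
contacts with no counterpart in the pairing are listed explicitly,
never dropped.

## Synthetic data

The fixture generator emulates the *shape* of the problem, not its
physics: sequences with hydrophobic-biased TM segments (default bias
0.9 toward {L,I,V,F,M,W,A}; loops drawn from a polar pool) threaded
onto CA-trace antiparallel helix bundles built from ideal α-helix
geometry (rise 1.5 Å, twist 100°, axial radius 2.3 Å — conventional
textbook values used as fixture parameters).  Default sizes (4 helices
of 20 residues, 6-residue loops) give a ~100-residue multi-pass
protein, small enough for the full pipeline to run in seconds.  Loops
are straight-line connectors; side chains are absent; nothing about the
bundle is energy-minimized.  Consequently, passing tests demonstrate
algorithmic correctness (bookkeeping, geometry, statistics, oracles) —
they do not demonstrate that a QTY analog of a real enzyme is soluble
or folded, which only experiments and full-scale structure prediction
can show.  `perturb_structure` adds i.i.d. Gaussian noise (σ per
coordinate); after superposition the expected RMSD is ≈ σ√3, slightly
reduced because the six fitted rigid degrees of freedom absorb ~6/(3N)
of the noise variance — the Monte-Carlo tests check the mean over seeds
within 20%.

All generators are pure functions of (parameters, seed), and fixtures
are written to real FASTA/TSV/PDB files so tests exercise the genuine
I/O paths.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated
inputs: the 10-residue worked record, ~100-residue synthetic bundles,
point sets of ≤ 6 points for the superposition oracle (100 sets),
100 random peptides for the pI oracle, and 960–1920 sample points for
SASA — sizes chosen so every oracle comparison is exact or
tightly-toleranced while the whole pipeline remains interactive.  Every
random draw flows from an explicit seed; structure and SASA code paths
contain no randomness at all.

## Known limitations

- The pI model omits Expasy's context-dependent pKa adjustments and all
  folded-state effects (buried groups, local electrostatics).
- The "align" pairing policy assumes co-linear sequences; it will not
  recover circular permutations or domain swaps.
- SASA treats all atoms as spheres with element-generic radii; no
  distinction between carbonyl and aliphatic carbons.
- The hydrophobic fraction is sequence-class-based; an exposed alanine
  in a soluble domain counts the same as one in the membrane belt.
- Contact analysis reports distances only; hydrogen bonds are not
  classified (a polar contact is just a contact).
- Fixture structures are CA traces; all-atom behaviour (e.g. SASA of
  real side chains) is exercised only when users supply real models.
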