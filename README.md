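# qtykit

Integral membrane proteins are hard to study: their transmembrane (TM)
helices are coated with hydrophobic residues that face the lipid bilayer,
so the proteins aggregate in water and must be handled in detergents.
The **QTY code** is a deterministic protein-engineering recipe that makes
such proteins water-soluble while preserving their fold: within each TM
helix it replaces the hydrophobic residues with hydrophilic residues of
near-identical side-chain shape and backbone electron density,

> L → Q  (leucine → glutamine)
> I → T  (isoleucine → threonine)
> V → T  (valine → threonine)
> F → Y  (phenylalanine → tyrosine)

leaving every position outside the TM segments untouched.  Because Q, T
and Y are uncharged, the substitutions change neither the charge
inventory nor (much) the isoelectric point, and the molecular weight
shifts only by the small per-pair mass differences.

`qtykit` implements the code and the full characterization pipeline used
to assess a QTY design:

- **`seq_io`** — FASTA I/O and UniProt-TRANSMEM-style TM annotations
  (`id<TAB>start<TAB>end[<TAB>kind]`, 1-based inclusive).
- **`qty_code`** — the substitution itself, TM / overall variation
  percentages, and a `|`/`*` alignment rendering.
- **`physchem`** — average molecular weight, Henderson–Hasselbalch net
  charge and isoelectric point (Expasy-compatible Bjellqvist pKa set by
  default, EMBOSS alternative), Kyte–Doolittle hydropathy profiles.
- **`structure`** — PDB/mmCIF parsing (via gemmi) into a uniform
  heavy-atom model, protomer extraction, and native↔analog residue
  pairing by author numbering (the loop-trimming rule: residues present
  in only one model drop out) or by QTY-aware sequence alignment.
- **`superpose`** — Kabsch superposition (SVD with reflection
  correction), RMSD, and optional PyMOL-style outlier-rejection cycles.
- **`surface`** — Shrake–Rupley solvent-accessible surface area with a
  deterministic sample-point spiral, and the hydrophobic surface
  fraction over the residue set {L, I, V, F, M, W, A}.
- **`sites`** — ligand contact residues (4 Å heavy-atom cutoff by
  default), inter-cofactor distances under two conventions, and a
  Jaccard pocket-conservation score.
- **`fixtures`** — synthetic TM proteins (ideal-helix bundles with
  hydrophobic-biased TM sequences) with known ground truth, so the whole
  pipeline runs and is tested without downloading anything.

## Worked example

A 10-residue toy protein with one annotated TM helix at positions 3–8:

```sh
cat > toy.fasta <<EOF
>toy
MKLLIVFAGW
EOF
printf 'toy\t3\t8\n' > toy.tm.tsv
qtykit apply --fasta toy.fasta --tm toy.tm.tsv --out analog.fasta
```

prints

```
id      n_sub   tm_len  total_len       tm_pct  overall_pct
toy     5       6       10              83.33   50.00
```

Five of the six TM residues (L3, L4, I5, V6, F7) carry a QTY
substitution, so the TM variation is 5/6 = 83.33% while the overall
variation is 5/10 = 50.00%; `analog.fasta` contains `MKQQTTYAGW`.  The
same pair in Python, with the alignment rendering (`H` marks the TM
helix, `|` identity, `*` a substitution):

```python
>>> import qtykit as q
>>> rec = q.attach_segments(q.ProteinRecord("toy", "MKLLIVFAGW"),
...                         [q.TMSegment(3, 8)])
>>> res = q.apply_qty(rec)
>>> print(q.render_alignment(rec, res.analog), end="")
  HHHHHH
MKLLIVFAGW
||*****|||
MKQQTTYAGW
>>> round(q.molecular_weight(res.analog.sequence)
...       - q.molecular_weight(rec.sequence), 2)
35.86
>>> round(abs(q.isoelectric_point(res.analog.sequence)
...           - q.isoelectric_point(rec.sequence)), 2)
0.16
```

The analog is 35.86 Da heavier (one L→Q at +14.97, one I→T at −12.05,
one V→T at +1.97, one F→Y at +16.00 Da) and its isoelectric point moves
by only 0.16 pH units — the invariance the code is designed for.

Structure-side commands work the same way on PDB/mmCIF files:

```sh
qtykit superpose native.pdb analog.pdb --chain A --pairing align --cycles 5
qtykit sasa model.pdb --probe 1.4 --points 960
qtykit contacts complex.pdb --ligand "resn FAD" --cutoff 4.0
qtykit distance complex.pdb --a "resn FAD" --b "resn HEM"
qtykit make-fixture --helices 6 --len 24 --seed 7 --out fixtures/
```

Every JSON report embeds its configuration and a `conventions` block
(pairing policy, distance convention, hydrophobic set) so numbers are
comparable across runs.

## Conventions and caveats

Sequence coordinates are 1-based inclusive; structure residues use
author numbering; hydrogens are ignored everywhere; superposition is
CA-only by default; SASA hydrophobicity is assigned per residue class,
not per atom.  See `docs/methods.md` for the full model description,
parameter defaults, and known limitations.
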