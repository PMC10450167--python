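# nucassign

Sequence assignment, identification and validation for nucleic-acid
models in cryo-EM and crystallographic maps.

At the resolutions where most RNA/DNA models are built (3–5 Å), adenine
is indistinguishable from guanine and cytosine from uracil/thymine, so
sequence register errors slip through standard validation.  `nucassign`
works with the two signals the density *does* support:

1. a neural-network classifier estimates, for every modelled nucleotide,
   the probability that its base is a **purine or pyrimidine**, from 403
   map values sampled around the base region in a backbone-anchored local
   frame;
2. **Watson–Crick base pairs** are detected from the sugar-phosphate
   backbone alone, by superposing short ideal-helix search fragments
   (P-atom triplet matching, all-backbone RMSD < 1.0 Å), ignoring base
   identities entirely.

A continuous fragment of n residues is aligned gaplessly to a target
sequence by the product of per-residue class probabilities,

    S(o) = Π_i p_i(class(t_{o+i})) · Π_{(i,j) WC} c_ij ,

with a 0.1 correction factor `c_ij` whenever a tentative alignment puts
two same-class bases across a detected WC pair.  Significance is a
p-value from an extreme-value (GEV) fit to block maxima of the profile's
scores on a long random sequence, matched to the number of placements in
the true target.  For database identification the probabilities and the
pairing pattern are encoded as a Stockholm MSA and queried with
covariance models (INFERNAL `cmbuild`/`cmcalibrate`/`cmsearch`) or
profile HMMs (`cmsearch --hmmonly`, or HMMER `hmmbuild`/`nhmmer` when
INFERNAL is not installed).

The four entry points: **restraints** (base-pair restraints for
REFMAC5/PHENIX/ISOLDE/COOT plus a PyMOL script), **identify** (best
database sequence for a model+map), **assign** (fragments to a known
target sequence, bases rebuilt), **validate** (register-shift scan of a
model against its own sequences).

## Worked example

Generate a synthetic bundle (ideal A-RNA duplex + simulated 3 Å map +
sequences + ground truth), train a classifier on synthetic descriptors,
and assign the model to its target sequence:

```bash
nucassign fixtures --sequence GGACUUCGGUCCGGACUUCGGUCC --noise-sd 0.1 \
    --seed 3 --out demo
nucassign train --n-per-class 500 --epochs 200 --seed 1 --out demo
nucassign assign --model demo/model.pdb --map demo/map.ccp4 \
    --sequence demo/target.fasta --classifier demo/classifier_em.npz \
    --seed 7 --out demo
```

The train step prints

```
validation accuracy 1.000; model saved to demo/classifier_em.npz
```

(descriptors from clean simulated maps separate essentially perfectly),
and the assign step prints one line per continuous fragment:

```
chain A offset 0 p=1e-300
chain B offset 0 p=3.12e-09
```

`offset 0` means each strand aligned at position 0 of its target record —
the correct placement — and the tiny p-values say scores this good are
essentially impossible among random placements.  `demo/assignment.tsv`
holds the per-fragment table (offset, log score, p-value, assigned
letters) and `demo/assigned.pdb` the model with bases rebuilt to the
assigned identities.  Restraints for the same model:

```bash
nucassign restraints --model demo/model.pdb --dialect REFMAC --out demo
# -> "24 WC pairs, restraints in demo/restraints_refmac.txt"
```

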