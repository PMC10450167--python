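# Methods

`nucassign` assigns, identifies and validates nucleic-acid sequences in
atomic models built into cryo-EM or crystallographic density.  This note
documents the models and procedures it implements, the parameters that
matter, and the choices made where the design was genuinely open.

## The problem

At the resolutions where most nucleic-acid models are built (3–5 Å),
adenine cannot be distinguished from guanine, nor cytosine from uracil or
thymine.  What the density does support is a binary decision — purine
(two-ring) versus pyrimidine (one-ring) — plus the backbone conformation,
which betrays base pairing independently of base identity.  The package
combines these two signals: a density classifier produces per-residue
purine/pyrimidine probabilities, and a backbone-only detector produces
Watson–Crick (WC) pairing, which together drive gapless alignment of
model fragments to candidate sequences.

## Residue descriptors

A nucleotide is summarized by 403 density values sampled on a fixed cloud
of points around its base region:

- **Cloud construction.** The guanine base of an idealized nucleotide
  template (from the Chemical Component Dictionary) is swept through all
  rotations about the glycosidic bond in 1° steps.  Nodes of a regular
  1.0 Å grid centred on N9 that lie within a cutoff of any swept atom
  position are kept.  With the base hydrogens included in the sweep, a
  cutoff of 0.937 Å (calibrated by binary search inside [0.8, 1.2] Å)
  selects exactly 403 nodes; with heavy atoms only no cutoff in that
  window reaches 403, so hydrogens are part of the sweep.  The cloud,
  with its anchor coordinates, is frozen as package data; its point order
  (lexicographic in grid index) is part of the classifier input contract.
- **Alignment to residues.** At prediction time the cloud is placed by
  least-squares superposition of the template's C2'/C1'/O4' sugar atoms
  onto the residue's, so only backbone/sugar atoms are needed — base
  atoms, which are unknown before assignment, play no role.
- **Normalization.** Each descriptor is z-scored (sd floor 1e-6).  Maps
  from different experiments are on arbitrary scales; per-descriptor
  normalization makes EM and MX descriptors commensurable.  A constant
  map therefore yields an all-zero descriptor.

Rigid-motion invariance of descriptors is limited only by trilinear
interpolation on the sampling grid.  The invariance measurement uses maps
simulated with 0.15 Å grid spacing so the discretization error (which
scales with the square of the spacing) stays below the 0.05 tolerance and
the geometric property itself is what is tested.

Purine/pyrimidine labels for arbitrary residue codes (including modified
bases such as pseudouridine or 1-methyladenosine) use an imidazole-ring
geometry rule: a residue whose base has both N1 and N9 atoms separated by
3.6–4.6 Å (ideal templates: ~4.1 Å) is a purine; standard codes
short-circuit by name.

## The base-type classifier

A two-layer fully connected network: 403 inputs → 403 hidden units with
ReLU → 2 outputs with log-softmax, a dropout layer (p = 0.5) between the
two layers during training.  Training minimizes the negative
log-likelihood with ADAM at learning rate 1e-5, batch size 20, for 1000
epochs by default, holding out a seeded 10% validation split; no early
stopping is applied, and the accuracy trajectory is recorded in the model
metadata.  Weights are initialized with seeded Glorot-style uniform
draws; identical data, configuration and seed reproduce bit-identical
weights.  Inference disables dropout and consumes no randomness.

The network is implemented directly in numpy (forward, backward, ADAM),
so trained models serialize to a flat `.npz` container and load without a
deep-learning runtime.  EM and MX weight sets are two trained artifacts of
the same architecture; the package ships a training entry point rather
than pre-trained weights, because meaningful weights depend on the user's
map corpus.

## Backbone-based secondary structure

Base pairs are detected by superposing small search fragments of known
secondary structure onto the model backbone:

- **Search fragments.** The default is a 2-bp ideal double helix (A-RNA
  twist 32.7°, rise 2.81 Å; B-DNA 36.0°, 3.38 Å), generated from an
  embedded reference WC pair.  That reference was produced once by
  restrained least squares: a G·C pair assembled against standard
  hydrogen-bond distances (O6–N4 2.91, N1–N3 2.95, N2–O2 2.86 Å,
  C1'–C1' 10.4 Å), then placed in the helix frame with glycosidic and
  backbone torsions free so that the helical repeat closes the
  sugar-phosphate chain (O3'–P ≈ 1.6–1.9 Å) without steric clashes,
  with soft targets on phosphate radius and base-pair axis displacement.
  The fitted conformers are shipped as plain-text package data.
- **Matching.** Every P-atom triplet of the fragment is compared against
  model P-atom triplets pre-filtered by pairwise-distance compatibility
  (each distance within 1.0 Å).  Surviving triplets are superposed
  (Kabsch), each fragment residue is mapped to the nearest model P within
  3.0 Å (discarded unless injective and complete), and the match is
  refined on all shared sugar-phosphate atoms.  Matches with refined
  RMSD < 1.0 Å are kept, deduplicated by residue mapping with the lowest
  RMSD winning.
- **Two-step protocol.** Step 1 matches the helical fragment and yields
  WC pairs and stackings.  WC multiplicity is resolved immediately
  (lowest RMSD per residue) — spurious overlapping helix matches must not
  distort the next step.  For RNA models with a motif library, interiors
  of stacked WC runs (≥ 3 consecutive pairs; the outermost pair of each
  run is kept as flanking context) are removed and each library fragment
  is matched against the remainder.  Step-2 assignments win conflicts,
  then lower RMSD.  Step-1 stacking annotations are retained even where
  step 2 removes stem interiors.
- **Motif libraries** are a pluggable input: a directory of PDB files
  with sidecar `.pairs` tables (`index_i index_j interaction`).  The
  package does not ship mined motif sets.

Restraints are emitted for REFMAC5 (`exte dist` records), PHENIX
(geometry edits), ISOLDE/COOT (python calls) and PyMOL (one dashed
distance per pair).  WC pairs of known identity get per-hydrogen-bond
restraints (target 2.9 Å, σ 0.15 — standard WC geometry); pairs whose
identity is unknown get a single glycosidic-N–glycosidic-N restraint
(8.9 Å, σ 0.3).  Dot-bracket strings render a maximum nested subset
(interval dynamic program) as `()` and remaining crossing pairs as `[]`.

## Sequence assignment and p-values

A continuous fragment (maximal run with O3'(i)–P(i+1) ≤ 2.5 Å; a generous
bonding cutoff, configurable) yields a probability profile: classifier
probabilities clipped to [1e-3, 1−1e-3] (preventing −∞ log scores), plus
the WC pairs internal to the fragment.  A gapless placement at offset o
scores

    log S(o) = Σ_i log p_i(class of target letter at o+i)
             + Σ_{(i,j) ∈ WC} log c_ij

with c_ij = 0.1 when the aligned letters at i and j are same-class
(unlikely across a true WC pair) and 1 otherwise; `N` letters contribute
log 0.5 and never trigger the correction.  All offsets are enumerated;
ties resolve to the smallest offset.  Assignment searches the forward
strand only — fragment polarity is fixed by the model.

**Significance.** The best score is compared with the profile's placement
scores on a long seeded random sequence.  Consecutive background scores
are cut into contiguous blocks of m = L − n + 1 placements — the same
number, and the same overlap correlation, as the placements in the true
target — and a generalized extreme-value distribution is fitted to the
block maxima (200 blocks by default).  The p-value is the fitted GEV
survival probability at the observed score; with m = 1 this reduces to a
single-placement tail probability.  A simpler construction (Gumbel fitted
by moments to the raw placement scores, then p = 1 − (1 − p₁)^m) was
evaluated and rejected: placement scores are approximately normal, so the
Gumbel grossly overestimates the upper tail and null p-values pile up
near 1 instead of being uniform.  The implemented construction passes a
Kolmogorov–Smirnov uniformity test under the null (α = 0.01, 500
replicates) with the fraction of null p-values below 0.05 close to
nominal.  A degenerate (zero-variance) background returns p = 1 with a
warning.

After assignment, residues are renamed to the aligned target letters and
base atoms are rebuilt from idealized templates superposed on the sugar
anchors, preserving each residue's glycosidic torsion; the backbone is
untouched.

## Sequence identification

Per-residue probabilities are encoded as a multiple sequence alignment:
100 rows per column, round(100·p_purine) purine letters split as evenly
as possible between A and G, the rest split between C and U (T for DNA),
rows shuffled column-independently with a fixed seed so no artificial
row-wise sequence is implied.  The MSA plus the fragment's dot-bracket
pairing pattern (as `#=GC SS_cons`) forms a Stockholm 1.0 file.

Queries run per continuous fragment of ≥ 20 nt and merge hits across
fragments (best E-value per target, 3 returned by default):

- **CM mode** builds a covariance model with `cmbuild`, calibrates it
  with `cmcalibrate`, and searches with `cmsearch` — base-pairing aware.
  This path requires the INFERNAL suite on PATH and raises an actionable
  error naming the missing executables otherwise.
- **HMM mode** ignores pairing.  With INFERNAL present it uses
  `cmsearch --hmmonly` (calibration skipped); otherwise it falls back to
  HMMER (`hmmbuild`/`nhmmer`), the same profile-HMM formalism, with RNA
  mapped to the DNA alphabet (U→T) on both query and database sides.

## Validation (register-shift scan)

Each chain is compared against its own deposited sequence in windows of
20 residues, stride 5.  For every window the p-value of the deposited
placement is compared with that of the best alternative placement; a
window is flagged when the alternative is at least two orders of
magnitude more significant and itself below p = 0.05.  Flags report the
residue range, both offsets and the implied register shift.

## Sequence randomization

For benchmarking, `randomize_sequence` class-swaps a seeded random subset
of ⌊fraction·N⌋ nucleobases (purines to a random pyrimidine and vice
versa).  When a mutated residue is WC-paired, the partner is co-mutated
to the WC complement and counted toward the quota, so canonical pairing
is preserved.  Bases are rebuilt from templates; the backbone is
untouched.

## Synthetic data: what it does and does not emulate

The fixture generator produces ideal A-RNA/B-DNA duplexes (full-atom,
ground-truth pairing attached), hairpins with a deliberately non-helical
loop, density maps simulated as Gaussian atoms, and random sequences.

- **Map model.** density = Σ Z·occ·exp(−|r−r_a|²/2σ²) with σ = 0.225 ×
  resolution (the Fourier amplitude falls to ~1/e at 1/resolution),
  atomic-number weights, grid spacing resolution/3 by default, 5 Å
  padding, optional seeded white noise as a fraction of the map sd.
  This reproduces the resolution-dependent blurring that makes single
  bases ambiguous, but not CTF effects, solvent flattening, anisotropy,
  radiation damage or model bias in crystallographic maps.
- **Consequence for the reported numbers.** Detection recall/precision of
  1.0 and classifier accuracies near 1.0 on these fixtures demonstrate
  internal consistency of the pipeline (generator → detector → classifier
  → assignment closes the loop), not performance on experimental maps,
  which depends on corpora this package does not download.  The study
  sizes used throughout (50 duplexes of 4–20 bp for pair detection, 2000
  balanced descriptors at 3 Å for the classifier, 100 40-mer fragments
  for assignment, 500 replicates for null calibration, 51-sequence
  databases for identification) are the package's fixed desk-scale
  conditions.

## Numerical choices and degenerate inputs

- Altlocs: highest-occupancy conformer kept per atom (ties → 'A');
  hydrogens ignored throughout (unresolved at the target resolutions).
- MTZ maps: Fourier synthesis on a grid at least as fine as d_min/3
  (sample_rate 3), periodic; CCP4/MRC axis order normalized to X,Y,Z on
  read.
- Trilinear interpolation everywhere; periodic wrap for crystallographic
  maps, zero outside the grid for box maps.
- Degenerate ribose geometry (collinear ring atoms) raises a frame error;
  missing anchor atoms skip the residue with a log entry.
- Tie-breaks: smallest offset, then lexicographic target id.

## Known limitations

- Gapless alignment only; register-shift detection emerges from windowed
  comparison, not gapped dynamic programming.
- CM-mode identification requires an external INFERNAL installation.
- The helical reference geometry is idealized; strongly distorted or
  non-canonical helices are matched only through a user-supplied motif
  library.
- Reverse-complement search for DNA duplexes is not attempted by default.
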