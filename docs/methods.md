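# Methods

## The screening model

β-lactam-forming NRPS thioesterase domains are identified by four hallmarks
read off a reference coordinate frame. A query protein is aligned locally
(Gotoh affine-gap dynamic programming, BLOSUM62) against the reference TE
domain; each alignment induces a *position map* from reference residue
numbers to query residue numbers (or "unaligned" where the query has a gap,
"outside" beyond the aligned span). All criteria interrogate the query
through this map, never by absolute position:

1. **Triad & motif.** The nucleophile, aspartate and histidine anchors
   (reference numbering 2818 / 2926 / 2956) are read through the map. The
   aspartate is called *position II* when an Asp/Glu sits at the
   position-II anchor inside the post-β7 loop (reference frame 2923–2946);
   *position I* when an acidic residue instead anchors in the window
   homologous to the loop after strand β6 (2845–2851, the start of the lid);
   *undetermined* otherwise. The criterion additionally requires the exact
   Gln-Cys-Asn motif at 2817–2819 (strict cysteine by default;
   `allow_ser_nucleophile` relaxes it) and His at the His anchor. The
   position call is made entirely at sequence level in the reference frame —
   no secondary-structure prediction on the query — because the windows are
   fixed by the reference structure and the call must be robust for remote
   homologs.
2. **Cationic site.** Arg/Lys at ≥ 2 of the three basic active-site anchors
   (2849, 2854, 2858). Unaligned anchors count as non-cationic.
3. **DAP specificity code.** Adenylation domains are found by local
   alignment to the reference A domain; the *last module* is the A hit
   closest upstream of the TE hit. Ten code residues are extracted at the
   GrsA-frame offsets (235, 236, 239, 278, 299, 301, 322, 330, 331, 517
   relative to the A-domain start) and matched against a substrate→code
   table, ignoring unaligned positions. The criterion passes when DAP
   attains the maximal match count with ≥ 8/10 matches and ≥ 6 mapped
   positions. The shipped table is synthetic configuration: the DAP entry is
   self-extracted from the bundled reference A domain and the other entries
   are decoys ≥ 3 mismatches away. Users screening real data should supply
   a curated table.
4. **Sulfotransferase gene.** A cluster gene passes by annotation keyword
   ("sulfotransferase") or by local alignment to the reference
   sulfotransferase above a score threshold.

A cluster is a *candidate* when ≥ `criteria_min` (default 4) criteria pass;
a cluster in which no gene yields a TE hit is rejected with reason
"no TE domain".

### Thresholds and defaults

| parameter | default | rationale |
|---|---|---|
| substitution matrix / gaps | BLOSUM62, open 11 extend 1 | standard protein-search convention; a gap of length L costs open + L·extend |
| `te_score_min` | 100 raw score | far above the random-alignment regime for a ~260-residue domain vs multi-kilobase NRPS (random maxima ≈ 40–60), far below genuine homologs (self ≈ 1500) |
| `a_score_min` / `sulfo_score_min` | 150 | same reasoning for the ~530/~295-residue references |
| `dap_min_matches` | 8/10 | strict-match convention for high-confidence specificity codes |
| `similarity_threshold` | 0.70 | fraction of alignment columns with positive substitution score; partitions near-identical homologs of the reference from diverged hits worth screening |
| `criteria_min` | 4 | all four hallmarks |

"Similarity" needed an operational definition since search tools report it
without one; here it is the fraction of alignment columns whose residue pair
scores positive (identical residues always count), computed on the local
alignment.

## The synthetic reference

The published reference protein sequence is not redistributed; instead the
package constructs a deterministic synthetic 2984-residue NRPS
(`reference.py`, fixed internal seed) with:

- module layout C-A-PCP-E-C-A-PCP-TE (A domains at 480–1010 and 2070–2600,
  carrier-protein Ser at 2688, TE at 2723–2984);
- every anchor residue planted at its published position (Q2817-C2818-N2819,
  D2926, H2956, R2849/K2854/R2858, lid boundaries G2844/V2918, post-β7 loop
  G2923…V2946 with the Y2932-P2933 helix start);
- the aspartate-position windows scrubbed of stray acidic residues and the
  cationic window scrubbed of stray Arg/Lys so the reference calls are
  unambiguous;
- a module-2 A domain that is a 20 %-diverged copy of module 3 carrying a
  different (Ala-like) code, so "last module" selection is genuinely
  exercised.

Consequences: sequence-level tests validate the *procedure* (anchoring,
mapping, thresholding, aggregation) exactly, but state nothing about real
NRPS sequence statistics — real TE domains share 17–28 % identity with each
other, have non-uniform composition, and homologous non-β-lactam TEs will
produce partial criterion matches that the synthetic decoys (uniform random
proteins) do not emulate. Threshold calibration against real databases is
therefore out of scope here and exposed as configuration.

## Synthetic data generation

`GeneratorSpec` fixes a seed, substitution rate, indel rate, and the planted
feature flags (motif present, Asp at I/II/none, 0–3 cationic positions, DAP
vs foreign A code, sulfotransferase present). Generation order matters:
planted edits are applied first and masked from random substitution, and
indels avoid anchor positions ± 2 residues, so the returned truth labels and
position maps remain exact by construction. Clusters add an optionally
annotated sulfotransferase homolog (mutated at the same rates) and uniform
random decoy genes. Panels randomize the flags per cluster
(position II with probability 0.5, I/none 0.25 each; other flags
Bernoulli(0.5); cationic count uniform on 0–3).

Toy structures are ideal poly-Ala Cα helices (rise 1.5 Å, twist 100°,
radius 2.3 Å), Gaussian coordinate clouds, and rigid-transformed copies with
the rotation/translation recorded; optional isotropic noise σ per coordinate
makes the post-superposition residual ≈ σ√3.

## Phylogeny

Distances are 1 − fractional identity over global alignment columns
(uncorrected by default; an optional Poisson correction −ln(1 − d) is
provided — no substitution model is implied by the data sizes involved).
Trees are built with Saitou–Nei neighbor joining: the pair minimizing the
Q-criterion is joined at each step, ties broken deterministically by the
smaller index pair in input order; negative branch lengths are clamped to
zero with the deficit moved to the sibling branch; the root is the standard
trifurcation of the unrooted tree. On additive matrices NJ is exact
(topology and branch lengths), which the suite verifies on seeded random
trees up to 8 taxa, plus a least-squares quartet oracle and an independent
NJ implementation as cross-checks. Newick output quotes labels containing
metacharacters and prints branch lengths losslessly.

## Structural metrics

- **Parsing.** PDB/mmCIF via gemmi; first model, waters dropped, one altloc
  per atom (highest occupancy by default). Author residue numbering with
  insertion codes is used throughout.
- **Superposition.** Kabsch least squares with the proper-rotation
  correction. Optional refinement iterates ≤ 5 cycles, rejecting pairs that
  deviate by > 2× the current RMSD and refitting on the survivors — a coarse
  stand-in for structure-superposition outlier rejection schedules, whose
  exact published behavior varies by tool; refined RMSDs should be read with
  a few tenths of an Å of tolerance. Cross-protein Cα pairing is mediated by
  global sequence alignment of the chains; exclusion ranges (e.g. the
  flexible lid 2844–2918) are removed before fitting.
- **SASA.** Shrake–Rupley with deterministic golden-spiral sphere points
  (default 960; 4000 brings an isolated sphere within 0.05 % of analytic),
  probe 1.4 Å, Bondi-type radii (C 1.70, N 1.55, O 1.52, S 1.80 Å),
  hydrogens ignored. Buried interface area is
  (SASA_A + SASA_B − SASA_AB)/2 over protein atoms only (cofactors such as
  the pantetheine excluded by default). Published interface areas from
  different programs differ at the 10–15 % level, so comparisons should use
  that tolerance.
- **Helix angles.** The Cα trace is averaged over a one-turn (4-residue)
  window to cancel helical wobble, then the axis is the principal
  eigenvector of the centered coordinates, sign-oriented N→C. Raw PCA on a
  finite helix tilts by ~2° depending on phase; smoothing reduces this below
  0.3°. Angles are reported in [0°, 180°] between *oriented* axes, so
  antiparallel helices read near 180°, not 0°.
- **Triad geometry.** Minimum distance from the His imidazole nitrogens
  (ND1/NE2) to the nucleophile S/O (SG, OG, OG1; CB for Cys→Ala variants)
  and to the Asp/Glu carboxylate oxygens.
- **Radius of gyration.** Mass-weighted by default, unit masses optional.

## Numerical and degenerate-input choices

- Superposition requires ≥ 3 non-collinear pairs (rank check at 1e−8).
- Local alignments with no positive-scoring subalignment return an explicit
  empty result (score 0, empty spans) rather than failing.
- Ambiguity codes B/Z/U are mapped to X with a warning (keeps matrix lookups
  total); any other non-standard character is rejected with its position.
- Distance matrices must be symmetric within 1e−9 with a zero diagonal.
- NJ with < 3 taxa, alignment of empty sequences, helix fits with < 5
  residues, and overlapping interface selections are errors, not silent
  results.

## Known limitations

- The bundled reference, A-domain code table and sulfotransferase are
  synthetic stand-ins; screening real genomes requires substituting curated
  references (a drop-in configuration change).
- The screen is single-reference and alignment-based; it does not use
  profile/HMM models, so very remote homologs below the score thresholds are
  missed by design.
- Criterion 3 reads one code per gene (the A hit nearest upstream of the
  TE); trans-AT style architectures or standalone A-domain genes are not
  modelled.
- Interface areas and refined RMSDs reproduce published values only within
  the method tolerances noted above.
- Tests that recompute geometry from deposited wwPDB entries require those
  coordinate files; all other results are generated offline.
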