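# lactamscan

Structure-guided screening for **β-lactam-forming NRPS thioesterase (TE)
domains** in biosynthetic gene clusters, with the supporting sequence,
phylogeny and structural-geometry machinery.

Monobactam antibiotics such as sulfazecin are released from their
nonribosomal peptide synthetase (NRPS) assembly line by an unusual
thioesterase: instead of hydrolysis or macrocyclization, a cysteine-triad TE
domain closes the four-membered β-lactam ring of an *N*-sulfo-2,3-
diaminopropionate (DAP) residue. Such domains carry recognizable hallmarks,
and `lactamscan` turns those hallmarks into a reproducible four-criteria
screen for gene clusters, aimed at natural-product genome miners:

1. **Triad & motif** — catalytic triad with the aspartate at *position II*
   (on the loop after strand β7 rather than after β6) and the
   **Gln-Cys-Asn** motif housing the nucleophilic cysteine.
2. **Cationic active site** — Arg/Lys at ≥ 2 of 3 basic active-site
   positions that accommodate the anionic sulfamate substrate.
3. **DAP specificity code** — the ~10-residue Stachelhaus/Challis code of
   the last-module adenylation (A) domain best matches DAP activation.
4. **Sulfotransferase gene** — the cluster encodes the sulfotransferase that
   *N*-sulfonates the peptide before ring closure.

Every sequence criterion is evaluated in a reference coordinate frame: query
proteins are anchored to a reference TE/A domain by affine-gap local
alignment (BLOSUM62, gap open/extend 11/1), and reference residue numbers
(e.g. the Cys2818 / Asp2926 / His2956 triad) are carried onto the query
through the alignment's position map.

> **Note on the bundled reference.** The package ships a *synthetic*
> SulM-like reference protein: a deterministic pseudo-random 2984-residue
> NRPS with every anchor residue planted at its published position
> (see `lactamscan/reference.py`). All anchors and thresholds are
> configuration, so a real reference sequence can be dropped in unchanged.

Also included:

- **`pairwise_align`** — global/local Gotoh alignment plus reference→query
  residue-number mapping (the anchoring mechanism).
- **`phylo`** — neighbor-joining trees over 1 − identity distances, Newick
  I/O (β-lactam/β-lactone TEs group with type-II proof-reading thioesterases).
- **`structmetrics`** — PDB/mmCIF reading (gemmi), Kabsch superposition with
  outlier-rejecting refinement, Cα RMSD with alignment-mediated pairing,
  Shrake–Rupley SASA and buried interface area, helix-axis angles,
  catalytic-triad distances, radius of gyration.
- **`synthetic_data`** — seeded generators for every input class (mutated
  NRPS genes with planted/ablated features, labelled cluster panels, toy
  helices and rigid-transformed coordinate sets) so the whole pipeline is
  testable offline with exact ground truth.

## Worked example

```console
$ lactamscan synth demo --outdir demo
demo FASTA (8 TE domains: 4 position-II, 4 position-I) and demo cluster -> demo

$ lactamscan mine demo/demo_cluster.json --out report
1 cluster(s) screened -> report.tsv / report.json

$ cut -f1-5 report.tsv
cluster_id      call    n_passed        te_gene_id      a_gene_id
demo_candidate  candidate       4       nrps1   nrps1
```

The demo cluster carries an NRPS gene (C-A-PCP … TE layout, 2 % mutated
from the reference) plus an unannotated sulfotransferase homolog; the screen
finds the TE domain, reads Q/C/N at the motif anchors, calls the aspartate
at position II, counts 3/3 cationic positions, extracts the last-module A
code (a 10/10 DAP match), detects the sulfotransferase by alignment, and
reports `candidate 4/4`. Dropping the sulfotransferase gene yields
`rejected 3/4` (the criteria minimum defaults to 4; `--min-criteria` relaxes
it).

```console
$ lactamscan tree demo/demo_te.fasta --out demo.nwk
(posI_3:0.0618...,(posI_1:0.0945...,(SulTE_like_3:0.0583...,(SulTE_like_1:...
```

The neighbor-joining tree keeps the four reference-like (position-II) TE
domains and the four diverged position-I domains in separate clades.

```console
$ lactamscan synth structure --seed 2 --sigma 0.3 --out toy.pdb
toy structure (sigma=0.3 A) -> toy.pdb
$ lactamscan struct rmsd toy.pdb toy.pdb --chain-a A --chain-b B
rmsd 0.473 A over 18 Calpha pairs (0 rejected; refine=False)
```

Chain B is a rigid-transformed copy of the 18-residue ideal helix in chain A
with 0.3 Å Gaussian coordinate noise; the superposition residual ≈ σ√3 as
expected. The same `struct` subcommands (`rmsd`, `interface`, `angle`,
`triad`, `rg`) apply to deposited PCP–TE structures, e.g.
`lactamscan struct triad 8W2C.pdb --residues 2818,2926,2956`.

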