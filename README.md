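# cladesig

Discovery of clade-specific molecular signatures — conserved signature
indels (CSIs) and conserved signature proteins (CSPs) — from bacterial
proteomes, together with the core-genome supermatrix phylogeny that
defines the clades being tested.

## Who this is for

Comparative genomicists looking for molecular markers that uniquely
demarcate a bacterial order, genus or species cluster (e.g. the
*Bifidobacteriales* and their *Scardovia*, *Bifidobacterium*–
*Gardnerella* or *B. asteroides* subclades). Given per-genome protein
FASTA files and a taxon→group map, the pipeline:

1. clusters all proteins into families by greedy identity clustering
   (≥50 % identity and ≥50 % alignment coverage of both sequences by
   default) and keeps the **core families** present in ≥80 % of
   genomes;
2. aligns each core family (progressive aligner: 3-mer distances →
   UPGMA guide tree → profile–profile Needleman–Wunsch, BLOSUM62 with
   affine gap penalties 11/1), trims each alignment to conserved
   blocks (relaxed Gblocks-style rule), and concatenates the trimmed
   alignments into a partition-mapped supermatrix;
3. builds a neighbor-joining tree from Poisson-corrected distances,
   midpoint-roots it, and optionally attaches column-resampling
   bootstrap supports (externally computed trees can be imported as
   newick);
4. scans every core-family alignment for **CSIs**: maximal indel
   intervals in which every focal-clade member carries residues while
   every outgroup member is gapped (or vice versa for deletions),
   flanked on both sides by ≥5 conserved columns within a 20-column
   window, with a net length difference between the two groups;
5. calls **CSPs**: proteins whose significant homology hits (e-value ≤
   1e-5) are confined to the focal group, from an external BLAST-style
   tabular hit file or the built-in Smith–Waterman mini-search.

A CSI is interpreted as a rare genetic event in the clade's common
ancestor; its polarity (insert vs deletion) follows from the outgroup
state. Reports mirror the field's signature tables: indel size
(`4 aa ins`, `2–7 aa ins`), indel region in reference-protein
coordinates (`106–144`), specificity, and dash-identity alignment
excerpts (60–100 reference residues, `-` = identical to the top line,
`.` = gap).

Because genome-scale BLAST universes are not reproducible on a
workstation, the package ships a first-class synthetic-data module
that generates proteome sets along a known tree with *planted* CSIs
and CSPs, so every stage can be validated against an exact ground
truth manifest.

## Worked example

```bash
cladesig simulate --seed 7 --out sim/
cladesig run --groups sim/groups.tsv --focal ingroup \
    --out run/ --seed 1 \
    $(for f in sim/*.faa; do echo --proteomes $f; done)
```

`simulate` writes 20 proteome FASTA files (12 ingroup, 8 outgroup
genomes; 100 shared families of ~300 residues; 15 planted CSIs of
sizes 1–7 plus one of 20; 5 ingroup-restricted genes; noise proteins)
plus `groups.tsv` and a ground-truth `manifest.json`. `run` prints
per-stage progress and writes the run directory; on this dataset:

```
clustering: 168 families, 100 core
alignment: 100 families, 30033 trimmed columns
csi-scan: 15 candidates (0 families skipped)
csp-scan: 108 queries, 5 specific
```

`run/csi_candidates.tsv` then lists the 15 recovered signatures with
their sizes and regions, e.g.

```
family_id  reference_id   indel_size  indel_region  specificity
F00020     IN01_SIM0015   20 aa ins   48–107        focal group
F00036     IN01_SIM0001   1 aa ins    151–191       focal group
```

meaning: in the family aligned around reference protein
`IN01_SIM0001`, all 12 ingroup genomes share a 1-residue insertion
absent from all 8 outgroup genomes, inside the conserved region
spanning residues 151–191 of the reference — exactly the planted
events recorded in `sim/manifest.json`. `run/csp_report.tsv` lists the
5 planted ingroup-restricted proteins, and `run/tree.nwk` holds the
midpoint-rooted NJ tree, which separates the ingroup and outgroup
clades.

Every stage is also available separately (`cladesig cluster / align /
trim / concat / tree / csi-scan / csp-scan`) so externally produced
alignments, hit tables or trees can be dropped in at any point.

## Layout

- `src/cladesig/sequence_io.py` — FASTA / newick / group-map /
  hit-table readers and writers (the only module touching files)
- `src/cladesig/core_families.py` — pairwise identity, greedy
  clustering, core-family selection
- `src/cladesig/msa_pipeline.py` — progressive alignment, block
  trimming, supermatrix concatenation
- `src/cladesig/tree_builder.py` — distances, neighbor joining,
  midpoint rooting, bootstrap, Robinson–Foulds
- `src/cladesig/csi_detect.py` — the CSI scanner, polarity calls,
  region mapping, signature excerpts
- `src/cladesig/csp_detect.py` — CSP verdicts and the built-in
  Smith–Waterman search
- `src/cladesig/synthetic_data.py` — tree simulation, sequence
  evolution, signature planting, dataset generation
- `src/cladesig/pipeline.py`, `src/cladesig/cli.py` — configuration,
  orchestration, reports, command-line interface

See `docs/methods.md` for the models, parameter semantics, and the
reasoning behind the numerical choices.
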