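# msacompress

Compress large multiple sequence alignments (MSAs) of multigene protein
families into per-column conservation statistics and render them as
paralogue-template heat-maps.

The intended user studies a protein family with many human paralogues and
thousands of orthologous sequences per paralogue — e.g. the FK506-binding
proteins and cyclophilins (the peptidyl-prolyl *cis/trans* isomerases). One
MSA per orthologue group is far too much to read side by side; this package
reduces each group to two per-column numbers and overlays all groups on the
alignment of the human reference members, so conservation across the whole
family is visible in a single matrix.

## The statistics

For column *j* of a group MSA, with residue frequencies *p₍ₓⱼ₎*:

**Shannon information entropy**

> *Iⱼ* = −Σₓ *p₍ₓⱼ₎* log *p₍ₓⱼ₎*

A fully conserved column has *Iⱼ* = 0; with the logarithm taken to base 20
(the default) the entropy of a residue column is ≤ 1, with equality at the
uniform column, which puts it on the same [0, 1] display scale as:

**Simpson population diversity index (PDI)** over eight physicochemical
residue classes — hydrophobic (A, I, L, V), aromatic (F, Y, W), small (G),
special (C), hydrophilic (N, Q, S, T), negatively charged (D, E),
positively charged (R, K), and H/M/P:

> PDI = 1 − Σᵢ *nᵢ*(*nᵢ* − 1) / *N*(*N* − 1)

the probability that two residues drawn from the column without replacement
fall in *different* classes. A column of chemically interchangeable residues
scores 0 even when the letters differ, so PDI measures chemical rather than
literal conservation.

Heat-map cells are colored white below 0.25 (conserved), then on a linear
green→red gradient up to 1 (maximally diverse); missing cells (template
gaps) are grey.

Around this core the package provides the supporting pipeline: GenBank
flat-file ingest (`.rem`/`.fas`/`.cod` companion outputs), sequence-set
curation (keyword/length filters, exact-sequence deduplication, accession
selection, window trimming), per-sequence physicochemical attributes
(hydrophobicity profiles and index, theoretical pI, moment statistics), and
a seeded synthetic-family generator for testing and calibration. The MSA
step itself is external — curated sets go out to the aligner of your
choice and the aligned files come back in.

## Worked example

Generate a synthetic three-group family (40 positions, 100 sequences per
group, conservation level 0.8), profile every group and assemble the
entropy heat-map:

```
$ msacompress run --seed 7 -o demo
grid 40 positions x 3 groups

$ head -4 demo/heatmap_entropy.tsv
position        grp1    grp2    grp3
1       0.345292        0.242703        0.382993
2       0.348708        0.349874        0.334399
3       0.265775        0.211079        0.398903
```

Each row is one template position, each column one orthologue group, each
cell the base-20 entropy of that group's MSA column aligned to that
template residue. At conservation level 0.8 the generating distribution has
population entropy ≈ 0.35, and the estimates scatter around it; cells at or
above 0.25 render green in `demo/heatmap_entropy.png`, below 0.25 white.
The per-group profile behind a column:

```
$ msacompress stats demo/grp1.fasta -o demo/p.tsv
101 sequences x 40 columns -> demo/p.tsv

$ head -3 demo/p.tsv
position        entropy pdi     gap_fraction    n_effective
1       0.3452921498    0.3532673267    0       101
2       0.3487076267    0.3215841584    0       101
```

With real data the flow is `msacompress ingest` → `msacompress curate` →
external alignment → `msacompress stats` → `msacompress heatmap`; see
`msacompress --help` and `docs/methods.md`.

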