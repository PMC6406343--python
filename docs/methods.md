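# Methods

## Model and procedure

The package treats each orthologue group of a multigene family as an MSA
whose columns are independent categorical samples of residues, and reduces
each column to two statistics.

**Shannon information entropy.** For column *j*, with *nₓ* occurrences of
residue *x* among *N* counted symbols, *p₍ₓⱼ₎ = nₓ/N* and

  *Iⱼ* = −Σₓ *p₍ₓⱼ₎* log *p₍ₓⱼ₎*,  with 0·log 0 ≡ 0.

The sign is chosen so a fully conserved column scores exactly 0 and
variability scores positive. Two log bases are supported: natural, and
base 20 (default), under which a gap-free residue column is bounded by 1
with equality at the uniform column. The base-20 scale is the display
default because the heat-map color thresholds (0.25 and 1.0) are only
meaningful on a normalized [0, 1] scale shared with the diversity index.

**Simpson population diversity index (PDI).** The 20 standard residues are
partitioned into *k* physicochemical classes; with *nᵢ* column residues in
class *i*,

  PDI = 1 − Σᵢ *nᵢ*(*nᵢ* − 1) / (*N*(*N* − 1)),

the unbiased (without-replacement) probability that two residues from the
column belong to different classes. PDI needs *N* ≥ 2 and is otherwise
reported as missing. It is 0 for any within-class column and at most 1.

**Residue classes.** The default scheme has eight classes: hydrophobic
(A, I, L, V), aromatic (F, Y, W), small (G), special (C), hydrophilic
(N, Q, S, T), negatively charged (D, E), positively charged (R, K), and an
eighth class gathering H, M and P. The first seven follow the standard
physicochemical grouping; H, M and P do not fit cleanly into any of them
and are collected into the residual class because the PDI formula requires
every standard residue to have exactly one class. Users studying
histidine- or proline-rich families should override the scheme
(`--classes`, a text file of `name: residues` lines); all statistics and
tests operate identically under any disjoint, total partition.

**Gap policy.** Default `exclude`: gaps and ambiguity codes (B, Z, X, U, O)
are dropped from the counts and *N* shrinks, so the statistics describe the
residues actually present; an all-gap column is missing. Alternative
`as_symbol`: `-` enters the entropy as a 21st symbol, in which case the
natural-log entropy can exceed ln 20 and the base-20 bound of 1 no longer
applies. Ambiguity codes never enter either statistic — they have no class
membership and no defined frequency among the 20 types. Gap fraction is
recorded per column regardless of mode, so no information is lost by
excluding gaps from the entropy.

## Template overlay

The heat-map rows are positions of a reference template alignment — the
aligned family members of one organism (e.g. the human paralogues), one row
per orthologue group. Each group's per-column values are transferred to
template coordinates through the group's reference sequence, which must be
present as a row of the group MSA: the k-th ungapped residue of the group's
template row corresponds to the group-MSA column holding the k-th ungapped
residue of the reference row. This is pure index bookkeeping; no
re-alignment is performed, and a residue-count mismatch between the two
copies of the reference is a hard error rather than a silent shift.
Template positions where a group's template row is gapped have no value.

**Colors.** Values below 0.25 render white (conserved); from 0.25 the color
interpolates linearly in RGB from green (0, 176, 80) to red (255, 0, 0) at
1.0, values above 1 clipping to red. Missing cells render grey — white
means "conserved", not "no data", and the two must not be conflated.
Negative values violate the statistics' contracts and raise. Output
formats: TSV (raw values, 6 decimals), PNG/SVG, XLSX with cell fills.

## Ingest and curation

GenBank flat-file entries are split at `//` boundaries and parsed
individually with Biopython, so one malformed entry (no ORIGIN block, no
accession) is skipped and counted instead of aborting the file. Sequence
letters are upper-cased and non-letters stripped; residues outside the
20 + B/Z/X/U/O alphabet flag the record rather than rejecting it — curation
decisions belong to the user, the tool only surfaces them. Input order is
preserved through every stage, because the downstream alignments keep the
order in which the homology search returned the sequences.

Companion outputs: `.rem` (tab-separated accession, length, organism,
description — the column layout is this package's convention), `.fas`
(FASTA, accession as first header token, 60-column wrap), `.cod` (one
accession per line, the handle for later selection).

Curation removes records by, in order: description keyword
(case-insensitive substring; defaults `synthetic`, `artificial`, `partial`,
`fragment`, `chain `), length outside `[min_length, max_length]`, and exact
duplicate of the full sequence string (first occurrence kept — duplicates
are redundant sequences under different identifiers, so deduplication keys
on the sequence, not the accession). Each record is counted under one
reason, so counts always balance. There is no universal numeric threshold
for "fragment"; the length bounds are user parameters with permissive
defaults (1–10000). Window trimming is 1-based inclusive, matching the
residue numbering used in the structural literature.

## Per-sequence attributes

- **Hydrophobicity**: Kyte–Doolittle values by default (overridable from a
  two-column file). The profile is a centered sliding-window mean (window
  odd, default 9; profile length L − window + 1); the overall
  hydrophobicity index is the mean over the whole sequence. The windowed
  mean is the simplest standard functional and is documented as this
  package's choice. Ambiguity codes carry no value and drop out of window
  means.
- **Theoretical pI**: root of the Henderson–Hasselbalch net charge
  (N-terminus + K, R, H positive; C-terminus + D, E, C, Y negative),
  located by bisection on [0, 14] to 1e-4 pH units — the charge is strictly
  decreasing in pH so the root is unique. pKa defaults are the EMBOSS
  values (overridable); tables differ by a few tenths of a pH unit, which
  is why the table is a parameter rather than a constant.
- **Moments** across a set: mean, sample standard deviation (n − 1
  denominator), skewness as the (biased) third standardized central moment,
  and *excess* kurtosis (normal → 0). A constant sample has σ = 0 and
  missing skewness/kurtosis (0/0).

## Synthetic families

The generator emulates column-wise conservation structure: each position of
each group carries a categorical residue distribution, sampled i.i.d.
across sequences, with i.i.d. gap placement at a per-position rate. The
one-parameter default maps a conservation level *c* to probability *c* on a
consensus residue and (1 − *c*)/19 on each other residue, giving
closed-form population entropy and class diversity for parameter-recovery
tests. Each group MSA includes its consensus as the reference row, and the
template is the alignment of these consensus rows. All randomness flows
from one integer seed; identical seeds give byte-identical output files.

What it does *not* emulate: phylogenetic correlation between sequences
(there is no tree or substitution model), alignment error, indel structure
beyond i.i.d. gaps, or composition bias. Passing recovery tests therefore
shows that the estimators converge to the truth of this sampling model —
not that real orthologue sets, whose sequences are correlated and unevenly
sampled across taxa, yield unbiased entropy estimates. On real data the
plug-in entropy estimator is biased downward at small N, of order
(K − 1)/(2N ln base).

Recovery-study conditions used by the test suite: one group, 60 positions
with conservation levels evenly spanning 0.05–0.95, no gaps, depths
N ∈ {10, 100, 1000}, fixed seed. Mean absolute error of the base-20
entropy falls monotonically with depth and is within 0.05 at N = 1000.

## Numerical notes and limitations

- Entropy and PDI are exact rational/log computations per column; a fully
  conserved column returns exactly 0.0 (single term with p = 1), not a
  rounded value.
- Missing values are NaN throughout; TSV files carry them as empty cells.
- The bisection tolerance (1e-4 pH) bounds the pI error; the net charge at
  the returned pI is correspondingly small but not exactly zero.
- Sequence weighting, relative entropy against a background composition,
  and other column scores are out of scope; the two statistics above are
  the deliberate core.
- The CLI never runs an aligner; alignment quality is the user's
  responsibility and column statistics inherit any alignment error.
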