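# Methods

## The problem

Mass-spectrometry immunopeptidomics measures the mixture of peptides eluted
from all MHC molecules a cell expresses: a typical human cell line presents
ligands of up to six HLA class I molecules (HLA-A/B/C, two alleles each) or
of several class II molecules (e.g. DRB1 plus a linked DRB3/4/5), and the
immunoprecipitate additionally carries co-purified contaminant peptides.
Motif deconvolution partitions such a multi-allelic peptide list into
per-allele clusters, each characterized by a binding motif. This package
implements the *supervised* approach: instead of clustering the sequences
de novo, every peptide is scored against each of the sample's declared
alleles, and assigned to the allele with the best (lowest) percentile rank —
or to a TRASH cluster when no allele plausibly explains it.

## Scoring backend and percentile ranks

The deconvolution logic is predictor-agnostic: it needs, for every
peptide x allele pair, a raw score, a percentile rank, and the 9-mer binding
core. Two backends satisfy that contract:

1. **External prediction tables.** Long-format TSV exported from any
   eluted-ligand predictor.
2. **The built-in PSSM backend.** Each allele is a 9x20 log-odds matrix
   `w[i][a] = log2(p_target[i][a] / q[a])` over the binding-core positions
   P1..P9 (columns in the fixed order `ACDEFGHIKLMNPQRSTVWY`). A peptide's
   raw score is the maximum window sum over all contiguous 9-mers, the
   argmax window being the reported binding core (ties go to the leftmost
   window). This mirrors how class II ligands bind: a 9-residue core in the
   groove with overhanging flanks.

Length handling in the PSSM backend: the same window maximization serves
class I and class II. Length-8 peptides — a real minority of class I
ligands — are scored over the nine single-position deletion registers (one
core position bulges out of the groove; the gap contributes 0, the log-odds
of background against itself). Peptides shorter than 8 residues get raw
score −inf (rank 100); no sub-core binding mode is modeled. The length
*preference* terms of neural eluted-ligand predictors are deliberately not
modeled; consequently trash capture of contaminants is driven purely by
motif mismatch (see Limitations).

**Percentile ranks.** For each allele, `n_bg` random natural peptides
(residues i.i.d. from a background frequency table, lengths uniform over the
active length window) are scored and their sorted scores stored. The rank of
a query score `s` is `100 · #{background ≥ s} / n_bg`: 0 means the score
beats every random natural peptide, 100 that none scores below it. Ranks are
therefore uniform on (0,100] for peptides drawn from the calibration
distribution — a property the test suite checks with a Kolmogorov–Smirnov
statistic (< 0.02 at n = 10,000 fresh peptides against a curve calibrated
with the default n_bg = 100,000).

Defaults and units: `n_bg = 100,000` per allele (empirical rank resolution
0.001%); calibration lengths pooled uniformly over the same window used to
filter the sample's peptides (class I 8–14, class II 13–21), because the
max-over-windows score grows with peptide length and a mismatched
calibration window would bias ranks by length. The default background is a
natural-protein amino-acid frequency table (Robinson–Robinson, renormalised);
a uniform 1/20 background is available. Ties count as "≥" per the rank
definition.

## Assignment and the trash cluster

After length filtering (user window, class defaults above) and
deduplication, each unique peptide is assigned to the allele with the
minimum rank, **unless** every rank is strictly greater than the trash
threshold (default 20% rank), in which case the peptide is treated as a
co-immunoprecipitated contaminant and lands in TRASH. The boundary is
inclusive for assignment (best rank exactly 20.0 is assigned); setting the
threshold to 101 disables the trash cluster. Exact rank ties break to the
lexicographically first allele name, making the assignment deterministic and
independent of input order. For class II runs contaminated by class I
ligands, an explicit prefilter removes peptides whose best class I rank is
≤ 2% (the conventional class I binder threshold) before assignment.

The sklearn-facing surface (`PSSMRankScorer` → rank matrix,
`MotifDeconvolver` → labels) exposes exactly this computation as a
transformer/classifier pair; the module-level functions wrap those classes.

## Reporting

Cluster motifs are built from the assigned peptides' predicted 9-mer cores:
raw per-position relative frequencies (no pseudocounts, no sequence
weighting), per-position information as the Kullback–Leibler divergence
`info_i = Σ_a p_ia log2(p_ia / q_a)` (bits, `0·log 0 ≡ 0`) against a uniform
background by default, and letter heights `p_ia · info_i` (the non-negative
rendering of the frequency-weighted KL logo; raw `p` and `q` are exported so
renderings that draw depleted residues below the axis can be layered on).
Logos are suppressed — counts still reported — for clusters under
`min_logo_peptides` (default 10). Cluster contributions are reported against
two denominators (all assigned peptides incl. TRASH, and allele-annotated
only), with display rounding half-up to integer percent. Motif consistency
across samples sharing an allele is the Pearson correlation of the flattened
9x20 frequency matrices (180-vectors, position-major order); constant
vectors make a pair's PCC undefined (reported missing, excluded from the
mean). Repertoire overlap between two co-expressed alleles classifies each
peptide as a binder of either, both, or neither at a 1%-rank threshold.

## Evaluation protocol

Benchmarks with known single-allele origin are scored through a
true-label x assigned-cluster confusion matrix (TRASH column included).
Anonymous clusterings are first mapped to alleles by the majority rule (an
allele claims the non-trash cluster holding most of its peptides; conflicts
resolve by descending dataset size, then lexicographically, the loser taking
the best remaining cluster). Per allele X with cluster C_X: TP = X-peptides
in C_X; FP = other alleles' peptides in C_X (trash is never a mapped
cluster); FN = X-peptides elsewhere, trash included; TN = other alleles'
peptides outside C_X, trash included — this tiling keeps TP+FP+FN+TN equal
to the matrix total. MCC uses the standard closed form with the MCC ≡ 0
zero-denominator convention; methods are compared by the median per-allele
MCC. Significance: peptides are resampled with replacement (default 100
replicates), the confusion matrix, mapping and median MCC recomputed per
replicate, and the 2.5/97.5 percentile interval reported.

## Synthetic data generator

The generator emulates multi-allelic eluted-ligand datasets with known
truth labels. A mock allele is a set of anchor positions with residue
frequency maps (non-anchors follow the background); its scoring matrix is
the log-odds of those target frequencies (floored at 1e-3 before the log).
Peptides are sampled by drawing a length from a class-specific distribution
(class I peaks at 9-mers over 8–14; class II at 15-mers over 13–21,
matching eluted-ligand length profiles), drawing a 9-mer core positionwise
from the target frequencies, then padding with background flanks at a
uniform offset (class II) or applying the middle-bulge convention (class I:
8-mers delete core position 5; longer peptides insert background residues
between core positions 5 and 6). Contaminants are random background
peptides. Everything is reproducible from a single seed.

Two bundled presets mirror the published artificial benchmark designs:
`classI_paper` (1000 ligands from each of four A/B-like alleles + 200 from
each of two weak-motif C-like alleles — the 5:1 abundance of HLA-A/B over
HLA-C) and `classII_paper` (800 ligands from each of four DR-like alleles).
Design choices in the preset motifs:

- Anchor residue sets are **per-position disjoint** across alleles, so
  cluster identifiability is controlled by design rather than by accident.
- Every spec carries one weak full-alphabet auxiliary position (a mild
  power tilt of the natural background). Real motifs are never exactly
  background off-anchor, and without it PSSM scores collapse onto few
  distinct values, whose rank ties distort the empirical calibration.
- The two C-like alleles are "weak" (max anchor frequency 0.3–0.35 spread
  over 4 residues, ≈5.5 bits of anchor information vs ≈9 for A/B-like) but
  mutually and externally distinct, so a supervised method can still
  resolve them at 5x lower abundance.

The generator also provides the benchmark-hygiene k-mer overlap filter
(drop candidates sharing a contiguous k-mer, k = 8 or 9, with an exclusion
set such as a predictor's training data) and the scrambled-peptide null
model (each peptide permuted `n_scrambles = 100` times, best rank over
scrambles and alleles retained, subsampled to match the source length
histogram exactly — per-length without replacement when the pool allows).

### What the synthetic benchmark does and does not show

Generated peptides are ideal motif samples and the deconvolution uses the
*generating* models, so recovery there measures the assignment machinery
(rank calibration, argmin-with-trash, evaluation protocol), not predictor
quality on real spectra. Real data add identification errors,
post-translationally modified sequences, shared/overlapping motifs between
alleles, expression-level differences and length-preference effects that
this generator does not model. In particular, **random-contaminant trash
capture is bounded**: a contaminant drawn from the same distribution as the
calibration peptides has, by construction, a Uniform(0,100] rank per
allele, so the probability that all k alleles exceed a 20% threshold is at
most 0.8 (perfectly dependent ranks) and ≈ 0.8^k when nearly independent
(≈ 41% for k = 4; the measured value). Higher capture rates on real data
come from predictor terms (length preference, context) that penalize
contaminants beyond motif mismatch, which the PSSM backend intentionally
omits.

## Numerical choices and degenerate inputs

- Alphabet: strictly the 20 canonical residues; entries containing
  B/J/O/U/X/Z are excluded at input with a logged, row-addressed count.
- Coordinates: core offsets are 0-based, cores half-open `[off, off+9)`.
- Ranks are printed with 4 decimals; write→read round-trips preserve them
  to that precision.
- Zero-count frequency cells are exactly 0 (no pseudocounts); KL terms use
  `0·log 0 ≡ 0`.
- Empty inputs, incomplete rank tables, zero denominators and constant
  PCC vectors raise or report "undefined" explicitly rather than
  returning 0.
- Deterministic tie-breaks throughout (leftmost window, lexicographic
  allele, fixed cluster-mapping order); all randomness flows from explicit
  seeds (`numpy.random.default_rng` / `SeedSequence.spawn`).

## Problem sizes

The bundled studies run at the published benchmark scale: 4,400 class I and
3,200 class II benchmark ligands, 10% injected contaminants, rank
calibration with 100,000 background peptides per allele, KS uniformity at
10,000 fresh peptides, oracle equivalence at 10,000 (MCC) / 1,000 (PSSM,
rank) random cases, bootstrap at 100 replicates.

## Known limitations

- No binding-affinity (IC50) output, no probabilistic/multi-allele soft
  assignment: every peptide gets exactly one cluster.
- Percentile ranks are pooled over the active length window, not
  length-binned.
- The PSSM backend cannot substitute for trained neural predictors on real
  data; it is the reference backend for testing the deconvolution and for
  synthetic studies. Real-data use should feed external prediction tables.
- Post-translationally modified peptide strings are not parsed; only plain
  sequences are accepted.
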