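# Methods

This note documents the models and procedures implemented in
`splicescan`, the defaults they ship with and why, and what the
synthetic data used throughout the test suite does and does not show.

## Problem setting

Eukaryotic introns almost always start with GT and end with AG, but a
genome contains orders of magnitude more GT/AG dinucleotides than real
splice sites (only ~0.1% of them are real in human).  A spliced aligner
choosing among sequence-equivalent junction placements therefore needs a
model of the splice *context* — the exonic bases before the donor, the
GTRAGT extension, the polypyrimidine tract and YAG before the acceptor,
and longer-range exon/intron composition.  `splicescan` learns that
context with a small CNN, converts its outputs into genome-calibrated
log-odds scores, and exposes them to a spliced-alignment DP.

## Classifier

Input: one-hot 4×L matrix of the window (L = 2·flank+2, default 202;
102 and 302 are supported).  `N` becomes an all-zero column and is
accepted at both training and scan time, since genome scans will
encounter N runs.

Stack (valid convolutions, bias-free; ceil-mode max-pooling of width 3):

| layer              | output (202 bp) | parameters |
|--------------------|-----------------|-----------:|
| conv 16×4×5        | 16×198          | 320        |
| ReLU + pool 3      | 16×66           |            |
| conv 16×16×5       | 16×62           | 1280       |
| ReLU + pool 3      | 16×21           |            |
| dense 336→16 +bias | 16              | 5392       |
| ReLU, dense 16→2   | 2 (softmax)     | 34         |

Total 7026 trainable parameters; at 302 bp the last pooling layer is
16×32.  Both values are enforced at construction for any configuration
claiming the canonical two-layer/16-feature/kernel-5 family, so a shape
regression fails immediately with the computed count and pool shape in
the error message.  These two constraints jointly pin the stack: with
convolution biases included there is no integer pool/dense configuration
reaching the same parameter count, which is why the convolutions are
bias-free and the hidden dense layer has 16 units.

Donor and acceptor examples are pooled into one joint model (the central
dinucleotide disambiguates the type at query time); per-type training
remains available via `train --site-type donor|acceptor`.

## Training

- Loss: softmax cross-entropy, optimizer Adam with decoupled weight
  decay.  Defaults: learning rate 3e-3, batch 64, weight decay 0.3,
  ≤ 20 epochs, early stopping after 3 epochs without validation
  improvement, best-epoch weights restored.  The optimizer settings are
  not part of the method's definition; they were chosen once by
  validation cost on the reference synthetic dataset (weight decay in
  particular roughly halves the generalization gap on ~13k training
  examples, validation cost 0.105 vs 0.124 without) and are all
  flag-exposed and recorded in the training log.
- Splits: contigs alternate train-pool/test-pool by FASTA order ("odd"
  = 1st, 3rd, …).  Genes on odd contigs are shuffled and split 80/20 at
  the *gene* level so isoforms sharing a junction can never straddle the
  boundary.  The test set is every window-fitting GT/AG candidate on the
  even contigs, labeled by the annotation.
- Negatives: unannotated GT/AG on the strand opposite an annotated gene
  span; regions covered by genes on both strands are excluded outright.
  Downsampling to 3 negatives per positive is done per site type and per
  partition (the ratio's scope is not pinned by the method's published
  description; per-type keeps donor/acceptor balance independent).
- Windows overrunning a contig end are skipped, never padded — padding
  would plant an artificial composition signal at fixed positions.

## Calibration

Raw scores are binned evenly (`i = ⌊tb⌋`, b = 50 by default, `t = 1`
clamped into the last bin) and transformed to
`s_i = 2·log2(P_i/(P_i+N_i) · (P+N)/P)`: the log odds of the bin's
empirical splicing probability against the uniform null, in half-bit
units so the scores compose with BLOSUM-scaled alignment scoring.
Degenerate bins: an empty bin inherits the nearest non-empty lower bin
(score floor −20 when none exists below); a bin with no positives is
floored at −20, finite so the aligner's arithmetic stays well-defined
while still meaning "effectively never spliced".  The deployed table is
fitted on the even-contig whole-genome scan by default — the transform
is meant to correct the downsampled training prior toward the
genome-wide prior — with `calibrate --on validation` as the alternative.

## Genome scan

Every GT (donor) and AG (acceptor) on both strands is scored; records
carry forward-genome boundary offsets (plus-strand intron =
`[donor_offset, acceptor_offset)`, minus-strand mirrored) and are sorted
by (contig, offset).  Contigs are processed independently and windows in
bounded batches, so peak memory does not scale with genome length.
Scores print with 2 decimals — 0.01 half-bits is far below any effect
the alignment DP can resolve.

## Spliced alignment

Four-state DP: H (match), E/F (affine gaps in reference/query), and an
intron state entered by paying `d(i) + q̃` at a donor boundary and left
by paying `a(i)` at an acceptor boundary.  Calibrated scores map to
penalties as `pen = max(0, base − min(w·s, cap))` with defaults base 12,
weight 1, cap 12 (half-bit units): score 12+ makes a boundary free,
score 0 costs the full base, negative scores cost more than base.  The
published recurrence does not pin this mapping; the testable contract is
monotonicity (higher score ⇒ cheaper intron ⇒ junction preferred), which
the suite asserts, including the exact flip point on a constructed
three-way-ambiguous junction.  Boundaries without a score record are
forbidden by default; `--allow-unscored` prices them at
`base + noncanonical_extra`.

Scope and mechanics: global in the query with free reference ends (a
transcript fragment inside a genomic window); full O(n·m) matrices, no
seeding, banding or chaining — this is a correctness reference, not a
production aligner.  Minimum intron length (default 4) is enforced by
delaying intron-state entries; the maximum (default 50 kb) expires the
stored best open intron, which is exact unless a better-but-younger
entry was displaced earlier — impossible in this package's uses, where
introns are far below the bound.  Tie-breaking is deterministic: state
priority diagonal > intron > E > F, then the smaller reference index.
Traceback re-derives predecessors from the stored matrices (tolerance
1e-6 on float64 sums of small rationals) and emits M/I/D/N CIGARs;
identity = matches / (M+I+D columns).

## Evaluation

ROC curves are computed over all scanned candidates (each GT/AG is one
test instance) with scikit-learn, keeping every threshold point.  The
headline metric is rAUC: the area under the curve restricted to
TPR ≥ 0.5 and FPR ≤ 0.1, rescaled by the 0.05 rectangle so rAUC ∈ [0,1],
integrated with trapezoids and explicit interpolation at both region
borders (so values are implementation-stable).  Junction accuracy is
exact-coordinate and strand-aware, with junction sets de-duplicated on
both sides; `% unannotated = 100·(1 − annotated/predicted)`, undefined
(reported as n/a) when nothing is predicted.

## Synthetic data

The simulator emits background DNA at a configurable GC (default 0.40)
and plants, for every annotated intron, a 9-position donor motif
(`MAG|GTRAGT`) and a 14-position acceptor motif (10-base polypyrimidine
tract + `YAG|G`), each position emitting its consensus set with
probability `strength` (default 0.9) and the GT/AG core always forced.
`strength = |S|/4` degenerates a position to uniform background, giving
a clean no-signal control.  A `gc_rich` mode raises intron GC to 0.64
to emulate the GC-rich introns of mammals and birds for composition-
sensitivity checks.  Genes are placed without overlap, ≥ 210 bp from
contig ends so every window is extractable.

Reference conditions used by the acceptance run: 8 contigs × 300 kb,
1000 five-exon genes (exons 80–200 bp, introns 60–400 bp), strength 0.9
— about 4k positive training sites on the odd contigs and ~290k
scanned candidates on the even contigs.  Under these conditions the
trained CNN reaches rAUC ≈ 0.86; an exact likelihood-ratio scorer built
from the true planted-motif distributions reaches ≈ 0.90, so the CNN
recovers most but not all of the available signal.

What this does not show: real genomes have exon/intron composition
differences, length distributions, branch points without fixed
positions, alternative isoforms and annotation errors, none of which
the simulator reproduces.  Passing tests demonstrate that the
implementation is faithful (labeling rules, formula identities, DP
optimality, end-to-end signal recovery), not that the model reaches any
particular accuracy on real data.

## Numerical and design choices

- All coordinates are 0-based half-open; GTF/GFF3 1-based inclusive
  inputs are converted on read.  "Odd chromosomes" means odd 1-based
  index in FASTA order, which generalizes to arbitrary assemblies.
- The score-file dialect is 5 fixed columns (contig, offset, strand,
  D/A, score); only the offset and score columns are forced by the
  method's published interface, the rest is this artifact's convention.
- BED12 carries no gene column, so `gene_id` is recovered from the
  transcript name's prefix before the last dot (`g7.t2` → `g7`), else
  the whole name; the simulator and converters follow this convention,
  making writer∘reader the identity.
- DP matrices are float64 with −1e18 as the impossible value;
  forbidden splice penalties are +inf (guarded so no inf−inf arises).
- Model containers are `.npz` files holding the weight arrays, the
  config as JSON, the training log and (after calibration) the count
  table; the calibration is embedded so a model/table mismatch cannot
  occur downstream.

## Known limitations

- GC..AG and AT..AC introns are not scored or aligned; non-canonical
  annotated junctions are skipped at training time.
- The aligner is quadratic and unseeded; genome-scale alignment is out
  of scope.
- Calibration on the even-contig scan consumes the same contigs used to
  report rAUC (the rAUC itself is computed on raw scores, and the
  monotone binning cannot change it).
- The early-stopping patience acts on consecutive non-improving epochs;
  plateaus with tiny oscillations can stop training before the budget
  is spent.
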