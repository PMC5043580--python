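# Methods

## Motif scoring model

A motif is a position probability matrix (PWM) `p[i, b]` over A, C, G, T.
A window `w` of the same width scores

    S(w) = Σ_i log2( p[i, w_i] / bg(w_i) )   [bits]

against a zero-order background `bg`, estimated by default from the pooled
scanned sequences (pseudocount 1 per base) and overridable with explicit
frequencies.  A motif instance is recorded wherever `S ≥ θ` on either
strand; the default threshold is **θ = 6 bits**, the conventional cutoff of
CLOVER-style scanners.  Both the log base and θ are configurable because
published "score 6" cutoffs do not pin down the score's base and
normalization; we document ours as bits and keep it fixed everywhere.

Numerical choices:

* **Pseudocount.**  Library matrices are normalized position-wise after
  adding 1e-4 to every count cell, so public matrices containing literal
  zeros cannot produce −∞ log-odds.  An explicitly zero pseudocount plus an
  all-zero position is a parse error, not a silent NaN.
* **Ambiguity codes.**  Any non-ACGT base voids its window (score −∞): a
  window containing N can never pass a finite threshold.  This is
  conservative and exactly testable.
* **Reverse strand.**  The minus-strand score of a window is the score of
  its reverse complement under the PWM, with the background applied to the
  complemented bases — equivalently, the log-odds matrix itself is
  reverse-complemented.  With this definition the hit count is invariant
  under reverse-complementing the input sequence for *any* background, even
  a strand-asymmetric one, and the test suite asserts it.
* **Overlapping hits.**  All windows above threshold on both strands are
  counted.  A greedy best-score-first overlap merge is available as a flag
  but is off by default: unsuppressed counting is the simplest well-defined
  rule, and the feature values are per-kilobase rates for which suppression
  heuristics only add hidden parameters.
* **PWM similarity** (for grouping redundant motifs) is the maximum, over
  all ungapped offsets and over the second motif versus its reverse
  complement, of the mean column-wise Pearson correlation across
  overlapping columns (≥ 4 columns, or the full shorter width).  Uniform
  (zero-variance) columns contribute 1 when identical and 0 otherwise.  The
  score is symmetric and lies in [−1, 1]; it deliberately replaces
  tree-based motif clustering, which is out of scope.

## Feature matrices and splits

Cell (i, j) of the raw matrix is the hit count of motif j in peak i (both
strands).  Counts stay integers until the explicit per-kilobase
normalization `count / (length/1000)`, and the normalized flag travels with
the matrix so downstream stages can refuse the wrong form (binarization,
for instance, only accepts raw counts).  Positive and background matrices
are stacked with class labels, and the 75/25 train/test split is
**stratified per class** and seeded.  Stratification is a design choice:
the protocol partitions each dataset separately, and stratification is the
deterministic version of that intent.

## Matched random backgrounds

Backgrounds are drawn with the template's exact length multiset, placed by
rejection sampling uniformly over the allowed regions (a region is chosen
with probability proportional to its number of valid start offsets, then a
uniform offset).  Lengths are placed in descending order to reduce
failures; placement is retried up to 1000 times per interval and then
fails loudly naming the length.  Outputs avoid the excluded set (by
default the template itself) and each other.  Excluding the real peaks
prevents label leakage into the negative class; a flag restores
unconstrained placement.

## Classifier and penalty selection

The classifier is logistic regression with an L1 penalty.  The penalty
grid is glmnet-style: 100 log-spaced values from λ_max (the smallest λ at
which the null model is stationary, so all coefficients are exactly zero)
down to 0.001·λ_max.  Features are standardized internally (constant
columns are left constant and therefore get zero weight); coefficients are
mapped back to the motifs/kb scale.  Ten-fold stratified CV, seeded, gives
a per-λ AUC mean and standard error; the CV folds share one λ grid.
Coefficients with |w| < 1e-8 are clipped to exactly zero (the usual
numerical thresholding for coordinate-descent solutions).

Two selection rules:

* **1-s.e. rule**: the largest λ whose CV AUC is within one standard error
  of the best CV AUC (ties resolved toward larger λ).
* **Knowledge-based rule**: the largest λ at which the anchor motif(s)
  retain nonzero coefficients (`any`/`all` modes for multiple anchors).
  If the anchor is never active the rule fails with an explicit "anchor
  not informative" error; if the anchor re-enters non-contiguously along
  the path, the largest qualifying λ is returned with a warning rather
  than silently picking an interior point.

The knowledge rule trades performance for interpretability *by
construction*: at its λ the anchor has only just entered, so the model is
informationally close to a cofactors-only model, and its held-out AUC sits
slightly below the 1-s.e. model's.  That is the intended behaviour — the
smallest model that still contains the prior knowledge.

Comparators — a linear-kernel max-margin classifier with penalty C chosen
by seeded 10-fold CV over decade steps 1e-5..1, and a 500-tree ensemble
with √p features per split — are library-backed and exposed through the
same predict/metrics interface; they serve as reference points, not as the
method.

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
FDR FP/(TP+FP) (= 1 − PPV whenever defined); zero denominators yield NaN
sentinels, never exceptions.  The classification cutoff for confusion
counts is 0.5 by default and recorded in every report.  ROC curves come
from the full threshold sweep; the AUC is the trapezoidal area, which with
tied scores collapsed equals the average-rank Mann–Whitney statistic (the
tests verify equality against a pair-counting oracle to 1e-12).

## Replicate concordance

Two replicate peak sets are partitioned by coordinate overlap (≥ 1 shared
base by default, minimum-fraction optional) into A (unique to set 1),
B1/B2 (the overlapping peaks, from each side) and C (unique to set 2).
Concordance is then measured where it matters — at the model level:
cross-prediction rate of one replicate's model on the other's peaks,
per-subset positive-prediction rates, the Jaccard overlap of the two
models' active features, and a *direct contrast* model that classifies
experiment-of-origin with the same machinery (near-random held-out AUC
means the replicates share grammar).

## Synthetic study conditions

The generator's defaults define the study conditions used throughout the
tests: 500 positives per replicate and 500 backgrounds; peak lengths
Normal(500, 120) truncated to [100, 1200] bp; genome GC 0.42; anchor motif
planted in 60% of direct positives; four cofactor motifs planted
independently at 40% each, leaking into backgrounds at 5%; 50 decoy motifs
never planted; 15% of positives *indirect* (no anchor, at least one
cofactor — tethered binding); replicate coordinate overlap 55% with reused
coordinates jittered by up to 10% of peak length; decoys and anchor never
planted in backgrounds.  A genome of ~3 Mb with 5 kb allowed regions
separated by 500 bp gaps comfortably hosts all placements.  These sizes
keep a full ten-seed study under two minutes on one CPU while leaving all
rates at their stated values.

Two generator choices deserve explanation:

* **The anchor PWM is short and soft** (width 8, dominant-base probability
  0.88), like real homeodomain elements of low information content.  It is
  detected in ~75% of its planted instances at θ = 6 and accrues ~0.4
  chance hits per peak in *both* classes.  This is deliberate: a crisp,
  long anchor would be the single strongest feature and would enter the
  lasso path first, making anchor-retention vacuous (a one-motif model).
  The noisy anchor enters after the four cofactors — the regime the
  knowledge rule is designed for.  Cofactor and decoy PWMs are long and
  sharp (cofactors width 16–18), so planted cofactor instances are
  recovered essentially always while chance hits stay rare.
* **Reproducibility is strength-biased.**  Replicate 2 reuses replicate-1
  coordinates sampled with probability ∝ (1 + planted-motif count):
  grammar-dense, strongly bound peaks reproduce preferentially, as in real
  repeated experiments where weak peaks hover at the detection threshold.
  This single mechanism produces the characteristic concordance pattern:
  shared (B) subsets are predicted better than replicate-unique (A/C)
  subsets, while direct-contrast models stay near AUC 0.5 because the
  underlying grammar is identical.  The exponent (`reproducibility_bias`)
  is configurable; 0 restores uniform reuse.

What the generator does *not* emulate: higher-order sequence composition
(the background is order-0), chromatin and nucleosome structure,
peak-calling artefacts, copy-number or mappability biases, and motif
co-occurrence *dependencies* (plantings are independent given the peak
class).  Passing tests therefore demonstrate that the pipeline recovers a
planted grammar under its own statistical assumptions — not that real
peaks are this clean.  In particular, real-data AUCs are expected to be
lower and model sizes larger than the synthetic ones.

Ground truth records every planted instance (peak, motif, offset, strand)
and every peak's class and provenance; any recorded planting is
recoverable by the scanner at its recorded position when the threshold is
set below that instance's score, and the tests assert this.

## Degenerate inputs and determinism

Empty sequences scan to empty hit lists; sequences shorter than the motif
width are not an error.  Zero-length intervals are rejected at BED parse
time with a line number.  Identical peak sets are rejected for direct
contrasts (duplicate rows across classes).  Every stochastic step — genome
synthesis, placement, planting, splits, CV folds, comparator seeds — flows
from explicit integer seeds, and pipeline reruns with the same
configuration are byte-identical (floats serialized at 12 significant
digits).

## Known limitations

De novo motif discovery is out of scope; the library analyses known PWMs
(imported via MEME-minimal, JASPAR PFM or TRANSFAC formats).  The
co-occurrence reports are descriptive proportions without significance
tests.  PWM similarity is an alignment score, not a clustering, and motif
redundancy is not collapsed before model fitting — correlated motifs split
coefficient mass, as is inherent to the lasso.  The anchor-exclusive
fraction's denominator is all peaks by default (frequency subtraction); a
per-motif-conditioned variant is provided because the natural-language
definition is ambiguous, and reports label which was used.
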