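# Methods

## Problem setting

Given molecules described by named binary fingerprint bits (presence /
absence of substructures or properties) and labeled active or inactive in a
phenotypic screen, the package builds and evaluates classifiers that
predict the label of new molecules. It was designed around the shape of
cell-line screening data — large, chemically diverse, with many near-
duplicate analogues inside chemical series — but is agnostic to where the
bits come from: any 0/1 table with a label column is accepted, and native
computation provides RDKit MACCS keys plus a shipped SMARTS key set.
Count-valued fingerprint families are out of scope; all statistics assume
bits.

## Single-fingerprint statistics and selection

For fingerprint *i*, the class means F_i^A and F_i^I are exact bit
fractions (integer bit counts divided by the class sizes N_A, N_I). The
compound score of molecule *j* is C_score = F^A − F^I when bit D_i^j = 1
and F^I − F^A when 0, so one bit yields at most two distinct scores. The
decision rule "active iff C_score > t" is swept over the midpoints of the
distinct observed scores plus one sentinel beyond each extreme — this is
the complete threshold sweep for a two-valued score, without an arbitrary
grid. The best threshold maximizes MCC; ties break toward higher
sensitivity, then lower threshold. AUC is the rank statistic over C_score.
A constant column, or one with F^A = F^I, is flagged degenerate and
reported with MCC 0 and AUC 0.5.

Selection keeps fingerprints with MCC **strictly** greater than the cutoff
(default 0.2), ranked by MCC descending with deterministic tie-breaks
(accuracy descending, then name ascending); an optional top-k truncates
after filtering. Ranking is a pure function of the statistics, so it is
stable under permutation of its input and idempotent.

## Potency score

Ts1(X,Y) = |X∧Y| / |X∨Y| over set bits; Ts0 is the same coefficient on the
complemented vectors, i.e. agreement in *absences*. The complement reading
of Ts0 is the natural set-algebraic one and is enforced by a test
(Ts0(x,y) = Ts1(¬x,¬y) bit-exactly). When a denominator is empty (both
vectors all-zero for Ts1, all-one for Ts0) the similarity is 0 with a
degeneracy flag: absence of shared evidence is not similarity.

The potency score of a query is
Ps = max(HaTs1, HaTs0) − max(HnTs1, HnTs0), where Ha/Hn are the highest
similarities to any active / inactive reference. Ps ∈ [−1, 1] and negates
when the reference classes are swapped. Classification is active iff
Ps > threshold; a score exactly at the threshold is called inactive (one
convention applied uniformly to the compound, potency and hybrid scores).
Similarity is computed on the selected fingerprint subset only. The bulk
scorer uses float64 matrix products of the bit matrices, which keeps the
small integer intersection/union counts exact, so it agrees bit-for-bit
with the scalar implementation (verified against exhaustive enumeration).
An `exclude_id` argument (and an `exclude_self` diagonal mask in the bulk
path) removes a molecule from its own reference set, guarding duplicate
leakage when calibrating on training data.

## Margin scorer, normalization, hybrid

The margin scorer is an RBF-kernel SVM (scikit-learn SVC) with defaults
γ = 0.1, C = 6 and class-cost ratio j = 1; j multiplies the error cost of
the active class, mirroring the asymmetric-cost option of classic SVM
tools. Features are the selected bits in a fixed name order; a persisted
model refuses tables missing any training fingerprint.

The SVM decision value is unbounded while Ps is already in [−1, 1], so
both are mapped to [−1, 1] before averaging. The map is affine min–max on
the **training** scores with clipping outside the observed range; a
degenerate calibration (min = max) maps everything to 0. Min–max was chosen
over rank or z-scaling because it is monotone (ranks and AUC preserved),
bounded, and parameter-free; fitting it inside the training fold is the
only leakage-free choice. The hybrid score is the arithmetic mean of the
two normalized scores.

## Evaluation protocol

Stratified 5-fold cross-validation, repeated (default 20 times; every
report is the mean over repeats with its standard deviation). Stratification
keeps per-fold class balance stable, which matters for the similarity
reference sets. Inside each training portion the fingerprint statistics,
selection, reference set, SVM and both calibrations are refit from scratch;
the held-out fifth is scored, the five folds' test scores pooled, and
metrics computed on a fixed threshold grid (−1.0 … 1.0, step 0.2) plus a
rank-based AUC. A `fixed_fingerprints` argument pins a global list instead
of per-fold refitting, for reproducing a published bit selection.

Metric conventions: sensitivity/specificity/accuracy as percents, MCC by
the four-count formula with any zero denominator factor giving 0, FPR =
FP/(FP+TN), AUC as the Mann–Whitney rank statistic with averaged ties
(equal to the trapezoidal ROC area, enforced by an oracle test). Reports
round to two decimals; the underlying objects keep full precision.

On data with no usable signal the strict MCC cutoff can select nothing,
which would leave the scorers undefined; after filtering, the top 10
ranked fingerprints (`min_k`) are kept as a floor. This choice only
activates when the cutoff rejects (nearly) everything — on null data — and
makes the permutation behaviour of the full pipeline measurable; it does
not affect datasets with real signal.

Where the repeat count of the protocol could be read two ways (a procedural
"repeat 20 times" versus an aggregate phrased as 25 folds), the implemented
default is 5 folds × 20 repeats = 100 test folds, with `repeats`
configurable.

## Functional-group profiling

Groups are SMARTS patterns in an editable `name<TAB>pattern` file; the
shipped vocabulary covers ROH, ROR, RCOR, RCOOR, RCHO, RCOOH, RNH2, R2NH,
R3N, RCN, RNO2, RSH, RSR, RX, phenol and aromatic N. Counts are distinct
substructure matches with symmetric duplicates merged (glycerol → 3 ROH).
Per class, F_G is the percent of molecules with count ≥ 1 and M_G the mean
count; for purely binary counts M_G = F_G/100 exactly. The vocabulary is
configuration, not code, because published group-perception schemes differ
in unverifiable details.

## Synthetic data generator

The generator emulates the statistical structure of a screening benchmark,
not its chemistry: independent Bernoulli bits with class-dependent presence
probabilities for informative bits (defaults 0.9 active / 0.1 inactive),
a common background rate (0.3), and two optional structures — a fraction of
actives (default 0.3) replaced by clones of other actives with a 5 %
per-bit flip rate, mimicking chemical-series redundancy that similarity
methods exploit; and XOR bit pairs whose marginals are 0.5 in both classes
but whose interaction carries the label, signal only a non-linear margin
model can use. Defaults are 1000 molecules per class and 100 bits with 10
informative. Everything is a deterministic function of the seed, and the
planted bit names are returned for recovery tests.

What passing on this generator does **not** show: real fingerprints are
correlated within families, class priors are imbalanced, activity labels
are noisy near the assay threshold, and similarity structure is far
richer than clone-with-flips. Results on the generator validate the
machinery (selection recovers planted signal at its analytic MCC; the
pipeline's cross-validated MCC exceeds 0.7 under the default conditions;
permuted labels drive MCC to 0 and AUC to 0.5) — they are not estimates of
performance on screening data.

## Problem sizes used in checks

The automated checks run the pipeline at desk scale: 2000-molecule
benchmarks for end-to-end cross-validation (5 folds × 5 repeats), 1000
molecules per class for planted-bit recovery, and ≥1000 random instances
per exactness oracle. The published-scale benchmark (8565/9804 molecules ×
9365 bits) is supported through the same interfaces by importing an
external fingerprint table.

## Known limitations

* Only binary fingerprints; no count or continuous descriptors.
* Native fingerprint schemes (MACCS, shipped SMARTS keys) are not
  bit-compatible with other generators; treat external tables as the
  ground truth for cross-tool comparisons.
* The potency score computes all pairwise similarities per fold (O(n²)
  in dataset size); no approximate nearest-neighbour indexing.
* No hyperparameter search and no probability calibration for the SVM.
* Metric consistency of one published comparison table could not be fully
  verified: reconstructing confusion counts from its SVM rows' sensitivity
  and specificity reproduces the MCC but not the printed accuracies
  (discrepancy 0.06–0.15), an internal inconsistency of the source table;
  the corresponding checks are left failing by design.
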