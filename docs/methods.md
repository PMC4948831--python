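# Methods

## Problem

qiRNAs are DNA-damage-induced small interfering RNAs of *Neurospora
crassa*, typically 20–21 nt, best distinguished from other small RNAs by
two positional preferences: uracil at the first (5') base and adenine at
the last (3') base. `qirnaforest` classifies short RNA sequences as
qiRNA-like versus background using positional log-odds features and a
random forest, and provides the surrounding machinery: negative-set
construction, F-score feature ranking, cross-validated evaluation, and a
synthetic data generator so the whole pipeline is testable without any
external download.

## Positional log-odds (PPM) features

Positions are indexed 1..w from the 5' end and −1..−w from the 3' end
(default w = 10, i.e. ten positions per end). From a training set of each
class we build a position probability matrix (PPM): the fraction of
contributing sequences carrying nucleotide *i* at position *j*. Sequences
shorter than w are skipped (not padded); sequences shorter than 2w
contribute their middle bases to *both* the 5'-anchored and the 3'-anchored
cell, since the two windows overlap on such short RNAs. Each PPM column
sums to 1 by construction.

From the positive-class PPM *P* and negative-class PPM *N* the score of
nucleotide *i* at position *j* is

    S(i, j) = log2(P_ij / N_ij),

set to 0 when `P_ij = N_ij` (no information) and also when either
probability is 0 — a zero cell in a PPM estimated from ~150 sequences
reflects sampling, not infinite evidence, so the guard replaces ±∞ with 0.
No pseudocount is added by default (the guard is the default behaviour);
an additive pseudocount is available as an option.

Each sequence is encoded as a `4·2w`-vector (80 features at w = 10): the
slot for `(i, j)` holds `S(i, j)` if the sequence carries nucleotide *i*
at position *j*, else 0. This one-hot-masked encoding yields
sequence-specific vectors compatible with per-feature F-scores and forest
training; a binary (indicator-only) variant is available for sensitivity
analysis. Feature names follow the `jN` convention (`1U`, `10C`, `-1A`).

## k-mer features

For comparison, sequences can be encoded as overlapping k-mer frequencies
for k = 1..kmax: the count of each of the 4^k strings divided by
L − k + 1. At kmax = 5 this is 1364 dimensions. The two encodings can be
concatenated (names are prefixed `ppm:` / `kmer:` to stay unique).

## F-score feature ranking

The discriminative power of feature *i* is

    F(i) = [(x̄⁺ᵢ − x̄ᵢ)² + (x̄⁻ᵢ − x̄ᵢ)²] /
           [ s²⁺ᵢ + s²⁻ᵢ ]

with class means x̄⁺, x̄⁻, overall mean x̄, and within-class *sample*
variances (ddof = 1). Larger F means better separation. A zero denominator
with positive numerator (perfect separation, zero within-class variance)
is flagged infinite and ranked first; 0/0 (a constant feature) scores 0.

## Negative-set construction

Given a FASTA pool of longer non-coding RNAs:

* **random** negatives: the pool is cut into non-overlapping segments,
  each segment's characters are uniformly permuted, and segments are
  sampled without replacement so the length histogram equals the
  positives' exactly. A single uniform permutation is used per segment:
  composing many uniform shuffles is distributionally identical to one,
  so repeated-shuffle protocols are reproduced by `--shuffle-rounds`
  without changing behaviour. Mononucleotide shuffling is the default; a
  dinucleotide-preserving (Eulerian-walk) mode is available.
* **fragment** negatives: the same pipeline without permutation, so every
  negative is a verbatim pool substring — an analogue of degradation
  fragments of longer small RNAs.
* curated confusable sets (e.g. fungal milRNAs) are imported as plain
  FASTA; their curation is literature work outside this package.

Fragmentation visits pool sequences in seeded random order and cuts left
to right, drawing each cut's length from the lengths still in demand
(weighted by remaining demand); this guarantees disjoint source intervals
and exact coverage whenever capacity suffices, and raises an explicit
shortfall error listing deficient lengths otherwise. Candidate segments
identical to a positive sequence are rejected (a ~10% spare demand is cut
when the pool allows, so rejected candidates can be replaced). Whether to
shuffle before or after length-matched sampling is underdetermined; this
package shuffles all candidates before sampling.

## Classifier

The forest is scikit-learn's `RandomForestClassifier` behind a fixed
contract: 500 trees and ⌊√d⌋ candidate features per split by default, no
class reweighting by default (a balanced option exists), bootstrap
sampling with out-of-bag accuracy recorded. Scores are the forest's
averaged per-tree positive-class probabilities, which for fully grown
trees coincide almost everywhere with the fraction of positive votes; they
lie in [0, 1]. The decision rule is `score ≥ cutoff → positive` (ties go
positive), default cutoff 0.5, with 0.667 documented as a stringent
cutoff trading sensitivity for specificity when shortlisting candidates
for experiments.

A trained model bundles the training-time score matrix and feature spec,
so novel sequences are always featurized with training statistics — never
with statistics of the query set. Persistence uses joblib with a schema
and version check.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/total (percentages printed
to two decimals), MCC = (TP·TN − FN·FP)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
An MCC with a zero marginal is reported as 0 with an `mcc_undefined` flag.
For balanced evaluation sets Ac = (Sn+Sp)/2 exactly. ROC curves sweep the
score threshold over distinct scores; AUC is the trapezoidal area, equal
to the tie-corrected Mann–Whitney concordance (tested against an O(n²)
pair-counting oracle).

Cross-validation (k-fold for any k ≥ 2, or leave-one-out) is stratified
by class and seeded. Within each fold the PPMs and score matrix are
rebuilt from the training samples only, both folds are featurized with
that training matrix, and held-out scores from all folds are pooled into
the headline confusion matrices (at cutoffs 0.5 and 0.667) and one
ROC/AUC. LOO forces pooling; k-fold uses the same convention for
comparability, with per-fold metric rows additionally reported (per-fold
rows are omitted for LOO, where single-sample folds have no meaningful
confusion matrix). Computing the PPMs globally before splitting leaks
held-out labels into the features and inflates performance; the leaky
variant is available as `global_ppm=True` (with a logged warning) for
sensitivity comparisons only.

## Synthetic data generator

Negatives are i.i.d. draws from a background composition (default
uniform); positives are identical except position 1 is U with probability
`pos_first_U` (default 0.8) and position −1 is A with probability
`pos_last_A` (default 0.7), otherwise drawn from the background
renormalized over the remaining three bases. Lengths are drawn from
`length_weights` (default 20 and 21 nt, equally likely). The default
signal strengths are generator choices — strong enough to be clearly
learnable yet imperfect at n = 155 per class — not measured frequencies
from any organism. The generator emulates only the two documented end
preferences; real data additionally carry weak internal-position
structure, non-uniform background composition and length–composition
correlations, so passing tests demonstrate that the pipeline recovers
planted positional signal, not field performance on real small-RNA
collections.

## Numerical and design choices

* PPM column normalization is exact by construction; tests tolerate 1e−9.
* Score-matrix and F-score implementations are vectorized; tests compare
  them to naive brute-force evaluation at 1e−9.
* Fold seeds and segment-shuffle seeds are spawned from the user seed via
  `numpy.random.SeedSequence`, so runs are reproducible end to end and
  independent components receive independent streams.
* Exact duplicate removal keeps the first occurrence; identity is
  full-string equality after normalization (uppercase, T→U). Strand or
  orientation variants are not collapsed.
* Problem sizes in the test suite and acceptance script: the end-to-end
  checks run leave-one-out on 155+155 synthetic sequences with 500-tree
  forests (the package's default study condition), the null control uses
  10-fold CV on the same sizes, and formula oracles run on randomized
  inputs of n ≤ 50.

## Known limitations

* The per-sequence encoding of positional scores (one-hot-masked values)
  is one of several defensible readings of "scores as features"; the
  binary variant is provided to probe sensitivity to this choice.
* Scores are tree-probability averages, not strict vote counts; the
  distinction matters only for trees with impure leaves.
* The dinucleotide shuffle uses rejection sampling over Eulerian walks
  and may (very rarely, with a logged warning) return its input.
* No secondary-structure or precursor-context features; feature selection
  beyond F-score ranking is out of scope.
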