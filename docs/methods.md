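# Methods

## Model and procedure

`enhmom` treats enhancer identification as two stacked binary
classification problems over hand-crafted sequence features. A dataset
D = D⁺ ∪ D⁻ of enhancers and non-enhancers, with D⁺ further partitioned
into strong and weak enhancers, is represented per sequence by a
102-dimensional super feature vector with fixed block layout

    seq_moments[30] | prim_moments[30] | rprim_moments[30]
    | fdv[4] | aapiv[4] | raapiv[4]

and boundaries (30, 60, 90, 94, 98, 102) that are part of the public
contract. Layer 1 (enhancer vs. non-enhancer) is trained on all rows;
layer 2 (strong vs. weak) on true enhancers with known strength only —
not on layer-1 predicted positives — matching the benchmark's design.
The features assume fixed-composition windows of roughly uniform length
(nominally 200 bp); no positional alignment between sequences is implied.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| nucleotide encoding | A=1, C=2, G=3, T=4 | integer codes for the sequence matrix (alphabetical) |
| Hahn shape x, y | 0, 0 | shape of the Hahn weight; 0,0 gives the symmetric (discrete-Chebyshev) case |
| moment degree | ≤ 3 | ten moments per family, order (j+k) ≤ 3 |
| PRIM order | 1 | 4×4 incidence matrices feed the SFV; orders 2–3 for heatmaps only |
| n_trees | 100 | forest size per layer |
| max_features | sqrt | feature subsetting per split |
| search space | 5–500 | tree-count range for successive halving |
| seed | 7 | all stochastic components (forests, folds, simulation) |

The nucleotide → integer map is the single most consequential free choice:
every sequence-matrix moment depends on it. It is therefore exposed in the
feature config and recorded in every feature-table header, alongside the
Hahn parameters and software version.

## Numerical choices

**Hahn basis.** The degree-m polynomial is the classical discrete Hahn
polynomial Q_m(i; x, y, N−1), evaluated as a terminating ₃F₂ sum with
multiplicative term updates (every factor is O(N²), so degree-3 evaluation
cannot overflow even at N = 64), and weighted by the binomial-product
weight ρ(i) = C(x+i, i)·C(y+N−1−i, N−1−i) computed in log-Gamma space.
The square norm k²_m is accumulated numerically as Σᵢ Q_m(i)²ρ(i) rather
than taken from a closed form, which makes row orthonormality exact by
construction up to rounding (observed ≤ 2·10⁻¹⁵ across supports 2–64).
The complete-basis transform is an isometry; the inverse transform
reconstructs random grids to ≤ 10⁻¹⁴. Formulations of this polynomial
family circulating in the applied literature are frequently garbled; we
verified numerically that our polynomial/weight pair is orthogonal before
adopting it (no positive weight can orthogonalize the common mistyped
variant — the pairwise-orthogonality constraint system is full rank).

**Moment conventions.** Grid indices are 1-based in the raw/central
moments so that the centroid M₁₀/M₀₀ is meaningful (0-based indexing
would zero out first-row contributions). The reshape pads with 0, which is
neutral under all three moment families. An all-zero matrix (impossible
for real sequences, possible for degenerate incidence matrices) yields
zero moment vectors plus a logged warning instead of aborting the run.
Grids smaller than 4×4 cannot support degree-3 Hahn moments; the
unavailable orders are reported as 0 with a warning, preserving the fixed
102-slot layout for sequences as short as 4 bp.

**Incidence rule.** The PRIM entry is fixed as
N(x→y) = Σ_p (p − f(x)) over all occurrences p of y, with f(x) the first
occurrence of x and zero rows for absent symbols. This concrete rule uses
all occurrences, is position-sensitive and sign-preserving; the verbal
descriptions in the literature fix the ingredients (positions of y
relative to x's first occurrence) but not the formula, so the rule is
stated here and enforced by oracle tests. k-mer tokenization for orders
2–3 is overlapping (step 1), maximizing incidence counts on 200 bp input.

**AAPIV.** Fixed as per-nucleotide sums of 1-based occurrence positions;
the circulating printed formula (β_i = Σ S_j) does not reference i and is
not implementable literally. FDV stores raw counts (a normalized variant
is a config flag); no feature scaling is applied anywhere since trees are
scale-equivariant.

**Metrics.** Zero denominators yield NaN as an explicit undefined
sentinel, except MCC where 0/0 conventionally maps to 0. The conventional
and Chou formulations are both implemented and agree to 10⁻¹⁶ on random
confusion matrices. Cross-validation uses stratified seeded folds
(balanced classes per fold, lower variance than plain random splits) and
pools predictions into one confusion matrix for headline metrics —
deterministic given the fold assignment — while retaining per-fold metrics
for dispersion and per-sequence scores for ROC/PR. ROC/AUC and PR/AUPR
come from scikit-learn's threshold sweep (trapezoid AUC, step-wise
average precision); tests cross-check AUC against a brute-force
Mann–Whitney pair count.

**Successive halving.** The tree-count tuner draws eight geometrically
spaced candidates from the search space, evaluates survivors on doubling
training fractions (final rung = full data), and eliminates the worse
half per rung, with OOB error as the default criterion (a held-out
validation split is available). Budget, halving factor (2) and resource
definition are this package's choices; deterministic given the seed.

## The synthetic generator

`simulate_dataset` draws sequences i.i.d. per position from class-specific
nucleotide distributions: non-enhancers uniform (0.25 each); enhancers
shift probability mass from A/T toward C/G, mimicking the GC-richness of
regulatory DNA. With per-nucleotide shift s, the distribution is
(0.25−s, 0.25+s, 0.25+s, 0.25−s) over (A, C, G, T); strong enhancers use
s = effect/4 and weak s = effect/8, so the two strengths differ by a
further effect/8 and, at effect = 1, the strong class reaches the extreme
(0, .5, .5, 0) while all probabilities remain valid. Defaults mirror the
benchmark layout: 742 strong + 742 weak vs. 1484 non-enhancers, 200 bp,
effect 0.6 (a clearly separable but not saturated setting), seed 7.

What the generator does **not** emulate: motif structure, positional
signal, chromatin-state or histone-mark correlates, homology/redundancy
between sequences, and realistic GC heterogeneity within a class. Passing
tests on this generator therefore demonstrate that the pipeline recovers
*compositional* class separation end-to-end and that all numerics are
correct — not that real enhancer benchmarks reach any particular accuracy.
Published benchmark results additionally depend on unstated choices
(nucleotide encoding, incidence formula, forest seed) that this package
fixes explicitly, so exact reproduction of printed accuracies is out of
scope; given the benchmark FASTA files the full two-layer 5-fold protocol
runs end-to-end and reports every headline metric.

## Problem sizes used in validation

The acceptance script validates numerics on 100 random 5×5 matrices, 1000
random confusion matrices and 100 random sequences; recovery runs use 200
sequences per class (effect 1 and effect 0), and the benchmark-scale run
uses the full 1484-per-class layout at 200 bp. These sizes give stable
statistics (binomial standard errors ≤ 2.5 % on recovery accuracies) while
keeping a full validation run under a minute on one CPU.

## Known limitations

* The i.i.d. compositional generator makes the classification task easier
  than real enhancer discrimination; its accuracies are upper bounds on
  nothing and should not be quoted as benchmark performance.
* Layer-2 training requires known strength labels; enhancers of unknown
  strength are excluded with a warning rather than imputed.
* Sequences shorter than 10 bp carry partially zero-filled Hahn blocks
  (grid < 4×4); all other features remain informative.
* The cascade prediction mode thresholds both layers at 0.5; per-layer
  evaluation is the primary, default mode.
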