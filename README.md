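# enhmom

Enhancer identification from DNA sequence via statistical moments and a
two-layer random forest.

Enhancers are short regulatory DNA segments (roughly 50–1500 bp) that boost
transcription of target genes, often across large genomic distances.
Locating them — and grading their regulatory potency as strong or weak — is
a long-standing sequence-classification problem in regulatory genomics.
`enhmom` implements a feature-engineering approach for fixed-length
(nominally 200 bp) candidate segments: each sequence is summarised by a
102-dimensional **super feature vector (SFV)** and classified by a cascade
of two random forests — layer 1 separates enhancers from non-enhancers,
layer 2 separates strong from weak enhancers.

## The feature vector

For a sequence *S* = Y₁Y₂…Y_w over {A, C, G, T}:

1. **Sequence moments (30).** Residues are encoded numerically (A=1, C=2,
   G=3, T=4 by default) and filled row-major into a *d* × *d* matrix with
   *d* = ⌈√w⌉, zero-padded. From this grid three moment families are
   computed up to combined degree 3, ten moments each in the fixed order
   (00, 01, 10, 11, 02, 20, 12, 21, 30, 03):
   - raw moments M_jk = Σ_a Σ_b a^j b^k f(a, b), with 1-based indices;
   - central moments μ_jk, the same sums about the centroid
     (M₁₀/M₀₀, M₀₁/M₀₀), so μ₁₀ = μ₀₁ = 0 identically;
   - Hahn moments H_uv, the projection of the grid onto discrete
     orthogonal Hahn polynomials whose weighted values form an orthonormal
     basis under summation (the complete transform is invertible, so the
     spectrum preserves the grid's information).
2. **Position-relative incidence matrices (30 + 30).** The PRIM is a 4 × 4
   matrix whose entry N(x→y) accumulates, over every occurrence of
   nucleotide *y* at position *p*, the signed offset *p* − f(x) from the
   first occurrence f(x) of nucleotide *x*; rows of absent nucleotides are
   zero. The RPRIM applies the same rule to the reversed sequence. Each
   matrix contributes its own 30-moment block. (16 × 16 and 64 × 64
   di-/tri-nucleotide variants are available for dataset-level heatmaps.)
3. **Positional vectors (4 + 4 + 4).** The frequency distribution vector
   (FDV, per-nucleotide counts), the accumulative absolute position
   incidence vector (AAPIV, per-nucleotide sums of 1-based occurrence
   positions) and its reverse-sequence counterpart (RAAPIV).

Both forest layers use 100 bootstrap trees with √-of-feature-count
subsetting (the tree count is tunable by successive halving over 5–500,
with the out-of-bag error as criterion). Evaluation supports 5-fold,
10-fold and jackknife (leave-one-out) cross-validation with pooled
confusion matrices, sensitivity/specificity/accuracy/MCC in both the
conventional and the Chou-style intuitive formulation, and ROC/PR curves
with AUC/AUPR.

## Worked example

Simulate a small two-layer dataset (100 sequences per layer-1 class,
200 bp, GC-shift effect 0.6), extract features, and cross-validate both
layers:

```sh
enhmom simulate --n 100 --length 200 --effect 0.6 --seed 7 --out sim/
enhmom extract --non-enhancers sim/non_enhancers.fasta \
    --strong sim/strong_enhancers.fasta --weak sim/weak_enhancers.fasta \
    --out features.tsv
enhmom cv --features features.tsv --layer 1 --k 5 --seed 7 --out cv1/
enhmom cv --features features.tsv --layer 2 --k 5 --seed 7 --out cv2/
```

which prints (layer 1 then layer 2):

```
wrote 200 x 102 feature table to features.tsv
{"sn": 99.0, "sp": 99.0, "acc": 99.0, "mcc": 0.98, "auc": 0.9992, "aupr": 0.9992}
{"sn": 100.0, "sp": 100.0, "acc": 100.0, "mcc": 1.0, "auc": 1.0, "aupr": 1.0}
```

Sn/Sp/Acc are pooled 5-fold percentages; MCC ∈ [−1, 1] and AUC/AUPR ∈
[0, 1] are fractions. The synthetic classes are strongly separated at
effect 0.6, so near-perfect pooled metrics are the expected outcome; each
`cv*/` directory also contains per-fold metrics, per-sequence predictions
and ROC/PR point tables. Real benchmark FASTA files are loaded the same
way (one file per class), and `enhmom train` / `enhmom predict` fit and
apply a persistent two-layer model.

`enhmom inspect AACGAACGAACGAACG` dumps the reshaped matrix and the three
10-moment vectors for one sequence, e.g. the 16-residue repeat reshapes to
four identical rows `1 1 2 3` and has raw moments starting
M₀₀ = 28, M₀₁ = 84, M₁₀ = 70.

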