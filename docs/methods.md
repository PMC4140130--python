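# Methods

## Model and procedure

`enrichsel` treats disease-gene identification as binary classification in
an enrichment-score feature space. The assumptions are:

* disease genes act through their interaction neighborhoods, so the
  functional profile of a gene's closed neighborhood (the gene plus its
  direct partners) carries the discriminative signal;
* annotation terms (GO terms, KEGG pathways) are the right functional
  vocabulary, and the hypergeometric upper tail against a fixed background
  is the right measure of neighborhood enrichment;
* negatives can be sampled uniformly from the non-positive universe, and
  class imbalance is handled by splitting negatives into portions rather
  than by reweighting.

The score for gene *g* and a term annotating *M* of *N* background genes is
`-log10 P(X >= m)` with `X ~ Hypergeometric(N, M, n)`, where `n` is the
neighborhood size and `m` its annotated-member count. The upper tail runs
from the observed `m` inclusive (not `m+1`, not two-sided). `m = 0` always
gives probability 1 and score 0.

Feature selection is three-staged per balanced dataset: a Cramér's-V filter
against the class label (threshold 0.1, values equal to the threshold are
kept), greedy mRMR ranking with the mutual-information-difference (MID)
criterion over the survivors, and incremental feature selection: every
prefix of the mRMR list is scored by stratified 10-fold cross-validation of
a linear-kernel soft-margin SVM (C = 1), pooling fold predictions into one
confusion matrix. The smallest prefix attaining the maximum Matthews
correlation coefficient is that dataset's optimal feature set; the union
over datasets is the final optimal set.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `negative_ratio` | 50 | negatives sampled per positive; the reference design (39 positives → 1,950 negatives) |
| `n_splits` | 10 | portions the negatives are split into; also the number of balanced datasets |
| `cramer_threshold` | 0.1 | V below this excludes a feature; equality keeps it |
| `max_ranked_features` | 500 | truncation of MaxRel/mRMR lists, bounding IFS cost |
| `cv_folds` | 10 | stratified folds; each sample is tested exactly once |
| `svm_kernel`, `svm_c`, `svm_degree` | linear (polynomial degree 1), C = 1 | the classifier's plain defaults; Gaussian kernel available |
| `discretization` | `three_state_mean_sd` | bins (−∞, μ−σ], (μ−σ, μ+σ), [μ+σ, ∞) per feature per dataset, shared by the Cramér and mRMR stages; `zero_vs_positive` is offered for the zero-inflated score distributions |
| `closed_neighborhood` | true | include the gene itself in the evaluated set; makes isolated genes well-defined (n = 1). An open-neighborhood switch gives the partners-only reading |

## Synthetic data

The generator emulates the statistical structure the method assumes: an
Erdős–Rényi network on `n_genes` (default 200, edge probability 0.03,
i.e. mean degree ≈ 6 — sparse, like a confidence-thresholded interaction
network), annotations drawn per gene × term at `base_annot_prob` (0.05),
and a planted subset of `n_informative_terms` (20) whose annotation
probability rises to `base + signal_strength` (0.55) for every gene within
distance one of a positive. Signal is planted in neighborhoods, not in
positives alone, because the encoder scores neighborhoods — this is the
structure the method can in principle detect. A toy hierarchy with three
roots (biological-process / cellular-component / molecular-function
analogues) and one category child each, GO terms dealt round-robin, makes
category reporting exercisable.

What it does **not** emulate: scale-free degree distributions, correlated
annotations between related terms, multi-parent GO topology, or curated
negative sets. Passing tests on this generator show the pipeline's
mechanics and its ability to recover planted neighborhood signal; they say
nothing about performance on real interaction networks.

With a 200-gene universe the reference `negative_ratio` of 50 is
infeasible (only 185 non-positives exist), so the default synthetic run
uses ratio 12 — the largest integer ratio the universe supports — while
keeping the 10-way split. Each balanced dataset then has 33 samples
(15 positives, 18 negatives).

## Numerical and design choices

* **Tail computation**: `scipy.stats.hypergeom.sf(m-1, N, M, n)`; validated
  against exact rational enumeration on a full lattice up to N = 30 at
  1e-12 relative error. Tails below 1e-300 clamp the score at 300 so
  matrices stay finite without affecting rankings.
* **Discretization boundaries**: values equal to μ−σ fall in the low bin
  and values equal to μ+σ in the high bin (closed outer intervals); a
  constant feature maps entirely to the middle bin.
* **Cramér's V**: plain Pearson χ² with no continuity correction — the
  coefficient is a ranking device, not an inference; rows/columns with zero
  marginals are dropped, and degenerate tables score 0.
* **mRMR**: MID (difference) rather than MIQ (quotient), matching the
  canonical program's default; plug-in mutual information in bits; ties in
  both MaxRel and the greedy step break toward the earlier feature in term
  order, making runs exactly reproducible.
* **Cross-validation**: folds are stratified (with 15–39 positives per
  dataset, unstratified folds can lack positives entirely) and fold
  predictions are pooled into a single confusion matrix ("each sample is
  tested once"). Standardization statistics are computed inside each
  training fold only.
* **Metric conventions**: any metric with a zero denominator returns 0.
* **Optimal-set ties**: the smallest prefix attaining the maximum MCC wins.
* **Background**: N is the union of genes in the network and annotation
  files unless an explicit background list is supplied. Genes in the
  positive/negative lists but absent from the background are dropped with a
  warning rather than aborting the run.
* **Seeding**: one master seed; per-stage seeds derive from CRC32 hashes of
  stage names, all below 2^31.
* **Pipeline idempotence**: a run directory with an existing manifest is
  not recomputed unless forced (run-level resume).

## Known limitations

* **Selection optimism.** Following the original study design, the Cramér
  filter and mRMR ranking are computed on the full dataset before the
  cross-validation inside IFS, so the test folds have already influenced
  feature selection. The resulting MCC values are optimistically biased —
  severely so when the feature count is large relative to the sample size
  (at the default synthetic scale, 33 samples against ~200 surviving
  features, even label-permuted data can reach near-perfect curve maxima).
  Absolute MCC values from this pipeline should therefore not be read as
  generalization estimates; the planted-term recovery rate, the null
  uniformity of planted-term ranks, and the signal-strength monotonicity of
  recovery are the calibrated checks of what the method detects. A
  leakage-free variant would nest all selection inside the CV loop, at
  roughly tenfold cost; it is not part of the reference procedure and is
  not implemented.
* The percentage denominator in category summaries counts all hierarchy
  descendants of a category, which is one of several defensible readings.
* Problem sizes in the test-suite experiments (for example 200-gene
  networks, 10 datasets of 33 samples, 5-seed replicates) are the
  package's chosen desk-scale reference conditions; larger simulations
  change runtimes, not the code paths.
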