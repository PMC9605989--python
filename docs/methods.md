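# Methods

## Problem setting

`dcgs` addresses genomic prediction in panels composed of a few
interconnected biparental families — the typical situation in perennial
breeding programs, where generating large unstructured populations is
impractical. In such panels most marker variance reflects family
structure, and the linkage phase between a marker and the QTLs it tags is
set by each family's parental haplotypes. A model pooled across families
therefore learns marker effects that do not transfer — the same tag can
carry the opposite sign in the next family — which is why pooled ridge
(BRR-type) and kernel models show weak accuracy on new genotypes in this
regime.

The package implements a two-stage ("divide and conquer") predictor:

1. **Divide / route.** A classification network assigns an unlabeled
   genotype to a subpopulation from its markers. Family membership is a
   strong, nearly linearly separable signal when families have diverged,
   so this stage is expected to be essentially error free.
2. **Conquer / regress.** A regression network trained only on that
   family's individuals, on that family's own marker subset, predicts the
   genotype's trait BLUP.

## Phenotype pipeline

Raw trial measurements are rank-normalized with an ordered-quantile
transform (rank *r* of *n* maps to Φ⁻¹((r−0.5)/n), ties averaged, then
centered/scaled). The transform is deterministic and rank-preserving; a
frozen record applies it to new values by interpolation. We fix this one
transform rather than running a per-trait transform competition: it is
the recommended default for arbitrary distributions and keeps results
reproducible.

The trial model is a linear mixed model with design factors (location,
block-in-location, watering regime; or block, line-in-block,
rank-in-line for single-site row-column trials) as fixed effects and
genotype as the single random effect:

y = Xβ + Z_g u + e,  u ~ N(0, σg² I),  e ~ N(0, σe² I).

REML profiles the variance ratio λ = σe²/σg²: after rotating into the
eigenbasis of Z_g Z_gᵀ the criterion is a cheap closed form, and a
golden-section search on log λ (tolerance 1e-8, bounds 1e-8…1e8) finds
the optimum. BLUPs are the posterior means u = K(K+λI)⁻¹(y−Xβ̂),
reported per genotype and centered. Broad-sense heritability is
H² = σg²/σp² with σp² = σg² + σe² on the single-observation (plot)
basis. Residual quality is summarized by the correlation of sorted
residuals with normal quantiles; values below 0.95 produce a warning
note, never a hard failure. Aliased fixed-effect columns (e.g. nested
factors) are dropped automatically and recorded.

Phenotypic groups are found by complete-linkage hierarchical clustering
of the BLUPs (Euclidean distance), with the cluster count chosen in
2…5 by two internal indexes (silhouette and Calinski–Harabasz); when
they disagree the silhouette choice wins. Only these two indexes are
implemented, not a full index battery.

## Genotype QC and imputation

Dosages are coded 0/1/2 with −1 as the missing sentinel ("NA", ".",
"./." accepted on input). QC order is fixed: individuals with more than
50% missing calls, then markers with more than 20% missing calls, then
markers with MAF below 5%, MAF computed on the individuals that survived
(f = dosage sum / 2×non-missing count, MAF = min(f, 1−f); the filter
removes only MAF *strictly below* the threshold). QC is idempotent. For
multi-family panels, QC can be run per family with the surviving marker
sets combined by intersection.

Missing calls are imputed from the k nearest individuals (default k=5):
Euclidean distance over mutually non-missing markers, weights 1/(d+1e−9),
the weighted mean rounded half-away-from-zero to {0,1,2}. Distance ties
are broken by individual-ID sort order so runs are reproducible. The k
default and the rounding are package choices; no standard value exists
for dosage data at this panel size.

## Statistical baselines

*Ridge marker-effect model*: y = 1μ + Zγ + e with γ shrunk by
λ = σe²/σγ² estimated by the same REML profile (empirical-Bayes ridge).
This is the posterior-mean equivalent of Gibbs-sampled Bayesian ridge
regression; we use the deterministic form deliberately — the posterior
mean is identical and MCMC nondeterminism disappears from tests.

*Gaussian-kernel genomic model (SM-GK analogue)*: K_ij = exp(−d²_ij/q)
with q the median off-diagonal squared Euclidean distance between
genotype rows (diagonal exactly 1), genetic effects
u = K(K+λI)⁻¹(y−μ̂) with REML λ. With a linear kernel ZZᵀ this reduces
exactly to ridge (dual identity), which the tests exploit as an oracle.

*Standard ML regressors*: AdaBoost, random forest, RBF-SVM and a
library-default MLP, all seeded, behind one predict interface. A
constant target short-circuits to a constant predictor.

## Consensus feature selection

Three selectors vote per marker:

* **L1**: linear model with L1 penalty on standardized dosages — an
  L1-penalized linear SVM (C=1) for classification; for continuous
  targets an L1 linear regression with α = 1/(C√n) on standardized X and
  y (no L1 ε-insensitive linear SVR exists in the supporting library,
  so squared loss stands in; C→0 still shrinks everything to zero).
  Constant columns are skipped.
* **Univariate**: per-marker two-sided t-test of the Pearson correlation
  (continuous target) or one-way ANOVA F-test (class target), selecting
  p < 0.05 strictly, no multiplicity correction. Zero-variance markers
  get p = 1 with a warning.
* **Boosting**: gradient-boosted trees (100 rounds, depth 3, learning
  rate 0.1, seeded); markers whose importance exceeds the mean importance
  over nonzero-variance markers. The mean threshold is the common
  select-from-model convention.

**Inter2** = markers with ≥2 votes; **Inter3** = markers with all 3.
Inter2 (looser) feeds the router; Inter3 (strict) feeds each family's
regressor. By default selection is refit inside every training fold
(leakage-free); a one-off selection on the development set can be pinned
for fold refits, mirroring a protocol where the development set defines
the architecture once.

## The perceptron and its training recipe

A fixed two-hidden-layer feedforward net (linear output for regression,
one output per class with argmax for classification) trained with MAE
loss for 200 epochs of shuffled mini-batches of 16 under Adam
(β1 = 0.9, β2 = 0.999, ε = 1e−8):

v_t = β1 v_{t−1} + (1−β1) g_t,  s_t = β2 s_{t−1} + (1−β2) g_t²,
Δw = −η v̂_t / (√ŝ_t + ε)  (bias-corrected moments).

The classification head is also trained with MAE against one-hot targets
(one loss for every task; a cross-entropy switch exists but is off by
default). Initialization is seeded Glorot-uniform; no early stopping, no
regularization beyond the recipe. Training is a pure function of (data,
config, seed).

Hidden-layer sizes are bounded by the approximation-theoretic limits for
m training samples and q outputs: n1 ≤ √((q+2)m) + 2√(m/(q+2)) and
n2 ≤ q√(m/(q+2)) (floors, clamped ≥1). Enumerating every integer is
wasteful, so the grid samples 8 evenly spaced sizes per layer (endpoints
included) crossed with activations {ReLU, sigmoid, tanh} and learning
rates {0.005, 0.001, 0.0001}. Regression winner: the config minimizing
Euclidean distance to the ideal corner (max R, min MAPE) after min-max
normalizing both metrics over the grid — a concrete operationalization
of "closest to the best corner of the R/MAPE plot"; ties go to higher
raw R, then fewer neurons. Classification winner: maximal held-out
accuracy, ties broken by minimal final training loss. Each config is
scored on an internal 75/25 split of the data handed to the search
(stratified for classification); an optional mode scores regression
configs by internal k-fold CV instead, which is stabler on very small
families but measurably hurt both pooled and holdout accuracy on the
built-in benchmark, so the single split remains the default.

## Two-stage model assembly

`dc_fit` trains the router on Inter2 markers for the family-label
target, then per family runs its own consensus selection (Inter3, with
a fallback to that family's Inter2 when the strict set is empty — small
families can produce an empty three-way intersection) and its own grid
search with bounds from that family's sample count. Because MAE training
targets the conditional median, each family regressor can retain a small
output offset; after training, the output intercept is recalibrated in
closed form so the mean training prediction equals the mean training
target. Per-family offsets would otherwise act as between-family noise
when predictions are pooled. `dc_predict` routes
by argmax and scores each individual with the routed family's regressor
on that family's markers; there is no abstention, and a misrouted
individual is simply scored by the wrong family's model. Families absent
at training time cannot appear at prediction (closed router vocabulary).
When no family assignment exists, an unsupervised mode induces labels by
k-means on leading genotype principal components (k by silhouette).

## Validation protocol

A 10% stratified holdout (largest-remainder allocation per family) is
set aside first; all selection and tuning happens on the remaining
development set, and the holdout is scored exactly once. Model
comparison uses repeated stratified k-fold (k = 4; 50 repetitions at
full scale, 10 in the built-in benchmark) with every model evaluated on
identical splits. Metrics: Pearson R between predicted and observed
BLUPs and MAPE (truth values with |t| < 1e−6 are excluded from MAPE
with a logged count — BLUPs are centered, so near-zero truths would
explode the ratio). Classification uses plain accuracy. Per-split R
values are compared across models with one-way ANOVA and Tukey's HSD
(α = 0.05) with compact letter groupings; MAPE is reported but not
letter-grouped.

## Synthetic data: what it emulates, and what it does not

`simulate_families` draws, per family, two parents from family-specific
allele frequencies (base ~U(0.1,0.9), drifted on the logit scale by
`family_divergence`), and produces F1 offspring by transmitting one
parental haplotype per LD block (default block 20 markers, no
within-block recombination). QTLs are hidden causal loci assigned to
blocks: they co-segregate with the block, so panel markers tag them with
a family-specific phase. Each family has its own QTL effect set
(~N(0,1)), sharing a `qtl_overlap` fraction of loci and effects with the
other families. Genetic values are centered within family, so trait
distributions overlap across families while marker PCA separates them;
noise variance is solved analytically from the empirical variance of
genetic values so realized h² matches the request exactly in
expectation. With zero divergence all families share one parent pair,
making them statistically exchangeable rather than merely
similar-frequency. Defaults mirror a three-family panel of 30/127/251
with 7414 markers and h² = 0.55; the benchmark and acceptance runs use
60/120/200 individuals and 2000 markers with 20 QTLs per family and
zero overlap, sizes chosen so the complete protocol (full hyperparameter
grid included) runs in minutes on one CPU.

Not emulated: deeper pedigrees, epistasis or dominance, genotyping
error, within-block recombination, environment-by-genotype structure,
and coalescent-grade allele-frequency histories. Passing tests
demonstrate that the pipeline behaves correctly under the mechanism it
targets (family-specific tag phase over shared trait architecture), not
that real panels will show gains of any particular size.

## Numerical choices and degenerate inputs

* REML λ search: golden section on log λ ∈ [log 1e−8, log 1e8], tol
  1e−8; rank-deficient fixed designs raise after aliased-column pruning.
* Ridge/kernel solves use dense Cholesky-backed `solve`; a singular
  (K+λI) raises.
* kNN imputation ties: individual-ID order; imputed values clipped to
  [0,2] after rounding.
* MAE gradient at zero residual uses sign(0) = 0.
* Grid-search metric normalization: when all configs tie on a metric its
  normalized value is 0.5 for every config (no discrimination).
* `mape` raises if every truth value is near zero; `pearson_r` raises on
  zero variance rather than returning NaN.

## Known limitations

* The router has no confidence threshold; far-out genotypes are still
  assigned to some training family.
* Single-environment, single-trait models only; no G×E kernels.
* The empirical-Bayes ridge is the posterior mean of Bayesian ridge
  regression but reports no posterior uncertainty.
* MAPE on centered BLUPs is scale-sensitive even with the near-zero
  exclusion; R is the primary comparison metric.
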