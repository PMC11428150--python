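# Methods note

This note records the modelling assumptions, default parameters and
numerical choices behind `slemnet`. Everything here is implemented in the
submodules named in parentheses.

## Network model (`slem.archinit`, `slem.network`)

The model is a feed-forward network with five named layers — SNPs,
transcript isoforms, protein markers, cellular phenotypes, disease — and
one weight matrix per adjacent layer pair. Hidden layers use tanh, the
output uses the logistic sigmoid, and there are **no bias terms**, so the
number of trainable parameters equals the number of unmasked edges
exactly. Each weight matrix is paired with a binary mask; masked entries
are zero at initialization and their gradients are zeroed during training,
so discarded edges can never reappear.

### Architecture from the multilevel cohort

* **Node selection.** Isoforms, markers and phenotypes are retained when
  their best SNP-association q-value (minimum over SNPs, Benjamini–
  Hochberg within each table) beats per-layer FDR thresholds, default
  0.1 / 0.05 / 0.05. The SNP layer keeps all input SNPs; the disease layer
  is a single node.
* **Edge initialization.** Each pair's two-sided association p-value maps
  to a signed weight on the Xavier (Glorot) normal scale,
  `w = sign · σ · Φ⁻¹(1 − p/2)`, `σ = sqrt(2/(fan_in + fan_out))`. Under
  the null (uniform p) the |w| population is half-normal with the Xavier
  scale, and smaller p always gives a larger |w|. Pairs with nominal
  p ≥ 0.05 are zeroed first; then only the largest 35% of |w| per layer
  (ceiling rounding, ties broken lexicographically by row then column) are
  kept. Phenotype→disease edges carry no association information and are
  drawn fresh from the Xavier normal under the build seed.
* **Log-space evaluation.** Strong associations underflow float64
  p-values. Association tables therefore carry ln(p) computed with
  `t.logsf`, and the weight transform is evaluated with
  `scipy.special.ndtri_exp` so ordering is preserved far below the float64
  minimum; magnitudes are capped at 1000 σ so an exactly-zero p (a
  noiseless fit) still yields a finite weight.

### Association tests (`slem.assoc`)

* SNP→isoform/marker/phenotype pairs: OLS of the response on
  `[1, SNP, covariates]` with a two-sided t-test on the SNP slope. The
  default covariates are age, sex and diagnosis, plus expression factors
  for the isoform response. The all-pairs pass is vectorized by
  Frisch–Waugh residualization against the shared covariate block (QR
  orthogonalization); per-pair listwise deletion is used when missing
  values are present.
* Expression factors are the top-k principal components of the isoform
  matrix **after projecting out the genotype matrix**. The factors stand
  in for hidden non-genetic confounders; extracting them from raw
  expression lets them absorb broad genetic signal and cancels the very
  associations under test. When the sample count is too small to
  residualize (n ≤ n_SNPs + k + 10), plain PCs are used. The default
  k = min(15, n_samples − 10, n_isoforms / 4).
* Isoform→marker and marker→phenotype pairs: Kendall tau-b with tie
  correction (exact p for n ≤ 10 without ties, normal approximation
  otherwise) — a rank test, because downstream features are not assumed
  Gaussian and the marker layer is generated through a monotone
  nonlinearity.

### Training (`slem.network`)

Binary cross-entropy, ADAM (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with
per-parameter masking applied to both gradients and weights after every
step. Defaults: learning rate 0.005, batch size 250, 750 epochs, shuffled
batches under a dedicated seed stream. Evaluation uses AUROC
(scikit-learn), stratified k-fold cross-validation (default 10 folds) and
optional repeated-split model averaging (default 100 repeats). A fully
connected comparator with the same layer shape is available as a baseline.

## Interpretation (`slem.interpret`, `slem.screen`)

* **Impact scores.** For SNP i, the score is
  `|[(W₁⊙M₁)(W₂⊙M₂)(W₃⊙M₃)w₄]ᵢ|` — the absolute sum over all directed
  paths from the SNP to the disease node of the product of edge weights.
  Two independent routes (matrix product and explicit path enumeration)
  are implemented and agree to 1e−9 in tests. A SNP with no unmasked path
  scores exactly zero.
* **Mediator modules.** A module keeps the globally strongest fraction of
  unmasked |weights| (one threshold across all layers) and then retains
  only edges from which an anchor phenotype is reachable.
* **Combination screen.** All genotype-state combinations (states 0/1/2
  per SNP, subset sizes within bounds) are enumerated; a combination
  passes when its carrier precision (patients among carriers) is
  **strictly** greater than 0.6 and its hypergeometric upper-tail
  enrichment p is strictly below 0.05. Samples with missing genotypes at a
  combination's SNPs are excluded from that combination's population.
  Holdout evaluation reports train and holdout precision, flags
  combinations with no holdout carriers, and marks combinations whose
  holdout precision falls below the holdout base rate as de-enriched.

## Synthetic-data generator (`slem.synthdata`)

The generator exists to exercise and validate the pipeline, not to model
biology. Genotypes are Binomial(2, MAF) per SNP; isoforms are linear in
standardized genotypes plus covariate effects and Gaussian noise; markers
apply tanh to standardized isoform signal before linear mixing (so the
rank-based layer tests face a non-Gaussian dependency); phenotypes are
linear in standardized markers; diagnosis is Bernoulli under a sigmoid
liability on phenotypes whose intercept is calibrated by root finding to a
target prevalence. Planted effect matrices are recorded as ground truth.
There is no linkage disequilibrium, imputation error or population
stratification. `dominant_chain_config` plants one SNP driving a
three-isoform → two-marker → one-phenotype chain with strong liability
weight on the chain phenotype, against a sparse background.

## Problem sizes and determinism

Default shapes are this package's own choice of desk-scale regimes: a
57-sample multilevel cohort with 138 SNPs and 67/42/19 intermediate
features at the reference shape, and 40 SNPs with 12/8/4 features,
500 multilevel / 5000 end-to-end samples for the recovery studies in the
test suite and the acceptance script — small enough to run on one CPU in
minutes, large enough for the planted-signal checks to be stable across
seeds. All random draws flow through `numpy.random.default_rng` with
fixed per-purpose stream identifiers combined with the user seed, so equal
seeds give bit-identical datasets, models and artifacts.

## Limitations

* The multilevel association pass assumes linear SNP effects (additive
  coding) and treats diagnosis as an ordinary covariate; no mixed models,
  no cis-window restriction, no permutation-based eQTL FDR.
* The expression-factor correction is a PCA surrogate, not a full factor
  model; with very small cohorts it falls back to raw PCs and can then
  absorb genetic signal.
* The combination screen is exhaustive and intended for a handful of
  candidate SNPs (4ᵏ − 1 combinations for k SNPs); it does not correct
  across combinations beyond the per-combination enrichment test.
* Impact scores summarize the network linearly through path products and
  ignore activation saturation; they rank inputs, they do not estimate
  causal effects.
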