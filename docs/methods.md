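# Methods

## Model

The model is a fully connected variational autoencoder over ln(x+1)
normalized bulk expression profiles.  Encoder: input dropout (rate 0.20),
one hidden layer of leaky-ReLU units (negative slope 0.01), and two linear
heads producing the latent means μ and log-variances log σ² for D latent
dimensions.  Decoder: one leaky-ReLU hidden layer and a linear output of
the input width.  The reference configuration is 128 hidden units and
D = 64; the desk-scale configuration used for synthetic cohorts is 128
hidden units and D = 32 (see *Desk scale* below).

The loss is the sum of a squared-error reconstruction term and the KL
divergence of the diagonal-Gaussian posterior from the standard-normal
prior:

    L_rec = β · (1/N) Σ_i ‖y_i − ŷ_i‖²            (mean over samples,
                                                   sum over genes)
    L_KL  = mean_i [ −½ Σ_j (1 + log σ_ij² − μ_ij² − σ_ij²) ]

The Gaussian-likelihood (squared-error) framing is deliberate: on ln(x+1)
data the residuals are approximately homoscedastic and a Bernoulli
likelihood would be meaningless.  The reconstruction term sums over genes.
This choice is load-bearing: if the reconstruction were averaged per gene
while the KL sums over latent dimensions, the prior would dominate at any
realistic gene count and weakly expressed co-expression factors would
never be encoded — the latent arithmetic downstream would have nothing to
work with.  When a "per input variable" reconstruction error is quoted it
is this term divided by β and the gene count.

β is annealed over sequential stages without weight resets — 500 epochs at
β = 100, then 100 epochs each at 50, 20 and 10 in the reference schedule —
so early training prioritises reconstruction and the final stage lets the
KL pull the posterior toward the prior until the two terms are of the same
order ("equilibrium").  Equilibrium matters because every downstream
operation decodes points near the latent origin: the N(0,1) background
draws, and amplified disease vectors anchored at 0.  A model whose
encodings sit far from the prior decodes garbage there.

Sampling (z = μ + σ⊙ε, fresh ε per minibatch) and dropout are active only
during training.  Encoding and decoding for analysis are deterministic
functions of μ.

### Optimisation and initialisation

The network is small enough that forward and backward passes are written
directly in numpy (Adam, lr 1e-3, batch 128); this keeps runs
bit-reproducible under a fixed seed with no framework nondeterminism.
Weights are Glorot-uniform.  Two biases get a data-dependent centering
initialisation on fresh models: the output bias starts at the training-set
mean profile and the first encoder bias at minus the mean input
activation.  Without it, the uncentered input pushes a large constant
offset into μ which the KL gradient then erodes at a rate limited by the
optimiser's step size — tens of thousands of steps that a desk-scale run
does not have.  With it the posterior starts centred on the prior and the
schedule's terminal stage converges to equilibrium (KL ≈ 0.5–3 nats per
latent dimension on the default synthetic cohort) in a few hundred
epochs.  The initialisation is exposed as `train(..., center_init=...)`
and is on by default.

A non-finite loss aborts training with the epoch and stage identified.
Checkpoints are single `.npz` archives holding weights, the architecture
spec, the gene order and the full history; loading re-validates gene-count
agreement.

## Latent arithmetic

* **Disease vector.**  Case and control samples are encoded separately;
  z for each condition is the per-dimension mean of the μ encodings, and
  ν = z_case − z_control.
* **Amplified decoding.**  g_aug = f(η·ν) with η = 3 by default.  η
  trades signal amplification against decoder extrapolation; the decoded
  point is deliberately anchored at the origin, not at the data mean,
  which is why prior-matching during training matters.
* **Background ensemble.**  B = 1,000 draws X ~ N(0, σ²I) (σ = 1 for
  disease modules) decoded to expression profiles.
* **Rank statistic.**  count_i = #{ j : g_aug_i > G_background_i,j },
  strict inequality, an integer in [0, B].  Implicitly this normalises
  each gene by its own background variability.  Top-k selection breaks
  count ties by larger decoded value, then lexicographic gene ID, so
  output lists are deterministic.
* **Tissue signatures** (no case-control design): the control condition is
  B decoded N(0,1) draws re-encoded through the model; the decoded
  difference vector is ranked against a second, independent background.
  Requires ≥ 10 tissue samples by default (configurable).
* **PCA augmentation.**  Linear PCA of the held-out μ matrix; each
  latent row is shifted 5 score-SDs along one component and the mean
  absolute decoder change per gene is the response.  The shift is applied
  to every sample (population-level response), not to a single synthetic
  point; the alternative was considered and rejected because a mean point
  discards the nonlinearity of the decoder across the data cloud.
* **TF perturbation.**  A gene's input coordinate is raised by 5 per-gene
  SDs (computed on the test split, in normalized space) in every sample
  and passed through the full VAE deterministically; responsivity is the
  mean target response over the mean non-target response, excluding the
  perturbed gene from both groups.
* **Random module profiles.**  For the modularity null: σ ~ U(0.01, 0.4),
  z ~ N(0, σ²), mimicking the low amplitude of condition-difference
  vectors relative to full-profile encodings.

## Module extraction and enrichment

The module is the largest connected component of the top-k (default 500)
ranked genes on the interaction network with edge score ≥ 700 (inclusive,
STRING's 0–1000 scale).  Component-size ties break by total rank count,
then by lexicographically smallest member set.  An edgeless induced
subgraph produces an empty module with a warning, not an error, so batch
runs continue.

Edge enrichment offers three null models: **degree** (default; Chung-Lu
expectation Σ k_i k_j / 2m over the cutoff-filtered network, Poisson
tail), **density** (global edge density × C(|S|,2), binomial tail) and
**permutation** (same-size uniform gene sets,
p = (1 + #{perm ≥ obs}) / (n_perm + 1)).  The degree method is the
default because it is closest in spirit to the network-enrichment tools
commonly used with STRING; the permutation method is the assumption-free
fallback.

## Statistics

Overlap testing is Fisher's right-sided exact test
(P(X ≥ a) under the fixed-margin hypergeometric, computed via scipy's
log-space survival functions; p values are never truncated to zero).  The
odds ratio is the sample cross-product (a·d)/(b·c) with a Haldane
correction (0.5 added to every cell) whenever any cell is zero; the
conditional-MLE OR was considered and not used because the cross-product
is transparent and the comparisons here are within-method.  Multiple
testing: Bonferroni (min(1, p·m)) and Benjamini-Hochberg step-up (via
statsmodels), the latter used for drug rankings.  Success/trial summaries
("k of n methods improved") use the exact one-sided binomial tail at
p₀ = ½; paired comparisons of odds ratios use the one-tailed paired t
test.  The module-vs-DEG harness harmonises inputs before testing:
DEGs restricted to network genes, disease-annotation genes restricted to
the DEG table's gene universe, DEG list cut to the module's size, plus a
largest-connected-component baseline of the top DEGs.

## Synthetic data

The generator emulates the statistical structure the method needs, not any
particular tissue atlas.  Per gene and sample, the count mean in natural
log space is

    baseline_g + archetype·[g marker of tissue] + Σ_m factor_{m,s}·[g ∈ m]

with baseline ~ N(3.0, 1.5²) (median ≈ 20 counts), archetype scale 2.0
(≈ 7-fold marker elevation), 20 disjoint modules of 20–100 genes whose
per-sample factors are N(0, 0.5²), and gamma-Poisson (negative binomial)
noise at dispersion 0.3 so that ln(x+1) normalization is meaningfully
exercised.  Defaults: 2,000 genes, 10 tissues × 60 samples.  The disease
contrast redraws case and control samples from one tissue and shifts the
implanted module's genes by 1.0 in log-mean space (≈ 2.7-fold, all upward
by default) in cases only — a strong but realistic bulk RNA-seq effect.
The PPI network wires within-module pairs at probability 0.3 with scores
U{700..999} over an Erdős–Rényi background at density 0.005 with scores
U{150..999}.  Annotations keep 80% of the implanted module plus 20%
random noise genes; the drug table has one true agent (20 targets inside
the implanted module) and 20 decoys with ≥ 11 random targets.
Transcription-factor ground truth reuses the module machinery: the first
gene of each of five modules acts as the TF, its co-members as targets
with unit coefficients, so TF and targets are linearly coupled in log
space.

What the generator does **not** emulate: batch effects, library-size
confounding, isoform structure, overlapping modules, hub-dominated
scale-free network topology, or annotation biases.  Passing tests
therefore demonstrate that the pipeline recovers implanted structure under
its own model assumptions — a correctness check, not a claim about any
real cohort.

## Desk scale

Synthetic runs use a deliberately small configuration chosen once: latent
dimension 32, hidden width 128, schedule (40, β=100), (10, 50), (10, 20),
(1000, 10), batch 128 — the same shape as the reference schedule with a
longer terminal stage, because the small cohort needs those extra steps at
the final β to reach the KL-reconstruction equilibrium.  One training run
takes roughly a minute on one CPU; the five-seed benchmark about six
minutes.

## Known limitations

* Modules near the generator's minimum size (≈ 20–30 genes) are at the
  edge of what the desk-scale latent space encodes: across seeds,
  occasionally such a module's co-expression factor is simply not
  represented, the disease vector then carries no signal, and recovery
  fails for that seed.  The multi-seed benchmark reports this honestly
  rather than hiding it; at full scale (D = 64, 17k samples) the
  equivalent failure mode is expected to be rarer but the dependence of
  recovery on effect prominence is intrinsic to the method.
* The rank statistic is one-sided upward: a disease vector whose decoded
  effect on its genes is predominantly negative needs η < 0 or swapped
  conditions.
* Decoding η·ν extrapolates away from the data manifold; η far above ~5
  amplifies decoder artefacts along with signal.
* The edge-count regressor over random latent profiles and any external
  module-inference comparison are out of scope; DEG lists are consumed as
  given, never computed from counts.
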