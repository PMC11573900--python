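# modvae

Disease-module extraction from the latent space of a variational
autoencoder trained on healthy bulk RNA-seq.

## The problem

Case-control transcriptomic studies of complex disease are chronically
under-powered: tens of samples against a background of ~17,000 genes.
Healthy expression data, by contrast, exist in abundance.  `modvae`
implements a transfer strategy: train a VAE once on a large healthy
multi-tissue cohort so that its latent space internalises the gene
regulatory structure (tissue identity, pathways, co-expression modules),
then analyse small disease datasets *through* that latent space.  The
package is for computational biologists who want disease gene modules and
drug-repurposing candidates out of ordinary case-control RNA-seq, and for
methods researchers who want every step of that pipeline testable without
any external download.

## The method

All expression is normalized as `x ↦ ln(x+1)` and restricted to genes
present in the protein-interaction network.  The VAE is a feedforward
encoder-decoder (input → 20% dropout → 128 leaky-ReLU units → 64 latent
(μ, log σ²) pairs → 128 leaky-ReLU units → linear output) trained with

```
L      = L_rec + L_KL
L_rec  = β · (1/N) Σ_i ‖y_true,i − y_pred,i‖²
L_KL   = −½ Σ_j (1 + log σ_j² − μ_j² − σ_j²)        (mean over samples)
```

where β is annealed over stages (500 epochs at β=100, then 100 epochs each
at 50, 20, 10) until the two terms are in equilibrium.  Sampling
`z = μ + σ⊙ε` happens only in training; every analysis uses the
deterministic μ coordinates.

Given case and control samples encoded to mean latent activations, the
**disease vector** is

```
ν = z_case − z_control
```

ν is amplified by a scalar η (default 3) and decoded to an
expression-space profile `g_aug = f(η·ν)`.  Each gene *i* is ranked by the
number of times `g_aug_i` strictly exceeds the same gene in B = 1,000
decoded draws from the latent prior `f(X), X ~ N(0,1)` — an integer in
[0, B].  The **disease module** is the largest connected component of the
top-500 ranked genes on the STRING-style PPI network at confidence
score ≥ 700.  Modules are scored by Fisher's right-sided exact test
against disease-gene annotations (odds ratio on the 2×2 overlap table
within a declared gene universe), and drug candidates are ranked by the
same test applied to each agent's target set, FDR-adjusted across agents.

Because the data resources a real analysis would use (GTEx-scale healthy
expression, STRING, DisGeNET, DrugBank) require large or controlled-access
downloads, the package ships a first-class synthetic generator: negative-binomial multi-tissue cohorts with tissue
archetypes and block-modular co-expression, an implanted case-control
perturbation on a known module, a module-consistent PPI network, and noisy
disease/drug annotation tables — so the whole pipeline is verifiable
against ground truth on a desk.

## Worked example

`examples/` holds one narrative script per capability.  The central one,
`examples/03_extract_disease_module.py`, simulates the default 2,000-gene
cohort, trains the desk-scale VAE (latent 16–32, a minute on one CPU),
implants a 2.7-fold disease signal on one co-expression module, and runs
the full extraction.  Its output:

```
implanted module: 43 genes; top-43 ranked genes recover 10 (hypergeometric p = 8.05e-09)
module (largest connected component of top 500): 408 genes, 1941 edges
edge enrichment: 1941 observed vs 1001.4 expected (1.94-fold, p = 2.94e-152)
```

The top-43 ranked genes recover 10 of the 43 implanted genes — far above
the ~1 expected by chance (hypergeometric p ≈ 10⁻⁸) — and the extracted
module is twice as densely wired as a degree-matched expectation.
`examples/04_rank_drugs.py` continues to drug ranking:

```
          agent  n_targets  overlap  odds_ratio  p_right      fdr
1     drug_true         20       19        77.7 8.85e-13 1.86e-11
2       decoy00         11        4        2.24     0.17        1
```

The agent whose targets sit inside the implanted module ranks first of 21
with a 13-order-of-magnitude FDR gap to the best decoy.
`examples/05_latent_structure.py` shows the latent space carries more than
the implant: all 30 known markers of a held tissue appear in its top-500
signature genes, and all five synthetic transcription factors show
responsivity ratios above 1 when over-expressed in silico.

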