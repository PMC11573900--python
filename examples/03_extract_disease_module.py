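"""Extract a disease module by latent-space arithmetic.

Encodes case and control samples, forms the disease vector
nu = z_case - z_control, amplifies it (eta = 3), decodes, ranks every gene
against 1,000 decoded random latent draws, and keeps the largest connected
component of the top-ranked genes on the synthetic PPI network at score
cutoff 700.  Because the cohort is synthetic we can score the module
against the implanted truth.
"""

from scipy import stats

from modvae import (
    SimulationConfig, edge_enrichment, extract_disease_ranking,
    extract_module, implant_disease_signal, log_normalize,
    simulate_healthy_cohort, simulate_network, top_k_genes,
)
from modvae.pipeline import desk_schedule, train_on_expression

config = SimulationConfig(seed=0)  # full default cohort: 2000 genes
expr, truth = simulate_healthy_cohort(config)
print("training the desk-scale VAE on the default cohort "
      "(2000 genes, 600 samples; about a minute)...")
model, test_x = train_on_expression(expr, seed=0)

case, control = implant_disease_signal(expr, truth, config)
ranking = extract_disease_ranking(model, log_normalize(case),
                                  log_normalize(control),
                                  eta=3.0, B=1000, seed=0)
network = simulate_network(truth, seed=0)
module = extract_module(ranking, network, k=500, cutoff=700)

implanted = set(truth.implanted_module)
k = len(implanted)
top = set(top_k_genes(ranking, k))
overlap = len(top & implanted)
p = stats.hypergeom.sf(overlap - 1, config.n_genes, k, k)
print(f"implanted module: {k} genes; top-{k} ranked genes recover "
      f"{overlap} (hypergeometric p = {p:.2e})")
print(f"module (largest connected component of top 500): "
      f"{module.size} genes, {len(module.subgraph_edges)} edges")
enrich = edge_enrichment(module.genes, network, cutoff=700, method="degree")
print(f"edge enrichment: {enrich.observed} observed vs "
      f"{enrich.expected:.1f} expected ({enrich.fold:.2f}-fold, "
      f"p = {enrich.p_value:.2e})")
print("\nA fold well above 1 says the extracted genes are far more "
      "densely wired than a degree-matched random set — they form a "
      "module, not a scatter.")
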