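"""Train the VAE on a synthetic healthy cohort and check reconstruction.

Normalizes counts to ln(x+1), splits 65/25/10, trains the staged
beta-annealing schedule (beta 100 -> 50 -> 20 -> 10), and reports the loss
equilibrium and the held-out per-profile Spearman correlation between input
and reconstruction — the model-quality metric used throughout.
"""

import numpy as np

from modvae import (
    ArchitectureSpec, SimulationConfig, SplitSpec, TrainingSchedule,
    build_vae, log_normalize, reconstruction_spearman, simulate_healthy_cohort,
    split_samples, train,
)

config = SimulationConfig(n_genes=500, n_tissues=4, samples_per_tissue=30,
                          n_modules=8, module_size_range=(15, 40),
                          n_markers_per_tissue=12, seed=7)
expr, truth = simulate_healthy_cohort(config)
norm = log_normalize(expr)
train_x, val_x, test_x = split_samples(norm, SplitSpec(seed=7))
print(f"split: {train_x.n_samples}/{val_x.n_samples}/{test_x.n_samples} "
      "train/val/test")

spec = ArchitectureSpec(input_dim=norm.n_genes, encoder_hidden=64,
                        latent_dim=16, decoder_hidden=64)
model = build_vae(spec, seed=7, gene_ids=norm.gene_ids)
schedule = TrainingSchedule(
    stages=[(40, 100.0), (10, 50.0), (10, 20.0), (300, 10.0)], seed=7)
train(model, train_x, val_x, schedule)

last = model.history[-1]
d = spec.latent_dim
g = spec.input_dim
print(f"final epoch (beta={last['beta']:.0f}): "
      f"reconstruction {last['val_rec']:.1f} "
      f"({last['val_rec'] / last['beta'] / g:.4f} per gene), "
      f"KL {last['val_kl']:.1f} ({last['val_kl'] / d:.3f} per latent dim)")
rho = reconstruction_spearman(model, test_x)
print(f"held-out reconstruction Spearman: mean {np.nanmean(rho):.3f} "
      f"(range {np.nanmin(rho):.3f}-{np.nanmax(rho):.3f}, "
      f"{test_x.n_samples} profiles)")
print("\nA mean rank correlation near 0.9 means the 16-dim latent space "
      "captures the cohort's tissue and co-expression structure.")
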