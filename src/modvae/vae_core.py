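"""A variational autoencoder for bulk RNA-seq expression profiles.

The model is a fully connected feedforward VAE: the encoder applies input
dropout, one leaky-ReLU hidden layer, and linear heads for the latent means
mu and log-variances; the decoder mirrors it with one leaky-ReLU hidden layer
and a linear output.  Reconstruction uses a squared loss on ln(x+1)
normalized counts (a Gaussian-likelihood framing), scaled by a factor beta
that is annealed downward over training stages so that early training
emphasises reconstruction and later training lets the KL term pull the
latent space toward the standard-normal prior:

    L      = L_rec + L_KL
    L_rec  = beta * (1/N) * sum_i || y_true,i - y_pred,i ||^2
    L_KL   = mean_samples [ -1/2 * sum_j (1 + log sigma_j^2
                                          - mu_j^2 - sigma_j^2) ]

The reconstruction term is the mean over samples of the per-sample squared
norm, i.e. it sums over genes.  This matters: against a KL term that sums
over latent dimensions, a per-gene-averaged reconstruction would be
overwhelmed by the prior at realistic gene counts and weakly expressed
co-expression factors would never be encoded.  (Divide by the gene count
when quoting a "per input variable" reconstruction error.)

Latent sampling (z = mu + sigma * eps) happens only during training; every
analysis path encodes to the deterministic mu coordinates and decodes latent
vectors directly.

The network is small (by deep-learning standards) and trained on CPU, so the
forward/backward passes are written directly in numpy with an Adam optimizer;
this keeps runs bit-reproducible under a fixed seed with no framework
nondeterminism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _sstats

from .data_io import ExpressionMatrix


@dataclass
class ArchitectureSpec:
    """Layer sizes and regularisation of the VAE.

    Defaults mirror the reference configuration: 128-unit hidden layers, a
    64-dimensional latent space, 20% input dropout and leaky-ReLU
    activations with negative slope 0.01.
    """

    input_dim: int
    encoder_hidden: int = 128
    latent_dim: int = 64
    decoder_hidden: int = 128
    dropout_rate: float = 0.20
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        for name in ("input_dim", "encoder_hidden", "latent_dim",
                     "decoder_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainingSchedule:
    """Staged beta-annealing schedule.

    ``stages`` is an ordered list of (epochs, beta); the default follows the
    reference recipe of 500 epochs at beta=100 followed by 100 epochs each at
    beta 50, 20 and 10.  Stages run sequentially without resetting weights.
    """

    stages: list[tuple[int, float]] = field(
        default_factory=lambda: [(500, 100.0), (100, 50.0), (100, 20.0),
                                 (100, 10.0)]
    )
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        for epochs, beta in self.stages:
            if epochs < 1:
                raise ValueError("each stage needs >= 1 epoch")
            if beta <= 0:
                raise ValueError("beta must be positive")


@dataclass
class LatentEncoding:
    """Per-sample latent means and log-variances (samples x D)."""

    mu: np.ndarray
    logvar: np.ndarray
    sample_ids: list[str] | None = None


class TrainingDiverged(RuntimeError):
    pass


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


_PARAM_NAMES = ("W1", "b1", "Wm", "bm", "Wv", "bv", "W2", "b2", "W3", "b3")


class VAEModel:
    """Architecture + weights + gene order + per-epoch training history."""

    def __init__(self, spec: ArchitectureSpec, gene_ids: list[str],
                 params: dict[str, np.ndarray], history: list[dict]):
        if len(gene_ids) != spec.input_dim:
            raise ValueError("gene_ids length must equal input_dim")
        self.spec = spec
        self.gene_ids = list(gene_ids)
        self.params = params
        self.history = history

    # -- deterministic application ------------------------------------------

    def _check_genes(self, expr: ExpressionMatrix) -> np.ndarray:
        if not expr.normalized:
            raise ValueError("expression must be ln(x+1) normalized")
        missing = [g for g in self.gene_ids if g not in set(expr.gene_ids)]
        if missing:
            raise ValueError(f"expression missing model genes: {missing[:5]}"
                             f" ({len(missing)} total)")
        return expr.values.loc[self.gene_ids].to_numpy().T  # samples x genes

    def encode_array(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic encoder on a samples x genes array (no dropout)."""
        p = self.params
        h1 = _leaky(x @ p["W1"] + p["b1"], self.spec.leaky_slope)
        return h1 @ p["Wm"] + p["bm"], h1 @ p["Wv"] + p["bv"]

    def decode_array(self, z: np.ndarray) -> np.ndarray:
        """Deterministic decoder on a samples x D latent array."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"latent width {z.shape[1]} != D={self.spec.latent_dim}"
            )
        p = self.params
        h2 = _leaky(z @ p["W2"] + p["b2"], self.spec.leaky_slope)
        return h2 @ p["W3"] + p["b3"]


def build_vae(spec: ArchitectureSpec, seed: int = 0,
              gene_ids: list[str] | None = None) -> VAEModel:
    """Untrained model with Glorot-uniform weight init under ``seed``."""
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(spec.input_dim)]

    def glorot(n_in, n_out):
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    d_in, h_e, d, h_d = (spec.input_dim, spec.encoder_hidden,
                         spec.latent_dim, spec.decoder_hidden)
    params = {
        "W1": glorot(d_in, h_e), "b1": np.zeros(h_e),
        "Wm": glorot(h_e, d), "bm": np.zeros(d),
        "Wv": glorot(h_e, d), "bv": np.zeros(d),
        "W2": glorot(d, h_d), "b2": np.zeros(h_d),
        "W3": glorot(h_d, d_in), "b3": np.zeros(d_in),
    }
    return VAEModel(spec, gene_ids, params, history=[])


# ---------------------------------------------------------------------------
# loss terms


def kl_term(mu: np.ndarray, logvar: np.ndarray,
            reduce: str = "mean") -> float | np.ndarray:
    """KL divergence from N(mu, sigma^2) to the standard normal prior.

    Per sample: -1/2 * sum_j (1 + logvar_j - mu_j^2 - exp(logvar_j)).
    ``reduce='mean'`` returns the batch mean; ``'none'`` the per-sample
    vector.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes differ")
    if not (np.isfinite(mu).all() and np.isfinite(logvar).all()):
        raise ValueError("non-finite latent parameters")
    per_sample = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
    if reduce == "none":
        return per_sample
    return float(per_sample.mean())


def reconstruction_term(y_true: np.ndarray, y_pred: np.ndarray,
                        beta: float) -> float:
    """beta * (1/N) * sum_i ||y_true,i - y_pred,i||^2.

    The per-sample squared norm (summed over genes), averaged over samples.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    return float(beta * np.mean(np.sum((y_true - y_pred) ** 2, axis=1)))


def total_loss(rec: float, kl: float) -> float:
    return rec + kl


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            params[k] -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


def _train_step(model: VAEModel, x: np.ndarray, beta: float,
                rng: np.random.Generator):
    """One minibatch forward/backward pass; returns (grads, rec, kl)."""
    p = model.params
    slope = model.spec.leaky_slope
    n = x.shape[0]
    drop = model.spec.dropout_rate
    if drop > 0:
        mask = (rng.random(x.shape) >= drop) / (1.0 - drop)
        xd = x * mask
    else:
        xd = x
    a1 = xd @ p["W1"] + p["b1"]
    h1 = _leaky(a1, slope)
    mu = h1 @ p["Wm"] + p["bm"]
    lv = h1 @ p["Wv"] + p["bv"]
    eps = rng.standard_normal(mu.shape)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    a2 = z @ p["W2"] + p["b2"]
    h2 = _leaky(a2, slope)
    out = h2 @ p["W3"] + p["b3"]

    rec = beta * float(np.mean(np.sum((out - x) ** 2, axis=1)))
    kl = float(np.mean(-0.5 * np.sum(1 + lv - mu**2 - np.exp(lv), axis=1)))

    dout = beta * 2.0 * (out - x) / n
    grads = {}
    grads["W3"] = h2.T @ dout
    grads["b3"] = dout.sum(0)
    dh2 = dout @ p["W3"].T
    da2 = dh2 * _leaky_grad(a2, slope)
    grads["W2"] = z.T @ da2
    grads["b2"] = da2.sum(0)
    dz = da2 @ p["W2"].T
    dmu = dz + mu / n
    dlv = dz * (0.5 * std * eps) + 0.5 * (np.exp(lv) - 1.0) / n
    grads["Wm"] = h1.T @ dmu
    grads["bm"] = dmu.sum(0)
    grads["Wv"] = h1.T @ dlv
    grads["bv"] = dlv.sum(0)
    dh1 = dmu @ p["Wm"].T + dlv @ p["Wv"].T
    da1 = dh1 * _leaky_grad(a1, slope)
    grads["W1"] = xd.T @ da1
    grads["b1"] = da1.sum(0)
    return grads, float(rec), kl


def _eval_losses(model: VAEModel, x: np.ndarray, beta: float):
    """Deterministic (mu, no dropout) loss components on an array."""
    mu, lv = model.encode_array(x)
    out = model.decode_array(mu)
    rec = reconstruction_term(x, out, beta)
    kl = kl_term(mu, lv)
    return rec, kl


def train(model: VAEModel, train_expr: ExpressionMatrix,
          val_expr: ExpressionMatrix | None,
          schedule: TrainingSchedule,
          center_init: bool = True) -> VAEModel:
    """Run the staged schedule, mutating the model's weights in place.

    Minibatches are reshuffled every epoch; dropout and the
    reparameterization noise z = mu + sigma*eps are drawn from a generator
    seeded by ``schedule.seed``, so identical data and seed reproduce the
    history exactly.  A non-finite loss aborts with the epoch and stage in
    the message.

    ``center_init`` (on fresh models only) initialises the output bias to
    the training-set mean profile and the first encoder bias to cancel the
    mean input activation.  Starting the posterior centred on the prior
    this way removes a large constant latent offset that the KL term would
    otherwise have to anneal away over thousands of optimiser steps.
    """
    x_train = model._check_genes(train_expr)
    x_val = model._check_genes(val_expr) if val_expr is not None else None
    if center_init and not model.history:
        xbar = x_train.mean(axis=0)
        model.params["b1"] = -(xbar @ model.params["W1"])
        model.params["b3"] = xbar.copy()
    rng = np.random.default_rng(schedule.seed)
    opt = _Adam(model.params, schedule.learning_rate)
    epoch_global = 0
    for stage_idx, (epochs, beta) in enumerate(schedule.stages):
        for _ in range(epochs):
            order = rng.permutation(len(x_train))
            ep_rec, ep_kl, n_batches = 0.0, 0.0, 0
            for start in range(0, len(order), schedule.batch_size):
                batch = x_train[order[start:start + schedule.batch_size]]
                grads, rec, kl = _train_step(model, batch, beta, rng)
                if not (np.isfinite(rec) and np.isfinite(kl)):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch_global}, "
                        f"stage {stage_idx} (beta={beta})"
                    )
                opt.step(model.params, grads)
                ep_rec += rec
                ep_kl += kl
                n_batches += 1
            record = {
                "epoch": epoch_global,
                "stage": stage_idx,
                "beta": beta,
                "train_rec": ep_rec / n_batches,
                "train_kl": ep_kl / n_batches,
                "train_loss": (ep_rec + ep_kl) / n_batches,
            }
            if x_val is not None:
                v_rec, v_kl = _eval_losses(model, x_val, beta)
                record.update(val_rec=v_rec, val_kl=v_kl,
                              val_loss=total_loss(v_rec, v_kl))
            model.history.append(record)
            epoch_global += 1
    return model


# ---------------------------------------------------------------------------
# application


def encode(model: VAEModel, expr: ExpressionMatrix) -> LatentEncoding:
    """Deterministic latent means/log-variances for every sample."""
    x = model._check_genes(expr)
    mu, lv = model.encode_array(x)
    return LatentEncoding(mu=mu, logvar=lv, sample_ids=expr.sample_ids)


def decode(model: VAEModel, latent: np.ndarray) -> np.ndarray:
    """Decode latent vectors (rows) to expression-space profiles."""
    return model.decode_array(latent)


def profile_correlation(x_profile, y_profile) -> float:
    """Spearman rank correlation between two expression profiles.

    Average ranks break ties; a constant profile has no defined rank
    correlation and yields NaN.
    """
    x = np.asarray(x_profile, dtype=float)
    y = np.asarray(y_profile, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("profiles must be equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(_sstats.spearmanr(x, y).statistic)


def reconstruction_spearman(model: VAEModel,
                            expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample Spearman rho between input and its reconstruction."""
    x = model._check_genes(expr)
    mu, _ = model.encode_array(x)
    out = model.decode_array(mu)
    return np.array([profile_correlation(x[i], out[i])
                     for i in range(len(x))])


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: VAEModel, path) -> None:
    """Write a single .npz archive with weights, spec, gene list, history."""
    meta = {
        "spec": asdict(model.spec),
        "gene_ids": model.gene_ids,
        "history": model.history,
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.params)


def load_model(path) -> VAEModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        params = {k: archive[k] for k in _PARAM_NAMES}
    spec = ArchitectureSpec(**meta["spec"])
    if len(meta["gene_ids"]) != spec.input_dim:
        raise ValueError("checkpoint gene list disagrees with input_dim")
    return VAEModel(spec, meta["gene_ids"], params, meta["history"])
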