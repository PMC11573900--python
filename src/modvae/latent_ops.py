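"""Latent-space arithmetic: disease vectors, amplified decoding, random
decoded backgrounds, the exceedance-rank statistic, principal-component
augmentation, transcription-factor perturbation, and tissue signatures.

The central operation contrasts two conditions in latent space.  Case and
control samples are encoded to their deterministic latent means, averaged per
condition, and subtracted:

    nu = z_case - z_control

The disease vector nu is amplified by a scalar eta (default 3) and decoded to
an expression-space profile g_augmented.  To decide which genes that profile
singles out, it is compared with B decoded draws from the latent prior
(z ~ N(0, 1), default B = 1000): each gene's rank statistic is the number of
background profiles it strictly exceeds, an integer in [0, B].  The top-k
genes by this count seed the module extraction step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .data_io import ExpressionMatrix
from .vae_core import VAEModel, encode


@dataclass
class DiseaseVector:
    """Latent difference vector with its provenance."""

    nu: np.ndarray
    n_case: int
    n_control: int
    label: str = ""

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        if not np.isfinite(self.nu).all():
            raise ValueError("disease vector must be finite")


@dataclass
class BackgroundEnsemble:
    """B latent prior draws and their decoded expression profiles."""

    latent_draws: np.ndarray   # B x D
    decoded: np.ndarray        # B x g
    sigma_spec: str
    seed: int

    def __post_init__(self) -> None:
        if self.latent_draws.shape[0] != self.decoded.shape[0]:
            raise ValueError("latent and decoded row counts differ")


@dataclass
class GeneRanking:
    """Per-gene exceedance counts over B decoded backgrounds."""

    gene_ids: list[str]
    counts: np.ndarray         # int in [0, B]
    B: int
    decoded: np.ndarray | None = None  # g_augmented, used for tie-breaks
    label: str = ""
    eta: float = float("nan")
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if ((self.counts < 0) | (self.counts > self.B)).any():
            raise ValueError("counts must lie in [0, B]")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"gene_id": self.gene_ids, "count": self.counts})
        if self.decoded is not None:
            df["decoded"] = self.decoded
        return df


@dataclass
class PCAxes:
    """Orthonormal principal axes of the latent means."""

    components: np.ndarray     # K x D, rows orthonormal
    score_sd: np.ndarray       # per-component SD of the scores
    center: np.ndarray         # D-vector mean


@dataclass
class PerturbationResponse:
    """Mean absolute decoder-level change per gene after a perturbation."""

    gene_ids: list[str]
    response: np.ndarray
    entity: str
    multiple: float = 5.0

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if (self.response < 0).any() or not np.isfinite(self.response).all():
            raise ValueError("responses must be non-negative and finite")


# ---------------------------------------------------------------------------
# condition vectors


def condition_mean_latent(model: VAEModel,
                          expr_subset: ExpressionMatrix) -> np.ndarray:
    """Mean latent activation z: column means of the encoded mu values."""
    if expr_subset.n_samples < 1:
        raise ValueError("need at least one sample")
    return encode(model, expr_subset).mu.mean(axis=0)


def disease_vector(z_case: np.ndarray, z_control: np.ndarray,
                   label: str = "", n_case: int = 0,
                   n_control: int = 0) -> DiseaseVector:
    """nu = z_case - z_control."""
    z_case = np.asarray(z_case, dtype=float)
    z_control = np.asarray(z_control, dtype=float)
    if z_case.shape != z_control.shape:
        raise ValueError("latent vectors differ in length")
    return DiseaseVector(z_case - z_control, n_case, n_control, label)


def amplify_decode(model: VAEModel, dv: DiseaseVector,
                   eta: float = 3.0) -> np.ndarray:
    """Decode the eta-amplified disease vector to one expression profile."""
    return model.decode_array(eta * dv.nu)[0]


def latent_distance(z_case: np.ndarray, z_control: np.ndarray) -> float:
    """Euclidean distance between two latent vectors."""
    return float(np.linalg.norm(np.asarray(z_case, dtype=float)
                                - np.asarray(z_control, dtype=float)))


# ---------------------------------------------------------------------------
# backgrounds and ranking


def random_background(model: VAEModel, B: int = 1000, sigma: float = 1.0,
                      seed: int = 0) -> BackgroundEnsemble:
    """B i.i.d. N(0, sigma^2) latent draws, decoded deterministically."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    draws = sigma * rng.standard_normal((B, model.spec.latent_dim))
    return BackgroundEnsemble(
        latent_draws=draws,
        decoded=model.decode_array(draws),
        sigma_spec=f"N(0, {sigma}^2)",
        seed=seed,
    )


def rank_genes(g_augmented: np.ndarray, background: BackgroundEnsemble,
               gene_ids: list[str] | None = None, label: str = "",
               eta: float = float("nan")) -> GeneRanking:
    """Count, per gene, how many background profiles it strictly exceeds."""
    g_augmented = np.asarray(g_augmented, dtype=float).ravel()
    if g_augmented.shape[0] != background.decoded.shape[1]:
        raise ValueError("gene dimension mismatch with background")
    counts = (g_augmented[None, :] > background.decoded).sum(axis=0)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(g_augmented))]
    return GeneRanking(
        gene_ids=list(gene_ids),
        counts=counts.astype(int),
        B=background.decoded.shape[0],
        decoded=g_augmented,
        label=label,
        eta=eta,
        seed=background.seed,
    )


def extract_disease_ranking(model: VAEModel, case: ExpressionMatrix,
                            control: ExpressionMatrix, eta: float = 3.0,
                            B: int = 1000, seed: int = 0,
                            label: str = "") -> GeneRanking:
    """Full case-control pass: encode, subtract, amplify, decode, rank."""
    z_case = condition_mean_latent(model, case)
    z_control = condition_mean_latent(model, control)
    dv = disease_vector(z_case, z_control, label=label,
                        n_case=case.n_samples, n_control=control.n_samples)
    g_aug = amplify_decode(model, dv, eta=eta)
    background = random_background(model, B=B, sigma=1.0, seed=seed)
    return rank_genes(g_aug, background, model.gene_ids, label=label, eta=eta)


# ---------------------------------------------------------------------------
# principal-component structure


def fit_latent_pca(mu_matrix: np.ndarray) -> PCAxes:
    """Centered linear PCA of the latent means (components orthonormal)."""
    mu_matrix = np.asarray(mu_matrix, dtype=float)
    if mu_matrix.ndim != 2 or mu_matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    k = min(mu_matrix.shape[0] - 1, mu_matrix.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(mu_matrix)
    return PCAxes(
        components=pca.components_,
        score_sd=scores.std(axis=0, ddof=1),
        center=pca.mean_,
    )


def augment_along_component(model: VAEModel, mu_matrix: np.ndarray,
                            axes: PCAxes, k_index: int,
                            multiple: float = 5.0) -> PerturbationResponse:
    """Shift every latent row along one principal axis and decode.

    The shift is ``multiple`` times the component's score SD; the response
    is the mean over samples of the absolute decoder-level change per gene.
    """
    if not 0 <= k_index < axes.components.shape[0]:
        raise ValueError("k_index out of range")
    mu_matrix = np.asarray(mu_matrix, dtype=float)
    shift = multiple * axes.score_sd[k_index] * axes.components[k_index]
    base = model.decode_array(mu_matrix)
    moved = model.decode_array(mu_matrix + shift[None, :])
    response = np.abs(moved - base).mean(axis=0)
    return PerturbationResponse(model.gene_ids, response,
                                entity=f"PC{k_index + 1}", multiple=multiple)


def top_changing_genes(response: PerturbationResponse, k: int = 500
                       ) -> list[str]:
    """Top-k genes by mean absolute output change (ties by gene ID)."""
    order = sorted(range(len(response.gene_ids)),
                   key=lambda i: (-response.response[i],
                                  response.gene_ids[i]))
    return [response.gene_ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# TF perturbation


def tf_perturbation_response(model: VAEModel, expr_test: ExpressionMatrix,
                             tf_gene: str, multiple: float = 5.0
                             ) -> PerturbationResponse:
    """In-silico TF over-expression passed through the full VAE.

    The TF's input coordinate is raised by ``multiple`` standard deviations
    (SD taken over the test samples, in ln(x+1) space) in every sample; the
    response per gene is the mean absolute change of the deterministic VAE
    output.
    """
    if tf_gene not in model.gene_ids:
        raise ValueError(f"{tf_gene!r} is not a model gene")
    x = model._check_genes(expr_test)
    tf_idx = model.gene_ids.index(tf_gene)
    sd = x[:, tf_idx].std(ddof=0)
    if sd == 0:
        raise ValueError(f"{tf_gene!r} has zero variance in the test data")
    x_pert = x.copy()
    x_pert[:, tf_idx] += multiple * sd

    def through(arr):
        mu, _ = model.encode_array(arr)
        return model.decode_array(mu)

    response = np.abs(through(x_pert) - through(x)).mean(axis=0)
    return PerturbationResponse(model.gene_ids, response, entity=tf_gene,
                                multiple=multiple)


def responsivity_ratio(response: PerturbationResponse,
                       target_genes) -> float:
    """Mean response of known targets over mean response of the rest.

    The perturbed gene itself is excluded from both groups.
    """
    targets = set(target_genes) - {response.entity}
    if not targets:
        raise ValueError("target set is empty after excluding the TF")
    in_t, out_t = [], []
    for gene, r in zip(response.gene_ids, response.response):
        if gene == response.entity:
            continue
        (in_t if gene in targets else out_t).append(r)
    if not in_t or not out_t:
        raise ValueError("targets must be a proper subset of the genes")
    denom = float(np.mean(out_t))
    if denom == 0:
        raise ValueError("zero mean response outside the target set")
    return float(np.mean(in_t)) / denom


# ---------------------------------------------------------------------------
# tissue signatures and random-latent modules


def tissue_signature(model: VAEModel, tissue_expr: ExpressionMatrix,
                     B: int = 1000, seed: int = 0, min_samples: int = 10
                     ) -> GeneRanking:
    """Tissue-vs-random contrast when no case-control design exists.

    Decoded standard-normal draws serve as the control group: they are
    re-encoded, their mean latent activation is subtracted from the tissue
    samples' mean, and the decoded difference is ranked against a second,
    independent background ensemble.
    """
    if tissue_expr.n_samples < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples for a tissue signature "
            f"(got {tissue_expr.n_samples}); lower min_samples to override"
        )
    rng = np.random.default_rng(seed)
    control_draws = rng.standard_normal((B, model.spec.latent_dim))
    control_profiles = model.decode_array(control_draws)
    mu_control, _ = model.encode_array(control_profiles)
    z_control = mu_control.mean(axis=0)
    z_case = condition_mean_latent(model, tissue_expr)
    dv = disease_vector(z_case, z_control, label="tissue",
                        n_case=tissue_expr.n_samples, n_control=B)
    profile = model.decode_array(dv.nu)[0]
    background = random_background(model, B=B, sigma=1.0,
                                   seed=int(rng.integers(2**31)))
    return rank_genes(profile, background, model.gene_ids,
                      label="tissue_signature", eta=1.0)


def random_module_latent(model: VAEModel, seed: int = 0
                         ) -> tuple[np.ndarray, float]:
    """Low-amplitude random latent vector for the modularity null.

    sigma ~ U(0.01, 0.4), then z ~ N(0, sigma^2) per coordinate — mimicking
    the small activations typical of condition-difference vectors rather
    than of whole compressed transcriptomes.
    """
    rng = np.random.default_rng(seed)
    sigma = float(rng.uniform(0.01, 0.4))
    z = sigma * rng.standard_normal(model.spec.latent_dim)
    return z, sigma
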