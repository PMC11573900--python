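"""Synthetic multi-tissue RNA-seq cohorts with known ground truth.

The generator emulates the statistical structure the module-extraction
method relies on, at desk scale:

* a multi-tissue healthy cohort whose main variance axes are tissue
  archetypes (marker genes elevated in their tissue) and block-modular
  co-expression (disjoint gene modules sharing a per-sample log-normal
  factor), with negative-binomial count noise so that ln(x+1)
  normalization is meaningfully exercised;
* a case-control disease contrast implanted on one known module by
  shifting its genes' log-means;
* a protein-interaction network in which true modules are densely wired at
  high confidence scores on top of a sparse random background;
* noisy disease-gene and drug-target annotation tables, including one
  "true drug" whose targets sit inside the implanted module.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    TargetTable,
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Counts follow a gamma-Poisson (negative binomial) law around per-gene,
    per-sample means built in natural-log space:

        log mean = baseline_g + archetype * [g is a marker of the tissue]
                   + sum_m factor_{m, sample} * [g in module m]

    with module factors ~ N(0, module_strength^2) drawn per sample.
    """

    n_genes: int = 2000
    n_tissues: int = 10
    samples_per_tissue: int = 60
    n_modules: int = 20
    module_size_range: tuple[int, int] = (20, 100)  # inclusive, ~U{20..100}
    n_markers_per_tissue: int = 30
    baseline_log_mean: tuple[float, float] = (3.0, 1.5)  # loc, scale (ln units)
    archetype_scale: float = 2.0      # marker elevation, ln units
    module_strength: float = 0.5      # SD of the shared module factor
    dispersion: float = 0.3           # NB dispersion: var = m + disp * m^2
    n_tf: int = 5                     # modules whose first gene acts as a TF
    # implanted case-control contrast
    implant_module_index: int = 0
    implant_effect: float = 1.0       # ln-space shift on implanted genes
    implant_signs: str = "positive"   # or "mixed"
    implant_n_case: int = 30
    implant_n_control: int = 30
    implant_tissue: str | None = None  # default: first tissue
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size_range[0] > self.module_size_range[1]:
            raise ValueError("bad module_size_range")
        if self.implant_signs not in ("positive", "mixed"):
            raise ValueError("implant_signs must be 'positive' or 'mixed'")
        if not 0 <= self.implant_module_index < self.n_modules:
            raise ValueError("implant_module_index out of range")


@dataclass
class GroundTruth:
    """What the generator knows and the analyses try to recover."""

    gene_ids: list[str]
    tissue_markers: dict[str, list[str]]
    modules: list[list[str]]
    implanted_module: list[str]
    tf_targets: dict[str, dict[str, float]]  # tf -> {target: coefficient}
    baseline_log_mean: np.ndarray = field(repr=False, default=None)
    config: SimulationConfig = None

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def _tissue_names(n: int) -> list[str]:
    return [f"tissue{t:02d}" for t in range(n)]


def _nb_counts(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def _log_mean_matrix(truth: GroundTruth, tissues: list[str],
                     rng: np.random.Generator) -> np.ndarray:
    """Per-gene, per-sample log means for samples of the given tissues."""
    cfg = truth.config
    g = len(truth.gene_ids)
    s = len(tissues)
    idx = truth.gene_index()
    logm = np.tile(truth.baseline_log_mean[:, None], (1, s))
    for j, tissue in enumerate(tissues):
        for gene in truth.tissue_markers.get(tissue, ()):
            logm[idx[gene], j] += cfg.archetype_scale
    for module in truth.modules:
        factors = rng.normal(0.0, cfg.module_strength, size=s)
        rows = [idx[gene] for gene in module]
        logm[rows, :] += factors[None, :]
    return logm


def simulate_healthy_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Multi-tissue healthy cohort plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]

    # disjoint module assignment from a shuffled gene pool
    pool = list(rng.permutation(config.n_genes))
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    if sizes.sum() > config.n_genes:
        raise ValueError("modules do not fit into the gene pool")
    modules: list[list[str]] = []
    for size in sizes:
        members = sorted(pool[:size])
        del pool[:size]
        modules.append([gene_ids[i] for i in members])

    tissues = _tissue_names(config.n_tissues)
    need = config.n_markers_per_tissue * config.n_tissues
    if need > len(pool):
        raise ValueError("not enough non-module genes for tissue markers")
    tissue_markers = {}
    for tissue in tissues:
        members = sorted(pool[:config.n_markers_per_tissue])
        del pool[:config.n_markers_per_tissue]
        tissue_markers[tissue] = [gene_ids[i] for i in members]

    tf_targets: dict[str, dict[str, float]] = {}
    for module in modules[:config.n_tf]:
        tf, targets = module[0], module[1:]
        tf_targets[tf] = {t: 1.0 for t in targets}

    baseline = rng.normal(*config.baseline_log_mean, size=config.n_genes)
    truth = GroundTruth(
        gene_ids=gene_ids,
        tissue_markers=tissue_markers,
        modules=modules,
        implanted_module=modules[config.implant_module_index],
        tf_targets=tf_targets,
        baseline_log_mean=baseline,
        config=config,
    )

    sample_tissues = [t for t in tissues
                      for _ in range(config.samples_per_tissue)]
    logm = _log_mean_matrix(truth, sample_tissues, rng)
    counts = _nb_counts(np.exp(logm), config.dispersion, rng)
    sample_ids = [f"S{i:05d}" for i in range(len(sample_tissues))]
    values = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"tissue": sample_tissues, "condition": "unknown"}, index=sample_ids
    )
    return ExpressionMatrix(values, meta), truth


def implant_disease_signal(
    expr: ExpressionMatrix, truth: GroundTruth, config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Fresh case and control samples from one tissue.

    Controls follow the healthy generative process; cases additionally shift
    the implanted module's genes by ``implant_effect`` in log-mean space
    (all upward by default, mixed signs optionally).
    """
    if config.implant_n_case < 2 or config.implant_n_control < 2:
        raise ValueError("need at least 2 case and 2 control samples")
    tissue = config.implant_tissue or _tissue_names(config.n_tissues)[0]
    rng = np.random.default_rng([config.seed, 7919])
    idx = truth.gene_index()
    rows = [idx[g] for g in truth.implanted_module]
    if config.implant_signs == "mixed":
        signs = rng.choice([-1.0, 1.0], size=len(rows))
    else:
        signs = np.ones(len(rows))

    def draw(n: int, with_effect: bool, label: str) -> ExpressionMatrix:
        logm = _log_mean_matrix(truth, [tissue] * n, rng)
        if with_effect:
            logm[rows, :] += (config.implant_effect * signs)[:, None]
        counts = _nb_counts(np.exp(logm), config.dispersion, rng)
        ids = [f"{label}{i:04d}" for i in range(n)]
        values = pd.DataFrame(counts, index=truth.gene_ids, columns=ids)
        meta = pd.DataFrame(
            {"tissue": tissue,
             "condition": "case" if with_effect else "control"},
            index=ids,
        )
        return ExpressionMatrix(values, meta)

    case = draw(config.implant_n_case, True, "case")
    control = draw(config.implant_n_control, False, "ctrl")
    return case, control


def simulate_network(
    truth: GroundTruth,
    background_density: float = 0.005,
    seed: int = 0,
    within_module_p: float = 0.3,
) -> InteractionNetwork:
    """PPI network where true modules are dense at high confidence.

    Within-module pairs get an edge with probability ``within_module_p`` and
    a score ~ U{700..999}; a sparse Erdos-Renyi background at
    ``background_density`` carries scores ~ U{150..999}.
    """
    if not 0 < background_density < 1:
        raise ValueError("background_density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(truth.gene_ids)
    n = len(truth.gene_ids)
    n_pairs = n * (n - 1) // 2
    k = rng.binomial(n_pairs, background_density)
    pair_idx = rng.choice(n_pairs, size=k, replace=False)
    # map linear index over the upper triangle to (i, j)
    i = (n - 2 - np.floor(
        np.sqrt(-8 * pair_idx + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
    j = (pair_idx + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    scores = rng.integers(150, 1000, size=k)
    for a, b, s in zip(i, j, scores):
        g.add_edge(truth.gene_ids[a], truth.gene_ids[b], score=int(s))
    for module in truth.modules:
        m = len(module)
        for a in range(m):
            for b in range(a + 1, m):
                if rng.random() < within_module_p:
                    g.add_edge(module[a], module[b],
                               score=int(rng.integers(700, 1000)))
    return InteractionNetwork(g)


def simulate_annotations(
    truth: GroundTruth,
    coverage: float = 0.8,
    noise: float = 0.2,
    seed: int = 0,
    n_decoys: int = 20,
) -> tuple[GeneSetCollection, TargetTable]:
    """Disease-gene and drug-target stand-ins with controllable noise.

    The disease set keeps a ``coverage`` fraction of the implanted module and
    adds ``noise`` (relative to the kept size) random non-module genes.  The
    drug table holds one true agent whose targets lie inside the implanted
    module plus ``n_decoys`` decoy agents with >= 11 random targets each.
    """
    if not (0 <= coverage <= 1 and 0 <= noise <= 1):
        raise ValueError("coverage and noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    implanted = list(truth.implanted_module)
    n_keep = max(1, round(coverage * len(implanted))) if coverage > 0 else 0
    kept = sorted(rng.choice(implanted, size=n_keep, replace=False)) \
        if n_keep else []
    module_genes = {g for m in truth.modules for g in m}
    others = [g for g in truth.gene_ids if g not in module_genes]
    n_noise = round(noise * max(n_keep, 1))
    if coverage == 0:  # fully random annotation of the implanted size
        kept, n_noise = [], len(implanted)
    noise_genes = sorted(rng.choice(others, size=n_noise, replace=False)) \
        if n_noise else []
    disease = GeneSetCollection(
        {"implanted_disease": ("synthetic disease annotation",
                               list(dict.fromkeys(kept + noise_genes)))}
    )
    rows = []
    n_true = min(20, len(implanted))
    true_targets = sorted(rng.choice(implanted, size=n_true, replace=False))
    rows += [("drug_true", g) for g in true_targets]
    for d in range(n_decoys):
        n_targets = int(rng.integers(11, 30))
        targets = sorted(rng.choice(truth.gene_ids, size=n_targets,
                                    replace=False))
        rows += [(f"decoy{d:02d}", g) for g in targets]
    table = TargetTable(pd.DataFrame(rows, columns=["agent", "gene"])
                        .drop_duplicates())
    return disease, table


def worked_fixture() -> dict:
    """Tiny deterministic bundle: 30 genes, 3 tissues, 2 modules.

    Synthetic stand-in for a full data download; everything derives from a
    fixed seed, so the bundle is bit-stable.
    """
    config = SimulationConfig(
        n_genes=30,
        n_tissues=3,
        samples_per_tissue=8,
        n_modules=2,
        module_size_range=(5, 8),
        n_markers_per_tissue=3,
        n_tf=1,
        implant_n_case=6,
        implant_n_control=6,
        seed=42,
    )
    expr, truth = simulate_healthy_cohort(config)
    case, control = implant_disease_signal(expr, truth, config)
    network = simulate_network(truth, background_density=0.02, seed=42)
    disease_sets, drug_table = simulate_annotations(truth, seed=42,
                                                    n_decoys=5)
    return {
        "config": config,
        "expression": expr,
        "truth": truth,
        "case": case,
        "control": control,
        "network": network,
        "disease_sets": disease_sets,
        "drug_targets": drug_table,
    }
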