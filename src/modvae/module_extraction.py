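"""From a gene ranking to a PPI-anchored disease module.

The top-k genes by exceedance count are mapped onto the interaction network
at a confidence cutoff (default: score >= 700 on the 0-1000 scale) and the
largest connected component of the induced subgraph is the module.  Edge
enrichment quantifies how much more densely wired a gene set is than
expected; three null models are provided (degree-preserving expectation,
global density, and uniform same-size permutation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import networkx as nx
import numpy as np

from .data_io import InteractionNetwork
from .latent_ops import GeneRanking


@dataclass
class Module:
    """Ordered gene list plus its induced PPI subgraph."""

    genes: list[str]                       # rank order
    subgraph_edges: set[tuple[str, str]]   # sorted pairs
    label: str = ""
    k: int = 0
    eta: float = float("nan")
    seed: int | None = None
    cutoff: int = 700

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("module genes must be unique")
        members = set(self.genes)
        for u, v in self.subgraph_edges:
            if u not in members or v not in members:
                raise ValueError(f"edge ({u}, {v}) leaves the module")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class EdgeEnrichment:
    observed: int
    expected: float
    fold: float
    p_value: float
    method: str
    n_perm: int | None = None


def top_k_genes(ranking: GeneRanking, k: int = 500) -> list[str]:
    """Top k genes by descending exceedance count.

    Ties break by larger decoded amplified value, then lexicographic gene
    ID, so output lists are deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking.gene_ids):
        raise ValueError("k exceeds the number of ranked genes")
    decoded = (ranking.decoded if ranking.decoded is not None
               else np.zeros(len(ranking.gene_ids)))
    order = sorted(
        range(len(ranking.gene_ids)),
        key=lambda i: (-int(ranking.counts[i]), -decoded[i],
                       ranking.gene_ids[i]),
    )
    return [ranking.gene_ids[i] for i in order[:k]]


def induced_subgraph(genes, network: InteractionNetwork,
                     cutoff: int = 700) -> set[tuple[str, str]]:
    """Edges with both endpoints in ``genes`` and score >= cutoff."""
    members = set(genes)
    edges = set()
    for gene in members & network.nodes:
        for nbr, attrs in network.graph[gene].items():
            if nbr in members and attrs["score"] >= cutoff:
                edges.add(tuple(sorted((gene, nbr))))
    return edges


def largest_connected_component(genes, network: InteractionNetwork,
                                cutoff: int = 700,
                                ranking: GeneRanking | None = None,
                                label: str = "", eta: float = float("nan"),
                                seed: int | None = None) -> Module:
    """The module: largest connected component of the induced subgraph.

    Size ties break by highest total exceedance count (when a ranking is
    supplied), then by lexicographically smallest member set.  An edgeless
    induced subgraph yields an empty module with a warning rather than an
    error, so batch runs over many contrasts keep going.
    """
    genes = list(genes)
    edges = induced_subgraph(genes, network, cutoff)
    if not edges:
        warnings.warn("no network edges at this cutoff: empty module",
                      stacklevel=2)
        return Module([], set(), label=label, k=len(genes), eta=eta,
                      seed=seed, cutoff=cutoff)
    g = nx.Graph(edges)
    count_of = {}
    if ranking is not None:
        count_of = dict(zip(ranking.gene_ids,
                            (int(c) for c in ranking.counts)))

    def keyfun(component):
        total = sum(count_of.get(x, 0) for x in component)
        # larger size, then larger total count, then smallest sorted members
        return (len(component), total,
                tuple(-ord(c) for c in "\x00".join(sorted(component))))

    best = max(nx.connected_components(g), key=keyfun)
    rank_order = {gene: pos for pos, gene in enumerate(genes)}
    ordered = sorted(best, key=lambda x: rank_order.get(x, len(genes)))
    module_edges = {e for e in edges if e[0] in best and e[1] in best}
    return Module(ordered, module_edges, label=label, k=len(genes),
                  eta=eta, seed=seed, cutoff=cutoff)


def edge_enrichment(genes, network: InteractionNetwork, cutoff: int = 700,
                    method: str = "degree", n_perm: int = 1000,
                    seed: int = 0) -> EdgeEnrichment:
    """Observed vs expected induced-edge count for a gene set.

    degree
        Chung-Lu expectation sum_{i<j in S} k_i k_j / (2m) on the
        cutoff-filtered network (p from a Poisson tail on that mean).
    density
        C(|S|, 2) times the global edge density.
    permutation
        Mean over ``n_perm`` uniformly drawn same-size gene sets, with
        p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    genes = [g for g in dict.fromkeys(genes)]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    g_cut = network.at_cutoff(cutoff)
    observed = len(induced_subgraph(genes, network, cutoff))
    nodes = list(g_cut.nodes)
    m = g_cut.number_of_edges()
    n = len(nodes)
    if method == "degree":
        deg = dict(g_cut.degree())
        ks = np.array([deg.get(x, 0) for x in genes], dtype=float)
        tot = ks.sum()
        expected = float((tot**2 - (ks**2).sum()) / 2.0 / (2.0 * m)) \
            if m else 0.0
        from scipy import stats
        p = float(stats.poisson.sf(observed - 1, expected)) \
            if expected > 0 else (1.0 if observed == 0 else 0.0)
        return EdgeEnrichment(observed, expected,
                              _fold(observed, expected), p, method)
    if method == "density":
        pairs = len(genes) * (len(genes) - 1) / 2.0
        density = m / (n * (n - 1) / 2.0) if n > 1 else 0.0
        expected = pairs * density
        from scipy import stats
        p = float(stats.binom.sf(observed - 1, int(pairs), density)) \
            if density > 0 else (1.0 if observed == 0 else 0.0)
        return EdgeEnrichment(observed, expected,
                              _fold(observed, expected), p, method)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        size = len(genes)
        counts = np.empty(n_perm)
        for r in range(n_perm):
            sample = rng.choice(nodes, size=size, replace=False)
            counts[r] = len(induced_subgraph(sample, network, cutoff))
        expected = float(counts.mean())
        p = float((1 + np.sum(counts >= observed)) / (n_perm + 1))
        return EdgeEnrichment(observed, expected,
                              _fold(observed, expected), p, method, n_perm)
    raise ValueError(f"unknown method {method!r}")


def _fold(observed: int, expected: float) -> float:
    if expected == 0:
        return float("inf") if observed else 0.0
    return observed / expected


def extract_module(ranking: GeneRanking, network: InteractionNetwork,
                   k: int = 500, cutoff: int = 700) -> Module:
    """Convenience: top-k genes, then their largest connected component."""
    genes = top_k_genes(ranking, k)
    return largest_connected_component(
        genes, network, cutoff, ranking=ranking, label=ranking.label,
        eta=ranking.eta, seed=ranking.seed,
    )
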