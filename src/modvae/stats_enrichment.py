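"""Hypothesis tests and the module-vs-DEG comparison harness.

Everything here is classical: right-sided Fisher's exact test on 2x2 overlap
tables, the sample (cross-product) odds ratio with optional Haldane
correction, Bonferroni and Benjamini-Hochberg multiple-testing adjustment,
exact one-sided binomial tails, and the one-tailed paired t test.  Tail
probabilities come from scipy's log-space survival functions and are never
truncated to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table.

    a = query ∩ annotation, b = query \\ annotation, c = annotation \\ query,
    d = neither; the universe size is a+b+c+d.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p_right: float
    p_adjusted: float = float("nan")
    label: str = ""


@dataclass
class ComparisonRow:
    """Per-disease module-vs-DEG comparison."""

    label: str
    module: EnrichmentResult
    top_deg: EnrichmentResult
    deg_component: EnrichmentResult
    module_size: int
    n_disease_genes: int
    testable: bool = True


@dataclass
class ComparisonReport:
    rows: list[ComparisonRow] = field(default_factory=list)

    def summary(self) -> dict:
        """Win counts plus the binomial and paired-t summaries."""
        rows = [r for r in self.rows if r.testable]
        n = len(rows)
        mod = np.array([r.module.odds_ratio for r in rows])
        deg = np.array([r.top_deg.odds_ratio for r in rows])
        comp = np.array([r.deg_component.odds_ratio for r in rows])
        wins_deg = int(np.sum(mod > deg))
        wins_comp = int(np.sum(mod > comp))
        out = {
            "n": n,
            "wins_vs_deg": wins_deg,
            "wins_vs_deg_component": wins_comp,
            "binom_p_vs_deg": binomial_right_tail(wins_deg, n) if n else 1.0,
            "mean_module_or": float(mod.mean()) if n else float("nan"),
            "mean_deg_or": float(deg.mean()) if n else float("nan"),
            "mean_deg_component_or": float(comp.mean()) if n else float("nan"),
        }
        if n >= 2 and np.std(mod - comp) > 0:
            t, df, p = paired_one_tailed_t(mod, comp)
            out.update({"paired_t": t, "paired_t_df": df, "paired_t_p": p})
        return out


def fisher_right_tail(table: ContingencyTable) -> float:
    """P(X >= a) under the hypergeometric fixed-margin null.

    Right-sided Fisher's exact test: the probability of observing an overlap
    at least as large as ``a`` given the row/column margins.
    """
    # hypergeom(M=N, n=row1, N=col1); sf(a-1) = P(X >= a)
    return float(
        stats.hypergeom.sf(table.a - 1, table.n, table.a + table.b,
                           table.a + table.c)
    )


def odds_ratio(table: ContingencyTable, haldane: bool = True) -> float:
    """Sample (cross-product) odds ratio (a*d)/(b*c).

    With ``haldane`` (default), 0.5 is added to every cell whenever any cell
    is zero, keeping the ratio finite.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def build_table(query, annotation, universe) -> ContingencyTable:
    query, annotation, universe = set(query), set(annotation), set(universe)
    if not query <= universe:
        raise ValueError(
            f"query genes outside universe: {sorted(query - universe)[:5]}"
        )
    if not annotation <= universe:
        raise ValueError(
            f"annotation genes outside universe: "
            f"{sorted(annotation - universe)[:5]}"
        )
    a = len(query & annotation)
    b = len(query - annotation)
    c = len(annotation - query)
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def set_enrichment(query, annotation, universe, label: str = "",
                   haldane: bool = True) -> EnrichmentResult:
    """Fisher right-tail enrichment of ``query`` in ``annotation``."""
    table = build_table(query, annotation, universe)
    return EnrichmentResult(
        table=table,
        odds_ratio=odds_ratio(table, haldane=haldane),
        p_right=fisher_right_tail(table),
        label=label,
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """min(1, p*m) per entry; ``m`` defaults to the family size."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of p values")
    return np.minimum(1.0, p * m).tolist()


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values (order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj.tolist()


def binomial_right_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided binomial tail P(X >= k) with X ~ Bin(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p0))


def paired_one_tailed_t(x, y) -> tuple[float, int, float]:
    """Paired t test of H1: mean(x - y) > 0.  Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(x, y, alternative="greater")
    return float(res.statistic), len(x) - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# module vs DEG comparison


def _largest_component(genes, network, cutoff: int) -> list[str]:
    g = network.at_cutoff(cutoff).subgraph([x for x in genes if x in
                                            network.nodes])
    comps = [c for c in nx.connected_components(g) if len(c) > 1]
    if not comps:
        return []
    best = max(comps, key=lambda c: (len(c), tuple(sorted(c))))
    return sorted(best)


def compare_module_vs_deg(module_genes, deg_table, disease_genes, universe,
                          network, cutoff: int = 700,
                          label: str = "") -> ComparisonRow:
    """One disease's three-way enrichment comparison.

    ``deg_table`` is an ordered gene list, most significant first.  The
    harmonization mirrors the benchmarking protocol: DEGs are restricted to
    network genes, disease-annotation genes are restricted to the DEG gene
    universe, the DEG list is cut to the module's size, and the same-size
    largest-connected-component baseline of the top DEGs is scored too.
    """
    module_genes = list(module_genes)
    universe = set(universe)
    net_nodes = network.nodes
    degs = [g for g in deg_table if g in net_nodes and g in universe]
    deg_universe = set(degs)
    disease = set(disease_genes) & deg_universe & universe
    k = len(module_genes)
    top_degs = degs[:k]
    deg_component = _largest_component(top_degs, network, cutoff)
    if not disease:
        empty = EnrichmentResult(ContingencyTable(0, 0, 0, len(universe)),
                                 float("nan"), 1.0, label=label)
        return ComparisonRow(label, empty, empty, empty, k, 0, testable=False)
    module_q = [g for g in module_genes if g in universe]
    return ComparisonRow(
        label=label,
        module=set_enrichment(module_q, disease, universe, f"{label}:module"),
        top_deg=set_enrichment(top_degs, disease, universe, f"{label}:deg"),
        deg_component=set_enrichment(deg_component, disease, universe,
                                     f"{label}:deg_lcc"),
        module_size=k,
        n_disease_genes=len(disease),
    )


def or_size_sweep(ranking, deg_table, disease_genes, universe, network,
                  sizes=tuple(range(50, 501, 50)), cutoff: int = 700):
    """Module OR and top-DEG OR as a function of gene-set size.

    ``ranking`` is a GeneRanking (or any object with ``top_k``); at each size
    the module side takes the top-``size`` genes then their largest connected
    component, the DEG side the top-``size`` DEGs.
    """
    from .module_extraction import largest_connected_component, top_k_genes

    rows = []
    for size in sizes:
        genes = top_k_genes(ranking, size)
        module = largest_connected_component(genes, network, cutoff,
                                             ranking=ranking)
        row = compare_module_vs_deg(module.genes, deg_table, disease_genes,
                                    universe, network, cutoff,
                                    label=f"size={size}")
        rows.append({
            "size": size,
            "module_or": row.module.odds_ratio,
            "deg_or": row.top_deg.odds_ratio,
            "module_size": len(module.genes),
        })
    return rows
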