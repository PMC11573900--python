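"""Drug repurposing by target-set enrichment against a disease module.

Each agent with more than ``min_targets`` known targets (after restriction
to the analysis universe) gets a right-sided Fisher's exact test of its
target set against the module, over a universe of genes shared by the model
and the target table.  p values are Benjamini-Hochberg adjusted across
agents and the table is ordered by FDR, then p, then agent name.  Direction
of dysregulation is deliberately ignored: overlap is purely set-based.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .data_io import TargetTable
from .stats_enrichment import bh_fdr, build_table, fisher_right_tail, odds_ratio


def filter_drugs(target_table: TargetTable, universe,
                 min_targets: int = 10) -> dict[str, set[str]]:
    """Agents with strictly more than ``min_targets`` targets in-universe."""
    universe = set(universe)
    kept = {}
    for agent, targets in sorted(target_table.to_map().items()):
        in_universe = targets & universe
        if len(in_universe) > min_targets:
            kept[agent] = in_universe
    if not kept:
        warnings.warn("no agents pass the target-count filter", stacklevel=2)
    return kept


def drug_enrichment(module_genes, drug_targets: dict[str, set[str]],
                    universe) -> pd.DataFrame:
    """Per-agent Fisher enrichment table, FDR-ordered.

    ``drug_targets`` is the output of :func:`filter_drugs`; ``universe``
    should be the intersection of the model's genes with the target table's
    gene space.
    """
    module = set(module_genes) & set(universe)
    if not module:
        raise ValueError("module is empty within the universe")
    rows = []
    for agent, targets in sorted(drug_targets.items()):
        table = build_table(module, targets, universe)
        rows.append({
            "agent": agent,
            "n_targets": len(targets),
            "overlap": table.a,
            "odds_ratio": odds_ratio(table),
            "p_right": fisher_right_tail(table),
        })
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_right"].tolist())
    df = df.sort_values(["fdr", "p_right", "agent"],
                        kind="mergesort").reset_index(drop=True)
    df.index += 1
    df.index.name = "rank"
    return df
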