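"""Readers, writers and preprocessing for the expression / network / gene-set
formats the pipeline consumes.

Expression matrices are gene x sample tables (TSV, gene IDs in the first
column, header row of sample IDs).  Interaction networks are STRING-style
three-column edge lists with integer confidence scores on the 0-1000 scale.
Gene sets travel as GMT, annotation tables as two-column (agent, gene) TSV.

All IDs live in a single namespace — that of the expression matrix.  Network
files that use a foreign identifier scheme (e.g. "9606."-prefixed protein IDs)
must be renamed through an explicit ``id_map``; unmapped nodes are dropped and
counted rather than silently kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("case", "control", "unknown")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with gene IDs as the index and sample IDs as columns.
        Non-negative raw counts when ``normalized`` is False, ln(x+1)
        values afterwards.
    sample_meta
        Per-sample table indexed by sample ID with columns ``tissue`` and
        ``condition`` (one of ``case``/``control``/``unknown``).
    normalized
        Whether :func:`log_normalize` has been applied.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if not self.normalized and (arr < 0).any():
            raise ValidationError("raw expression values must be >= 0")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {"tissue": "unknown", "condition": "unknown"},
                index=cols.copy(),
            )
        else:
            self.sample_meta = self.sample_meta.reindex(cols)
            self.sample_meta["tissue"] = self.sample_meta["tissue"].fillna("unknown")
            self.sample_meta["condition"] = (
                self.sample_meta["condition"].fillna("unknown")
            )
            bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
            if bad:
                raise ValidationError(f"unknown condition labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Column subset preserving metadata and the normalized flag."""
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.values[sample_ids].copy(),
            self.sample_meta.loc[sample_ids].copy(),
            self.normalized,
        )

    def samples_where(self, tissue: str | None = None,
                      condition: str | None = None) -> "ExpressionMatrix":
        """Select samples by metadata fields."""
        mask = pd.Series(True, index=self.sample_meta.index)
        if tissue is not None:
            mask &= self.sample_meta["tissue"] == tissue
        if condition is not None:
            mask &= self.sample_meta["condition"] == condition
        return self.subset_samples(self.sample_meta.index[mask])


@dataclass
class InteractionNetwork:
    """Undirected PPI network with integer confidence scores in [0, 1000]."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def at_cutoff(self, cutoff: int) -> nx.Graph:
        """Subnetwork keeping edges with score >= cutoff (inclusive)."""
        keep = [(u, v) for u, v, s in self.graph.edges(data="score")
                if s >= cutoff]
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(
            (u, v, {"score": self.graph[u][v]["score"]}) for u, v in keep
        )
        return g


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member IDs)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def members(self, name: str) -> set[str]:
        return set(self.sets[name][1])

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class TargetTable:
    """(agent, target gene) pairs for drugs or transcription factors."""

    rows: pd.DataFrame  # columns: agent, gene

    def __post_init__(self) -> None:
        if list(self.rows.columns) != ["agent", "gene"]:
            self.rows = self.rows.rename(
                columns=dict(zip(self.rows.columns, ["agent", "gene"]))
            )
        if self.rows.duplicated().any():
            raise ValidationError("duplicate (agent, gene) pairs")

    def to_map(self) -> dict[str, set[str]]:
        return {a: set(g) for a, g in self.rows.groupby("agent")["gene"]}


@dataclass
class SplitSpec:
    """Train/validation/test fractions plus the shuffle seed."""

    fractions: tuple[float, float, float] = (0.65, 0.25, 0.10)
    seed: int = 0
    counts: tuple[int, int, int] | None = None  # exact override

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValidationError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_tsv(path, meta_path=None) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene IDs, header sample IDs).

    ``meta_path``, when given, is a TSV with columns sample_id, tissue,
    condition, joined by sample ID.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ValidationError(f"malformed expression file {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric cell in column {col!r}, row {row!r} of {path}"
            )
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return ExpressionMatrix(df, meta, normalized=False)


def write_expression_tsv(expr: ExpressionMatrix, path, meta_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")
    if meta_path is not None:
        expr.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_edge_list(path, id_map: dict[str, str] | None = None) -> InteractionNetwork:
    """Read a STRING-style 3-column edge list (node, node, combined score).

    A header line is tolerated.  With ``id_map`` the node IDs are renamed;
    edges touching unmapped nodes are dropped (the count is logged).
    """
    g = nx.Graph()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = int(float(raw))
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValidationError(f"{path}:{lineno}: bad score {raw!r}")
            if not 0 <= score <= 1000:
                raise ValidationError(
                    f"{path}:{lineno}: score {score} outside [0, 1000]"
                )
            if id_map is not None:
                if a not in id_map or b not in id_map:
                    dropped += 1
                    continue
                a, b = id_map[a], id_map[b]
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], score)
            else:
                g.add_edge(a, b, score=score)
    if dropped:
        logger.info("read_edge_list: dropped %d edges with unmapped nodes", dropped)
    return InteractionNetwork(g)


def write_edge_list(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for u, v, s in sorted(network.graph.edges(data="score")):
            fh.write(f"{u}\t{v}\t{s}\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} empty")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_target_table(path) -> TargetTable:
    """Two-column (agent, gene) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (agent, gene)")
    df = df.iloc[:, :2]
    df.columns = ["agent", "gene"]
    return TargetTable(df)


def write_target_table(table: TargetTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing


def log_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every count x by ln(x + 1).

    The only normalization the model uses; applying it twice is an error.
    """
    if expr.normalized:
        raise ValidationError("expression matrix is already normalized")
    return ExpressionMatrix(
        np.log1p(expr.values), expr.sample_meta.copy(), normalized=True
    )


def filter_to_network_genes(
    expr: ExpressionMatrix, network: InteractionNetwork
) -> tuple[ExpressionMatrix, int]:
    """Keep only genes present in the network, preserving gene order.

    Returns the filtered matrix and the number of genes removed.  Genes with
    no network annotation carry little interpretable signal for module
    extraction, so they are excluded before training.
    """
    nodes = network.nodes
    keep = [g for g in expr.gene_ids if g in nodes]
    if not keep:
        raise ValidationError("no expression genes present in the network")
    removed = expr.n_genes - len(keep)
    out = ExpressionMatrix(
        expr.values.loc[keep].copy(), expr.sample_meta.copy(), expr.normalized
    )
    return out, removed


def split_samples(
    expr: ExpressionMatrix, spec: SplitSpec
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Random, seeded train/validation/test partition of the samples.

    Validation and test sizes are round(s * fraction); the remainder goes to
    train.  ``spec.counts`` forces exact sizes when a published partition must
    be matched.
    """
    s = expr.n_samples
    if s < 3:
        raise ValidationError("need at least 3 samples to split")
    if spec.counts is not None:
        n_train, n_val, n_test = spec.counts
        if n_train + n_val + n_test != s:
            raise ValidationError("split counts do not sum to sample count")
    else:
        n_val = round(s * spec.fractions[1])
        n_test = round(s * spec.fractions[2])
        n_train = s - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValidationError("a split partition would be empty")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(s)
    ids = np.asarray(expr.sample_ids)
    train = ids[order[:n_train]]
    val = ids[order[n_train:n_train + n_val]]
    test = ids[order[n_train + n_val:]]
    return (
        expr.subset_samples(train),
        expr.subset_samples(val),
        expr.subset_samples(test),
    )
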