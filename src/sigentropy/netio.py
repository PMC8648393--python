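"""Input/output and preprocessing for signaling-entropy analyses.

Reads the external formats the pipeline consumes — a protein-protein
interaction (PPI) edge list, gene-by-sample expression matrices, clinical
tables and GMT gene-set collections — harmonizes gene identifiers between
network and expression data, and applies the preprocessing rules the
entropy computation requires (proteomic log-ratio normalization, zero
pseudocounting, largest-connected-component restriction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("sigentropy")

LINEAR = "linear-nonnegative"
LOGRATIO = "log-ratio"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Undirected interaction pairs, deduplicated, without self-loops."""

    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        clean: list[tuple[str, str]] = []
        n_self = n_dup = 0
        for a, b in self.edges:
            a, b = a.strip(), b.strip()
            if not a or not b:
                raise ValueError("empty gene identifier in edge list")
            if a == b:
                n_self += 1
                continue
            key = frozenset((a, b))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            clean.append((a, b) if a <= b else (b, a))
        if n_self or n_dup:
            logger.info("edge list cleaning dropped %d self-loops, %d duplicates",
                        n_self, n_dup)
        self.edges = clean

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample real matrix with a declared scale.

    ``scale`` is either ``"linear-nonnegative"`` (RSEM-like abundances,
    usable as mass-action masses directly) or ``"log-ratio"`` (e.g. TMT
    proteome ratios, which must pass through :func:`preprocess_proteome`
    before entropy computation).
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOGRATIO):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.scale == LINEAR:
            vals = self.values.to_numpy()
            if np.isnan(vals).any():
                raise ValueError("missing values in linear-nonnegative matrix")
            if (vals < 0).any():
                raise ValueError("negative values in linear-nonnegative matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class SignalingNetwork:
    """Connected PPI subgraph over genes measured in the expression data.

    Houses the node order, the symmetric 0/1 adjacency ``A`` (sparse CSR)
    and neighborhood lookups used by the transition model.
    """

    nodes: list[str]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node list")
        self.node_index = {g: i for i, g in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbors(self, gene: str) -> list[str]:
        i = self.node_index[gene]
        row = self.adjacency.getrow(i)
        return [self.nodes[j] for j in row.indices]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


@dataclass
class ClinicalTable:
    """Survival time (days), event indicator and optional covariates."""

    data: pd.DataFrame  # index: sample id; columns: time, event, covariates...

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample identifiers in clinical table")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        bad = self.data.index[self.data["time"] <= 0]
        if len(bad):
            raise ValueError(f"non-positive survival time for sample {bad[0]!r}")
        if not self.data["event"].isin((0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, delimiter: str = "\t") -> EdgeList:
    """Parse a 2-column (SIF-like) edge file; extra columns are ignored.

    Duplicate unordered pairs and self-loops are dropped (counts logged).
    A line with fewer than two fields is a hard error naming the line.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p for p in line.split(delimiter)]
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed edge at line {lineno}: {line!r}")
            edges.append((parts[0], parts[1]))
    return EdgeList(edges)


def write_edge_list(edges: EdgeList, path: str | Path,
                    header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for a, b in sorted(edges.edges):
            fh.write(f"{a}\t{b}\n")


def read_expression(path: str | Path, scale: str = LINEAR) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column and sample ids as header.

    Duplicate gene rows are resolved by keeping the row with the highest
    mean (deterministic; the event is logged).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no genes parsed")
    df.index = df.index.astype(str).str.strip()
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value: {exc}") from exc
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("resolving %d duplicate gene rows by highest mean", n_dup)
        order = df.mean(axis=1, skipna=True).to_numpy()
        df = (df.assign(_mean=order)
                .sort_values("_mean", ascending=False)
                .groupby(level=0, sort=False).head(1)
                .drop(columns="_mean")
                .sort_index())
    return ExpressionMatrix(df, scale)


def write_expression(m: ExpressionMatrix, path: str | Path,
                     header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        m.values.to_csv(fh, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            members = {g.strip() for g in parts[2:] if g.strip()}
            sets[name] = members
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_proteome(m: ExpressionMatrix) -> ExpressionMatrix:
    """Turn a proteomic log-ratio matrix into positive mass-action inputs.

    Each column is centered and scaled to unit (population) standard
    deviation, remaining missing entries in each protein row are replaced
    by that row's median, and the result is mapped to linear scale by
    base-2 exponentiation so every value is a strictly positive mass.
    Rows that are entirely missing are dropped with a warning.
    """
    if m.scale != LOGRATIO:
        raise ValueError("preprocess_proteome expects a log-ratio matrix")
    df = m.values.copy()
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d all-missing protein rows", int(all_missing.sum()))
        df = df.loc[~all_missing]
    # per-column z-score; a zero-variance column is centered only
    centered = df - df.mean(axis=0)
    sd = df.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = centered / sd
    med = z.median(axis=1)
    z = z.apply(lambda row: row.fillna(med[row.name]), axis=1)
    linear = np.exp2(z)
    return ExpressionMatrix(linear, LINEAR)


def apply_pseudocount(values: pd.DataFrame,
                      pseudocount: float | str = "auto") -> pd.DataFrame:
    """Replace zeros so the transition model is defined everywhere.

    ``"auto"`` uses half the smallest positive value in the matrix; a float
    is used verbatim.  A row of zero-expression neighbors would otherwise
    make p_ij undefined.
    """
    vals = values.to_numpy(float)
    if (vals < 0).any():
        raise ValueError("pseudocounting expects a non-negative matrix")
    if not (vals == 0).any():
        return values
    if pseudocount == "auto":
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValueError("matrix is identically zero")
        eps = 0.5 * float(positive.min())
    else:
        eps = float(pseudocount)
        if eps <= 0:
            raise ValueError("pseudocount must be positive")
    out = values.copy()
    out[out == 0] = eps
    logger.info("replaced %d zero entries with pseudocount %.3g",
                int((vals == 0).sum()), eps)
    return out


def build_network(e: EdgeList, m: ExpressionMatrix) -> SignalingNetwork:
    """Restrict the PPI graph to measured genes and keep the largest
    connected component; node order is sorted and recorded."""
    shared = e.genes & set(m.genes)
    if not shared:
        raise ValueError("no overlap between edge-list genes and expression genes")
    g = nx.Graph()
    g.add_edges_from((a, b) for a, b in e.edges if a in shared and b in shared)
    if g.number_of_nodes() == 0:
        raise ValueError("no edges remain after restricting to measured genes")
    lcc = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    if len(lcc) < 3:
        raise ValueError(
            f"largest connected component has {len(lcc)} nodes (<3); "
            "entropy is not usefully defined")
    nodes = sorted(lcc)
    sub = g.subgraph(nodes)
    adj = nx.to_scipy_sparse_array(sub, nodelist=nodes, format="csr", dtype=float)
    logger.info("network: %d/%d PPI genes measured, LCC %d nodes / %d edges",
                len(shared), len(e.genes), len(nodes), sub.number_of_edges())
    return SignalingNetwork(nodes, sp.csr_matrix(adj))
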