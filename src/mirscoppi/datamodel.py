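"""Core domain types and readers/writers for the tabular inputs and network outputs.

All identifiers are case-sensitive gene symbols; no ID mapping is performed.
Undirected edges are stored in canonical lexicographic order (a < b), and all
set operations use that form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mirscoppi")

NODE_KINDS = frozenset({"lncRNA", "mRNA_protein", "protein"})
EDGE_TYPES = frozenset({"mirna_target", "ppi", "lnc_target", "sponge"})

TUMOR = "tumor"
NORMAL = "normal"


class FormatError(ValueError):
    """Malformed input file (bad column count, duplicate samples, bad label ...)."""


class UndefinedScoreError(ValueError):
    """A score (correlation, cosine, collaboration) is undefined for the input."""


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Return the undirected edge (a, b) with endpoints in lexicographic order."""
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix.

    Values are taken as provided (assumed normalized / log-scale); no
    transformation is applied. Duplicate gene rows are collapsed by averaging
    at read time.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf)")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        cols = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids),
                                self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


def concat_expression(*matrices: ExpressionMatrix) -> ExpressionMatrix:
    """Stack matrices sharing an identical sample panel (e.g. lncRNA + mRNA)."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.sample_ids != first.sample_ids:
            raise ValueError("sample panels differ; cannot concatenate")
    genes: list[str] = []
    for m in matrices:
        genes.extend(m.gene_ids)
    return ExpressionMatrix(genes, list(first.sample_ids),
                            np.vstack([m.values for m in matrices]))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene symbol, header = samples).

    Duplicate gene rows are averaged element-wise; rows with an empty symbol
    are dropped. Column order is preserved.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = [s.strip() for s in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample ids in header")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str).str.strip()
    df = df[df.index != ""]
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        col = bad[0]
        for gene, cell in df[col].items():
            try:
                float(cell)
            except (ValueError, TypeError):
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at row {gene!r}, "
                    f"column {col!r}"
                ) from None
        raise FormatError(f"{path}: non-numeric column {col!r}")
    numeric = df
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("averaging %d duplicate gene rows in %s", n_dup, path)
        order = list(dict.fromkeys(numeric.index))
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(list(numeric.index), sample_ids,
                            numeric.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Edge lists, gene lists, sample labels
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Undirected, deduplicated edge set of a single type."""

    edges: set[tuple[str, str]]
    edge_type: str

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge_type {self.edge_type!r}")
        self.edges = {canonical_edge(a, b) for a, b in self.edges if a != b}

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_edge(*pair) in self.edges

    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}


def read_edge_list(path: str | Path, edge_type: str) -> EdgeList:
    """Read a >=2-column TSV of node pairs; extra columns ignored.

    Edges are deduplicated after lexicographic ordering; self-loops are
    dropped (count logged).
    """
    edges: set[tuple[str, str]] = set()
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                self_loops += 1
                continue
            edges.add(canonical_edge(a, b))
    if self_loops:
        logger.info("dropped %d self-loop(s) reading %s", self_loops, path)
    return EdgeList(edges, edge_type)


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edge_list.edges):
            fh.write(f"{a}\t{b}\n")


@dataclass
class GeneList:
    symbols: set[str]
    label: str = ""

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


def read_gene_list(path: str | Path, label: str = "") -> GeneList:
    """One symbol per line; whitespace trimmed, duplicates collapsed."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                symbols.add(sym)
    return GeneList(symbols, label)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(genes.symbols):
            fh.write(sym + "\n")


@dataclass
class SampleLabels:
    """Mapping sample_id -> class in {tumor, normal}."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {TUMOR, NORMAL}
        if bad:
            raise FormatError(f"unknown sample label(s): {sorted(bad)}")

    def __contains__(self, sample: str) -> bool:
        return sample in self.labels

    def __getitem__(self, sample: str) -> str:
        return self.labels[sample]

    def __len__(self) -> int:
        return len(self.labels)

    def classes(self) -> tuple[set[str], set[str]]:
        tum = {s for s, c in self.labels.items() if c == TUMOR}
        nor = {s for s, c in self.labels.items() if c == NORMAL}
        return tum, nor


def read_sample_labels(path: str | Path) -> SampleLabels:
    """Two-column TSV: sample_id, label in {tumor, normal}."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sample, lab = parts[0].strip(), parts[1].strip()
            if lab not in (TUMOR, NORMAL):
                raise FormatError(
                    f"{path}:{lineno}: unknown label {lab!r} "
                    f"(expected {TUMOR!r} or {NORMAL!r})"
                )
            labels[sample] = lab
    return SampleLabels(labels)


def write_sample_labels(labels: SampleLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample in sorted(labels.labels):
            fh.write(f"{sample}\t{labels.labels[sample]}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, members (tab-separated)."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT rows need term, description, members"
                )
            gene_sets[parts[0].strip()] = {p.strip() for p in parts[2:] if p.strip()}
    return gene_sets


# ---------------------------------------------------------------------------
# Typed heterogeneous network
# ---------------------------------------------------------------------------

@dataclass
class TypedNetwork:
    """Undirected graph with node kinds and typed edges.

    Nodes carry a kind in {lncRNA, mRNA_protein, protein}; edges carry a type
    in {sponge, ppi, lnc_target}. Typed edges are stored canonically
    (endpoints lexicographic) and deduplicated.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def add_node(self, node: str, kind: str) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        self.nodes[node] = kind

    def add_edge(self, a: str, b: str, edge_type: str,
                 kind_a: str | None = None, kind_b: str | None = None) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if kind_a is not None:
            self.add_node(a, kind_a)
        elif a not in self.nodes:
            raise ValueError(f"unknown node {a!r} (no kind given)")
        if kind_b is not None:
            self.add_node(b, kind_b)
        elif b not in self.nodes:
            raise ValueError(f"unknown node {b!r} (no kind given)")
        x, y = canonical_edge(a, b)
        self.edges.add((x, y, edge_type))

    def kind(self, node: str) -> str:
        return self.nodes[node]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_of_type(self, edge_type: str) -> set[tuple[str, str]]:
        return {(a, b) for a, b, t in self.edges if t == edge_type}

    def edge_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, t in self.edges:
            counts[t] = counts.get(t, 0) + 1
        return counts

    def as_edge_list(self, edge_type: str) -> EdgeList:
        return EdgeList(self.edges_of_type(edge_type), edge_type)

    def degree(self) -> dict[str, int]:
        """Incident-edge count per node, edge types ignored."""
        deg = {n: 0 for n in self.nodes}
        for a, b, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self):
        """Simple undirected graph (parallel typed edges collapse)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((a, b) for a, b, _ in self.edges)
        return g

    def induced_subgraph(self, members: set[str]) -> "TypedNetwork":
        sub = TypedNetwork()
        for n in members:
            if n in self.nodes:
                sub.add_node(n, self.nodes[n])
        for a, b, t in self.edges:
            if a in members and b in members:
                sub.edges.add((a, b, t))
        return sub


def write_network(network: TypedNetwork, path: str | Path) -> None:
    """Write a 3-column TSV (node_a, node_b, edge_type) in sorted row order."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tedge_type\n")
        for a, b, t in sorted(network.edges):
            fh.write(f"{a}\t{b}\t{t}\n")
    counts = network.edge_type_counts()
    logger.info("wrote %s: %s", path,
                ", ".join(f"{t}={n}" for t, n in sorted(counts.items())) or "empty")


def read_network(path: str | Path,
                 lncrna_ids: set[str] | None = None) -> TypedNetwork:
    """Read a network written by :func:`write_network`.

    Node kinds are reconstructed from edge types and (optionally) a set of
    known lncRNA symbols: lncRNAs as declared, other sponge endpoints as
    mRNA_protein, remaining nodes as protein.
    """
    lncrna_ids = lncrna_ids or set()
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("node_a\t"):
            raise FormatError(f"{path}: missing node_a/node_b/edge_type header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            rows.append((parts[0], parts[1], parts[2]))
    sponge_nodes = {n for a, b, t in rows if t == "sponge" for n in (a, b)}
    net = TypedNetwork()
    for a, b, t in rows:
        for n in (a, b):
            if n in lncrna_ids:
                net.add_node(n, "lncRNA")
            elif n in sponge_nodes:
                net.add_node(n, "mRNA_protein")
            else:
                net.add_node(n, "protein")
        net.add_edge(a, b, t)
    return net


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and parameters of the full pipeline.

    Defaults follow the method's published operating point: pairs must share
    at least ``min_shared_mirnas`` miRNAs with hypergeometric p <
    ``hypergeom_alpha``; regulation-pattern similarity Sim >=
    ``sim_threshold``; positive expression correlation at p < ``corr_alpha``.
    """

    min_shared_mirnas: int = 3
    hypergeom_alpha: float = 0.01
    sim_threshold: float = 0.5
    corr_alpha: float = 0.01
    hub_fraction: float = 0.10
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    min_module_size: int = 4
    signature_cutoff: float = 0.9
    cv_folds: int = 10
    enrichment_alpha: float = 0.01
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hypergeom_alpha", "corr_alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_shared_mirnas < 1:
            raise ValueError("min_shared_mirnas must be >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.hub_fraction <= 1.0:
            raise ValueError("hub_fraction must be in (0, 1]")
        if self.mcl_inflation <= 1.0:
            raise ValueError("mcl_inflation must be > 1")
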