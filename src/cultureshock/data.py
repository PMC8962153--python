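"""Core containers and readers/writers for the standard exchange formats.

The pipeline operates on three in-memory types:

``CellMatrix``
    A genes x cells UMI count matrix (sparse) with aligned gene/cell
    identifier lists and a per-cell metadata table.  All downstream
    statistics are defined on raw counts unless an operation states
    otherwise.

``GeneSetCollection``
    Named gene-symbol lists (microglial state programs, marker panels)
    with provenance strings, optionally guaranteed pairwise disjoint.

``DirectedNetwork``
    A directed gene graph (causal/regulatory), with an acyclicity flag
    computed on construction.

On-disk formats are the field's plain-text standards: Matrix Market
coordinate files with features/barcodes TSVs for counts, GMT for gene
sets, and two-column TSV edge lists for networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

PREPARATIONS = ("fresh", "astro", "micro", "synthetic")


class FormatError(ValueError):
    """Raised when an on-disk file does not conform to its declared format."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a container invariant."""


# ---------------------------------------------------------------------------
# CellMatrix
# ---------------------------------------------------------------------------


@dataclass
class CellMatrix:
    """Genes x cells UMI counts with aligned identifiers and cell metadata.

    Parameters
    ----------
    counts
        Sparse non-negative integer matrix, genes on rows.
    gene_ids
        Unique gene identifiers (one per row).
    gene_symbols
        Display symbols, parallel to ``gene_ids``.  Symbols may repeat;
        symbol-based lookup resolves duplicates to the highest-total-count
        record (see :meth:`symbol_rows`).
    cell_ids
        Unique cell barcodes (one per column).
    cell_meta
        Per-cell table indexed by ``cell_ids``.  Downstream stages append
        QC metrics, cluster ids and state labels here.
    embeddings
        Optional named low-dimensional cell embeddings (cells x dims).
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = None  # type: ignore[assignment]
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} genes"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.cell_ids)} barcodes"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        if self.counts.nnz and not np.allclose(
            self.counts.data, np.round(self.counts.data)
        ):
            raise ValidationError("non-integral counts")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        else:
            self.cell_meta = self.cell_meta.copy()
            if len(self.cell_meta) != n_cells:
                raise ValidationError("cell_meta length does not match cell count")
            self.cell_meta.index = pd.Index(self.cell_ids, name="cell")

    # -- basic properties ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "CellMatrix":
        return CellMatrix(
            self.counts.copy(),
            list(self.gene_ids),
            list(self.gene_symbols),
            list(self.cell_ids),
            self.cell_meta.copy(),
            {k: v.copy() for k, v in self.embeddings.items()},
        )

    # -- gene lookup --------------------------------------------------------

    def symbol_rows(self) -> dict[str, int]:
        """Map symbol -> row index; duplicate symbols resolve to the row
        with the highest total count (the drop is logged)."""
        totals = np.asarray(self.counts.sum(axis=1)).ravel()
        out: dict[str, int] = {}
        for i, sym in enumerate(self.gene_symbols):
            if sym in out:
                j = out[sym]
                keep = i if totals[i] > totals[j] else j
                drop = j if keep == i else i
                logger.info(
                    "duplicate symbol %s: keeping row %d, dropping row %d",
                    sym, keep, drop,
                )
                out[sym] = keep
            else:
                out[sym] = i
        return out

    def rows_for_symbols(
        self, symbols: Iterable[str], missing: str = "ignore"
    ) -> np.ndarray:
        """Row indices for the given symbols.

        ``missing='ignore'`` skips absent symbols with a warning;
        ``missing='error'`` raises :class:`ValidationError`.
        """
        table = self.symbol_rows()
        rows, absent = [], []
        for s in symbols:
            if s in table:
                rows.append(table[s])
            else:
                absent.append(s)
        if absent:
            if missing == "error":
                raise ValidationError(f"symbols absent from gene universe: {absent}")
            warnings.warn(f"{len(absent)} symbols not in gene universe: {absent[:5]}")
        return np.array(sorted(set(rows)), dtype=int)

    # -- subsetting ---------------------------------------------------------

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        """Return a new CellMatrix restricted to cells where ``mask`` holds.

        ``mask`` may be boolean (length n_cells) or integer positions.
        """
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return CellMatrix(
            self.counts[:, idx],
            list(self.gene_ids),
            list(self.gene_symbols),
            [self.cell_ids[i] for i in idx],
            self.cell_meta.iloc[idx],
            {k: v[idx] for k, v in self.embeddings.items()},
        )

    def subset_genes(self, rows: np.ndarray) -> "CellMatrix":
        rows = np.asarray(rows, dtype=int)
        return CellMatrix(
            self.counts[rows, :],
            [self.gene_ids[i] for i in rows],
            [self.gene_symbols[i] for i in rows],
            list(self.cell_ids),
            self.cell_meta,
            dict(self.embeddings),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes) for interop."""
        import anndata  # lazy: interop only

        ad = anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(
                {"gene_symbol": self.gene_symbols},
                index=pd.Index(self.gene_ids, name="gene_id"),
            ),
        )
        for name, emb in self.embeddings.items():
            ad.obsm[f"X_{name}"] = emb
        return ad


def read_counts(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CellMatrix:
    """Read a Matrix Market counts triplet into a :class:`CellMatrix`.

    The features file is TSV with one gene per line (id, or id<TAB>symbol);
    the barcodes file has one barcode per line.  Genes are placed on rows
    regardless of on-disk orientation: if the declared shape matches
    (cells, genes) instead, the matrix is transposed.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"could not parse Matrix Market file: {exc}") from exc
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    bars = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    gene_ids = feats.iloc[:, 0].tolist()
    gene_symbols = (
        feats.iloc[:, 1].tolist() if feats.shape[1] > 1 else list(gene_ids)
    )
    cell_ids = bars.iloc[:, 0].tolist()
    if mat.shape == (len(gene_ids), len(cell_ids)):
        pass
    elif mat.shape == (len(cell_ids), len(gene_ids)):
        mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"({len(gene_ids)}, {len(cell_ids)}) nor its transpose"
        )
    return CellMatrix(sp.csr_matrix(mat), gene_ids, gene_symbols, cell_ids)


def write_counts(matrix: CellMatrix, out_dir: str | Path, prefix: str = "") -> None:
    """Write the MTX/TSV triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(out / f"{prefix}matrix.mtx"), sp.coo_matrix(matrix.counts), field="integer"
    )
    pd.DataFrame({"id": matrix.gene_ids, "symbol": matrix.gene_symbols}).to_csv(
        out / f"{prefix}features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.cell_ids).to_csv(
        out / f"{prefix}barcodes.tsv", sep="\t", header=False, index=False
    )
    if len(matrix.cell_meta.columns):
        matrix.cell_meta.to_csv(out / f"{prefix}cell_meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# GeneSetCollection
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene-symbol lists with provenance.

    ``nonoverlapping`` asserts that all pairwise intersections are empty;
    it is verified on construction when set.
    """

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)
    nonoverlapping: bool = False

    def __post_init__(self) -> None:
        self.sets = {str(k): [str(g) for g in v] for k, v in self.sets.items()}
        if self.nonoverlapping:
            names = list(self.sets)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    inter = set(self.sets[a]) & set(self.sets[b])
                    if inter:
                        raise ValidationError(
                            f"sets {a} and {b} overlap ({sorted(inter)[:3]}...) "
                            "but nonoverlapping=True"
                        )

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, member genes per line)."""
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: GMT needs name and description")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            if not genes:
                warnings.warn(f"gene set {name!r} is empty; retained")
            sets[name] = genes
            provenance[name] = desc
    return GeneSetCollection(sets, provenance, nonoverlapping=False)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# DirectedNetwork
# ---------------------------------------------------------------------------


@dataclass
class DirectedNetwork:
    """Directed gene graph with an acyclicity flag.

    Edge endpoints must be members of ``nodes``; self-loops are rejected.
    The ``acyclic`` flag is recomputed on construction.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    acyclic: bool = True

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        self.edges = [(str(a), str(b)) for a, b in self.edges]
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValidationError("duplicate node names")
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise ValidationError(f"edge ({a}, {b}) endpoint not in node list")
        self.acyclic = nx.is_directed_acyclic_graph(self.to_networkx())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def children(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
        return adj


def read_network(path: str | Path) -> DirectedNetwork:
    """Read a directed edge list from TSV (columns ``source``, ``target``,
    or headerless two-column)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "source" in cols and "target" in cols:
        src = df[df.columns[cols.index("source")]]
        tgt = df[df.columns[cols.index("target")]]
    else:
        # no header: first row was consumed as column names; re-read
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] < 2:
            raise FormatError("edge list needs at least two columns")
        src, tgt = df.iloc[:, 0], df.iloc[:, 1]
    edges = list(zip(src.tolist(), tgt.tolist()))
    nodes = sorted({n for e in edges for n in e})
    return DirectedNetwork(nodes, edges)


def write_network(network: DirectedNetwork, path: str | Path) -> None:
    pd.DataFrame(network.edges, columns=["source", "target"]).to_csv(
        path, sep="\t", index=False
    )
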