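"""Correlation-graph co-expression analysis: strength, modules, hubs,
and the signed weighted-module-expression statistic.

The graph is built from pairwise correlation of log-normalised
expression (Pearson by default, Spearman by flag) on the per-cluster
downsampled matrix; genes expressed in fewer than ``min_cells`` cells
are excluded.  An edge is kept where its correlation-test p-value
survives Benjamini-Hochberg at the chosen FDR, with |r| stored as the
weight.  Node *strength* is the sum of |r| over a gene's significant
edges (configurable to signed r or edge counts).  Modules come from
Louvain community detection on the |r|-weighted graph, *hubs* are genes
whose within-module degree z-score clears a threshold, and the
per-cell weighted module expression is

    score(cell) = sum_g  sign(cor(g, hub)) * strength(g) * expr(g, cell)

over the module's genes, where *hub* is the module's highest-strength
gene and expr is log-normalised expression.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cluster import normalize_log
from .data import CellMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    """Undirected weighted gene graph with per-gene statistics.

    ``edges`` stores each pair once (gene_a < gene_b by position in
    ``genes``).  ``modules`` / ``hubs`` are filled by
    :func:`detect_modules` and :func:`identify_hubs`.
    """

    genes: list[str]
    edges: pd.DataFrame  # columns: gene_a, gene_b, r, p_raw, p_adj
    strength: pd.Series = None  # type: ignore[assignment]
    modules: pd.Series = None  # type: ignore[assignment]
    hubs: pd.Series = None  # type: ignore[assignment]
    strength_mode: str = "abs_r"
    meta: dict = field(default_factory=dict)

    def degree(self) -> pd.Series:
        d = pd.Series(0, index=self.genes, dtype=int)
        if len(self.edges):
            d = d.add(self.edges["gene_a"].value_counts(), fill_value=0)
            d = d.add(self.edges["gene_b"].value_counts(), fill_value=0)
        return d.astype(int).reindex(self.genes)

    def module_genes(self, module_id: int) -> list[str]:
        if self.modules is None:
            raise ValidationError("modules not assigned; run detect_modules")
        return self.modules.index[self.modules == module_id].tolist()


def node_strength(
    network: CoexpressionNetwork, mode: str | None = None
) -> pd.Series:
    """Per-gene strength: sum over significant incident edges of |r|
    (default), signed r, or 1 (edge count).  Isolated genes score 0."""
    mode = mode or network.strength_mode
    if mode not in {"abs_r", "r", "count"}:
        raise ValidationError(f"unknown strength mode {mode!r}")
    s = pd.Series(0.0, index=network.genes)
    if len(network.edges):
        if mode == "abs_r":
            w = network.edges["r"].abs()
        elif mode == "r":
            w = network.edges["r"]
        else:
            w = pd.Series(1.0, index=network.edges.index)
        s = s.add(w.groupby(network.edges["gene_a"]).sum(), fill_value=0.0)
        s = s.add(w.groupby(network.edges["gene_b"]).sum(), fill_value=0.0)
    return s.reindex(network.genes).fillna(0.0)


class CorrelationNetworkBuilder(BaseEstimator):
    """Build a :class:`CoexpressionNetwork` from expression, sklearn style.

    ``fit(X)`` takes log-normalised expression, cells x genes.  Fitted
    attribute ``network_`` carries the FDR-thresholded graph with
    strength, Louvain modules and hub flags already assigned.
    """

    def __init__(
        self,
        min_cells: int = 10,
        fdr: float = 0.05,
        method: str = "pearson",
        strength_mode: str = "abs_r",
        z_threshold: float = 2.0,
        random_state: int = 0,
    ):
        self.min_cells = min_cells
        self.fdr = fdr
        self.method = method
        self.strength_mode = strength_mode
        self.z_threshold = z_threshold
        self.random_state = random_state

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        n_cells, n_genes = X.shape
        names = list(feature_names) if feature_names is not None else [
            f"g{i}" for i in range(n_genes)
        ]
        expressed = (X > 0).sum(axis=0)
        keep = np.flatnonzero(expressed >= self.min_cells)
        if keep.size < 2:
            raise ValidationError(
                f"fewer than 2 genes expressed in >= {self.min_cells} cells"
            )
        Xk = X[:, keep]
        kept_names = [names[i] for i in keep]
        if self.method == "spearman":
            Xk = st.rankdata(Xk, axis=0)
        elif self.method != "pearson":
            raise ValidationError(f"unknown correlation method {self.method!r}")
        R = np.corrcoef(Xk, rowvar=False)
        R = np.nan_to_num(R, nan=0.0)  # zero-variance genes -> no edges
        iu, ju = np.triu_indices(len(keep), k=1)
        r = R[iu, ju]
        df = n_cells - 2
        rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = rr * np.sqrt(df / (1.0 - rr**2))
        p = 2.0 * st.t.sf(np.abs(t), df)
        p[np.abs(r) >= 1 - 1e-12] = 0.0
        p_adj = multipletests(p, method="fdr_bh")[1]
        sig = p_adj < self.fdr
        edges = pd.DataFrame(
            {
                "gene_a": [kept_names[i] for i in iu[sig]],
                "gene_b": [kept_names[j] for j in ju[sig]],
                "r": r[sig],
                "p_raw": p[sig],
                "p_adj": p_adj[sig],
            }
        )
        net = CoexpressionNetwork(
            kept_names,
            edges,
            strength_mode=self.strength_mode,
            meta={
                "method": self.method,
                "fdr": self.fdr,
                "min_cells": self.min_cells,
                "module_algorithm": "louvain-on-correlation-graph",
            },
        )
        net.strength = node_strength(net)
        detect_modules(net, seed=self.random_state)
        identify_hubs(net, z_threshold=self.z_threshold)
        self.network_ = net
        return self


def build_correlation_graph(
    matrix: CellMatrix,
    min_cells: int = 10,
    fdr: float = 0.05,
    method: str = "pearson",
    strength_mode: str = "abs_r",
    seed: int = 0,
    norm: np.ndarray | None = None,
) -> CoexpressionNetwork:
    """Correlation network of a (typically per-cluster downsampled)
    CellMatrix; see :class:`CorrelationNetworkBuilder`."""
    if norm is None:
        norm = normalize_log(matrix)
    builder = CorrelationNetworkBuilder(
        min_cells=min_cells,
        fdr=fdr,
        method=method,
        strength_mode=strength_mode,
        random_state=seed,
    )
    builder.fit(norm.T, feature_names=matrix.gene_symbols)
    return builder.network_


def detect_modules(network: CoexpressionNetwork, seed: int = 0) -> pd.Series:
    """Louvain modules on the |r|-weighted graph, ids ordered by size
    (module 0 largest); isolated genes become singleton modules.  The
    assignment is stored on the network and returned."""
    n = len(network.genes)
    index = {g: i for i, g in enumerate(network.genes)}
    if len(network.edges) == 0:
        raise ValidationError("network has no edges")
    g = ig.Graph(
        n=n,
        edges=[
            (index[a], index[b])
            for a, b in zip(network.edges["gene_a"], network.edges["gene_b"])
        ],
        directed=False,
    )
    ig.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(weights=network.edges["r"].abs().tolist())
    raw = np.asarray(part.membership)
    uniq, counts = np.unique(raw, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    labels = np.asarray([mapping[m] for m in raw])
    network.modules = pd.Series(labels, index=network.genes, dtype=int)
    return network.modules


def identify_hubs(
    network: CoexpressionNetwork, z_threshold: float = 2.0
) -> pd.Series:
    """Flag hub genes: within-module degree z-score >= ``z_threshold``.

    Modules with fewer than 3 genes, or with no degree variance, have no
    hubs.  Stored on the network and returned.
    """
    if network.modules is None:
        raise ValidationError("modules not assigned; run detect_modules")
    mods = network.modules
    within = pd.Series(0, index=network.genes, dtype=int)
    if len(network.edges):
        same = network.edges[
            mods.loc[network.edges["gene_a"]].to_numpy()
            == mods.loc[network.edges["gene_b"]].to_numpy()
        ]
        within = within.add(same["gene_a"].value_counts(), fill_value=0)
        within = within.add(same["gene_b"].value_counts(), fill_value=0)
        within = within.astype(int).reindex(network.genes).fillna(0).astype(int)
    hubs = pd.Series(False, index=network.genes)
    for m in mods.unique():
        genes = mods.index[mods == m]
        if len(genes) < 3:
            continue
        deg = within.loc[genes].to_numpy(float)
        sd = deg.std()
        if sd == 0:
            continue
        z = (deg - deg.mean()) / sd
        hubs.loc[genes] = z >= z_threshold - 1e-9
    network.hubs = hubs
    return hubs


@dataclass
class ModuleScore:
    """Per-cell signed weighted module expression."""

    scores: np.ndarray
    module_id: int
    reference_hub: str
    gene_weights: pd.Series  # signed strength weight per module gene


def weighted_module_expression(
    matrix: CellMatrix,
    network: CoexpressionNetwork,
    module_id: int,
    norm: np.ndarray | None = None,
) -> ModuleScore:
    """Signed, strength-weighted sum of module gene expression per cell.

    The reference hub is the module gene with maximal strength (ties
    break alphabetically, logged); each gene contributes with the sign of
    its correlation with the hub (the hub itself counts positive).
    """
    genes = network.module_genes(module_id)
    if not genes:
        raise ValidationError(f"module {module_id} is empty")
    if norm is None:
        norm = normalize_log(matrix)
    strengths = network.strength.loc[genes]
    best = strengths.max()
    candidates = sorted(strengths.index[strengths == best])
    hub = candidates[0]
    if len(candidates) > 1:
        logger.info("module %d hub tie %s; using %s", module_id, candidates, hub)
    rows = {s: i for i, s in enumerate(matrix.gene_symbols)}
    hub_expr = norm[rows[hub], :]
    if hub_expr.std() == 0:
        raise ValidationError(f"hub {hub!r} has zero expression variance")
    weights = {}
    score = np.zeros(matrix.n_cells)
    for g in genes:
        expr = norm[rows[g], :]
        if g == hub:
            sign = 1.0
        else:
            sd = expr.std()
            r = np.corrcoef(expr, hub_expr)[0, 1] if sd > 0 else 0.0
            sign = -1.0 if r < 0 else 1.0
        w = sign * float(network.strength.loc[g])
        weights[g] = w
        score += w * expr
    return ModuleScore(score, module_id, hub, pd.Series(weights))


def write_network(network: CoexpressionNetwork, edges_path, nodes_path) -> None:
    """Write the edge list and the per-gene node table (strength, module,
    hub) as TSV."""
    network.edges.to_csv(edges_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        {
            "gene": network.genes,
            "strength": network.strength.reindex(network.genes).to_numpy(),
            "module": (
                network.modules.reindex(network.genes).to_numpy()
                if network.modules is not None
                else -1
            ),
            "hub": (
                network.hubs.reindex(network.genes).to_numpy()
                if network.hubs is not None
                else False
            ),
        }
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)
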