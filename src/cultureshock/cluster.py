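"""Normalisation, SNN-graph community clustering, integration, downsampling.

The workflow mirrors the standard droplet scRNA-seq recipe: per-cell
depth normalisation to a fixed total followed by log1p; optional linear
regression of nuisance covariates (e.g. percent_mito) out of each gene;
per-gene z-scaling (clipped); PCA; a shared-nearest-neighbour (SNN)
graph with Jaccard edge weights over the top principal components; and
Louvain community detection at a chosen resolution (Leiden available).

Cross-sample integration is a mutual-nearest-neighbour (MNN) shift in
PCA space: anchors are MNN pairs across batches and each cell is moved
by a kernel-weighted average of its batch's anchor correction vectors.
Counts are never modified by integration - only the embedding.

Estimators follow scikit-learn conventions (``fit`` / ``fit_predict`` /
``transform``, ``get_params``); module-level functions are thin wrappers
that adapt :class:`~cultureshock.data.CellMatrix` inputs.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data import CellMatrix, ValidationError


@dataclass
class ClusterParams:
    """Clustering hyper-parameters.

    Defaults follow the common preset: 50 principal components, SNN graph
    over 30 of them, k=20 neighbours, Louvain at the chosen resolution.
    """

    n_pcs: int = 50
    snn_dims: int = 30
    resolution: float = 0.6
    k_neighbors: int = 20
    seed: int = 0
    n_hvg: int = 2000
    method: str = "louvain"  # or "leiden"

    def __post_init__(self) -> None:
        if self.snn_dims > self.n_pcs:
            raise ValidationError("snn_dims must be <= n_pcs")
        if self.resolution <= 0:
            raise ValidationError("resolution must be > 0")


@dataclass
class ClusterAssignment:
    """Per-cell cluster ids, relabelled so cluster 0 is the largest."""

    labels: np.ndarray
    params: ClusterParams

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids by descending size (stable: ties keep the
    order of the smaller original label)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.asarray([mapping[l] for l in labels], dtype=int)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Depth-normalise each cell to ``scale_total`` counts, then log1p.

    Stateless transformer (``fit`` is a no-op); input is cells x genes.
    Zero-count cells map to zero vectors, and scaling a cell's counts by
    any positive constant leaves its normalised vector unchanged.
    """

    def __init__(self, scale_total: float = 10_000.0):
        self.scale_total = scale_total

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(
            X.todense() if sp.issparse(X) else X, dtype=float
        )
        totals = X.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(totals > 0, X / np.maximum(totals, 1e-300), 0.0)
        return np.log1p(scaled * self.scale_total)


def normalize_log(matrix: CellMatrix, scale_total: float = 10_000.0) -> np.ndarray:
    """Log-normalised expression, genes x cells (matching CellMatrix)."""
    return LogNormalizer(scale_total).transform(matrix.counts.T).T


def regress_out(X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualise each column of ``X`` (cells x genes) on the covariates
    (with intercept) by ordinary least squares."""
    C = np.column_stack([np.ones(len(X)), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ beta


def scale_genes(X: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Per-gene z-score (cells x genes), zero-variance genes -> 0, clipped."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return np.clip(Z, -clip, clip)


# ---------------------------------------------------------------------------
# SNN + Louvain
# ---------------------------------------------------------------------------


def snn_graph(
    embedding: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15
) -> sp.csr_matrix:
    """Shared-nearest-neighbour graph with Jaccard weights.

    Each cell is linked to its k nearest neighbours (self included); the
    edge weight between two cells is the Jaccard overlap of their
    neighbour sets, pruned below ``prune``.
    """
    n = len(embedding)
    k = min(k_neighbors, n)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    indices = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), k - 0)
    A = sp.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), indices.ravel())),
        shape=(n, n),
    )
    A = A.maximum(sp.eye(n, format="csr"))  # include self
    kk = np.asarray(A.sum(axis=1)).ravel()
    shared = (A @ A.T).tocoo()
    union = kk[shared.row] + kk[shared.col] - shared.data
    jac = shared.data / union
    keep = (jac >= prune) & (shared.row != shared.col)
    W = sp.csr_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    return W


def _community_labels(
    W: sp.spmatrix, resolution: float, seed: int, method: str
) -> np.ndarray:
    """Louvain/Leiden communities of a weighted undirected graph."""
    W = sp.triu(W.maximum(W.T), k=1).tocoo()
    n = W.shape[0]
    g = ig.Graph(
        n=n, edges=list(zip(W.row.tolist(), W.col.tolist())), directed=False
    )
    weights = W.data.tolist()
    if method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=resolution,
            seed=seed,
        )
        return np.asarray(part.membership)
    ig.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return np.asarray(part.membership)


class SNNLouvainClusterer(BaseEstimator, ClusterMixin):
    """PCA -> SNN graph -> Louvain communities, scikit-learn style.

    ``fit`` expects log-normalised expression, cells x genes.  Nuisance
    covariates may be regressed out of every gene first.  Fitted
    attributes: ``labels_`` (size-ordered cluster ids), ``embedding_``
    (cells x n_pcs PCA scores), ``snn_`` (the pruned SNN graph).
    """

    def __init__(
        self,
        n_pcs: int = 50,
        snn_dims: int = 30,
        resolution: float = 0.6,
        k_neighbors: int = 20,
        n_hvg: int = 2000,
        method: str = "louvain",
        random_state: int = 0,
    ):
        self.n_pcs = n_pcs
        self.snn_dims = snn_dims
        self.resolution = resolution
        self.k_neighbors = k_neighbors
        self.n_hvg = n_hvg
        self.method = method
        self.random_state = random_state

    def fit(self, X, y=None, covariates: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        n_cells = X.shape[0]
        if n_cells < self.k_neighbors + 1:
            raise ValidationError(
                f"need at least k_neighbors+1={self.k_neighbors + 1} cells, "
                f"got {n_cells}"
            )
        if self.snn_dims > self.n_pcs:
            raise ValidationError("snn_dims must be <= n_pcs")
        # highly variable gene selection
        variances = X.var(axis=0)
        n_hvg = min(self.n_hvg, X.shape[1])
        hvg = np.sort(np.argsort(-variances, kind="stable")[:n_hvg])
        Xs = X[:, hvg]
        if covariates is not None:
            Xs = regress_out(Xs, covariates)
        Xs = scale_genes(Xs)
        n_comp = max(1, min(self.n_pcs, n_cells - 1, Xs.shape[1]))
        pca = PCA(n_components=n_comp, svd_solver="auto",
                  random_state=self.random_state)
        emb = pca.fit_transform(Xs)
        self.embedding_ = emb
        dims = min(self.snn_dims, emb.shape[1])
        self.snn_ = snn_graph(emb[:, :dims], self.k_neighbors)
        raw = _community_labels(
            self.snn_, self.resolution, self.random_state, self.method
        )
        self.labels_ = relabel_by_size(raw)
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).labels_


def cluster_cells(
    matrix: CellMatrix,
    params: ClusterParams | None = None,
    covariates: tuple[str, ...] = (),
) -> ClusterAssignment:
    """Cluster cells of a CellMatrix; covariates name ``cell_meta`` columns
    (e.g. ``percent_mito``) regressed out of every gene before PCA."""
    params = params or ClusterParams()
    cov = None
    if covariates:
        for c in covariates:
            if c not in matrix.cell_meta.columns:
                raise ValidationError(f"covariate {c!r} absent from cell_meta")
        cov = matrix.cell_meta[list(covariates)].to_numpy(float)
    norm = LogNormalizer().transform(matrix.counts.T)
    est = SNNLouvainClusterer(
        n_pcs=params.n_pcs,
        snn_dims=params.snn_dims,
        resolution=params.resolution,
        k_neighbors=params.k_neighbors,
        n_hvg=params.n_hvg,
        method=params.method,
        random_state=params.seed,
    )
    labels = est.fit_predict(norm, covariates=cov)
    return ClusterAssignment(labels, params)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


class MNNIntegrator(BaseEstimator, TransformerMixin):
    """Mutual-nearest-neighbour batch correction in PCA space.

    ``fit_transform(X, batches)`` takes log-normalised cells x genes and
    a batch label per cell, and returns a corrected embedding
    (cells x dims).  The first batch (in label order of appearance) is
    the reference; each later batch is shifted towards it by the
    kernel-smoothed correction vectors of its anchor pairs.
    """

    def __init__(self, anchor_features: int = 3000, dims: int = 30,
                 k_anchors: int = 20, random_state: int = 0):
        self.anchor_features = anchor_features
        self.dims = dims
        self.k_anchors = k_anchors
        self.random_state = random_state

    def fit_transform(self, X, batches) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        variances = X.var(axis=0)
        n_feat = min(self.anchor_features, X.shape[1])
        hvg = np.sort(np.argsort(-variances, kind="stable")[:n_feat])
        Z = scale_genes(X[:, hvg])
        n_comp = max(1, min(self.dims, X.shape[0] - 1, Z.shape[1]))
        emb = PCA(n_components=n_comp, random_state=self.random_state).fit_transform(Z)

        order = list(pd.unique(batches))
        if len(order) == 1:
            self.embedding_ = emb
            return emb
        corrected = emb.copy()
        ref_idx = np.flatnonzero(batches == order[0])
        for b in order[1:]:
            b_idx = np.flatnonzero(batches == b)
            ref_pts = corrected[ref_idx]
            b_pts = corrected[b_idx]
            k = min(self.k_anchors, len(ref_idx), len(b_idx))
            nn_rb = NearestNeighbors(n_neighbors=k).fit(b_pts)
            nn_br = NearestNeighbors(n_neighbors=k).fit(ref_pts)
            to_b = nn_rb.kneighbors(ref_pts, return_distance=False)
            to_ref = nn_br.kneighbors(b_pts, return_distance=False)
            pairs = []
            ref_nbr_sets = [set(row) for row in to_b]
            for j, row in enumerate(to_ref):
                for r in row:
                    if j in ref_nbr_sets[r]:
                        pairs.append((r, j))
            if not pairs:
                ref_idx = np.concatenate([ref_idx, b_idx])
                continue
            pairs = np.asarray(pairs)
            anchor_pos = b_pts[pairs[:, 1]]
            vectors = ref_pts[pairs[:, 0]] - anchor_pos
            # kernel-smoothed per-cell correction
            d2 = (
                (b_pts[:, None, :] - anchor_pos[None, :, :]) ** 2
            ).sum(-1) if len(pairs) * len(b_pts) < 5_000_000 else None
            if d2 is None:
                nn_a = NearestNeighbors(
                    n_neighbors=min(10, len(pairs))
                ).fit(anchor_pos)
                dist, idx = nn_a.kneighbors(b_pts)
                sigma = np.median(dist) + 1e-12
                w = np.exp(-(dist**2) / (2 * sigma**2))
                w /= w.sum(axis=1, keepdims=True)
                corr = np.einsum("ij,ijk->ik", w, vectors[idx])
            else:
                sigma = np.median(np.sqrt(d2)) + 1e-12
                w = np.exp(-d2 / (2 * sigma**2))
                w /= w.sum(axis=1, keepdims=True)
                corr = w @ vectors
            corrected[b_idx] = b_pts + corr
            ref_idx = np.concatenate([ref_idx, b_idx])
        self.embedding_ = corrected
        return corrected


def integrate_samples(
    matrices: list[CellMatrix],
    anchor_features: int = 3000,
    dims: int = 30,
    seed: int = 0,
) -> CellMatrix:
    """Merge CellMatrices on shared genes and attach an MNN-corrected
    joint embedding (``embeddings['integrated']``).  Counts are
    concatenated unchanged; the source sample is recorded per cell in
    ``cell_meta['batch']``.
    """
    if not matrices:
        raise ValidationError("no matrices to integrate")
    if len(matrices) == 1:
        out = matrices[0].copy()
        norm = LogNormalizer().transform(out.counts.T)
        emb = MNNIntegrator(anchor_features, dims, random_state=seed).fit_transform(
            norm, np.zeros(out.n_cells, dtype=int)
        )
        out.embeddings["integrated"] = emb
        out.cell_meta["batch"] = "batch0"
        return out
    shared = set(matrices[0].gene_symbols)
    for m in matrices[1:]:
        shared &= set(m.gene_symbols)
    if not shared:
        raise ValidationError("matrices share no genes")
    shared = sorted(shared)
    parts, metas, ids, batches = [], [], [], []
    for bi, m in enumerate(matrices):
        rows = m.rows_for_symbols(shared, missing="error")
        sub = m.subset_genes(rows)
        order = np.argsort(np.asarray(sub.gene_symbols, dtype=object))
        sub = sub.subset_genes(order)
        parts.append(sub.counts)
        meta = sub.cell_meta.copy()
        meta["batch"] = f"batch{bi}"
        metas.append(meta)
        ids.extend(f"b{bi}:{c}" for c in sub.cell_ids)
        batches.extend([f"batch{bi}"] * sub.n_cells)
    gene_syms = sorted(shared)
    counts = sp.hstack(parts).tocsr()
    meta = pd.concat(metas, axis=0)
    meta.index = ids
    merged = CellMatrix(counts, gene_syms, gene_syms, ids, meta)
    norm = LogNormalizer().transform(counts.T)
    emb = MNNIntegrator(anchor_features, dims, random_state=seed).fit_transform(
        norm, np.asarray(batches)
    )
    merged.embeddings["integrated"] = emb
    return merged


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------


def downsample_per_cluster(
    matrix: CellMatrix,
    clusters: np.ndarray | ClusterAssignment,
    n_per_cluster: int = 400,
    seed: int = 0,
) -> CellMatrix:
    """Uniformly subsample each cluster to at most ``n_per_cluster`` cells
    (without replacement); smaller clusters are kept whole."""
    if n_per_cluster < 1:
        raise ValidationError("n_per_cluster must be >= 1")
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else clusters
    labels = np.asarray(labels)
    if len(labels) != matrix.n_cells:
        raise ValidationError("cluster assignment does not cover all cells")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cl in sorted(pd.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cl)
        if len(idx) > n_per_cluster:
            idx = np.sort(rng.choice(idx, size=n_per_cluster, replace=False))
        keep.append(idx)
    sel = np.sort(np.concatenate(keep))
    return matrix.subset_cells(sel)
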