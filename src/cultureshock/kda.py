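"""Causal DAG construction and key-driver analysis (KDA).

The causal graph over top-varying genes is learned by greedy score-based
hill climbing (Gaussian BIC, add/remove/reverse moves, acyclicity
enforced, parent cap), or supplied externally as a directed edge list.

Key-driver analysis asks, for every network node, whether the gene set
reachable from it within a few directed layers is enriched for an
*effector set* - the significant DE genes, a co-expression module, or
their overlap - under the hypergeometric distribution with the network's
node set as universe.  Drivers found in two networks (e.g. the two
culture preparations) are then prioritised lexicographically by
replication, the number of effector categories nominating them, and the
total number of nominating sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cluster import normalize_log
from .data import CellMatrix, DirectedNetwork, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# top-varying gene selection
# ---------------------------------------------------------------------------


def covariate_matrix(
    matrix: CellMatrix, covariates: tuple[str, ...]
) -> np.ndarray:
    """Numeric design matrix for the named ``cell_meta`` columns;
    categorical columns are one-hot encoded (first level dropped)."""
    parts = []
    for c in covariates:
        if c not in matrix.cell_meta.columns:
            raise ValidationError(f"covariate {c!r} absent from cell_meta")
        col = matrix.cell_meta[c]
        if pd.api.types.is_numeric_dtype(col):
            arr = col.to_numpy(float)[:, None]
        else:
            arr = pd.get_dummies(col, drop_first=True).to_numpy(float)
        if arr.shape[1] and np.any(arr.std(axis=0) == 0):
            raise ValidationError(f"zero-variance covariate {c!r}")
        parts.append(arr)
    return np.column_stack(parts) if parts else np.empty((matrix.n_cells, 0))


def residualize(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of X (cells x genes) on C + intercept."""
    D = np.column_stack([np.ones(len(X)), C])
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    return X - D @ beta


def top_varying_genes(
    matrix: CellMatrix,
    covariates: tuple[str, ...] = (),
    n_top: int = 300,
    norm: np.ndarray | None = None,
) -> list[str]:
    """Genes ranked by residual expression variance, descending.

    Expression is log-normalised; the named ``cell_meta`` covariates
    (numeric or categorical, e.g. percent_mito and the cluster label) are
    regressed out (OLS with intercept) before the per-gene variance is
    taken.  Ties break alphabetically.
    """
    if n_top > matrix.n_genes:
        raise ValidationError("n_top exceeds gene count")
    if norm is None:
        norm = normalize_log(matrix)
    X = norm.T  # cells x genes
    if covariates:
        X = residualize(X, covariate_matrix(matrix, covariates))
    var = X.var(axis=0)
    order = sorted(
        range(matrix.n_genes), key=lambda i: (-var[i], matrix.gene_symbols[i])
    )
    return [matrix.gene_symbols[i] for i in order[:n_top]]


# ---------------------------------------------------------------------------
# greedy DAG learning
# ---------------------------------------------------------------------------


class GreedyDAGLearner(BaseEstimator):
    """Score-based DAG structure learning by hill climbing.

    Starts from the empty graph and repeatedly applies the single best
    add/remove/reverse edge move under the decomposable Gaussian BIC
    score, subject to acyclicity and a parent cap, until no move improves
    the score.  Deterministic: moves are scanned in sorted order and ties
    go to the lexicographically first operation.

    ``fit(X)`` takes cells x genes expression; fitted attributes are
    ``network_`` (a :class:`DirectedNetwork`), ``edges_`` and ``score_``.
    """

    def __init__(self, max_parents: int = 3, max_iter: int = 2000,
                 tol: float = 1e-6, penalty: float = 2.0,
                 random_state: int = 0):
        self.max_parents = max_parents
        self.max_iter = max_iter
        self.tol = tol
        # multiplier on the BIC complexity term (extended-BIC style);
        # >1 suppresses the dense tail of weak edges typical of
        # compositionally coupled expression data
        self.penalty = penalty
        self.random_state = random_state

    # local Gaussian BIC score of node i given parent tuple, from the
    # (standardised) covariance matrix
    def _local(self, i: int, parents: tuple[int, ...]) -> float:
        key = (i, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        S = self._cov
        if parents:
            P = list(parents)
            coef = np.linalg.solve(
                S[np.ix_(P, P)] + 1e-10 * np.eye(len(P)), S[P, i]
            )
            sigma2 = S[i, i] - float(S[i, P] @ coef)
        else:
            sigma2 = S[i, i]
        sigma2 = max(sigma2, 1e-12)
        val = -0.5 * self._n * np.log(sigma2) - 0.5 * self.penalty * np.log(
            self._n
        ) * (len(parents) + 1)
        self._cache[key] = val
        return val

    @staticmethod
    def _reach(adj: np.ndarray) -> np.ndarray:
        """Boolean reachability (paths of length >= 1)."""
        R = adj.copy()
        while True:
            R2 = R | (R @ adj)
            if (R2 == R).all():
                return R
            R = R2

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        names = list(feature_names) if feature_names is not None else [
            f"g{i}" for i in range(p)
        ]
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)
        if np.any(sd == 0):
            raise ValidationError("constant-expression gene passed to DAG learner")
        Xc = Xc / sd
        self._cov = (Xc.T @ Xc) / n
        self._n = n
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

        parents: list[set[int]] = [set() for _ in range(p)]
        adj = np.zeros((p, p), dtype=bool)
        S = self._cov
        n_log = np.log(n)
        pen = 0.5 * self.penalty * n_log

        def ptup(i):
            return tuple(sorted(parents[i]))

        def add_deltas(v: int) -> np.ndarray:
            """Score gain of adding each candidate parent u to v
            (vectorised via the rank-one residual-variance update)."""
            P = sorted(parents[v])
            if P:
                SPP = S[np.ix_(P, P)] + 1e-10 * np.eye(len(P))
                w = np.linalg.solve(SPP, S[P, v])
                sigma2_P = S[v, v] - float(S[P, v] @ w)
                SuP = S[:, P]
                M = np.linalg.solve(SPP, SuP.T)  # k x p
                c = S[:, v] - SuP @ w
                d = np.diag(S) - np.einsum("ik,ki->i", SuP, M)
            else:
                sigma2_P = S[v, v]
                c = S[:, v].copy()
                d = np.diag(S).copy()
            sigma2_P = max(sigma2_P, 1e-12)
            sigma2_u = np.maximum(sigma2_P - c**2 / np.maximum(d, 1e-12), 1e-12)
            return -0.5 * n * (np.log(sigma2_u) - np.log(sigma2_P)) - pen

        def op_delta(kind: str, u: int, v: int) -> float:
            pv = ptup(v)
            base_v = self._local(v, pv)
            if kind == "add":
                return self._local(v, tuple(sorted(parents[v] | {u}))) - base_v
            if kind == "del":
                return self._local(v, tuple(sorted(parents[v] - {u}))) - base_v
            d_del = self._local(v, tuple(sorted(parents[v] - {u}))) - base_v
            pu = ptup(u)
            d_add = self._local(u, tuple(sorted(parents[u] | {v}))) - self._local(u, pu)
            return d_del + d_add

        moves = 0
        for _sweep in range(50):
            changed_any = False

            # forward phase: best single-parent addition until none improves
            D = np.empty((p, p))
            for v in range(p):
                D[:, v] = add_deltas(v)
            R = self._reach(adj)
            while moves < self.max_iter:
                mask = (~adj) & (~adj.T) & (~R.T)
                np.fill_diagonal(mask, False)
                full = np.array([len(parents[v]) >= self.max_parents
                                 for v in range(p)])
                mask[:, full] = False
                Dm = np.where(mask, D, -np.inf)
                u, v = np.unravel_index(int(np.argmax(Dm)), Dm.shape)
                if Dm[u, v] <= self.tol:
                    break
                parents[v].add(u)
                adj[u, v] = True
                moves += 1
                changed_any = True
                # incremental reachability: new paths run through u -> v
                Ru = R[:, u].copy()
                Ru[u] = True
                Rv = R[v, :].copy()
                Rv[v] = True
                R |= np.outer(Ru, Rv)
                D[:, v] = add_deltas(v)

            # backward phase: best deletion until none improves
            while moves < self.max_iter:
                best = None
                for u, v in zip(*np.nonzero(adj)):
                    d = op_delta("del", int(u), int(v))
                    if d > self.tol and (best is None or d > best[0] + 1e-12):
                        best = (d, int(u), int(v))
                if best is None:
                    break
                _, u, v = best
                parents[v].discard(u)
                adj[u, v] = False
                moves += 1
                changed_any = True

            # reversal phase: best acyclic reversal until none improves
            while moves < self.max_iter:
                R = self._reach(adj)
                best = None
                for u, v in zip(*np.nonzero(adj)):
                    u, v = int(u), int(v)
                    if len(parents[u]) >= self.max_parents:
                        continue
                    d = op_delta("rev", u, v)
                    if d > self.tol and (best is None or d > best[0] + 1e-12):
                        adj[u, v] = False
                        ok = not self._reach(adj)[u, v]
                        adj[u, v] = True
                        if ok:
                            best = (d, u, v)
                if best is None:
                    break
                _, u, v = best
                parents[v].discard(u)
                adj[u, v] = False
                parents[u].add(v)
                adj[v, u] = True
                moves += 1
                changed_any = True

            if not changed_any:
                break

        edges = [
            (names[u], names[v]) for v in range(p) for u in sorted(parents[v])
        ]
        edges.sort()
        self.network_ = DirectedNetwork(names, edges)
        self.edges_ = edges
        self.score_ = float(sum(self._local(i, ptup(i)) for i in range(p)))
        return self


def learn_dag(
    matrix: CellMatrix,
    genes: list[str],
    max_parents: int = 3,
    seed: int = 0,
    covariates: tuple[str, ...] = (),
    norm: np.ndarray | None = None,
    penalty: float = 2.0,
) -> DirectedNetwork:
    """Learn a causal DAG over the given genes from a CellMatrix.

    Expression is log-normalised with the named covariates regressed out
    (the same residual the top-varying selection ranks on).  Constant-
    expression genes are dropped with a warning; at least 50 cells are
    required.
    """
    if matrix.n_cells < 50:
        raise ValidationError("need at least 50 cells to learn a DAG")
    if norm is None:
        norm = normalize_log(matrix)
    rows = {s: i for i, s in enumerate(matrix.gene_symbols)}
    missing = [g for g in genes if g not in rows]
    if missing:
        raise ValidationError(f"genes not in matrix: {missing[:5]}")
    X = norm[[rows[g] for g in genes], :].T
    if covariates:
        X = residualize(X, covariate_matrix(matrix, covariates))
    sd = X.std(axis=0)
    if np.any(sd == 0):
        dropped = [g for g, s in zip(genes, sd) if s == 0]
        warnings.warn(f"dropping {len(dropped)} constant genes: {dropped[:5]}")
        keep = sd > 0
        X = X[:, keep]
        genes = [g for g, k in zip(genes, keep) if k]
    learner = GreedyDAGLearner(
        max_parents=max_parents, penalty=penalty, random_state=seed
    )
    learner.fit(X, feature_names=genes)
    return learner.network_


# ---------------------------------------------------------------------------
# effector sets and enrichment
# ---------------------------------------------------------------------------


@dataclass
class EffectorSetCollection:
    """Named effector gene sets with category labels.

    For M modules the construction always defines 2M+1 sets (1 DE set,
    M module sets, M DE-module overlap sets); ``n_total`` records that
    identity while empty sets are dropped from ``sets`` (``n_dropped``).
    """

    sets: dict[str, set]
    categories: dict[str, str]
    n_modules: int
    n_total: int
    n_dropped: int
    network_id: str = ""

    def __post_init__(self) -> None:
        assert self.n_total == 2 * self.n_modules + 1


def build_effector_sets(
    de_genes: set,
    modules: pd.Series | dict,
    network: DirectedNetwork,
    network_id: str = "",
) -> EffectorSetCollection:
    """The three effector categories for one network: significant DE
    genes, each co-expression module, and each DE-module overlap, all
    restricted to the network's nodes."""
    de_genes = set(de_genes)
    if not de_genes:
        raise ValidationError("empty DE gene set")
    if isinstance(modules, dict):
        modules = pd.Series(modules)
    if len(modules) == 0:
        raise ValidationError("empty module assignment")
    nodes = set(network.nodes)
    module_ids = sorted(pd.unique(modules).tolist())
    M = len(module_ids)
    raw: dict[str, set] = {"DE": de_genes & nodes}
    cats: dict[str, str] = {"DE": "DE"}
    for m in module_ids:
        genes = set(modules.index[modules == m]) & nodes
        raw[f"module_{m}"] = genes
        cats[f"module_{m}"] = "module"
        raw[f"DE_module_{m}"] = genes & de_genes
        cats[f"DE_module_{m}"] = "DE_module"
    n_total = 2 * M + 1
    kept = {k: v for k, v in raw.items() if v}
    n_dropped = n_total - len(kept)
    if n_dropped:
        logger.info("dropped %d empty effector sets (of %d)", n_dropped, n_total)
    return EffectorSetCollection(
        sets=kept,
        categories={k: cats[k] for k in kept},
        n_modules=M,
        n_total=n_total,
        n_dropped=n_dropped,
        network_id=network_id,
    )


def downstream_set(
    network: DirectedNetwork, node: str, depth: int | None = 3
) -> set:
    """Nodes reachable from ``node`` by directed paths of length <=
    ``depth`` (``None`` = unbounded), excluding the node itself."""
    if node not in set(network.nodes):
        raise ValidationError(f"node {node!r} not in network")
    adj = network.children()
    frontier = {node}
    seen = {node}
    out: set = set()
    d = 0
    while frontier and (depth is None or d < depth):
        nxt = set()
        for n in frontier:
            for c in adj[n]:
                if c not in seen:
                    seen.add(c)
                    nxt.add(c)
        out |= nxt
        frontier = nxt
        d += 1
    return out


def kda_enrich(
    network: DirectedNetwork,
    effector_sets: EffectorSetCollection,
    depth: int | None = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every node's downstream set in every
    effector set; universe = network nodes; BH across all (node, set)
    pairs.  A node is a key driver for a set iff adjusted p < alpha."""
    if len(network.nodes) < 5:
        raise ValidationError("network too small for enrichment (need >= 5 nodes)")
    nodes = set(network.nodes)
    N = len(nodes)
    rows = []
    for node in sorted(network.nodes):
        dset = downstream_set(network, node, depth)
        if not dset:
            continue
        n_down = len(dset)
        for name, S in effector_sets.sets.items():
            S_net = S & nodes
            K = len(S_net)
            k = len(S_net & dset)
            p = float(st.hypergeom.sf(k - 1, N, K, n_down))
            rows.append(
                {
                    "node": node,
                    "effector_set": name,
                    "category": effector_sets.categories[name],
                    "overlap": k,
                    "downstream_size": n_down,
                    "set_size": K,
                    "p_raw": p,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
        table["is_key_driver"] = table["p_adj"] < alpha
    else:
        table["p_adj"] = []
        table["is_key_driver"] = []
    return table


def driver_records(enrich_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary of one network's KDA: number of nominating sets,
    number of nominating categories, minimal adjusted p."""
    hits = enrich_table[enrich_table["is_key_driver"]]
    if not len(hits):
        return pd.DataFrame(
            columns=["n_sets", "n_categories", "min_p_adj"]
        ).rename_axis("gene")
    grouped = hits.groupby("node")
    out = pd.DataFrame(
        {
            "n_sets": grouped.size(),
            "n_categories": grouped["category"].nunique(),
            "min_p_adj": grouped["p_adj"].min(),
        }
    )
    out.index.name = "gene"
    return out


def prioritize(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> pd.DataFrame:
    """Rank key drivers across two networks.

    Lexicographic criteria: (1) nominated in both networks, (2) larger
    summed category count, (3) larger summed nominating-set count; ties
    break alphabetically (logged).  Rank 1 is best.  The numeric
    ``score`` (4*both + categories + 0.01*sets) is for display only.
    """
    a = records_a.add_suffix("_a")
    b = records_b.add_suffix("_b")
    merged = a.join(b, how="outer")
    for c in merged.columns:
        if c.startswith(("n_sets", "n_categories")):
            merged[c] = merged[c].fillna(0).astype(int)
    merged["in_both"] = (merged["n_sets_a"] > 0) & (merged["n_sets_b"] > 0)
    merged["categories_total"] = merged["n_categories_a"] + merged["n_categories_b"]
    merged["sets_total"] = merged["n_sets_a"] + merged["n_sets_b"]
    merged = merged.sort_index()
    merged = merged.sort_values(
        ["in_both", "categories_total", "sets_total"],
        ascending=[False, False, False],
        kind="stable",
    )
    dup = merged.duplicated(
        subset=["in_both", "categories_total", "sets_total"], keep=False
    )
    if dup.any():
        logger.info("%d prioritisation ties broken alphabetically", int(dup.sum()))
    merged["score"] = (
        4.0 * merged["in_both"].astype(int)
        + merged["categories_total"]
        + 0.01 * merged["sets_total"]
    )
    merged["rank"] = np.arange(1, len(merged) + 1)
    merged.index.name = "gene"
    return merged
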