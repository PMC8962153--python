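"""Marker discovery and pseudo-bulk two-group differential expression.

Per-gene tests are Wilcoxon rank-sum on log-normalised expression.  The
reported fold change, ``avg_logFC``, is the natural-log difference of
``log(mean(expm1(normalised)) + 1)`` between groups - the convention of
the single-cell toolchain this pipeline mirrors, stated explicitly
because "average logFC" conventions differ.  Multiple testing uses
Bonferroni over the genes tested (Benjamini-Hochberg behind a flag).

"Pseudo-bulk" here means all cells of each preparation pooled as two
groups with cell-level tests; true per-sample aggregation is a separate,
differently-named option (:func:`aggregate_pseudobulk`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .cluster import normalize_log
from .data import CellMatrix, ValidationError


@dataclass
class DEResult:
    """Per-gene two-group DE table for one contrast.

    Columns: ``avg_logFC`` (natural log, group_a vs group_b), ``p_raw``,
    ``p_adj``, ``pct_a`` / ``pct_b`` (fraction of cells with a nonzero
    raw count per group).  Swapping the groups negates every avg_logFC
    and leaves p-values unchanged.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str

    def significant(self, alpha: float = 0.05, lfc_min: float = 0.5) -> pd.DataFrame:
        """Genes with ``p_adj < alpha`` and ``|avg_logFC| >= lfc_min``."""
        t = self.table
        return t[(t["p_adj"] < alpha) & (t["avg_logFC"].abs() >= lfc_min)]


def exact_rank_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum permutation p-value (midranks for ties).

    Enumerates every assignment of the pooled observations to the two
    group sizes; p is the fraction of assignments whose rank-sum deviates
    from its expectation at least as much as observed.  Intended for tiny
    groups (pooled n <= ~12).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = st.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    expect = n_a * (n + 1) / 2.0
    obs = abs(ranks[:n_a].sum() - expect)
    hits = total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - expect) >= obs - 1e-12:
            hits += 1
    return hits / total


def _wilcoxon_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per row of (genes x cells) blocks."""
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a + n_b <= 12:
        return np.array([exact_rank_p(A[i], B[i]) for i in range(A.shape[0])])
    res = st.mannwhitneyu(A, B, axis=1, method="asymptotic")
    return np.asarray(res.pvalue)


def _avg_log_fc(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    mean_a = np.expm1(norm_a).mean(axis=1)
    mean_b = np.expm1(norm_b).mean(axis=1)
    return np.log(mean_a + 1.0) - np.log(mean_b + 1.0)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValidationError(f"unknown adjustment {method!r}")


def pairwise_de(
    matrix: CellMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    lfc_min: float = 0.5,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("group_a", "group_b"),
    adjust: str = "bonferroni",
    norm: np.ndarray | None = None,
) -> DEResult:
    """Two-group DE over all genes (Wilcoxon + Bonferroni).

    ``group_a`` / ``group_b`` are disjoint boolean cell masks, each
    covering at least 3 cells.  The full per-gene table is returned; the
    significant set at ``(alpha, lfc_min)`` is available via
    :meth:`DEResult.significant`.
    """
    group_a = np.asarray(group_a, bool)
    group_b = np.asarray(group_b, bool)
    if (group_a & group_b).any():
        raise ValidationError("group masks overlap")
    if group_a.sum() < 3 or group_b.sum() < 3:
        raise ValidationError("each group needs at least 3 cells")
    if norm is None:
        norm = normalize_log(matrix)
    A = norm[:, group_a]
    B = norm[:, group_b]
    counts = matrix.counts.tocsc()
    pct_a = np.asarray((counts[:, group_a] > 0).mean(axis=1)).ravel()
    pct_b = np.asarray((counts[:, group_b] > 0).mean(axis=1)).ravel()
    p = _wilcoxon_pvalues(A, B)
    table = pd.DataFrame(
        {
            "avg_logFC": _avg_log_fc(A, B),
            "p_raw": p,
            "p_adj": _adjust(p, adjust),
            "pct_a": pct_a,
            "pct_b": pct_b,
        },
        index=pd.Index(matrix.gene_symbols, name="gene"),
    ).sort_values("avg_logFC", ascending=False)
    return DEResult(table, labels[0], labels[1])


def cluster_markers(
    matrix: CellMatrix,
    clusters: np.ndarray,
    min_pct: float = 0.25,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> dict[int, DEResult]:
    """One-vs-rest marker tables per cluster.

    Genes are pre-filtered to those expressed in at least ``min_pct`` of
    the cluster's cells before testing; Bonferroni runs over the genes
    actually tested.  Singleton clusters are skipped with a warning.
    """
    clusters = np.asarray(clusters)
    uniq = sorted(pd.unique(clusters).tolist())
    if len(uniq) < 2:
        raise ValidationError("need at least 2 clusters for marker discovery")
    norm = normalize_log(matrix)
    counts = matrix.counts.tocsc()
    out: dict[int, DEResult] = {}
    for cl in uniq:
        mask = clusters == cl
        if mask.sum() < 2:
            warnings.warn(f"cluster {cl} is a singleton; skipped")
            continue
        rest = ~mask
        pct_a = np.asarray((counts[:, mask] > 0).mean(axis=1)).ravel()
        tested = np.flatnonzero(pct_a >= min_pct)
        if tested.size == 0:
            warnings.warn(f"cluster {cl}: no genes pass min_pct; skipped")
            continue
        A = norm[np.ix_(tested, mask)]
        B = norm[np.ix_(tested, rest)]
        p = _wilcoxon_pvalues(A, B)
        pct_b = np.asarray((counts[np.ix_(tested, rest)] > 0).mean(axis=1)).ravel()
        table = pd.DataFrame(
            {
                "avg_logFC": _avg_log_fc(A, B),
                "p_raw": p,
                "p_adj": _adjust(p, adjust),
                "pct_a": pct_a[tested],
                "pct_b": pct_b,
            },
            index=pd.Index(
                [matrix.gene_symbols[i] for i in tested], name="gene"
            ),
        ).sort_values("avg_logFC", ascending=False)
        out[int(cl)] = DEResult(table, f"cluster_{cl}", "rest")
    return out


def volcano_classify(
    result: DEResult, alpha: float = 0.01, lfc: float = 1.0
) -> tuple[list[str], list[str]]:
    """Split a DE table into (up, down) gene lists at ``p_adj < alpha``
    and ``|avg_logFC| > lfc`` (strict, matching volcano highlighting)."""
    t = result.table
    up = t[(t["p_adj"] < alpha) & (t["avg_logFC"] > lfc)].index.tolist()
    down = t[(t["p_adj"] < alpha) & (t["avg_logFC"] < -lfc)].index.tolist()
    return up, down


def culture_shock_signature(
    result: DEResult,
    n: int = 20,
    alpha: float = 0.05,
    lfc_min: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Top-n up- and down-regulated genes of the significant set, ordered
    by avg_logFC (the in-vitro activation signature)."""
    sig = result.significant(alpha, lfc_min)
    up = sig[sig["avg_logFC"] > 0].sort_values("avg_logFC", ascending=False)
    down = sig[sig["avg_logFC"] < 0].sort_values("avg_logFC", ascending=True)
    if len(up) < n or len(down) < n:
        warnings.warn(
            f"fewer than n={n} significant genes in a direction "
            f"({len(up)} up, {len(down)} down); returning all available"
        )
    return up.index[:n].tolist(), down.index[:n].tolist()


def overlap_sets(deg_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every region of the Venn partition of the given sets.

    Keys are the sorted tuple of set names a region belongs to; only
    regions inside at least one set are reported (zero counts included
    for every non-empty combination of names).
    """
    if len(deg_sets) < 2:
        raise ValidationError("need at least 2 sets to overlap")
    names = list(deg_sets)
    sets = {k: set(v) for k, v in deg_sets.items()}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[tuple(sorted(combo))] = 0
    for g in set().union(*sets.values()):
        membership = tuple(sorted(k for k in names if g in sets[k]))
        regions[membership] += 1
    return regions


def composition_table(clusters: np.ndarray, source: np.ndarray) -> pd.DataFrame:
    """Per-cluster source percentages (rows sum to 100)."""
    clusters = np.asarray(clusters)
    source = np.asarray(source)
    if len(clusters) != len(source):
        raise ValidationError("labels do not cover all cells")
    tab = pd.crosstab(pd.Series(clusters, name="cluster"),
                      pd.Series(source, name="source"))
    return 100.0 * tab.div(tab.sum(axis=1), axis=0)


def aggregate_pseudobulk(
    matrix: CellMatrix, sample: np.ndarray
) -> pd.DataFrame:
    """True per-sample aggregation: summed raw counts per sample (genes x
    samples).  This is *not* the cell-level pooled comparison used by the
    main contrasts; it is provided for sample-level modelling."""
    sample = np.asarray(sample)
    if len(sample) != matrix.n_cells:
        raise ValidationError("sample labels do not cover all cells")
    out = {}
    for s in pd.unique(sample):
        mask = sample == s
        out[s] = np.asarray(matrix.counts[:, mask].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=pd.Index(matrix.gene_symbols, name="gene"))
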