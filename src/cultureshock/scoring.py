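"""Gene-set percentage scoring and cluster state classification.

A cell's score for a gene set is the percentage of its UMIs that come
from genes in the set (0-100).  For a collection of disjoint sets that
covers the whole gene universe, per-cell scores sum to exactly 100.
Clusters are classified by their mean score per set after z-scaling
across clusters, mirroring heat-map based assignment of clusters to
microglial state families (proliferation, macrophage-like,
monocyte-like, microglia-like; or homeostatic / activated / interferon).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from .data import CellMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

#: seed marker lists for the seven microglial state programs; users supply
#: full lists via GMT.  Sources are the meta-analysis marker panels the
#: state names come from.
DEFAULT_STATE_MARKERS: dict[str, list[str]] = {
    "PROLIFERATION": ["Top2a", "Birc5"],
    "MACROPHAGE": ["F13a1", "Mrc1"],
    "INTERFERON": ["Ifit1", "Irf7"],
    "LPS": ["Ifitm3", "Crip1"],
    "MONOCYTE": ["S100a4", "Anxa1"],
    "RESTING_MICROGLIA": ["Tmem119", "P2ry12", "Cx3cr1", "Hexb"],
    "NEURODEGENERATION": ["Lpl", "Cst7", "Apoe", "Spp1", "Lyz2", "Ccl4"],
}


def default_state_sets() -> GeneSetCollection:
    """Small built-in microglial state panel (see DEFAULT_STATE_MARKERS)."""
    return GeneSetCollection(
        {k: list(v) for k, v in DEFAULT_STATE_MARKERS.items()},
        provenance={k: "built-in seed markers" for k in DEFAULT_STATE_MARKERS},
    )


def enforce_nonoverlap(
    collection: GeneSetCollection, priority: list[str]
) -> GeneSetCollection:
    """Resolve overlaps: each gene is kept only in its highest-priority set.

    ``priority`` must cover all set names (earlier = higher priority).
    The union of genes is preserved.
    """
    missing = set(collection.sets) - set(priority)
    if missing:
        raise ValidationError(f"priority does not cover sets: {sorted(missing)}")
    claimed: set[str] = set()
    new_sets: dict[str, list[str]] = {}
    for name in priority:
        if name not in collection.sets:
            continue
        kept = [g for g in collection.sets[name] if g not in claimed]
        claimed.update(kept)
        new_sets[name] = kept
    # preserve original ordering of set names
    ordered = {name: new_sets[name] for name in collection.sets}
    return GeneSetCollection(ordered, dict(collection.provenance), nonoverlapping=True)


def percent_feature_set(matrix: CellMatrix, gene_set: list[str]) -> np.ndarray:
    """Per-cell percentage of UMIs from the given genes (0 for empty cells).

    Genes absent from the universe are ignored with a warning.
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    if not gene_set:
        return np.zeros(matrix.n_cells)
    rows = matrix.rows_for_symbols(gene_set, missing="ignore")
    if rows.size == 0:
        return np.zeros(matrix.n_cells)
    in_set = np.asarray(matrix.counts[rows, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, 100.0 * in_set / np.maximum(totals, 1.0), 0.0)


def score_table(matrix: CellMatrix, collection: GeneSetCollection) -> pd.DataFrame:
    """Cells x sets table of gene-set percentages (the state score table)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = {
            name: percent_feature_set(matrix, genes)
            for name, genes in collection.sets.items()
        }
    return pd.DataFrame(data, index=matrix.cell_ids)


def detection_summary(
    matrix: CellMatrix, collection: GeneSetCollection, min_cells: int = 10
) -> pd.DataFrame:
    """Per-set detection summary: size, n_detected, percent_detected.

    A gene is detected iff it has a nonzero count in at least
    ``min_cells`` cells; genes of the set absent from the matrix count as
    undetected.  ``percent_detected`` is rounded to one decimal; empty
    sets report it as missing (NaN).
    """
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    cells_expressing = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    detected_syms = {
        s
        for s, n in zip(matrix.gene_symbols, cells_expressing)
        if n >= min_cells
    }
    rows = []
    for name, genes in collection.sets.items():
        size = len(genes)
        n_det = sum(1 for g in genes if g in detected_syms)
        pct = round(100.0 * n_det / size, 1) if size else float("nan")
        rows.append(
            {"gene_set": name, "size": size, "n_detected": n_det,
             "percent_detected": pct}
        )
    return pd.DataFrame(rows).set_index("gene_set")


@dataclass
class ClusterStateLabel:
    """Per-cluster state labels plus the scaled score matrix behind them."""

    labels: dict[int, str]
    scaled_scores: pd.DataFrame  # clusters x sets, z-scaled per set
    mean_scores: pd.DataFrame  # clusters x sets, raw means
    linkage: np.ndarray | None  # hierarchical clustering for display order


def classify_clusters(
    scores: pd.DataFrame,
    clusters: np.ndarray,
    class_map: dict[str, str],
    priority: list[str] | None = None,
) -> ClusterStateLabel:
    """Label each cluster by its most enriched class-defining gene set.

    Per-cluster mean scores are z-scaled *across clusters* within each
    set; a cluster's label is the class of its argmax scaled score among
    the sets named in ``class_map``.  Ties resolve to the earliest set in
    ``priority`` (default: ``class_map`` order) and are logged.  Average-
    linkage Euclidean hierarchical clustering of the scaled matrix is
    returned for display ordering (None for fewer than two clusters).
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(scores):
        raise ValidationError("cluster assignment does not cover all scored cells")
    for s in class_map:
        if s not in scores.columns:
            raise ValidationError(f"class-defining set {s!r} not in score table")
    priority = priority or list(class_map)
    mean_scores = scores.groupby(clusters).mean()
    mu = mean_scores.mean(axis=0)
    sd = mean_scores.std(axis=0, ddof=0)
    scaled = (mean_scores - mu) / sd.replace(0.0, np.nan)
    scaled = scaled.fillna(0.0)
    defining = [s for s in priority if s in class_map]
    labels: dict[int, str] = {}
    for cl in mean_scores.index:
        row = scaled.loc[cl, defining]
        best = row.max()
        winners = [s for s in defining if row[s] == best]
        if len(winners) > 1:
            logger.warning(
                "cluster %s: tie between %s; using priority order", cl, winners
            )
        labels[int(cl)] = class_map[winners[0]]
    link = None
    if len(mean_scores) > 1:
        from scipy.spatial.distance import pdist

        link = sch.linkage(pdist(scaled.to_numpy()), method="average")
    return ClusterStateLabel(labels, scaled, mean_scores, link)


def compare_scores(
    scores: pd.DataFrame,
    clusters: np.ndarray,
    cluster_a: int,
    cluster_b: int,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Two-tailed two-sample t-test of each gene-set score between two
    clusters, Bonferroni-adjusted over the batch of tests.

    ``n_tests`` defaults to the number of gene sets in the table.
    """
    clusters = np.asarray(clusters)
    a_mask = clusters == cluster_a
    b_mask = clusters == cluster_b
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValidationError("both clusters need at least 2 cells for a t-test")
    n_tests = n_tests or scores.shape[1]
    rows = []
    for name in scores.columns:
        a = scores.loc[a_mask, name].to_numpy(float)
        b = scores.loc[b_mask, name].to_numpy(float)
        t, p = st.ttest_ind(a, b)
        if not np.isfinite(t):
            t, p = 0.0, 1.0
        rows.append(
            {
                "gene_set": name,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": float(min(1.0, p * n_tests)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")


def fraction_percent(part: float, whole: float, ndigits: int = 1) -> float:
    """``100 * part / whole`` rounded to ``ndigits`` - the convention used
    for all reported cell-count percentages."""
    if whole == 0:
        raise ValidationError("whole must be nonzero")
    return round(100.0 * part / whole, ndigits)
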