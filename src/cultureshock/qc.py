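"""Per-cell QC metrics and preparation-specific filtering rules.

Metrics follow the droplet scRNA-seq conventions: ``nCount_RNA`` (total
UMIs), ``nFeature_RNA`` (genes with nonzero count) and ``percent_mito``
(percentage of UMIs from "mt-" prefixed genes, 0-100).

Filter presets encode the two-round cleaning used for each preparation
(astrocyte co-culture, freshly isolated, shaken-off monoculture).  All
comparisons are strict: a cell sitting exactly on a threshold is
retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CellMatrix, ValidationError

logger = logging.getLogger(__name__)

QC_COLUMNS = ("nCount_RNA", "nFeature_RNA", "percent_mito")

#: default marker panel used to call a cluster myeloid
MYELOID_MARKERS = ("Hexb", "Trem2", "C1qa", "Ctss")


@dataclass
class FilterRules:
    """An ordered list of removal clauses ``(metric, comparator, threshold)``.

    A cell is removed if it matches *any* clause; comparators are strict
    (``<`` or ``>``) or inclusive (``<=`` / ``>=``).
    """

    clauses: list[tuple[str, str, float]]
    name: str = "custom"

    _OPS = {
        "<": np.less,
        ">": np.greater,
        "<=": np.less_equal,
        ">=": np.greater_equal,
    }

    def __post_init__(self) -> None:
        for metric, comp, thr in self.clauses:
            if comp not in self._OPS:
                raise ValidationError(f"bad comparator {comp!r}")
            if not np.isfinite(thr):
                raise ValidationError(f"non-finite threshold for {metric}")

    def matches(self, meta: pd.DataFrame) -> dict[str, np.ndarray]:
        """Per-clause boolean removal masks, keyed by a readable label."""
        out = {}
        for metric, comp, thr in self.clauses:
            if metric not in meta.columns:
                raise ValidationError(
                    f"rules reference metric {metric!r} absent from cell_meta; "
                    "run compute_qc_metrics first"
                )
            out[f"{metric} {comp} {thr:g}"] = self._OPS[comp](
                meta[metric].to_numpy(float), thr
            )
        return out


_PRESETS: dict[str, list[tuple[str, str, float]]] = {
    # astro-plated co-culture, round 1: drop huge libraries and high-mito
    "astro_round1": [("nCount_RNA", ">", 50000), ("percent_mito", ">", 10)],
    # astro round 2: tighter mito cut, low-count droplets, doublet-like cells
    "astro_round2": [
        ("percent_mito", ">", 5),
        ("nCount_RNA", "<", 3000),
        ("nFeature_RNA", ">", 6000),
    ],
    # freshly isolated, round 1: library-size cut only
    "fresh_round1": [("nCount_RNA", ">", 10000)],
    # fresh round 2: mito cut
    "fresh_round2": [("percent_mito", ">", 10)],
    # shaken-off monoculture, round 1
    "micro_round1": [("nCount_RNA", ">", 10000), ("percent_mito", ">", 20)],
    # micro round 2: stringent mito cut
    "micro_round2": [("percent_mito", ">", 5)],
}


def compute_qc_metrics(matrix: CellMatrix, mito_prefix: str = "mt-") -> CellMatrix:
    """Append nCount_RNA / nFeature_RNA / percent_mito to ``cell_meta``.

    ``percent_mito`` is 100 x (UMIs from ``mito_prefix`` genes / total
    UMIs), defined as 0 for zero-count cells.
    """
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValidationError("empty matrix")
    counts = matrix.counts.tocsc()
    n_count = np.asarray(counts.sum(axis=0)).ravel()
    n_feature = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_rows = [
        i for i, s in enumerate(matrix.gene_symbols) if s.startswith(mito_prefix)
    ]
    if mito_rows:
        mito = np.asarray(counts[mito_rows, :].sum(axis=0)).ravel()
    else:
        warnings.warn(f"no genes with prefix {mito_prefix!r}; percent_mito set to 0")
        mito = np.zeros_like(n_count, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_count > 0, 100.0 * mito / np.maximum(n_count, 1), 0.0)
    out = matrix.copy()
    out.cell_meta["nCount_RNA"] = n_count.astype(float)
    out.cell_meta["nFeature_RNA"] = n_feature.astype(int)
    out.cell_meta["percent_mito"] = pct.astype(float)
    return out


def preset_rules(preparation: str) -> FilterRules:
    """Return the filter clause list for a named cleaning round."""
    if preparation not in _PRESETS:
        raise ValidationError(
            f"unknown preset {preparation!r}; valid presets: {sorted(_PRESETS)}"
        )
    return FilterRules(list(_PRESETS[preparation]), name=preparation)


def apply_filter(
    matrix: CellMatrix, rules: FilterRules
) -> tuple[CellMatrix, pd.DataFrame]:
    """Drop cells matching any removal clause.

    Returns the surviving subset and a removal log with the per-clause
    match count (clauses can overlap), the total removed and survivors.
    Filtering is idempotent: reapplying the same rules removes nothing.
    """
    masks = rules.matches(matrix.cell_meta)
    removed = np.zeros(matrix.n_cells, dtype=bool)
    rows = []
    for label, m in masks.items():
        rows.append({"clause": label, "n_matched": int(m.sum())})
        removed |= m
    rows.append({"clause": "TOTAL_REMOVED", "n_matched": int(removed.sum())})
    rows.append({"clause": "SURVIVORS", "n_matched": int((~removed).sum())})
    log = pd.DataFrame(rows)
    logger.info("filter %s removed %d/%d cells", rules.name, removed.sum(), len(removed))
    return matrix.subset_cells(~removed), log


def select_myeloid(
    matrix: CellMatrix,
    clusters: np.ndarray,
    markers: tuple[str, ...] = MYELOID_MARKERS,
    min_positive_fraction: float = 0.5,
) -> tuple[CellMatrix, pd.DataFrame]:
    """Keep clusters whose cells express the myeloid marker panel.

    A cell is marker-positive if it has >= 1 count for at least half of
    the panel; a cluster is kept when its positive fraction exceeds
    ``min_positive_fraction``.  Returns the subset plus the per-cluster
    decision table.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != matrix.n_cells:
        raise ValidationError("cluster assignment does not cover all cells")
    rows = matrix.rows_for_symbols(markers, missing="error")
    pos_counts = np.asarray((matrix.counts[rows, :] > 0).sum(axis=0)).ravel()
    need = len(markers) / 2.0
    positive = pos_counts >= need
    records = []
    keep_mask = np.zeros(matrix.n_cells, dtype=bool)
    for cl in sorted(pd.unique(clusters).tolist()):
        in_cl = clusters == cl
        frac = float(positive[in_cl].mean())
        kept = frac > min_positive_fraction
        records.append(
            {"cluster": cl, "n_cells": int(in_cl.sum()), "positive_fraction": frac,
             "kept": kept}
        )
        if kept:
            keep_mask |= in_cl
    table = pd.DataFrame(records)
    return matrix.subset_cells(keep_mask), table


def drop_clusters(
    matrix: CellMatrix, clusters: np.ndarray, drop: list
) -> CellMatrix:
    """Remove all cells belonging to a user-supplied cluster list.

    Cluster contamination (ribosomal/mitochondrial, empty droplets) has no
    objective in-pipeline criterion, so the call is explicit.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != matrix.n_cells:
        raise ValidationError("cluster assignment does not cover all cells")
    keep = ~np.isin(clusters, list(drop))
    return matrix.subset_cells(keep)
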