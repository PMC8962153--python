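"""Shared fixtures.

The heavy planted-truth recovery chain (default-scale simulation,
clustering, DE, co-expression network, learned causal networks) is
computed once per session and shared between the module tests and the
acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cultureshock as cs


@pytest.fixture(scope="session")
def truth():
    """Default-scale planted truth: 1500 genes, 4 states, 3 modules,
    150-node regulatory DAG with 5 driver roots, 60 condition genes."""
    return cs.generate_truth(seed=1)


@pytest.fixture(scope="session")
def clean_matrix(truth):
    """Single-condition ('clean') simulation for state-recovery checks."""
    m = cs.simulate_counts(truth, cells_per_state=500, conditions=("fresh",), seed=2)
    return cs.compute_qc_metrics(m)


@pytest.fixture(scope="session")
def clean_clusters(clean_matrix):
    return cs.cluster_cells(
        clean_matrix, cs.ClusterParams(seed=3), covariates=("percent_mito",)
    )


@pytest.fixture(scope="session")
def shock_matrix(truth):
    """Three-preparation simulation (fresh reference + two cultures) at
    the default ~2000-cell scale, with QC metrics and cluster labels."""
    m = cs.simulate_counts(
        truth, cells_per_state=167, conditions=("fresh", "astro", "micro"), seed=4
    )
    m = cs.compute_qc_metrics(m)
    asn = cs.cluster_cells(m, cs.ClusterParams(seed=5), covariates=("percent_mito",))
    m.cell_meta["cluster"] = asn.labels
    return m


@pytest.fixture(scope="session")
def shock_de(shock_matrix):
    cond = shock_matrix.cell_meta["condition"].to_numpy()
    return cs.pairwise_de(
        shock_matrix, cond == "astro", cond == "fresh", labels=("astro", "fresh")
    )


@pytest.fixture(scope="session")
def shock_network(shock_matrix):
    down = cs.downsample_per_cluster(
        shock_matrix, shock_matrix.cell_meta["cluster"].to_numpy(), 400, seed=6
    )
    return cs.build_correlation_graph(down, seed=7)


@pytest.fixture(scope="session")
def learned_driver_records(truth, shock_matrix, shock_de, shock_network):
    """Per-culture learned causal networks and their KDA driver records."""
    cond = shock_matrix.cell_meta["condition"].to_numpy()
    de_set = set(shock_de.significant(0.05, 0.5).index)
    records = {}
    for grp in ("astro", "micro"):
        sub = shock_matrix.subset_cells(cond == grp)
        genes = cs.top_varying_genes(
            sub, covariates=("percent_mito", "cluster"), n_top=200
        )
        dag = cs.learn_dag(
            sub, genes, covariates=("percent_mito", "cluster"), seed=8
        )
        eff = cs.build_effector_sets(de_set, shock_network.modules, dag, grp)
        records[grp] = cs.driver_records(cs.kda_enrich(dag, eff, depth=3))
    return records


@pytest.fixture(scope="session")
def null_de():
    """Null experiment: zero condition effect, 600 genes, 300 cells/arm."""
    t = cs.generate_truth(
        n_genes=600, n_states=2, n_modules=0, n_dag_nodes=0, n_drivers=0,
        effect_size=0.0, n_condition_genes=0, seed=100,
    )
    m = cs.simulate_counts(t, cells_per_state=150, conditions=("fresh", "astro"), seed=200)
    cond = m.cell_meta["condition"].to_numpy()
    return cs.pairwise_de(m, cond == "astro", cond == "fresh")


def make_matrix(counts, gene_symbols=None, cell_meta=None):
    """Small helper: dense counts (genes x cells) -> CellMatrix."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    syms = list(gene_symbols) if gene_symbols else [f"g{i}" for i in range(n_genes)]
    return cs.CellMatrix(
        counts, syms, syms, [f"c{i}" for i in range(n_cells)], cell_meta
    )


@pytest.fixture
def tiny_matrix():
    return make_matrix(
        [[2, 0, 1], [8, 0, 3], [0, 0, 5]],
        gene_symbols=["mt-Nd1", "Hexb", "Trem2"],
    )
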