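"""Synthetic scRNA-seq count simulator with planted ground truth.

Generates UMI count matrices that exercise every pipeline stage without
any external download:

* discrete cell states, each defined by a disjoint marker-gene program
  with multiplicative rate boosts (cluster / state-scoring recovery);
* a condition effect ("culture shock" analogue): a planted set of genes
  shifted between a reference preparation and cultured preparations
  (differential-expression recovery);
* correlated gene modules induced by per-cell latent Gaussian factors
  (co-expression module recovery);
* a planted directed acyclic regulatory graph whose designated driver
  roots sit upstream of most condition-effect genes, with latent values
  propagated by linear structural equations before count sampling
  (causal learning and key-driver recovery);
* mitochondrial ("mt-" prefixed) genes and injectable QC artifacts
  (high-mito / low-count cells) for filter testing.

Counts are negative binomial (gamma-Poisson) around per-cell library
sizes drawn log-normally.  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import CellMatrix, DirectedNetwork, ValidationError

#: mouse mitochondrial protein-coding genes; the "mt-" prefix is what the
#: QC metric convention keys on.
MITO_SYMBOLS = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

#: preparation labels the simulator understands; the first acts as the
#: in-vivo reference (no condition effect).
KNOWN_CONDITIONS = ("fresh", "astro", "micro")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated experiment."""

    gene_symbols: list[str]
    state_names: list[str]
    state_programs: dict[str, dict[str, float]]  # state -> gene -> multiplier
    condition_effects: dict[str, float]  # gene -> log fold change (natural log)
    module_membership: dict[str, int]  # gene -> module id
    module_loadings: dict[str, float]  # gene -> latent-factor loading
    dag: DirectedNetwork
    drivers: list[str]
    baseline: np.ndarray  # per-gene baseline rate weights
    seed: int
    dag_layer: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.gene_symbols)
        for state, program in self.state_programs.items():
            missing = set(program) - universe
            if missing:
                raise ValidationError(
                    f"state {state} program genes not in universe: {sorted(missing)[:3]}"
                )
        if not all(np.isfinite(list(self.condition_effects.values()) or [0.0])):
            raise ValidationError("non-finite condition effect")
        if not self.dag.acyclic:
            raise ValidationError("planted regulatory graph must be acyclic")

    @property
    def condition_genes(self) -> list[str]:
        return sorted(self.condition_effects)

    def to_dict(self) -> dict:
        return {
            "gene_symbols": self.gene_symbols,
            "state_names": self.state_names,
            "state_programs": self.state_programs,
            "condition_effects": self.condition_effects,
            "module_membership": self.module_membership,
            "module_loadings": self.module_loadings,
            "dag_nodes": self.dag.nodes,
            "dag_edges": self.dag.edges,
            "drivers": self.drivers,
            "baseline": self.baseline.tolist(),
            "seed": self.seed,
            "dag_layer": self.dag_layer,
        }


def save_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict()))


def load_truth(path: str | Path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        gene_symbols=d["gene_symbols"],
        state_names=d["state_names"],
        state_programs={
            s: {g: float(m) for g, m in p.items()} for s, p in d["state_programs"].items()
        },
        condition_effects={g: float(v) for g, v in d["condition_effects"].items()},
        module_membership={g: int(v) for g, v in d["module_membership"].items()},
        module_loadings={g: float(v) for g, v in d["module_loadings"].items()},
        dag=DirectedNetwork(d["dag_nodes"], [tuple(e) for e in d["dag_edges"]]),
        drivers=d["drivers"],
        baseline=np.asarray(d["baseline"], dtype=float),
        seed=int(d["seed"]),
        dag_layer={g: int(v) for g, v in d.get("dag_layer", {}).items()},
    )


def generate_truth(
    n_genes: int = 1500,
    n_states: int = 4,
    n_modules: int = 3,
    n_dag_nodes: int = 150,
    effect_size: float = 1.0,
    seed: int = 0,
    program_size: int = 20,
    module_size: int = 25,
    n_drivers: int = 5,
    n_condition_genes: int = 60,
    neg_loading_frac: float = 0.0,
) -> SyntheticTruth:
    """Draw a planted truth: states, modules, condition effects and a DAG.

    The gene universe is partitioned into disjoint blocks: mitochondrial
    genes, one marker program per state, one block per co-expression
    module, the regulatory-DAG genes, and unstructured background.  The
    DAG places ``n_drivers`` root nodes, each heading a three-layer
    fan-out subtree, so every non-driver DAG gene lies within three
    layers of some driver; most condition-effect genes are drawn from
    those subtrees (coverage >= 80% by construction, the rest from
    background), which is what makes key-driver recovery well-posed.

    ``effect_size`` is the magnitude (natural-log scale) of the planted
    per-gene condition shift; 0 yields a null experiment.
    """
    if n_states < 2:
        raise ValidationError("n_states must be >= 2")
    if n_dag_nodes > n_genes:
        raise ValidationError("n_dag_nodes cannot exceed n_genes")
    n_needed = len(MITO_SYMBOLS) + n_states * program_size + n_modules * module_size + n_dag_nodes
    if n_needed > n_genes:
        raise ValidationError(
            f"requested blocks need {n_needed} genes but universe has {n_genes}"
        )
    if n_dag_nodes > 0 and n_drivers >= n_dag_nodes:
        raise ValidationError("need more DAG nodes than drivers")

    rng = np.random.default_rng(seed)
    n_plain = n_genes - len(MITO_SYMBOLS)
    symbols = [f"Gene{i:04d}" for i in range(1, n_plain + 1)] + list(MITO_SYMBOLS)

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        block = symbols[cursor : cursor + k]
        cursor += k
        return block

    state_names = [f"state_{i}" for i in range(n_states)]
    state_programs: dict[str, dict[str, float]] = {}
    for state in state_names:
        genes = take(program_size)
        mults = rng.uniform(4.0, 8.0, size=program_size)
        state_programs[state] = dict(zip(genes, mults.round(3).tolist()))

    module_membership: dict[str, int] = {}
    module_loadings: dict[str, float] = {}
    for m in range(n_modules):
        genes = take(module_size)
        load = rng.uniform(0.4, 0.8, size=module_size)
        sign = np.where(rng.random(module_size) >= neg_loading_frac, 1.0, -1.0)
        for g, l, s in zip(genes, load, sign):
            module_membership[g] = m
            module_loadings[g] = float(round(l * s, 4))

    dag_genes = take(n_dag_nodes)
    drivers = dag_genes[:n_drivers]
    rest = dag_genes[n_drivers:]
    # 60% of the non-driver nodes form per-driver subtrees (round-robin,
    # three layers with parents one layer up); the remainder is background
    # regulatory structure carrying no condition effect - the contrast
    # that makes driver downstream sets *enriched* for the DE genes
    n_subtree = round(0.5 * len(rest)) if n_drivers else 0
    subtree_nodes = rest[:n_subtree]
    background_nodes = rest[n_subtree:]
    edges: list[tuple[str, str]] = []
    dag_layer: dict[str, int] = {d: 0 for d in drivers}
    for d_idx, driver in enumerate(drivers):
        subtree = subtree_nodes[d_idx::n_drivers]
        n1 = max(1, round(0.25 * len(subtree)))
        n2 = max(1, round(0.35 * len(subtree)))
        layer1 = subtree[:n1]
        layer2 = subtree[n1 : n1 + n2]
        layer3 = subtree[n1 + n2 :]
        for g in layer1:
            edges.append((driver, g))
            # a second driver-parent for some layer-1 nodes: the resulting
            # colliders make the driver out-edges orientable from data
            if n_drivers > 1 and rng.random() < 0.5:
                others = [d for d in drivers if d != driver]
                edges.append((str(rng.choice(others)), g))
            dag_layer[g] = 1
        for g in layer2:
            n_par = int(rng.integers(1, min(2, len(layer1)) + 1))
            for p in rng.choice(layer1, size=n_par, replace=False):
                edges.append((str(p), g))
            dag_layer[g] = 2
        for g in layer3:
            pool = layer2 if layer2 else layer1
            n_par = int(rng.integers(1, min(2, len(pool)) + 1))
            for p in rng.choice(pool, size=n_par, replace=False):
                edges.append((str(p), g))
            dag_layer[g] = 3
    # background DAG: forward edges among the background nodes only
    for i, g in enumerate(background_nodes):
        n_par = int(rng.integers(0, min(2, i) + 1)) if i else 0
        depth = 0
        for par in rng.choice(background_nodes[:i], size=n_par, replace=False) if n_par else []:
            edges.append((str(par), g))
            depth = max(depth, dag_layer[str(par)] + 1)
        dag_layer[g] = depth
    dag = DirectedNetwork(dag_genes, edges)

    # condition-effect genes: mostly driver-subtree genes (driver
    # descendants within 3 layers by construction), sampled evenly across
    # subtrees so every driver's downstream set is comparably enriched;
    # remainder from outside the DAG
    n_in_dag = min(round(n_condition_genes * 0.9), len(subtree_nodes))
    cond_dag: list[str] = []
    if n_drivers and n_in_dag:
        per_tree = [n_in_dag // n_drivers] * n_drivers
        for i in range(n_in_dag - sum(per_tree)):
            per_tree[i] += 1
        for d_idx in range(n_drivers):
            tree = subtree_nodes[d_idx::n_drivers]
            k = min(per_tree[d_idx], len(tree))
            cond_dag += [str(g) for g in rng.choice(tree, size=k, replace=False)]
    background = symbols[cursor : n_plain]
    n_bg = n_condition_genes - n_in_dag
    cond_bg = [str(g) for g in rng.choice(background, size=n_bg, replace=False)]
    condition_effects: dict[str, float] = {}
    for g in cond_dag + cond_bg:
        sign = 1.0 if rng.random() < 0.7 else -1.0
        condition_effects[g] = float(sign * effect_size)

    # baseline rate weights: log-normal, with condition/DAG genes boosted so
    # their fold changes survive shrinkage at realistic library sizes, and
    # mitochondrial genes pinned to ~3% of total baseline mass
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    sym_index = {s: i for i, s in enumerate(symbols)}
    for g in dag_genes:
        baseline[sym_index[g]] = max(baseline[sym_index[g]], 1.0) * 2.0
    for g in module_membership:
        baseline[sym_index[g]] = max(baseline[sym_index[g]], 1.0) * 2.0
    for g in condition_effects:
        baseline[sym_index[g]] = max(baseline[sym_index[g]], 1.0) * 3.0
    mito_idx = [sym_index[s] for s in MITO_SYMBOLS]
    non_mito_mass = baseline.sum() - baseline[mito_idx].sum()
    baseline[mito_idx] = 0.03 / 0.97 * non_mito_mass / len(mito_idx)

    return SyntheticTruth(
        gene_symbols=symbols,
        state_names=state_names,
        state_programs=state_programs,
        condition_effects=condition_effects,
        module_membership=module_membership,
        module_loadings=module_loadings,
        dag=dag,
        drivers=list(drivers),
        baseline=baseline,
        seed=seed,
        dag_layer=dag_layer,
    )


def simulate_counts(
    truth: SyntheticTruth,
    cells_per_state: int = 250,
    conditions: tuple[str, ...] = ("fresh", "astro"),
    seed: int = 0,
    dispersion: float = 0.5,
    lib_size_mean: float = 6000.0,
    lib_size_sigma: float = 0.25,
) -> CellMatrix:
    """Sample a UMI count matrix from the planted truth.

    Per-cell gene rates are ``baseline x state multiplier x condition
    multiplier``, modulated by the module latent factors and the DAG
    structural-equation latents (unit edge coefficients, noise sd 0.3;
    driver roots get sd 0.6 so upstream variation is visible downstream),
    then normalised per cell and scaled by a log-normal library size.
    Counts are gamma-Poisson with the given dispersion (0 = Poisson).

    The returned ``cell_meta`` carries ``condition`` / ``preparation``,
    ``sample`` and the ground-truth ``state_true`` label.
    """
    if cells_per_state < 1:
        raise ValidationError("cells_per_state must be >= 1")
    unknown = [c for c in conditions if c not in KNOWN_CONDITIONS]
    if unknown:
        raise ValidationError(
            f"unknown condition labels {unknown}; valid: {KNOWN_CONDITIONS}"
        )

    rng = np.random.default_rng(seed)
    n_genes = len(truth.gene_symbols)
    sym_index = {s: i for i, s in enumerate(truth.gene_symbols)}
    states = truth.state_names
    n_cells = cells_per_state * len(states) * len(conditions)

    cond_col, state_col = [], []
    for cond in conditions:
        for state in states:
            cond_col += [cond] * cells_per_state
            state_col += [state] * cells_per_state

    log_rate = np.tile(np.log(truth.baseline)[:, None], (1, n_cells))

    state_arr = np.asarray(state_col)
    for state, program in truth.state_programs.items():
        cols = np.flatnonzero(state_arr == state)
        if cols.size == 0:
            continue
        for g, mult in program.items():
            log_rate[sym_index[g], cols] += np.log(mult)

    reference = "fresh" if "fresh" in conditions else conditions[0]
    cond_arr = np.asarray(cond_col)
    shocked = np.flatnonzero(cond_arr != reference)
    if shocked.size:
        for g, beta in truth.condition_effects.items():
            log_rate[sym_index[g], shocked] += beta

    n_modules = (
        max(truth.module_membership.values()) + 1 if truth.module_membership else 0
    )
    if n_modules:
        z = rng.standard_normal((n_modules, n_cells))
        for g, m in truth.module_membership.items():
            log_rate[sym_index[g], :] += truth.module_loadings[g] * z[m]

    # DAG latents: topological order is layer order by construction
    if truth.dag.nodes:
        order = sorted(truth.dag.nodes, key=lambda g: (truth.dag_layer.get(g, 0), g))
        parents: dict[str, list[str]] = {n: [] for n in truth.dag.nodes}
        for a, b in truth.dag.edges:
            parents[b].append(a)
        u = {}
        for g in order:
            ps = parents[g]
            if not ps:
                # driver roots: intrinsically the most variable nodes
                val = 1.2 * rng.standard_normal(n_cells)
            else:
                # damped propagation: children receive 0.8 x the parent
                # average plus fresh noise, so regulatory influence decays
                # downstream and upstream regulators stay the top-varying
                # genes (as variance-ranked selection assumes)
                val = 0.45 * rng.standard_normal(n_cells)
                for p in ps:
                    val = val + 0.8 * u[p] / len(ps)
            u[g] = val
            log_rate[sym_index[g], :] += val

    rate = np.exp(log_rate)
    probs = rate / rate.sum(axis=0, keepdims=True)
    lib = rng.lognormal(mean=np.log(lib_size_mean), sigma=lib_size_sigma, size=n_cells)
    mu = probs * lib[None, :]
    if dispersion > 0:
        r = 1.0 / dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    cell_ids = [f"cell_{i:06d}" for i in range(n_cells)]
    import pandas as pd

    meta = pd.DataFrame(
        {
            "sample": [f"{c}_rep1" for c in cond_col],
            "preparation": cond_col,
            "condition": cond_col,
            "state_true": state_col,
        },
        index=cell_ids,
    )
    return CellMatrix(
        counts=np.asarray(counts, dtype=np.int64),
        gene_ids=list(truth.gene_symbols),
        gene_symbols=list(truth.gene_symbols),
        cell_ids=cell_ids,
        cell_meta=meta,
    )


def inject_qc_artifacts(
    matrix: CellMatrix,
    frac_high_mito: float,
    frac_low_count: float = 0.0,
    seed: int = 0,
) -> CellMatrix:
    """Corrupt a fraction of cells with QC artifacts and flag them.

    ``frac_high_mito`` cells get their mitochondrial counts inflated to a
    25-45% share of UMIs (above both the 10% and 20% filter thresholds);
    a disjoint ``frac_low_count`` fraction has its library binomially
    thinned to a total below 3000.  Exactly ``round(frac * n_cells)``
    cells are hit by each artifact; ground-truth flags are recorded in
    ``cell_meta`` as ``injected_high_mito`` / ``injected_low_count``.
    """
    for frac in (frac_high_mito, frac_low_count):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("artifact fractions must be in [0, 1]")
    mito_rows = [
        i for i, s in enumerate(matrix.gene_symbols) if s.startswith("mt-")
    ]
    if not mito_rows:
        raise ValidationError(
            "no 'mt-' prefixed genes in universe; cannot inject mito artifacts"
        )
    rng = np.random.default_rng(seed)
    n_cells = matrix.n_cells
    n_high = int(round(frac_high_mito * n_cells))
    n_low = int(round(frac_low_count * n_cells))
    perm = rng.permutation(n_cells)
    high_cells = np.sort(perm[:n_high])
    low_cells = np.sort(perm[n_high : n_high + n_low])

    dense = np.asarray(matrix.counts.todense(), dtype=np.int64)
    mito_rows_arr = np.asarray(mito_rows)
    non_mito_mask = np.ones(matrix.n_genes, dtype=bool)
    non_mito_mask[mito_rows_arr] = False

    for c in high_cells:
        target = rng.uniform(0.25, 0.45)
        non_mito_total = int(dense[non_mito_mask, c].sum())
        new_mito_total = int(np.ceil(target / (1 - target) * max(non_mito_total, 1)))
        v = dense[mito_rows_arr, c].astype(float)
        if v.sum() > 0:
            scaled = np.floor(v * new_mito_total / v.sum()).astype(np.int64)
            scaled[int(np.argmax(v))] += new_mito_total - int(scaled.sum())
        else:
            scaled = np.zeros(len(mito_rows_arr), dtype=np.int64)
            scaled[0] = new_mito_total
        dense[mito_rows_arr, c] = scaled

    for c in low_cells:
        total = int(dense[:, c].sum())
        target = rng.uniform(500, 2500)
        if total > 0 and total > target:
            p = target / total
            dense[:, c] = rng.binomial(dense[:, c], p)

    out = CellMatrix(
        counts=dense,
        gene_ids=list(matrix.gene_ids),
        gene_symbols=list(matrix.gene_symbols),
        cell_ids=list(matrix.cell_ids),
        cell_meta=matrix.cell_meta,
        embeddings=dict(matrix.embeddings),
    )
    flag_high = np.zeros(n_cells, dtype=bool)
    flag_high[high_cells] = True
    flag_low = np.zeros(n_cells, dtype=bool)
    flag_low[low_cells] = True
    out.cell_meta["injected_high_mito"] = flag_high
    out.cell_meta["injected_low_count"] = flag_low
    return out
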