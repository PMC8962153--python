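"""Differential expression: Wilcoxon semantics, thresholds, signatures."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import cultureshock as cs
from cultureshock.data import ValidationError
from cultureshock.de import DEResult, exact_rank_p

from conftest import make_matrix


def brute_force_rank_p(a, b):
    """Independent oracle: enumerate all group assignments of the pooled
    midrank values and count rank-sums at least as extreme as observed."""
    pooled = list(a) + list(b)
    ranks = st.rankdata(pooled)
    n_a = len(a)
    expect = n_a * (len(pooled) + 1) / 2
    obs = abs(sum(ranks[: n_a]) - expect)
    hits = total = 0
    for combo in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(sum(ranks[i] for i in combo) - expect) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_smallest_attainable_three_vs_three(self):
        m = make_matrix([[0, 0, 0, 5, 6, 7], [1, 1, 1, 1, 1, 1]])
        res = cs.pairwise_de(
            m, np.array([1, 1, 1, 0, 0, 0], bool), np.array([0, 0, 0, 1, 1, 1], bool)
        )
        assert res.table.loc["g0", "p_raw"] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exact_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 6, size=2)
        a = rng.integers(0, 4, size=n_a)  # ties likely
        b = rng.integers(0, 4, size=n_b)
        assert exact_rank_p(a, b) == pytest.approx(brute_force_rank_p(a, b), abs=1e-12)

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.poisson(3, size=(30, 40)))
        ga = np.zeros(40, bool)
        ga[:20] = True
        ab = cs.pairwise_de(m, ga, ~ga)
        ba = cs.pairwise_de(m, ~ga, ga)
        a = ab.table.sort_index()
        b = ba.table.sort_index()
        assert np.allclose(a["avg_logFC"], -b["avg_logFC"])
        assert np.allclose(a["p_raw"], b["p_raw"])


class TestPairwiseDE:
    def test_overlapping_masks_rejected(self):
        m = make_matrix(np.ones((2, 6), dtype=int))
        g = np.ones(6, bool)
        with pytest.raises(ValidationError):
            cs.pairwise_de(m, g, g)

    def test_minimum_group_size(self):
        m = make_matrix(np.ones((2, 5), dtype=int))
        with pytest.raises(ValidationError):
            cs.pairwise_de(m, np.array([1, 1, 0, 0, 0], bool),
                           np.array([0, 0, 1, 1, 1], bool))

    def test_significance_thresholds(self):
        table = pd.DataFrame(
            {
                "avg_logFC": [0.6, 0.4, -0.7],
                "p_raw": [0.001, 0.001, 0.001],
                "p_adj": [0.04, 0.04, 0.2],
                "pct_a": [0.5] * 3,
                "pct_b": [0.5] * 3,
            },
            index=pd.Index(["up_in", "small_fc", "not_sig"], name="gene"),
        )
        res = DEResult(table, "a", "b")
        sig = res.significant(0.05, 0.5)
        assert list(sig.index) == ["up_in"]


class TestVolcano:
    def make_result(self):
        table = pd.DataFrame(
            {
                "avg_logFC": [1.2, -1.2, 0.9, 1.5],
                "p_adj": [0.005, 0.005, 0.005, 0.5],
                "p_raw": [0.001] * 4,
                "pct_a": [0.5] * 4,
                "pct_b": [0.5] * 4,
            },
            index=pd.Index(["up", "down", "weak_fc", "weak_p"], name="gene"),
        )
        return DEResult(table, "a", "b")

    def test_classification_rules(self):
        up, down = cs.volcano_classify(self.make_result(), alpha=0.01, lfc=1.0)
        assert up == ["up"] and down == ["down"]


class TestSignature:
    def test_recovers_planted_up_genes(self, truth, shock_de):
        """Top-20 up genes are (almost) all planted up-regulated genes."""
        with pytest.warns(UserWarning):
            # fewer than 20 significant down genes is acceptable
            up, down = cs.culture_shock_signature(shock_de, n=20)
        planted_up = {g for g, b in truth.condition_effects.items() if b > 0}
        planted_down = {g for g, b in truth.condition_effects.items() if b < 0}
        assert len(set(up) & planted_up) / len(up) >= 0.9
        assert set(down) <= planted_down

    def test_swapped_contrast_swaps_directions(self, shock_matrix):
        cond = shock_matrix.cell_meta["condition"].to_numpy()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fwd = cs.pairwise_de(shock_matrix, cond == "astro", cond == "fresh")
            rev = cs.pairwise_de(shock_matrix, cond == "fresh", cond == "astro")
            up_f, down_f = cs.culture_shock_signature(fwd)
            up_r, down_r = cs.culture_shock_signature(rev)
        assert set(up_f) == set(down_r) and set(down_f) == set(up_r)


class TestOverlapSets:
    def test_hand_example(self):
        regions = cs.overlap_sets({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        assert regions[("A", "B")] == 1
        assert regions[("A",)] == 1 and regions[("B",)] == 1

    def test_identical_sets_fully_shared(self):
        regions = cs.overlap_sets({"A": {"x", "y"}, "B": {"x", "y"}})
        assert regions[("A", "B")] == 2 and regions[("A",)] == 0

    def test_matches_brute_force_tabulation(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        A = set(rng.choice(genes, 30, replace=False))
        B = set(rng.choice(genes, 40, replace=False))
        regions = cs.overlap_sets({"A": A, "B": B})
        assert regions[("A", "B")] == len(A & B)
        assert regions[("A",)] == len(A - B)
        assert regions[("B",)] == len(B - A)


class TestComposition:
    def test_hand_percentages(self):
        clusters = np.array([0] * 100)
        source = np.array(["fresh"] * 80 + ["astro"] * 20)
        tab = cs.composition_table(clusters, source)
        assert tab.loc[0, "fresh"] == pytest.approx(80.0)
        assert tab.loc[0, "astro"] == pytest.approx(20.0)

    def test_rows_sum_to_100_and_order_invariant(self):
        rng = np.random.default_rng(2)
        clusters = rng.integers(0, 3, 200)
        source = rng.choice(["fresh", "astro", "micro"], 200)
        tab = cs.composition_table(clusters, source)
        assert np.allclose(tab.sum(axis=1), 100.0)
        perm = rng.permutation(200)
        tab2 = cs.composition_table(clusters[perm], source[perm])
        pd.testing.assert_frame_equal(tab, tab2)


class TestClusterMarkers:
    def test_planted_marker_found_and_min_pct_filter(self, truth, clean_matrix):
        states = clean_matrix.cell_meta["state_true"].to_numpy()
        labels = pd.factorize(states)[0]
        markers = cs.cluster_markers(clean_matrix, labels)
        state0_idx = list(pd.factorize(states)[1]).index(truth.state_names[0])
        program = truth.state_programs[truth.state_names[0]]
        top_gene = max(program, key=program.get)
        table = markers[state0_idx].table
        sig = table[(table["p_adj"] < 0.05) & (table["avg_logFC"] > 0)]
        assert top_gene in set(sig.index)
        assert (table["pct_a"] >= 0.25).all()

    def test_identical_clusters_yield_no_markers(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.poisson(5, size=(50, 60)))
        labels = np.repeat([0, 1], 30)
        markers = cs.cluster_markers(m, labels)
        for res in markers.values():
            assert (res.table["p_adj"] < 0.05).sum() <= 2


def test_null_type_one_error_calibrated(null_de):
    """Under the synthetic null the raw-p false-positive rate at 0.05 is
    nominal within +-0.02 over >=500 genes."""
    rate = float((null_de.table["p_raw"] < 0.05).mean())
    assert len(null_de.table) >= 500
    assert 0.03 <= rate <= 0.07
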