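"""Network construction: correlations, soft threshold, TOM, clustering,
dynamic tree cut, eigengenes and meta-modules, each against an
independent oracle where the computation is non-trivial."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from sklearn.metrics import adjusted_rand_score

from conftest import random_symmetric_adjacency
from coexnet import network, synth
from coexnet.network import (
    ModuleAssignment, adjacency, cluster_genes, correlation_matrix,
    dynamic_tree_cut, eigengene_network, module_eigengenes, pick_power,
    scan_soft_thresholds, topological_overlap,
)


# ---------------------------------------------------------------- oracles
def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def upgma_bruteforce(d: np.ndarray):
    """Naive UPGMA: cluster distance = mean pairwise original distance.

    Returns the cophenetic matrix."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ii, ki in enumerate(keys):
            for kj in keys[ii + 1:]:
                dist = np.mean([d[a, b] for a in clusters[ki] for b in clusters[kj]])
                if best is None or dist < best[0]:
                    best = (dist, ki, kj)
        dist, ki, kj = best
        for a in clusters[ki]:
            for b in clusters[kj]:
                coph[a, b] = coph[b, a] = dist
        clusters[ki] = clusters[ki] + clusters[kj]
        del clusters[kj]
    return coph


def pearson_twopass(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = x[i], x[j]
            cov = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            denom = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
            out[i, j] = out[j, i] = cov / denom
    return out


# ------------------------------------------------------------ correlation
class TestCorrelationMatrix:
    def test_duplicate_and_negated_genes(self, rng):
        base = rng.standard_normal(10)
        expr = pd.DataFrame([base, base, -base], index=["a", "b", "c"])
        r = correlation_matrix(expr)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_twopass_formula(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 10))
        r = correlation_matrix(pd.DataFrame(x))
        assert np.allclose(r.to_numpy(), pearson_twopass(x), atol=1e-12)

    def test_zero_variance_gene_named(self):
        expr = pd.DataFrame([[1, 1, 1], [1, 2, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(expr)


# ----------------------------------------------------------- soft threshold
class TestSoftThreshold:
    def test_adjacency_values(self):
        r = pd.DataFrame([[1, 0.5], [0.5, 1.0]])
        assert adjacency(r, 12).iloc[0, 1] == pytest.approx(0.000244140625, abs=1e-15)
        r2 = pd.DataFrame([[1, -0.8], [-0.8, 1.0]])
        assert adjacency(r2, 2).iloc[0, 1] == pytest.approx(0.64)
        assert adjacency(r2, 2).iloc[0, 0] == 0.0  # diagonal zeroed

    def test_power_law_degree_sequence_fits_well(self):
        # expected-degree construction from an exact power-law weight sequence
        k_raw = np.arange(1, 1001) ** (-1 / 2.0)
        w = k_raw / k_raw.max() * 25
        a = np.clip(np.outer(w, w) / w.sum(), 0, 1)
        np.fill_diagonal(a, 0)
        from coexnet.network import _scale_free_fit

        r2, slope = _scale_free_fit(a.sum(0), 10)
        assert r2 >= 0.95
        assert slope < 0

    def test_all_equal_correlations_report_missing_fit(self):
        r = np.full((6, 6), 0.5)
        np.fill_diagonal(r, 1.0)
        scan = scan_soft_thresholds(r, powers=[1, 2])
        assert scan.table["r2_signed"].isna().all()

    def test_mean_k_decreases_with_power(self, rng):
        x = rng.standard_normal((20, 15))
        scan = scan_soft_thresholds(correlation_matrix(pd.DataFrame(x)))
        mk = scan.table["mean_k"].to_numpy()
        assert (np.diff(mk) < 0).all()

    def test_pick_power_first_crossing(self):
        t = pd.DataFrame(
            {"power": [4, 8, 12, 16], "r2_signed": [0.3, 0.85, 0.92, 0.95],
             "slope": [-1] * 4, "mean_k": [9, 5, 3, 2]}
        )
        assert pick_power(network.SoftThresholdScan(t)) == 12
        assert pick_power(network.SoftThresholdScan(t), r2_min=0.0) == 4
        with pytest.warns(UserWarning, match="argmax"):
            assert pick_power(network.SoftThresholdScan(t), r2_min=0.99) == 16


# ------------------------------------------------------------------- TOM
class TestTopologicalOverlap:
    def test_complete_graph_is_maximal(self):
        a = np.ones((3, 3))
        np.fill_diagonal(a, 0)
        tom = topological_overlap(a)
        assert np.allclose(tom, 1.0)

    def test_empty_graph_has_zero_overlap(self):
        tom = topological_overlap(np.zeros((4, 4)))
        assert np.allclose(tom[~np.eye(4, dtype=bool)], 0.0)
        assert np.allclose(np.diag(tom), 1.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        a = random_symmetric_adjacency(20, rng)
        tom = topological_overlap(a)
        assert np.abs(tom - tom_bruteforce(a)).max() < 1e-12

    def test_out_of_range_adjacency_rejected(self):
        a = np.full((3, 3), 1.5)
        np.fill_diagonal(a, 0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            topological_overlap(a)


# ------------------------------------------------------------- clustering
class TestClusterGenes:
    def test_tight_pairs_merge_first(self):
        d = np.array(
            [[0, 0.0, 1, 1], [0.0, 0, 1, 1], [1, 1, 0, 0.0], [1, 1, 0.0, 0]]
        , dtype=float)
        Z = cluster_genes(d)
        assert Z[0, 2] == 0.0

    def test_hand_worked_upgma_heights(self):
        # merge (0,1)@2; (2,3)@4; then the two clusters at mean distance 7.5
        d = np.array(
            [[0, 2, 6, 10], [2, 0, 5, 9], [6, 5, 0, 4], [10, 9, 4, 0]], float
        )
        Z = cluster_genes(d)
        assert np.allclose(sorted(Z[:, 2]), [2, 4, 7.5])

    def test_matches_naive_upgma_cophenetic(self):
        rng = np.random.default_rng(8)
        d = random_symmetric_adjacency(12, rng)  # reuse as distances
        Z = cluster_genes(d)
        coph = cophenet(Z)
        from scipy.spatial.distance import squareform

        assert np.allclose(squareform(coph), upgma_bruteforce(d), atol=1e-10)

    def test_permutation_invariance_of_tree(self):
        rng = np.random.default_rng(9)
        d = random_symmetric_adjacency(15, rng)
        perm = rng.permutation(15)
        from scipy.spatial.distance import squareform

        c1 = squareform(cophenet(cluster_genes(d)))
        c2 = squareform(cophenet(cluster_genes(d[np.ix_(perm, perm)])))
        assert np.allclose(c1[np.ix_(perm, perm)], c2, atol=1e-10)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_genes(d)


def planted_block_diss(sizes, within=0.1, between=0.9, jitter=0.0, seed=0):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0, jitter, size=(n, n))
        d = d + (noise + noise.T) / 2
    np.fill_diagonal(d, 0.0)
    return d, labels


class TestDynamicTreeCut:
    def test_three_planted_blocks_recovered_no_grey(self):
        d, labels = planted_block_diss([50, 40, 30])
        Z = cluster_genes(d)
        res = dynamic_tree_cut(Z, d)
        assert (res.labels > 0).all()
        assert adjusted_rand_score(labels, res.labels) == 1.0
        # fixed-height oracle at 0.5 gives the identical partition
        from scipy.cluster.hierarchy import fcluster

        oracle = fcluster(Z, 0.5, criterion="distance")
        assert adjusted_rand_score(oracle, res.labels) == 1.0

    def test_all_equal_dissimilarities_flagged_degenerate(self):
        d = np.full((40, 40), 0.7)
        np.fill_diagonal(d, 0.0)
        Z = cluster_genes(d)
        with pytest.warns(UserWarning, match="degenerate"):
            res = dynamic_tree_cut(Z, d)
        assert res.degenerate
        assert len(set(res.labels)) == 1  # single module or all grey

    def test_small_blocks_below_min_size_stay_grey(self):
        d, _ = planted_block_diss([10] * 6)
        Z = cluster_genes(d)
        res = dynamic_tree_cut(Z, d, min_module_size=30)
        assert (res.labels == 0).all()

    def test_min_module_size_gate_value(self):
        with pytest.raises(ValueError, match="min_module_size"):
            dynamic_tree_cut(np.zeros((1, 4)), np.zeros((2, 2)), min_module_size=1)

    def test_jittered_blocks_with_noise_background(self):
        rng = np.random.default_rng(4)
        d, labels = planted_block_diss([40, 35], within=0.2, between=0.95,
                                       jitter=0.05, seed=4)
        # append 30 background objects far from everything
        n_bg = 30
        n = d.shape[0]
        full = np.full((n + n_bg, n + n_bg), 0.98)
        full[:n, :n] = d
        noise = rng.uniform(0.9, 1.0, size=(n_bg, n_bg))
        full[n:, n:] = (noise + noise.T) / 2
        np.fill_diagonal(full, 0.0)
        Z = cluster_genes(full)
        res = dynamic_tree_cut(Z, full)
        truth = np.concatenate([labels + 1, np.zeros(n_bg, int)])
        assert adjusted_rand_score(truth, res.labels) >= 0.90

    def test_labels_to_colors_largest_first(self):
        labels = np.array([0, 2, 2, 2, 1, 1])
        colors = network.labels_to_colors(labels)
        assert colors.tolist() == [
            "grey", "turquoise", "turquoise", "turquoise", "blue", "blue"
        ]


# ------------------------------------------------------------- eigengenes
class TestModuleEigengenes:
    def test_identical_genes_reproduce_profile(self, rng):
        base = rng.standard_normal(8)
        expr = pd.DataFrame([base, base, base], index=["a", "b", "c"],
                            columns=[f"S{i}" for i in range(8)])
        colors = pd.Series(["turquoise"] * 3, index=expr.index)
        eig = module_eigengenes(expr, colors)
        z = (base - base.mean()) / base.std(ddof=1)
        me = eig.eigengenes.loc["turquoise"].to_numpy()
        assert np.allclose(me, z, atol=1e-10)
        assert eig.variance_explained["turquoise"] == pytest.approx(1.0)

    def test_two_gene_module_matches_closed_form(self):
        expr = pd.DataFrame([[1.0, 2.0, 4.0], [0.0, 3.0, 5.0]], index=["a", "b"])
        colors = pd.Series(["blue", "blue"], index=expr.index)
        eig = module_eigengenes(expr, colors)
        z = expr.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        # closed form: for 2 standardized genes the first PC direction is
        # (z1 + z2)/|..| when cor>0, (z1 - z2) otherwise
        rho = np.corrcoef(z)[0, 1]
        v = z[0] + z[1] if rho > 0 else z[0] - z[1]
        v = (v - v.mean()) / v.std(ddof=1)
        me = eig.eigengenes.loc["blue"].to_numpy()
        assert np.allclose(np.abs(np.corrcoef(me, v)[0, 1]), 1.0, atol=1e-10)
        assert eig.eigengenes.loc["blue"].std(ddof=1) == pytest.approx(1.0)

    def test_orientation_contract_under_sign_flip(self, rng):
        x = rng.standard_normal((6, 12))
        expr = pd.DataFrame(x)
        colors = pd.Series(["red"] * 6, index=expr.index)
        me1 = module_eigengenes(expr, colors).eigengenes.loc["red"]
        me2 = module_eigengenes(-expr, colors).eigengenes.loc["red"]
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        assert np.corrcoef(me1, z.mean(axis=0))[0, 1] >= 0
        assert np.corrcoef(me2, -z.mean(axis=0))[0, 1] >= 0

    def test_constant_module_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        colors = pd.Series(["blue", "blue"], index=expr.index)
        with pytest.raises(ValueError, match="constant"):
            module_eigengenes(expr, colors)


class TestEigengeneNetwork:
    def _two_me_frame(self, rho, n=200, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n)
        b = rho * a + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        return pd.DataFrame([a, b], index=["blue", "red"])

    def test_highly_correlated_pair_share_meta_module(self):
        meta = eigengene_network(self._two_me_frame(0.95))
        assert meta.meta_module_of["blue"] == meta.meta_module_of["red"]

    def test_uncorrelated_pair_split_at_default_cut(self):
        meta = eigengene_network(self._two_me_frame(0.0))
        assert meta.meta_module_of["blue"] != meta.meta_module_of["red"]

    def test_single_module_trivial(self):
        eig = pd.DataFrame([np.arange(5.0)], index=["blue"])
        meta = eigengene_network(eig)
        assert meta.meta_module_of.tolist() == [1]

    def test_adjacency_is_half_one_plus_cor(self):
        frame = self._two_me_frame(0.5, seed=3)
        meta = eigengene_network(frame)
        rho = np.corrcoef(frame.to_numpy())[0, 1]
        assert meta.adjacency.loc["blue", "red"] == pytest.approx((1 + rho) / 2)


# --------------------------------------------------- end-to-end recovery
class TestRecovery:
    def test_module_recovery_on_planted_data(self, small_dataset, small_network):
        _, _, truth, _ = small_dataset
        ari = adjusted_rand_score(
            truth.module_of_gene, small_network.module_of_gene
        )
        assert ari >= 0.90

    def test_me_faithfulness(self, small_dataset, small_network):
        _, values, _, _ = small_dataset
        colors = small_network.module_of_gene
        eig = small_network.eigengenes.eigengenes
        own, other = [], []
        x = values.to_numpy()
        for i, g in enumerate(values.index):
            c = colors[g]
            if c == network.GREY:
                continue
            for m in eig.index:
                r = abs(np.corrcoef(x[i], eig.loc[m])[0, 1])
                (own if m == c else other).append(r)
        assert np.mean(own) >= np.mean(other)

    def test_meta_modules_recover_planted_super_groups(self):
        cfg = synth.SyntheticConfig(
            n_genes=1000, n_samples=100, module_sizes=(150, 120, 100, 80),
            loading_range=(0.7, 0.95), meta_groups=((1, 3), (2, 4)),
            super_factor_weight=0.6, seed=11,
        )
        values, truth = synth.simulate_expression(cfg)
        model = network.build_network(values, beta=6)
        colors = model.module_of_gene
        planted_group, detected_group = [], []
        for color in model.assignment.module_colors:
            planted_mod = truth.module_of_gene[colors == color].mode()[0]
            planted_group.append(truth.super_group_of[planted_mod])
            detected_group.append(model.meta.meta_module_of[color])
        assert len(planted_group) == 4
        assert adjusted_rand_score(planted_group, detected_group) == 1.0
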