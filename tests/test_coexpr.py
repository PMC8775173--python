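import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from iescore.coexpr import (
    CoexpressionNetwork,
    adjacency_matrix,
    choose_beta,
    detect_modules,
    module_trait_correlation,
    soft_threshold_scan,
    tom_similarity,
    variance_filter,
)
from iescore.simulate import generate_hub_expression

from conftest import random_expression


def tom_oracle(a):
    """Direct triple-loop topological overlap."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i, j] = 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


def planted_blocks(seed=7, n_samples=100, block=50, n_blocks=3, n_background=150,
                   factor_sd=2.0):
    """Blocks with within-block correlation ~ factor_sd^2/(factor_sd^2+1)."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for m in range(n_blocks):
        f = rng.normal(0.0, factor_sd, n_samples)
        rows.append(f[None, :] + rng.standard_normal((block, n_samples)))
        truth += [m] * block
    rows.append(rng.standard_normal((n_background, n_samples)))
    truth += [-1] * n_background
    x = np.vstack(rows)
    expr = pd.DataFrame(x, index=[f"g{i:04d}" for i in range(x.shape[0])],
                        columns=[f"s{j}" for j in range(n_samples)])
    return expr, np.array(truth)


class TestVarianceFilter:
    def test_top_quantile_by_variance(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((8, 10)),
                            index=[f"g{i}" for i in range(8)])
        kept = variance_filter(expr, 0.25)
        variances = expr.var(axis=1, ddof=1)
        assert set(kept.index) == set(variances.nlargest(2).index)

    def test_ceil_convention(self):
        rng = np.random.default_rng(1)
        expr = random_expression(rng, 101, 10)
        assert variance_filter(expr, 0.25).shape[0] == int(np.ceil(0.25 * 101))

    def test_constant_matrix_rejected(self):
        expr = pd.DataFrame(np.ones((5, 4)), index=list("abcde"))
        with pytest.raises(ValueError):
            variance_filter(expr, 0.25)


class TestSoftThreshold:
    def test_mean_connectivity_decreasing(self):
        rng = np.random.default_rng(2)
        scan = soft_threshold_scan(random_expression(rng, 60, 30))
        k = scan["mean_connectivity"].to_numpy()
        assert np.all(np.diff(k) <= 0)
        assert k[0] > k[-1]

    def test_hub_structure_reaches_threshold(self):
        scan = soft_threshold_scan(generate_hub_expression(seed=1))
        assert scan["signed_r2"].max() >= 0.9
        assert choose_beta(scan) is not None

    def test_iid_noise_stays_below_threshold(self):
        rng = np.random.default_rng(3)
        expr = random_expression(rng, 300, 100)
        scan = soft_threshold_scan(expr)
        assert scan["signed_r2"].max() < 0.9
        assert choose_beta(scan) is None


class TestTOM:
    def test_identity_adjacency(self):
        assert np.allclose(tom_similarity(np.eye(5)), np.eye(5))

    def test_clique_saturation(self):
        a = np.ones((3, 3))
        assert np.allclose(tom_similarity(a), np.ones((3, 3)))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.random((10, 10))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            assert np.max(np.abs(tom_similarity(a) - tom_oracle(a))) < 1e-12

    def test_symmetry_required(self):
        a = np.random.default_rng(5).random((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)

    def test_output_range_and_symmetry(self):
        rng = np.random.default_rng(6)
        a = rng.random((15, 15))
        a = (a + a.T) / 2
        t = tom_similarity(a)
        assert np.allclose(t, t.T)
        assert t.min() >= 0 and t.max() <= 1 + 1e-12


class TestModules:
    def test_planted_blocks_recovered(self):
        expr, truth = planted_blocks()
        tom = tom_similarity(adjacency_matrix(expr, 6))
        labels, megs = detect_modules(tom, expr.index, expr, 30, 0.99)
        mask = truth >= 0
        ari = adjusted_rand_score(truth[mask], labels.to_numpy()[mask])
        assert ari >= 0.9
        assert megs.shape[1] >= 3

    def test_min_size_larger_than_clusters_all_grey(self):
        expr, _ = planted_blocks(block=10, n_blocks=2, n_background=20)
        tom = tom_similarity(adjacency_matrix(expr, 6))
        with pytest.warns(UserWarning, match="grey"):
            labels, megs = detect_modules(tom, expr.index, expr, 500, 0.99)
        assert (labels == "grey").all()
        assert megs.empty

    def test_eigengene_orientation_and_unit_variance(self):
        expr, truth = planted_blocks(seed=8)
        tom = tom_similarity(adjacency_matrix(expr, 6))
        labels, megs = detect_modules(tom, expr.index, expr, 30, 0.99)
        for me in megs.columns:
            color = me[2:]
            sub = expr.loc[labels[labels == color].index]
            r = np.corrcoef(megs[me], sub.mean(axis=0))[0, 1]
            assert r > 0
            assert megs[me].std(ddof=0) == pytest.approx(1.0)

    def test_gene_order_invariance(self):
        expr, _ = planted_blocks(seed=9, n_background=50)
        perm = expr.sample(frac=1, random_state=3)
        t1 = tom_similarity(adjacency_matrix(expr, 6))
        t2 = tom_similarity(adjacency_matrix(perm, 6))
        l1, _ = detect_modules(t1, expr.index, expr, 30, 0.99)
        l2, _ = detect_modules(t2, perm.index, perm, 30, 0.99)
        assert (l1.sort_index() == l2.sort_index()).all()


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self):
        expr, _ = planted_blocks(seed=10)
        tom = tom_similarity(adjacency_matrix(expr, 6))
        _, megs = detect_modules(tom, expr.index, expr, 30, 0.99)
        traits = pd.DataFrame({"t": megs.iloc[:, 0]})
        res = module_trait_correlation(megs, traits)
        top = res.loc[res["module"] == megs.columns[0]].iloc[0]
        assert top["pearson_r"] == pytest.approx(1.0)
        assert top["p_value"] < 1e-10

    def test_zero_variance_trait_missing(self):
        expr, _ = planted_blocks(seed=11)
        tom = tom_similarity(adjacency_matrix(expr, 6))
        _, megs = detect_modules(tom, expr.index, expr, 30, 0.99)
        res = module_trait_correlation(megs, pd.DataFrame({"t": np.ones(expr.shape[1])}))
        assert res["pearson_r"].isna().all()

    def test_permuted_trait_rarely_flagged(self):
        expr, _ = planted_blocks(seed=12, n_samples=88, n_background=300)
        tom = tom_similarity(adjacency_matrix(expr, 6))
        _, megs = detect_modules(tom, expr.index, expr, 30, 0.99)
        rng = np.random.default_rng(0)
        y = (np.arange(88) < 30).astype(float)
        flagged = 0
        for _ in range(100):
            t = pd.DataFrame({"p": rng.permutation(y)}, index=megs.index)
            if module_trait_correlation(megs, t)["associated"].any():
                flagged += 1
        assert flagged < 5


class TestEstimator:
    def test_fit_exposes_scan_labels_eigengenes(self):
        expr, _ = planted_blocks(seed=13)
        net = CoexpressionNetwork(fallback_beta=6).fit(expr.T)
        assert set(net.scan_.columns) == {"signed_r2", "mean_connectivity"}
        assert len(net.labels_) == expr.shape[0]
        assert net.eigengenes_.shape[0] == expr.shape[1]
        assert net.beta_ >= 1
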