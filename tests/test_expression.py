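import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenogrn.expression import (
    ElasticNetSpec,
    bh_adjust,
    compute_tf_gene_expr_stats,
    elastic_net_path_select,
    inverse_quantile_normalize,
    ols_pseudo_pvalues,
    select_de_genes,
)
from phenogrn.simulate import SimulationConfig, generate_expression, generate_planted_network


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def bh_oracle(p):
    """Direct BH definition: adj_i = min over j with p_j >= p_i of p_j*n/rank_j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(n)
    for pos, i in enumerate(order):
        tail = [p[order[j]] * n / (j + 1) for j in range(pos, n)]
        out[i] = min(1.0, min(tail))
    return out


def enet_cd_oracle(X, y, alpha, rho, n_iter=20000, tol=1e-14):
    """Cyclic coordinate descent for 1/(2n)||y-Xw||^2 + a*rho|w|_1 + a(1-rho)/2|w|^2."""
    n, k = X.shape
    w = np.zeros(k)
    col_sq = (X ** 2).sum(axis=0) / n
    for _ in range(n_iter):
        w_old = w.copy()
        for j in range(k):
            r = y - X @ w + X[:, j] * w[j]
            rho_j = X[:, j] @ r / n
            z = np.sign(rho_j) * max(abs(rho_j) - alpha * rho, 0.0)
            w[j] = z / (col_sq[j] + alpha * (1.0 - rho))
        if np.max(np.abs(w - w_old)) < tol:
            break
    return w


def ols_t_oracle(y, X):
    """Textbook OLS p-values: beta/se against t(n-k-1), two-sided."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    k = D.shape[1]
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    s2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(D.T @ D)))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - k)
    return p[1:], beta[1:]


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


class TestBHAdjust:
    def test_hand_computed_fixture(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_never_decreases(self):
        rng = np.random.default_rng(1)
        p = rng.random(100).clip(1e-9)
        assert np.all(bh_adjust(p) >= p)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(40).clip(1e-9)
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([])
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestSelectDEGenes:
    def test_rule_application(self):
        de = pd.DataFrame(
            {"gene": ["A", "B"], "logFC": [-3.0, 1.5],
             "PValue": [0.001, 0.001], "FDR": [0.005, 0.005]}
        )
        assert select_de_genes(de, 0.01, 2.0) == {"A"}

    def test_boundary_excluded(self):
        de = pd.DataFrame(
            {"gene": ["A"], "logFC": [5.0], "PValue": [0.005], "FDR": [0.01]}
        )
        assert select_de_genes(de, 0.01, 2.0) == set()

    def test_empty_table(self):
        assert select_de_genes(pd.DataFrame(), 0.01, 2.0) == set()

    def test_lfc_boundary_excluded(self):
        de = pd.DataFrame(
            {"gene": ["A"], "logFC": [2.0], "PValue": [0.001], "FDR": [0.001]}
        )
        assert select_de_genes(de, 0.01, 2.0) == set()


class TestInverseQuantileNormalize:
    def test_middle_maps_to_zero(self):
        out = inverse_quantile_normalize([10, 20, 30])
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_rank_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=17) * 100
        a = np.sort(inverse_quantile_normalize(x))
        b = np.sort(inverse_quantile_normalize(np.arange(1, 18)))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_recomputed_plotting_positions(self):
        out = inverse_quantile_normalize([5, 1, 9])
        expected = stats.norm.ppf((np.array([2, 1, 3]) - 0.5) / 3)
        np.testing.assert_allclose(out, expected)
        assert out[1] < out[0] < out[2]

    def test_constant_input_zeros(self):
        np.testing.assert_array_equal(inverse_quantile_normalize([2.0, 2.0, 2.0]), 0.0)

    def test_ties_average(self):
        out = inverse_quantile_normalize([1.0, 1.0, 5.0, 9.0])
        assert out[0] == out[1]


class TestElasticNetPathSelect:
    def _standardise(self, X):
        return (X - X.mean(axis=0)) / X.std(axis=0)

    def test_perfect_predictor_selected(self):
        rng = np.random.default_rng(8)
        X = self._standardise(rng.normal(size=(30, 4)))
        y = X[:, 2].copy()
        sel = elastic_net_path_select(y, X, ElasticNetSpec(), tf_names=list("abcd"))
        assert "c" in sel.tfs

    def test_heavy_penalty_empty(self):
        rng = np.random.default_rng(9)
        X = self._standardise(rng.normal(size=(20, 3)))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        alpha_max = np.max(np.abs(X.T @ y)) / (20 * 0.5)
        from sklearn.linear_model import ElasticNet

        fit = ElasticNet(alpha=10 * alpha_max, l1_ratio=0.5, fit_intercept=False).fit(X, y)
        assert np.all(fit.coef_ == 0.0)

    def test_coordinate_descent_oracle(self):
        rng = np.random.default_rng(10)
        X = self._standardise(rng.normal(size=(28, 5)))
        y = 1.0 * X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.1, size=28)
        spec = ElasticNetSpec()
        sel = elastic_net_path_select(y, X, spec, tf_names=list("abcde"))
        assert "a" in sel.tfs
        w = enet_cd_oracle(X, y, sel.alpha, spec.rho)
        for name, coef in sel.coefficients.items():
            j = "abcde".index(name)
            assert coef == pytest.approx(w[j], abs=1e-6)

    def test_zero_y_empty_selection(self):
        X = np.eye(6)
        sel = elastic_net_path_select(np.zeros(6), X, ElasticNetSpec())
        assert sel.tfs == ()

    def test_support_cap_respected(self):
        rng = np.random.default_rng(12)
        n, k = 10, 20
        X = self._standardise(rng.normal(size=(n, k)))
        y = X @ rng.normal(size=k)
        sel = elastic_net_path_select(y, X, ElasticNetSpec())
        assert len(sel.tfs) <= min(15, n - 3)


class TestOLSPseudoPvalues:
    def test_perfect_fit_tiny_p(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 1))
        y = X[:, 0].copy()
        out = ols_pseudo_pvalues(y, X, tf_names=["a"])
        assert out.loc[0, "pseudo_p"] < 1e-10

    def test_textbook_oracle_six_samples(self):
        X = np.array([[0.5, 1.0], [-1.2, 0.3], [0.7, -0.9],
                      [1.5, 0.2], [-0.3, -1.1], [0.1, 0.8]])
        y = np.array([1.0, -0.8, 0.2, 1.4, -0.9, 0.5])
        out = ols_pseudo_pvalues(y, X, tf_names=["a", "b"])
        p_exp, b_exp = ols_t_oracle(y, X)
        np.testing.assert_allclose(out["pseudo_p"], p_exp, atol=1e-10)
        np.testing.assert_allclose(out["coefficient"], b_exp, atol=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(200):
            X = rng.normal(size=(15, 2))
            y = rng.normal(size=15)
            out = ols_pseudo_pvalues(y, X, tf_names=["a", "b"])
            pvals.append(out.loc[0, "pseudo_p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.05

    def test_rank_deficient_drops_columns(self, caplog):
        rng = np.random.default_rng(15)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x, rng.normal(size=20)])
        out = ols_pseudo_pvalues(np.sin(x), X, tf_names=["a", "b", "c"])
        assert set(out["tf"]) == {"a", "c"}

    def test_too_many_regressors_rejected(self):
        with pytest.raises(ValueError):
            ols_pseudo_pvalues(np.zeros(5), np.zeros((5, 4)))


class TestComputeTFGeneExprStats:
    def test_zero_noise_planted_recovered(self):
        cfg = SimulationConfig(
            n_tfs=4, n_genes=8, frac_pheno_genes=1.0, edges_per_pheno_gene=1,
            noise_sd=0.0, class_shift=0.0, n_samples_per_class=15, seed=44,
        )
        net = generate_planted_network(cfg)
        expr, _ = generate_expression(net, cfg)
        table = compute_tf_gene_expr_stats(expr, list(net.tfs), list(net.genes))
        pairs = {(r.tf, r.gene): r.pseudo_p for r in table.itertuples()}
        for tf, gene in net.edges:
            assert (tf, gene) in pairs
            assert pairs[(tf, gene)] < 1e-6

    def test_no_genes_empty(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)),
                            index=["t1", "t2"])
        out = compute_tf_gene_expr_stats(expr, ["t1", "t2"], [])
        assert out.empty

    def test_closure_over_tfs(self, small_net, small_cfg):
        expr, _ = generate_expression(small_net, small_cfg)
        table = compute_tf_gene_expr_stats(expr, list(small_net.tfs), list(small_net.genes))
        assert set(table["tf"]) <= set(small_net.tfs)

    def test_missing_gene_named(self):
        expr = pd.DataFrame(np.zeros((2, 8)), index=["t1", "g1"])
        with pytest.raises(KeyError, match="g2"):
            compute_tf_gene_expr_stats(expr, ["t1"], ["g1", "g2"])

    def test_overlapping_ids_rejected(self):
        expr = pd.DataFrame(np.zeros((2, 8)), index=["a", "b"])
        with pytest.raises(ValueError):
            compute_tf_gene_expr_stats(expr, ["a"], ["a", "b"])
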