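"""Phylogenetic covariance, Kmult, Procrustes ANOVA/PGLS, GLS residuals,
allometric regression."""

import numpy as np
import pandas as pd
import pytest

from canalmorph import comparative as cmp
from canalmorph import io as cio
from canalmorph.simulate import simulate_bm, simulate_tree


class TestPhyloCov:
    def test_star_tree_is_scaled_identity(self):
        tree = cio.read_tree("(A:2,B:2,C:2,D:2);")
        C, labels = cmp.phylo_cov_matrix(tree)
        np.testing.assert_allclose(C, 2.0 * np.eye(4), atol=1e-12)

    def test_three_tip_path_arithmetic(self):
        tree = cio.read_tree("((A:1,B:1):1,C:2);")
        C, labels = cmp.phylo_cov_matrix(tree, order=["A", "B", "C"])
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(0.0)
        assert C[0, 0] == pytest.approx(2.0)

    def test_matches_brute_force_path_enumeration(self):
        tree = simulate_tree(10, seed=31)
        C, labels = cmp.phylo_cov_matrix(tree)
        # oracle: explicit root-to-MRCA walk per pair
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

        def ancestors(nd):
            out = []
            while nd is not None:
                out.append(nd)
                nd = nd.parent_node
            return out

        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                anc_a = ancestors(leaves[a])
                mrca = next(nd for nd in ancestors(leaves[b]) if nd in anc_a)
                assert C[i, j] == pytest.approx(mrca.root_distance, abs=1e-9)


class TestKmult:
    def test_univariate_matches_blomberg_oracle(self):
        tree = simulate_tree(5, seed=32)
        labels = sorted(t.label for t in tree.taxon_namespace)
        rng = np.random.default_rng(33)
        y = rng.normal(size=5)
        K = cmp.kmult(y[:, None], tree, labels, nperm=0).K
        # independently coded univariate Blomberg K
        C, _ = cmp.phylo_cov_matrix(tree, order=labels)
        Cinv = np.linalg.inv(C)
        ones = np.ones(5)
        a = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
        mse0 = (y - a) @ (y - a)
        mse = (y - a) @ Cinv @ (y - a)
        expected = (mse0 / mse) / ((np.trace(C)
                                    - 5 / (ones @ Cinv @ ones)) / 4)
        assert abs(K - expected) < 1e-9

    def test_zero_variance_raises(self):
        tree = simulate_tree(5, seed=34)
        labels = sorted(t.label for t in tree.taxon_namespace)
        with pytest.raises(ValueError, match="zero variance"):
            cmp.kmult(np.ones((5, 2)), tree, labels, nperm=0)

    def test_too_few_tips(self):
        tree = cio.read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            cmp.kmult(np.zeros((3, 2)), tree, ["A", "B", "C"], nperm=0)

    def test_permutation_p_detects_strong_signal(self):
        tree = simulate_tree(20, seed=35)
        Y, labels = simulate_bm(tree, rate=1.0, dims=3, seed=36)
        res = cmp.kmult(Y, tree, labels, nperm=199, seed=0)
        assert 0 < res.p <= 1
        res2 = cmp.kmult(Y, tree, labels, nperm=199, seed=0)
        assert res.p == res2.p  # seeded reproducibility


class TestProcrustesAnova:
    def test_covariate_signal_r2(self):
        rng = np.random.default_rng(37)
        n = 25
        x = rng.normal(size=n)
        v = rng.normal(size=6)
        Y = np.outer(x, v) + rng.normal(scale=1e-4, size=(n, 6))
        tab = cmp.procrustes_anova(Y, pd.DataFrame({"x": x}), ["x"],
                                   nperm=99, seed=0)
        assert tab["x"]["R2"] > 0.99
        assert tab["x"]["p"] == pytest.approx(0.01)  # 1/(99+1) floor

    def test_univariate_matches_sequential_anova_oracle(self):
        # oracle: statsmodels type-I ANOVA on a univariate response
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(38)
        n = 24
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], n // 3),
            "x": rng.normal(size=n),
        })
        y = (rng.normal(size=n)
             + 2.0 * (df["g"] == "b") + 0.5 * df["x"]).to_numpy()
        tab = cmp.procrustes_anova(y[:, None], df, ["g", "x"], nperm=0)
        df2 = df.assign(y=y)
        oracle = sm.stats.anova_lm(ols("y ~ g + x", data=df2).fit(), typ=1)
        assert tab["g"]["SS"] == pytest.approx(oracle.loc["g", "sum_sq"])
        assert tab["x"]["SS"] == pytest.approx(oracle.loc["x", "sum_sq"])
        assert tab["g"]["F"] == pytest.approx(oracle.loc["g", "F"])
        assert tab["g"]["df"] == oracle.loc["g", "df"]
        assert tab["residuals"]["SS"] == pytest.approx(
            oracle.loc["Residual", "sum_sq"])

    def test_ss_decomposition_conserved(self):
        rng = np.random.default_rng(39)
        n = 30
        df = pd.DataFrame({"g": np.repeat(["a", "b", "c"], 10),
                           "x": rng.normal(size=n)})
        Y = rng.normal(size=(n, 8))
        tab = cmp.procrustes_anova(Y, df, ["g", "x", "g:x"], nperm=0)
        terms = sum(r["SS"] for r in tab.rows if r["term"] not in
                    ("residuals", "total"))
        assert terms + tab["residuals"]["SS"] == pytest.approx(
            tab["total"]["SS"], abs=1e-9)
        for r in tab.rows[:-2]:
            assert r["MS"] == pytest.approx(r["SS"] / r["df"])
            assert r["R2"] == pytest.approx(r["SS"] / tab["total"]["SS"])

    def test_rank_deficiency_raises(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"],
                           "h": ["x", "x", "y", "y"]})  # aliased with g
        Y = np.arange(8.0).reshape(4, 2)
        with pytest.raises(np.linalg.LinAlgError, match="aliased"):
            cmp.procrustes_anova(Y, df, ["g", "h"], nperm=0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(40)
        df = pd.DataFrame({"g": np.repeat(["a", "b"], 10)})
        Y = rng.normal(size=(20, 4))
        p1 = cmp.procrustes_anova(Y, df, ["g"], nperm=200, seed=5)["g"]["p"]
        p2 = cmp.procrustes_anova(Y, df, ["g"], nperm=200, seed=5)["g"]["p"]
        assert p1 == p2


class TestPGLS:
    def test_star_tree_equals_ordinary_anova(self):
        n = 12
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        tree = cio.read_tree(newick)
        labels = [f"t{i}" for i in range(n)]
        rng = np.random.default_rng(41)
        Y = rng.normal(size=(n, 5))
        df = pd.DataFrame({"g": np.repeat(["a", "b", "c"], 4),
                           "x": rng.normal(size=n)})
        t_lm = cmp.procrustes_anova(Y, df, ["g", "x"], nperm=150, seed=9)
        t_pg = cmp.procrustes_pgls(Y, df, ["g", "x"], tree, labels,
                                   nperm=150, seed=9)
        for term in ("g", "x", "residuals", "total"):
            for col in ("df", "SS", "MS", "R2", "F", "p"):
                a, b = t_lm[term][col], t_pg[term][col]
                if isinstance(a, float) and np.isnan(a):
                    assert np.isnan(b)
                else:
                    assert a == pytest.approx(b, abs=1e-9)

    def test_transformed_residual_ss_matches_direct_gls_algebra(self):
        tree = simulate_tree(6, seed=42)
        labels = sorted(t.label for t in tree.taxon_namespace)
        rng = np.random.default_rng(43)
        Y = rng.normal(size=(6, 3))
        x = rng.normal(size=6)
        df = pd.DataFrame({"x": x})
        tab = cmp.procrustes_pgls(Y, df, ["x"], tree, labels, nperm=0)
        # oracle: GLS residual SS by direct C^-1 algebra
        C, _ = cmp.phylo_cov_matrix(tree, order=labels)
        Cinv = np.linalg.inv(C)
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ Cinv @ X, X.T @ Cinv @ Y)
        R = Y - X @ beta
        ss_gls = float(np.einsum("ji,jk,ki->", R, Cinv, R))
        assert tab["residuals"]["SS"] == pytest.approx(ss_gls, rel=1e-9)


class TestPairwise:
    def test_symmetric_zero_diagonal_distances(self):
        rng = np.random.default_rng(44)
        Y = rng.normal(size=(30, 4))
        groups = np.repeat(["a", "b", "c"], 10)
        d, p = cmp.pairwise_group_test(Y, groups, nperm=99, seed=1)
        np.testing.assert_allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)
        pm = p.to_numpy()
        np.testing.assert_allclose(pm, pm.T, equal_nan=True)

    def test_separated_groups_hit_p_floor(self):
        rng = np.random.default_rng(45)
        Y = rng.normal(size=(30, 3))
        groups = np.repeat(["a", "b"], 15)
        Y[groups == "b"] += 10.0
        _, p = cmp.pairwise_group_test(Y, groups, nperm=199, seed=2)
        assert p.loc["a", "b"] == pytest.approx(1 / 200)

    def test_singleton_group_excluded(self):
        rng = np.random.default_rng(46)
        Y = rng.normal(size=(9, 2))
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["s"])
        d, p = cmp.pairwise_group_test(Y, groups, nperm=49, seed=3)
        assert d.attrs["excluded_groups"] == ["s"]
        assert list(d.index) == ["a", "b"]


class TestPhyloResiduals:
    def test_star_tree_equals_ols(self):
        n = 8
        tree = cio.read_tree("(" + ",".join(f"t{i}:1" for i in range(n)) + ");")
        labels = [f"t{i}" for i in range(n)]
        rng = np.random.default_rng(47)
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, 3))
        res = cmp.phylo_residuals(Y, x, tree, labels)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_allclose(res, Y - X @ beta, atol=1e-9)

    def test_exact_linear_response_zero_residuals(self):
        tree = simulate_tree(6, seed=48)
        labels = sorted(t.label for t in tree.taxon_namespace)
        x = np.arange(6.0)
        Y = np.outer(x, [2.0, -1.0]) + 3.0
        res = cmp.phylo_residuals(Y, x, tree, labels)
        assert np.abs(res).max() < 1e-9

    def test_beta_matches_gls_normal_equations(self):
        tree = simulate_tree(6, seed=49)
        labels = sorted(t.label for t in tree.taxon_namespace)
        rng = np.random.default_rng(50)
        x = rng.normal(size=6)
        Y = rng.normal(size=(6, 2))
        res = cmp.phylo_residuals(Y, x, tree, labels)
        C, _ = cmp.phylo_cov_matrix(tree, order=labels)
        Cinv = np.linalg.inv(C)
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ Cinv @ X, X.T @ Cinv @ Y)
        np.testing.assert_allclose(res, Y - X @ beta, atol=1e-10)

    def test_constant_predictor_raises(self):
        tree = simulate_tree(5, seed=51)
        labels = sorted(t.label for t in tree.taxon_namespace)
        with pytest.raises(ValueError, match="constant"):
            cmp.phylo_residuals(np.zeros((5, 2)), np.ones(5), tree, labels)


class TestOlsSlope:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = cmp.ols_slope_ci(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_negative_allometry_labelling(self):
        rng = np.random.default_rng(52)
        x = rng.normal(size=50)
        res = cmp.ols_slope_ci(x, 0.63 * x + rng.normal(scale=0.1, size=50))
        assert res.negative_allometry  # slope < 1 in the log-log convention

    def test_ci_coverage_simulation(self):
        rng = np.random.default_rng(53)
        hits = 0
        for _ in range(1000):
            x = rng.normal(size=30)
            y = 0.63 * x + rng.normal(scale=0.3, size=30)
            res = cmp.ols_slope_ci(x, y)
            hits += res.ci_low <= 0.63 <= res.ci_high
        assert 0.93 <= hits / 1000 <= 0.97

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            cmp.ols_slope_ci(np.ones(5), np.arange(5.0))
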