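"""CVA, cross-validation, typicality, log-likelihood assignment, ellipses."""

import numpy as np
import pytest
from scipy import stats as sps

from canalmorph import classify as cls


def make_groups(rng, offsets, n_each=20, p=3, scale=1.0):
    X, g = [], []
    for i, off in enumerate(offsets):
        X.append(rng.normal(size=(n_each, p)) * scale + np.asarray(off))
        g.extend([f"g{i}"] * n_each)
    return np.vstack(X), np.array(g)


class TestReduceDimensions:
    def test_cumulative_sum_rule(self):
        scores = np.zeros((50, 4))
        vf = np.array([0.6, 0.3, 0.08, 0.02])
        _, m = cls.reduce_dimensions(scores, vf, n_groups=3,
                                     variance_target=0.99)
        assert m == 3

    def test_target_one_keeps_all(self):
        scores = np.zeros((50, 4))
        vf = np.array([0.6, 0.3, 0.08, 0.02])
        _, m = cls.reduce_dimensions(scores, vf, n_groups=3,
                                     variance_target=1.0)
        assert m == 4

    def test_hard_cap_applies(self):
        scores = np.zeros((50, 4))
        vf = np.array([0.6, 0.3, 0.08, 0.02])
        red, m = cls.reduce_dimensions(scores, vf, n_groups=3,
                                       variance_target=0.99, hard_cap=2)
        assert m == 2 and red.shape == (50, 2)

    def test_sample_size_cap(self):
        scores = np.zeros((10, 8))
        vf = np.full(8, 1 / 8)
        _, m = cls.reduce_dimensions(scores, vf, n_groups=3,
                                     variance_target=1.0)
        assert m == 10 - 3 - 1


class TestCVA:
    def test_two_groups_one_dimension(self):
        rng = np.random.default_rng(60)
        X, g = make_groups(rng, [[0.0], [3.0]], n_each=30, p=1)
        model = cls.cva(X, g)
        assert model.n_axes == 1
        z = model.scores[:, 0]
        within = np.concatenate([z[g == "g0"] - z[g == "g0"].mean(),
                                 z[g == "g1"] - z[g == "g1"].mean()])
        assert np.isclose(within.var(ddof=2), 1.0, atol=1e-6)

    def test_within_group_covariance_is_identity(self):
        rng = np.random.default_rng(61)
        X, g = make_groups(rng, [[0, 0, 0], [2, 1, 0], [0, 2, 1]], n_each=40)
        model = cls.cva(X, g)
        n, gg = len(g), 3
        W = np.zeros((model.n_axes, model.n_axes))
        for lab in model.group_labels:
            sub = model.group_scores[lab]
            d = sub - sub.mean(axis=0)
            W += d.T @ d
        W /= n - gg
        assert np.abs(W - np.eye(model.n_axes)).max() < 1e-6

    def test_cv1_parallel_to_fisher_discriminant(self):
        rng = np.random.default_rng(62)
        X, g = make_groups(rng, [[0, 0], [2, 1]], n_each=50, p=2)
        model = cls.cva(X, g)
        mu0 = X[g == "g0"].mean(axis=0)
        mu1 = X[g == "g1"].mean(axis=0)
        W = np.zeros((2, 2))
        for lab in ("g0", "g1"):
            d = X[g == lab] - X[g == lab].mean(axis=0)
            W += d.T @ d
        W /= len(g) - 2
        fisher = np.linalg.solve(W, mu1 - mu0)
        a = model.axes[:, 0]
        cos = abs(a @ fisher) / (np.linalg.norm(a) * np.linalg.norm(fisher))
        assert cos > 1 - 1e-9

    def test_affine_rescaling_leaves_mahalanobis_invariant(self):
        rng = np.random.default_rng(63)
        X, g = make_groups(rng, [[0, 0, 0], [3, 0, 0]], n_each=40)
        m1 = cls.cva(X, g)
        S = np.diag([3.0, 0.5, 7.0])
        m2 = cls.cva(X @ S, g)
        d1 = np.linalg.norm(m1.group_means_cv[0] - m1.group_means_cv[1])
        d2 = np.linalg.norm(m2.group_means_cv[0] - m2.group_means_cv[1])
        assert np.isclose(d1, d2, atol=1e-6)

    def test_singular_within_instructs_reduction(self):
        X = np.zeros((6, 4))
        X[:, 0] = np.arange(6)
        g = np.repeat(["a", "b"], 3)
        with pytest.raises(np.linalg.LinAlgError, match="fewer"):
            cls.cva(X, g)


class TestCrossValidate:
    def test_perfect_separation(self):
        rng = np.random.default_rng(64)
        X, g = make_groups(rng, [[0, 0, 0], [10, 0, 0], [0, 10, 0]],
                           n_each=15)
        acc, conf = cls.cross_validate(X, g)
        assert acc == 1.0
        assert np.trace(conf.to_numpy()) == 45

    def test_null_two_groups_near_chance(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(80, 3))
            g = np.repeat(["a", "b"], 40)
            acc, _ = cls.cross_validate(X, g)
            accs.append(acc)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_confusion_bookkeeping(self):
        rng = np.random.default_rng(65)
        X, g = make_groups(rng, [[0, 0], [1.5, 0]], n_each=25, p=2)
        acc, conf = cls.cross_validate(X, g)
        assert conf.to_numpy().sum() == 50
        assert (conf.sum(axis=1) == 25).all()  # rows sum to group sizes
        assert np.trace(conf.to_numpy()) / 50 == pytest.approx(acc)

    def test_singleton_group_raises(self):
        X = np.random.default_rng(66).normal(size=(5, 2))
        with pytest.raises(ValueError):
            cls.cross_validate(X, np.array(["a", "a", "a", "a", "b"]))


class TestMahalanobis:
    def test_zero_at_mean(self):
        assert cls.mahalanobis_distance([1.0, 2.0], [1.0, 2.0],
                                        np.eye(2)) == 0.0

    def test_identity_covariance_is_euclidean(self):
        assert cls.mahalanobis_distance([3.0, 4.0], [0.0, 0.0],
                                        np.eye(2)) == pytest.approx(5.0)

    def test_hand_inverted_2x2(self):
        cov = np.array([[2.0, 0.0], [0.0, 0.5]])
        d = cls.mahalanobis_distance([1.0, 1.0], [0.0, 0.0], cov)
        assert d == pytest.approx(np.sqrt(2.5))

    def test_singular_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            cls.mahalanobis_distance([1.0, 0.0], [0.0, 0.0], np.zeros((2, 2)))


class TestTypicality:
    def test_specimen_at_mean_is_typical(self):
        rng = np.random.default_rng(67)
        G = rng.normal(size=(30, 3))
        p = cls.typicality_probability(G.mean(axis=0), G, nresample=500,
                                       seed=0)
        assert p >= 0.95

    def test_extreme_outlier_rejected(self):
        rng = np.random.default_rng(68)
        G = rng.normal(size=(30, 2))
        x = G.mean(axis=0) + np.array([10.0, 0.0])
        p = cls.typicality_probability(x, G, nresample=500, seed=0)
        assert p < 0.01

    def test_p_floor_and_range(self):
        rng = np.random.default_rng(69)
        G = rng.normal(size=(10, 2))
        p = cls.typicality_probability(G.mean(axis=0) + 100, G,
                                       nresample=100, seed=0)
        assert 0 < p <= 1
        assert p >= 1.0 / (1.0 + 100 * 10)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            cls.typicality_probability([0.0], np.zeros((2, 1)), nresample=10)


class TestLogLikelihood:
    def test_assigns_to_own_mean(self):
        means = np.array([[0.0, 0.0], [5.0, 0.0]])
        lls, rel, lab, tied = cls.log_likelihood_assign(
            [0.0, 0.0], means, ["A", "B"])
        assert lab == "A" and not tied
        assert rel[0] > 0.99

    def test_equidistant_tie_flagged(self):
        means = np.array([[-1.0, 0.0], [1.0, 0.0]])
        lls, rel, lab, tied = cls.log_likelihood_assign(
            [0.0, 3.0], means, ["A", "B"])
        assert abs(lls[0] - lls[1]) < 1e-9
        assert tied and lab == "A"  # tie broken by label order

    def test_matches_hand_computed_gaussian(self):
        means = np.array([[0.0], [2.0]])
        x = 0.7
        lls, _, _, _ = cls.log_likelihood_assign([x], means, ["A", "B"])
        hand_a = -0.5 * np.log(2 * np.pi) - 0.5 * x ** 2
        hand_b = -0.5 * np.log(2 * np.pi) - 0.5 * (x - 2) ** 2
        assert lls[0] == pytest.approx(hand_a)
        assert lls[1] == pytest.approx(hand_b)

    def test_agrees_with_min_mahalanobis_under_pooled_cov(self):
        rng = np.random.default_rng(70)
        X, g = make_groups(rng, [[0, 0, 0], [2, 1, 0], [0, 0, 3]], n_each=20)
        model = cls.cva(X, g)
        for x in rng.normal(size=(20, 3)) * 2:
            z = model.transform(x)
            dists = np.linalg.norm(model.group_means_cv - z, axis=1)
            _, _, lab, _ = cls.log_likelihood_assign(
                z, model.group_means_cv, model.group_labels)
            assert lab == model.group_labels[int(np.argmin(dists))]


class TestGroupSeparation:
    def test_separated_groups_hit_floor(self):
        rng = np.random.default_rng(71)
        X, g = make_groups(rng, [[0, 0], [10, 0]], n_each=20, p=2)
        p = cls.group_separation_test(X, g, nperm=199, seed=0)
        assert p.loc["g0", "g1"] == pytest.approx(1 / 200)

    def test_symmetric_with_nan_diagonal(self):
        rng = np.random.default_rng(72)
        X, g = make_groups(rng, [[0, 0], [1, 0], [0, 1]], n_each=10, p=2)
        p = cls.group_separation_test(X, g, nperm=99, seed=1)
        m = p.to_numpy()
        np.testing.assert_allclose(m, m.T, equal_nan=True)
        assert np.isnan(np.diag(m)).all()


class TestConfidenceEllipse:
    def test_isotropic_cloud_radius(self):
        rng = np.random.default_rng(73)
        pts = rng.normal(size=(50_000, 2))
        e = cls.confidence_ellipse(pts, level=0.95)
        target = np.sqrt(sps.chi2.ppf(0.95, 2))
        assert np.allclose(e.radii, target, rtol=0.03)
        assert not e.degenerate

    def test_level_zero_degenerates_to_mean(self):
        rng = np.random.default_rng(74)
        pts = rng.normal(size=(100, 2))
        e = cls.confidence_ellipse(pts, level=0.0)
        assert np.allclose(e.radii, 0.0)
        np.testing.assert_allclose(e.center, pts.mean(axis=0))

    def test_collinear_points_flagged(self):
        t = np.linspace(0, 1, 10)
        e = cls.confidence_ellipse(np.column_stack([t, 2 * t]))
        assert e.degenerate

    def test_containment_simulation(self):
        rng = np.random.default_rng(75)
        A = np.array([[1.0, 0.4], [0.0, 0.7]])
        train = rng.normal(size=(5000, 2)) @ A.T + [3.0, -1.0]
        e = cls.confidence_ellipse(train, level=0.95)
        fresh = rng.normal(size=(5000, 2)) @ A.T + [3.0, -1.0]
        R = np.array([[np.cos(e.angle), -np.sin(e.angle)],
                      [np.sin(e.angle), np.cos(e.angle)]])
        local = (fresh - e.center) @ R
        inside = ((local / e.radii) ** 2).sum(axis=1) <= 1.0
        assert abs(inside.mean() - 0.95) < 0.02


class TestClassifyUnknowns:
    def test_far_outlier_rejected_everywhere_but_still_assigned(self):
        rng = np.random.default_rng(76)
        X, g = make_groups(rng, [[0, 0, 0], [6, 0, 0], [0, 6, 0]], n_each=25)
        model = cls.cva(X, g)
        outlier = np.array([50.0, 50.0, 50.0])
        member = X[g == "g1"].mean(axis=0)
        res = cls.classify_unknowns(model, np.vstack([outlier, member]),
                                    ["out", "in"], nresample=500, seed=0)
        assert res[0].rejected_all
        assert res[0].assigned in model.group_labels
        assert not res[1].rejected_all
        assert res[1].assigned == "g1"
        table = cls.classification_table(res)
        assert set(table["specimen_id"]) == {"out", "in"}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(77)
        X, g = make_groups(rng, [[0, 0], [4, 0]], n_each=20, p=2)
        model = cls.cva(X, g)
        unk = rng.normal(size=(3, 2))
        r1 = cls.classify_unknowns(model, unk, list("abc"), nresample=300,
                                   seed=11)
        r2 = cls.classify_unknowns(model, unk, list("abc"), nresample=300,
                                   seed=11)
        assert all(np.array_equal(a.typicality, b.typicality)
                   for a, b in zip(r1, r2))
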