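import itertools

import numpy as np
import pytest

from tanmix.evaluation_metrics import shd
from tanmix.synthetic_data import sim_tan_chain
from tanmix.tan_model import (
    LabeledDataset,
    TANConfig,
    build_nb,
    build_tan,
    cross_validate,
    estimate_cmi,
    fit_class_conditional,
    load_csv,
    prim_max_spanning_tree,
)


def _chain_dataset(n=1000, seed=0):
    ds = sim_tan_chain(n, seed=seed)
    return ds, LabeledDataset(ds.x, ds.labels, list(ds.feature_names))


@pytest.fixture(scope="module")
def chain_gmm_clf():
    _, data = _chain_dataset(1500, seed=0)
    return data, build_tan(data, backend="gmm", seed=0)


class TestLoader:
    def test_mean_imputation(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,b,cls\n1.0,2.0,x\n3.0,,x\n5.0,4.0,y\n7.0,6.0,y\n")
        data = load_csv(p, "cls")
        assert data.x[1, 1] == pytest.approx(4.0)  # column mean of b
        assert list(data.feature_names) == ["a", "b"]

    def test_missing_class_column(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="class column"):
            load_csv(p, "cls")

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            LabeledDataset(np.zeros((3, 2)), np.array([0, 0, 1]), ["a", "b"])


class TestClassConditional:
    def test_gmm_k1_is_class_gaussian(self):
        r = np.random.default_rng(0)
        x = np.column_stack([
            np.concatenate([r.normal(2, 1, 300), r.normal(-2, 1, 300)]),
            r.normal(0, 1, 600),
        ])
        labels = np.repeat([0, 1], 300)
        data = LabeledDataset(x, labels, ["f0", "f1"])
        cfg = TANConfig(gmm_components=1)
        dens = fit_class_conditional(data, [0], 0, backend="gmm", config=cfg)
        x0 = x[labels == 0, 0]
        g = np.linspace(-2, 6, 50)[:, None]
        from scipy import stats

        expected = stats.norm.logpdf(g[:, 0], x0.mean(), x0.std())
        np.testing.assert_allclose(dens.logpdf(g), expected, atol=0.02)

    def test_kde_joint_factorises_for_independent_features(self):
        """Orthogonalised toy data: fitted joint ~ product of marginals.

        The pointwise log-ratio retains KDE sampling noise that peaks in the
        low-density grid corners, so the bound is on the bulk (mean and 90th
        percentile over a 32x32 grid), not the maximum.
        """
        r = np.random.default_rng(1)
        n = 3000
        a = r.standard_normal(n)
        b = r.standard_normal(n)
        b -= a * (a @ b) / (a @ a)  # exact zero sample correlation
        x = np.column_stack([a, b])
        data = LabeledDataset(x, np.repeat([0, 1], n // 2), ["a", "b"])
        joint = fit_class_conditional(data, [0, 1], 0, backend="kde")
        mi = fit_class_conditional(data, [0], 0, backend="kde")
        mj = fit_class_conditional(data, [1], 0, backend="kde")
        g = np.linspace(-1.5, 1.5, 32)
        XX, YY = np.meshgrid(g, g)
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        ratio = np.abs(
            joint.logpdf(pts) - mi.logpdf(pts[:, :1]) - mj.logpdf(pts[:, 1:])
        )
        assert ratio.mean() < 0.1
        assert np.quantile(ratio, 0.9) < 0.15

    def test_same_seed_same_model(self):
        _, data = _chain_dataset(400, seed=3)
        g = np.linspace(-3, 3, 20)[:, None]
        a = fit_class_conditional(data, [2], 0, backend="fgbmle", seed=5)
        b = fit_class_conditional(data, [2], 0, backend="fgbmle", seed=5)
        np.testing.assert_array_equal(a.logpdf(g), b.logpdf(g))

    def test_small_class_error_names_class(self):
        x = np.random.default_rng(0).standard_normal((104, 2))
        labels = np.array(["rare"] * 4 + ["common"] * 100)
        data = LabeledDataset(x, labels, ["a", "b"])
        with pytest.raises(ValueError, match="rare"):
            fit_class_conditional(data, [0], "rare")


class TestCMI:
    def test_independent_joint_gives_zero(self):
        """CMI of an exact product density is 0 up to Monte-Carlo error."""
        from scipy import stats

        class G1:
            def __init__(self, mu):
                self.mu = mu

            def logpdf(self, Y):
                return stats.norm.logpdf(np.atleast_2d(Y)[:, 0], self.mu)

            def sample(self, n, rng):
                return (self.mu + rng.standard_normal(n))[:, None]

        class Prod:
            def logpdf(self, Y):
                Y = np.atleast_2d(Y)
                return stats.norm.logpdf(Y[:, 0]) + stats.norm.logpdf(Y[:, 1], 1.0)

            def sample(self, n, rng):
                return np.column_stack([rng.standard_normal(n),
                                        1.0 + rng.standard_normal(n)])

        S = 20_000
        raw, clamped = estimate_cmi(
            {0: G1(0.0)}, {0: G1(1.0)}, {0: Prod()}, {0: 1.0},
            S=S, rng=np.random.default_rng(0),
        )
        se = 1.0 / np.sqrt(S)
        assert abs(raw) < 3 * se
        assert clamped >= 0

    def test_bivariate_gaussian_closed_form(self):
        """rho = 0.9 Gaussian: MI = -0.5 log(1 - rho^2) ~ 0.830 nats."""
        r = np.random.default_rng(2)
        n = 4000
        z = r.standard_normal((n, 2))
        x = np.column_stack([z[:, 0], 0.9 * z[:, 0] + np.sqrt(1 - 0.81) * z[:, 1]])
        data = LabeledDataset(x, np.repeat([0, 1], n // 2), ["a", "b"])
        cfg = TANConfig(gmm_components=1, cmi_samples=20_000)
        joint = {c: fit_class_conditional(data, [0, 1], c, "gmm", cfg) for c in (0, 1)}
        mi = {c: fit_class_conditional(data, [0], c, "gmm", cfg) for c in (0, 1)}
        mj = {c: fit_class_conditional(data, [1], c, "gmm", cfg) for c in (0, 1)}
        raw, _ = estimate_cmi(mi, mj, joint, {0: 0.5, 1: 0.5},
                              S=20_000, rng=np.random.default_rng(3))
        assert raw == pytest.approx(-0.5 * np.log(1 - 0.81), abs=0.05)

    def test_symmetric_under_swap(self):
        """Swapping the two coordinates of the joint leaves CMI unchanged."""
        r = np.random.default_rng(4)
        n = 1000
        z = r.standard_normal((n, 2))
        x = np.column_stack([z[:, 0], 0.5 * z[:, 0] + z[:, 1]])
        data = LabeledDataset(x, np.repeat([0, 1], n // 2), ["a", "b"])
        cfg = TANConfig(gmm_components=1, cmi_samples=5000)
        mi = {c: fit_class_conditional(data, [0], c, "gmm", cfg) for c in (0, 1)}
        mj = {c: fit_class_conditional(data, [1], c, "gmm", cfg) for c in (0, 1)}
        joint = {c: fit_class_conditional(data, [0, 1], c, "gmm", cfg) for c in (0, 1)}

        class Swap:
            def __init__(self, inner):
                self.inner = inner

            def logpdf(self, Y):
                return self.inner.logpdf(np.atleast_2d(Y)[:, ::-1])

            def sample(self, n_, rng_):
                return self.inner.sample(n_, rng_)[:, ::-1]

        a, _ = estimate_cmi(mi, mj, joint, {0: 0.5, 1: 0.5}, S=5000,
                            rng=np.random.default_rng(9))
        b, _ = estimate_cmi(mj, mi, {c: Swap(j) for c, j in joint.items()},
                            {0: 0.5, 1: 0.5}, S=5000,
                            rng=np.random.default_rng(9))
        assert a == pytest.approx(b, rel=1e-9)


class TestPrim:
    def test_three_node_enumeration(self):
        W = np.array([[0, 3, 1], [3, 0, 2], [1, 2, 0]], dtype=float)
        edges = prim_max_spanning_tree(W)
        assert set(edges) == {(0, 1), (1, 2)}

    def test_equal_weights_give_star_at_zero(self):
        W = np.ones((5, 5)) - np.eye(5)
        edges = prim_max_spanning_tree(W)
        assert set(edges) == {(0, v) for v in range(1, 5)}

    def test_matches_bruteforce_enumeration(self):
        """200 random symmetric matrices, d <= 6, vs all-spanning-trees max."""
        r = np.random.default_rng(6)
        for _ in range(200):
            d = int(r.integers(3, 7))
            W = r.random((d, d))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            edges = prim_max_spanning_tree(W)
            got = sum(W[i, j] for i, j in edges)
            all_edges = list(itertools.combinations(range(d), 2))
            best = -np.inf
            for subset in itertools.combinations(all_edges, d - 1):
                # connectivity check via union-find
                parent = list(range(d))

                def find(v):
                    while parent[v] != v:
                        parent[v] = parent[parent[v]]
                        v = parent[v]
                    return v

                ok = True
                for i, j in subset:
                    ri, rj = find(i), find(j)
                    if ri == rj:
                        ok = False
                        break
                    parent[ri] = rj
                if ok:
                    best = max(best, sum(W[i, j] for i, j in subset))
            assert got == pytest.approx(best, rel=1e-12)

    def test_nonfinite_weight_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = np.inf
        with pytest.raises(ValueError):
            prim_max_spanning_tree(W)


class TestBuildTan:
    def test_two_features_single_edge(self):
        r = np.random.default_rng(0)
        x = r.standard_normal((200, 2))
        data = LabeledDataset(x, np.repeat([0, 1], 100), ["a", "b"])
        clf = build_tan(data, backend="gmm", seed=0)
        assert clf.structure.edges == [(0, 1)]

    def test_chain_recovery_gmm(self):
        hits = 0
        for rep in range(4):
            ds, data = _chain_dataset(2000, seed=rep)
            clf = build_tan(data, backend="gmm", seed=rep)
            if shd(ds.true_adjacency, clf.structure.adjacency()) <= 1:
                hits += 1
        assert hits >= 3

    def test_cmi_matrix_properties(self, chain_gmm_clf):
        _, clf = chain_gmm_clf
        v = clf.cmi.values
        assert np.array_equal(v, v.T)
        assert np.all(v >= 0)
        assert np.all(np.diag(v) == 0)

    def test_row_shuffle_leaves_structure(self):
        ds, data = _chain_dataset(600, seed=8)
        perm = np.random.default_rng(1).permutation(data.n)
        shuffled = LabeledDataset(data.x[perm], data.labels[perm],
                                  data.feature_names)
        a = build_tan(data, backend="kde", seed=2)
        b = build_tan(shuffled, backend="kde", seed=2)
        assert set(a.structure.edges) == set(b.structure.edges)


class TestClassification:
    def test_root_invariance(self, chain_gmm_clf):
        """Log-joints are invariant to the orientation root (telescoping)."""
        data, clf = chain_gmm_clf
        pts = data.x[:20]
        base = clf.class_log_scores(pts)
        for root in range(1, clf.structure.n_nodes):
            alt = clf.rerooted(root).class_log_scores(pts)
            np.testing.assert_allclose(alt, base, atol=1e-9)

    def test_separated_classes_high_accuracy(self):
        r = np.random.default_rng(3)
        n = 2000
        labels = np.repeat([0, 1], n // 2)
        means = np.where(labels[:, None] == 0, -3.0, 3.0)
        x = means + r.standard_normal((n, 4))
        # chain-style dependence on top
        for j in range(1, 4):
            x[:, j] = 0.5 * x[:, j - 1] + 0.5 * x[:, j]
        data = LabeledDataset(x, labels, [f"f{j}" for j in range(4)])
        clf = build_tan(data, backend="gmm", seed=0)
        pred, _ = clf.predict_batch(data.x)
        assert np.mean(pred == labels) >= 0.95

    def test_d1_marginal_bayes_rule(self):
        r = np.random.default_rng(5)
        x = np.concatenate([r.normal(-2, 1, 150), r.normal(2, 1, 50)])[:, None]
        labels = np.repeat([0, 1], [150, 50])
        data = LabeledDataset(x, labels, ["f"])
        clf = build_nb(data, backend="gmm", config=TANConfig(gmm_components=1))
        # far left: prior * density for class 0 dominates
        assert clf.classify(np.array([-2.0])) == 0
        assert clf.classify(np.array([3.0])) == 1

    def test_nb_equals_tan_under_product_pairs(self):
        """With diagonal-covariance pair models, TAN decisions match NB."""
        from tanmix import classical_estimators as ce
        from tanmix.tan_model import StandardizedDensity, TANStructure, TANClassifier

        ds, data = _chain_dataset(800, seed=11)
        cfg = TANConfig(gmm_components=1)
        nb = build_nb(data, backend="gmm", config=cfg, seed=0)
        # build a TAN whose pair models are exact products of the marginals
        struct = TANStructure(
            edges=[(j, j + 1) for j in range(data.dim - 1)],
            n_nodes=data.dim, root=0,
        )

        class ProductPair:
            def __init__(self, m_child, m_parent):
                self.mc, self.mp = m_child, m_parent

            def logpdf(self, Y):
                Y = np.atleast_2d(Y)
                return self.mc.logpdf(Y[:, :1]) + self.mp.logpdf(Y[:, 1:])

        pair_models = {}
        for child, parent in struct.parent.items():
            if parent is None:
                continue
            for c in nb.classes:
                pair_models[(child, parent, c)] = ProductPair(
                    nb.marginal_models[(child, c)],
                    nb.marginal_models[(parent, c)],
                )
        tan = TANClassifier(
            structure=struct, classes=nb.classes,
            class_priors=nb.class_priors,
            marginal_models=nb.marginal_models,
            pair_models=pair_models, backend="gmm",
        )
        pts = data.x[:100]
        np.testing.assert_allclose(
            tan.class_log_scores(pts), nb.class_log_scores(pts), atol=1e-9
        )


class TestCrossValidate:
    def test_majority_class_stub(self):
        """A constant-prediction classifier scores the majority frequency."""
        r = np.random.default_rng(0)
        x = r.standard_normal((100, 2))
        labels = np.repeat([0, 1], [70, 30])
        data = LabeledDataset(x, labels, ["a", "b"])

        class Stub:
            classes = np.array([0, 1])

            def predict_batch(self, X):
                return np.zeros(len(X), dtype=int), np.zeros((len(X), 2))

            def _cidx(self, c):
                return int(c)

        res = cross_validate(data, folds=5, seed=0,
                             model=lambda *a, **k: Stub())
        assert res["accuracy_mean"] == pytest.approx(0.7, abs=1e-9)

    def test_leave_one_out_runs(self):
        # 6 rows per class so every LOO training split keeps >= 5 per class
        r = np.random.default_rng(1)
        x = np.concatenate([r.normal(-2, 0.5, 6), r.normal(2, 0.5, 6)])[:, None]
        x = np.column_stack([x, x[:, 0] + 0.1 * r.standard_normal(12)])
        labels = np.repeat([0, 1], 6)
        data = LabeledDataset(x, labels, ["a", "b"])
        res = cross_validate(data, backend="gmm", folds=12, seed=0,
                             config=TANConfig(gmm_components=1))
        assert len(res["fold_accuracy"]) == 12

    def test_tan_beats_nb_on_chain(self):
        """Paired over seeds, the tree model outscores naive Bayes."""
        wins = 0
        for seed in range(2):
            ds, data = _chain_dataset(1200, seed=seed)
            cv_tan = cross_validate(data, backend="gmm", folds=2, seed=seed,
                                    model="tan")
            cv_nb = cross_validate(data, backend="gmm", folds=2, seed=seed,
                                   model="nb")
            if cv_tan["accuracy_mean"] >= cv_nb["accuracy_mean"]:
                wins += 1
        assert wins == 2
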