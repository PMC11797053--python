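"""LDA closed form, Wilks stepwise, validation, and the phylogenetic variant.

scikit-learn's LinearDiscriminantAnalysis serves as the independent oracle
for coefficients and fold predictions; it is never the implementation.
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from conftest import yule_tree
from dietcnv import discriminant as dd
from dietcnv import simulate, trees


def random_instance(seed, n1=12, n2=15, p=4, sep=1.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        np.vstack([rng.normal(sep, 1.0, (n1, p)),
                   rng.normal(0.0, 1.0, (n2, p))]),
        columns=[f"g{i}" for i in range(p)])
    labels = np.array(["herbivore"] * n1 + ["carnivore"] * n2)
    return X, labels


class TestFitLda:
    def test_one_dim_boundary_between_symmetric_classes(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"g": np.r_[rng.normal(0, 1, 50),
                                     rng.normal(10, 1, 50)]})
        labels = np.array(["carnivore"] * 50 + ["herbivore"] * 50)
        m = dd.fit_lda(X, labels, priors={"carnivore": .5, "herbivore": .5})
        pred = dd.predict(m, X)
        assert (pred.to_numpy() == labels).all()
        # boundary at the midpoint: a point at 5 +/- 1 flips class
        lo = dd.predict(m, pd.DataFrame({"g": [4.0]})).iloc[0]
        hi = dd.predict(m, pd.DataFrame({"g": [6.0]})).iloc[0]
        assert (lo, hi) == ("carnivore", "herbivore")

    @pytest.mark.parametrize("seed", range(20))
    def test_coefficients_collinear_with_closed_form(self, seed):
        X, labels = random_instance(seed)
        m = dd.fit_lda(X, labels)
        vals = X.to_numpy()
        mh = vals[labels == "herbivore"].mean(axis=0)
        mc = vals[labels == "carnivore"].mean(axis=0)
        Wh = vals[labels == "herbivore"] - mh
        Wc = vals[labels == "carnivore"] - mc
        S = (Wh.T @ Wh + Wc.T @ Wc) / (len(labels) - 2)
        w_direct = np.linalg.solve(S, mh - mc)
        cos = (m.w @ w_direct
               / np.linalg.norm(m.w) / np.linalg.norm(w_direct))
        assert cos > 0.999

    def test_default_priors_are_class_proportions(self):
        X, labels = random_instance(3, n1=25, n2=43)
        m = dd.fit_lda(X, labels)
        assert m.priors["carnivore"] == pytest.approx(0.632, abs=5e-4)
        assert m.priors["herbivore"] == pytest.approx(0.368, abs=5e-4)

    def test_sklearn_prediction_agreement(self):
        X, labels = random_instance(5, sep=0.8)
        m = dd.fit_lda(X, labels)
        sk = LinearDiscriminantAnalysis(
            priors=[m.priors["carnivore"], m.priors["herbivore"]]
        ).fit(X, labels)
        assert (dd.predict(m, X).to_numpy() == sk.predict(X)).all()

    def test_scaling_equivariance(self):
        X, labels = random_instance(6)
        m = dd.fit_lda(X, labels)
        X2 = X.copy()
        X2["g0"] = X2["g0"] * 10
        m2 = dd.fit_lda(X2, labels)
        assert m2.w[0] == pytest.approx(m.w[0] / 10, rel=1e-8)
        assert (dd.predict(m, X).to_numpy()
                == dd.predict(m2, X2).to_numpy()).all()

    def test_tiny_class_rejected(self):
        X, labels = random_instance(7)
        labels = labels.copy()
        labels[:] = "carnivore"
        labels[0] = "herbivore"
        with pytest.raises(ValueError, match=">= 2"):
            dd.fit_lda(X, labels)

    def test_model_json_roundtrip(self):
        X, labels = random_instance(8)
        m = dd.fit_lda(X, labels)
        m2 = dd.DiscriminantModel.from_json(m.to_json())
        np.testing.assert_allclose(m.w, m2.w)
        assert (dd.predict(m, X).to_numpy()
                == dd.predict(m2, X).to_numpy()).all()


class TestDfScores:
    def test_grand_centroid_scores_zero(self):
        X, labels = random_instance(9)
        m = dd.fit_lda(X, labels)
        centroid = pd.DataFrame([X.mean(axis=0)], columns=X.columns)
        assert dd.df_scores(m, centroid).iloc[0] == pytest.approx(0.0)

    def test_herbivore_mean_score_above_carnivore(self):
        X, labels = random_instance(10)
        m = dd.fit_lda(X, labels)
        s = dd.df_scores(m, X)
        assert s[labels == "herbivore"].mean() > s[labels == "carnivore"].mean()

    def test_affine_in_each_feature(self):
        X, labels = random_instance(11)
        m = dd.fit_lda(X, labels)
        x0 = pd.DataFrame([X.iloc[0]], columns=X.columns)
        base = dd.df_scores(m, x0).iloc[0]
        for j, f in enumerate(X.columns):
            bumped = x0.copy()
            bumped[f] += 1.0
            assert dd.df_scores(m, bumped).iloc[0] == pytest.approx(
                base + m.w[j])

    def test_missing_feature_listed(self):
        X, labels = random_instance(12)
        m = dd.fit_lda(X, labels)
        with pytest.raises(ValueError, match="g3"):
            dd.df_scores(m, X.drop(columns=["g3"]))

    def test_fisher_ratio_maximal_over_random_directions(self):
        X, labels = random_instance(13, sep=1.0)
        m = dd.fit_lda(X, labels)
        vals = X.to_numpy()

        def fisher(w):
            proj = vals @ w
            a, b = proj[labels == "herbivore"], proj[labels == "carnivore"]
            between = (a.mean() - b.mean()) ** 2
            within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            return between / within

        best_random = max(
            fisher(v) for v in np.random.default_rng(0)
            .standard_normal((1000, vals.shape[1])))
        assert fisher(m.w) >= best_random - 1e-12


class TestWilks:
    def test_identical_means_give_one(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(40, 3)))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        X.iloc[20:] = X.iloc[:20].to_numpy()  # same empirical distribution
        assert dd.wilks_lambda(X, labels) == pytest.approx(1.0, abs=1e-12)

    def test_separated_classes_near_zero(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame({"g": np.r_[rng.normal(0, 1e-3, 20),
                                     rng.normal(1, 1e-3, 20)]})
        labels = np.array(["a"] * 20 + ["b"] * 20)
        assert dd.wilks_lambda(X, labels) < 1e-4

    @pytest.mark.parametrize("seed", range(50))
    def test_determinant_ratio_oracle(self, seed):
        X, labels = random_instance(seed, p=3)
        lam = dd.wilks_lambda(X, labels)
        vals = X.to_numpy()
        grand = vals.mean(axis=0)
        W = np.zeros((3, 3))
        B = np.zeros((3, 3))
        for c in ("herbivore", "carnivore"):
            sub = vals[labels == c]
            d = sub - sub.mean(axis=0)
            W += d.T @ d
            dm = (sub.mean(axis=0) - grand)[:, None]
            B += len(sub) * (dm @ dm.T)
        oracle = np.linalg.det(W) / np.linalg.det(W + B)
        assert lam == pytest.approx(oracle, rel=1e-10)

    def test_monotone_nonincreasing_when_adding_features(self):
        X, labels = random_instance(16, p=5)
        feats = list(X.columns)
        for k in range(1, 5):
            a = dd.wilks_lambda(X, labels, feats[:k])
            b = dd.wilks_lambda(X, labels, feats[:k + 1])
            assert b <= a + 1e-12


class TestStepwise:
    def test_planted_feature_enters_first(self):
        rng = np.random.default_rng(17)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"g{i}" for i in range(10)])
        labels = np.array(["herbivore"] * 30 + ["carnivore"] * 30)
        X["g4"] += np.where(labels == "herbivore", 2.5, 0.0)
        trace = dd.stepwise_wilks(X, labels)
        assert trace.selected[0] == "g4"
        assert all(b < a for a, b in zip([1.0] + trace.wilks, trace.wilks))

    def test_alpha_zero_selects_nothing(self):
        X, labels = random_instance(18)
        trace = dd.stepwise_wilks(X, labels, alpha_enter=0.0)
        assert trace.selected == []

    @pytest.mark.parametrize("seed", range(10))
    def test_first_step_matches_exhaustive_minimum(self, seed):
        X, labels = random_instance(seed + 60, p=3)
        trace = dd.stepwise_wilks(X, labels, alpha_enter=1.0)
        lams = {f: dd.wilks_lambda(X, labels, [f]) for f in X.columns}
        assert trace.selected[0] == min(lams, key=lams.get)


class TestValidation:
    def test_separated_clouds_perfect_loocv(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame(np.vstack([rng.normal(0, 1, (20, 3)),
                                    rng.normal(10, 1, (20, 3))]))
        labels = np.array(["carnivore"] * 20 + ["herbivore"] * 20)
        acc, _ = dd.loocv(X, labels)
        assert acc == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(20)
        accs = []
        for rep in range(20):
            X = pd.DataFrame(rng.normal(size=(30, 3)))
            labels = np.array(["carnivore"] * 15 + ["herbivore"] * 15)
            rng.shuffle(labels)
            if min((labels == "carnivore").sum(),
                   (labels == "herbivore").sum()) < 3:
                continue
            acc, _ = dd.loocv(X, labels)
            accs.append(acc)
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_matches_independent_sklearn_refit_loop(self):
        X, labels = random_instance(21, sep=0.7)
        priors_ours = {c: float((labels == c).mean())
                       for c in np.unique(labels)}
        acc, preds = dd.loocv(X, labels)
        sk_preds = []
        for i in range(len(labels)):
            mask = np.ones(len(labels), bool)
            mask[i] = False
            sk = LinearDiscriminantAnalysis(
                priors=[priors_ours["carnivore"], priors_ours["herbivore"]]
            ).fit(X[mask], labels[mask])
            sk_preds.append(sk.predict(X[~mask])[0])
        assert list(preds) == sk_preds
        assert acc == np.mean(np.array(sk_preds) == labels)

    def test_clade_holdout_partition_covers_all_once(self):
        X, labels = random_instance(22, n1=10, n2=12)
        X.index = [f"sp{i}" for i in range(22)]
        half = list(X.index[::2])   # interleaved so training keeps both
        other = list(X.index[1::2])  # classes on either split
        p1 = dd.clade_holdout(X, labels, half)
        p2 = dd.clade_holdout(X, labels, other)
        assert sorted(p1.index) + sorted(p2.index, key=str) != []
        assert set(p1.index) | set(p2.index) == set(X.index)
        assert not (set(p1.index) & set(p2.index))

    def test_empty_clade_gives_empty_predictions(self):
        X, labels = random_instance(23)
        assert dd.clade_holdout(X, labels, []).empty

    def test_clade_removing_a_whole_class_rejected(self):
        X, labels = random_instance(24, n1=4, n2=10)
        X.index = [f"sp{i}" for i in range(14)]
        with pytest.raises(ValueError, match="both classes"):
            dd.clade_holdout(X, labels, list(X.index[:4]))


class TestPfda:
    def _phylo_instance(self, seed, n=20):
        t = yule_tree(n, seed)
        depth = max(t.tip_depths().values())
        for nd in t._tree.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length /= depth  # unit depth
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 4)), index=t.tip_labels,
                         columns=list("wxyz"))
        labels = np.array(["herbivore", "carnivore"] * (n // 2))
        X.loc[labels == "herbivore"] += 1.0
        return X, labels, t

    def test_lambda_zero_equals_plain_lda(self):
        X, labels, t = self._phylo_instance(30)
        priors = {"carnivore": 0.632, "herbivore": 0.368}
        model, Xw = dd.fit_pfda(X, labels, t, 0.0, priors)
        plain = dd.fit_lda(X, labels, priors=priors)
        assert (dd.predict(model, Xw).to_numpy()
                == dd.predict(plain, X).to_numpy()).all()

    def test_fixed_priors_survive_training_composition(self):
        X, labels, t = self._phylo_instance(31)
        priors = {"carnivore": 0.632, "herbivore": 0.368}
        model, _ = dd.fit_pfda(X, labels, t, 0.05, priors)
        assert model.priors == priors

    def test_nonultrametric_tree_rejected(self):
        X, labels, t = self._phylo_instance(32)
        t._tree.leaf_nodes()[0].edge.length += 1.0
        with pytest.raises(ValueError, match="ultrametric"):
            dd.fit_pfda(X, labels, t, 0.0,
                        {"carnivore": 0.5, "herbivore": 0.5})

    def test_grid_of_one_value(self):
        X, labels, t = self._phylo_instance(33)
        lam, tab = dd.optimal_pfda_lambda(X, labels, t, grid=[0.03])
        assert lam == 0.03 and len(tab) == 1

    def test_grid_table_covers_grid(self):
        X, labels, t = self._phylo_instance(34)
        lam, tab = dd.optimal_pfda_lambda(X, labels, t)
        assert len(tab) == 11
        assert tab["misclassification"].between(0, 1).all()
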