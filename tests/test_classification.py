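import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from eggshell import (
    Algorithm,
    ComparatorSpec,
    SplitSpec,
    ValidationError,
    fit_comparator,
    fit_lda,
    partition_consistency,
    predict_lda,
    split_dataset,
)
from .conftest import random_dataset


def _brute_force_lda(X, y):
    """Independent oracle: dense eigensolution of W^-1 B.

    Forms the scatter matrices explicitly, solves the non-symmetric
    eigenproblem with numpy's general solver, and normalizes eigenvectors
    to unit within-class variance.
    """
    classes = np.unique(y)
    n, p = X.shape
    g = len(classes)
    W = np.zeros((p, p))
    means = []
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        means.append(mu)
        W += (Xc - mu).T @ (Xc - mu)
    W /= n - g
    means = np.array(means)
    counts = np.array([(y == c).sum() for c in classes])
    grand = counts @ means / n
    dm = means - grand
    B = (dm * counts[:, None]).T @ dm / (g - 1)
    evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
    evals, evecs = np.real(evals), np.real(evecs)
    order = np.argsort(evals)[::-1][: min(p, g - 1)]
    vals = evals[order]
    vecs = evecs[:, order]
    for j in range(vecs.shape[1]):
        vecs[:, j] /= np.sqrt(vecs[:, j] @ W @ vecs[:, j])
    return vals, vecs


def _separable_toy(rng, n_per=30):
    means = np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0]], dtype=float)
    X = np.vstack(
        [rng.normal(m, 1.0, size=(n_per, 3)) for m in means]
    )
    y = np.repeat(["c1", "c2", "c3"], n_per)
    return X, y


class TestSplit:
    def test_sizes(self, rng):
        ds = random_dataset(rng, n=100)
        tr, te = split_dataset(ds, SplitSpec(train_fraction=0.7, seed=1))
        assert len(tr) == 70 and len(te) == 30
        assert set(tr.df["egg_id"]) & set(te.df["egg_id"]) == set()

    def test_deterministic(self, rng):
        ds = random_dataset(rng, n=80)
        a = split_dataset(ds, SplitSpec(seed=5, stratified=False))
        b = split_dataset(ds, SplitSpec(seed=5, stratified=False))
        assert a[0] == b[0] and a[1] == b[1]

    def test_stratification_counts(self, calibrated):
        _, ds, _ = calibrated
        cons, _, _ = partition_consistency(ds)
        tr, te = split_dataset(cons, SplitSpec(train_fraction=0.7, seed=2))
        for ave in np.unique(cons.aveobs):
            n_all = (cons.aveobs == ave).sum()
            n_tr = (tr.aveobs == ave).sum()
            assert abs(n_tr - 0.7 * n_all) <= 1.0

    def test_singleton_class_rejected(self, rng):
        ds = random_dataset(rng, n=40)
        # force one unique AveObs category
        df = ds.df.copy()
        df.loc[:, ["obs1", "obs2", "obs3", "obs4"]] = 2
        df.loc[0, ["obs1", "obs2", "obs3", "obs4"]] = [1, 1, 1, 1]
        from eggshell import Dataset

        with pytest.raises(ValidationError, match="single record"):
            split_dataset(Dataset(df[ds.df.columns[:9]]), SplitSpec())


class TestLDA:
    def test_separable_training_accuracy(self, rng):
        X, y = _separable_toy(rng)
        model = fit_lda(X, y)
        assert np.mean(predict_lda(model, X) == y) == 1.0

    def test_six_point_toy_matches_brute_force(self):
        X = np.array(
            [
                [0.0, 0.0, 0.0], [1.0, 0.5, 0.0],
                [4.0, 1.0, 1.0], [5.0, 1.5, 0.5],
                [2.0, 4.0, 3.0], [3.0, 5.0, 3.5],
            ]
        )
        y = np.array([0, 0, 1, 1, 2, 2])
        model = fit_lda(X, y)
        vals, vecs = _brute_force_lda(X, y)
        assert np.allclose(model.eigenvalues, vals, atol=1e-8)
        assert np.allclose(np.abs(model.scalings), np.abs(vecs), atol=1e-8)

    def test_random_instances_match_brute_force(self, rng):
        """Random 5-class, 60-sample problems: scalings agree with the
        dense-eigensolver oracle up to column sign."""
        for _ in range(5):
            X = rng.normal(size=(60, 3)) + rng.normal(
                scale=3.0, size=(5, 3)
            ).repeat(12, axis=0)
            y = np.repeat(np.arange(5), 12)
            model = fit_lda(X, y)
            vals, vecs = _brute_force_lda(X, y)
            assert np.allclose(model.eigenvalues, vals, atol=1e-6)
            assert np.allclose(np.abs(model.scalings), np.abs(vecs), atol=1e-6)

    def test_transformed_within_covariance_is_identity(self, rng):
        X = rng.normal(size=(90, 3)) + np.repeat(
            rng.normal(scale=4.0, size=(3, 3)), 30, axis=0
        )
        y = np.repeat(list("abc"), 30)
        model = fit_lda(X, y)
        Z = X @ model.scalings
        W = np.zeros((Z.shape[1], Z.shape[1]))
        for c in np.unique(y):
            d = Z[y == c] - Z[y == c].mean(axis=0)
            W += d.T @ d
        W /= len(X) - 3
        assert np.allclose(W, np.eye(Z.shape[1]), atol=1e-6)

    def test_proportion_of_trace_properties(self, rng):
        X, y = _separable_toy(rng)
        model = fit_lda(X, y)
        pot = model.proportion_of_trace
        assert pot.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(pot) <= 1e-12)  # non-increasing
        assert model.scalings.shape == (3, 2)  # min(p, g-1) discriminants

    def test_class_mean_maps_to_own_class_with_equal_priors(self, rng):
        X, y = _separable_toy(rng, n_per=25)
        model = fit_lda(X, y)
        pred = predict_lda(model, model.means)
        assert list(pred) == list(model.classes)

    def test_affine_invariance_of_predictions(self, rng):
        X, y = _separable_toy(rng)
        Xt = rng.normal(size=(40, 3)) * 5 + np.array([5, 5, 5])
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        shift = np.array([1.0, -2.0, 0.5])
        base = predict_lda(fit_lda(X, y), Xt)
        trans = predict_lda(fit_lda(X @ A.T + shift, y), Xt @ A.T + shift)
        assert np.array_equal(base, trans)

    def test_matches_sklearn_predictions(self, rng):
        X = rng.normal(size=(120, 3)) + np.repeat(
            rng.normal(scale=2.5, size=(4, 3)), 30, axis=0
        )
        y = np.repeat(np.arange(4), 30)
        Xt = rng.normal(size=(60, 3)) + X.mean(axis=0)
        ours = predict_lda(fit_lda(X, y), Xt)
        sk = LinearDiscriminantAnalysis().fit(X, y).predict(Xt)
        assert np.array_equal(ours, sk)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValidationError):
            fit_lda(X, np.zeros(10))  # single class
        y = np.array([0] * 9 + [1])
        with pytest.raises(ValidationError, match="fewer than 2"):
            fit_lda(X, y)
        with pytest.raises(ValidationError):
            predict_lda(fit_lda(X, np.repeat([0, 1], 5)), rng.normal(size=(4, 2)))


class TestComparators:
    @pytest.mark.parametrize("alg", list(Algorithm))
    def test_separable_toy_and_totality(self, rng, alg):
        ds = random_dataset(rng, n=120)
        # make the colors perfectly informative of the AveObs category
        df = ds.df.copy()
        df.loc[:, ["obs1", "obs2", "obs3", "obs4"]] = np.tile(
            np.repeat([1, 2, 3, 4], 30)[:, None], (1, 4)
        )
        df.loc[:, "L"] = np.repeat([20.0, 40.0, 60.0, 80.0], 30) + rng.normal(
            scale=0.5, size=120
        )
        from eggshell import Dataset

        toy = Dataset(df[ds.df.columns[:9]])
        fitted = fit_comparator(
            ComparatorSpec(algorithm=alg, cv_folds=5), toy, seed=0
        )
        pred = fitted.predict(toy.colors)
        assert len(pred) == len(toy)
        assert set(pred) <= set(fitted.classes)
        assert np.mean(pred == toy.aveobs.astype(str)) == 1.0
        assert fitted.cv_accuracy > 0.9

    def test_lda_accuracy_on_consistent_synthetic(self, corrected_full):
        """Calibration run: unanimous-egg LDA test accuracy across seeds."""
        cons, _, _ = partition_consistency(corrected_full)
        accs = []
        for seed in range(5):
            tr, te = split_dataset(cons, SplitSpec(seed=seed))
            fitted = fit_comparator(
                ComparatorSpec(Algorithm.LDA, cv_folds=10), tr, seed=seed
            )
            accs.append(
                float(np.mean(fitted.predict(te.colors) == te.aveobs.astype(str)))
            )
        assert np.mean(accs) > 0.85

    def test_unknown_algorithm_rejected(self, rng):
        with pytest.raises(ValueError):
            ComparatorSpec(algorithm="GRADIENT_BOOST")

    def test_folds_reduced_for_rare_classes(self, rng):
        # smallest class has 3 members; 10-fold CV must drop to 3 folds
        ds = random_dataset(rng, n=43)
        df = ds.df.copy()
        labels = np.array([1] * 20 + [2] * 20 + [3] * 3)
        df.loc[:, ["obs1", "obs2", "obs3", "obs4"]] = np.tile(
            labels[:, None], (1, 4)
        )
        from eggshell import Dataset

        fitted = fit_comparator(
            ComparatorSpec(Algorithm.LDA, cv_folds=10),
            Dataset(df[ds.df.columns[:9]]),
        )
        assert np.isfinite(fitted.cv_accuracy)
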