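"""The four fruit/non-fruit classifiers against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from litchivision import classifiers as clf
from litchivision.errors import (
    DegenerateProblemError,
    ParameterError,
    UndefinedSimilarityError,
)


def make_training_set(rng, n=20, d=2, sep=6.0):
    fruit = rng.normal(sep, 1.0, (n // 2, d))
    bg = rng.normal(0.0, 1.0, (n // 2, d))
    X = np.vstack([fruit, bg])
    y = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
    return clf.TrainingSet(X, y)


class TestBayes:
    def test_posteriors_match_closed_form_oracle(self, rng):
        """Posteriors equal a direct evaluation of Bayes' rule with
        hand-computed per-feature Gaussian densities."""
        data = make_training_set(rng, n=20, d=2, sep=3.0)
        model = clf.BayesClassifier.train(data)
        for x in rng.normal(1.5, 2.0, (10, 2)):
            joint = []
            for c in (0, 1):
                Xc = data.features[data.labels == c]
                prior = len(Xc) / len(data.features)
                dens = prior
                for j in range(2):
                    mu, var = Xc[:, j].mean(), max(Xc[:, j].var(), 1e-9)
                    dens *= np.exp(-((x[j] - mu) ** 2) / (2 * var)) / np.sqrt(
                        2 * np.pi * var
                    )
                joint.append(dens)
            oracle = np.array(joint) / sum(joint)
            assert np.allclose(model.posterior(x)[0], oracle, atol=1e-12)

    def test_posteriors_sum_to_one(self, rng):
        data = make_training_set(rng)
        model = clf.BayesClassifier.train(data)
        X = rng.normal(0, 5, (50, 2))
        assert np.allclose(model.posterior(X).sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_point_has_even_posterior(self):
        # equal priors, mirror-image classes -> midpoint is 50/50
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = clf.BayesClassifier.train(clf.TrainingSet(X, y))
        assert model.posterior([0.0])[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_class_mean_classified_as_fruit(self, rng):
        data = make_training_set(rng, sep=8.0)
        model = clf.BayesClassifier.train(data)
        fruit_mean = data.features[data.labels == 1].mean(axis=0)
        label, post = model.classify(fruit_mean)
        assert label == clf.FRUIT
        assert post > 0.99

    def test_zero_variance_feature_floored_not_fatal(self):
        X = np.array([[1.0, 5.0], [1.0, 6.0], [3.0, 0.0], [3.0, 1.0]])
        y = np.array([1, 1, 0, 0])
        model = clf.BayesClassifier.train(clf.TrainingSet(X, y))
        label, post = model.classify([1.0, 5.5])
        assert label == clf.FRUIT and np.isfinite(post)


class TestCosineKnn:
    def test_cosine_examples(self):
        assert clf.cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert clf.cosine_similarity([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_cosine_matches_brute_force_sum(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        num = sum(xi * yi for xi, yi in zip(x, y))
        den = np.sqrt(sum(v * v for v in x)) * np.sqrt(sum(v * v for v in y))
        assert clf.cosine_similarity(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            clf.cosine_similarity(np.zeros(3), np.ones(3))

    def test_stored_sample_is_own_neighbor(self, rng):
        data = make_training_set(rng, d=4)
        model = clf.KnnClassifier.train(data, k=1)
        fruit_sample = data.features[data.labels == 1][0]
        assert model.classify(fruit_sample, k=1) == clf.FRUIT

    def test_majority_forced_when_k_covers_all(self, rng):
        X = np.abs(rng.normal(3, 1, (10, 3)))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])  # 60% non-fruit
        model = clf.KnnClassifier.train(clf.TrainingSet(X, y), k=10)
        for q in np.abs(rng.normal(3, 1, (5, 3))):
            assert model.classify(q) == clf.NON_FRUIT

    def test_matches_exhaustive_sort_and_vote(self, rng):
        data = make_training_set(rng, n=30, d=5, sep=2.0)
        model = clf.KnnClassifier.train(data, k=5)
        for q in rng.normal(1.0, 2.0, (20, 5)):
            sims = [
                clf.cosine_similarity(q, s) for s in data.features
            ]
            top = np.argsort(sims, kind="stable")[::-1][:5]
            votes = data.labels[top].sum()
            oracle = clf.FRUIT if 2 * votes > 5 else clf.NON_FRUIT
            assert model.classify(q) == oracle

    def test_cosine_scale_invariance(self, rng):
        data = make_training_set(rng, d=4)
        model1 = clf.KnnClassifier.train(data, k=5)
        scaled = clf.TrainingSet(data.features * 37.0, data.labels)
        model2 = clf.KnnClassifier.train(scaled, k=5)
        Q = np.abs(rng.normal(2, 1, (20, 4)))
        assert np.array_equal(model1.predict(Q), model2.predict(Q * 37.0))
        assert np.array_equal(model1.predict(Q), model2.predict(Q))

    def test_parameter_validation(self, rng):
        model = clf.KnnClassifier.train(make_training_set(rng), k=5)
        with pytest.raises(ParameterError):
            model.predict(np.ones((1, 2)), k=0)
        with pytest.raises(ParameterError):
            model.predict(np.ones((1, 2)), k=1000)


class TestBpNetwork:
    def test_hidden_size_rule(self):
        assert clf.hidden_size(9, 1, 4) == 7  # the working value
        assert clf.hidden_size(9, 1, 1) == 4
        assert clf.hidden_size(9, 1, 10) == 13
        with pytest.raises(ParameterError):
            clf.hidden_size(9, 1, 0)
        with pytest.raises(ParameterError):
            clf.hidden_size(9, 1, 11)

    def test_sigmoid_midpoint(self):
        assert clf.sigmoid(np.array([0.0]))[0] == 0.5

    def test_training_converges_on_separable_set(self, rng):
        """Full-batch gradient descent: loss decreases monotonically after
        warm-up and the separable problem is fit exactly."""
        X = np.vstack(
            [rng.normal(0.8, 0.05, (20, 9)), rng.normal(0.2, 0.05, (20, 9))]
        )
        y = np.concatenate([np.ones(20), np.zeros(20)])
        model = clf.BpClassifier.train(X, y, J=7, seed=1234, epochs=1500)
        losses = np.array(model.loss_history)
        warm = losses[50:]
        assert np.all(np.diff(warm) <= 1e-12)
        assert losses[-1] < losses[0]
        assert np.mean(model.predict(X) == y) == 1.0

    def test_input_dimension_validated(self, rng):
        with pytest.raises(ParameterError):
            clf.BpClassifier.train(rng.normal(0, 1, (10, 5)), np.zeros(10))


def svm_qp_oracle(X, y_pm, C=10.0):
    """Generic quadratic-programming solve of the soft-margin primal."""
    n, d = X.shape

    def objective(z):
        w, b, xi = z[:d], z[d], z[d + 1 :]
        return 0.5 * np.dot(w, w) + C * xi.sum()

    cons = [
        {
            "type": "ineq",
            "fun": lambda z, i=i: y_pm[i] * (np.dot(z[:d], X[i]) + z[d])
            - 1
            + z[d + 1 + i],
        }
        for i in range(n)
    ] + [{"type": "ineq", "fun": lambda z, i=i: z[d + 1 + i]} for i in range(n)]
    z0 = np.zeros(d + 1 + n)
    res = minimize(objective, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 400, "ftol": 1e-10})
    return res.x[:d], res.x[d]


class TestLinearSvm:
    def test_one_dimensional_symmetric_margin(self):
        X = np.array([[-1.0], [1.0], [-1.2], [1.2]])
        y = np.array([0, 1, 0, 1])
        model = clf.SvmClassifier.train(clf.TrainingSet(X, y))
        # decision boundary at 0; support vectors on the unit margin
        assert model.decision([[0.0]])[0] == pytest.approx(0.0, abs=1e-6)
        assert abs(model.decision([[1.0]])[0]) == pytest.approx(1.0, abs=1e-3)
        assert model.classify([2.0]) == clf.FRUIT
        assert model.classify([-2.0]) == clf.NON_FRUIT

    def test_support_vectors_on_active_constraint(self, rng):
        data = make_training_set(rng, n=30, d=2, sep=6.0)
        model = clf.SvmClassifier.train(data)
        margins = np.abs(model.decision(data.features))
        assert margins.min() == pytest.approx(1.0, abs=1e-4)

    def test_labels_match_qp_oracle(self, rng):
        """Same decisions as a generic QP solve of the margin program."""
        data = make_training_set(rng, n=20, d=2, sep=5.0)
        model = clf.SvmClassifier.train(data)
        mean, std = model.scale_mean, model.scale_std
        Xs = (data.features - mean) / std
        y_pm = np.where(data.labels == 1, 1, -1)
        w, b = svm_qp_oracle(Xs, y_pm)
        grid = rng.normal(2.5, 3.0, (50, 2))
        grid_s = (grid - mean) / std
        oracle_labels = (grid_s @ w + b > 0).astype(int)
        assert np.array_equal(model.predict(grid), oracle_labels)

    def test_duplicate_sample_invariance(self, rng):
        data = make_training_set(rng, n=20, d=2, sep=6.0)
        model1 = clf.SvmClassifier.train(data)
        X2 = np.vstack([data.features, data.features[:1]])
        y2 = np.concatenate([data.labels, data.labels[:1]])
        model2 = clf.SvmClassifier.train(clf.TrainingSet(X2, y2))
        Q = rng.normal(3, 3, (50, 2))
        assert np.array_equal(model1.predict(Q), model2.predict(Q))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateProblemError):
            clf.TrainingSet(np.ones((4, 2)), np.ones(4, int))


class TestAllClassifiers:
    def test_all_reach_perfect_training_accuracy(self, separable_features):
        X, y = separable_features
        data = clf.TrainingSet(X, y)
        for model in (
            clf.BayesClassifier.train(data),
            clf.KnnClassifier.train(data, k=5),
            clf.SvmClassifier.train(data),
        ):
            assert np.mean(model.predict(X) == y) == 1.0
        Xb = (X[:, :9] - X[:, :9].min()) / np.ptp(X[:, :9])
        bp = clf.BpClassifier.train(Xb, y, J=7, seed=1234, epochs=1500)
        assert np.mean(bp.predict(Xb) == y) == 1.0

    def test_save_load_predictions_bit_identical(self, rng, tmp_path):
        data = make_training_set(rng, n=20, d=9, sep=4.0)
        Q = rng.normal(2, 3, (30, 9))
        models = {
            "bayes": clf.BayesClassifier.train(data),
            "knn": clf.KnnClassifier.train(data, k=5),
            "svm": clf.SvmClassifier.train(data),
            "bp": clf.BpClassifier.train(
                data.features, data.labels, J=5, seed=7, epochs=100
            ),
        }
        for kind, model in models.items():
            path = tmp_path / f"{kind}.json"
            clf.save_model(model, path)
            reloaded = clf.load_model(path)
            assert np.array_equal(model.predict(Q), reloaded.predict(Q))
            if kind == "bayes":
                assert np.array_equal(model.posterior(Q), reloaded.posterior(Q))
            if kind == "bp":
                assert np.array_equal(model.forward(Q), reloaded.forward(Q))


class TestSegmentation:
    def test_disjoint_windows_equal_per_window_map(self, trained_models, rng):
        """At stride 40 the mask is exactly the per-window decision map."""
        from litchivision.features import window_features
        from litchivision.synthetic_scenes import SceneSpec, generate_scene

        left, _, _ = generate_scene(
            SceneSpec(
                image_size=(240, 160),
                cluster_plan=(1,),
                depth_range_mm=(2400.0, 2600.0),
                seed=5,
            )
        )
        model = trained_models["bayes"]
        mask = clf.segment_image(left, model, stride=40)
        xs, ys = clf.window_grid(left.shape, stride=40)
        for y0 in ys:
            for x0 in xs:
                vec = window_features(left, (x0, y0, 40, 40))
                expected = bool(model.predict(vec)[0])
                block = mask[y0 : y0 + 40, x0 : x0 + 40]
                assert np.all(block == expected)

    def test_background_scene_yields_empty_fused_mask(self, trained_models):
        from litchivision.fruit_detection import detect_circles_from_mask
        from litchivision.synthetic_scenes import SceneSpec, generate_scene

        left, _, _ = generate_scene(
            SceneSpec(image_size=(320, 240), cluster_plan=(), seed=11)
        )
        masks = clf.segment_image_all(left, trained_models, stride=8)
        circles = []
        for kind, mask in masks.items():
            circles += detect_circles_from_mask(mask, source=kind)
        assert circles == []

    def test_missing_model_reported_by_name(self, trained_models):
        incomplete = {k: v for k, v in trained_models.items() if k != "svm"}
        from litchivision.errors import MissingModelError

        with pytest.raises(MissingModelError, match="svm"):
            clf.segment_image_all(np.zeros((60, 60, 3)), incomplete)
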