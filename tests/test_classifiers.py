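"""MLP, RBF-SVM, and HRCNN classifiers over 20-feature vectors."""

import numpy as np
import pytest

from wbckit.classifiers import (
    CLASS_LABELS, Hyperrectangle, HRCNNModel, evaluate, hrcnn_classifier,
    hrcnn_hidden, hrcnn_output, hrcnn_rules, hrcnn_train, load_classifier,
    mlp_train, parse_rules, predict, save_classifier, svm_train,
)
from wbckit.synthetic_data import generate_feature_dataset


@pytest.fixture(scope="module")
def five_class_data():
    """50 vectors per class, well-separated clusters, fixed seed."""
    return generate_feature_dataset(n_per_class=50, separation=5.0, seed=7)


@pytest.fixture(scope="module")
def train_test_data():
    X, y = generate_feature_dataset(n_per_class=80, separation=5.0, seed=7)
    tr = np.concatenate([np.arange(k * 80, k * 80 + 50) for k in range(5)])
    te = np.concatenate([np.arange(k * 80 + 50, (k + 1) * 80) for k in range(5)])
    return X[tr], y[tr], X[te], y[te]


@pytest.fixture(scope="module")
def separable_2class():
    rng = np.random.default_rng(13)
    a = rng.standard_normal((60, 20)) + 8.0
    b = rng.standard_normal((60, 20)) - 8.0
    X = np.vstack([a, b])
    y = np.array(["lymphocyte"] * 60 + ["neutrophil"] * 60, dtype=object)
    return X, y


class TestHrcnnHidden:
    def test_interior_point_fires(self):
        h = Hyperrectangle(m=np.zeros(20), M=np.ones(20))
        assert hrcnn_hidden(np.full(20, 0.5), h) == 1

    def test_boundary_point_fires(self):
        # (M-x)(x-m) = 0 on the face and f(0) = 1
        h = Hyperrectangle(m=np.zeros(20), M=np.ones(20))
        x = np.full(20, 0.5)
        x[3] = 1.0
        assert hrcnn_hidden(x, h) == 1

    def test_exterior_point_silent(self):
        h = Hyperrectangle(m=np.zeros(20), M=np.ones(20))
        x = np.full(20, 0.5)
        x[7] = 1.01
        assert hrcnn_hidden(x, h) == 0

    def test_equals_interval_containment_oracle(self):
        rng = np.random.default_rng(21)
        h = Hyperrectangle(m=rng.uniform(-1, 0, 20), M=rng.uniform(0, 1, 20))
        X = rng.uniform(-1.5, 1.5, size=(10_000, 20))
        for x in X:
            want = int(np.all((h.m <= x) & (x <= h.M)))
            assert hrcnn_hidden(x, h) == want

    def test_dimension_mismatch_rejected(self):
        h = Hyperrectangle(m=np.zeros(20), M=np.ones(20))
        with pytest.raises(ValueError):
            hrcnn_hidden(np.zeros(19), h)


class TestHrcnnOutput:
    @pytest.fixture()
    def toy_model(self):
        boxes = {
            "lymphocyte": [Hyperrectangle(m=[0.0], M=[0.3]),
                           Hyperrectangle(m=[0.5], M=[0.6])],
            "monocyte": [Hyperrectangle(m=[0.8], M=[1.0])],
        }
        return HRCNNModel(boxes=boxes, eta=0.5,
                          classes=("lymphocyte", "monocyte"))

    def test_fires_when_any_box_contains(self, toy_model):
        assert hrcnn_output([0.55], toy_model, "lymphocyte") == 1

    def test_silent_when_no_box_contains(self, toy_model):
        assert hrcnn_output([0.7], toy_model, "lymphocyte") == 0

    def test_unknown_class_rejected(self, toy_model):
        with pytest.raises(ValueError):
            hrcnn_output([0.5], toy_model, "basophil")

    def test_equals_disjunction_oracle(self, toy_model):
        rng = np.random.default_rng(22)
        for x in rng.uniform(-0.2, 1.2, size=(500, 1)):
            for cls in toy_model.classes:
                want = int(any(b.contains(x) for b in toy_model.boxes[cls]))
                assert hrcnn_output(x, toy_model, cls) == want


class TestHrcnnTrain:
    def test_hand_run_1d_covering(self):
        X = np.array([[0.1], [0.2], [0.9]])
        y = np.array(["A", "A", "B"], dtype=object)
        m = hrcnn_train(X, y)
        assert len(m.boxes["A"]) == 1
        np.testing.assert_allclose(m.boxes["A"][0].m, [0.1])
        np.testing.assert_allclose(m.boxes["A"][0].M, [0.2])
        np.testing.assert_allclose(m.boxes["B"][0].m, [0.9])
        np.testing.assert_allclose(m.boxes["B"][0].M, [0.9])
        clf = hrcnn_classifier(m, X, y)
        assert clf.training_report["overall"] == 1.0

    def test_hundred_percent_training_accuracy(self, five_class_data):
        X, y = five_class_data
        clf = hrcnn_classifier(hrcnn_train(X, y), X, y)
        assert clf.training_report["overall"] == 1.0
        assert all(v == 1.0 for v in clf.training_report["per_class"].values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_training_contract_across_random_datasets(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((100, 5))
        y = np.asarray(rng.choice(list(CLASS_LABELS), size=100), dtype=object)
        clf = hrcnn_classifier(hrcnn_train(X, y))
        assert evaluate(clf, X, y)["overall"] == 1.0

    def test_single_point_per_class(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 20))
        y = np.array(list(CLASS_LABELS), dtype=object)
        m = hrcnn_train(X, y)
        assert all(len(m.boxes[c]) == 1 for c in CLASS_LABELS)
        clf = hrcnn_classifier(m)
        assert evaluate(clf, X, y)["overall"] == 1.0

    def test_contradictory_duplicates_rejected(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        y = np.array(["A", "B"], dtype=object)
        with pytest.raises(ValueError, match="inconsistent"):
            hrcnn_train(X, y)

    def test_boxes_never_contain_other_classes(self, five_class_data):
        X, y = five_class_data
        m = hrcnn_train(X, y)
        for c in m.classes:
            others = X[y != c]
            for b in m.boxes[c]:
                assert not np.any(np.all((others >= b.m) & (others <= b.M),
                                         axis=1))


class TestHrcnnRules:
    def test_one_rule_per_box_and_verbatim_bounds(self):
        boxes = {"monocyte": [Hyperrectangle(m=[0.25, -1.5], M=[0.75, 2.5])]}
        m = HRCNNModel(boxes=boxes, classes=("monocyte",))
        text = hrcnn_rules(m, feature_names=["area", "comp"])
        rules = [l for l in text.splitlines() if l.startswith("Rule")]
        assert len(rules) == 1
        assert "area in [0.25, 0.75]" in rules[0]
        assert "comp in [-1.5, 2.5]" in rules[0]
        assert rules[0].endswith("THEN monocyte")

    def test_round_trip_preserves_predictions(self, five_class_data):
        X, y = five_class_data
        m = hrcnn_train(X, y)
        m2 = parse_rules(hrcnn_rules(m))
        clf, clf2 = hrcnn_classifier(m), hrcnn_classifier(m2)
        rng = np.random.default_rng(30)
        probe = rng.uniform(X.min(0), X.max(0), size=(300, X.shape[1]))
        np.testing.assert_array_equal(clf.predict(probe), clf2.predict(probe))


class TestMlp:
    def test_hidden_architecture(self, separable_2class):
        X, y = separable_2class
        clf = mlp_train(X, y, seed=0, epochs=30)
        shapes = [w.shape for w in clf.params["weights"]]
        assert shapes[:2] == [(20, 12), (12, 10)]

    def test_five_class_head_has_437_parameters(self, five_class_data):
        X, y = five_class_data
        clf = mlp_train(X, y, seed=0, epochs=5)
        n = sum(w.size for w in clf.params["weights"]) + \
            sum(b.size for b in clf.params["biases"])
        assert n == 437

    def test_separable_toy_training_accuracy(self, separable_2class):
        X, y = separable_2class
        clf = mlp_train(X, y, seed=0, epochs=200)
        assert clf.training_report["overall"] >= 0.99

    def test_same_seed_identical_predictions(self, separable_2class):
        X, y = separable_2class
        a = mlp_train(X, y, seed=5, epochs=50)
        b = mlp_train(X, y, seed=5, epochs=50)
        rng = np.random.default_rng(1)
        probe = rng.standard_normal((50, 20)) * 4
        np.testing.assert_array_equal(a.predict(probe), b.predict(probe))

    def test_single_class_rejected(self):
        X = np.zeros((10, 20))
        y = np.array(["lymphocyte"] * 10, dtype=object)
        with pytest.raises(ValueError):
            mlp_train(X, y)


class TestSvm:
    def test_separable_toy_heldout_accuracy(self, separable_2class):
        X, y = separable_2class
        clf = svm_train(X, y, seed=0)
        rng = np.random.default_rng(14)
        Xt = np.vstack([rng.standard_normal((40, 20)) + 8.0,
                        rng.standard_normal((40, 20)) - 8.0])
        yt = np.array(["lymphocyte"] * 40 + ["neutrophil"] * 40, dtype=object)
        assert evaluate(clf, Xt, yt)["overall"] >= 0.99

    def test_single_class_rejected(self):
        X = np.zeros((10, 20))
        y = np.array(["monocyte"] * 10, dtype=object)
        with pytest.raises(ValueError):
            svm_train(X, y)

    def test_support_vectors_subset_of_training(self, separable_2class):
        X, y = separable_2class
        clf = svm_train(X, y, seed=0)
        mean, std = clf.scaler
        Xs = (X - mean) / std
        sv = clf.params["support_vectors"]
        assert clf.training_report["n_support_vectors"] == sv.shape[0]
        for v in sv:
            assert np.any(np.all(np.isclose(Xs, v, atol=1e-12), axis=1))

    def test_predict_matches_sklearn(self, five_class_data):
        from sklearn.svm import SVC

        X, y = five_class_data
        clf = svm_train(X, y, seed=0)
        mean, std = clf.scaler
        ref = SVC(kernel="rbf", gamma="scale", C=10.0).fit((X - mean) / std, y)
        rng = np.random.default_rng(15)
        probe = rng.uniform(X.min(0), X.max(0), size=(400, X.shape[1]))
        np.testing.assert_array_equal(clf.predict(probe),
                                      ref.predict((probe - mean) / std))


class TestPredictEvaluate:
    def test_hrcnn_training_data_perfect(self, five_class_data):
        X, y = five_class_data
        clf = hrcnn_classifier(hrcnn_train(X, y))
        rep = evaluate(clf, X, y)
        assert rep["overall"] == 1.0

    def test_single_example_dataset(self):
        X = np.array([[0.5] * 20, [5.0] * 20])
        y = np.array(["basophil", "eosinophil"], dtype=object)
        clf = hrcnn_classifier(hrcnn_train(X, y))
        assert predict(clf, X[0]) == "basophil"
        assert evaluate(clf, X[:1], y[:1])["overall"] == 1.0

    def test_accuracy_is_hand_counted_fraction(self):
        X = np.vstack([np.full((5, 20), 0.0), np.full((5, 20), 10.0)])
        X += np.arange(10)[:, None] * 0.01          # make rows distinct
        y = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
        clf = hrcnn_classifier(hrcnn_train(X, y))
        y_wrong = y.copy()
        y_wrong[[0, 7]] = ["B", "A"]                # 2 of 10 mislabeled
        rep = evaluate(clf, X, y_wrong)
        assert rep["overall"] == pytest.approx(0.8)

    def test_class_recovery_all_three_classifiers(self, train_test_data):
        Xtr, ytr, Xte, yte = train_test_data
        results = {}
        results["mlp"] = evaluate(mlp_train(Xtr, ytr, seed=1), Xte, yte)
        results["svm"] = evaluate(svm_train(Xtr, ytr, seed=1), Xte, yte)
        results["hrcnn"] = evaluate(hrcnn_classifier(hrcnn_train(Xtr, ytr)),
                                    Xte, yte)
        for kind, rep in results.items():
            assert rep["overall"] >= 0.95, (kind, rep["overall"])


class TestSerialization:
    def test_hrcnn_round_trip(self, tmp_path, five_class_data):
        X, y = five_class_data
        clf = hrcnn_classifier(hrcnn_train(X, y), X, y)
        p = tmp_path / "hrcnn.json"
        save_classifier(clf, p)
        loaded = load_classifier(p)
        rng = np.random.default_rng(40)
        probe = rng.uniform(X.min(0), X.max(0), size=(200, X.shape[1]))
        np.testing.assert_array_equal(clf.predict(probe), loaded.predict(probe))

    def test_mlp_round_trip(self, tmp_path, separable_2class):
        X, y = separable_2class
        clf = mlp_train(X, y, seed=2, epochs=50)
        p = tmp_path / "mlp.json"
        save_classifier(clf, p)
        loaded = load_classifier(p)
        rng = np.random.default_rng(41)
        probe = rng.standard_normal((100, 20)) * 5
        np.testing.assert_array_equal(clf.predict(probe), loaded.predict(probe))

    def test_svm_round_trip(self, tmp_path, separable_2class):
        X, y = separable_2class
        clf = svm_train(X, y, seed=2)
        p = tmp_path / "svm.json"
        save_classifier(clf, p)
        loaded = load_classifier(p)
        rng = np.random.default_rng(42)
        probe = rng.standard_normal((100, 20)) * 5
        np.testing.assert_array_equal(clf.predict(probe), loaded.predict(probe))
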