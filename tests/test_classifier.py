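"""Origin classifier: kernels, class weighting, training, probability
calibration, prediction invariances, persistence, cross-validation."""

import numpy as np
import pytest

from nporigin import classifier, metrics
from nporigin.classifier import (
    KernelSpec,
    TrainedOriginClassifier,
    compute_kernel_matrix,
    cross_validate,
    fit,
    inverse_frequency_weights,
)
from nporigin.errors import (
    ConfigurationError,
    DegenerateTrainingError,
    DimensionError,
)


class TestKernelSpec:
    def test_rbf_requires_gamma(self):
        with pytest.raises(ConfigurationError):
            KernelSpec("rbf")

    def test_gamma_forbidden_elsewhere(self):
        with pytest.raises(ConfigurationError):
            KernelSpec("tanimoto", gamma=0.1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            KernelSpec("cosine")


class TestKernelMatrix:
    def test_map4_match_unit_diagonal_and_symmetry(self, small_fingerprints):
        X, _ = small_fingerprints
        K = compute_kernel_matrix(X[:25], X[:25], KernelSpec("map4_match"))
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)
        assert K.min() >= 0.0 and K.max() <= 1.0

    def test_map4_match_worked_toy_example(self):
        X = np.array([[1, 2, 3, 4], [1, 2, 9, 9]], dtype=np.uint32)
        K = compute_kernel_matrix(X, X, KernelSpec("map4_match"))
        assert K[0, 1] == K[1, 0] == 0.5

    def test_tanimoto_worked_example(self):
        a = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        b = np.array([[1, 0, 1, 0]], dtype=np.uint8)
        K = compute_kernel_matrix(a, b, KernelSpec("tanimoto"))
        assert K[0, 0] == pytest.approx(1 / 3)

    def test_dice_worked_example(self):
        a = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        b = np.array([[1, 0, 1, 0]], dtype=np.uint8)
        K = compute_kernel_matrix(a, b, KernelSpec("dice"))
        assert K[0, 0] == pytest.approx(2 * 1 / (2 + 2))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(DimensionError):
            compute_kernel_matrix(np.ones((2, 4)), np.ones((2, 5)),
                                  KernelSpec("map4_match"))


class TestClassWeights:
    def test_inverse_frequency_ratio(self):
        labels = ["a"] * 100 + ["b"] * 50 + ["c"] * 50
        w = inverse_frequency_weights(labels)
        assert w["b"] / w["a"] == pytest.approx(2.0)
        assert w["c"] / w["a"] == pytest.approx(2.0)

    def test_doubling_a_class_halves_its_relative_weight(self):
        w1 = inverse_frequency_weights(["a"] * 50 + ["b"] * 50)
        w2 = inverse_frequency_weights(["a"] * 100 + ["b"] * 50)
        # weight * count is constant within a weighting
        assert w1["a"] * 50 == pytest.approx(w1["b"] * 50)
        assert w2["a"] * 100 == pytest.approx(w2["b"] * 50)
        # so doubling class a halves its weight relative to class b
        assert (w2["a"] / w2["b"]) == pytest.approx((w1["a"] / w1["b"]) / 2)


def _separable_features(n_per_class=50, d=64, seed=0):
    """Three well-separated clusters of MinHash-like integer vectors:
    class prototypes with a few mutated positions per sample."""
    rng = np.random.default_rng(seed)
    protos = rng.integers(0, 2**31 - 1, size=(3, d), dtype=np.uint32)
    X, y = [], []
    for c, proto in enumerate(protos):
        for _ in range(n_per_class):
            v = proto.copy()
            flip = rng.integers(0, d, size=d // 8)
            v[flip] = rng.integers(0, 2**31 - 1, size=len(flip), dtype=np.uint32)
            X.append(v)
            y.append(f"class{c}")
    return np.stack(X), np.array(y)


class TestFit:
    def test_separable_clusters_reach_perfect_training_accuracy(self):
        X, y = _separable_features()
        # nearest-centroid oracle in match-fraction space confirms separability
        K = compute_kernel_matrix(X, X, KernelSpec("map4_match"))
        oracle_pred = []
        for i in range(len(y)):
            sims = [K[i][y == c].mean() for c in ("class0", "class1", "class2")]
            oracle_pred.append(f"class{int(np.argmax(sims))}")
        assert (np.array(oracle_pred) == y).all()

        model = fit(X, y, KernelSpec("map4_match"), seed=0)
        pred = model.predict_features(X)
        conf = metrics.confusion_matrix(y, pred, model.classes)
        assert metrics.balanced_accuracy(conf) == 1.0
        assert model.C in classifier.DEFAULT_C_GRID

    def test_single_class_is_degenerate(self):
        X, _ = _separable_features(n_per_class=10)
        with pytest.raises(DegenerateTrainingError):
            fit(X[:10], ["only"] * 10)

    def test_determinism_same_inputs_same_model(self):
        X, y = _separable_features(n_per_class=20, seed=3)
        m1 = fit(X, y, seed=5)
        m2 = fit(X, y, seed=5)
        assert m1.C == m2.C
        assert np.array_equal(
            m1.predict_proba_features(X, prepared=True),
            m2.predict_proba_features(X, prepared=True),
        )

    def test_class_weights_stored_inversely_proportional(self):
        X, y = _separable_features(n_per_class=20, seed=3)
        y = y.copy()
        y[:10] = "class1"  # unbalance: class0=10, class1=30, class2=20
        model = fit(X, y, seed=0)
        w = model.class_weights
        assert w["class0"] * 10 == pytest.approx(w["class1"] * 30)
        assert w["class0"] * 10 == pytest.approx(w["class2"] * 20)


@pytest.fixture(scope="module")
def model(small_fingerprints):
    X, y = small_fingerprints
    return fit(X, y, C_grid=[1.0], seed=0)


class TestPredict:

    def test_percentages_normalized(self, model):
        label, pct = model.predict("CC(=O)NC1OC(CO)C(O)C1O")
        assert label in model.classes
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)
        assert all(0.0 <= v <= 100.0 for v in pct.values())

    def test_training_molecule_recovers_its_class(self, model, small_dataset):
        hits = 0
        probe = [small_dataset[i] for i in (0, 35, 65)]  # one per class block
        for m in probe:
            label, _ = model.predict(m.smiles)
            hits += label == m.origin
        assert hits == len(probe)

    def test_stereo_and_smiles_form_invariance(self, model):
        variants = [
            "C[C@H](N)C(=O)O",
            "C[C@@H](N)C(=O)O",
            "CC(N)C(O)=O",
            "OC(=O)C(C)N",
        ]
        outputs = [model.predict(s) for s in variants]
        for label, pct in outputs[1:]:
            assert label == outputs[0][0]
            assert pct == outputs[0][1]


class TestPersistence:
    def test_save_load_reproduces_predictions_bitwise(self, small_fingerprints,
                                                      tmp_path):
        X, y = small_fingerprints
        model = fit(X, y, C_grid=[1.0], seed=0)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedOriginClassifier.load(path)
        assert loaded.classes == model.classes
        assert loaded.C == model.C
        assert loaded.platt_params == model.platt_params
        a = model.predict_proba_features(X, prepared=True)
        b = loaded.predict_proba_features(X, prepared=True)
        assert np.array_equal(a, b)


class TestCrossValidate:
    def test_every_sample_in_exactly_one_test_fold(self, small_fingerprints):
        X, y = small_fingerprints
        report = cross_validate(X, y, k=5, seed=2, C_grid=[1.0])
        assert report.confusion.sum() == len(y)
        assert report.folds == 5
        # row sums equal per-class totals
        for c, row in zip(sorted(set(y)), report.confusion):
            assert row.sum() == (y == c).sum()

    def test_perfectly_separable_reaches_metric_maxima(self):
        X, y = _separable_features(n_per_class=25, seed=4)
        report = cross_validate(X, y, k=5, seed=0, C_grid=[1.0])
        assert report.balanced_accuracy[0] == 1.0
        assert report.mcc[0] == 1.0
        assert report.f1[0] == 1.0

    def test_small_class_cannot_be_stratified(self):
        X, y = _separable_features(n_per_class=3, seed=4)
        with pytest.raises(DegenerateTrainingError):
            cross_validate(X, y, k=5)

    def test_determinism(self, small_fingerprints):
        X, y = small_fingerprints
        r1 = cross_validate(X, y, k=3, seed=11, C_grid=[1.0])
        r2 = cross_validate(X, y, k=3, seed=11, C_grid=[1.0])
        assert r1.per_fold.equals(r2.per_fold)
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_signal_well_above_chance_on_synthetic_classes(self, small_fingerprints):
        X, y = small_fingerprints
        report = cross_validate(X, y, k=5, seed=2, C_grid=[1.0])
        assert report.balanced_accuracy[0] >= 0.8  # chance level is 1/3


class TestComparatorPipelines:
    """The three baseline representations train end to end."""

    @pytest.mark.parametrize(
        "spec",
        [
            KernelSpec("tanimoto"),
            KernelSpec("dice"),
            KernelSpec("rbf", gamma=0.1),
        ],
        ids=["tanimoto-circular", "dice-atompair", "rbf-properties"],
    )
    def test_comparator_crossval_beats_chance(self, spec, small_dataset):
        from nporigin.fingerprints import featurize

        smiles = [m.smiles for m in small_dataset]
        y = np.array([m.origin for m in small_dataset])
        X = featurize(smiles, spec.feature_representation,
                      strip_stereochemistry=True)
        report = cross_validate(X, y, spec, k=3, seed=0, C_grid=[1.0])
        assert report.balanced_accuracy[0] > 0.5

    def test_rbf_scaler_fit_on_training_only(self, small_dataset):
        from nporigin.fingerprints import featurize

        smiles = [m.smiles for m in small_dataset]
        y = np.array([m.origin for m in small_dataset])
        X = featurize(smiles, "properties")
        model = fit(X[:60], y[:60], KernelSpec("rbf", gamma=0.1), C_grid=[1.0])
        assert model.scaler_mean is not None
        np.testing.assert_allclose(
            model.scaler_mean, X[:60].mean(axis=0), rtol=1e-10
        )
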