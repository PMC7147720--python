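import numpy as np
import pytest

from lesionfuse.classifiers import (
    ClassifierModel,
    LesionDecision,
    MlpNetwork,
    mlp_forward,
    predict,
    register_external_classifier,
    train_hog_svm,
    train_mlp,
)
from lesionfuse.classifiers.mlp import sigmoid, softmax
from lesionfuse.hogfeatures import HogParams
from lesionfuse.preprocess import DermoscopyImage, GrayImage


def _random_net(rng, sizes=(4, 5, 2)):
    ws = [rng.normal(size=(sizes[i + 1], sizes[i])) for i in range(len(sizes) - 1)]
    bs = [rng.normal(size=sizes[i + 1]) for i in range(len(sizes) - 1)]
    return MlpNetwork(layer_sizes=sizes, weights=ws, biases=bs)


def brute_force_forward(net, x):
    """Per-neuron re-evaluation of the layer recurrence, scalar arithmetic."""
    a = list(map(float, x))
    n_layers = len(net.weights)
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        z = []
        for j in range(w.shape[0]):
            s = b[j]
            for k in range(w.shape[1]):
                s += w[j, k] * a[k]
            z.append(s)
        if l == n_layers - 1:
            m = max(z)
            e = [np.exp(v - m) for v in z]
            a = [v / sum(e) for v in e]
        else:
            a = [1.0 / (1.0 + np.exp(-v)) for v in z]
    return np.array(a)


class TestForward:
    def test_zero_net_gives_even_scores(self):
        net = MlpNetwork(
            layer_sizes=(3, 4, 2),
            weights=[np.zeros((4, 3)), np.zeros((2, 4))],
            biases=[np.zeros(4), np.zeros(2)],
        )
        out = mlp_forward(net, np.zeros(3))
        assert np.allclose(out, [0.5, 0.5])

    def test_hand_evaluated_tiny_net(self):
        # 1 input, 1 hidden (w=1, b=0), outputs weights (1, -1): input 0
        # -> hidden sigma(0)=0.5 -> softmax(0.5, -0.5)
        net = MlpNetwork(
            layer_sizes=(1, 1, 2),
            weights=[np.array([[1.0]]), np.array([[1.0], [-1.0]])],
            biases=[np.zeros(1), np.zeros(2)],
        )
        out = mlp_forward(net, np.array([0.0]))
        expected = np.exp([0.5, -0.5]) / np.exp([0.5, -0.5]).sum()
        assert np.allclose(out, expected)
        assert np.isclose(out[0], 0.7310585786300049)

    def test_scores_sum_to_one_random_nets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            net = _random_net(rng)
            out = mlp_forward(net, rng.normal(size=4))
            assert abs(out.sum() - 1.0) < 1e-9

    def test_matches_per_neuron_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            net = _random_net(rng, sizes=(3, 6, 2))
            x = rng.normal(size=3)
            assert np.allclose(mlp_forward(net, x), brute_force_forward(net, x), atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            mlp_forward(_random_net(rng), np.zeros(7))


def _blobs(rng, n=40, sep=4.0):
    x0 = rng.normal(size=(n // 2, 2)) + [0, 0]
    x1 = rng.normal(size=(n // 2, 2)) + [sep, sep]
    x = np.vstack([x0, x1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return x, y


class TestTrainMlp:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        x, y = _blobs(rng)
        model = train_mlp(x, y, hidden_units=8, seed=0)
        net = model.parameters["network"]
        scores = mlp_forward(net, x)[:, 0]
        assert ((scores >= 0.5).astype(int) == y).all()

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(1)
        x, y = _blobs(rng)
        m1 = train_mlp(x, y, hidden_units=6, seed=3)
        m2 = train_mlp(x, y, hidden_units=6, seed=3)
        for w1, w2 in zip(m1.parameters["network"].weights, m2.parameters["network"].weights):
            assert np.array_equal(w1, w2)

    def test_single_class_input_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            train_mlp(x, np.ones(10, dtype=int), hidden_units=4, seed=0)

    def test_label_swap_yields_complementary_decisions(self):
        rng = np.random.default_rng(2)
        x, y = _blobs(rng, sep=2.0)
        m1 = train_mlp(x, y, hidden_units=6, seed=5)
        m2 = train_mlp(x, 1 - y, hidden_units=6, seed=5)
        s1 = mlp_forward(m1.parameters["network"], x)[:, 0]
        s2 = mlp_forward(m2.parameters["network"], x)[:, 0]
        d1 = (s1 >= 0.5).astype(int)
        d2 = (s2 >= 0.5).astype(int)
        assert np.array_equal(d1, 1 - d2)


def _stripe_images(n, vertical, rng):
    """Gray images whose only structure is a global vertical/horizontal stripe set."""
    out = []
    for _ in range(n):
        px = np.full((32, 32), 120, dtype=np.uint8)
        phase = rng.integers(0, 8)
        if vertical:
            px[:, phase::8] = 40
        else:
            px[phase::8, :] = 40
        out.append(GrayImage(pixels=px))
    return out


class TestTrainHogSvm:
    def test_orthogonal_stripes_perfectly_separated(self):
        rng = np.random.default_rng(0)
        hog = HogParams(window_size=(32, 32))
        imgs = _stripe_images(8, True, rng) + _stripe_images(8, False, rng)
        y = np.array([1] * 8 + [0] * 8)
        test = _stripe_images(4, True, rng) + _stripe_images(4, False, rng)
        model = train_hog_svm(imgs, y, hog=hog, seed=0)
        from lesionfuse.classifiers.svm import hog_svm_score

        preds = [int(hog_svm_score(model, g) >= 0.5) for g in test]
        assert preds == [1] * 4 + [0] * 4

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_hog_svm([], np.array([], dtype=int))

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        imgs = _stripe_images(4, True, rng)
        with pytest.raises(ValueError):
            train_hog_svm(imgs, np.ones(4, dtype=int), hog=HogParams(window_size=(32, 32)))


class TestExternal:
    def test_registered_accuracy_becomes_weight_basis(self):
        model = register_external_classifier({}, validation_accuracy=0.9166)
        from lesionfuse._util import round_half_away

        assert round_half_away(model.validation_accuracy, 2) == 0.92

    def test_accuracy_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            register_external_classifier({}, validation_accuracy=1.2)

    def test_unknown_image_id_raises_lookup_error(self):
        table = {
            "a": LesionDecision(d=1, score=0.9),
            "b": LesionDecision(d=0, score=0.2),
        }
        model = register_external_classifier(table, 0.8)
        img = DermoscopyImage(
            pixels=np.zeros((8, 8, 3), dtype=np.uint8), source_id="c"
        )
        with pytest.raises(KeyError):
            predict(model, img)

    def test_registered_decision_echoed(self):
        table = {"x": LesionDecision(d=1, score=0.77)}
        model = register_external_classifier(table, 0.5)
        img = DermoscopyImage(pixels=np.zeros((8, 8, 3), dtype=np.uint8), source_id="x")
        out = predict(model, img)
        assert out.d == 1 and out.score == 0.77

    def test_empty_table_valid_but_unusable(self):
        model = register_external_classifier({}, 0.5)
        img = DermoscopyImage(pixels=np.zeros((8, 8, 3), dtype=np.uint8), source_id="q")
        with pytest.raises(KeyError):
            predict(model, img)


class TestPredictFrontEnd:
    def test_predict_deterministic(self, small_nevus):
        img, _, _ = small_nevus
        net = MlpNetwork(
            layer_sizes=(32 * 32, 2, 2),
            weights=[np.zeros((2, 32 * 32)), np.zeros((2, 2))],
            biases=[np.zeros(2), np.zeros(2)],
        )
        model = ClassifierModel(kind="mlp", parameters={"network": net, "input_shape": (32, 32)})
        out1 = predict(model, img)
        out2 = predict(model, img)
        assert out1 == out2

    def test_tie_score_resolves_to_melanoma(self, small_nevus):
        img, _, _ = small_nevus
        net = MlpNetwork(
            layer_sizes=(32 * 32, 2, 2),
            weights=[np.zeros((2, 32 * 32)), np.zeros((2, 2))],
            biases=[np.zeros(2), np.zeros(2)],
        )
        model = ClassifierModel(kind="mlp", parameters={"network": net, "input_shape": (32, 32)})
        out = predict(model, img)
        assert out.score == 0.5 and out.d == 1

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierModel(kind="forest", parameters={})


class TestActivations:
    def test_sigmoid_extremes_stable(self):
        assert sigmoid(np.array([-1000.0]))[0] == 0.0
        assert sigmoid(np.array([1000.0]))[0] == 1.0

    def test_softmax_shift_invariant(self):
        z = np.array([1.0, 2.0])
        assert np.allclose(softmax(z), softmax(z + 100.0))
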