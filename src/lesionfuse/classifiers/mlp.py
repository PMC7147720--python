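"""Two-layer feed-forward pattern-recognition network.

Hidden units apply the logistic sigmoid to an affine combination of the
previous layer,

    a^l_j = sigma( sum_k w^l_jk a^{l-1}_k + b^l_j ),

and the two output units (melanoma, common nevus) pass through a softmax,
so the class scores always sum to 1.  Training minimizes the mean
cross-entropy with L-BFGS; the output layer is initialized to zero, which
makes training exactly symmetric under swapping the two class labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ..preprocess import DermoscopyImage, resize_gray, to_grayscale
from .base import ClassifierModel, LesionDecision, decision_from_score

#: Default raster fed to the network: flattened resized grayscale.
DEFAULT_INPUT_SIDE = 32

_L2 = 1e-4  # weight decay; symmetric under label swap


@dataclass
class MlpNetwork:
    """Layer sizes plus per-layer weight matrices and bias vectors.

    ``weights[l]`` has shape (units_l, units_{l-1}); the final layer has
    exactly two units.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        if len(sizes) < 2:
            raise ValueError("need at least input and output layers")
        if sizes[-1] != 2:
            raise ValueError("output layer must have exactly 2 units (Me, Cn)")
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise ValueError("one weight matrix and bias vector per non-input layer")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l + 1], sizes[l]):
                raise ValueError(
                    f"layer {l + 1}: weight shape {w.shape} != ({sizes[l + 1]}, {sizes[l]})"
                )
            if b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l + 1}: bias shape {b.shape} != ({sizes[l + 1]},)")
        self.layer_sizes = sizes


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mlp_forward(net: MlpNetwork, features: np.ndarray) -> np.ndarray:
    """Forward pass; returns the two softmax class scores (Me, Cn).

    Accepts a single feature vector or a batch (rows = examples).
    """
    a = np.atleast_2d(np.asarray(features, dtype=float))
    if a.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"feature length {a.shape[1]} != input layer size {net.layer_sizes[0]}"
        )
    single = np.asarray(features).ndim == 1
    n_layers = len(net.weights)
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        z = a @ w.T + b
        a = softmax(z) if l == n_layers - 1 else sigmoid(z)
    return a[0] if single else a


def _pack(ws, bs):
    return np.concatenate([w.ravel() for w in ws] + [b.ravel() for b in bs])


def _unpack(theta, sizes):
    ws, bs, k = [], [], 0
    for l in range(len(sizes) - 1):
        n = sizes[l + 1] * sizes[l]
        ws.append(theta[k : k + n].reshape(sizes[l + 1], sizes[l]))
        k += n
    for l in range(len(sizes) - 1):
        n = sizes[l + 1]
        bs.append(theta[k : k + n])
        k += n
    return ws, bs


def _loss_grad(theta, sizes, x, t):
    ws, bs = _unpack(theta, sizes)
    n = x.shape[0]
    acts = [x]
    a = x
    for l in range(len(ws)):
        z = a @ ws[l].T + bs[l]
        a = softmax(z) if l == len(ws) - 1 else sigmoid(z)
        acts.append(a)
    p = np.clip(acts[-1], 1e-12, 1.0)
    loss = -np.sum(t * np.log(p)) / n
    loss += _L2 * sum(np.sum(w**2) for w in ws)
    delta = (acts[-1] - t) / n  # softmax + cross-entropy
    gws = [None] * len(ws)
    gbs = [None] * len(ws)
    for l in range(len(ws) - 1, -1, -1):
        gws[l] = delta.T @ acts[l] + 2 * _L2 * ws[l]
        gbs[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ ws[l]) * acts[l] * (1.0 - acts[l])
    return loss, _pack(gws, gbs)


def train_mlp(
    features: np.ndarray,
    labels: np.ndarray,
    hidden_units: int = 72,
    seed: int = 0,
    max_epochs: int = 300,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    input_shape: tuple[int, int] | None = None,
) -> ClassifierModel:
    """Train the network on a feature matrix (rows = examples, labels 1=Me).

    Deterministic given the seed.  ``input_shape`` records the grayscale
    raster size images must be resized to before flattening at predict
    time (set automatically by the image-level helper).  When a validation
    split is supplied its accuracy is recorded on the model.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.size:
        raise ValueError("features must be (n, p) with one label per row")
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("need at least 2 examples of each class")
    sizes = (x.shape[1], int(hidden_units), 2)
    rng = np.random.default_rng(seed)
    ws = [
        rng.normal(0.0, np.sqrt(2.0 / (sizes[0] + sizes[1])), size=(sizes[1], sizes[0])),
        np.zeros((2, sizes[1])),  # zero output layer: label-swap symmetric
    ]
    bs = [np.zeros(sizes[1]), np.zeros(2)]
    t = np.column_stack([y, 1 - y]).astype(float)  # columns: (Me, Cn)
    res = minimize(
        _loss_grad,
        _pack(ws, bs),
        args=(sizes, x, t),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": int(max_epochs)},
    )
    ws, bs = _unpack(res.x, sizes)
    net = MlpNetwork(layer_sizes=sizes, weights=list(ws), biases=list(bs))
    params = {"network": net, "input_shape": input_shape}
    model = ClassifierModel(kind="mlp", parameters=params)
    if validation is not None:
        xv, yv = validation
        scores = mlp_forward(net, np.asarray(xv, dtype=float))[:, 0]
        dv = (scores >= 0.5).astype(int)
        model.validation_accuracy = float(np.mean(dv == np.asarray(yv, dtype=int)))
    return model


def image_features(img: DermoscopyImage, side: int = DEFAULT_INPUT_SIDE) -> np.ndarray:
    """Flattened resized grayscale raster scaled to [0, 1]."""
    g = resize_gray(to_grayscale(img), side, side)
    return g.pixels.astype(float).ravel() / 255.0


def train_mlp_on_images(
    images,
    labels,
    hidden_units: int = 72,
    seed: int = 0,
    max_epochs: int = 300,
    validation_images=None,
    validation_labels=None,
    side: int = DEFAULT_INPUT_SIDE,
) -> ClassifierModel:
    """Image-level wrapper: flattened resized grayscale features."""
    x = np.stack([image_features(im, side) for im in images])
    val = None
    if validation_images is not None:
        xv = np.stack([image_features(im, side) for im in validation_images])
        val = (xv, np.asarray(validation_labels, dtype=int))
    model = train_mlp(x, labels, hidden_units, seed, max_epochs, validation=val)
    model.parameters["input_shape"] = (side, side)
    return model


def predict_mlp(model: ClassifierModel, img: DermoscopyImage) -> LesionDecision:
    net: MlpNetwork = model.parameters["network"]
    shape = model.parameters.get("input_shape") or (DEFAULT_INPUT_SIDE, DEFAULT_INPUT_SIDE)
    feats = image_features(img, shape[0])
    scores = mlp_forward(net, feats)
    return decision_from_score(float(scores[0]))
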