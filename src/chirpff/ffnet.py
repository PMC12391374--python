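"""Forward-forward classifier with an RMS goodness function.

Instead of backpropagating a global error, each fully connected layer is
trained greedily with two forward passes: positive samples (true-label
encoding) should produce an activity vector whose *goodness* lies well above
a threshold theta, negative samples (wrong-label encoding) well below it.
The goodness used here is the root-mean-square of the ReLU activities,

    g = sqrt((1/n) * sum_j O_j**2),

with Hinton's sum-of-squares, the mean square and the mean absolute value
available as alternatives.  The per-layer loss is a squared sum of softplus
terms,

    L = (L+ + L-)**2,
    L+ = mean_i softplus(-(g_pos_i - theta)),
    L- = mean_i softplus(+(g_neg_i - theta)),

minimised by plain full-batch gradient descent.  After a layer is trained,
only the *orientation* of its activity vector (length-normalised output) is
passed to the next layer, so each layer must learn new features rather than
reading off the previous layer's goodness.

At inference time the sample is encoded with each candidate label in turn;
the accumulated goodness of all but the first hidden layer decides the
label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import (
    EncodedSample,
    FeatureMatrix,
    FeatureScaler,
    encode_label,
    make_training_pairs,
)

log = logging.getLogger(__name__)

GOODNESS_KINDS = ("rms", "sum_sq", "mean_sq", "mean_abs")
#: Hidden layer widths of the reference architecture.
DEFAULT_LAYER_SIZES = (500, 1000, 1000)


def sigmoid(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x):
    """log(1 + exp(x)), stable for |x| up to at least 1e4."""
    return np.logaddexp(0.0, np.asarray(x, dtype=np.float64))


@dataclass
class GoodnessResult:
    """Pre-squash goodness `g` and squashed probability ``p = sigma(g - theta)``."""

    g: np.ndarray
    p: np.ndarray
    n: int


@dataclass
class LossBreakdown:
    l_pos: float
    l_neg: float

    @property
    def total(self) -> float:
        return (self.l_pos + self.l_neg) ** 2


@dataclass
class TrainConfig:
    """Hyperparameters of greedy forward-forward training."""

    learning_rate: float = 0.1
    epochs: int = 500
    seed: int = 1234
    theta: float = 3.5
    goodness_kind: str = "rms"
    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    batch_size: int | None = 4  # None = full batch
    init_scale: float | None = None  # None = 1/sqrt(n_in)
    calibrate_init: bool = True  # rescale init so mean goodness starts at theta
    precision: str = "float32"  # training dtype; "float64" for gradient checks

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.goodness_kind not in GOODNESS_KINDS:
            raise ValueError(f"goodness_kind must be one of {GOODNESS_KINDS}")


def goodness(activities, kind: str = "rms", theta: float = 3.5) -> GoodnessResult:
    """Scalar goodness of one activity vector or of each row of a batch."""
    a = np.asarray(activities, dtype=np.float64)
    squeeze = a.ndim == 1
    a = np.atleast_2d(a)
    if a.shape[1] == 0:
        raise ValueError("activity vector must be non-empty")
    if not np.all(np.isfinite(a)):
        raise ValueError("activities must be finite")
    if kind == "rms":
        g = np.sqrt(np.mean(a**2, axis=1))
    elif kind == "sum_sq":
        g = np.sum(a**2, axis=1)
    elif kind == "mean_sq":
        g = np.mean(a**2, axis=1)
    elif kind == "mean_abs":
        g = np.mean(np.abs(a), axis=1)
    else:
        raise ValueError(f"unknown goodness kind: {kind}")
    p = sigmoid(g - theta)
    if squeeze:
        g, p = g[0], p[0]
    return GoodnessResult(g=g, p=p, n=a.shape[1])


def layer_loss(g_pos, g_neg, theta: float = 3.5) -> LossBreakdown:
    """Squared two-sided softplus loss of a positive and a negative batch.

    Per-sample terms are averaged (not summed) within each batch so the
    loss scale does not depend on the batch size; the square is applied to
    the sum of the two means.
    """
    g_pos = np.atleast_1d(np.asarray(g_pos, dtype=np.float64))
    g_neg = np.atleast_1d(np.asarray(g_neg, dtype=np.float64))
    if g_pos.size == 0 or g_neg.size == 0:
        raise ValueError("both batches must be non-empty")
    l_pos = float(np.mean(softplus(-(g_pos - theta))))
    l_neg = float(np.mean(softplus(+(g_neg - theta))))
    return LossBreakdown(l_pos=l_pos, l_neg=l_neg)


def layer_normalize(activities) -> np.ndarray:
    """Keep only the orientation: divide by the L2 norm (eps-guarded)."""
    a = np.asarray(activities, dtype=np.float64)
    norm = np.linalg.norm(a, axis=-1, keepdims=True)
    return a / np.maximum(norm, 1e-8)


class FFLayer:
    """One fully connected ReLU layer trained by its local goodness loss."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        goodness_kind: str = "rms",
        theta: float = 3.5,
        init_scale: float | None = None,
    ) -> None:
        scale = init_scale if init_scale is not None else 1.0 / np.sqrt(n_in)
        self.weights = rng.uniform(-scale, scale, size=(n_out, n_in))
        self.bias = np.zeros(n_out)
        self.goodness_kind = goodness_kind
        self.theta = theta

    @property
    def n_in(self) -> int:
        return self.weights.shape[1]

    @property
    def n_out(self) -> int:
        return self.weights.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """ReLU(x W^T + b) for a batch (rows are samples)."""
        return np.maximum(np.atleast_2d(x) @ self.weights.T + self.bias, 0.0)

    def goodness(self, x: np.ndarray) -> GoodnessResult:
        return goodness(self.forward(x), self.goodness_kind, self.theta)


def _goodness_grad(o: np.ndarray, g: np.ndarray, kind: str) -> np.ndarray:
    """d g / d O for each row; `o` is the (batch, n) activity matrix."""
    n = o.shape[1]
    if kind == "rms":
        denom = np.maximum(g, 1e-12)[:, None] * n
        return o / denom
    if kind == "sum_sq":
        return 2.0 * o
    if kind == "mean_sq":
        return 2.0 * o / n
    if kind == "mean_abs":
        return np.sign(o) / n
    raise ValueError(kind)


def _loss_and_grads(layer: FFLayer, x_pos, x_neg, theta):
    """Analytic loss and parameter gradients of one layer on one batch.

    Positive and negative rows are stacked so the forward pass, the
    gradient contraction and the weight update each run as a single BLAS
    call — the update touches the full weight matrix every step, so this
    fusion dominates the training cost.
    """
    n_pos, n_neg = x_pos.shape[0], x_neg.shape[0]
    x = np.vstack([x_pos, x_neg])
    s = x @ layer.weights.T + layer.bias
    o = np.maximum(s, 0.0)
    g = goodness(o, layer.goodness_kind, theta).g
    loss = layer_loss(g[:n_pos], g[n_pos:], theta)
    # d(mean softplus(sign*(g - theta)))/dg_i = sign * sigma(sign*(g-theta))/n
    sign = np.empty(n_pos + n_neg, dtype=x.dtype)
    sign[:n_pos] = -1.0 / n_pos
    sign[n_pos:] = +1.0 / n_neg
    coef = sign * sigmoid(np.sign(sign) * (g - theta))
    outer = 2.0 * (loss.l_pos + loss.l_neg)  # chain rule through the square
    d_s = (outer * coef)[:, None] * _goodness_grad(o, g, layer.goodness_kind)
    d_s *= s > 0.0
    d_s = d_s.astype(x.dtype, copy=False)
    return loss, d_s.T @ x, d_s.sum(axis=0)


def calibrate_layer(layer: FFLayer, inputs: np.ndarray, theta: float) -> None:
    """Rescale the (freshly initialised) weights so the mean goodness of
    `inputs` equals `theta`.

    ReLU layers with zero bias are positively homogeneous, so a single
    scalar on the weights moves the goodness exactly; training then starts
    at the decision boundary, where the loss gradients are largest, instead
    of spending its schedule growing weight magnitude.
    """
    g = float(np.mean(layer.goodness(inputs).g))
    if g <= 0:
        return
    if layer.goodness_kind in ("sum_sq", "mean_sq"):
        c = np.sqrt(theta / g)  # goodness quadratic in the weight scale
    else:
        c = theta / g
    layer.weights *= c


def train_layer(
    layer: FFLayer,
    pos_inputs: np.ndarray,
    neg_inputs: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Gradient-descent training of one layer on its local loss.

    Returns the per-epoch loss history.  With ``batch_size=None`` every
    epoch is one full-batch step; otherwise seeded mini-batches are drawn
    without replacement each epoch and the history records the epoch's mean
    batch loss.

    When the input dimension exceeds the number of training samples the
    descent trajectory is confined to the span of the inputs, so the update
    is computed in that span's orthonormal basis and mapped back — an exact
    algebraic shortcut, not an approximation (see docs/methods.md).
    """
    dtype = layer.weights.dtype
    x_pos = np.atleast_2d(np.asarray(pos_inputs, dtype=dtype))
    x_neg = np.atleast_2d(np.asarray(neg_inputs, dtype=dtype))
    theta = config.theta
    n_total = x_pos.shape[0] + x_neg.shape[0]
    project = layer.n_in > n_total + 8
    if project:
        x_all = np.vstack([x_pos, x_neg])
        q, _ = np.linalg.qr(x_all.T)  # (n_in, n_total) orthonormal basis
        w_full = layer.weights
        layer.weights = w_full @ q
        x_pos, x_neg = x_pos @ q, x_neg @ q
        w0_red = layer.weights.copy()

    def step(xp, xn):
        loss, d_w, d_b = _loss_and_grads(layer, xp, xn, theta)
        if not np.isfinite(loss.total):
            raise FloatingPointError(
                "non-finite layer loss: learning rate too large?"
            )
        d_w *= config.learning_rate
        d_b *= config.learning_rate
        np.subtract(layer.weights, d_w, out=layer.weights)
        np.subtract(layer.bias, d_b, out=layer.bias)
        return loss.total

    history: list[float] = []
    try:
        if config.batch_size is None:
            for _ in range(config.epochs):
                history.append(step(x_pos, x_neg))
        else:
            if rng is None:
                rng = np.random.default_rng(config.seed)
            bs = config.batch_size
            for _ in range(config.epochs):
                perm_p = rng.permutation(x_pos.shape[0])
                perm_n = rng.permutation(x_neg.shape[0])
                epoch_losses = []
                for i in range(0, len(perm_p), bs):
                    idx_p = perm_p[i : i + bs]
                    # cycle through the negative permutation in step
                    idx_n = perm_n[np.arange(i, i + len(idx_p)) % len(perm_n)]
                    epoch_losses.append(step(x_pos[idx_p], x_neg[idx_n]))
                history.append(float(np.mean(epoch_losses)))
    finally:
        if project:
            layer.weights = w_full + (layer.weights - w0_red) @ q.T
    return history


class FFNetwork:
    """Ordered stack of forward-forward layers plus the feature scaler."""

    def __init__(
        self,
        input_dim: int,
        config: TrainConfig | None = None,
        scaler: FeatureScaler | None = None,
    ) -> None:
        self.config = config or TrainConfig()
        self.input_dim = input_dim
        self.scaler = scaler
        rng = np.random.default_rng(self.config.seed)
        self.layers: list[FFLayer] = []
        n_in = input_dim
        for n_out in self.config.layer_sizes:
            self.layers.append(
                FFLayer(
                    n_in, n_out, rng,
                    goodness_kind=self.config.goodness_kind,
                    theta=self.config.theta,
                    init_scale=self.config.init_scale,
                )
            )
            n_in = n_out
        self.trained = False
        self.loss_histories: list[list[float]] = []

    def hidden_activities(self, x: np.ndarray) -> list[np.ndarray]:
        """Raw (un-normalised) activities of every layer for a batch.

        Layer h > 1 receives the length-normalised output of layer h-1;
        the encoded input of layer 1 is used as-is.
        """
        acts = []
        h = np.atleast_2d(x)
        for layer in self.layers:
            o = layer.forward(h)
            acts.append(o)
            h = layer_normalize(o)
        return acts

    def predict(self, features: FeatureMatrix):
        """Classify by accumulated goodness over all but the first layer.

        The sample is encoded with each candidate label's *positive* code;
        the label with the larger accumulated goodness wins (ties go to
        label 0).  Returns ``(label, {label: accumulated_g}, margin)`` with
        ``margin = accum(1) - accum(0)`` usable as an AUC ranking score.
        The stored label of `features` is never consulted.
        """
        if not self.trained:
            raise RuntimeError("network has not been trained")
        accum: dict[int, float] = {}
        for candidate in (0, 1):
            sample = encode_label(features, candidate, "positive", self.scaler)
            acts = self.hidden_activities(sample.vector[None, :])
            total = 0.0
            for layer, o in zip(self.layers[1:], acts[1:]):
                total += float(goodness(o, layer.goodness_kind, layer.theta).g[0])
            accum[candidate] = total
        label = 1 if accum[1] > accum[0] else 0
        return label, accum, accum[1] - accum[0]

    def predict_batch(self, features_list: list[FeatureMatrix]):
        """Vectorised :meth:`predict` over a list of segments."""
        if not self.trained:
            raise RuntimeError("network has not been trained")
        margins = np.empty(len(features_list))
        labels = np.empty(len(features_list), dtype=int)
        for c in (0, 1):
            x = np.stack(
                [encode_label(f, c, "positive", self.scaler).vector for f in features_list]
            )
            acts = self.hidden_activities(x)
            total = np.zeros(len(features_list))
            for layer, o in zip(self.layers[1:], acts[1:]):
                total += goodness(o, layer.goodness_kind, layer.theta).g
            if c == 0:
                accum0 = total
            else:
                margins = total - accum0
        labels = (margins > 0).astype(int)
        return labels, margins


def train_network(
    data,
    config: TrainConfig | None = None,
    scaler: FeatureScaler | None = None,
) -> FFNetwork:
    """Greedy layer-wise training of the full stack.

    `data` is either a labelled segment / FeatureMatrix list (training pairs
    are built here) or a ``(positives, negatives)`` tuple of
    :class:`~chirpff.features.EncodedSample` lists.  Layer 1 is trained to
    convergence of its schedule, its normalised outputs become the training
    set of layer 2, and so on.  Runs with the same data and seed are
    bit-identical.
    """
    config = config or TrainConfig()
    if isinstance(data, tuple):
        positives, negatives = data
    else:
        positives, negatives, scaler = make_training_pairs(data, scaler)
    x_pos = np.stack([s.vector for s in positives])
    x_neg = np.stack([s.vector for s in negatives])
    net = FFNetwork(x_pos.shape[1], config, scaler)
    rng = np.random.default_rng(config.seed + 1)
    if config.precision == "float32":
        x_pos = x_pos.astype(np.float32)
        x_neg = x_neg.astype(np.float32)
        for layer in net.layers:
            layer.weights = layer.weights.astype(np.float32)
            layer.bias = layer.bias.astype(np.float32)
    for idx, layer in enumerate(net.layers):
        if config.calibrate_init:
            calibrate_layer(layer, np.vstack([x_pos, x_neg]), config.theta)
        try:
            history = train_layer(layer, x_pos, x_neg, config, rng=rng)
        except FloatingPointError as err:
            raise FloatingPointError(f"layer {idx + 1}: {err}") from err
        net.loss_histories.append(history)
        log.info("layer %d trained, final loss %.4g", idx + 1, history[-1])
        x_pos = layer_normalize(layer.forward(x_pos))
        x_neg = layer_normalize(layer.forward(x_neg))
    net.trained = True
    return net


CHECKPOINT_SCHEMA = 1


def save_checkpoint(net: FFNetwork, path) -> None:
    """Persist weights, goodness settings and scaler as NPZ + JSON metadata."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(net.layers):
        arrays[f"w{i}"] = layer.weights
        arrays[f"b{i}"] = layer.bias
    if net.scaler is not None:
        arrays["scale_min"] = net.scaler._scaler.data_min_
        arrays["scale_max"] = net.scaler._scaler.data_max_
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "input_dim": net.input_dim,
        "trained": net.trained,
        "block_gain": None if net.scaler is None else net.scaler.block_gain,
        "config": {
            "learning_rate": net.config.learning_rate,
            "epochs": net.config.epochs,
            "seed": net.config.seed,
            "theta": net.config.theta,
            "goodness_kind": net.config.goodness_kind,
            "layer_sizes": list(net.config.layer_sizes),
            "batch_size": net.config.batch_size,
            "calibrate_init": net.config.calibrate_init,
        },
    }
    np.savez(path, **arrays)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> FFNetwork:
    meta = json.loads(Path(str(path) + ".json").read_text())
    cfg = meta["config"]
    config = TrainConfig(
        learning_rate=cfg["learning_rate"], epochs=cfg["epochs"], seed=cfg["seed"],
        theta=cfg["theta"], goodness_kind=cfg["goodness_kind"],
        layer_sizes=tuple(cfg["layer_sizes"]),
        batch_size=cfg.get("batch_size"),
        calibrate_init=cfg.get("calibrate_init", True),
    )
    with np.load(path) as arrays:
        scaler = None
        if "scale_min" in arrays:
            scaler = FeatureScaler()
            mn, mx = arrays["scale_min"], arrays["scale_max"]
            scaler._scaler.fit(np.vstack([mn, mx]))
            if meta.get("block_gain") is not None:
                scaler.block_gain = float(meta["block_gain"])
        net = FFNetwork(meta["input_dim"], config, scaler)
        for i, layer in enumerate(net.layers):
            layer.weights = arrays[f"w{i}"]
            layer.bias = arrays[f"b{i}"]
    net.trained = bool(meta["trained"])
    return net
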