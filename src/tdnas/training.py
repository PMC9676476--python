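"""Model construction, training, and unpromising-trial detection.

The network is a fixed convolutional backbone (depth templates A, B, D,
E of the classic 16/19-layer plain-conv family, plus a desk-scale
``tiny`` variant) followed by the searched fully connected head: ln - 1
hidden dense layers with per-layer width and dropout, then an output
layer of ``num_classes`` units with softmax and no dropout.

Only the head is trained. The backbone acts as a frozen, seeded
random-projection feature extractor (3x3 He-initialized filters, ReLU,
2x2 max pooling per block): its structure — the number and position of
convolution and pooling layers — is exactly the template's, its weights
are fixed across all trials, so every configuration is compared on an
identical feature representation and a trial's cost is dominated by the
head being searched. Head training is plain minibatch SGD with momentum
on the cross-entropy loss, fully seeded.

A trial that is going badly is aborted early: after each epoch its
validation error is compared against the mean per-epoch error curve of
previously completed trials, and once it has exceeded that reference by
``margin`` at each of the last ``patience`` comparable epochs the trial
is declared unpromising and stopped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .metrics import EvalResult, evaluate
from .space import HyperparamConfig

__all__ = [
    "BackboneSpec", "ModelDescription", "EpochTrace", "ReferenceCurve",
    "build_model", "extract_features", "train_validate",
    "unpromising_check", "update_reference_curve", "HeadNetClassifier",
    "COMPLETED", "UNPROMISING_ABORTED",
]

COMPLETED = "completed"
UNPROMISING_ABORTED = "unpromising_aborted"

#: Conv stacks as (layers, channels) per block. A/B/D/E are the 8/10/13/16
#: conv-layer templates; with a 3-layer head, D is the 16-weighted-layer net.
_VARIANTS = {
    "A": ((1, 64), (1, 128), (2, 256), (2, 512), (2, 512)),
    "B": ((2, 64), (2, 128), (2, 256), (2, 512), (2, 512)),
    "D": ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512)),
    "E": ((2, 64), (2, 128), (4, 256), (4, 512), (4, 512)),
    "tiny": ((1, 16), (1, 32)),
}
_DEFAULT_INPUT = {"A": 224, "B": 224, "D": 224, "E": 224, "tiny": 32}


@dataclass(frozen=True)
class BackboneSpec:
    """A fixed convolutional feature-extractor template."""

    variant: str
    conv_block_widths: tuple[tuple[int, int], ...]
    input_size: int

    @classmethod
    def from_variant(cls, variant: str, input_size: int | None = None) -> "BackboneSpec":
        if variant not in _VARIANTS:
            raise ValueError(f"unknown backbone variant {variant!r}; "
                             f"choose from {sorted(_VARIANTS)}")
        return cls(variant=variant, conv_block_widths=_VARIANTS[variant],
                   input_size=input_size or _DEFAULT_INPUT[variant])

    @property
    def num_conv_layers(self) -> int:
        return sum(n for n, _ in self.conv_block_widths)

    @property
    def num_blocks(self) -> int:
        return len(self.conv_block_widths)

    def output_spatial(self) -> int:
        s = self.input_size
        for _ in self.conv_block_widths:
            if s % 2:
                raise ValueError(
                    f"input size {self.input_size} is not divisible by "
                    f"2^{self.num_blocks} pooling stages")
            s //= 2
        if s < 1:
            raise ValueError("input too small for the pooling depth")
        return s

    def feature_dim(self, in_channels: int = 1) -> int:
        return self.output_spatial() ** 2 * self.conv_block_widths[-1][1]


@dataclass(frozen=True)
class ModelDescription:
    """Backbone + head for one configuration; what a trial trains."""

    config: HyperparamConfig
    backbone: BackboneSpec
    num_classes: int
    head_widths: tuple[int, ...]     # hidden widths then num_classes
    head_dropouts: tuple[float, ...]  # per hidden layer, then 0.0 for output

    @property
    def num_weighted_layers(self) -> int:
        """Conv layers plus all dense layers."""
        return self.backbone.num_conv_layers + self.config.ln


def build_model(config: HyperparamConfig, backbone: BackboneSpec,
                num_classes: int) -> ModelDescription:
    """Assemble the network description for one configuration.

    The conv stack is the backbone template unchanged; the head is the
    configuration's ln - 1 hidden layers followed by the implicit
    ``num_classes`` output layer with no dropout.
    """
    backbone.output_spatial()  # raises if input_size incompatible
    return ModelDescription(
        config=config, backbone=backbone, num_classes=num_classes,
        head_widths=config.nn + (num_classes,),
        head_dropouts=config.dr + (0.0,),
    )


# -- frozen convolutional feature extraction -----------------------------

def _conv3x3(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution, NHWC layout, via a strided patch view."""
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, h, wd, 3, 3, x.shape[3]), (s[0], s[1], s[2], s[1], s[2], s[3]))
    return np.tensordot(view, w, axes=([3, 4, 5], [0, 1, 2]))


def _maxpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


def extract_features(images: np.ndarray, backbone: BackboneSpec,
                     seed: int = 0, chunk: int = 256) -> np.ndarray:
    """Forward images through the frozen backbone; returns (n, d) features.

    Filters are He-initialized from ``seed`` and identical for every
    call with the same backbone and seed, so all trials in a search see
    the same representation.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[..., None]
    if images.shape[1] != backbone.input_size or images.shape[2] != backbone.input_size:
        raise ValueError(
            f"images are {images.shape[1]}x{images.shape[2]}, backbone "
            f"expects {backbone.input_size}x{backbone.input_size}")
    rng = np.random.default_rng(seed)
    filters = []
    cin = images.shape[3]
    for layers, cout in backbone.conv_block_widths:
        for _ in range(layers):
            w = rng.normal(0.0, np.sqrt(2.0 / (9 * cin)),
                           size=(3, 3, cin, cout)).astype(np.float32)
            filters.append(w)
            cin = cout
    out = []
    for start in range(0, images.shape[0], chunk):
        x = images[start:start + chunk]
        fi = 0
        for layers, _ in backbone.conv_block_widths:
            for _ in range(layers):
                x = np.maximum(_conv3x3(x, filters[fi]), 0.0)
                fi += 1
            x = _maxpool2(x)
        out.append(x.reshape(x.shape[0], -1))
    return np.vstack(out)


# -- epoch traces and the reference curve --------------------------------

@dataclass
class EpochTrace:
    """Per-epoch validation error of one trial."""

    val_error: list[float] = field(default_factory=list)
    aborted_at: Optional[int] = None

    @property
    def epochs_run(self) -> int:
        return len(self.val_error)

    def to_dict(self) -> dict:
        return {"val_error": list(self.val_error), "aborted_at": self.aborted_at}

    @classmethod
    def from_dict(cls, d: dict) -> "EpochTrace":
        return cls(val_error=list(d["val_error"]), aborted_at=d.get("aborted_at"))


@dataclass
class ReferenceCurve:
    """Per-epoch mean validation error over completed prior trials."""

    mean_val_error: np.ndarray = field(default_factory=lambda: np.empty(0))
    support: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.mean_val_error)

    @property
    def empty(self) -> bool:
        return len(self.mean_val_error) == 0


def update_reference_curve(traces: Sequence[EpochTrace]) -> ReferenceCurve:
    """Per-epoch arithmetic mean over completed (non-aborted) traces."""
    done = [t for t in traces if t.aborted_at is None and t.epochs_run]
    if not done:
        return ReferenceCurve()
    n_ep = max(t.epochs_run for t in done)
    total = np.zeros(n_ep)
    support = np.zeros(n_ep, dtype=np.int64)
    for t in done:
        e = np.asarray(t.val_error)
        total[: e.size] += e
        support[: e.size] += 1
    return ReferenceCurve(mean_val_error=total / np.maximum(support, 1),
                          support=support)


def unpromising_check(trace: EpochTrace, reference: ReferenceCurve,
                      margin: float = 0.02, patience: int = 3) -> bool:
    """True iff the trial has run above the reference for long enough.

    The trial's error must exceed ``reference + margin`` at each of the
    last ``patience`` epochs where the reference is defined; with an
    empty reference (no completed prior trials) the answer is always
    False.
    """
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if reference.empty:
        return False
    comparable = [i for i in range(min(trace.epochs_run, len(reference)))
                  if reference.support[i] >= 1]
    if len(comparable) < patience:
        return False
    recent = comparable[-patience:]
    return all(trace.val_error[i] > reference.mean_val_error[i] + margin
               for i in recent)


# -- the trained head ----------------------------------------------------

class HeadNetClassifier(BaseEstimator, ClassifierMixin):
    """Fully connected softmax classifier trained with SGD + momentum.

    This is the searched part of the network: hidden layers of the
    given widths with ReLU and (inverted) dropout, then a softmax
    output layer. Inputs are standardized with statistics from the
    training set.

    Parameters
    ----------
    hidden_widths, hidden_dropouts : tuple
        Per hidden layer; may be empty for a head that is only the
        output layer.
    num_classes : int
    epochs : int
        Default 50.
    lr : float
        Initial learning rate, default 0.01 (constant schedule).
    momentum, batch_size : SGD settings.
    seed : int
        Controls initialization, shuffling and dropout masks.
    """

    def __init__(self, hidden_widths=(), hidden_dropouts=(), num_classes=2,
                 epochs=50, lr=0.01, momentum=0.9, batch_size=32, seed=0,
                 max_grad_norm=5.0):
        self.hidden_widths = tuple(hidden_widths)
        self.hidden_dropouts = tuple(hidden_dropouts)
        self.num_classes = num_classes
        self.epochs = epochs
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.seed = seed
        self.max_grad_norm = max_grad_norm

    # initialization -----------------------------------------------------

    def _init_params(self, d_in: int, rng: np.random.Generator):
        widths = [d_in, *self.hidden_widths, self.num_classes]
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]),
                       size=(widths[i], widths[i + 1])).astype(np.float32)
            for i in range(len(widths) - 1)
        ]
        self.biases_ = [np.zeros(widths[i + 1], dtype=np.float32)
                        for i in range(len(widths) - 1)]
        self._vel_w = [np.zeros_like(w) for w in self.weights_]
        self._vel_b = [np.zeros_like(b) for b in self.biases_]

    # forward / backward -------------------------------------------------

    def _forward(self, X, rng=None):
        """Returns activations list and dropout masks (None at eval)."""
        acts, masks = [X], []
        h = X
        for li, (W, b) in enumerate(zip(self.weights_[:-1], self.biases_[:-1])):
            h = np.maximum(h @ W + b, 0.0)
            p = self.hidden_dropouts[li] if li < len(self.hidden_dropouts) else 0.0
            if rng is not None and p > 0.0:
                mask = (rng.random(h.shape, dtype=np.float32) >= p).astype(
                    np.float32) / np.float32(1.0 - p)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        logits = h @ self.weights_[-1] + self.biases_[-1]
        return acts, masks, logits

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _step(self, X, y, rng):
        acts, masks, logits = self._forward(X, rng)
        probs = self._softmax(logits)
        n = X.shape[0]
        delta = probs.astype(np.float32)
        delta[np.arange(n), y] -= 1.0
        delta /= np.float32(n)
        grads_w, grads_b = [None] * len(self.weights_), [None] * len(self.biases_)
        for li in range(len(self.weights_) - 1, -1, -1):
            grads_w[li] = acts[li].T @ delta
            grads_b[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.weights_[li].T
                if masks[li - 1] is not None:
                    delta = delta * masks[li - 1]
                delta = delta * (acts[li] > 0)
        if self.max_grad_norm is not None:
            # global-norm clipping keeps wide heads stable at lr 0.01
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads_w)
                            + sum(float(np.sum(g * g)) for g in grads_b))
            if gnorm > self.max_grad_norm:
                scale = np.float32(self.max_grad_norm / gnorm)
                grads_w = [g * scale for g in grads_w]
                grads_b = [g * scale for g in grads_b]
        for li in range(len(self.weights_)):
            self._vel_w[li] = self.momentum * self._vel_w[li] - self.lr * grads_w[li]
            self._vel_b[li] = self.momentum * self._vel_b[li] - self.lr * grads_b[li]
            self.weights_[li] += self._vel_w[li]
            self.biases_[li] += self._vel_b[li]

    # public API ----------------------------------------------------------

    def fit(self, X, y, epoch_callback=None):
        """Train; ``epoch_callback(epoch_index)`` may return True to stop early."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X.shape[0] == 0:
            raise ValueError("empty training data")
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0) + 1e-8
        Xs = (X - self._mu) / self._sd
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)
        n = X.shape[0]
        self.n_epochs_run_ = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                self._step(Xs[idx], y[idx], rng)
            self.n_epochs_run_ += 1
            if epoch_callback is not None and epoch_callback(epoch):
                break
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float32)
        Xs = (X - self._mu) / self._sd
        _, _, logits = self._forward(Xs, rng=None)
        return self._softmax(logits)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


# -- trial execution ----------------------------------------------------

def _as_features(data, backbone: BackboneSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    X, y = data
    X = np.asarray(X)
    if X.ndim >= 3:  # raw images: run the frozen backbone
        X = extract_features(X, backbone, seed=seed)
    return np.asarray(X, dtype=np.float32), np.asarray(y, dtype=np.int64)


def train_validate(model: ModelDescription, train_data, val_data,
                   epochs: int = 50, lr: float = 0.01,
                   monitor: Optional[ReferenceCurve] = None,
                   margin: float = 0.02, patience: int = 3,
                   seed: int = 0, batch_size: int = 32,
                   ) -> tuple[EvalResult, EpochTrace, str]:
    """Train one configuration's head and score it on the validation set.

    ``train_data``/``val_data`` are (X, y) pairs where X is either raw
    images (forwarded through the frozen backbone) or precomputed
    feature matrices. After each epoch the validation error is appended
    to the trace and, when ``monitor`` is given, checked against it;
    a positive check aborts the trial with status
    ``"unpromising_aborted"``. The returned metrics use the
    configuration's omega1 and beta, evaluated at the last epoch reached.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    Xtr, ytr = _as_features(train_data, model.backbone, seed=0)
    Xva, yva = _as_features(val_data, model.backbone, seed=0)
    if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")

    clf = HeadNetClassifier(
        hidden_widths=model.config.nn, hidden_dropouts=model.config.dr,
        num_classes=model.num_classes, epochs=epochs, lr=lr,
        batch_size=batch_size, seed=seed)
    trace = EpochTrace()
    status = COMPLETED

    def after_epoch(epoch: int) -> bool:
        nonlocal status
        err = 1.0 - float(np.mean(clf.predict(Xva) == yva))
        trace.val_error.append(err)
        if monitor is not None and unpromising_check(trace, monitor,
                                                     margin, patience):
            status = UNPROMISING_ABORTED
            trace.aborted_at = epoch + 1
            return True
        return False

    clf.fit(Xtr, ytr, epoch_callback=after_epoch)
    pred = clf.predict(Xva)
    result = evaluate(yva, pred, model.num_classes,
                      omega1=model.config.omega1, beta=model.config.beta)
    return result, trace, status
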