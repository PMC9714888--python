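"""Two-stage temporal convolutional classifier for single-period biosignals.

The network stacks residual blocks of dilated causal 1-D convolutions.
Each block applies two weight-normalised convolutions at the same dilation
(each followed by ReLU and spatial dropout) and adds the input back through
an identity shortcut, with a 1x1 projection when channel widths differ:
``o = sigma(F(x) + x)``.  Dilations double up the ladder [1, 2, 4, ...,
64]; the ladder is run twice — a front stage of 32 filters and a back
stage of 64 — so the nominal receptive field grows from 509 samples to
1017, enough to cover an entire 800-sample input period.  A global average
pool over time and a dense softmax head yield probabilities over the three
fatigue states.

Receptive-field accounting: for constant kernel size k the span of one
conv per dilation level is ``RF = 1 + (k-1) * sum(d_i)``; the model's
``receptive_field`` reports this schedule-level figure.  Because every
block contains two convolutions at its dilation, the exact causal span of
a block is obtained from the per-conv-layer list ``[d, d]`` with the same
formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._nn import (
    Adam,
    Conv1x1,
    Dense,
    GlobalAvgPool,
    Param,
    SpatialDropout,
    WeightNormConv1d,
    relu,
    softmax,
    softmax_xent,
)
from .preprocess import PeriodSeries
from .states import STATES
from .synthgen import derive_seed

__all__ = [
    "NetConfig",
    "ConvParams",
    "StateProbabilities",
    "receptive_field",
    "causal_conv",
    "ResidualBlock",
    "TCNClassifier",
    "build_model",
    "train",
    "predict_proba",
]


@dataclass
class NetConfig:
    """Architecture and training hyper-parameters of the classifier."""

    input_len: int = 800
    kernel_size: int = 5
    stride: int = 1
    filters_per_stage: list[int] = field(default_factory=lambda: [32, 64])
    dilations: list[int] = field(default_factory=lambda: [1, 2, 4, 8, 16, 32, 64])
    n_classes: int = 3
    dropout_rate: float = 0.05
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 2e-3
    val_fraction: float = 0.1
    patience: int = 3
    stop_train_acc: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.input_len < 1:
            raise ValueError("kernel_size and input_len must be >= 1")
        if any(d < 1 for d in self.dilations):
            raise ValueError("all dilations must be >= 1")
        if self.n_classes != 3:
            raise ValueError("the fatigue frame has exactly 3 classes")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")


@dataclass
class ConvParams:
    """Explicit kernel for the functional causal-convolution primitive.

    ``W`` is indexed (tap, in-channel, out-channel) with tap k-1 at the
    current time step; ``activation`` defaults to identity.
    """

    W: np.ndarray
    b: np.ndarray | None = None
    activation: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim == 1:
            self.W = self.W[:, None, None]
        if self.b is None:
            self.b = np.zeros(self.W.shape[2])
        self.b = np.asarray(self.b, dtype=float)


@dataclass
class StateProbabilities:
    """Softmax output over the fatigue frame, in canonical state order."""

    p: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.p.values())
        if any(v < -1e-9 for v in self.p.values()) or abs(total - 1.0) > 1e-6:
            raise ValueError("probabilities must be >= 0 and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p[s] for s in STATES])

    @property
    def argmax_state(self) -> int:
        return max(STATES, key=lambda s: self.p[s])


def receptive_field(k_per_layer, d_per_layer) -> int:
    """Receptive field at the input for stacked dilated convs, stride 1.

    ``RF = 1 + sum_i d_i * (k_i - 1)``; with constant kernel size k this is
    ``1 + (k-1) * sum(d_i)``.  ``k_per_layer`` may be a scalar, which is
    broadcast over the dilation list.  Empty lists give the degenerate
    RF = 1 (no convolution).
    """
    d = list(d_per_layer)
    k = [int(k_per_layer)] * len(d) if np.isscalar(k_per_layer) else list(k_per_layer)
    if len(k) != len(d):
        raise ValueError("k_per_layer and d_per_layer must have equal length")
    if any(ki < 1 for ki in k) or any(di < 1 for di in d):
        raise ValueError("kernel sizes and dilations must be >= 1")
    return 1 + int(sum(di * (ki - 1) for ki, di in zip(k, d)))


def causal_conv(x: np.ndarray, params: ConvParams, dilation: int = 1) -> np.ndarray:
    """Dilated causal convolution of a sequence, output length preserved.

    The output at time t is ``sigma(sum_tap W[tap] . x[t - (k-1-tap)*d] + b)``
    with missing (pre-signal) samples taken as zero, so no future value
    ever enters the sum.  ``x`` may be (L,) or (L, Cin).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    L, cin = x.shape
    k, w_cin, cout = params.W.shape
    if w_cin != cin:
        raise ValueError(f"kernel expects {w_cin} input channels, got {cin}")
    pad = (k - 1) * dilation
    xp = np.vstack([np.zeros((pad, cin)), x])
    y = np.zeros((L, cout))
    for tap in range(k):
        y += xp[tap * dilation : tap * dilation + L, :] @ params.W[tap]
    y += params.b
    if params.activation is not None:
        y = params.activation(y)
    return y[:, 0] if squeeze and cout == 1 else y


class ResidualBlock:
    """o = sigma(F(x) + x) with F = [dilated causal conv, ReLU, dropout] x 2.

    Both convolutions share the block's dilation and kernel size.  When the
    input channel width differs from the block width, a 1x1 convolution
    projects the shortcut.  ``activation`` is the outer sigma: "relu"
    (default) or "identity".
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        dilation: int,
        dropout: float,
        rng,
        activation: str = "relu",
    ):
        if activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")
        self.activation = activation
        self.dilation = int(dilation)
        self.k = int(k)
        self.conv1 = WeightNormConv1d(in_ch, out_ch, k, dilation, rng)
        self.conv2 = WeightNormConv1d(out_ch, out_ch, k, dilation, rng, init_gain=0.1)
        self.drop1 = SpatialDropout(dropout)
        self.drop2 = SpatialDropout(dropout)
        self.proj = Conv1x1(in_ch, out_ch, rng) if in_ch != out_ch else None
        self._cache = None

    def params(self) -> list[Param]:
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    @property
    def conv_layer_dilations(self) -> list[int]:
        """Per-conv-layer dilation list (two convs per block)."""
        return [self.dilation, self.dilation]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        h1 = self.conv1.forward(x, train)
        a1 = relu(h1)
        d1 = self.drop1.forward(a1, train, rng)
        h2 = self.conv2.forward(d1, train)
        a2 = relu(h2)
        d2 = self.drop2.forward(a2, train, rng)
        s = x if self.proj is None else self.proj.forward(x, train)
        pre = d2 + s
        out = relu(pre) if self.activation == "relu" else pre
        if train:
            self._cache = (h1, h2, pre)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h1, h2, pre = self._cache
        dpre = dout * (pre > 0) if self.activation == "relu" else dout
        ds = dpre
        dd2 = dpre
        da2 = self.drop2.backward(dd2)
        dh2 = da2 * (h2 > 0)
        dd1 = self.conv2.backward(dh2)
        da1 = self.drop1.backward(dd1)
        dh1 = da1 * (h1 > 0)
        dx = self.conv1.backward(dh1)
        dx_short = ds if self.proj is None else self.proj.backward(ds)
        return dx + dx_short


class TCNClassifier:
    """Stacked residual stages + global average pool + dense softmax head."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(derive_seed(config.seed, 0))
        self.blocks: list[ResidualBlock] = []
        in_ch = 1
        for width in config.filters_per_stage:
            for d in config.dilations:
                self.blocks.append(
                    ResidualBlock(
                        in_ch, width, config.kernel_size, d, config.dropout_rate, rng
                    )
                )
                in_ch = width
        self.pool = GlobalAvgPool()
        self.head = Dense(in_ch, config.n_classes, rng)
        self.classes = list(STATES)
        self.history: dict | None = None
        # global input standardisation (scalars, set from the training set;
        # per-sample scaling would erase the amplitude information that
        # separates the fatigue states)
        self.norm_mu: float = 0.0
        self.norm_sd: float = 1.0

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.blocks:
            ps += b.params()
        return ps + self.head.params()

    @property
    def receptive_field(self) -> int:
        """Schedule-level RF: one conv per dilation level (Eq-3 accounting)."""
        sched = list(self.config.dilations) * len(self.config.filters_per_stage)
        return receptive_field(self.config.kernel_size, sched)

    def forward(self, X: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Logits for X of shape (B, L) or (B, L, 1)."""
        h = np.asarray(X, dtype=np.float32)
        if h.ndim == 2:
            h = h[:, :, None]
        if h.shape[1] != self.config.input_len:
            raise ValueError(
                f"input length {h.shape[1]} != configured {self.config.input_len}"
            )
        h = (h - self.norm_mu) / self.norm_sd
        for block in self.blocks:
            h = block.forward(h, train=train, rng=rng)
        pooled = self.pool.forward(h, train)
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dp = self.head.backward(dlogits.astype(np.float32))
        dh = self.pool.backward(dp)
        for block in reversed(self.blocks):
            dh = block.backward(dh)

    def predict_proba_batch(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.forward(X, train=False))

    def predict_states(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba_batch(X)
        return np.array([self.classes[i] for i in proba.argmax(axis=1)])

    # -- persistence: npz weights + JSON metadata -------------------------

    def save(self, basepath: str | Path) -> None:
        basepath = Path(basepath)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(basepath.with_suffix(".npz"), **arrays)
        meta = {
            "config": asdict(self.config),
            "class_order": self.classes,
            "norm": [self.norm_mu, self.norm_sd],
        }
        basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, basepath: str | Path) -> "TCNClassifier":
        basepath = Path(basepath)
        meta = json.loads(basepath.with_suffix(".json").read_text())
        model = cls(NetConfig(**meta["config"]))
        with np.load(basepath.with_suffix(".npz")) as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        model.classes = [int(c) for c in meta["class_order"]]
        model.norm_mu, model.norm_sd = meta.get("norm", [0.0, 1.0])
        return model


def build_model(config: NetConfig | None = None) -> TCNClassifier:
    """Construct the classifier; weights are seeded from ``config.seed``."""
    return TCNClassifier(config or NetConfig())


def _series_to_arrays(series: Sequence[PeriodSeries] | np.ndarray, labels=None):
    if isinstance(series, np.ndarray):
        X = np.asarray(series, dtype=np.float32)
        y = np.asarray(labels)
    else:
        X = np.stack([np.asarray(s.values, dtype=np.float32) for s in series])
        y = np.array([s.state for s in series]) if labels is None else np.asarray(labels)
    return X, y


def train(
    model: TCNClassifier,
    series: Sequence[PeriodSeries] | np.ndarray,
    labels=None,
    config: NetConfig | None = None,
) -> tuple[TCNClassifier, dict]:
    """Train with Adam on minibatches; deterministic given ``config.seed``.

    A validation split (``val_fraction``) drives early stopping with the
    configured patience; training also halts once the epoch's running
    training accuracy reaches ``stop_train_acc``.  Returns the model and a
    history dict with per-epoch loss/accuracy curves.
    """
    config = config or model.config
    X, y = _series_to_arrays(series, labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    y_idx = np.array([model.classes.index(int(c)) for c in y])

    model.norm_mu = float(X.mean())
    model.norm_sd = float(max(X.std(), 1e-8))

    rng = np.random.default_rng(derive_seed(config.seed, 2))
    n = len(X)
    n_val = int(round(config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y_idx[tr_idx]
    Xval, yval = X[val_idx], y_idx[val_idx]

    opt = Adam(model.params(), lr=config.learning_rate)
    history = {"loss": [], "train_acc": [], "val_loss": []}
    best_val = np.inf
    stale = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        losses, correct = [], 0
        for start in range(0, len(Xtr), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(Xtr[idx], train=True, rng=rng)
            loss, proba, dlogits = softmax_xent(logits, ytr[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((proba.argmax(axis=1) == ytr[idx]).sum())
        acc = correct / len(Xtr)
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(acc)
        if len(Xval):
            vloss, _, _ = softmax_xent(model.forward(Xval), yval)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-4:
                best_val, stale = vloss, 0
            else:
                stale += 1
        if acc >= config.stop_train_acc or stale > config.patience:
            break
    model.history = history
    return model, history


def predict_proba(model: TCNClassifier, series: PeriodSeries | np.ndarray) -> StateProbabilities:
    """Class probabilities for one length-normalised period."""
    x = series.values if isinstance(series, PeriodSeries) else np.asarray(series)
    if len(x) != model.config.input_len:
        raise ValueError(
            f"input length {len(x)} != configured {model.config.input_len}"
        )
    proba = model.predict_proba_batch(x[None, :])[0]
    return StateProbabilities(p={s: float(proba[i]) for i, s in enumerate(model.classes)})
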