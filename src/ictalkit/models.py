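"""The two classifiers and their training loop.

Binary seizure detector: three 3x3 convolutional layers of 16/32/64 feature
maps over the (frequency x time) plane with electrodes as input channels,
each followed by ReLU, 2x2 max pooling and batch normalization (normalizing
the pooled output), then dense layers of 256 and ``n_out`` units. With the
33 x 8 spectro-temporal input the spatial sizes run 33x8 -> 16x4 -> 8x2 ->
4x1, so the flattened width is 64*4*1 = 256.

Multigroup (8-type) classifier: the 8 STFT timesteps form a sequence of
one-channel (electrodes x frequencies) frames fed through two ConvLSTM
modules (16 then 32 filters, same-padded 3x3, each followed by batch
normalization, 2x2 pooling and dropout; the first returns the full sequence,
the second its final hidden state), then dense 256 -> 8 with softmax.

Training minimizes class-weighted cross-entropy with Adam and records
accuracy, ROC-AUC, recall and precision per epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = [
    "BinaryCNNConfig",
    "MultigroupConfig",
    "TrainingConfig",
    "TrainedModel",
    "build_binary_cnn",
    "build_multigroup_model",
    "train_model",
    "predict_proba",
    "pipeline_predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class BinaryCNNConfig:
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 3
    padding: int = 1
    dense_units: int = 256
    n_out: int = 2


@dataclass(frozen=True)
class MultigroupConfig:
    n_modules: int = 2
    convlstm_filters: tuple[int, int] = (16, 32)
    kernel: int = 3
    dropout: float = 0.3
    dense_units: int = 256
    n_out: int = 8


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    class_weights: dict[str, float] | None = None
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


class _BinaryCNN:
    kind = "binary_cnn"

    def __init__(self, input_shape, cfg: BinaryCNNConfig, seed: int):
        c, h, w = input_shape
        hh, ww = h, w
        for _ in range(3):
            hh, ww = hh // 2, ww // 2
            if hh == 0 or ww == 0:
                raise ValueError(
                    f"input {h}x{w} collapses to zero under three 2x2 poolings"
                )
        rng = np.random.default_rng(seed)
        ch = cfg.conv_channels
        self.conv = [
            nn.Conv2d(c, ch[0], cfg.kernel, cfg.padding, rng),
            nn.Conv2d(ch[0], ch[1], cfg.kernel, cfg.padding, rng),
            nn.Conv2d(ch[1], ch[2], cfg.kernel, cfg.padding, rng),
        ]
        self.bn = [nn.BatchNorm2d(f) for f in ch]
        self.flat_width = ch[2] * hh * ww
        self.dense1 = nn.Dense(self.flat_width, cfg.dense_units, rng)
        self.dense2 = nn.Dense(cfg.dense_units, cfg.n_out, rng)
        self.cfg = cfg

    def forward(self, x: Tensor, train: bool, rng=None) -> Tensor:
        h = x
        for conv, bn in zip(self.conv, self.bn):
            h = ad.relu(conv(h))
            h = ad.maxpool2x2(h)
            h = bn(h, train)
        h = ad.reshape(h, (h.shape[0], self.flat_width))
        h = ad.relu(self.dense1(h))
        return self.dense2(h)

    def layers(self):
        return self.conv + self.bn + [self.dense1, self.dense2]


class _MultigroupConvLSTM:
    kind = "multigroup_convlstm"

    def __init__(self, input_shape, cfg: MultigroupConfig, seed: int):
        c, n_freq, self.n_steps = input_shape
        rng = np.random.default_rng(seed)
        f1, f2 = cfg.convlstm_filters
        self.clstm1 = nn.ConvLSTM2d(1, f1, cfg.kernel, rng)
        self.clstm2 = nn.ConvLSTM2d(f1, f2, cfg.kernel, rng)
        self.bn1 = nn.BatchNorm2d(f1)
        self.bn2 = nn.BatchNorm2d(f2)
        h1, w1 = c // 2, n_freq // 2
        h2, w2 = h1 // 2, w1 // 2
        if h2 == 0 or w2 == 0:
            raise ValueError(f"frame {c}x{n_freq} collapses under two poolings")
        self.flat_width = f2 * h2 * w2
        self.dense1 = nn.Dense(self.flat_width, cfg.dense_units, rng)
        self.dense2 = nn.Dense(cfg.dense_units, cfg.n_out, rng)
        self.cfg = cfg

    def forward(self, x: Tensor, train: bool, rng=None) -> Tensor:
        rng = rng or np.random.default_rng(0)
        n, c, n_freq, n_steps = x.shape
        # timesteps as the sequence axis; each frame a 1-channel c x n_freq map
        frames = [
            ad.reshape(
                ad.slice_(x, (slice(None), slice(None), slice(None), t)),
                (n, 1, c, n_freq),
            )
            for t in range(n_steps)
        ]
        seq = self.clstm1.forward_sequence(frames, return_sequence=True)
        seq = [
            ad.dropout(ad.maxpool2x2(self.bn1(h, train)), self.cfg.dropout, rng, train)
            for h in seq
        ]
        last = self.clstm2.forward_sequence(seq, return_sequence=False)[0]
        h = ad.dropout(
            ad.maxpool2x2(self.bn2(last, train)), self.cfg.dropout, rng, train
        )
        h = ad.reshape(h, (h.shape[0], self.flat_width))
        h = ad.relu(self.dense1(h))
        return self.dense2(h)

    def layers(self):
        return [self.clstm1, self.clstm2, self.bn1, self.bn2, self.dense1, self.dense2]


# ---------------------------------------------------------------------------
# TrainedModel facade
# ---------------------------------------------------------------------------


class TrainedModel:
    """Classifier facade with probability-output and input-gradient contracts."""

    def __init__(self, net, input_shape, class_labels, config):
        self.net = net
        self.input_shape = tuple(input_shape)
        self.class_labels = tuple(class_labels)
        self.config = config
        self.history: list[dict] = []

    # -- prediction --------------------------------------------------------

    def _check(self, tensors: np.ndarray) -> np.ndarray:
        x = np.asarray(tensors, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model "
                f"input {self.input_shape}"
            )
        return x

    def predict_logits(self, tensors, batch_size: int = 64) -> np.ndarray:
        x = self._check(tensors)
        out = []
        with ad.no_grad():
            for i in range(0, x.shape[0], batch_size):
                out.append(
                    self.net.forward(Tensor(x[i : i + batch_size]), train=False).data
                )
        return np.concatenate(out, axis=0)

    def predict_proba(self, tensors) -> np.ndarray:
        return ad.softmax(self.predict_logits(tensors))

    def predict(self, tensors) -> list[str]:
        p = self.predict_proba(tensors)
        return [self.class_labels[i] for i in p.argmax(axis=1)]

    # -- gradients ---------------------------------------------------------

    def input_gradient(self, tensors, class_index: int) -> np.ndarray:
        """d(pre-softmax logit of ``class_index``)/d(input), eval mode."""
        if not 0 <= class_index < len(self.class_labels):
            raise IndexError(f"class_index {class_index} out of range")
        x = Tensor(self._check(tensors), requires_grad=True)
        logits = self.net.forward(x, train=False)
        target = ad.sum_all(ad.slice_(logits, (slice(None), class_index)))
        target.backward()
        return x.grad

    def params(self):
        return [p for layer in self.net.layers() for p in layer.params()]


def build_binary_cnn(
    input_shape, cfg: BinaryCNNConfig | None = None, seed: int = 0,
    class_labels=("bckg", "seiz"),
) -> TrainedModel:
    cfg = cfg or BinaryCNNConfig()
    if len(class_labels) != cfg.n_out:
        raise ValueError("class_labels length must equal n_out")
    return TrainedModel(_BinaryCNN(input_shape, cfg, seed), input_shape,
                        class_labels, cfg)


def build_multigroup_model(
    input_shape, cfg: MultigroupConfig | None = None, seed: int = 0,
    class_labels=("fnsz", "gnsz", "spsz", "cpsz", "absz", "tnsz", "tcsz", "mysz"),
) -> TrainedModel:
    cfg = cfg or MultigroupConfig()
    if len(class_labels) != cfg.n_out:
        raise ValueError("class_labels length must equal n_out")
    return TrainedModel(_MultigroupConvLSTM(input_shape, cfg, seed), input_shape,
                        class_labels, cfg)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _epoch_metrics(y_true, probs, n_classes) -> dict:
    from sklearn.metrics import (
        accuracy_score, precision_score, recall_score, roc_auc_score,
    )

    pred = probs.argmax(axis=1)
    avg = "binary" if n_classes == 2 else "macro"
    out = {
        "accuracy": accuracy_score(y_true, pred),
        "recall": recall_score(y_true, pred, average=avg, zero_division=0),
        "precision": precision_score(y_true, pred, average=avg, zero_division=0),
    }
    try:
        if n_classes == 2:
            out["auc"] = roc_auc_score(y_true, probs[:, 1])
        else:
            out["auc"] = roc_auc_score(
                y_true, probs, multi_class="ovr", average="macro",
                labels=list(range(n_classes)),
            )
    except ValueError:
        out["auc"] = float("nan")
    return out


def train_model(
    model: TrainedModel,
    train_set: tuple[np.ndarray, list],
    val_set: tuple[np.ndarray, list] | None,
    tcfg: TrainingConfig,
) -> tuple[TrainedModel, list[dict]]:
    """Fit in place with Adam on class-weighted cross-entropy.

    ``train_set``/``val_set`` are ``(tensors, labels)`` with string labels
    drawn from ``model.class_labels``. Returns the model and per-epoch
    history (losses plus accuracy/AUC/recall/precision).
    """
    x_train, y_train = train_set
    x_train = np.asarray(x_train, dtype=float)
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    label_to_idx = {lab: i for i, lab in enumerate(model.class_labels)}
    unknown = sorted(set(y_train) - set(label_to_idx))
    if unknown:
        raise ValueError(f"labels outside model classes: {unknown}")
    y_idx = np.array([label_to_idx[y] for y in y_train])
    cw = tcfg.class_weights or {}
    w = np.array([cw.get(y, 1.0) for y in y_train], dtype=float)

    rng = np.random.default_rng(tcfg.seed)
    opt = nn.Adam(model.params(), lr=tcfg.learning_rate)
    n = x_train.shape[0]
    n_classes = len(model.class_labels)
    history = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses, probs_acc, y_acc = [], [], []
        for i in range(0, n, tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            xb = Tensor(x_train[idx])
            logits = model.net.forward(xb, train=True, rng=rng)
            loss = ad.softmax_cross_entropy(logits, y_idx[idx], w[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            probs_acc.append(ad.softmax(logits.data))
            y_acc.append(y_idx[idx])
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        row.update(
            {f"train_{k}": v
             for k, v in _epoch_metrics(
                 np.concatenate(y_acc), np.concatenate(probs_acc), n_classes
             ).items()}
        )
        if val_set is not None and len(val_set[1]) > 0:
            xv, yv = val_set
            yv_idx = np.array([label_to_idx[y] for y in yv])
            pv = model.predict_proba(xv)
            wv = np.array([cw.get(y, 1.0) for y in yv])
            nll = -np.log(np.maximum(pv[np.arange(len(yv)), yv_idx], 1e-12))
            row["val_loss"] = float((wv * nll).sum() / max(wv.sum(), 1e-12))
            row.update(
                {f"val_{k}": v
                 for k, v in _epoch_metrics(yv_idx, pv, n_classes).items()}
            )
        history.append(row)
    model.history.extend(history)
    return model, history


def predict_proba(model: TrainedModel, tensors) -> np.ndarray:
    """Row-stochastic class probabilities for a batch of input tensors."""
    return model.predict_proba(tensors)


def pipeline_predict(
    binary_model: TrainedModel, multigroup_model: TrainedModel, tensors,
    seizure_label: str = "seiz",
) -> list[str]:
    """Two-stage routing: detect first, type only the detected seizures.

    Windows the binary detector calls background keep the background label;
    only windows predicted as seizure are passed to the multigroup model.
    """
    x = np.asarray(tensors, dtype=float)
    binary_pred = binary_model.predict(x)
    out = list(binary_pred)
    hit = [i for i, p in enumerate(binary_pred) if p == seizure_label]
    if hit:
        types = multigroup_model.predict(x[hit])
        for i, t in zip(hit, types):
            out[i] = t
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    """Single-file checkpoint: npz weights + embedded JSON descriptor."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    for li, layer in enumerate(model.net.layers()):
        for k, v in layer.state().items():
            arrays[f"state_{li}_{k}"] = v
    desc = {
        "kind": model.net.kind,
        "input_shape": list(model.input_shape),
        "class_labels": list(model.class_labels),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.config.__dict__.items()
        },
    }
    arrays["descriptor"] = np.frombuffer(
        json.dumps(desc).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as f:
        desc = json.loads(bytes(f["descriptor"].tobytes()).decode())
        arrays = {k: f[k] for k in f.files if k != "descriptor"}
    cfg_kw = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in desc["config"].items()
    }
    if desc["kind"] == "binary_cnn":
        model = build_binary_cnn(
            desc["input_shape"], BinaryCNNConfig(**cfg_kw),
            class_labels=desc["class_labels"],
        )
    elif desc["kind"] == "multigroup_convlstm":
        model = build_multigroup_model(
            desc["input_shape"], MultigroupConfig(**cfg_kw),
            class_labels=desc["class_labels"],
        )
    else:
        raise ValueError(f"unknown checkpoint kind {desc['kind']!r}")
    for i, p in enumerate(model.params()):
        p.data = arrays[f"param_{i}"].astype(float)
    for li, layer in enumerate(model.net.layers()):
        st = layer.state()
        for k in st:
            layer.running[k] = arrays[f"state_{li}_{k}"].astype(float)
    return model
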