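"""The four spectral predictors: SVM, CNN, LSTM, and the CNN-LSTM hybrid.

All four map a sample's mean reflectance spectrum to either a binary
fumigation class or a single content value.  The three networks share one
design language:

* **CNN** — batch-norm on the input, a 32-kernel length-2 stride-2
  convolution with ReLU, average pooling + dropout, a 128-kernel stride-2
  convolution with batch-norm/ReLU/dropout, then fully connected layers of
  widths 128 (tanh) and ``n_out``.
* **LSTM** — the spectrum as a band-ordered sequence into a 64-unit LSTM,
  then the same 128-wide tanh head.
* **CLSTM** — the CNN's convolutional stack feeds its output sequence
  stepwise into the 64-unit LSTM, which replaces the first fully connected
  layer; conv settings are identical to the CNN and the LSTM width
  identical to the plain LSTM so the comparison isolates the combination.

The SVM baseline uses an RBF kernel (epsilon-insensitive regression for
content targets) via scikit-learn.

Training is Adam on cross-entropy (classification) or mean squared error
(regression), with per-band input standardisation, z-scored regression
targets, and early stopping on a held-out validation split.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.svm import SVC, SVR

from .nn import (
    Adam,
    AvgPool2,
    BatchNorm,
    ConvPair,
    Dense,
    Dropout,
    Flatten,
    LSTMLayer,
    MSELoss,
    Reshape,
    ReLU,
    Sequential,
    SoftmaxCrossEntropy,
    Tanh,
)
from .synthetic import ANALYTES, Dataset, SampleRecord

MODEL_KINDS = ("svm", "cnn", "lstm", "clstm")
CLASSIFICATION = "classification"
REGRESSION = "regression"
TARGETS = ("label", *ANALYTES)


@dataclass(frozen=True)
class ArchitectureConfig:
    """Architecture hyperparameters shared across the model family."""

    kind: str
    task: str = CLASSIFICATION
    conv1_kernels: int = 32
    conv2_kernels: int = 128
    lstm_hidden: int = 64
    fc_width: int = 128
    dropout: float = 0.3
    lstm_chunk: int = 4  # bands per time step for the plain LSTM

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError("task must be classification or regression")

    @property
    def n_out(self) -> int:
        return 2 if self.task == CLASSIFICATION else 1


@dataclass(frozen=True)
class TrainingConfig:
    optimizer: str = "adam"
    lr: float = 1e-3
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0
    patience: int = 30
    min_epochs: int = 40  # cross-entropy often plateaus before features form
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainedModel:
    """A (possibly not-yet-fitted) model plus its preprocessing state."""

    arch: ArchitectureConfig
    n_bands: int
    seed: int
    net: Sequential | None = None
    svm: object = None
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    classes: tuple[str, ...] = ()
    history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# LSTM cell contract (explicit gate equations, used as the oracle surface)


@dataclass
class LSTMCellParams:
    """Explicit per-gate LSTM parameters; each W_* is (hidden, hidden+input)."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_g: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_g: np.ndarray
    b_o: np.ndarray


def lstm_cell_forward(
    params: LSTMCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step from the gate equations.

        f = sigma(W_f [h, x] + b_f),  i = sigma(W_i [h, x] + b_i),
        g = tanh (W_g [h, x] + b_g),  o = sigma(W_o [h, x] + b_o),
        c_t = f * c_prev + i * g,     h_t = o * tanh(c_t).
    """
    hx = np.concatenate([h_prev, x_t])
    H = h_prev.size
    for W in (params.W_f, params.W_i, params.W_g, params.W_o):
        if W.shape != (H, hx.size):
            raise ValueError(f"gate weight shape {W.shape} != ({H}, {hx.size})")
    sigma = lambda z: 1.0 / (1.0 + np.exp(-z))
    f = sigma(params.W_f @ hx + params.b_f)
    i = sigma(params.W_i @ hx + params.b_i)
    g = np.tanh(params.W_g @ hx + params.b_g)
    o = sigma(params.W_o @ hx + params.b_o)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def layer_cell_params(layer: LSTMLayer) -> LSTMCellParams:
    """Unpack an :class:`LSTMLayer`'s fused weights into per-gate matrices."""
    H = layer.hidden
    W, b = layer.W, layer.b  # packed gate order (i, f, g, o) on [h, x]
    return LSTMCellParams(
        W_i=W[:, :H].T, W_f=W[:, H:2 * H].T,
        W_g=W[:, 2 * H:3 * H].T, W_o=W[:, 3 * H:].T,
        b_i=b[:H], b_f=b[H:2 * H], b_g=b[2 * H:3 * H], b_o=b[3 * H:],
    )


# ---------------------------------------------------------------------------
# Architecture construction


def conv_stack_lengths(n_bands: int) -> tuple[int, int, int]:
    """Sequence lengths after conv1, pooling, and conv2.

    Each stride-2, length-2 convolution maps L -> floor(L/2); the pooling
    stage halves again but is skipped when fewer than 4 positions remain.
    """
    l1 = n_bands // 2
    l2 = l1 // 2 if l1 >= 4 else l1
    l3 = l2 // 2
    return l1, l2, l3


def _conv_stack(arch: ArchitectureConfig, n_bands: int,
                rng: np.random.Generator) -> tuple[list, int, int]:
    l1, l2, l3 = conv_stack_lengths(n_bands)
    if l3 < 1:
        raise ValueError(
            f"n_bands={n_bands} too small for two stride-2 convolutions (need >= 4)"
        )
    layers = [
        Reshape(n_bands, 1),
        BatchNorm(1),
        ConvPair(1, arch.conv1_kernels, rng),
        ReLU(),
    ]
    if l1 >= 4:
        layers.append(AvgPool2())
    layers += [
        Dropout(arch.dropout, rng),
        ConvPair(arch.conv1_kernels, arch.conv2_kernels, rng),
        BatchNorm(arch.conv2_kernels),
        ReLU(),
        Dropout(arch.dropout, rng),
    ]
    return layers, l3, arch.conv2_kernels


def build_model(arch: ArchitectureConfig, n_bands: int, seed: int = 0) -> TrainedModel:
    """Instantiate an untrained model with seeded parameter initialisation."""
    if arch.kind == "svm":
        return TrainedModel(arch=arch, n_bands=n_bands, seed=seed)
    rng = np.random.default_rng(seed)
    if arch.kind == "cnn":
        conv, l3, ch = _conv_stack(arch, n_bands, rng)
        head = [
            Flatten(),
            Dense(l3 * ch, arch.fc_width, rng),
            Tanh(),
            Dense(arch.fc_width, arch.n_out, rng),
        ]
        net = Sequential(conv + head)
    elif arch.kind == "clstm":
        conv, _, ch = _conv_stack(arch, n_bands, rng)
        head = [
            LSTMLayer(ch, arch.lstm_hidden, rng),
            Dense(arch.lstm_hidden, arch.fc_width, rng),
            Tanh(),
            Dense(arch.fc_width, arch.n_out, rng),
        ]
        net = Sequential(conv + head)
    elif arch.kind == "lstm":
        steps = n_bands // arch.lstm_chunk
        if steps < 1:
            raise ValueError(f"n_bands={n_bands} smaller than one LSTM chunk")
        net = Sequential([
            Reshape(steps, arch.lstm_chunk),
            LSTMLayer(arch.lstm_chunk, arch.lstm_hidden, rng),
            Dense(arch.lstm_hidden, arch.fc_width, rng),
            Tanh(),
            Dense(arch.fc_width, arch.n_out, rng),
        ])
    return TrainedModel(arch=arch, n_bands=n_bands, seed=seed, net=net)


# ---------------------------------------------------------------------------
# Data plumbing


def records_xy(
    data: Dataset | list[SampleRecord], target: str
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the design matrix and the requested target vector."""
    records = data.records if isinstance(data, Dataset) else list(data)
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    X = np.stack([r.spectrum for r in records])
    if target == "label":
        y = np.array([r.label for r in records])
    else:
        y = np.array([r.contents[target] for r in records], dtype=float)
    return X, y


def _snapshot(net: Sequential) -> list[np.ndarray]:
    return [p.copy() for p, _ in net.parameters()]


def _restore(net: Sequential, snap: list[np.ndarray]) -> None:
    for (p, _), saved in zip(net.parameters(), snap):
        p[...] = saved


# ---------------------------------------------------------------------------
# Training / prediction


def train(
    model: TrainedModel,
    data: Dataset | list[SampleRecord],
    target: str,
    cfg: TrainingConfig | None = None,
) -> TrainedModel:
    """Fit a model in place and return it.

    Inputs are standardised per band; regression targets are z-scored
    internally and de-standardised at predict time.  Networks train with
    Adam and early stopping (patience on a validation split when the set
    is large enough, else on training loss).  A NaN loss aborts with
    diagnostics rather than silently producing a broken model.
    """
    cfg = cfg or TrainingConfig()
    X, y = records_xy(data, target)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if X.shape[1] != model.n_bands:
        raise ValueError(f"records have {X.shape[1]} bands, model expects {model.n_bands}")
    task = model.arch.task
    expected_task = CLASSIFICATION if target == "label" else REGRESSION
    if task != expected_task:
        raise ValueError(f"target {target!r} needs a {expected_task} architecture")

    model.x_mean = X.mean(axis=0)
    sd = X.std(axis=0)
    model.x_sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - model.x_mean) / model.x_sd

    if task == CLASSIFICATION:
        classes = tuple(sorted(np.unique(y).tolist()))
        if len(classes) != 2:
            raise ValueError(f"binary classification needs 2 classes, got {len(classes)}")
        model.classes = classes
        y_t = np.array([classes.index(v) for v in y])
    else:
        y = y.astype(float)
        model.y_mean = float(y.mean())
        y_sd = float(y.std())
        model.y_sd = y_sd if y_sd > 0 else 1.0
        y_t = (y - model.y_mean) / model.y_sd

    if model.arch.kind == "svm":
        if task == CLASSIFICATION:
            est = SVC(kernel="rbf", C=10.0, gamma="scale", random_state=cfg.seed)
        else:
            est = SVR(kernel="rbf", C=10.0, gamma="scale", epsilon=0.1)
        est.fit(Xs, y_t)
        model.svm = est
        model.history = [0.0]
        return model

    rng = np.random.default_rng(cfg.seed)
    loss_fn = SoftmaxCrossEntropy() if task == CLASSIFICATION else MSELoss()

    n_val = int(round(cfg.val_fraction * n))
    use_val = cfg.patience > 0 and n_val >= 4
    if use_val:
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if task == CLASSIFICATION and np.unique(y_t[tr_idx]).size < 2:
            use_val = False
    if not use_val:
        tr_idx = np.arange(n)
        val_idx = np.array([], dtype=int)

    opt = Adam(model.net.parameters(), lr=cfg.lr)
    best_obj, best_snap, since_best = np.inf, None, 0
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            if batch.size < 2 and n_batches > 0:
                continue  # batch-norm needs >= 2 rows; fold stragglers away
            out = model.net.forward(Xs[batch], train=True)
            loss, grad = loss_fn.loss_and_grad(out, y_t[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={cfg.lr}); "
                    "lower the learning rate or check the inputs"
                )
            model.net.zero_grad()
            model.net.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(1, n_batches))

        if cfg.patience > 0:
            if use_val:
                out = model.net.forward(Xs[val_idx], train=False)
                obj, _ = loss_fn.loss_and_grad(out, y_t[val_idx])
            else:
                obj = history[-1]
            if obj < best_obj - 1e-6:
                best_obj, best_snap, since_best = obj, _snapshot(model.net), 0
            else:
                since_best += 1
                if since_best >= cfg.patience and epoch + 1 >= cfg.min_epochs:
                    break
    if best_snap is not None:
        _restore(model.net, best_snap)
    model.history = history
    return model


def predict(model: TrainedModel, data: Dataset | list[SampleRecord]):
    """Predict labels+probabilities (classification) or content values.

    Returns ``(labels, probabilities)`` for classification, with
    probability rows summing to 1, or a value array for regression.
    """
    records = data.records if isinstance(data, Dataset) else list(data)
    X = np.stack([r.spectrum for r in records])
    if X.shape[1] != model.n_bands:
        raise ValueError(f"records have {X.shape[1]} bands, model expects {model.n_bands}")
    if model.x_mean is None:
        raise RuntimeError("model has not been trained")
    Xs = (X - model.x_mean) / model.x_sd

    if model.arch.kind == "svm":
        raw = model.svm.predict(Xs)
        if model.arch.task == CLASSIFICATION:
            labels = np.array([model.classes[int(v)] for v in raw])
            probs = np.zeros((len(records), 2))
            probs[np.arange(len(records)), raw.astype(int)] = 1.0
            return labels, probs
        return raw * model.y_sd + model.y_mean

    out = model.net.forward(Xs, train=False)
    if model.arch.task == CLASSIFICATION:
        probs = SoftmaxCrossEntropy.probabilities(out)
        labels = np.array([model.classes[i] for i in probs.argmax(axis=1)])
        return labels, probs
    return out.ravel() * model.y_sd + model.y_mean


def svm_fit_predict(
    train_data: Dataset | list[SampleRecord],
    test_data: Dataset | list[SampleRecord],
    target: str,
    kernel: str = "rbf",
    C: float = 10.0,
    epsilon: float = 0.1,
    seed: int = 0,
):
    """One-shot SVM baseline: fit on train, predict test.

    Classification uses margins (SVC), regression the epsilon-insensitive
    loss (SVR).  Inputs are standardised by the training statistics.
    """
    X_tr, y_tr = records_xy(train_data, target)
    X_te, _ = records_xy(test_data, target)
    mean, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs_tr, Xs_te = (X_tr - mean) / sd, (X_te - mean) / sd

    if target == "label":
        if np.unique(y_tr).size < 2:
            raise ValueError("single-class training data")
        est = SVC(kernel=kernel, C=C, gamma="scale", random_state=seed)
        est.fit(Xs_tr, y_tr)
        return est.predict(Xs_te)
    est = SVR(kernel=kernel, C=C, gamma="scale", epsilon=epsilon)
    est.fit(Xs_tr, y_tr.astype(float))
    return est.predict(Xs_te)


# ---------------------------------------------------------------------------
# Checkpointing


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise a trained model to a single ``.npz`` archive."""
    if model.arch.kind == "svm":
        raise NotImplementedError("SVM baselines are refit from data, not checkpointed")
    arrays: dict[str, np.ndarray] = {}
    for i, (p, _) in enumerate(model.net.parameters()):
        arrays[f"param_{i}"] = p
    for i, layer in enumerate(model.net.layers):
        if isinstance(layer, BatchNorm):
            arrays[f"bn_{i}_mean"] = layer.run_mean
            arrays[f"bn_{i}_var"] = layer.run_var
    arrays["x_mean"] = model.x_mean
    arrays["x_sd"] = model.x_sd
    meta = {
        "arch": asdict(model.arch),
        "n_bands": model.n_bands,
        "seed": model.seed,
        "classes": list(model.classes),
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
        "history": model.history,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta_json"].tobytes()).decode())
        model = build_model(
            ArchitectureConfig(**meta["arch"]), meta["n_bands"], meta["seed"]
        )
        for i, (p, _) in enumerate(model.net.parameters()):
            p[...] = archive[f"param_{i}"]
        for i, layer in enumerate(model.net.layers):
            if isinstance(layer, BatchNorm):
                layer.run_mean = archive[f"bn_{i}_mean"]
                layer.run_var = archive[f"bn_{i}_var"]
        model.x_mean = archive["x_mean"]
        model.x_sd = archive["x_sd"]
    model.classes = tuple(meta["classes"])
    model.y_mean = meta["y_mean"]
    model.y_sd = meta["y_sd"]
    model.history = meta["history"]
    return model
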