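"""Three-layer sigmoid backpropagation network trained on squared error.

One hidden layer of logistic units and a logistic output layer (one unit per
class, one-hot targets). Gradients descend the ½·Σ(o − t)² surrogate, whose
minimizer coincides with the RMSE that is logged per epoch and used for
model selection; training is per-sample (or full-batch) gradient descent with
momentum, a stratified internal validation split, early stopping, and a
best-validation-RMSE snapshot. The hidden-layer width is chosen by training
one model per candidate size and keeping the size with the lowest validation
RMSE.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .vectorize import FeatureMatrix

__all__ = [
    "BPNNConfig",
    "BPNNModel",
    "Gradients",
    "sigmoid",
    "forward",
    "rmse",
    "backward",
    "train",
    "select_hidden_size",
    "predict",
    "one_hot",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class BPNNConfig:
    """Training protocol parameters.

    ``hidden_sizes_grid`` lists the candidate hidden-node counts tried by
    :func:`select_hidden_size`. ``batch_mode`` is ``per_sample`` (stochastic,
    shuffled each epoch) or ``full_batch``. Early stopping monitors the
    validation RMSE with the given patience.
    """

    hidden_sizes_grid: tuple[int, ...] = (4, 8, 16, 32, 64)
    learning_rate: float = 0.1
    momentum: float = 0.9
    max_epochs: int = 500
    batch_mode: str = "per_sample"
    early_stop_patience: int = 25
    validation_fraction: float = 0.15
    weight_init_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not self.hidden_sizes_grid:
            raise ValueError("hidden_sizes_grid must be non-empty")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_mode not in ("per_sample", "full_batch"):
            raise ValueError("batch_mode must be 'per_sample' or 'full_batch'")
        if self.weight_init_scale <= 0:
            raise ValueError("weight_init_scale must be positive")


@dataclass
class BPNNModel:
    """Weights of the three-layer network."""

    W_in_hidden: np.ndarray  # (n_inputs, n_hidden)
    b_hidden: np.ndarray  # (n_hidden,)
    W_hidden_out: np.ndarray  # (n_hidden, n_outputs)
    b_out: np.ndarray  # (n_outputs,)
    class_names: tuple[str, ...]
    feature_names: tuple[str, ...] = ()

    @property
    def n_hidden(self) -> int:
        return self.W_in_hidden.shape[1]

    @property
    def n_inputs(self) -> int:
        return self.W_in_hidden.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W_hidden_out.shape[1]


@dataclass
class Gradients:
    dW_in_hidden: np.ndarray
    db_hidden: np.ndarray
    dW_hidden_out: np.ndarray
    db_out: np.ndarray


def sigmoid(x):
    """Logistic function, overflow-safe for |x| up to at least 500."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def forward(model: BPNNModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden and output activations for one input row.

    The "net excitation" of each unit is the weighted pre-activation sum;
    both layers apply the sigmoid.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.n_inputs,):
        raise ValueError(f"input length {x.shape} does not match {model.n_inputs} inputs")
    h = sigmoid(x @ model.W_in_hidden + model.b_hidden)
    o = sigmoid(h @ model.W_hidden_out + model.b_out)
    return h, o


def _forward_batch(model: BPNNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = sigmoid(X @ model.W_in_hidden + model.b_hidden)
    O = sigmoid(H @ model.W_hidden_out + model.b_out)
    return H, O


def rmse(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Root mean square error over all entries."""
    outputs = np.asarray(outputs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must have the same shape")
    if outputs.size == 0:
        raise ValueError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((outputs - targets) ** 2)))


def backward(model: BPNNModel, x: np.ndarray, target: np.ndarray) -> Gradients:
    """Gradients of ½·Σ(o − t)² for one sample.

    Output deltas (o − t)·o·(1 − o) are propagated back through the hidden
    layer; weight gradients are outer products with the layer inputs.
    """
    x = np.asarray(x, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    h, o = forward(model, x)
    if target.shape != o.shape:
        raise ValueError("target shape does not match output layer")
    delta_o = (o - target) * o * (1.0 - o)
    delta_h = (model.W_hidden_out @ delta_o) * h * (1.0 - h)
    return Gradients(
        dW_in_hidden=np.outer(x, delta_h),
        db_hidden=delta_h,
        dW_hidden_out=np.outer(h, delta_o),
        db_out=delta_o,
    )


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    T = np.zeros((labels.shape[0], n_classes), dtype=np.float64)
    T[np.arange(labels.shape[0]), labels] = 1.0
    return T


def _init_model(
    n_inputs: int,
    n_hidden: int,
    n_outputs: int,
    class_names: tuple[str, ...],
    feature_names: tuple[str, ...],
    config: BPNNConfig,
    rng: np.random.Generator,
) -> BPNNModel:
    s1 = config.weight_init_scale / np.sqrt(max(n_inputs, 1))
    s2 = config.weight_init_scale / np.sqrt(max(n_hidden, 1))
    return BPNNModel(
        W_in_hidden=rng.uniform(-s1, s1, size=(n_inputs, n_hidden)),
        b_hidden=rng.uniform(-s1, s1, size=n_hidden),
        W_hidden_out=rng.uniform(-s2, s2, size=(n_hidden, n_outputs)),
        b_out=rng.uniform(-s2, s2, size=n_outputs),
        class_names=class_names,
        feature_names=feature_names,
    )


def _carve_validation(
    matrix: FeatureMatrix, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation row indices; classes with a single row
    stay in training."""
    train_rows: list[np.ndarray] = []
    val_rows: list[np.ndarray] = []
    for k in range(matrix.n_classes):
        idx = np.flatnonzero(matrix.labels == k)
        if idx.size == 0:
            continue
        if idx.size == 1:
            train_rows.append(idx)
            continue
        n_val = min(max(1, int(np.floor(idx.size * fraction + 0.5))), idx.size - 1)
        perm = rng.permutation(idx)
        val_rows.append(np.sort(perm[:n_val]))
        train_rows.append(np.sort(perm[n_val:]))
    train = np.sort(np.concatenate(train_rows))
    val = np.sort(np.concatenate(val_rows)) if val_rows else np.empty(0, np.int64)
    return train, val


def train(
    matrix: FeatureMatrix,
    n_hidden: int,
    config: BPNNConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[BPNNModel, dict[str, list[float]]]:
    """Train one network; returns the best-validation-RMSE snapshot.

    Targets are one-hot class rows. If ``validation`` (features, one-hot
    targets) is not supplied, a stratified ``validation_fraction`` of the
    training rows is carved out internally. The history holds per-epoch
    training and validation RMSE; training stops at ``max_epochs`` or when the
    validation RMSE has not improved for ``early_stop_patience`` epochs.
    """
    if config is None:
        config = BPNNConfig()
    if matrix.n_classes < 2:
        raise ValueError("training requires at least 2 classes")
    rng = np.random.default_rng(config.seed)
    K = matrix.n_classes
    if validation is None:
        tr_rows, val_rows = _carve_validation(matrix, config.validation_fraction, rng)
        X_tr = matrix.values[tr_rows]
        T_tr = one_hot(matrix.labels[tr_rows], K)
        X_val = matrix.values[val_rows]
        T_val = one_hot(matrix.labels[val_rows], K)
    else:
        X_tr = matrix.values
        T_tr = one_hot(matrix.labels, K)
        X_val, T_val = validation
    if X_val.shape[0] == 0:  # degenerate: monitor training RMSE instead
        X_val, T_val = X_tr, T_tr

    model = _init_model(
        matrix.n_features, n_hidden, K, matrix.class_names, matrix.feature_names, config, rng
    )
    vel = Gradients(
        dW_in_hidden=np.zeros_like(model.W_in_hidden),
        db_hidden=np.zeros_like(model.b_hidden),
        dW_hidden_out=np.zeros_like(model.W_hidden_out),
        db_out=np.zeros_like(model.b_out),
    )
    lr, mom = config.learning_rate, config.momentum
    history: dict[str, list[float]] = {"train": [], "validation": []}
    best_val = np.inf
    best_model = copy.deepcopy(model)
    stale = 0
    n = X_tr.shape[0]
    for _epoch in range(config.max_epochs):
        if config.batch_mode == "per_sample":
            order = rng.permutation(n)
            for i in order:
                g = backward(model, X_tr[i], T_tr[i])
                vel.dW_in_hidden = mom * vel.dW_in_hidden - lr * g.dW_in_hidden
                vel.db_hidden = mom * vel.db_hidden - lr * g.db_hidden
                vel.dW_hidden_out = mom * vel.dW_hidden_out - lr * g.dW_hidden_out
                vel.db_out = mom * vel.db_out - lr * g.db_out
                model.W_in_hidden += vel.dW_in_hidden
                model.b_hidden += vel.db_hidden
                model.W_hidden_out += vel.dW_hidden_out
                model.b_out += vel.db_out
        else:
            H, O = _forward_batch(model, X_tr)
            delta_o = (O - T_tr) * O * (1.0 - O)
            delta_h = (delta_o @ model.W_hidden_out.T) * H * (1.0 - H)
            gW2 = H.T @ delta_o / n
            gb2 = delta_o.mean(axis=0)
            gW1 = X_tr.T @ delta_h / n
            gb1 = delta_h.mean(axis=0)
            vel.dW_in_hidden = mom * vel.dW_in_hidden - lr * gW1
            vel.db_hidden = mom * vel.db_hidden - lr * gb1
            vel.dW_hidden_out = mom * vel.dW_hidden_out - lr * gW2
            vel.db_out = mom * vel.db_out - lr * gb2
            model.W_in_hidden += vel.dW_in_hidden
            model.b_hidden += vel.db_hidden
            model.W_hidden_out += vel.dW_hidden_out
            model.b_out += vel.db_out
        _, O_tr = _forward_batch(model, X_tr)
        _, O_val = _forward_batch(model, X_val)
        train_rmse = rmse(O_tr, T_tr)
        val_rmse = rmse(O_val, T_val)
        history["train"].append(train_rmse)
        history["validation"].append(val_rmse)
        if val_rmse < best_val:
            best_val = val_rmse
            best_model = copy.deepcopy(model)
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
    return best_model, history


def select_hidden_size(
    matrix: FeatureMatrix,
    config: BPNNConfig | None = None,
) -> tuple[int, dict[int, float]]:
    """Pick the hidden-layer width with the lowest validation RMSE.

    One model is trained per grid size on a single fixed stratified split of
    the training rows; ties resolve to the smaller size.
    """
    if config is None:
        config = BPNNConfig()
    rng = np.random.default_rng(config.seed)
    tr_rows, val_rows = _carve_validation(matrix, config.validation_fraction, rng)
    sub = matrix.take_rows(tr_rows)
    X_val = matrix.values[val_rows]
    T_val = one_hot(matrix.labels[val_rows], matrix.n_classes)
    if X_val.shape[0] == 0:
        sub = matrix
        X_val = matrix.values
        T_val = one_hot(matrix.labels, matrix.n_classes)
    table: dict[int, float] = {}
    for size in config.hidden_sizes_grid:
        _, hist = train(sub, size, config, validation=(X_val, T_val))
        table[int(size)] = min(hist["validation"])
    best = None
    for size in sorted(table):
        if best is None or table[size] < table[best]:
            best = size
    assert best is not None
    return best, table


def predict(model: BPNNModel, matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predicted class codes: argmax of output activations, ties → lowest."""
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model inputs {model.n_inputs}"
        )
    _, O = _forward_batch(model, X)
    return np.argmax(O, axis=1)


def save_model(model: BPNNModel, path: str | Path) -> None:
    """Persist the model as structured JSON text."""
    payload = {
        "W_in_hidden": model.W_in_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "W_hidden_out": model.W_hidden_out.tolist(),
        "b_out": model.b_out.tolist(),
        "class_names": list(model.class_names),
        "feature_names": list(model.feature_names),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")


def load_model(path: str | Path) -> BPNNModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return BPNNModel(
        W_in_hidden=np.asarray(payload["W_in_hidden"], dtype=np.float64),
        b_hidden=np.asarray(payload["b_hidden"], dtype=np.float64),
        W_hidden_out=np.asarray(payload["W_hidden_out"], dtype=np.float64),
        b_out=np.asarray(payload["b_out"], dtype=np.float64),
        class_names=tuple(payload["class_names"]),
        feature_names=tuple(payload["feature_names"]),
    )
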