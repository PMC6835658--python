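"""From-scratch multilayer perceptron with momentum backpropagation.

The surrogate maps a resin composition (optionally plus the per-layer
exposure time) to cumulative drug release at a fixed grid of dissolution
time points.  Two reference architectures are provided: a 3-8-5 network with
linear activations (inputs PEGDA/PEG 400/water %, outputs release at
1/2/4/6/8 h) and a 4-5-5-6-5-6-4 network mixing log-sigmoid hidden layers
with a linear output (the fourth input is the exposure time; outputs at
2/4/6/8 h).

Training is deliberately plain: full-batch gradient descent on half the mean
squared error with a momentum term,

    dw_t = -lr * dE/dw + momentum * dw_{t-1},

early-stopped on validation RMS.  Inputs and outputs are min-max scaled to
[0, 1]; reported RMS is on that scale, predictions are returned in % units.
Everything is deterministic for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .data import Formulation

__all__ = [
    "MLPConfig",
    "TrainedMLP",
    "NN1_CONFIG",
    "NN2_CONFIG",
    "init_mlp",
    "forward",
    "loss_and_gradients",
    "train_backprop",
    "architecture_search",
    "predict_release",
    "save_mlp",
    "load_mlp",
]

ACTIVATIONS = ("linear", "log_sigmoid")

#: Dissolution time grids (h) the two reference architectures predict at.
NN1_TIMES = (1.0, 2.0, 4.0, 6.0, 8.0)
NN2_TIMES = (2.0, 4.0, 6.0, 8.0)


@dataclass(frozen=True)
class MLPConfig:
    layer_sizes: tuple[int, ...]
    activations: tuple[str, ...]
    learning_rate: float = 0.6
    momentum: float = 0.6
    max_epochs: int = 20_000
    patience: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2 or any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer_sizes needs >= 2 entries, all >= 1")
        if len(self.activations) != len(self.layer_sizes) - 1:
            raise ValueError("one activation per non-input layer is required")
        if any(a not in ACTIVATIONS for a in self.activations):
            raise ValueError(f"activations must be among {ACTIVATIONS}")
        if not (0.0 <= self.learning_rate <= 1.0) or not (0.0 <= self.momentum <= 1.0):
            raise ValueError("learning rate and momentum must lie in [0, 1]")


#: Composition-only network: single hidden layer of 8 units, linear throughout.
NN1_CONFIG = MLPConfig(layer_sizes=(3, 8, 5), activations=("linear", "linear"))

#: Composition + exposure-time network: five log-sigmoid hidden layers
#: (5, 5, 6, 5, 6 units) and a linear output layer.
NN2_CONFIG = MLPConfig(
    layer_sizes=(4, 5, 5, 6, 5, 6, 4),
    activations=("log_sigmoid",) * 5 + ("linear",),
)


@dataclass
class TrainedMLP:
    config: MLPConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: np.ndarray
    y_range: np.ndarray
    training_history: list[float] = field(default_factory=list)
    times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        sizes = self.config.layer_sizes
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[layer], sizes[layer + 1]) or b.shape != (sizes[layer + 1],):
                raise ValueError("weight shapes inconsistent with layer_sizes")

    @property
    def n_inputs(self) -> int:
        return self.config.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.config.layer_sizes[-1]


def init_mlp(config: MLPConfig, times: Sequence[float] = ()) -> TrainedMLP:
    """Fresh network with weights uniform in (−0.5, 0.5) from the seeded RNG."""
    rng = np.random.default_rng(config.seed)
    sizes = config.layer_sizes
    weights = [rng.uniform(-0.5, 0.5, size=(sizes[i], sizes[i + 1]))
               for i in range(len(sizes) - 1)]
    biases = [rng.uniform(-0.5, 0.5, size=sizes[i + 1])
              for i in range(len(sizes) - 1)]
    n_in, n_out = sizes[0], sizes[-1]
    return TrainedMLP(
        config=config, weights=weights, biases=biases,
        x_min=np.zeros(n_in), x_range=np.ones(n_in),
        y_min=np.zeros(n_out), y_range=np.ones(n_out),
        times=tuple(times),
    )


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return z
    return 1.0 / (1.0 + np.exp(-z))


def _activate_deriv(a: np.ndarray, kind: str) -> np.ndarray:
    # expressed in the activation output a
    if kind == "linear":
        return np.ones_like(a)
    return a * (1.0 - a)


def _forward_scaled(mlp: TrainedMLP, Xs: np.ndarray) -> list[np.ndarray]:
    """Per-layer activations on the scaled scale; index 0 is the input."""
    acts = [Xs]
    for W, b, kind in zip(mlp.weights, mlp.biases, mlp.config.activations):
        acts.append(_activate(acts[-1] @ W + b, kind))
    return acts


def _scale_x(mlp: TrainedMLP, X: np.ndarray) -> np.ndarray:
    return (X - mlp.x_min) / mlp.x_range


def _unscale_y(mlp: TrainedMLP, Ys: np.ndarray) -> np.ndarray:
    return Ys * mlp.y_range + mlp.y_min


def forward(mlp: TrainedMLP, inputs: np.ndarray) -> np.ndarray:
    """Predict in original (%) units for one input vector or a batch."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != mlp.n_inputs:
        raise ValueError(
            f"expected {mlp.n_inputs} input features, got {X.shape[1]}"
        )
    out = _unscale_y(mlp, _forward_scaled(mlp, _scale_x(mlp, X))[-1])
    return out[0] if np.ndim(inputs) == 1 else out


def loss_and_gradients(
    mlp: TrainedMLP, Xs: np.ndarray, Ys: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Half mean squared error on the scaled scale and its exact gradients.

    E = 0.5 · mean over samples and outputs of (pred − target)².
    """
    acts = _forward_scaled(mlp, Xs)
    n, m = Ys.shape
    err = acts[-1] - Ys
    loss = 0.5 * float(np.mean(err**2))
    delta = err / (n * m)  # dE/d(pre-activation output) before activation deriv
    grads_W: list[np.ndarray] = [np.empty(0)] * len(mlp.weights)
    grads_b: list[np.ndarray] = [np.empty(0)] * len(mlp.biases)
    for layer in range(len(mlp.weights) - 1, -1, -1):
        delta = delta * _activate_deriv(acts[layer + 1], mlp.config.activations[layer])
        grads_W[layer] = acts[layer].T @ delta
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ mlp.weights[layer].T
    return loss, grads_W, grads_b


def _rms(mlp: TrainedMLP, Xs: np.ndarray, Ys: np.ndarray) -> float:
    pred = _forward_scaled(mlp, Xs)[-1]
    return float(np.sqrt(np.mean((pred - Ys) ** 2)))


def _fit_scalers(mlp: TrainedMLP, X: np.ndarray, Y: np.ndarray) -> None:
    mlp.x_min = X.min(axis=0)
    mlp.x_range = np.where(np.ptp(X, axis=0) > 0, np.ptp(X, axis=0), 1.0)
    mlp.y_min = Y.min(axis=0)
    mlp.y_range = np.where(np.ptp(Y, axis=0) > 0, np.ptp(Y, axis=0), 1.0)


def train_backprop(
    mlp: TrainedMLP,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: Optional[np.ndarray] = None,
    Y_val: Optional[np.ndarray] = None,
) -> tuple[TrainedMLP, dict[str, float]]:
    """Full-batch momentum gradient descent with validation early stopping.

    Min-max scalers are fitted on the training set.  Training stops at
    ``max_epochs`` or when the monitored RMS (validation when supplied,
    otherwise training) has not improved for ``patience`` epochs; the best
    weights seen are restored.  Returns the trained network and metrics:
    ``rms`` (monitored set, scaled units) and ``r2`` (squared correlation of
    observed vs predicted on the monitored set).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    if len(X_train) == 0:
        raise ValueError("training set is empty")
    _fit_scalers(mlp, X_train, Y_train)
    Xs, Ys = _scale_x(mlp, X_train), (Y_train - mlp.y_min) / mlp.y_range
    have_val = X_val is not None and len(X_val) > 0
    if have_val:
        Xvs = _scale_x(mlp, np.atleast_2d(np.asarray(X_val, dtype=float)))
        Yvs = (np.atleast_2d(np.asarray(Y_val, dtype=float)) - mlp.y_min) / mlp.y_range

    vel_W = [np.zeros_like(W) for W in mlp.weights]
    vel_b = [np.zeros_like(b) for b in mlp.biases]
    cfg = mlp.config
    best = np.inf
    best_state: Optional[tuple[list[np.ndarray], list[np.ndarray]]] = None
    since_best = 0
    mlp.training_history = []
    for epoch in range(cfg.max_epochs):
        loss, gW, gb = loss_and_gradients(mlp, Xs, Ys)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {epoch}"
            )
        mlp.training_history.append(loss)
        for layer in range(len(mlp.weights)):
            vel_W[layer] = -cfg.learning_rate * gW[layer] + cfg.momentum * vel_W[layer]
            vel_b[layer] = -cfg.learning_rate * gb[layer] + cfg.momentum * vel_b[layer]
            mlp.weights[layer] = mlp.weights[layer] + vel_W[layer]
            mlp.biases[layer] = mlp.biases[layer] + vel_b[layer]
        monitored = _rms(mlp, Xvs, Yvs) if have_val else _rms(mlp, Xs, Ys)
        if monitored < best - 1e-12:
            best = monitored
            best_state = (
                [W.copy() for W in mlp.weights],
                [b.copy() for b in mlp.biases],
            )
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        mlp.weights, mlp.biases = best_state

    if have_val:
        obs, pred = Yvs, _forward_scaled(mlp, Xvs)[-1]
    else:
        obs, pred = Ys, _forward_scaled(mlp, Xs)[-1]
    rms = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(obs) > 0 and np.ptp(pred) > 0:
        r2 = float(np.corrcoef(obs.ravel(), pred.ravel())[0, 1] ** 2)
    else:
        r2 = float("nan")
    return mlp, {"rms": rms, "r2": r2}


def architecture_search(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    hidden_layer_counts: Sequence[int] = range(1, 9),
    nodes_per_layer: Sequence[int] = range(4, 11),
    template: Optional[MLPConfig] = None,
    times: Sequence[float] = NN1_TIMES,
) -> tuple[TrainedMLP, MLPConfig, list[dict]]:
    """Trial-and-error grid over depth and width.

    For each (hidden layers, nodes per hidden layer) cell a network is
    trained from a seed derived deterministically from the template seed;
    the winner has minimal validation RMS, ties broken by higher r².
    Failed cells are recorded on the leaderboard, never fatal.
    """
    template = template or MLPConfig(
        layer_sizes=(X_train.shape[1], 8, Y_train.shape[1]),
        activations=("linear", "linear"),
    )
    leaderboard: list[dict] = []
    best_entry: Optional[dict] = None
    best_mlp: Optional[TrainedMLP] = None
    for depth in hidden_layer_counts:
        for width in nodes_per_layer:
            sizes = (X_train.shape[1],) + (width,) * depth + (Y_train.shape[1],)
            acts = (template.activations[0],) * depth + (template.activations[-1],)
            cfg = replace(
                template,
                layer_sizes=sizes,
                activations=acts,
                seed=template.seed + 1000 * depth + width,
            )
            row: dict = {"hidden_layers": depth, "nodes": width}
            try:
                mlp, metrics = train_backprop(
                    init_mlp(cfg, times=times), X_train, Y_train, X_val, Y_val
                )
                row.update(metrics)
            except (FloatingPointError, ValueError) as exc:
                row.update({"rms": float("nan"), "r2": float("nan"), "error": str(exc)})
                leaderboard.append(row)
                continue
            leaderboard.append(row)
            if np.isfinite(row["rms"]) and (
                best_entry is None
                or (row["rms"], -row["r2"]) < (best_entry["rms"], -best_entry["r2"])
            ):
                best_entry, best_mlp = row, mlp
    if best_mlp is None:
        raise ValueError("every architecture cell failed to train")
    return best_mlp, best_mlp.config, leaderboard


def predict_release(
    mlp: TrainedMLP,
    formulation: Formulation,
    exposure_time: Optional[float] = None,
) -> np.ndarray:
    """Cumulative % release at the network's time grid, clipped to [0, 100].

    Networks with four inputs require the per-layer exposure time (s) as the
    fourth feature.
    """
    x = list(formulation.components)
    if mlp.n_inputs == 4:
        if exposure_time is None:
            raise ValueError("this network requires an exposure_time input")
        x.append(float(exposure_time))
    elif exposure_time is not None and mlp.n_inputs == 3:
        raise ValueError("this network does not accept an exposure_time input")
    return np.clip(forward(mlp, np.asarray(x)), 0.0, 100.0)


def save_mlp(mlp: TrainedMLP, path: str | Path) -> None:
    """Serialize a trained network as a portable JSON weight bundle."""
    payload = {
        "config": {
            "layer_sizes": list(mlp.config.layer_sizes),
            "activations": list(mlp.config.activations),
            "learning_rate": mlp.config.learning_rate,
            "momentum": mlp.config.momentum,
            "max_epochs": mlp.config.max_epochs,
            "patience": mlp.config.patience,
            "seed": mlp.config.seed,
        },
        "weights": [W.tolist() for W in mlp.weights],
        "biases": [b.tolist() for b in mlp.biases],
        "x_min": mlp.x_min.tolist(),
        "x_range": mlp.x_range.tolist(),
        "y_min": mlp.y_min.tolist(),
        "y_range": mlp.y_range.tolist(),
        "times": list(mlp.times),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_mlp(path: str | Path) -> TrainedMLP:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    cfg = payload["config"]
    config = MLPConfig(
        layer_sizes=tuple(cfg["layer_sizes"]),
        activations=tuple(cfg["activations"]),
        learning_rate=cfg["learning_rate"],
        momentum=cfg["momentum"],
        max_epochs=cfg["max_epochs"],
        patience=cfg["patience"],
        seed=cfg["seed"],
    )
    return TrainedMLP(
        config=config,
        weights=[np.array(W) for W in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        x_min=np.array(payload["x_min"]),
        x_range=np.array(payload["x_range"]),
        y_min=np.array(payload["y_min"]),
        y_range=np.array(payload["y_range"]),
        times=tuple(payload["times"]),
    )
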