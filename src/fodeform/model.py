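"""Surrogate regression from triad orientations to plantar-surface positions.

A densely connected feed-forward network maps the 15 relative-orientation
angles to the 165 surface-marker coordinates. Hyperparameters are tuned by
exhaustive grid search with region-stratified 5-fold cross-validation; the
selected architecture (two hidden layers, Adam, learning rate 0.005, batch
16, 100 epochs, mean-square-error loss) is the package default.

The network is implemented directly in numpy — dense layers with
rectified-linear hidden activations and a linear 165-unit output — with
Adam, Adadelta and Adagrad optimizers, so training is fully deterministic
for a given seed. Inputs and outputs are z-scored per dimension on the
learning set only.
"""

from __future__ import annotations

import itertools
import json
import zipfile
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .exceptions import DivergenceError, ParameterError

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "FULL_GRID",
    "FINAL_CONFIG",
    "enumerate_grid",
    "kfold_cv_score",
    "grid_search",
    "train",
    "predict_surface",
    "save_model",
    "load_model",
]

OPTIMIZERS = ("adam", "adadelta", "adagrad")

# Global gradient-norm clip applied to every optimizer step; stabilizes the
# small-batch training without touching learning rate, batch size or epochs.
GRAD_CLIP_NORM = 1.0

# The hyperparameter grid explored during tuning: number of dense layers 1-5,
# three optimizers, two learning rates, four batch sizes, three epoch counts
# (5 x 3 x 2 x 4 x 3 = 360 configurations).
FULL_GRID: dict[str, list] = {
    "n_layers": [1, 2, 3, 4, 5],
    "optimizer": list(OPTIMIZERS),
    "learning_rate": [0.01, 0.005],
    "batch_size": [16, 32, 64, 128],
    "epochs": [20, 50, 100],
}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one candidate network.

    ``n_layers`` counts dense weight layers including the linear output, so
    ``n_layers=3`` is the selected four-layer (input + two hidden + output)
    architecture and ``n_layers=1`` is a plain affine map. ``hidden_width``
    is a package default (64); the tuning grid does not vary it.
    ``tail_average`` is the number of final per-epoch weight snapshots
    averaged into the returned weights (1 = plain final weights); it
    de-noises the stochastic-gradient plateau of small-batch training.
    """

    n_layers: int = 3
    optimizer: str = "adam"
    learning_rate: float = 0.005
    batch_size: int = 16
    epochs: int = 100
    hidden_width: int = 64
    tail_average: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ParameterError("n_layers must be >= 1")
        if self.optimizer not in OPTIMIZERS:
            raise ParameterError(f"optimizer must be one of {OPTIMIZERS}")
        if self.hidden_width < 1:
            raise ParameterError("hidden_width must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ParameterError("learning_rate, batch_size and epochs must be positive")
        if self.tail_average < 1:
            raise ParameterError("tail_average must be >= 1")


FINAL_CONFIG = ModelConfig()


@dataclass
class _Affine:
    """Per-dimension z-score normalizer fitted on learning data only."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "_Affine":
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale < 1e-8, 1.0, scale)
        return cls(mean, scale)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.scale + self.mean


@dataclass
class TrainedModel:
    config: ModelConfig
    weights: list[np.ndarray] = field(repr=False)
    biases: list[np.ndarray] = field(repr=False)
    input_normalizer: _Affine = field(repr=False)
    output_normalizer: _Affine = field(repr=False)
    training_history: list[float] = field(default_factory=list)


def enumerate_grid(grids: dict[str, list] | None = None) -> list[ModelConfig]:
    """Cartesian product of the hyperparameter grids, in deterministic order."""
    grids = dict(FULL_GRID if grids is None else grids)
    for key, values in grids.items():
        if len(values) == 0:
            raise ParameterError(f"grid for {key!r} is empty")
    keys = list(grids)
    configs = []
    for combo in itertools.product(*(grids[k] for k in keys)):
        configs.append(replace(ModelConfig(), **dict(zip(keys, combo))))
    return configs


# ---------------------------------------------------------------------------
# numpy network internals


def _init_params(
    sizes: list[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        gain = np.sqrt(2.0 / fan_in) if i < len(sizes) - 2 else np.sqrt(1.0 / fan_in)
        weights.append(gain * rng.standard_normal((fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(x, weights, biases):
    acts = [x]
    h = x
    for i, (W, b) in enumerate(zip(weights, biases)):
        h = h @ W + b
        if i < len(weights) - 1:
            h = np.maximum(h, 0.0)
        acts.append(h)
    return acts


def _backward(acts, y, weights):
    n = len(y)
    grads_w, grads_b = [], []
    delta = 2.0 * (acts[-1] - y) / (n * y.shape[1])  # d(MSE)/d(out)
    for i in range(len(weights) - 1, -1, -1):
        grads_w.insert(0, acts[i].T @ delta)
        grads_b.insert(0, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ weights[i].T) * (acts[i] > 0)
    return grads_w, grads_b


class _Optimizer:
    def __init__(self, kind: str, lr: float, params: list[np.ndarray]):
        self.kind = kind
        self.lr = lr
        self.t = 0
        self.state = [
            {"m": np.zeros_like(p), "v": np.zeros_like(p)} for p in params
        ]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, s in zip(params, grads, self.state):
            if self.kind == "adam":
                b1, b2, eps = 0.9, 0.999, 1e-8
                s["m"] = b1 * s["m"] + (1 - b1) * g
                s["v"] = b2 * s["v"] + (1 - b2) * g * g
                mhat = s["m"] / (1 - b1**self.t)
                vhat = s["v"] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            elif self.kind == "adagrad":
                s["v"] += g * g
                p -= self.lr * g / (np.sqrt(s["v"]) + 1e-10)
            elif self.kind == "adadelta":
                rho, eps = 0.95, 1e-6
                s["v"] = rho * s["v"] + (1 - rho) * g * g
                dx = -np.sqrt(s["m"] + eps) / np.sqrt(s["v"] + eps) * g
                s["m"] = rho * s["m"] + (1 - rho) * dx * dx
                p += self.lr * dx


def train(
    features: np.ndarray, targets: np.ndarray, config: ModelConfig = FINAL_CONFIG
) -> TrainedModel:
    """Fit the network on learning-set samples (features 15, targets 165).

    Normalizers are fitted on these samples only; epochs are fixed (no early
    stopping). Deterministic for a given ``config.seed``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or len(x) != len(y):
        raise ParameterError("features and targets must be aligned 2D arrays")
    if len(x) < 1:
        raise ParameterError("cannot train on an empty learning set")
    norm_in = _Affine.fit(x)
    norm_out = _Affine.fit(y)
    xz = norm_in.forward(x)
    yz = norm_out.forward(y)

    rng = np.random.default_rng(config.seed)
    sizes = [x.shape[1]] + [config.hidden_width] * (config.n_layers - 1) + [y.shape[1]]
    weights, biases = _init_params(sizes, rng)
    opt = _Optimizer(config.optimizer, config.learning_rate, weights + biases)

    n = len(xz)
    history: list[float] = []
    n_w = len(weights)
    acc: list[np.ndarray] | None = None
    n_snap = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            acts = _forward(xz[idx], weights, biases)
            resid = acts[-1] - yz[idx]
            epoch_loss += float(np.sum(resid**2))
            gw, gb = _backward(acts, yz[idx], weights)
            grads = gw + gb
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if gnorm > GRAD_CLIP_NORM:
                grads = [g * (GRAD_CLIP_NORM / gnorm) for g in grads]
            opt.step(weights + biases, grads)
        epoch_loss /= n * yz.shape[1]
        if not np.isfinite(epoch_loss):
            raise DivergenceError(f"training diverged (non-finite loss) for {config}")
        history.append(epoch_loss)
        if epoch >= config.epochs - config.tail_average:
            snap = [p.copy() for p in weights + biases]
            acc = snap if acc is None else [a + s for a, s in zip(acc, snap)]
            n_snap += 1
    params = [a / n_snap for a in acc]
    return TrainedModel(config, params[:n_w], params[n_w:], norm_in, norm_out, history)


def predict_surface(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Predict MPS vectors (mm, session-local frame) from OT features.

    Stateless: batch prediction equals stacking per-frame predictions. Rows
    containing NaN features are skipped (returned as NaN) rather than fed to
    the network.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.weights[0].shape[0]:
        raise ParameterError(
            f"expected feature length {model.weights[0].shape[0]}, got {x.shape[1]}"
        )
    out = np.full((len(x), model.weights[-1].shape[1]), np.nan)
    ok = np.isfinite(x).all(axis=1)
    if ok.any():
        z = model.input_normalizer.forward(x[ok])
        pred = _forward(z, model.weights, model.biases)[-1]
        out[ok] = model.output_normalizer.inverse(pred)
    if np.asarray(features).ndim == 1:
        return out[0]
    return out


def kfold_cv_score(
    features: np.ndarray,
    targets: np.ndarray,
    regions: np.ndarray,
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean validation MSE (mm^2) over region-stratified K folds.

    The model is retrained from scratch on each fold's train part and scored
    on its validation part, so no validation sample ever influences the
    weights or normalizers that score it.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if len(x) < k:
        raise ParameterError(f"K={k} folds require at least {k} samples, got {len(x)}")
    codes = np.unique(np.asarray(regions, dtype=object), return_inverse=True)[1]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    losses = []
    for fold, (tr, va) in enumerate(skf.split(x, codes)):
        m = train(x[tr], y[tr], replace(config, seed=config.seed + fold))
        pred = predict_surface(m, x[va])
        losses.append(float(np.mean((pred - y[va]) ** 2)))
    return float(np.mean(losses))


def grid_search(
    features: np.ndarray,
    targets: np.ndarray,
    regions: np.ndarray,
    grids: dict[str, list] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[ModelConfig, list[tuple[ModelConfig, float]]]:
    """Exhaustive search over the grid; returns the argmin config and all scores."""
    results = []
    for cfg in enumerate_grid(grids):
        score = kfold_cv_score(features, targets, regions, cfg, k=k, seed=seed)
        results.append((cfg, score))
    best = min(results, key=lambda cs: cs[1])[0]
    return best, results


# ---------------------------------------------------------------------------
# persistence: a single zip archive holding weights, normalizers and config


def save_model(model: TrainedModel, path) -> None:
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    arrays["in_mean"] = model.input_normalizer.mean
    arrays["in_scale"] = model.input_normalizer.scale
    arrays["out_mean"] = model.output_normalizer.mean
    arrays["out_scale"] = model.output_normalizer.scale
    meta = {
        "config": asdict(model.config),
        "n_weight_layers": len(model.weights),
        "training_history": model.training_history,
    }
    with zipfile.ZipFile(path, "w") as zf:
        import io as _io

        buf = _io.BytesIO()
        np.savez(buf, **arrays)
        zf.writestr("arrays.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta))


def load_model(path) -> TrainedModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        import io as _io

        arrays = np.load(_io.BytesIO(zf.read("arrays.npz")))
        nl = meta["n_weight_layers"]
        weights = [arrays[f"w{i}"] for i in range(nl)]
        biases = [arrays[f"b{i}"] for i in range(nl)]
        return TrainedModel(
            ModelConfig(**meta["config"]),
            weights,
            biases,
            _Affine(arrays["in_mean"], arrays["in_scale"]),
            _Affine(arrays["out_mean"], arrays["out_scale"]),
            meta["training_history"],
        )
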