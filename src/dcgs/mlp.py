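"""Two-hidden-layer perceptron trained with Adam under MAE loss.

The network is deliberately small and fully deterministic: feedforward
input -> n1 -> n2 -> output, Glorot-uniform seeded initialization, 200
epochs of shuffled mini-batches of 16, mean-absolute-error loss for both
regression (linear output) and classification (one output per class,
argmax prediction).  Hyperparameter search is a grid over (n1, n2,
activation, learning rate), with the layer sizes bounded by the
approximation-theoretic limits for m training samples and q outputs:

    n1 <= sqrt((q+2) m) + 2 sqrt(m / (q+2))
    n2 <= q sqrt(m / (q+2))

Enumerating every integer up to the bound is wasteful for large m, so
the grid samples a fixed number of evenly spaced sizes per layer
(default 8, endpoints included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import mape, pearson_r

_ACTIVATIONS = ("relu", "sigmoid", "tanh")
_LEARNING_RATES = (0.005, 0.001, 0.0001)


@dataclass(frozen=True)
class MLPConfig:
    n1: int = 8
    n2: int = 4
    activation: str = "relu"
    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 200
    batch_size: int = 16
    loss: str = "mae"  # classification may use "cross_entropy" instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.loss not in ("mae", "cross_entropy"):
            raise ValueError("loss must be 'mae' or 'cross_entropy'")


def hl_bounds(m: int, q: int) -> tuple[int, int]:
    """Upper bounds on hidden-layer sizes for m samples, q outputs.

    upper1 = floor(sqrt((q+2) m) + 2 sqrt(m/(q+2))),
    upper2 = floor(q sqrt(m/(q+2))), both clamped to >= 1.
    """
    if m < 1 or q < 1:
        raise ValueError("m and q must be >= 1")
    upper1 = math.floor(math.sqrt((q + 2) * m) + 2.0 * math.sqrt(m / (q + 2)))
    upper2 = math.floor(q * math.sqrt(m / (q + 2)))
    return max(upper1, 1), max(upper2, 1)


@dataclass
class OptimizerState:
    """Adam first/second-moment averages and step counter, per weight array."""

    v: np.ndarray
    s: np.ndarray
    t: int = 0


def adam_step(
    state: OptimizerState, gradient: np.ndarray, cfg: MLPConfig
) -> tuple[OptimizerState, np.ndarray]:
    """One Adam update; returns (new state, weight delta).

    Moments: v_t = b1 v_{t-1} + (1-b1) g_t, s_t = b2 s_{t-1} + (1-b2) g_t^2,
    both bias-corrected; delta = -eta * v_hat / (sqrt(s_hat) + eps).
    """
    g = np.asarray(gradient, float)
    t = state.t + 1
    v = cfg.beta1 * state.v + (1.0 - cfg.beta1) * g
    s = cfg.beta2 * state.s + (1.0 - cfg.beta2) * g**2
    v_hat = v / (1.0 - cfg.beta1**t)
    s_hat = s / (1.0 - cfg.beta2**t)
    delta = -cfg.learning_rate * v_hat / (np.sqrt(s_hat) + cfg.epsilon)
    return OptimizerState(v=v, s=s, t=t), delta


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return np.tanh(z)


def _act_grad(a: np.ndarray, z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(float)
    if kind == "sigmoid":
        return a * (1.0 - a)
    return 1.0 - a**2


class MLPNetwork:
    """Feedforward net input -> n1 -> n2 -> output with linear output layer."""

    def __init__(self, n_inputs: int, n_outputs: int, cfg: MLPConfig, task: str = "regression"):
        if task not in ("regression", "classification"):
            raise ValueError("task must be regression or classification")
        self.cfg = cfg
        self.task = task
        self.n_inputs = n_inputs
        self.n_outputs = n_outputs
        rng = np.random.default_rng(cfg.seed)
        sizes = [n_inputs, cfg.n1, cfg.n2, n_outputs]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.loss_trace: list[float] = []
        self.classes_: np.ndarray | None = None

    def _forward(self, X: np.ndarray):
        a = X
        acts, zs = [X], []
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            zs.append(z)
            a = z if layer == 2 else _act(z, self.cfg.activation)
            acts.append(a)
        return acts, zs

    def forward(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, float))[0][-1]

    def fit(self, X: np.ndarray, targets: np.ndarray) -> "MLPNetwork":
        """Train for ``cfg.epochs`` epochs of shuffled MAE mini-batches."""
        X = np.asarray(X, float)
        if self.task == "classification":
            self.classes_ = np.unique(targets)
            T = (targets[:, None] == self.classes_[None, :]).astype(float)
        else:
            T = np.asarray(targets, float).reshape(len(X), -1)
        if T.shape[1] != self.n_outputs:
            raise ValueError(f"target width {T.shape[1]} != n_outputs {self.n_outputs}")
        n = len(X)
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 1)
        states = [
            (OptimizerState(np.zeros_like(W), np.zeros_like(W)), OptimizerState(np.zeros_like(b), np.zeros_like(b)))
            for W, b in zip(self.weights, self.biases)
        ]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_abs_err = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, Tb = X[idx], T[idx]
                acts, zs = self._forward(Xb)
                out = acts[-1]
                if cfg.loss == "cross_entropy" and self.task == "classification":
                    # softmax + CE: delta = (softmax - T) / batch
                    z = out - out.max(axis=1, keepdims=True)
                    sm = np.exp(z)
                    sm /= sm.sum(axis=1, keepdims=True)
                    # scaled so the epoch loss divisor yields mean CE/sample
                    epoch_abs_err += -np.log(
                        np.clip((sm * Tb).sum(axis=1), 1e-12, None)
                    ).sum() * self.n_outputs
                    delta = (sm - Tb) / len(Xb)
                else:
                    err = out - Tb
                    epoch_abs_err += np.abs(err).sum()
                    # MAE gradient wrt outputs
                    delta = np.sign(err) / err.size
                grads_W, grads_b = [None] * 3, [None] * 3
                for layer in (2, 1, 0):
                    grads_W[layer] = acts[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ self.weights[layer].T) * _act_grad(
                            acts[layer], zs[layer - 1], cfg.activation
                        )
                for layer in range(3):
                    sW, sB = states[layer]
                    sW, dW = adam_step(sW, grads_W[layer], cfg)
                    sB, dB = adam_step(sB, grads_b[layer], cfg)
                    states[layer] = (sW, sB)
                    self.weights[layer] += dW
                    self.biases[layer] += dB
            loss = epoch_abs_err / (n * self.n_outputs)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss at epoch {epoch})")
            self.loss_trace.append(loss)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = self.forward(X)
        if self.task == "classification":
            return self.classes_[np.argmax(out, axis=1)]
        return out[:, 0] if self.n_outputs == 1 else out

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "n_inputs": self.n_inputs,
            "n_outputs": self.n_outputs,
            "config": {
                "n1": self.cfg.n1,
                "n2": self.cfg.n2,
                "activation": self.cfg.activation,
                "learning_rate": self.cfg.learning_rate,
                "epochs": self.cfg.epochs,
                "batch_size": self.cfg.batch_size,
                "loss": self.cfg.loss,
                "seed": self.cfg.seed,
            },
            "classes": None if self.classes_ is None else self.classes_.tolist(),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPNetwork":
        cfg = MLPConfig(**d["config"])
        net = cls(d["n_inputs"], d["n_outputs"], cfg, task=d["task"])
        net.weights = [np.array(W) for W in d["weights"]]
        net.biases = [np.array(b) for b in d["biases"]]
        net.classes_ = None if d["classes"] is None else np.array(d["classes"])
        return net


def train_mlp(
    X: np.ndarray, targets: np.ndarray, cfg: MLPConfig, task: str = "regression"
) -> MLPNetwork:
    """Build and train a network; classification infers classes from targets."""
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    n_out = len(np.unique(targets)) if task == "classification" else 1
    net = MLPNetwork(X.shape[1], n_out, cfg, task=task)
    return net.fit(X, targets)


@dataclass
class GridSpec:
    """Hyperparameter grid bounded by :func:`hl_bounds`.

    ``from_data`` samples ``points_per_layer`` evenly spaced integer
    sizes per hidden layer between 1 and the bound (endpoints included).
    """

    n1_candidates: tuple[int, ...]
    n2_candidates: tuple[int, ...]
    activations: tuple[str, ...] = _ACTIVATIONS
    learning_rates: tuple[float, ...] = _LEARNING_RATES

    @classmethod
    def from_data(
        cls,
        m: int,
        q: int,
        points_per_layer: int = 8,
        activations: tuple[str, ...] = _ACTIVATIONS,
        learning_rates: tuple[float, ...] = _LEARNING_RATES,
    ) -> "GridSpec":
        upper1, upper2 = hl_bounds(m, q)
        n1 = tuple(sorted({int(v) for v in np.linspace(1, upper1, min(points_per_layer, upper1)).round()}))
        n2 = tuple(sorted({int(v) for v in np.linspace(1, upper2, min(points_per_layer, upper2)).round()}))
        return cls(n1, n2, tuple(activations), tuple(learning_rates))

    def configs(self, base: MLPConfig | None = None) -> list[MLPConfig]:
        base = base or MLPConfig()
        out = []
        for n1 in self.n1_candidates:
            for n2 in self.n2_candidates:
                for act in self.activations:
                    for lr in self.learning_rates:
                        out.append(replace(base, n1=n1, n2=n2, activation=act, learning_rate=lr))
        if not out:
            raise ValueError("empty hyperparameter grid")
        return out


@dataclass
class GridResult:
    best: MLPConfig
    records: list[dict] = field(default_factory=list)


def _regression_winner(records: list[dict]) -> int:
    rs = np.array([rec["r"] for rec in records])
    ms = np.array([rec["mape"] for rec in records])

    def norm(v):
        lo, hi = v.min(), v.max()
        return np.full_like(v, 0.5) if hi == lo else (v - lo) / (hi - lo)

    dist = np.sqrt((norm(rs) - 1.0) ** 2 + (norm(ms) - 0.0) ** 2)
    # ties: higher raw R, then smaller total hidden size
    size = np.array([rec["config"].n1 + rec["config"].n2 for rec in records])
    order = np.lexsort((size, -rs, np.round(dist, 12)))
    return int(order[0])


def _classification_winner(records: list[dict]) -> int:
    accs = np.array([rec["accuracy"] for rec in records])
    losses = np.array([rec["loss"] for rec in records])
    best_acc = accs.max()
    cand = np.flatnonzero(accs == best_acc)
    return int(cand[np.argmin(losses[cand])])


def _safe_r(pred: np.ndarray, truth: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(truth) == 0:
        return 0.0
    return pearson_r(pred, truth)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: GridSpec,
    task: str = "regression",
    val_fraction: float = 0.25,
    cv: int = 1,
    seed: int = 0,
    base: MLPConfig | None = None,
) -> GridResult:
    """Train every config and pick the winner.

    Regression: each config is scored by (Pearson R, MAPE), either on a
    single internal held-out split (``cv=1``) or by ``cv``-fold
    cross-validation over the supplied rows (mean R/MAPE across folds) —
    the stabler choice when few rows are available; the winner minimizes
    distance to the ideal corner (max R, min MAPE) after min-max
    normalizing both metrics over the grid.  Classification: the winner
    has maximal held-out accuracy, ties broken by minimal final training
    loss.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = len(X)
    rng = np.random.default_rng(seed)

    if task == "regression" and cv > 1:
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % cv
        splits = [(fold_of != f, fold_of == f) for f in range(cv)]
    elif task == "classification":
        # stratified split so every class appears in both parts
        val_idx = []
        for c in np.unique(y):
            members = np.flatnonzero(y == c)
            members = members[rng.permutation(len(members))]
            k = max(1, int(round(val_fraction * len(members))))
            val_idx.extend(members[:k])
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        splits = [(~val_mask, val_mask)]
    else:
        perm = rng.permutation(n)
        val_mask = np.zeros(n, dtype=bool)
        val_mask[perm[: max(2, int(round(val_fraction * n)))]] = True
        splits = [(~val_mask, val_mask)]

    base = base or MLPConfig()
    records: list[dict] = []
    for cfg in grid.configs(base=base):
        rs, mapes, accs, losses = [], [], [], []
        for tr_mask, va_mask in splits:
            net = train_mlp(X[tr_mask], y[tr_mask], cfg, task=task)
            pred = net.predict(X[va_mask])
            losses.append(net.loss_trace[-1])
            if task == "regression":
                yv = np.asarray(y[va_mask], float)
                rs.append(_safe_r(pred, yv))
                mapes.append(mape(pred, yv))
            else:
                accs.append(float(np.mean(pred == y[va_mask])))
        rec: dict = {"config": cfg, "loss": float(np.mean(losses))}
        if task == "regression":
            rec["r"] = float(np.mean(rs))
            rec["mape"] = float(np.mean(mapes))
        else:
            rec["accuracy"] = float(np.mean(accs))
        records.append(rec)
    win = _regression_winner(records) if task == "regression" else _classification_winner(records)
    return GridResult(best=records[win]["config"], records=records)
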