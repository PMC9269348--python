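"""Per-window fatigue classifier: a small back-propagation network.

The network maps the three window features (longest eye closure in
seconds, yawn count, PERCLOS fraction) to a fatigue probability through
a single hidden layer: 3 inputs -> m logistic hidden units -> 1 logistic
output.  Training minimizes binary cross-entropy with Adam on seeded
minibatches (defaults: batch size 8, 4000 epochs, 90/10 train/validation
split) and records per-epoch train/validation loss and accuracy.

The features have incommensurate units (seconds, count, fraction), so
they are z-scored with statistics of the training split; the scaling
parameters travel with the model, making prediction invariant to any
affine re-encoding applied consistently at train and test time.

Hidden-layer sizing follows the empirical rule m = round(sqrt(i + j)) + c
with c in 1..10; ``compare_hidden_nodes`` runs the sweep used to pick m
(default m = 4).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "MLPModel",
    "TrainingConfig",
    "hidden_node_candidates",
    "train",
    "predict",
    "compare_hidden_nodes",
]

FEATURE_COLUMNS = ["longest_closure_s", "yawn_count", "perclos"]


def hidden_node_candidates(i: int, j: int, rule: str = "sqrt") -> list[int]:
    """Candidate hidden-layer sizes m for i inputs and j outputs.

    ``rule="sqrt"`` (default): m = round(sqrt(i + j)) + c, c = 1..10 —
    for i=3, j=1 this gives 3..12, the range the sizing sweep draws
    from.  ``rule="linear"``: m = i + j + c.
    """
    if i < 1 or j < 1:
        raise ValueError("layer dimensions must be positive")
    if rule == "sqrt":
        base = round(math.sqrt(i + j))
    elif rule == "linear":
        base = i + j
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return [base + c for c in range(1, 11)]


@dataclass
class TrainingConfig:
    """Training hyper-parameters (defaults follow the pipeline regime)."""

    hidden_nodes: int = 4
    batch_size: int = 8
    epochs: int = 4000
    learning_rate: float = 1e-3
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class MLPModel:
    """Trained 3-m-1 network with its feature-scaling parameters."""

    w1: np.ndarray  # (n_features, m)
    b1: np.ndarray  # (m,)
    w2: np.ndarray  # (m, 1)
    b2: np.ndarray  # (1,)
    mu: np.ndarray  # per-feature shift
    sigma: np.ndarray  # per-feature scale
    config: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.w1.shape[1] != self.w2.shape[0]:
            raise ValueError("inconsistent layer shapes")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("scaling parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        Z = (X - self.mu) / self.sigma
        h = _sigmoid(Z @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2).ravel()

    def to_json(self) -> str:
        payload = {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "config": self.config.__dict__,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(
            w1=np.array(d["w1"]),
            b1=np.array(d["b1"]),
            w2=np.array(d["w2"]),
            b2=np.array(d["b2"]),
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
            config=TrainingConfig(**d["config"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _coerce_features(features) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS + ["label"] if c not in features]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
        y = features["label"].to_numpy(dtype=float)
    else:
        X, y = features
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("features and labels must be finite")
    return X, y


def train(
    features,
    config: TrainingConfig | None = None,
) -> tuple[MLPModel, pd.DataFrame]:
    """Fit the network; returns the model and a per-epoch history table.

    ``features`` is either a DataFrame with columns
    ``longest_closure_s, yawn_count, perclos, label`` (label 1 =
    fatigue) or a tuple ``(X, y)``.  Deterministic given
    ``config.seed``.
    """
    config = config or TrainingConfig()
    X, y = _coerce_features(features)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1")

    rng = np.random.default_rng(config.seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if np.unique(y[train_idx]).size < 2:
        raise ValueError("training split lost a class; provide more data")

    mu = X[train_idx].mean(axis=0)
    sigma = X[train_idx].std(axis=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    Xt = (X[train_idx] - mu) / sigma
    Xv = (X[val_idx] - mu) / sigma
    yt, yv = y[train_idx], y[val_idx]

    m = config.hidden_nodes
    d = X.shape[1]
    w1 = rng.normal(0.0, math.sqrt(2.0 / (d + m)), size=(d, m))
    b1 = np.zeros(m)
    w2 = rng.normal(0.0, math.sqrt(2.0 / (m + 1)), size=(m, 1))
    b2 = np.zeros(1)
    params = [w1, b1, w2, b2]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def forward(Z):
        h = _sigmoid(Z @ params[0] + params[1])
        p = _sigmoid(h @ params[2] + params[3]).ravel()
        return h, p

    history = {k: [] for k in ("epoch", "train_loss", "train_acc", "val_loss", "val_acc")}

    for epoch in range(config.epochs):
        order = rng.permutation(len(yt))
        for start in range(0, len(yt), config.batch_size):
            idx = order[start : start + config.batch_size]
            Zb, yb = Xt[idx], yt[idx]
            h, p = forward(Zb)
            # BCE + sigmoid output: dL/dlogit = p - y
            delta_out = (p - yb)[:, None] / len(yb)
            g_w2 = h.T @ delta_out
            g_b2 = delta_out.sum(axis=0)
            delta_h = (delta_out @ params[2].T) * h * (1.0 - h)
            g_w1 = Zb.T @ delta_h
            g_b1 = delta_h.sum(axis=0)
            grads = [g_w1, g_b1, g_w2, g_b2]
            step += 1
            for k, (p_k, g_k) in enumerate(zip(params, grads)):
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g_k
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g_k**2
                m_hat = adam_m[k] / (1 - beta1**step)
                v_hat = adam_v[k] / (1 - beta2**step)
                p_k -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        _, pt = forward(Xt)
        _, pv = forward(Xv)
        history["epoch"].append(epoch)
        history["train_loss"].append(_bce(pt, yt))
        history["train_acc"].append(float(np.mean((pt > 0.5) == yt)))
        history["val_loss"].append(_bce(pv, yv))
        history["val_acc"].append(float(np.mean((pv > 0.5) == yv)))

    model = MLPModel(
        w1=params[0], b1=params[1], w2=params[2], b2=params[3],
        mu=mu, sigma=sigma, config=config,
    )
    return model, pd.DataFrame(history)


def predict(model: MLPModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Fatigue probability and binary state for feature vectors.

    State 1 (fatigue) requires probability strictly above 0.5; a tie at
    exactly 0.5 counts awake (conservative toward fewer false alarms).
    Accepts a WindowFeatures object, an array of shape (3,) or (n, 3),
    or a feature DataFrame.
    """
    from .temporal import WindowFeatures

    if isinstance(features, WindowFeatures):
        X = features.as_array()[None, :]
    elif isinstance(features, pd.DataFrame):
        X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    proba = model.predict_proba(X)
    state = (proba > 0.5).astype(int)
    return proba, state


def compare_hidden_nodes(
    features,
    node_list,
    config: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Train once per candidate m (same seed/data) and tabulate the
    final-epoch losses and accuracies — the sweep used to choose m."""
    node_list = list(node_list)
    if not node_list:
        raise ValueError("node_list must be non-empty")
    base = config or TrainingConfig()
    rows = []
    for m in node_list:
        cfg = TrainingConfig(
            hidden_nodes=m,
            batch_size=base.batch_size,
            epochs=base.epochs,
            learning_rate=base.learning_rate,
            validation_fraction=base.validation_fraction,
            seed=base.seed,
        )
        _, hist = train(features, cfg)
        last = hist.iloc[-1]
        rows.append(
            {
                "hidden_nodes": m,
                "train_loss": last["train_loss"],
                "val_loss": last["val_loss"],
                "train_acc": last["train_acc"],
                "val_acc": last["val_acc"],
            }
        )
    return pd.DataFrame(rows)
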