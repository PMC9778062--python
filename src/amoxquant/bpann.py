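"""From-scratch backpropagation network for concentration regression.

A three-layer feedforward network (9 inputs, 18 sigmoid hidden units, 1
linear output) trained by full-batch gradient descent with momentum on
the mean-squared prediction error. Inputs and the target are min-max
scaled to [0, 1] on the training data; the per-epoch training MSE is
recorded on the original µM scale so the stopping criterion (default
0.07 µM²) is directly comparable across datasets.

The implementation is deliberately explicit — forward pass, gradients and
the momentum update are a few lines of numpy each — so the analytic
gradients can be verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FEATURE_NAMES

__all__ = [
    "NetworkConfig",
    "AffineScaler",
    "NetworkState",
    "TrainingTrace",
    "init_network",
    "forward",
    "predict_batch",
    "train",
    "loss_and_gradients",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters of the 9-18-1 regressor."""

    n_input: int = 9
    n_hidden: int = 18
    n_output: int = 1
    learning_rate: float = 0.1
    momentum: float = 0.1
    max_epochs: int = 1000
    target_mse: float = 0.07   # µM²; training stops once the trace reaches it
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("layer sizes must be >= 1")
        if not 0 <= self.learning_rate <= 1 or not 0 <= self.momentum <= 1:
            raise ValueError("learning_rate and momentum must lie in [0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.seed is None:
            raise ValueError("an explicit seed is required")


@dataclass
class AffineScaler:
    """Invertible per-dimension min-max map x -> (x - lo) / (hi - lo)."""

    lo: np.ndarray
    span: np.ndarray

    @classmethod
    def fit(cls, data: np.ndarray) -> "AffineScaler":
        data = np.atleast_2d(np.asarray(data, dtype=float))
        lo = data.min(axis=0)
        span = data.max(axis=0) - lo
        if np.any(span <= 0):
            raise ValueError("degenerate (constant) dimension; scaler undefined")
        return cls(lo=lo, span=span)

    @classmethod
    def identity(cls, ndim: int) -> "AffineScaler":
        return cls(lo=np.zeros(ndim), span=np.ones(ndim))

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.lo) / self.span

    def inverse(self, data: np.ndarray) -> np.ndarray:
        return np.asarray(data, dtype=float) * self.span + self.lo


@dataclass
class NetworkState:
    """Weights, biases, momentum buffers and fitted scalers."""

    W1: np.ndarray  # n_hidden × n_input
    b1: np.ndarray  # n_hidden
    W2: np.ndarray  # n_output × n_hidden
    b2: np.ndarray  # n_output
    vW1: np.ndarray = field(repr=False, default=None)
    vb1: np.ndarray = field(repr=False, default=None)
    vW2: np.ndarray = field(repr=False, default=None)
    vb2: np.ndarray = field(repr=False, default=None)
    feature_scaler: AffineScaler | None = None
    target_scaler: AffineScaler | None = None

    def __post_init__(self) -> None:
        for name in ("vW1", "vb1", "vW2", "vb2"):
            if getattr(self, name) is None:
                ref = getattr(self, name[1:])
                setattr(self, name, np.zeros_like(ref))


@dataclass
class TrainingTrace:
    """Per-epoch training MSE (µM² scale) and when the target was reached."""

    mse: list[float]
    epoch_reached_target: int | None = None


def init_network(cfg: NetworkConfig = NetworkConfig()) -> NetworkState:
    """Seeded initialization: uniform weights in ±init_scale, zero biases."""
    rng = np.random.default_rng(cfg.seed)
    s = cfg.init_scale
    W1 = rng.uniform(-s, s, size=(cfg.n_hidden, cfg.n_input))
    W2 = rng.uniform(-s, s, size=(cfg.n_output, cfg.n_hidden))
    return NetworkState(
        W1=W1, b1=np.zeros(cfg.n_hidden), W2=W2, b2=np.zeros(cfg.n_output)
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _require_scalers(state: NetworkState) -> None:
    if state.feature_scaler is None or state.target_scaler is None:
        raise ValueError(
            "scalers not fitted; train the network or set identity scalers"
        )


def predict_batch(state: NetworkState, X: np.ndarray) -> np.ndarray:
    """Predicted concentrations (µM) for an n×n_input feature matrix."""
    _require_scalers(state)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != state.W1.shape[1]:
        raise ValueError(
            f"feature length {X.shape[1]} != network input size {state.W1.shape[1]}"
        )
    Xs = state.feature_scaler.transform(X)
    hidden = _sigmoid(Xs @ state.W1.T + state.b1)
    ys = hidden @ state.W2.T + state.b2
    return state.target_scaler.inverse(ys)[:, 0]


def forward(state: NetworkState, x: np.ndarray) -> float:
    """Predicted concentration (µM) for a single 9-feature vector."""
    return float(predict_batch(state, np.atleast_2d(x))[0])


def loss_and_gradients(state: NetworkState, Xs: np.ndarray, ys: np.ndarray):
    """Scaled-space MSE and its gradients w.r.t. every parameter.

    Loss L = mean_i (yhat_i - y_i)^2 over the batch, computed in the
    scaled (unit-interval) space the network trains in.
    """
    n = Xs.shape[0]
    A = Xs @ state.W1.T + state.b1
    H = _sigmoid(A)
    yhat = H @ state.W2.T + state.b2
    err = yhat - ys
    loss = float(np.mean(err ** 2))

    d_out = 2.0 * err / (n * ys.shape[1])       # n × n_output
    gW2 = d_out.T @ H
    gb2 = d_out.sum(axis=0)
    d_hid = (d_out @ state.W2) * H * (1.0 - H)  # n × n_hidden
    gW1 = d_hid.T @ Xs
    gb1 = d_hid.sum(axis=0)
    return loss, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


def train(
    state: NetworkState,
    X: np.ndarray,
    y: np.ndarray,
    cfg: NetworkConfig = NetworkConfig(),
) -> tuple[NetworkState, TrainingTrace]:
    """Online backpropagation with momentum; mutates and returns state.

    Scalers are fit on (X, y). Each epoch visits every training sample
    once in a freshly shuffled order (shuffle stream seeded from
    ``cfg.seed``, so training is fully deterministic) and applies the
    momentum update v ← momentum·v − lr·grad, w ← w + v after each
    sample. The epoch's full-batch MSE is recorded on the µM scale and
    training stops as soon as it reaches ``cfg.target_mse`` (or at
    ``cfg.max_epochs``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and y must be non-empty with matching lengths")

    if X.shape[0] == 1:
        # single sample: feature span degenerate, use identity feature map
        state.feature_scaler = AffineScaler.identity(X.shape[1])
        state.target_scaler = AffineScaler(
            lo=np.zeros(1), span=np.maximum(np.abs(y[0]), 1.0)
        )
    else:
        state.feature_scaler = AffineScaler.fit(X)
        state.target_scaler = AffineScaler.fit(y)
    Xs = state.feature_scaler.transform(X)
    ys = state.target_scaler.transform(y)
    to_uM2 = float(state.target_scaler.span[0] ** 2)

    # separate stream from init_network so init and shuffling don't interact
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    trace = TrainingTrace(mse=[])
    for epoch in range(cfg.max_epochs):
        loss, _ = loss_and_gradients(state, Xs, ys)
        mse_uM = loss * to_uM2
        trace.mse.append(mse_uM)
        if mse_uM <= cfg.target_mse:
            trace.epoch_reached_target = epoch + 1
            break
        for i in shuffle_rng.permutation(Xs.shape[0]):
            _, g = loss_and_gradients(state, Xs[i:i + 1], ys[i:i + 1])
            for name in ("W1", "b1", "W2", "b2"):
                v = getattr(state, "v" + name)
                v *= cfg.momentum
                v -= cfg.learning_rate * g[name]
                getattr(state, name).__iadd__(v)
    return state, trace


# ----------------------------------------------------------------------
# persistence

def save_model(
    state: NetworkState,
    path: str | Path,
    cfg: NetworkConfig | None = None,
    trace: TrainingTrace | None = None,
) -> None:
    """Persist the model as JSON; round-trip is bit-faithful for predictions."""
    _require_scalers(state)
    doc = {
        "feature_names": list(FEATURE_NAMES),
        "weights": {k: getattr(state, k).tolist() for k in ("W1", "b1", "W2", "b2")},
        "feature_scaler": {
            "lo": state.feature_scaler.lo.tolist(),
            "span": state.feature_scaler.span.tolist(),
        },
        "target_scaler": {
            "lo": state.target_scaler.lo.tolist(),
            "span": state.target_scaler.span.tolist(),
        },
    }
    if cfg is not None:
        doc["config"] = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    if trace is not None:
        doc["trace"] = {
            "mse": trace.mse,
            "epoch_reached_target": trace.epoch_reached_target,
        }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> NetworkState:
    doc = json.loads(Path(path).read_text())
    w = {k: np.array(v, dtype=float) for k, v in doc["weights"].items()}
    state = NetworkState(**w)
    state.feature_scaler = AffineScaler(
        lo=np.array(doc["feature_scaler"]["lo"], dtype=float),
        span=np.array(doc["feature_scaler"]["span"], dtype=float),
    )
    state.target_scaler = AffineScaler(
        lo=np.array(doc["target_scaler"]["lo"], dtype=float),
        span=np.array(doc["target_scaler"]["span"], dtype=float),
    )
    return state
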