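"""Three-layer feed-forward network trained by backpropagation.

The estimator is a classic single-hidden-layer perceptron: logistic
("S-function") hidden units, a linear output unit computed as the
weighted sum of the hidden activations plus a threshold, trained by
full-batch gradient descent on the mean square error of the development
set with early stopping on the internal-validation MSE.  The candidate
hidden-layer sizes searched are 1-13; the winner is the topology with
the lowest internal-validation MSE, ties broken toward the smaller
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Optional, Tuple

import numpy as np
from numba import njit
from scipy.special import expit as _sigmoid  # numerically stable logistic

__all__ = [
    "NetworkTopology",
    "NetworkParameters",
    "TrainingConfig",
    "TrainingError",
    "forward",
    "mse",
    "gradients",
    "train_bp",
    "topology_search",
    "DEFAULT_HIDDEN_RANGE",
]

DEFAULT_HIDDEN_RANGE = range(1, 14)


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass(frozen=True)
class NetworkTopology:
    n_input: int
    n_hidden: int
    n_output: int = 1

    def __post_init__(self) -> None:
        if self.n_input < 1:
            raise ValueError("n_input must be >= 1")
        if not 1 <= self.n_hidden <= 13:
            raise ValueError(f"n_hidden must lie in 1..13, got {self.n_hidden}")
        if self.n_output != 1:
            raise ValueError("only single-output networks are supported")

    @property
    def n_parameters(self) -> int:
        """Weights plus thresholds: h·d + h + h + 1."""
        return self.n_hidden * self.n_input + 2 * self.n_hidden + 1

    def __str__(self) -> str:  # "6-2-1" style
        return f"{self.n_input}-{self.n_hidden}-{self.n_output}"


@dataclass
class NetworkParameters:
    """All weights and thresholds of the three-layer network."""

    w_hidden: np.ndarray  # (n_hidden, n_input)
    b_hidden: np.ndarray  # (n_hidden,)
    w_output: np.ndarray  # (n_hidden,)
    b_output: float

    def __post_init__(self) -> None:
        self.w_hidden = np.atleast_2d(np.asarray(self.w_hidden, dtype=float))
        self.b_hidden = np.asarray(self.b_hidden, dtype=float).ravel()
        self.w_output = np.asarray(self.w_output, dtype=float).ravel()
        self.b_output = float(self.b_output)
        h, _ = self.w_hidden.shape
        if self.b_hidden.shape != (h,) or self.w_output.shape != (h,):
            raise ValueError("parameter shapes inconsistent with topology")
        if not (
            np.all(np.isfinite(self.w_hidden))
            and np.all(np.isfinite(self.b_hidden))
            and np.all(np.isfinite(self.w_output))
            and np.isfinite(self.b_output)
        ):
            raise ValueError("network parameters must be finite")

    @property
    def topology(self) -> NetworkTopology:
        h, d = self.w_hidden.shape
        return NetworkTopology(n_input=d, n_hidden=h)

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            self.w_hidden.copy(), self.b_hidden.copy(), self.w_output.copy(), self.b_output
        )

    @classmethod
    def random(
        cls, topology: NetworkTopology, rng: np.random.Generator, scale: float = 0.5
    ) -> "NetworkParameters":
        """Uniform initialization in [-scale, scale]."""
        h, d = topology.n_hidden, topology.n_input
        return cls(
            w_hidden=rng.uniform(-scale, scale, size=(h, d)),
            b_hidden=rng.uniform(-scale, scale, size=h),
            w_output=rng.uniform(-scale, scale, size=h),
            b_output=float(rng.uniform(-scale, scale)),
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Backpropagation hyperparameters.

    Full-batch gradient descent at ``learning_rate`` for up to
    ``max_epochs`` epochs, returning the parameter snapshot with the best
    internal-validation MSE; training stops early when that best has not
    improved for ``patience`` epochs.
    """

    learning_rate: float = 0.5
    max_epochs: int = 20000
    patience: int = 2000
    seed: int = 0
    #: evaluate the internal-validation MSE every this many epochs; the
    #: early-stopping snapshot is taken over evaluated epochs only
    val_interval: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.val_interval < 1:
            raise ValueError("val_interval must be >= 1")


def forward(params: NetworkParameters, x) -> np.ndarray | float:
    """Network output for one feature vector or an (n, d) matrix.

    h = σ(W·x + θ_hidden); output = v·h + θ_out (linear output unit).
    """
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    h, d = params.w_hidden.shape
    if X.shape[1] != d:
        raise ValueError(f"input has {X.shape[1]} features, network expects {d}")
    act = _sigmoid(X @ params.w_hidden.T + params.b_hidden)
    out = act @ params.w_output + params.b_output
    return float(out[0]) if single else out


def mse(predictions, targets) -> float:
    p = np.asarray(predictions, dtype=float).ravel()
    t = np.asarray(targets, dtype=float).ravel()
    if p.size == 0 or p.size != t.size:
        raise ValueError("predictions and targets must be non-empty and equal length")
    return float(np.mean((p - t) ** 2))


def gradients(
    params: NetworkParameters, X: np.ndarray, y: np.ndarray
) -> Dict[str, np.ndarray]:
    """Analytic gradient of the MSE loss with respect to every parameter.

    Loss L = mean_i (ŷ_i − y_i)²; with a = σ(XWᵀ + b) and ŷ = a·v + c:
    ∂L/∂v = (2/n)·aᵀe, ∂L/∂c = (2/n)·Σe, and the hidden-layer terms
    backpropagate through σ' = a(1−a).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    act = _sigmoid(X @ params.w_hidden.T + params.b_hidden)  # (n, h)
    pred = act @ params.w_output + params.b_output
    err = pred - y  # (n,)
    g_out = (2.0 / n) * (act.T @ err)  # (h,)
    g_bout = (2.0 / n) * float(np.sum(err))
    delta = (err[:, None] * params.w_output[None, :]) * act * (1.0 - act)  # (n, h)
    g_hid = (2.0 / n) * (delta.T @ X)  # (h, d)
    g_bhid = (2.0 / n) * delta.sum(axis=0)  # (h,)
    return {
        "w_hidden": g_hid,
        "b_hidden": g_bhid,
        "w_output": g_out,
        "b_output": np.asarray(g_bout),
    }


@dataclass
class TrainingHistory:
    dev_mse: List[float] = field(default_factory=list)
    val_mse: List[float] = field(default_factory=list)
    best_val_mse: List[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def train_bp(
    X_dev: np.ndarray,
    y_dev: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    initial: NetworkParameters,
    config: TrainingConfig = TrainingConfig(),
) -> Tuple[NetworkParameters, TrainingHistory]:
    """Train by full-batch gradient descent, early-stopping on validation MSE.

    Returns the parameter snapshot with the lowest internal-validation
    MSE observed at any epoch (including epoch 0, i.e. the initial
    parameters), so the result never validates worse than the start.
    """
    X_dev = np.atleast_2d(np.asarray(X_dev, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_dev = np.asarray(y_dev, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if len(X_dev) == 0 or len(X_val) == 0:
        raise ValueError("development and validation sets must be non-empty")

    params = initial.copy()
    best_val0 = mse(forward(params, X_val), y_val)

    (
        wh, bh, wo, bo,
        dev_hist, val_hist, best_hist,
        best_epoch, stopped, diverged,
    ) = _bp_loop(
        X_dev, y_dev, X_val, y_val,
        params.w_hidden.copy(), params.b_hidden.copy(),
        params.w_output.copy(), float(params.b_output), best_val0,
        config.learning_rate, config.max_epochs, config.patience,
        config.val_interval,
    )
    if diverged:
        raise TrainingError(
            f"loss diverged at epoch {stopped}; try a smaller learning rate "
            f"than {config.learning_rate}"
        )
    best = (
        NetworkParameters(wh, bh, wo, bo) if best_epoch >= 0 else initial.copy()
    )
    history = TrainingHistory(
        dev_mse=dev_hist.tolist(),
        val_mse=val_hist.tolist(),
        best_val_mse=best_hist.tolist(),
        best_epoch=int(best_epoch),
        stopped_epoch=int(stopped),
    )
    return best, history


@njit(cache=False)
def _bp_loop(
    Xd, yd, Xv, yv, wh, bh, wo, bo, best_val, lr, max_epochs, patience, k
):  # pragma: no cover - exercised through train_bp
    n, d = Xd.shape
    h = wh.shape[0]
    best_wh, best_bh, best_wo, best_bo = wh.copy(), bh.copy(), wo.copy(), bo
    dev_hist = np.empty(max_epochs)
    val_hist_full = np.empty(max_epochs)
    best_hist_full = np.empty(max_epochs)
    n_val = 0
    best_epoch = -1
    since_improvement = 0
    scale = 2.0 * lr / n
    epoch = 0
    diverged = False
    for epoch in range(max_epochs):
        act = 1.0 / (1.0 + np.exp(-(Xd @ wh.T + bh)))
        err = act @ wo + bo - yd
        dev_loss = np.mean(err**2)
        if not np.isfinite(dev_loss):
            diverged = True
            break
        delta = (err.reshape(n, 1) * wo.reshape(1, h)) * act * (1.0 - act)
        wo -= scale * (act.T @ err)
        bo -= scale * np.sum(err)
        wh -= scale * (delta.T @ Xd)
        bh -= scale * delta.sum(axis=0)
        dev_hist[epoch] = dev_loss
        if epoch % k == 0 or epoch == max_epochs - 1:
            act_v = 1.0 / (1.0 + np.exp(-(Xv @ wh.T + bh)))
            err_v = act_v @ wo + bo - yv
            val_loss = np.mean(err_v**2)
            if not np.isfinite(val_loss):
                diverged = True
                break
            val_hist_full[n_val] = val_loss
            if val_loss < best_val:
                best_val = val_loss
                best_wh, best_bh, best_wo, best_bo = wh.copy(), bh.copy(), wo.copy(), bo
                best_epoch = epoch
                since_improvement = 0
            else:
                since_improvement += k
            best_hist_full[n_val] = best_val
            n_val += 1
            if patience > 0 and since_improvement >= patience:
                break
    return (
        best_wh, best_bh, best_wo, best_bo,
        dev_hist[: epoch + (0 if diverged else 1)],
        val_hist_full[:n_val],
        best_hist_full[:n_val],
        best_epoch, epoch, diverged,
    )


def topology_search(
    X_dev: np.ndarray,
    y_dev: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hidden_range: Iterable[int] = DEFAULT_HIDDEN_RANGE,
    config: TrainingConfig = TrainingConfig(),
    initializer: Optional[Callable[[NetworkTopology], NetworkParameters]] = None,
    trainer: Optional[Callable] = None,
) -> Tuple[NetworkTopology, Dict[int, float]]:
    """Search hidden-layer sizes; return the argmin of validation MSE.

    One network is trained per candidate size with the supplied
    ``initializer`` (default: seeded uniform random).  Ties break toward
    fewer hidden units.  A custom ``trainer(X_dev, y_dev, X_val, y_val,
    initial, config) -> (params, history)`` may be injected.
    """
    candidates = sorted(set(int(h) for h in hidden_range))
    if not candidates or candidates[0] < 1 or candidates[-1] > 13:
        raise ValueError("hidden_range must be a non-empty subset of 1..13")
    n_input = np.atleast_2d(np.asarray(X_dev)).shape[1]
    rng = np.random.default_rng(config.seed)
    if initializer is None:
        initializer = lambda topo: NetworkParameters.random(topo, rng)
    train = trainer if trainer is not None else train_bp

    table: Dict[int, float] = {}
    for h in candidates:
        topo = NetworkTopology(n_input=n_input, n_hidden=h)
        try:
            params, _ = train(X_dev, y_dev, X_val, y_val, initializer(topo), config)
        except TrainingError as exc:
            raise TrainingError(f"hidden size {h}: {exc}") from exc
        table[h] = mse(forward(params, X_val), y_val)
    # ties toward fewer hidden units: candidates iterated in ascending order
    best_h = min(candidates, key=lambda h: (table[h], h))
    return NetworkTopology(n_input=n_input, n_hidden=best_h), table
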