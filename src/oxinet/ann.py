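"""Feedforward regression network trained by scaled conjugate gradient.

The network maps a 300-sample downsampled SpO2 epoch to a single
events/hour index through three symmetric-sigmoid hidden layers of sizes
60, 15 and 5 and a linear scalar output.  Training is full-batch Moller
scaled conjugate gradient (SCG): conjugate search directions, a one-sided
finite-difference estimate of the Hessian-vector product along the
direction (scale ``sigma``), and Levenberg-Marquardt-style adaptation of
the scaling parameter ``lambda`` with step acceptance governed by the
comparison parameter.  Early stopping monitors validation MSE and returns
the parameters of the best-validation iteration.

Everything here is plain NumPy; there is no deep-learning framework
behind it.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SERIALIZATION_SCHEMA = 1


# ---------------------------------------------------------------------------
# activations

def symmetric_sigmoid(x: np.ndarray) -> np.ndarray:
    """2/(1+exp(-2x)) - 1, the symmetric sigmoid (identical to tanh)."""
    return np.tanh(x)


def symmetric_sigmoid_deriv(y: np.ndarray) -> np.ndarray:
    """Derivative expressed in terms of the activation value y."""
    return 1.0 - y * y


_ACTIVATIONS = {
    "symmetric_sigmoid": (symmetric_sigmoid, symmetric_sigmoid_deriv),
    "identity": (lambda x: x, lambda y: np.ones_like(y)),
}


# ---------------------------------------------------------------------------
# normalization

@dataclass
class MinMaxNorm:
    """Per-feature min-max map onto [-1, 1]; constant features map to 0."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.atleast_1d(np.asarray(self.lo, dtype=float))
        self.hi = np.atleast_1d(np.asarray(self.hi, dtype=float))

    @classmethod
    def fit(cls, data: np.ndarray) -> "MinMaxNorm":
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.size == 0:
            raise ValueError("cannot fit normalization on an empty set")
        return cls(lo=data.min(axis=0), hi=data.max(axis=0))

    @property
    def _span(self) -> np.ndarray:
        return self.hi - self.lo

    def transform(self, x: np.ndarray) -> np.ndarray:
        span = self._span
        out = np.zeros_like(np.asarray(x, dtype=float))
        nz = span != 0
        out[..., nz] = 2.0 * (x[..., nz] - self.lo[nz]) / span[nz] - 1.0
        return out

    def inverse(self, y: np.ndarray) -> np.ndarray:
        span = self._span
        out = np.broadcast_to(self.lo, np.asarray(y, dtype=float).shape).copy()
        nz = span != 0
        out[..., nz] = (np.asarray(y)[..., nz] + 1.0) / 2.0 * span[nz] + self.lo[nz]
        return out


def fit_normalization(train_inputs: np.ndarray,
                      train_targets: np.ndarray) -> tuple[MinMaxNorm, MinMaxNorm]:
    """Fit input and target min-max maps on the training data only."""
    return (MinMaxNorm.fit(train_inputs),
            MinMaxNorm.fit(np.atleast_2d(np.asarray(train_targets, float).reshape(-1, 1))))


# ---------------------------------------------------------------------------
# model

@dataclass
class MLPModel:
    """Weights, biases, activations and normalization of one network."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_activation: str = "symmetric_sigmoid"
    output_activation: str = "identity"
    input_norm: MinMaxNorm | None = None
    target_norm: MinMaxNorm | None = None

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise ValueError(f"need >= 2 positive layer sizes, got {sizes}")
        self.layer_sizes = sizes
        for layer, (w, b, nin, nout) in enumerate(
                zip(self.weights, self.biases, sizes[:-1], sizes[1:])):
            if w.shape != (nout, nin) or b.shape != (nout,):
                raise ValueError(f"inconsistent shapes at layer {layer}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes) - 1

    def _activation(self, layer: int):
        name = (self.hidden_activation if layer < self.n_layers - 1
                else self.output_activation)
        return _ACTIVATIONS[name]

    # -- parameter vector interface (for the optimizer) --

    def get_flat(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights]
                              + [b.ravel() for b in self.biases])

    def set_flat(self, theta: np.ndarray) -> None:
        k = 0
        for w in self.weights:
            w[...] = theta[k:k + w.size].reshape(w.shape)
            k += w.size
        for b in self.biases:
            b[...] = theta[k:k + b.size]
            k += b.size
        if k != theta.size:
            raise ValueError("flat parameter vector has the wrong length")

    # -- forward / loss / gradient in normalized space --

    def forward_normalized(self, xh: np.ndarray,
                           return_activations: bool = False):
        """Forward pass on already-normalized inputs, shape (n, d_in)."""
        a = np.atleast_2d(xh)
        acts = [a]
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            f, _ = self._activation(layer)
            a = f(a @ w.T + b)
            acts.append(a)
        return (a, acts) if return_activations else a

    def mse_loss(self, xh: np.ndarray, th: np.ndarray) -> float:
        """Mean over samples of squared error in normalized target space."""
        xh = np.atleast_2d(xh)
        if xh.shape[0] == 0:
            raise ValueError("empty batch")
        th = np.asarray(th, dtype=float).reshape(xh.shape[0], -1)
        pred = self.forward_normalized(xh)
        return float(np.mean(np.sum((pred - th) ** 2, axis=1)))

    def backprop_gradient(self, xh: np.ndarray, th: np.ndarray) -> np.ndarray:
        """Exact gradient of ``mse_loss`` w.r.t. the flat parameter vector."""
        xh = np.atleast_2d(xh)
        if xh.shape[0] == 0:
            raise ValueError("empty batch")
        th = np.asarray(th, dtype=float).reshape(xh.shape[0], -1)
        n = xh.shape[0]
        out, acts = self.forward_normalized(xh, return_activations=True)
        delta = 2.0 * (out - th) / n
        grads_w: list[np.ndarray] = [None] * self.n_layers
        grads_b: list[np.ndarray] = [None] * self.n_layers
        for layer in range(self.n_layers - 1, -1, -1):
            _, dfdy = self._activation(layer)
            delta = delta * dfdy(acts[layer + 1])
            grads_w[layer] = delta.T @ acts[layer]
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer]
        return np.concatenate([g.ravel() for g in grads_w]
                              + [g.ravel() for g in grads_b])

    # -- user-facing prediction in physical units --

    def predict(self, epochs: np.ndarray) -> np.ndarray:
        """Events/hour estimate per epoch; negative outputs clamped to 0."""
        x = np.atleast_2d(np.asarray(epochs, dtype=float))
        if x.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"expected epochs of length {self.layer_sizes[0]}, got {x.shape[1]}"
            )
        if self.input_norm is None or self.target_norm is None:
            raise ValueError("normalization parameters are not fitted")
        yh = self.forward_normalized(self.input_norm.transform(x))
        y = self.target_norm.inverse(yh)[:, 0]
        return np.maximum(y, 0.0)

    # -- serialization --

    def to_dict(self) -> dict:
        def b64(a: np.ndarray) -> str:
            return base64.b64encode(
                np.ascontiguousarray(a, dtype="<f8").tobytes()).decode("ascii")

        d = {
            "schema": SERIALIZATION_SCHEMA,
            "layer_sizes": list(self.layer_sizes),
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "weights": [b64(w) for w in self.weights],
            "biases": [b64(b) for b in self.biases],
        }
        for name in ("input_norm", "target_norm"):
            norm = getattr(self, name)
            d[name] = None if norm is None else {"lo": b64(norm.lo), "hi": b64(norm.hi)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        if d.get("schema") != SERIALIZATION_SCHEMA:
            raise ValueError(f"unsupported model schema {d.get('schema')!r}")

        def arr(s: str) -> np.ndarray:
            return np.frombuffer(base64.b64decode(s), dtype="<f8").copy()

        sizes = tuple(d["layer_sizes"])
        weights = [arr(s).reshape(nout, nin)
                   for s, nin, nout in zip(d["weights"], sizes[:-1], sizes[1:])]
        biases = [arr(s) for s in d["biases"]]
        norms = {}
        for name in ("input_norm", "target_norm"):
            norms[name] = (None if d[name] is None
                           else MinMaxNorm(lo=arr(d[name]["lo"]), hi=arr(d[name]["hi"])))
        return cls(layer_sizes=sizes, weights=weights, biases=biases,
                   hidden_activation=d["hidden_activation"],
                   output_activation=d["output_activation"], **norms)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def init_model(layer_sizes=(300, 60, 15, 5, 1), seed: int = 0,
               hidden_activation: str = "symmetric_sigmoid",
               output_activation: str = "identity") -> MLPModel:
    """Glorot-style scaled-uniform initialization, zero biases.

    Weights for a layer with fan_in/fan_out are drawn from
    U(-r, r) with r = sqrt(6 / (fan_in + fan_out)); reproducible from
    ``seed``.
    """
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least an input and an output layer")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for nin, nout in zip(sizes[:-1], sizes[1:]):
        r = np.sqrt(6.0 / (nin + nout))
        weights.append(rng.uniform(-r, r, size=(nout, nin)))
        biases.append(np.zeros(nout))
    return MLPModel(layer_sizes=sizes, weights=weights, biases=biases,
                    hidden_activation=hidden_activation,
                    output_activation=output_activation)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingConfig:
    """Hyperparameters of SCG training with validation-based early stopping."""

    max_iterations: int = 500
    max_val_failures: int = 100
    seed: int = 0
    sigma: float = 5e-5     # scale of the finite-difference curvature probe
    lambda0: float = 5e-7   # initial Levenberg-Marquardt scaling
    val_check_every: int = 1
    min_gradient_norm: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_val_failures < 1:
            raise ValueError("max_val_failures must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class TrainingHistory:
    """Per-iteration record of an SCG run."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    lambdas: list[float] = field(default_factory=list)
    step_success: list[bool] = field(default_factory=list)
    best_iteration: int = -1
    best_val_mse: float = np.inf
    stop_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "train_mse": self.train_mse,
            "val_mse": self.val_mse,
            "lambdas": self.lambdas,
            "step_success": self.step_success,
            "best_iteration": self.best_iteration,
            "best_val_mse": self.best_val_mse,
            "stop_reason": self.stop_reason,
        }


def scg_train(model: MLPModel, train_inputs: np.ndarray, train_targets: np.ndarray,
              val_inputs: np.ndarray, val_targets: np.ndarray,
              config: TrainingConfig | None = None,
              ) -> tuple[MLPModel, TrainingHistory]:
    """Train ``model`` in place by Moller's scaled conjugate gradient.

    Inputs/targets are given in physical units; normalization must already
    be fitted on the model (see :func:`fit_normalization`), and the loss is
    the MSE in normalized target space.  After every iteration the
    validation MSE is evaluated; when it has failed to improve on its
    running best for ``max_val_failures`` consecutive checks, training
    stops and the best-validation parameters are restored.

    Returns the model (parameters set to the best-validation iterate) and
    the full training history.
    """
    config = config or TrainingConfig()
    if model.input_norm is None or model.target_norm is None:
        raise ValueError("fit normalization before training")
    for name, arr in (("training", train_inputs), ("validation", val_inputs)):
        if np.atleast_2d(arr).shape[0] == 0:
            raise ValueError(f"empty {name} set")

    xh = model.input_norm.transform(np.atleast_2d(np.asarray(train_inputs, float)))
    th = model.target_norm.transform(
        np.asarray(train_targets, float).reshape(-1, 1))
    vxh = model.input_norm.transform(np.atleast_2d(np.asarray(val_inputs, float)))
    vth = model.target_norm.transform(
        np.asarray(val_targets, float).reshape(-1, 1))

    def loss_at(theta: np.ndarray) -> float:
        model.set_flat(theta)
        return model.mse_loss(xh, th)

    def grad_at(theta: np.ndarray) -> np.ndarray:
        model.set_flat(theta)
        return model.backprop_gradient(xh, th)

    history = TrainingHistory()
    w = model.get_flat()
    n_params = w.size
    E = loss_at(w)
    r = -grad_at(w)
    p = r.copy()
    lam = config.lambda0
    lam_bar = 0.0
    success = True
    delta = 0.0
    fail_count = 0
    best_w = w.copy()

    for k in range(1, config.max_iterations + 1):
        p_norm2 = float(p @ p)
        p_norm = np.sqrt(p_norm2)
        if p_norm < config.min_gradient_norm:
            history.stop_reason = "gradient vanished"
            break

        if success:
            # second-order estimate along p by one-sided finite difference
            sigma_k = config.sigma / p_norm
            s = (grad_at(w + sigma_k * p) - (-r)) / sigma_k
            delta = float(p @ s)

        # scale the curvature estimate
        delta = delta + (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar

        mu = float(p @ r)
        alpha = mu / delta
        E_new = loss_at(w + alpha * p)
        if not np.isfinite(E_new):
            model.set_flat(best_w)
            raise FloatingPointError(
                f"non-finite training loss at iteration {k}"
            )
        comparison = 2.0 * delta * (E - E_new) / (mu * mu) if mu != 0 else 0.0

        if comparison >= 0:  # successful step: accept the new point
            w = w + alpha * p
            E = E_new
            r_new = -grad_at(w)
            lam_bar = 0.0
            success = True
            if k % n_params == 0:  # restart the conjugate directions
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-18)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_norm2

        # bookkeeping + early stopping
        history.train_mse.append(E)
        history.lambdas.append(lam)
        history.step_success.append(bool(success))
        if k % config.val_check_every == 0:
            model.set_flat(w)
            val_mse = model.mse_loss(vxh, vth)
        else:
            val_mse = history.val_mse[-1] if history.val_mse else np.inf
        history.val_mse.append(val_mse)
        if val_mse < history.best_val_mse:
            history.best_val_mse = val_mse
            history.best_iteration = k - 1
            best_w = w.copy()
            fail_count = 0
        else:
            fail_count += 1
            if fail_count >= config.max_val_failures:
                history.stop_reason = (
                    f"validation MSE not improved for {fail_count} iterations"
                )
                break
    else:
        history.stop_reason = "max_iterations reached"

    model.set_flat(best_w)
    if history.best_iteration < 0:  # no iteration ran or none improved
        history.best_val_mse = model.mse_loss(vxh, vth)
        history.best_iteration = 0
    return model, history
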