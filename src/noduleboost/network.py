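"""Self-normalizing multiview CNN base learner (SNMV-CNN).

A compact CNN engine written directly on NumPy: convolution + SELU +
2×2 max-pooling blocks over the multiview channel stack, fully connected
SELU layers with alpha-dropout, and a single logistic output unit giving
P(nodule).  Training minimizes per-sample-weighted binary cross-entropy with
Adam, so the network slots into a boosting loop that reweights samples
between rounds.

SELU (scaled exponential linear unit),

    selu(x) = lambda * x                      for x > 0
    selu(x) = lambda * alpha * (exp(x) - 1)   for x <= 0

with alpha = 1.6733, lambda = 1.0507, together with variance-preserving
initialization (zero-mean normals, variance 1/fan-in) and alpha-dropout,
keeps activations near zero mean / unit variance through depth — the
"self-normalizing" property that removes the need for batch normalization.

Everything is deterministic given the spec's seed and a fixed data order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "SeluParams",
    "BaseLearnerSpec",
    "ConfigurationError",
    "TrainingError",
    "selu",
    "selu_grad",
    "alpha_dropout",
    "SnmvNet",
    "build_base_learner",
    "train_base_learner",
    "predict_score",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    """Invalid architecture specification."""


class TrainingError(RuntimeError):
    """Training cannot proceed (empty or single-class data)."""


@dataclass(frozen=True)
class SeluParams:
    """SELU hyperparameters; the canonical fixed-point values."""

    alpha: float = 1.6733
    lam: float = 1.0507

    def __post_init__(self) -> None:
        if not (self.alpha > 1 and self.lam > 1):
            raise ValueError("SELU requires alpha > 1 and lambda > 1")


def selu(x: np.ndarray | float, params: SeluParams = SeluParams()) -> np.ndarray:
    """SELU activation, elementwise; x = 0 takes the (vanishing) negative branch."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(
        x > 0, params.lam * x, params.lam * params.alpha * np.expm1(x)
    )


def selu_grad(x: np.ndarray, params: SeluParams = SeluParams()) -> np.ndarray:
    """d selu/dx: lambda above zero, lambda*alpha*exp(x) at or below."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, params.lam, params.lam * params.alpha * np.exp(x))


def alpha_dropout(
    x: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    params: SeluParams = SeluParams(),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Alpha-dropout: drop units to the SELU negative-saturation value.

    Dropped activations are set to alpha' = -lambda*alpha and the result is
    affinely corrected (a*x + b) so mean and variance of a standardized input
    are preserved, keeping the self-normalizing regime under dropout.

    Returns (output, keep_mask, a) — mask and scale are what the backward
    pass needs.
    """
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must be in [0, 1)")
    if rate == 0:
        return x, np.ones_like(x, dtype=bool), 1.0
    alpha_prime = -params.lam * params.alpha
    q = 1.0 - rate
    keep = rng.random(x.shape) < q
    a = (q + alpha_prime**2 * q * (1 - q)) ** -0.5
    b = -a * (1 - q) * alpha_prime
    out = a * np.where(keep, x, alpha_prime) + b
    return out, keep, a


# ---------------------------------------------------------------------------
# architecture spec


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Architecture + optimization settings of one SNMV-CNN base learner.

    Optimizer defaults are the full-scale profile: Adam with learning rate
    1e-4, first-moment momentum 0.9, binary cross-entropy, batch 128.  The
    desk-scale pipeline overrides learning_rate/batch_size/input_size to fit
    CPU budgets; the architecture fields are fully configurable.
    """

    input_size: int = 32
    n_views: int = 3
    conv_blocks: tuple[tuple[int, int], ...] = ((8, 3), (16, 3))
    fc_widths: tuple[int, ...] = (32,)
    alpha_dropout_rate: float = 0.05
    selu: SeluParams = field(default_factory=SeluParams)
    optimizer: str = "adam"
    learning_rate: float = 0.0001
    beta1: float = 0.9  # Adam first-moment momentum
    beta2: float = 0.999
    loss: str = "binary_cross_entropy"
    batch_size: int = 128
    epochs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conv_blocks or not self.fc_widths:
            raise ConfigurationError("conv_blocks and fc_widths must be non-empty")
        if not 0 <= self.alpha_dropout_rate < 1:
            raise ConfigurationError("alpha_dropout_rate must be in [0, 1)")
        size = self.input_size
        for i, (nf, k) in enumerate(self.conv_blocks):
            if nf < 1 or k < 1:
                raise ConfigurationError(f"conv block {i}: bad ({nf}, {k})")
            if size < 2 or size % 2 != 0:
                raise ConfigurationError(
                    f"conv block {i}: spatial size {size} cannot be 2x2-pooled; "
                    f"input_size {self.input_size} is too small for "
                    f"{len(self.conv_blocks)} pooling stages"
                )
            size //= 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BaseLearnerSpec":
        d = dict(d)
        if "conv_blocks" in d:
            d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
        if "fc_widths" in d:
            d["fc_widths"] = tuple(d["fc_widths"])
        if isinstance(d.get("selu"), dict):
            d["selu"] = SeluParams(**d["selu"])
        return cls(**d)


# ---------------------------------------------------------------------------
# layers (forward + backward on float64 arrays)


class _Conv2D:
    """Same-padded k×k convolution via sliding windows + GEMM."""

    def __init__(self, in_c, out_c, k, rng):
        fan_in = in_c * k * k
        self.W = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(out_c, in_c, k, k))
        self.b = np.zeros(out_c)
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (n, c, h, w, k, k) -> columns (n*h*w, c*k*k)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        out = col @ self.W.reshape(self.W.shape[0], -1).T + self.b
        self._cache = (x.shape, col)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        (n, c, h, w), col = self._cache
        k, p = self.k, self.k // 2
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, -1)  # (nhw, out_c)
        self.dW = (g.T @ col).reshape(self.W.shape)
        self.db = g.sum(axis=0)
        dcol = (g @ self.W.reshape(self.W.shape[0], -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcol[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]

    def grads(self):
        return [self.dW, self.db]


class _Selu:
    def __init__(self, params: SeluParams):
        self.p = params

    def params(self):
        return []

    def forward(self, x):
        self._x = x
        return selu(x, self.p)

    def backward(self, grad):
        return grad * selu_grad(self._x, self.p)

    def grads(self):
        return []


class _MaxPool2:
    """2×2 max-pooling, stride 2; every output dominates its window."""

    def params(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._argmax[..., None], grad[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    def grads(self):
        return []


class _Flatten:
    def params(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def grads(self):
        return [self.dW, self.db]


class _AlphaDropout:
    """Active only during training; identity at inference."""

    def __init__(self, rate, selu_params, rng):
        self.rate = rate
        self.selu_params = selu_params
        self.rng = rng
        self.training = False

    def params(self):
        return []

    def forward(self, x):
        if not self.training or self.rate == 0:
            self._mask, self._a = None, 1.0
            return x
        out, keep, a = alpha_dropout(x, self.rate, self.rng, self.selu_params)
        self._mask, self._a = keep, a
        return out

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask * self._a

    def grads(self):
        return []


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the network


class SnmvNet:
    """Multiview CNN with SELU activations and a logistic output unit.

    Views enter as channels of a single (n_views, s, s) input tensor.  The
    forward pass produces a logit; ``predict_proba`` squashes it to P(nodule).
    Construction is deterministic given ``spec.seed``.
    """

    def __init__(self, spec: BaseLearnerSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self._dropout_rng = np.random.default_rng([spec.seed, 7919])
        layers = []
        c, size = spec.n_views, spec.input_size
        for nf, k in spec.conv_blocks:
            layers.append(_Conv2D(c, nf, k, rng))
            layers.append(_Selu(spec.selu))
            layers.append(_MaxPool2())
            c, size = nf, size // 2
        layers.append(_Flatten())
        n_in = c * size * size
        for width in spec.fc_widths:
            layers.append(_Dense(n_in, width, rng))
            layers.append(_Selu(spec.selu))
            layers.append(
                _AlphaDropout(spec.alpha_dropout_rate, spec.selu, self._dropout_rng)
            )
            n_in = width
        layers.append(_Dense(n_in, 1, rng))
        self.layers = layers

    # -- plumbing

    def _set_training(self, flag: bool):
        for layer in self.layers:
            if isinstance(layer, _AlphaDropout):
                layer.training = flag

    def parameters(self):
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        expected = (self.spec.n_views, self.spec.input_size, self.spec.input_size)
        if x.shape[1:] != expected:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match learner spec {expected}"
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits, shape (n,)."""
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        return h[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    # -- public API

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(nodule) in (0,1) for a batch (or a single patch)."""
        x = self._check_input(x)
        self._set_training(False)
        return _sigmoid(self.forward(x))

    def predict_hard(self, x: np.ndarray) -> np.ndarray:
        """±1 labels; P(nodule) >= 0.5 maps to +1 (ties positive)."""
        return np.where(self.predict_proba(x) >= 0.5, 1, -1)

    def fit(
        self,
        x: np.ndarray,
        labels: np.ndarray,
        sample_weights: np.ndarray | None = None,
    ) -> "SnmvNet":
        """Minimize weighted binary cross-entropy with Adam.

        ``labels`` are ±1; ``sample_weights`` (default uniform) are
        normalized to a distribution, then rescaled to mean 1 so they act as
        per-sample loss weights without changing the effective learning rate.
        Deterministic given the spec seed and the data order.
        """
        x = self._check_input(x)
        labels = np.asarray(labels)
        n = x.shape[0]
        if n == 0:
            raise TrainingError("cannot train on an empty dataset")
        if labels.shape != (n,):
            raise TrainingError(f"labels shape {labels.shape} != ({n},)")
        if len(np.unique(labels)) < 2:
            raise TrainingError("training data contains a single class")
        y = (labels > 0).astype(np.float64)
        if sample_weights is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weights, dtype=np.float64)
            if np.any(w < 0):
                raise TrainingError("sample weights must be nonnegative")
            w = w / w.sum() * n  # mean-1 per-sample loss weights

        opt = _Adam(
            self.parameters(), self.spec.learning_rate, self.spec.beta1, self.spec.beta2
        )
        shuffle_rng = np.random.default_rng([self.spec.seed, 104729])
        self._set_training(True)
        bs = self.spec.batch_size
        for _epoch in range(self.spec.epochs):
            order = shuffle_rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                logits = self.forward(x[idx])
                # d/dlogit of mean_i w_i * BCE_i
                dlogits = w[idx] * (_sigmoid(logits) - y[idx]) / len(idx)
                self.backward(dlogits)
                opt.step(self.gradients())
        self._set_training(False)
        return self


# ---------------------------------------------------------------------------
# functional wrappers and checkpoints


def build_base_learner(spec: BaseLearnerSpec) -> SnmvNet:
    """Construct an untrained SNMV-CNN from its spec (deterministic init)."""
    return SnmvNet(spec)


def train_base_learner(
    learner: SnmvNet,
    x: np.ndarray,
    labels: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> SnmvNet:
    return learner.fit(x, labels, sample_weights)


def predict_score(learner: SnmvNet, patch: np.ndarray) -> np.ndarray | float:
    """P(nodule); scalar for a single patch, vector for a batch."""
    single = np.asarray(patch).ndim == 3
    p = learner.predict_proba(patch)
    return float(p[0]) if single else p


def save_checkpoint(learner: SnmvNet, path: str | Path) -> None:
    """NPZ of parameters + JSON sidecar with the spec for reconstruction."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(learner.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"spec": learner.spec.to_dict()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_checkpoint(path: str | Path) -> SnmvNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    net = SnmvNet(BaseLearnerSpec.from_dict(sidecar["spec"]))
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(net.parameters()):
            p[...] = data[f"p{i}"]
    return net
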