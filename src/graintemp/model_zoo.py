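"""Network building blocks and the forecasting model registry.

Everything is built from first principles on a small NumPy autodiff tape:
the LSTM cell (input/forget/output gates and candidate memory), valid 1-D
convolution with ReLU, non-overlapping max pooling, the squeeze-and-
excitation (SE) channel-attention block, and standard GRU/dense layers for
the baselines.  ``build_model`` assembles the registry used by the
ablation ladder; every network ends in a single linear unit because the
task is one-step temperature regression.

Plain-array wrappers (``lstm_cell_forward``, ``conv1d_forward``,
``se_block_forward`` ...) expose the same computations on raw arrays for
inspection and testing; they run the identical code path as the trainable
layers, just without gradient tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, conv1d, maxpool1d
from .synthetic_granary import ValidationError

__all__ = [
    "LSTMParams",
    "ConvParams",
    "SEBlockParams",
    "ModelSpec",
    "lstm_cell_forward",
    "conv1d_forward",
    "relu",
    "maxpool1d_forward",
    "se_block_forward",
    "softmax",
    "build_model",
    "MODEL_NAMES",
]

MODEL_NAMES = (
    "LSM", "BP", "GRU", "CNN", "TCN", "LSTM",
    "CNN-LSTM", "CNN-SE-LSTM", "FTA-CNN-SE-LSTM",
)

#: the four-model ladder used to attribute gains (baseline -> conv features
#: -> channel attention -> dual-domain augmentation)
LADDER = ("LSTM", "CNN-LSTM", "CNN-SE-LSTM", "FTA-CNN-SE-LSTM")


# ---------------------------------------------------------------------------
# Parameter containers (plain-array surface)
# ---------------------------------------------------------------------------


@dataclass
class LSTMParams:
    """Gate weights of one LSTM cell.

    Input-to-hidden matrices are (h, d), hidden-to-hidden are (h, h),
    biases are (h,).  Gates: i = input, f = forget, o = output, c = candidate.
    """

    W_ix: np.ndarray; W_fx: np.ndarray; W_ox: np.ndarray; W_cx: np.ndarray
    W_ih: np.ndarray; W_fh: np.ndarray; W_oh: np.ndarray; W_ch: np.ndarray
    b_i: np.ndarray; b_f: np.ndarray; b_o: np.ndarray; b_c: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.W_ix.shape
        for m in (self.W_fx, self.W_ox, self.W_cx):
            if m.shape != (h, d):
                raise ValidationError("input weight shapes inconsistent")
        for m in (self.W_ih, self.W_fh, self.W_oh, self.W_ch):
            if m.shape != (h, h):
                raise ValidationError("hidden weight shapes inconsistent")
        for b in (self.b_i, self.b_f, self.b_o, self.b_c):
            if b.shape != (h,):
                raise ValidationError("bias shapes inconsistent")


@dataclass
class ConvParams:
    """1-D convolution bank: weights (out_channels, in_channels, kernel_size)."""

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self) -> None:
        if self.weights.ndim != 3 or self.biases.shape != (self.weights.shape[0],):
            raise ValidationError("conv parameter shapes inconsistent")
        if self.weights.shape[2] < 1:
            raise ValidationError("kernel_size must be >= 1")


@dataclass
class SEBlockParams:
    """Squeeze-and-excitation gating weights: W1 (C/r, C), W2 (C, C/r)."""

    W1: np.ndarray
    W2: np.ndarray

    def __post_init__(self) -> None:
        cr, c = self.W1.shape
        if self.W2.shape != (c, cr):
            raise ValidationError("W2 must be the transpose shape of W1")
        if c % cr != 0:
            raise ValidationError("channels must be divisible by the reduction ratio")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative layer list plus the regularization hyperparameters."""

    name: str
    layers: tuple[dict, ...]
    dropout: float = 0.2
    l2: float = 1e-4


# ---------------------------------------------------------------------------
# Core block computations (shared by trainable layers and array wrappers)
# ---------------------------------------------------------------------------


def _lstm_cell(x, h_prev, c_prev, Wx, Wh, b):
    """One LSTM step on Tensors.  Wx/Wh/b are dicts keyed by gate
    ('i', 'f', 'o', 'c'); Wx entries are (d, h), Wh entries (h, h)."""
    gate = lambda k: x @ Wx[k] + h_prev @ Wh[k] + b[k]
    c_tilde = gate("c").tanh()
    i = gate("i").sigmoid()
    f = gate("f").sigmoid()
    o = gate("o").sigmoid()
    c_t = f * c_prev + i * c_tilde
    h_t = o * c_t.tanh()
    return h_t, c_t


def _se_gate(z, W1, W2):
    """Channel weights s = sigmoid(W2 relu(W1 z)) for z of shape (B, C);
    W1 is stored transposed as (C, C/r) and W2 as (C/r, C)."""
    return ((z @ W1).relu() @ W2).sigmoid()


def lstm_cell_forward(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Standard LSTM cell on plain arrays; rows are batch samples."""
    flat = np.asarray(x_t, float).ndim == 1
    x_t, h_prev, c_prev = (np.atleast_2d(np.asarray(a, float)) for a in (x_t, h_prev, c_prev))
    Wx = {k: Tensor(getattr(params, f"W_{k}x").T) for k in "ifoc"}
    Wh = {k: Tensor(getattr(params, f"W_{k}h").T) for k in "ifoc"}
    b = {k: Tensor(getattr(params, f"b_{k}")) for k in "ifoc"}
    h, c = _lstm_cell(Tensor(x_t), Tensor(h_prev), Tensor(c_prev), Wx, Wh, b)
    return (h.data[0], c.data[0]) if flat else (h.data, c.data)


def conv1d_forward(x: np.ndarray, params: ConvParams) -> np.ndarray:
    """Valid 1-D cross-correlation on plain arrays.

    x may be (L,), (C_in, L) or (B, C_in, L); the output has length
    L - kernel_size + 1 and matching leading dimensions.
    """
    x = np.asarray(x, float)
    squeeze = []
    if x.ndim == 1:
        x = x[None, None, :]
        squeeze = [0, 1]
    elif x.ndim == 2:
        x = x[None, :, :]
        squeeze = [0]
    if x.shape[2] < params.weights.shape[2]:
        raise ValidationError("input shorter than the convolution kernel")
    out = conv1d(Tensor(x), Tensor(params.weights), Tensor(params.biases)).data
    for ax in reversed(squeeze):
        out = out.squeeze(axis=ax)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, np.asarray(x, float))


def maxpool1d_forward(x: np.ndarray, pool_size: int) -> np.ndarray:
    """Non-overlapping max pooling on plain arrays (remainder truncated)."""
    x = np.asarray(x, float)
    squeeze = []
    if x.ndim == 1:
        x = x[None, None, :]
        squeeze = [0, 1]
    elif x.ndim == 2:
        x = x[None, :, :]
        squeeze = [0]
    if x.shape[2] < pool_size:
        raise ValidationError("input shorter than the pooling window")
    out = maxpool1d(Tensor(x), pool_size).data
    for ax in reversed(squeeze):
        out = out.squeeze(axis=ax)
    return out


def se_block_forward(u: np.ndarray, params: SEBlockParams) -> np.ndarray:
    """Squeeze-and-excitation on a (C, T) or (B, C, T) feature map.

    Squeeze: temporal mean per channel.  Excite: two-layer gate with ReLU
    then sigmoid.  Scale: each channel multiplied by its weight in (0, 1).
    """
    u = np.asarray(u, float)
    squeeze = u.ndim == 2
    if squeeze:
        u = u[None, :, :]
    ut = Tensor(u)
    z = ut.mean(axis=2)                              # (B, C)
    s = _se_gate(z, Tensor(params.W1.T), Tensor(params.W2.T))
    out = (ut * s.reshape(u.shape[0], u.shape[1], 1)).data
    return out[0] if squeeze else out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax.  Provided as a standalone classification
    head; none of the regression models use it."""
    x = np.asarray(x, float)
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Trainable layers
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Orthogonal recurrent initializer: preserves hidden-state norm across
    timesteps, the standard choice for recurrent weight matrices."""
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


class _Layer:
    """Base class collecting named parameters."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def _add(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self.params[name] = t
        return t


class DenseLayer(_Layer):
    def __init__(self, d_in: int, d_out: int, rng, activation: str | None = None,
                 prefix: str = "dense"):
        super().__init__()
        self.W = self._add(f"{prefix}.W", _glorot(rng, d_in, d_out, (d_in, d_out)))
        self.b = self._add(f"{prefix}.b", np.zeros(d_out))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W + self.b
        if self.activation == "relu":
            y = y.relu()
        elif self.activation == "tanh":
            y = y.tanh()
        return y


class ConvLayer(_Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng, prefix: str = "conv"):
        super().__init__()
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = self._add(f"{prefix}.W", _glorot(rng, fan_in, fan_out, (c_out, c_in, kernel)))
        self.b = self._add(f"{prefix}.b", np.zeros(c_out))
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b).relu()


class LSTMLayer(_Layer):
    def __init__(self, d_in: int, hidden: int, rng, prefix: str = "lstm"):
        super().__init__()
        self.hidden = hidden
        self.Wx = {k: self._add(f"{prefix}.Wx_{k}", _glorot(rng, d_in, hidden, (d_in, hidden)))
                   for k in "ifoc"}
        self.Wh = {k: self._add(f"{prefix}.Wh_{k}", _orthogonal(rng, hidden))
                   for k in "ifoc"}
        # unit forget-gate bias keeps the cell state flowing early in training
        self.b = {k: self._add(f"{prefix}.b_{k}",
                               np.ones(hidden) if k == "f" else np.zeros(hidden))
                  for k in "ifoc"}

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].data.shape[0]
        h = Tensor(np.zeros((batch, self.hidden)))
        c = Tensor(np.zeros((batch, self.hidden)))
        out = []
        for x in xs:
            h, c = _lstm_cell(x, h, c, self.Wx, self.Wh, self.b)
            out.append(h)
        return out


class GRULayer(_Layer):
    """Standard GRU gating; the candidate activation is configurable
    (the baseline uses ReLU)."""

    def __init__(self, d_in: int, hidden: int, rng, activation: str = "relu",
                 prefix: str = "gru"):
        super().__init__()
        self.hidden = hidden
        self.activation = activation
        self.Wx = {k: self._add(f"{prefix}.Wx_{k}", _glorot(rng, d_in, hidden, (d_in, hidden)))
                   for k in "rzn"}
        self.Wh = {k: self._add(f"{prefix}.Wh_{k}", _orthogonal(rng, hidden))
                   for k in "rzn"}
        self.b = {k: self._add(f"{prefix}.b_{k}", np.zeros(hidden)) for k in "rzn"}

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].data.shape[0]
        h = Tensor(np.zeros((batch, self.hidden)))
        out = []
        for x in xs:
            r = (x @ self.Wx["r"] + h @ self.Wh["r"] + self.b["r"]).sigmoid()
            z = (x @ self.Wx["z"] + h @ self.Wh["z"] + self.b["z"]).sigmoid()
            n_pre = x @ self.Wx["n"] + r * (h @ self.Wh["n"]) + self.b["n"]
            n = n_pre.relu() if self.activation == "relu" else n_pre.tanh()
            h = (1.0 - z) * n + z * h
            out.append(h)
        return out


class SELayer(_Layer):
    def __init__(self, channels: int, reduction: int, rng, prefix: str = "se"):
        super().__init__()
        if channels % reduction != 0:
            raise ValidationError("channels must be divisible by the reduction ratio")
        mid = channels // reduction
        # stored pre-transposed for row-batch matmul: (C, C/r) then (C/r, C)
        self.W1 = self._add(f"{prefix}.W1", _glorot(rng, channels, mid, (channels, mid)))
        self.W2 = self._add(f"{prefix}.W2", _glorot(rng, mid, channels, (mid, channels)))

    def scale_map(self, u: Tensor) -> Tensor:
        """SE over a (B, C, T) feature map."""
        s = _se_gate(u.mean(axis=2), self.W1, self.W2)
        return u * s.reshape(u.data.shape[0], u.data.shape[1], 1)

    def scale_sequence(self, hs: list[Tensor]) -> list[Tensor]:
        """SE over a sequence of (B, H) hidden states (channel = unit)."""
        z = hs[0]
        for h in hs[1:]:
            z = z + h
        s = _se_gate(z * (1.0 / len(hs)), self.W1, self.W2)
        return [h * s for h in hs]


def _dropout(x: Tensor, rate: float, rng, train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * mask


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------


class Network:
    """A forecasting network: ordered layers plus a linear output unit."""

    def __init__(self, spec: ModelSpec, lookback: int, seed: int):
        self.spec = spec
        self.lookback = lookback
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        self._layers: list[_Layer] = []
        self._rng = np.random.default_rng(seed)

    def _register(self, layer: _Layer) -> _Layer:
        self._layers.append(layer)
        self.params.update(layer.params)
        return layer

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def weight_tensors(self) -> list[Tensor]:
        """Matrices subject to L2 regularization (biases excluded)."""
        return [t for name, t in self.params.items() if not name.rsplit(".", 1)[1].startswith("b")]

    def forward(self, X: np.ndarray, train: bool = False, rng=None) -> Tensor:
        raise NotImplementedError

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(X, float), train=False).data[:, 0]


def _as_sequence(X: np.ndarray) -> list[Tensor]:
    """(B, L) window matrix viewed as L scalar timesteps of shape (B, 1)."""
    return [Tensor(X[:, t : t + 1]) for t in range(X.shape[1])]


def _timesteps(feat: Tensor) -> list[Tensor]:
    """(B, C, T) feature map viewed as T channel vectors of shape (B, C)."""
    return [feat[:, :, t] for t in range(feat.data.shape[2])]


class BPNetwork(Network):
    """Three-layer fully connected baseline: 64-ReLU, 32-ReLU, linear out."""

    def __init__(self, spec, lookback, seed):
        super().__init__(spec, lookback, seed)
        self.fc1 = self._register(DenseLayer(lookback, 64, self._rng, "relu", "fc1"))
        self.fc2 = self._register(DenseLayer(64, 32, self._rng, "relu", "fc2"))
        self.out = self._register(DenseLayer(32, 1, self._rng, None, "out"))

    def forward(self, X, train=False, rng=None):
        return self.out(self.fc2(self.fc1(Tensor(X))))


class LSTMNetwork(Network):
    """Plain LSTM baseline: one recurrent layer, then a single linear unit."""

    def __init__(self, spec, lookback, seed, hidden: int = 8):
        super().__init__(spec, lookback, seed)
        self.hidden = hidden
        self.lstm = self._register(LSTMLayer(1, hidden, self._rng, "lstm"))
        self.out = self._register(DenseLayer(hidden, 1, self._rng, None, "out"))

    def forward(self, X, train=False, rng=None):
        hs = self.lstm(_as_sequence(X))
        return self.out(hs[-1])


class GRUNetwork(Network):
    def __init__(self, spec, lookback, seed, hidden: int = 64):
        super().__init__(spec, lookback, seed)
        self.gru = self._register(GRULayer(1, hidden, self._rng, "relu", "gru"))
        self.out = self._register(DenseLayer(hidden, 1, self._rng, None, "out"))

    def forward(self, X, train=False, rng=None):
        hs = self.gru(_as_sequence(X))
        return self.out(hs[-1])


class CNNNetwork(Network):
    """Conv bank + pooling + flattening + linear head."""

    def __init__(self, spec, lookback, seed, channels: int = 64, kernel: int = 3,
                 pool: int = 2):
        super().__init__(spec, lookback, seed)
        self.pool = pool
        self.conv = self._register(ConvLayer(1, channels, kernel, self._rng, "conv"))
        t_out = (lookback - kernel + 1) // pool
        self.out = self._register(DenseLayer(channels * t_out, 1, self._rng, None, "out"))
        self._flat = channels * t_out

    def forward(self, X, train=False, rng=None):
        feat = maxpool1d(self.conv(Tensor(X[:, None, :])), self.pool)
        return self.out(feat.reshape(X.shape[0], self._flat))


class TCNNetwork(Network):
    """Small temporal-conv baseline: a causal conv layer, then two ordinary
    conv+pool stages, flatten, linear head."""

    def __init__(self, spec, lookback, seed, channels: int = 16, kernel: int = 3):
        super().__init__(spec, lookback, seed)
        self.kernel = kernel
        self.c1 = self._register(ConvLayer(1, channels, kernel, self._rng, "c1"))
        self.c2 = self._register(ConvLayer(channels, channels, kernel, self._rng, "c2"))
        self.c3 = self._register(ConvLayer(channels, channels, kernel, self._rng, "c3"))
        t = lookback                      # causal conv preserves length
        t = (t - kernel + 1) // 2         # stage 2
        t = (t - kernel + 1) // 2         # stage 3
        if t < 1:
            raise ValidationError("lookback too short for the TCN stack")
        self.out = self._register(DenseLayer(channels * t, 1, self._rng, None, "out"))
        self._flat = channels * t

    def forward(self, X, train=False, rng=None):
        padded = np.pad(X[:, None, :], ((0, 0), (0, 0), (self.kernel - 1, 0)))
        y = self.c1(Tensor(padded))
        y = maxpool1d(self.c2(y), 2)
        y = maxpool1d(self.c3(y), 2)
        return self.out(y.reshape(X.shape[0], self._flat))


class CNNLSTMNetwork(Network):
    """The ladder's hybrid: Conv(64, k3, ReLU) -> MaxPool(2) -> optional SE ->
    LSTM(64, tanh) -> Dropout -> LSTM(32, tanh) -> Dropout -> linear unit.

    ``se_position`` places the SE block either right after the conv features
    (default, matching the prose description of the architecture) or between
    the two LSTM layers (the tabulated ordering).
    """

    def __init__(self, spec, lookback, seed, use_se: bool,
                 channels: int = 64, kernel: int = 3, pool: int = 2,
                 se_reduction: int = 4, se_position: str = "after_conv"):
        super().__init__(spec, lookback, seed)
        if se_position not in ("after_conv", "between_lstm"):
            raise ValidationError("se_position must be 'after_conv' or 'between_lstm'")
        self.pool = pool
        self.use_se = use_se
        self.se_position = se_position
        self.dropout = spec.dropout
        self.conv = self._register(ConvLayer(1, channels, kernel, self._rng, "conv"))
        if use_se:
            se_channels = channels if se_position == "after_conv" else 64
            self.se = self._register(SELayer(se_channels, se_reduction, self._rng, "se"))
        self.lstm1 = self._register(LSTMLayer(channels, 64, self._rng, "lstm1"))
        self.lstm2 = self._register(LSTMLayer(64, 32, self._rng, "lstm2"))
        self.out = self._register(DenseLayer(32, 1, self._rng, None, "out"))

    def forward(self, X, train=False, rng=None):
        rng = rng or np.random.default_rng(0)
        feat = maxpool1d(self.conv(Tensor(X[:, None, :])), self.pool)
        if self.use_se and self.se_position == "after_conv":
            feat = self.se.scale_map(feat)
        hs = self.lstm1(_timesteps(feat))
        if self.use_se and self.se_position == "between_lstm":
            hs = self.se.scale_sequence(hs)
        hs = [_dropout(h, self.dropout, rng, train) for h in hs]
        h2 = self.lstm2(hs)[-1]
        h2 = _dropout(h2, self.dropout, rng, train)
        return self.out(h2)


class LeastSquaresModel:
    """Ordinary least squares on the flattened window (the LSM baseline).

    Closed-form fit via the normal equations; no iterative training.
    """

    def __init__(self, spec: ModelSpec, lookback: int, seed: int = 0):
        self.spec = spec
        self.lookback = lookback
        self.seed = seed
        self.coef: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        A = np.column_stack([np.asarray(X, float), np.ones(len(X))])
        self.coef, *_ = np.linalg.lstsq(A, np.asarray(y, float), rcond=None)

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        if self.coef is None:
            raise ValidationError("model has not been fitted")
        A = np.column_stack([np.asarray(X, float), np.ones(len(X))])
        return A @ self.coef

    def parameter_count(self) -> int:
        return self.lookback + 1


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


def _spec(name: str, layers: list[dict], dropout: float, l2: float) -> ModelSpec:
    return ModelSpec(name=name, layers=tuple(layers), dropout=dropout, l2=l2)


def build_model(
    name: str,
    lookback: int = 10,
    seed: int = 0,
    dropout: float = 0.2,
    l2: float = 1e-4,
    se_reduction: int = 4,
    se_position: str = "after_conv",
):
    """Instantiate a registry model with seeded Glorot-uniform weights."""
    if name not in MODEL_NAMES:
        raise ValidationError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    hybrid_layers = [
        {"type": "conv1d", "channels": 64, "kernel": 3, "activation": "relu"},
        {"type": "maxpool", "channels": 64, "pool": 2},
        {"type": "se", "reduction": se_reduction,
         "activation": "relu+sigmoid", "position": se_position},
        {"type": "lstm", "hidden": 64, "activation": "tanh"},
        {"type": "lstm", "hidden": 32, "activation": "tanh"},
        {"type": "dense", "units": 1, "activation": "linear"},
    ]
    if name == "LSM":
        return LeastSquaresModel(_spec(name, [{"type": "ols"}], 0.0, 0.0), lookback, seed)
    if name == "BP":
        layers = [{"type": "dense", "units": u, "activation": a}
                  for u, a in ((64, "relu"), (32, "relu"), (1, "linear"))]
        return BPNetwork(_spec(name, layers, dropout, l2), lookback, seed)
    if name == "GRU":
        layers = [{"type": "gru", "hidden": 64, "activation": "relu"},
                  {"type": "dense", "units": 1, "activation": "linear"}]
        return GRUNetwork(_spec(name, layers, dropout, l2), lookback, seed)
    if name == "CNN":
        layers = [{"type": "conv1d", "channels": 64, "kernel": 3, "activation": "relu"},
                  {"type": "maxpool", "channels": 64, "pool": 2},
                  {"type": "dense", "units": 1, "activation": "linear"}]
        return CNNNetwork(_spec(name, layers, dropout, l2), lookback, seed)
    if name == "TCN":
        layers = [{"type": "causal_conv", "channels": 16, "kernel": 3},
                  {"type": "conv1d+pool", "channels": 16, "kernel": 3},
                  {"type": "conv1d+pool", "channels": 16, "kernel": 3},
                  {"type": "dense", "units": 1, "activation": "linear"}]
        return TCNNetwork(_spec(name, layers, dropout, l2), lookback, seed)
    if name == "LSTM":
        layers = [{"type": "lstm", "hidden": 8, "activation": "tanh"},
                  {"type": "dense", "units": 1, "activation": "linear"}]
        return LSTMNetwork(_spec(name, layers, dropout, l2), lookback, seed, hidden=8)
    if name == "CNN-LSTM":
        layers = [l for l in hybrid_layers if l["type"] != "se"]
        return CNNLSTMNetwork(_spec(name, layers, dropout, l2), lookback, seed,
                              use_se=False)
    # CNN-SE-LSTM and FTA-CNN-SE-LSTM share the architecture; the FTA prefix
    # only switches on dual-domain augmentation upstream.
    return CNNLSTMNetwork(_spec(name, hybrid_layers, dropout, l2), lookback, seed,
                          use_se=True, se_reduction=se_reduction,
                          se_position=se_position)
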