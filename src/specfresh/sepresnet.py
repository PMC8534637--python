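"""A one-dimensional squeeze-and-excitation residual network, in NumPy.

The classifier maps a raw absorbance spectrum (1 channel x n wavelength
points) to two class probabilities through:

* a convolutional stem: conv -> batch norm -> activation -> max pool;
* eight residual modules. Each module runs a stacked path
  conv -> BN -> activation -> conv -> BN, recalibrates the resulting feature
  maps with a squeeze-and-excitation (SE) gate placed right after the last
  BN, adds the shortcut (identity, or a strided 1x1 projection when the
  shape changes), and applies the activation after the addition;
* global average pooling over the length axis, flatten, one fully connected
  layer, and a softmax.

The SE gate squeezes each feature map to its global average, passes the
C-vector through a bottleneck (dense C -> C/r, nonlinearity, dense C/r -> C,
sigmoid) and multiplies each channel by its gate in (0, 1). Disabling the
gate (``se_enabled=False``) yields a plain 1D-ResNet with otherwise
identical structure, which is the controlled comparison for the attention
mechanism. A shallow reference CNN (one conv block plus two dense layers)
is also provided.

Everything — forward pass, backpropagation, batch normalization statistics,
Adam — is implemented here on float64 NumPy arrays, so training is exactly
reproducible from a single integer seed. Optimization minimizes mean
cross-entropy; class order is (non-fresh, fresh) with fresh the positive
class, and probability ties resolve toward fresh.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import BuildError, ConfigError, NotFittedError

ACTIVATIONS = ("sigmoid", "relu", "elu")
CLASS_ORDER = ("non-fresh", "fresh")  # index 1 = fresh = positive


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class StemSpec:
    kernel_size: int = 7
    out_channels: int = 16
    stride: int = 1
    pool_size: int = 2


@dataclass
class StageSpec:
    out_channels: int
    kernel_size: int = 3
    stride: int = 1


def _default_stages() -> list:
    # widths double three times; stride 2 at each width increase
    widths = (16, 16, 32, 32, 64, 64, 128, 128)
    stages = []
    prev = 16
    for w in widths:
        stages.append(StageSpec(out_channels=w, stride=2 if w > prev else 1))
        prev = w
    return stages


@dataclass
class ArchitectureConfig:
    """Structural hyperparameters of the network.

    None of these are dictated by the method itself; the defaults follow
    canonical ResNet/SENet proportions scaled to spectra of a few hundred
    points, and every field can be overridden.
    """

    stem: StemSpec = field(default_factory=StemSpec)
    stages: list = field(default_factory=_default_stages)
    se_reduction_ratio: int = 8
    se_enabled: bool = True
    activation: str = "elu"
    elu_alpha: float = 1.0
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ConfigError(
                f"activation must be one of {ACTIVATIONS}, got {self.activation!r}"
            )
        if self.se_reduction_ratio < 1:
            raise ConfigError("se_reduction_ratio must be >= 1")
        if self.n_classes != 2:
            raise ConfigError("this classifier is binary (n_classes must be 2)")
        self.stages = [
            s if isinstance(s, StageSpec) else StageSpec(**s) for s in self.stages
        ]
        if isinstance(self.stem, dict):
            self.stem = StemSpec(**self.stem)
        for i, s in enumerate(self.stages):
            if s.out_channels < 1 or s.kernel_size < 1 or s.stride < 1:
                raise ConfigError(f"stage {i}: all structural values must be >= 1")

    @classmethod
    def default(cls) -> "ArchitectureConfig":
        return cls()

    @classmethod
    def compact(cls) -> "ArchitectureConfig":
        """Small preset (8 narrow stages) for quick experiments and tests."""
        widths = (8, 8, 16, 16, 24, 24, 32, 32)
        stages, prev = [], 8
        for w in widths:
            stages.append(StageSpec(out_channels=w, stride=2 if w > prev else 1))
            prev = w
        return cls(stem=StemSpec(out_channels=8), stages=stages, se_reduction_ratio=4)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    """Optimization settings; the seed is mandatory for reproducibility."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 200
    seed: int = 0
    early_stop_patience: int | None = 30

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 0:
            raise ConfigError("learning_rate > 0, batch_size >= 1, max_epochs >= 0 required")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# activation primitives (closed forms, shared by layers and `activation_eval`)
# ---------------------------------------------------------------------------


def activation_eval(name: str, x, alpha: float = 1.0):
    """Evaluate one of the three supported activations elementwise.

    sigmoid(x) = 1/(1+e^-x); relu(x) = max(x, 0);
    elu(x) = x for x >= 0 and alpha*(e^x - 1) for x < 0.
    """
    x = np.asarray(x, dtype=float)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "elu":
        return np.where(x >= 0, x, alpha * (np.expm1(x)))
    raise ConfigError(f"unknown activation {name!r}; valid: {ACTIVATIONS}")


def _activation_grad(name: str, x: np.ndarray, out: np.ndarray, alpha: float) -> np.ndarray:
    if name == "sigmoid":
        return out * (1.0 - out)
    if name == "relu":
        return (x > 0).astype(float)
    return np.where(x >= 0, 1.0, out + alpha)  # elu' = alpha*e^x = out + alpha for x<0


# ---------------------------------------------------------------------------
# primitive layers
# ---------------------------------------------------------------------------


class _Layer:
    """Base: parameterized layers fill `params`/`grads` with aligned keys."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(_Layer):
    """1-D convolution with 'same' zero padding (pad = kernel // 2)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, rng):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2
        std = np.sqrt(2.0 / (in_ch * kernel))
        self.params = {
            "W": rng.standard_normal((out_ch, in_ch, kernel)) * std,
            "b": np.zeros(out_ch),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def out_length(self, L: int) -> int:
        return (L + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._L = x.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride, :]
        self._win = win
        out = np.tensordot(win, self.params["W"], axes=([1, 3], [1, 2]))
        return out.transpose(0, 2, 1) + self.params["b"][None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        self.grads["b"] = g.sum(axis=(0, 2))
        self.grads["W"] = np.tensordot(g, self._win, axes=([0, 2], [0, 2]))
        dwin = np.tensordot(g, W, axes=([1], [0]))  # (b, Lout, Ci, k)
        b, Lout = g.shape[0], g.shape[2]
        dxp = np.zeros((b, self.in_ch, self._L + 2 * self.pad))
        for j in range(self.kernel):
            dxp[:, :, j : j + self.stride * Lout : self.stride] += dwin[
                :, :, :, j
            ].transpose(0, 2, 1)
        return dxp[:, :, self.pad : self.pad + self._L]


class BatchNorm1d(_Layer):
    """Per-channel batch normalization over (batch, length).

    Inference uses running statistics accumulated with momentum 0.1 during
    training (biased batch variance in both roles)."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(ch), "beta": np.zeros(ch)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._inv_std[None, :, None]
        self._N = x.shape[0] * x.shape[2]
        return self.params["gamma"][None, :, None] * self._xhat + self.params["beta"][None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std, N = self._xhat, self._inv_std, self._N
        self.grads["gamma"] = (g * xhat).sum(axis=(0, 2))
        self.grads["beta"] = g.sum(axis=(0, 2))
        dxhat = g * self.params["gamma"][None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / N) * (N * dxhat - s1 - xhat * s2)


class Activation(_Layer):
    def __init__(self, name: str, alpha: float = 1.0):
        super().__init__()
        self.name, self.alpha = name, alpha

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        self._out = activation_eval(self.name, x, self.alpha)
        return self._out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * _activation_grad(self.name, self._x, self._out, self.alpha)


class MaxPool1d(_Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the
    pool is dropped."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def out_length(self, L: int) -> int:
        return L // self.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, L = x.shape
        Lo = L // self.size
        self._L = L
        xv = x[:, :, : Lo * self.size].reshape(b, c, Lo, self.size)
        self._arg = xv.argmax(axis=3)
        return np.take_along_axis(xv, self._arg[..., None], axis=3)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, Lo = g.shape
        z = np.zeros((b, c, Lo, self.size))
        np.put_along_axis(z, self._arg[..., None], g[..., None], axis=3)
        out = np.zeros((b, c, self._L))
        out[:, :, : Lo * self.size] = z.reshape(b, c, Lo * self.size)
        return out


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.standard_normal((n_in, n_out)) * std, "b": np.zeros(n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class SEBlock(_Layer):
    """Squeeze-and-excitation channel gate.

    squeeze: per-channel global average over length; excitation:
    dense(C -> max(1, C//r)) -> nonlinearity -> dense(-> C) -> sigmoid;
    recalibration: channel c of the input scaled by its gate in (0, 1).
    """

    def __init__(self, ch: int, reduction: int, act_name: str, alpha: float, rng):
        super().__init__()
        self.ch = ch
        self.hidden = max(1, ch // reduction)
        self.act_name, self.alpha = act_name, alpha
        self.params = {
            "W1": rng.standard_normal((ch, self.hidden)) * np.sqrt(2.0 / ch),
            "b1": np.zeros(self.hidden),
            "W2": rng.standard_normal((self.hidden, ch)) * np.sqrt(2.0 / self.hidden),
            "b2": np.zeros(ch),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        self._L = x.shape[2]
        z = x.mean(axis=2)  # squeeze (b, C)
        self._z = z
        self._h = z @ self.params["W1"] + self.params["b1"]
        self._a = activation_eval(self.act_name, self._h, self.alpha)
        pre = self._a @ self.params["W2"] + self.params["b2"]
        self._s = 1.0 / (1.0 + np.exp(-pre))  # gates in (0,1)
        return x * self._s[:, :, None]

    @property
    def last_gates(self) -> np.ndarray:
        return self._s

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        dx = g * s[:, :, None]
        ds = (g * x).sum(axis=2)
        dpre = ds * s * (1.0 - s)
        self.grads["W2"] = self._a.T @ dpre
        self.grads["b2"] = dpre.sum(axis=0)
        da = dpre @ self.params["W2"].T
        dh = da * _activation_grad(self.act_name, self._h, self._a, self.alpha)
        self.grads["W1"] = self._z.T @ dh
        self.grads["b1"] = dh.sum(axis=0)
        dz = dh @ self.params["W1"].T
        dx += dz[:, :, None] / self._L
        return dx


class GlobalAvgPool(_Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.repeat(g[:, :, None], self._L, axis=2) / self._L


class Flatten(_Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


# ---------------------------------------------------------------------------
# composite modules
# ---------------------------------------------------------------------------


class ResidualBlock(_Layer):
    """conv-BN-act-conv-BN, SE recalibration, shortcut add, post-activation.

    The shortcut is the identity when shape is preserved, otherwise a
    strided 1x1 convolution followed by BN.
    """

    def __init__(
        self,
        in_ch: int,
        spec: StageSpec,
        se_reduction: int,
        se_enabled: bool,
        act_name: str,
        alpha: float,
        rng,
    ):
        super().__init__()
        c = spec.out_channels
        self.conv1 = Conv1d(in_ch, c, spec.kernel_size, spec.stride, rng)
        self.bn1 = BatchNorm1d(c)
        self.act1 = Activation(act_name, alpha)
        self.conv2 = Conv1d(c, c, spec.kernel_size, 1, rng)
        self.bn2 = BatchNorm1d(c)
        self.se = SEBlock(c, se_reduction, act_name, alpha, rng) if se_enabled else None
        self.projection = None
        if spec.stride != 1 or in_ch != c:
            self.proj_conv = Conv1d(in_ch, c, 1, spec.stride, rng)
            self.proj_bn = BatchNorm1d(c)
            self.projection = (self.proj_conv, self.proj_bn)
        self.act2 = Activation(act_name, alpha)

    def sublayers(self) -> Iterable[_Layer]:
        yield from (self.conv1, self.bn1, self.act1, self.conv2, self.bn2)
        if self.se is not None:
            yield self.se
        if self.projection is not None:
            yield from self.projection
        yield self.act2

    def out_length(self, L: int) -> int:
        return self.conv1.out_length(L)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.act1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        if self.se is not None:
            h = self.se.forward(h, training)
        if self.projection is not None:
            s = self.proj_bn.forward(self.proj_conv.forward(x, training), training)
        else:
            s = x
        return self.act2.forward(h + s, training)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.act2.backward(g)
        gh = g
        if self.se is not None:
            gh = self.se.backward(gh)
        gh = self.bn2.backward(gh)
        gh = self.conv2.backward(gh)
        gh = self.act1.backward(gh)
        gh = self.bn1.backward(gh)
        gh = self.conv1.backward(gh)
        if self.projection is not None:
            gs = self.proj_conv.backward(self.proj_bn.backward(g))
        else:
            gs = g
        return gh + gs


class _Network:
    """Sequential container with softmax head and parameter bookkeeping."""

    def __init__(self, layers: Sequence[_Layer], config: dict, n_wavelengths: int):
        self._layers = list(layers)
        self.config = config
        self.n_wavelengths = n_wavelengths

    def layers(self) -> Iterable[_Layer]:
        for layer in self._layers:
            if isinstance(layer, ResidualBlock):
                yield from layer.sublayers()
            else:
                yield layer

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers() for p in layer.params.values())

    def forward_logits(self, X: np.ndarray, training: bool) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        if h.ndim == 2:
            h = h[:, None, :]
        if h.shape[2] != self.n_wavelengths:
            raise ValueError(
                f"input has {h.shape[2]} wavelength points, model expects "
                f"{self.n_wavelengths}"
            )
        for layer in self._layers:
            h = layer.forward(h, training)
        return h

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self._layers):
            g = layer.backward(g)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(X, training=False))

    # -- parameter (de)serialization ------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                out[f"L{i}.{k}"] = v
            if isinstance(layer, BatchNorm1d):
                out[f"L{i}.running_mean"] = layer.running_mean
                out[f"L{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict) -> None:
        for i, layer in enumerate(self.layers()):
            for k in layer.params:
                layer.params[k] = np.array(state[f"L{i}.{k}"])
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = np.array(state[f"L{i}.running_mean"])
                layer.running_var = np.array(state[f"L{i}.running_var"])

    def copy_state(self) -> dict:
        return {k: v.copy() for k, v in self.state_arrays().items()}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def build_model(
    arch: ArchitectureConfig, n_wavelengths: int, seed: int = 0
) -> _Network:
    """Instantiate the SE-ResNet for a given grid size.

    Sequence lengths are validated stage by stage at build time; a stage
    that would reduce the length below 1 raises :class:`BuildError` naming
    the stage. Two builds with the same seed have identical parameters.
    """
    rng = np.random.default_rng(seed)
    act, alpha = arch.activation, arch.elu_alpha
    layers: list[_Layer] = []

    stem_conv = Conv1d(1, arch.stem.out_channels, arch.stem.kernel_size, arch.stem.stride, rng)
    L = stem_conv.out_length(n_wavelengths)
    if L < 1:
        raise BuildError(f"stem convolution reduces length to {L}")
    pool = MaxPool1d(arch.stem.pool_size)
    L = pool.out_length(L)
    if L < 1:
        raise BuildError("stem max-pool reduces length below 1")
    layers += [stem_conv, BatchNorm1d(arch.stem.out_channels), Activation(act, alpha), pool]

    in_ch = arch.stem.out_channels
    for i, spec in enumerate(arch.stages):
        block = ResidualBlock(
            in_ch, spec, arch.se_reduction_ratio, arch.se_enabled, act, alpha, rng
        )
        L = block.out_length(L)
        if L < 1:
            raise BuildError(f"stage {i} (out_channels={spec.out_channels}) "
                             f"reduces length below 1")
        layers.append(block)
        in_ch = spec.out_channels

    layers += [GlobalAvgPool(), Flatten(), Dense(in_ch, arch.n_classes, rng)]
    return _Network(layers, {"kind": "se-resnet", "arch": arch.to_dict()}, n_wavelengths)


def build_shallow_cnn(
    n_wavelengths: int,
    seed: int = 0,
    out_channels: int = 16,
    kernel_size: int = 7,
    pool_size: int = 2,
    hidden: int = 32,
    activation: str = "elu",
    elu_alpha: float = 1.0,
) -> _Network:
    """Reference shallow CNN: one conv block plus two dense layers."""
    rng = np.random.default_rng(seed)
    conv = Conv1d(1, out_channels, kernel_size, 1, rng)
    pool = MaxPool1d(pool_size)
    L = pool.out_length(conv.out_length(n_wavelengths))
    if L < 1:
        raise BuildError("conv block reduces length below 1")
    layers = [
        conv,
        BatchNorm1d(out_channels),
        Activation(activation, elu_alpha),
        pool,
        Flatten(),
        Dense(out_channels * L, hidden, rng),
        Activation(activation, elu_alpha),
        Dense(hidden, 2, rng),
    ]
    cfg = {
        "kind": "shallow-cnn",
        "out_channels": out_channels,
        "kernel_size": kernel_size,
        "pool_size": pool_size,
        "hidden": hidden,
        "activation": activation,
        "elu_alpha": elu_alpha,
    }
    return _Network(layers, cfg, n_wavelengths)


# ---------------------------------------------------------------------------
# standalone SE recalibration and residual forward (functional views)
# ---------------------------------------------------------------------------


def se_recalibrate(feature_maps: np.ndarray, gate_params: dict,
                   act_name: str = "elu", alpha: float = 1.0) -> np.ndarray:
    """Apply a squeeze-excitation pass to a C x H array (or batch thereof)
    with explicit gate parameters {W1, b1, W2, b2}."""
    x = np.asarray(feature_maps, dtype=float)
    squeeze_batch = x.ndim == 2
    if squeeze_batch:
        x = x[None]
    z = x.mean(axis=2)
    a = activation_eval(act_name, z @ gate_params["W1"] + gate_params["b1"], alpha)
    s = 1.0 / (1.0 + np.exp(-(a @ gate_params["W2"] + gate_params["b2"])))
    out = x * s[:, :, None]
    return out[0] if squeeze_batch else out


def residual_forward(x: np.ndarray, block: ResidualBlock) -> np.ndarray:
    """Inference-mode forward pass of one residual module."""
    x = np.asarray(x, dtype=float)
    squeeze_batch = x.ndim == 2
    if squeeze_batch:
        x = x[None]
    out = block.forward(x, training=False)
    return out[0] if squeeze_batch else out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, model: _Network, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = [
            (layer, key, np.zeros_like(v), np.zeros_like(v))
            for layer in model.layers()
            for key, v in layer.params.items()
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, key, m, v in self.slots:
            g = layer.grads[key]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            layer.params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))))


def train_model(
    model: _Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    val: tuple[np.ndarray, np.ndarray] | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[_Network, TrainHistory]:
    """Minimize mean cross-entropy with Adam.

    ``y`` uses the integer coding (fresh = 1). When a validation set and an
    early-stop patience are given, training stops after ``patience`` epochs
    without a new best validation loss and the best-epoch weights are
    restored. Fully reproducible given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; "
                         "cross-entropy training is degenerate for the task")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, cfg.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_state = None
    stale = 0

    for _ in range(cfg.max_epochs):
        order = rng.permutation(len(y))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(y), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward_logits(xb, training=True)
            probs = softmax(logits)
            losses.append(_cross_entropy(probs, yb) * len(yb))
            hits += int(np.sum(_argmax_fresh(probs) == yb))
            seen += len(yb)
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            model.backward(grad / len(yb))
            opt.step()
        history.train_loss.append(float(np.sum(losses) / seen))
        history.train_acc.append(hits / seen)

        if val is not None:
            Xv, yv = val
            pv = model.predict_proba(Xv)
            vloss = _cross_entropy(pv, np.asarray(yv, dtype=int))
            history.val_loss.append(vloss)
            history.val_acc.append(float(np.mean(_argmax_fresh(pv) == yv)))
            if cfg.early_stop_patience is not None:
                if vloss < best_val - 1e-12:
                    best_val, best_state, stale = vloss, model.copy_state(), 0
                else:
                    stale += 1
                    if stale >= cfg.early_stop_patience:
                        break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def _argmax_fresh(probs: np.ndarray) -> np.ndarray:
    """Argmax with ties resolved toward the positive (fresh) class."""
    return (probs[:, 1] >= probs[:, 0]).astype(int)


def predict(model: _Network, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (fresh = 1) and softmax probabilities."""
    probs = model.predict_proba(X)
    return _argmax_fresh(probs), probs


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: _Network, path: str | Path) -> Path:
    """Single-file checkpoint: config JSON plus all parameter arrays."""
    path = Path(path)
    state = model.state_arrays()
    np.savez(
        path,
        __config__=json.dumps(model.config),
        __n_wavelengths__=model.n_wavelengths,
        **state,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> _Network:
    with np.load(Path(path), allow_pickle=False) as data:
        config = json.loads(str(data["__config__"]))
        n_wl = int(data["__n_wavelengths__"])
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    if config["kind"] == "se-resnet":
        model = build_model(ArchitectureConfig.from_dict(config["arch"]), n_wl)
    else:
        cfg = {k: v for k, v in config.items() if k != "kind"}
        model = build_shallow_cnn(n_wl, **cfg)
    model.load_state_arrays(state)
    return model


# ---------------------------------------------------------------------------
# sklearn-style wrapper used by the nested-CV harness
# ---------------------------------------------------------------------------


class NetworkClassifier:
    """fit/predict facade over build + train for the CV harness.

    ``variant`` is ``"se-resnet"`` (default), ``"resnet"`` (SE gates
    disabled) or ``"cnn"`` (shallow reference CNN). Training inside the
    harness runs a fixed number of epochs without early stopping so folds
    are strictly comparable.
    """

    def __init__(
        self,
        variant: str = "se-resnet",
        arch: ArchitectureConfig | None = None,
        epochs: int = 60,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        seed: int = 0,
    ):
        if variant not in ("se-resnet", "resnet", "cnn"):
            raise ConfigError(f"unknown variant {variant!r}")
        self.variant = variant
        self.arch = arch
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self._model: _Network | None = None

    def _build(self, n_wavelengths: int) -> _Network:
        if self.variant == "cnn":
            return build_shallow_cnn(n_wavelengths, seed=self.seed)
        arch = self.arch or ArchitectureConfig.default()
        if self.variant == "resnet":
            arch = ArchitectureConfig.from_dict({**arch.to_dict(), "se_enabled": False})
        return build_model(arch, n_wavelengths, seed=self.seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NetworkClassifier":
        self._model = self._build(np.asarray(X).shape[1])
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.epochs,
            seed=self.seed,
            early_stop_patience=None,
        )
        self._model, self.history_ = train_model(self._model, X, y, cfg=cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise NotFittedError("classifier used before fit")
        return predict(self._model, X)[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise NotFittedError("classifier used before fit")
        return self._model.predict_proba(X)
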