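"""Residual dilated grouped-convolution network for paired splice-site scoring.

The network maps a one-hot encoded 800-nt window pair (4 x 800) to per-base
class probabilities (3 x 800; channels = neither / acceptor / donor).  Its
shape is controlled by four hyperparameters: ``F`` filters per convolution,
per-group kernel width ``W``, per-group dilation ``D``, and the grouped
convolution group count ``G`` used inside residual units.  Twenty residual
units are arranged in five residual groups; the output of every residual
group is folded into a pointwise skip sum, which a final pointwise
convolution and per-position softmax turn into class probabilities.

Everything here is plain numpy with explicit backward passes.  Convolutions
are evaluated as grouped im2col matrix products against single-threaded
BLAS; internally all activations live in channels-first ``(C, B, L)`` layout
and im2col buffers are built in small batch chunks so they stay cache
resident.  Training and inference are deterministic bit-for-bit for a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ModelConfig",
    "ConvSpec",
    "Parameter",
    "SpliceSiteNet",
    "build_model",
    "count_parameters",
    "receptive_span",
    "dilated_conv1d_oracle",
    "save_model",
    "load_model",
]

_F32 = np.float32
_CHUNK = 4  # batch elements per im2col chunk; keeps cols in cache


@dataclass
class ModelConfig:
    """Hyperparameter schedule defining the network.

    Defaults reproduce the published architecture: F=64 filters everywhere,
    five residual groups of four residual units, kernel widths
    [11, 11, 11, 21, 21], dilations [1, 5, 10, 15, 20], and grouped
    convolutions with G=4 inside residual units.
    """

    n_channels: int = 64
    group_window: list[int] = field(default_factory=lambda: [11, 11, 11, 21, 21])
    group_dilation: list[int] = field(default_factory=lambda: [1, 5, 10, 15, 20])
    ru_groups: int = 4
    rus_per_group: int = 4
    n_groups: int = 5
    lrelu_slope: float = 0.1
    in_channels: int = 4
    out_channels: int = 3
    window_length: int = 800

    def __post_init__(self) -> None:
        if len(self.group_window) != self.n_groups or len(self.group_dilation) != self.n_groups:
            raise ValueError("group_window and group_dilation must have n_groups entries")
        if any(w < 1 or w % 2 == 0 for w in self.group_window):
            raise ValueError("kernel widths must be odd and >= 1")
        if any(d < 1 for d in self.group_dilation):
            raise ValueError("dilations must be >= 1")
        if self.n_channels % self.ru_groups != 0:
            raise ValueError("n_channels must be divisible by ru_groups")
        if self.window_length % 2 != 0:
            raise ValueError("window_length must be even")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ConvSpec:
    """Shape of one (possibly grouped, dilated) 1-D convolution."""

    in_features: int
    out_features: int
    width: int
    dilation: int = 1
    groups: int = 1

    def __post_init__(self) -> None:
        if self.in_features % self.groups or self.out_features % self.groups:
            raise ValueError("channel counts must be divisible by groups")

    @property
    def n_parameters(self) -> int:
        return self.out_features * (self.in_features // self.groups) * self.width + self.out_features


class Parameter:
    """A trainable array together with its gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=_F32)
        self.grad = np.zeros_like(self.data)


# ---------------------------------------------------------------------------
# layers (all activations are (channels, batch, length) float32)


class Conv1d:
    """Grouped dilated 1-D convolution with 'same' zero padding.

    Weight layout is (out_channels, in_channels // groups, width); output
    channel ``g * (out/G) + o`` reads input channels ``[g*in/G, (g+1)*in/G)``.
    """

    def __init__(self, spec: ConvSpec, rng: np.random.Generator):
        self.spec = spec
        fan_in = (spec.in_features // spec.groups) * spec.width
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(spec.out_features, spec.in_features // spec.groups, spec.width))
        )
        self.bias = Parameter(np.zeros(spec.out_features))
        self.pad = spec.dilation * (spec.width - 1) // 2
        self._x: np.ndarray | None = None  # cached (padded) input, training only
        self._colbufs: dict = {}

    def parameters(self):
        return [self.weight, self.bias]

    def _cols(self, b: int, length: int):
        s = self.spec
        key = (b, length)
        buf = self._colbufs.get(key)
        if buf is None:
            ci = s.in_features // s.groups
            buf = np.empty((s.groups, ci, s.width, b, length), dtype=_F32)
            self._colbufs = {key: buf}  # keep at most one
        return buf

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = self.spec
        C, B, L = x.shape
        if C != s.in_features:
            raise ValueError(f"expected {s.in_features} input channels, got {C}")
        G, W, D = s.groups, s.width, s.dilation
        Ci, Co = C // G, s.out_features // G
        if W == 1 and G == 1:
            if training:
                self._x = x
            out = self.weight.data[:, :, 0] @ x.reshape(C, B * L)
            out = out.reshape(s.out_features, B, L)
            out += self.bias.data[:, None, None]
            return out
        Lp = L + 2 * self.pad
        if self.pad:
            xp = np.zeros((C, B, Lp), dtype=_F32)
            xp[:, :, self.pad : self.pad + L] = x
        else:
            xp = np.ascontiguousarray(x, dtype=_F32)
        if training:
            self._x = xp
        xg = xp.reshape(G, Ci, B, Lp)
        wg = self.weight.data.reshape(G, Co, Ci * W)
        out = np.empty((G, Co, B, L), dtype=_F32)
        for i in range(0, B, _CHUNK):
            b = min(_CHUNK, B - i)
            cols = self._cols(b, L)
            for t in range(W):
                cols[:, :, t] = xg[:, :, i : i + b, t * D : t * D + L]
            o = np.matmul(wg, cols.reshape(G, Ci * W, b * L))
            out[:, :, i : i + b] = o.reshape(G, Co, b, L)
        out = out.reshape(s.out_features, B, L)
        out += self.bias.data[:, None, None]
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        s = self.spec
        O, B, L = gy.shape
        C = s.in_features
        G, W, D = s.groups, s.width, s.dilation
        Ci, Co = C // G, O // G
        self.bias.grad += gy.sum(axis=(1, 2))
        if W == 1 and G == 1:
            x = self._x
            self._x = None
            g2 = gy.reshape(O, B * L)
            self.weight.grad += (g2 @ x.reshape(C, B * L).T)[:, :, None]
            return (self.weight.data[:, :, 0].T @ g2).reshape(C, B, L)
        xp = self._x
        self._x = None
        Lp = xp.shape[2]
        xg = xp.reshape(G, Ci, B, Lp)
        # batch-chunk slices of (G, Co, B*L) are plain column blocks: no copy
        gyf = np.ascontiguousarray(gy).reshape(G, Co, B * L)
        gxp = np.zeros((G, Ci, B, Lp), dtype=_F32)
        gwg = np.zeros((G, Co, Ci * W), dtype=_F32)
        wgT = np.ascontiguousarray(self.weight.data.reshape(G, Co, Ci * W).transpose(0, 2, 1))
        for i in range(0, B, _CHUNK):
            b = min(_CHUNK, B - i)
            cols = self._cols(b, L)
            for t in range(W):
                cols[:, :, t] = xg[:, :, i : i + b, t * D : t * D + L]
            gt = gyf[:, :, i * L : (i + b) * L]
            gwg += np.matmul(gt, cols.reshape(G, Ci * W, b * L).transpose(0, 2, 1))
            dcols = np.matmul(wgT, gt).reshape(G, Ci, W, b, L)
            for t in range(W):
                gxp[:, :, i : i + b, t * D : t * D + L] += dcols[:, :, t]
        self.weight.grad += gwg.reshape(O, Ci, W)
        if self.pad:
            return np.ascontiguousarray(
                gxp.reshape(C, B, Lp)[:, :, self.pad : self.pad + L]
            )
        return gxp.reshape(C, B, L)


class BatchNorm1d:
    """Per-channel batch normalization with affine scale/shift.

    Only gamma/beta are trainable; running statistics are tracked for
    evaluation mode and are not counted as parameters.
    """

    def __init__(self, n_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_channels, dtype=_F32)
        self.running_var = np.ones(n_channels, dtype=_F32)
        self._xhat: np.ndarray | None = None
        self._invstd: np.ndarray | None = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(1, 2))
            xhat = x - mean[:, None, None]
            var = np.mean(xhat * xhat, axis=(1, 2))
            m = self.momentum
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (var - self.running_var)
            invstd = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
            xhat *= invstd[:, None, None]
            self._xhat, self._invstd = xhat, invstd
        else:
            invstd = (1.0 / np.sqrt(self.running_var + self.eps)).astype(_F32)
            xhat = (x - self.running_mean[:, None, None]) * invstd[:, None, None]
        out = xhat * self.gamma.data[:, None, None]
        out += self.beta.data[:, None, None]
        return out.astype(_F32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self._xhat = self._invstd = None
        n = gy.shape[1] * gy.shape[2]
        self.gamma.grad += (gy * xhat).sum(axis=(1, 2))
        self.beta.grad += gy.sum(axis=(1, 2))
        gxhat = gy * self.gamma.data[:, None, None]
        s1 = gxhat.sum(axis=(1, 2), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(1, 2), keepdims=True)
        gx = gxhat - s1 / n - xhat * (s2 / n)
        gx *= invstd[:, None, None]
        return gx.astype(_F32, copy=False)


class LeakyReLU:
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._factor: np.ndarray | None = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # elementwise multiplier (1 where x >= 0, slope elsewhere); doubles
        # as the derivative in backward
        factor = (x > 0).astype(_F32)
        factor *= _F32(1.0 - self.slope)
        factor += _F32(self.slope)
        if training:
            self._factor = factor
        return x * factor

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._factor
        self._factor = None
        return gx


class ResidualUnit:
    """Pre-activation residual unit: 2 x (BN -> LReLU -> grouped dilated conv),
    with an identity shortcut around the pair."""

    def __init__(self, channels: int, width: int, dilation: int, groups: int,
                 slope: float, rng: np.random.Generator):
        spec = ConvSpec(channels, channels, width, dilation, groups)
        self.bn1 = BatchNorm1d(channels)
        self.act1 = LeakyReLU(slope)
        self.conv1 = Conv1d(spec, rng)
        self.bn2 = BatchNorm1d(channels)
        self.act2 = LeakyReLU(slope)
        self.conv2 = Conv1d(spec, rng)
        # zero-init the closing conv so each unit starts as the identity;
        # keeps activation variance flat across the 20-unit stack at init
        self.conv2.weight.data[...] = 0.0
        self.width = width
        self.dilation = dilation

    def sublayers(self):
        return [self.bn1, self.act1, self.conv1, self.bn2, self.act2, self.conv2]

    def parameters(self):
        return [p for m in self.sublayers() for p in m.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.conv1.forward(self.act1.forward(self.bn1.forward(x, training), training), training)
        h = self.conv2.forward(self.act2.forward(self.bn2.forward(h, training), training), training)
        h += x
        return h

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.bn2.backward(self.act2.backward(self.conv2.backward(gy)))
        g = self.bn1.backward(self.act1.backward(self.conv1.backward(g)))
        return gy + g


class SpliceSiteNet:
    """The full scorer: entry conv, residual groups, pointwise skip sum, softmax.

    ``forward`` takes (batch, in_channels, window_length) one-hot input and
    returns per-position class probabilities of the same batch shape with
    ``out_channels`` channels; every position's probabilities sum to 1.
    ``backward`` expects the gradient of the loss with respect to those
    probabilities and propagates it through the softmax and the body.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        F = config.n_channels
        self.conv_entry = Conv1d(ConvSpec(config.in_channels, F, 1), rng)
        self.conv_skip = Conv1d(ConvSpec(F, F, 1), rng)
        self.groups: list[list[ResidualUnit]] = []
        self.group_convs: list[Conv1d] = []
        for w, d in zip(config.group_window, config.group_dilation):
            units = [
                ResidualUnit(F, w, d, config.ru_groups, config.lrelu_slope, rng)
                for _ in range(config.rus_per_group)
            ]
            self.groups.append(units)
            self.group_convs.append(Conv1d(ConvSpec(F, F, 1), rng))
        self.conv_final = Conv1d(ConvSpec(F, F, 1), rng)
        self.conv_out = Conv1d(ConvSpec(F, config.out_channels, 1), rng)
        # start the output at the class prior (rare acceptor/donor classes
        # near 1%) so early training is not dominated by the overwhelming
        # neither class: zero output weights + prior log-odds in the bias
        self.conv_out.weight.data[...] = 0.0
        if config.out_channels == 3:
            self.conv_out.bias.data[1:] = np.log(0.01)
        self._probs: np.ndarray | None = None  # (out, B, L), training only

    # -- structure ----------------------------------------------------------

    @property
    def residual_units(self) -> list[ResidualUnit]:
        return [u for g in self.groups for u in g]

    @property
    def pointwise_skip_convs(self) -> list[Conv1d]:
        """The F->F pointwise convolutions feeding the skip sum."""
        return [self.conv_skip, *self.group_convs, self.conv_final]

    def modules(self):
        mods = [self.conv_entry, self.conv_skip]
        for units, gconv in zip(self.groups, self.group_convs):
            for u in units:
                mods.extend(u.sublayers())
            mods.append(gconv)
        mods.extend([self.conv_final, self.conv_out])
        return mods

    def parameters(self) -> list[Parameter]:
        return [p for m in self.modules() for p in m.parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def describe(self) -> list[dict]:
        """Ordered layer list with shapes, for inspection and sidecar files."""
        out = []
        for m in self.modules():
            if isinstance(m, Conv1d):
                out.append({"layer": "conv1d", **asdict(m.spec)})
            elif isinstance(m, BatchNorm1d):
                out.append({"layer": "batchnorm1d", "channels": m.gamma.data.size})
            elif isinstance(m, LeakyReLU):
                out.append({"layer": "leaky_relu", "slope": m.slope})
        return out

    # -- computation --------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cfg = self.config
        if x.ndim != 3 or x.shape[1] != cfg.in_channels or x.shape[2] != cfg.window_length:
            raise ValueError(
                f"expected input of shape (B, {cfg.in_channels}, {cfg.window_length}), got {x.shape}"
            )
        xi = np.ascontiguousarray(np.asarray(x, dtype=_F32).transpose(1, 0, 2))
        h = self.conv_entry.forward(xi, training)
        skip = self.conv_skip.forward(h, training)
        for units, gconv in zip(self.groups, self.group_convs):
            for u in units:
                h = u.forward(h, training)
            skip += gconv.forward(h, training)
        skip += self.conv_final.forward(h, training)
        z = self.conv_out.forward(skip, training)
        z -= z.max(axis=0, keepdims=True)
        np.exp(z, out=z)
        z /= z.sum(axis=0, keepdims=True)
        if training:
            self._probs = z
        return np.ascontiguousarray(z.transpose(1, 0, 2))

    def backward(self, gprobs: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probs) through softmax and the body."""
        p = self._probs
        gp = np.ascontiguousarray(np.asarray(gprobs, dtype=_F32).transpose(1, 0, 2))
        gz = p * (gp - (gp * p).sum(axis=0, keepdims=True))
        self.backward_logits(gz.transpose(1, 0, 2))

    def backward_logits(self, glogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits) (softmax Jacobian already folded in)."""
        self._probs = None
        gz = np.ascontiguousarray(np.asarray(glogits, dtype=_F32).transpose(1, 0, 2))
        gskip = self.conv_out.backward(gz)
        gh = self.conv_final.backward(gskip)
        for units, gconv in zip(reversed(self.groups), reversed(self.group_convs)):
            gh += gconv.backward(gskip)
            for u in reversed(units):
                gh = u.backward(gh)
        gh += self.conv_skip.backward(gskip)
        self.conv_entry.backward(gh)

    def predict(self, x: np.ndarray, batch_size: int = 100) -> np.ndarray:
        """Evaluation-mode forward in mini-batches; returns (N, 3, L) probabilities."""
        if len(x) == 0:
            return np.zeros((0, self.config.out_channels, self.config.window_length), _F32)
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SpliceSiteNet:
    """Build the network from a configuration (defaults = published schedule)."""
    return SpliceSiteNet(config or ModelConfig(), seed=seed)


def count_parameters(network) -> int:
    """Number of trainable scalars (conv weights+biases, BN scale+shift).

    Accepts a network / layer exposing ``parameters()`` or any iterable of
    such objects; an empty iterable counts zero.
    """
    if hasattr(network, "parameters"):
        return int(sum(p.data.size for p in network.parameters()))
    return int(sum(count_parameters(item) for item in network))


def receptive_span(config: ModelConfig) -> int:
    """Total neighboring span S = sum over residual units of 2 * D * (W - 1)."""
    return int(
        config.rus_per_group
        * sum(2 * d * (w - 1) for w, d in zip(config.group_window, config.group_dilation))
    )


def dilated_conv1d_oracle(x: np.ndarray, kernel: np.ndarray, dilation: int = 1) -> np.ndarray:
    """Reference dilated convolution by direct summation over {(s, t): s + D*t = n}.

    ``x`` is (C_in, L) (a 1-D array is treated as one channel) and ``kernel``
    is (C_out, C_in, W) (a 1-D array as a single-channel kernel).  The output
    covers every reachable index n in [0, (L-1) + D*(W-1)].  Used only as a
    test oracle for the framework convolution.
    """
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim == 1:
        kernel = kernel[None, None, :]
    c_out, c_in, width = kernel.shape
    n_out = x.shape[1] + dilation * (width - 1)
    out = np.zeros((c_out, n_out))
    for o in range(c_out):
        for n in range(n_out):
            acc = 0.0
            for t in range(width):
                s = n - dilation * t
                if 0 <= s < x.shape[1]:
                    acc += float(x[:, s] @ kernel[o, :, t])
            out[o, n] = acc
    return out


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON config sidecar


def save_model(net: SpliceSiteNet, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, p in enumerate(net.parameters()):
        arrays[f"p{i}"] = p.data
    for i, m in enumerate(net.modules()):
        if isinstance(m, BatchNorm1d):
            arrays[f"rm{i}"] = m.running_mean
            arrays[f"rv{i}"] = m.running_var
    np.savez(str(prefix) + ".npz", **arrays)
    Path(str(prefix) + ".json").write_text(net.config.to_json())


def load_model(prefix: str | Path) -> SpliceSiteNet:
    prefix = str(prefix)
    config = ModelConfig.from_json(Path(prefix + ".json").read_text())
    net = SpliceSiteNet(config, seed=0)
    with np.load(prefix + ".npz") as data:
        for i, p in enumerate(net.parameters()):
            p.data[...] = data[f"p{i}"]
        for i, m in enumerate(net.modules()):
            if isinstance(m, BatchNorm1d):
                m.running_mean[...] = data[f"rm{i}"]
                m.running_var[...] = data[f"rv{i}"]
    return net
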