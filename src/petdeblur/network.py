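"""A 3D sequential dilated residual network, implemented in numpy.

The architecture is a fully convolutional stack of modules, each a 3x3x3
convolution (zero-padded by its dilation so spatial shape is preserved)
followed by batch normalization and a ReLU.  Modules are grouped in stages
of constant channel count and dilation; the default -- seven modules of 16
channels at dilation 1, six of 32 at dilation 2, six of 64 at dilation 4,
nineteen modules in all -- widens the receptive field to 89 voxels per axis
without any resampling, so resolution is maintained throughout.  A final
linear 3x3x3 convolution maps to one channel, and a global residual
connection adds the input to that output: the network learns the correction
from a degraded volume to its ground truth, and with all weights zero it is
exactly the identity.

Forward and backward passes are written against BLAS-backed matmul (one
GEMM per kernel tap), which is fast enough for desk-scale training and
keeps the package free of GPU framework dependencies.  Convolution inputs
are float32 by default; float64 is available where tighter agreement
matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import ConfigurationError

_TAPS = list(product(range(3), repeat=3))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: stages of (module_count, channels, dilation)."""

    stages: tuple[tuple[int, int, int], ...] = ((7, 16, 1), (6, 32, 2), (6, 64, 4))
    kernel_size: int = 3
    normalization: str = "batch"  # "batch" or "none"
    global_residual: bool = True
    zero_init_residual: bool = True
    dtype: str = "float32"

    def validate(self) -> None:
        if not self.stages:
            raise ConfigurationError("stage list must be non-empty")
        for m, c, d in self.stages:
            if m < 1 or c < 1 or d < 1:
                raise ConfigurationError(
                    f"invalid stage ({m}, {c}, {d}): counts, channels and "
                    "dilations must be positive integers"
                )
        if self.kernel_size != 3:
            raise ConfigurationError("only 3x3x3 kernels are supported")
        if self.normalization not in ("batch", "none"):
            raise ConfigurationError("normalization must be 'batch' or 'none'")

    @property
    def module_count(self) -> int:
        """Number of conv-norm-ReLU modules before the output convolution."""
        return sum(m for m, _, _ in self.stages)

    @property
    def receptive_field(self) -> int:
        """Theoretical receptive-field edge length in voxels per axis.

        Each 3x3x3 convolution at dilation d grows the field by 2d; the
        output convolution (dilation 1) contributes a final 2.
        """
        r = 1
        for m, _, d in self.stages:
            r += 2 * d * m
        return r + 2  # output convolution


def count_parameters(spec: NetworkSpec, in_channels: int = 1) -> int:
    """Exact learnable-parameter count from the spec arithmetic."""
    spec.validate()
    k3 = spec.kernel_size**3
    total = 0
    cin = in_channels
    for m, c, _ in spec.stages:
        for _ in range(m):
            total += k3 * cin * c + c  # conv weight + bias
            if spec.normalization == "batch":
                total += 2 * c  # gain + shift
            cin = c
    total += k3 * cin * 1 + 1  # output convolution
    return total


class _Conv3d:
    """3x3x3 convolution, stride 1, zero padding equal to the dilation.

    One small GEMM per kernel tap; the contiguous tap slices built during
    the training forward are kept and reused by the backward pass, which
    trades memory for bandwidth (the dominant cost on one core).
    """

    def __init__(self, cin, cout, dilation, rng, dtype, zero_init=False):
        self.cin, self.cout, self.dilation = cin, cout, dilation
        fan_in = 27 * cin
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.w = (scale * rng.standard_normal((cout, cin, 3, 3, 3))).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._slices = None
        self._shape = None

    def forward(self, x, training):
        d = self.dilation
        B, C, D, H, W = x.shape
        n = D * H * W
        xp = np.pad(x, ((0, 0), (0, 0), (d, d), (d, d), (d, d)))
        slices = []
        y = np.broadcast_to(self.b.reshape(1, self.cout, 1), (B, self.cout, n)).copy()
        for i, j, k in _TAPS:
            sl = np.ascontiguousarray(
                xp[:, :, i * d:i * d + D, j * d:j * d + H, k * d:k * d + W]
            ).reshape(B, C, n)
            y += self.w[:, :, i, j, k] @ sl
            if training:
                slices.append(sl)
        if training:
            self._slices = slices
            self._shape = (B, C, D, H, W)
        return y.reshape(B, self.cout, D, H, W)

    def backward(self, dy):
        B, C, D, H, W = self._shape
        d = self.dilation
        n = D * H * W
        dyf = np.ascontiguousarray(dy.reshape(B, self.cout, n))
        self.gb[:] = dyf.sum(axis=(0, 2))
        dxp = np.zeros((B, C, D + 2 * d, H + 2 * d, W + 2 * d), dtype=dy.dtype)
        for (i, j, k), sl in zip(_TAPS, self._slices):
            self.gw[:, :, i, j, k] = np.tensordot(
                dyf, sl, axes=([0, 2], [0, 2])
            )
            dxp[:, :, i * d:i * d + D, j * d:j * d + H, k * d:k * d + W] += (
                self.w[:, :, i, j, k].T @ dyf
            ).reshape(B, C, D, H, W)
        self._slices = None
        return dxp[:, :, d:-d, d:-d, d:-d]

    def params(self, prefix):
        return [(f"{prefix}.w", self.w, self.gw, True),
                (f"{prefix}.b", self.b, self.gb, False)]


class _BatchNorm3d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, dtype, eps=1e-5, momentum=0.1):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def forward(self, x, training):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        istd = 1.0 / np.sqrt(var + self.eps)
        shape = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(shape)) * istd.astype(x.dtype).reshape(shape)
        if training:
            self._cache = (xhat, istd.astype(x.dtype))
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dy):
        xhat, istd = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.ggamma[:] = (dy * xhat).sum(axis=axes)
        self.gbeta[:] = dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(shape)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape) / m
        )
        return term * istd.reshape(shape)

    def params(self, prefix):
        return [(f"{prefix}.gamma", self.gamma, self.ggamma, False),
                (f"{prefix}.beta", self.beta, self.gbeta, False)]


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        if training:
            self._mask = x > 0
            return np.where(self._mask, x, 0)
        return np.maximum(x, 0)

    def backward(self, dy):
        out = np.where(self._mask, dy, 0)
        self._mask = None
        return out

    def params(self, prefix):
        return []


class Network:
    """The assembled network.  Use ``forward`` / ``backward``; parameters are
    exposed as (name, value, grad, is_decayed) tuples for the optimizer."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        dtype = np.dtype(spec.dtype)
        self.layers: list = []
        cin = 1
        for si, (m, c, d) in enumerate(spec.stages):
            for mi in range(m):
                self.layers.append(_Conv3d(cin, c, d, rng, dtype))
                if spec.normalization == "batch":
                    self.layers.append(_BatchNorm3d(c, dtype))
                self.layers.append(_ReLU())
                cin = c
        self.output = _Conv3d(cin, 1, 1, rng, dtype,
                              zero_init=spec.zero_init_residual)
        self.training = False

    # -- parameter access -------------------------------------------------
    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend(layer.params(f"layer{i}"))
        out.extend(self.output.params("output"))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: value for name, value, _, _ in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm3d):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, value, _, _ in self.parameters():
            value[...] = state[name]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm3d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a batch of single-channel volumes (B, D, H, W) to the same
        shape.  Spatial dims must be at least 16 per axis (normalization
        stability floor)."""
        x = np.asarray(x)
        if x.ndim != 4:
            raise ValueError("expected a batch of volumes with shape (B, D, H, W)")
        if min(x.shape[1:]) < 16:
            raise ValueError("spatial dimensions must be at least 16 per axis")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in network input")
        dtype = np.dtype(self.spec.dtype)
        h = x.astype(dtype, copy=False)[:, None]
        for layer in self.layers:
            h = layer.forward(h, self.training)
        h = self.output.forward(h, self.training)
        out = h[:, 0]
        if self.spec.global_residual:
            out = out + x.astype(dtype, copy=False)
        return out

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients for the last training forward."""
        g = np.asarray(dout, dtype=np.dtype(self.spec.dtype))[:, None]
        g = self.output.backward(g)
        for layer in reversed(self.layers):
            g = layer.backward(g)


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Instantiate a network with seeded He-initialized weights (the output
    convolution starts at zero when ``spec.zero_init_residual``, so a
    global-residual network begins as the identity map)."""
    return Network(spec, np.random.default_rng(seed))


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(net: Network, path, train_config: dict | None = None) -> None:
    """Write spec + parameters (+ an optional training-config snapshot)."""
    meta = {
        "format_version": 1,
        "spec": {
            "stages": [list(s) for s in net.spec.stages],
            "kernel_size": net.spec.kernel_size,
            "normalization": net.spec.normalization,
            "global_residual": net.spec.global_residual,
            "zero_init_residual": net.spec.zero_init_residual,
            "dtype": net.spec.dtype,
        },
        "train_config": train_config or {},
    }
    np.savez_compressed(
        str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **net.state_dict(),
    )


def load_checkpoint(path) -> tuple[Network, dict]:
    """Load a checkpoint written by :func:`save_checkpoint`."""
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != 1:
            raise ConfigurationError(
                f"unsupported checkpoint version {meta.get('format_version')}"
            )
        spec = NetworkSpec(
            stages=tuple(tuple(s) for s in meta["spec"]["stages"]),
            kernel_size=meta["spec"]["kernel_size"],
            normalization=meta["spec"]["normalization"],
            global_residual=meta["spec"]["global_residual"],
            zero_init_residual=meta["spec"]["zero_init_residual"],
            dtype=meta["spec"]["dtype"],
        )
        net = build_network(spec)
        net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return net, meta["train_config"]
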