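"""NumPy building blocks for trainable 3D convolutional networks.

All layers operate on arrays of shape ``(batch, channels, x, y, z)`` and
implement an explicit ``forward`` / ``backward`` pair; gradients
accumulate into :class:`Param` objects.  Convolutions loop over kernel
offsets (at most ``k^3`` BLAS calls) rather than materialising an
im2col matrix, which keeps memory flat for the patch sizes used here.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "TrilinearUpsample",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name", "decay")

    def __init__(self, value: np.ndarray, name: str = "", decay: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name
        #: whether weight decay applies (conv kernels yes, biases/BN no)
        self.decay = decay

    @property
    def size(self) -> int:
        return self.value.size


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or 3-tuple, got {v!r}")
    return t


class Conv3d:
    """3D convolution with odd kernel, 'same'-style padding, any stride.

    Output extent per axis is ``floor((n + 2*(k//2) - k) / s) + 1``,
    i.e. ``n / s`` for even ``n`` and odd ``k``.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel=3,
        stride=1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        self.cin, self.cout = cin, cout
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError(f"kernel dims must be odd, got {self.kernel}")
        rng = rng or np.random.default_rng(0)
        fan_in = cin * int(np.prod(self.kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, *self.kernel))
        self.weight = Param(w, name=f"{name}.weight", decay=True)
        self.bias = Param(np.zeros(cout), name=f"{name}.bias", decay=False) if bias else None
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad(self) -> tuple[int, int, int]:
        return tuple(k // 2 for k in self.kernel)  # type: ignore[return-value]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        kx, ky, kz = self.kernel
        sx, sy, sz = self.stride
        px, py, pz = self._pad()
        b, c, nx, ny, nz = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (px, px), (py, py), (pz, pz)))
        ox = (nx + 2 * px - kx) // sx + 1
        oy = (ny + 2 * py - ky) // sy + 1
        oz = (nz + 2 * pz - kz) // sz + 1
        out = np.zeros((b, self.cout, ox, oy, oz))
        w = self.weight.value
        for dx in range(kx):
            for dy in range(ky):
                for dz in range(kz):
                    xs = xp[
                        :,
                        :,
                        dx : dx + sx * (ox - 1) + 1 : sx,
                        dy : dy + sy * (oy - 1) + 1 : sy,
                        dz : dz + sz * (oz - 1) + 1 : sz,
                    ]
                    out += np.einsum("oc,bcxyz->boxyz", w[:, :, dx, dy, dz], xs, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None, None]
        if train:
            self._cache = (xp, x.shape, out.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape, out_shape = self._cache
        kx, ky, kz = self.kernel
        sx, sy, sz = self.stride
        px, py, pz = self._pad()
        b, _, ox, oy, oz = out_shape
        dxp = np.zeros_like(xp)
        w = self.weight.value
        for dx in range(kx):
            for dy in range(ky):
                for dz in range(kz):
                    sl = (
                        slice(None),
                        slice(None),
                        slice(dx, dx + sx * (ox - 1) + 1, sx),
                        slice(dy, dy + sy * (oy - 1) + 1, sy),
                        slice(dz, dz + sz * (oz - 1) + 1, sz),
                    )
                    xs = xp[sl]
                    self.weight.grad[:, :, dx, dy, dz] += np.einsum(
                        "boxyz,bcxyz->oc", dout, xs, optimize=True
                    )
                    dxp[sl] += np.einsum("oc,boxyz->bcxyz", w[:, :, dx, dy, dz], dout, optimize=True)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        _, _, nx, ny, nz = x_shape
        return dxp[:, :, px : px + nx, py : py + ny, pz : pz + nz]


class BatchNorm3d:
    """Per-channel batch normalisation with affine terms and running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma", decay=False)
        self.beta = Param(np.zeros(channels), name=f"{name}.beta", decay=False)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            axes = (0, 2, 3, 4)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        out = self.gamma.value[None, :, None, None, None] * xhat + self.beta.value[None, :, None, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, x_shape = self._cache
        axes = (0, 2, 3, 4)
        n = dout.size // dout.shape[1]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        dxhat = dout * g
        # standard batch-norm backward over the (batch, spatial) axes
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv[None, :, None, None, None]
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def _linear_upsample_matrix(n_in: int, factor: int) -> np.ndarray:
    """1D linear-interpolation matrix mapping length ``n_in`` to
    ``factor * n_in`` (half-voxel aligned, edges clamped)."""
    n_out = n_in * factor
    u = np.zeros((n_out, n_in))
    for j in range(n_out):
        src = (j + 0.5) / factor - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        u[j, i0c] += 1.0 - frac
        u[j, i1c] += frac
    return u


class TrilinearUpsample:
    """Trilinear upsampling by per-axis integer factors (transpose-exact
    backward)."""

    def __init__(self, factor=2):
        self.factor = _triple(factor)
        self._mats: dict[tuple[int, int], np.ndarray] = {}

    @property
    def params(self) -> list[Param]:
        return []

    def _mat(self, n_in: int, f: int) -> np.ndarray:
        key = (n_in, f)
        if key not in self._mats:
            self._mats[key] = _linear_upsample_matrix(n_in, f)
        return self._mats[key]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = x
        for axis, f in zip((2, 3, 4), self.factor):
            if f == 1:
                continue
            u = self._mat(out.shape[axis], f)
            out = np.moveaxis(np.tensordot(u, out, axes=(1, axis)), 0, axis)
        self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout
        for axis, f in zip((4, 3, 2), self.factor[::-1]):
            if f == 1:
                continue
            u = self._mat(self._in_shape[axis], f)
            dx = np.moveaxis(np.tensordot(u.T, dx, axes=(1, axis)), 0, axis)
        return dx
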