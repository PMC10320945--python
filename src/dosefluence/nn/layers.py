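"""Minimal 3D convolutional network building blocks on numpy.

Tensors are ``(N, C, D, H, W)`` float32.  Every layer implements
``forward(x, train)`` and ``backward(grad_out)``; in training mode the
forward pass caches what the backward pass needs.  Convolutions are
evaluated as 27 (or 1) shifted GEMMs so the heavy lifting stays in BLAS
without materializing a full im2col buffer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "TrilinearUpsample",
    "concat_forward",
    "concat_backward",
]


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


def _out_len(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


class Conv3d:
    """3D convolution, kernel 3 (pad 1) or 1 (pad 0), stride 1 or 2.

    He-normal weight init from the provided RNG; bias zero-init.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out))
        self.kernel = kernel
        self.stride = stride
        self.pad = 1 if kernel == 3 else 0
        self.name = name
        self._cache = None

    def params(self):
        return {f"{self.name}.weight": self.weight, f"{self.name}.bias": self.bias}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, D, H, W = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        Do, Ho, Wo = (_out_len(n, k, s, p) for n in (D, H, W))
        cout = self.weight.value.shape[0]
        dt = np.result_type(x.dtype, self.weight.value.dtype)
        if k == 1:
            if s != 1:
                raise ValueError("1x1x1 convolutions are stride-1 only")
            wmat = self.weight.value[:, :, 0, 0, 0]
            y = np.empty((N, cout, D, H, W), dtype=dt)
            for n in range(N):
                y[n] = (wmat @ x[n].reshape(C, -1)).reshape(cout, D, H, W)
            y += self.bias.value[None, :, None, None, None]
            if train:
                self._cache = x
            return y
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        wflat = self.weight.value.reshape(cout, -1)  # (cout, C*27)
        y = np.empty((N, cout, Do, Ho, Wo), dtype=dt)
        for n in range(N):
            for z0, z1 in self._blocks(C, Do, Ho, Wo):
                cols = self._im2col(xp[n], C, k, s, (Ho, Wo), z0, z1, dt)
                y[n, :, z0:z1] = (wflat @ cols).reshape(cout, z1 - z0, Ho, Wo)
        y += self.bias.value[None, :, None, None, None]
        if train:
            self._cache = (xp, x.shape)
        return y

    # column buffers are built per output-slice block so the transient
    # im2col memory stays bounded on large volumes
    _BLOCK_BYTES = 150e6

    @classmethod
    def _blocks(cls, C, Do, Ho, Wo):
        per_slice = C * 27 * Ho * Wo * 4
        step = max(1, int(cls._BLOCK_BYTES // max(per_slice, 1)))
        return [(z, min(z + step, Do)) for z in range(0, Do, step)]

    @staticmethod
    def _im2col(xpn, C, k, s, hw, z0, z1, dt):
        """Column matrix (C*k^3, M) for output slices [z0, z1)."""
        Ho, Wo = hw
        nz = z1 - z0
        cols = np.empty((C, k * k * k, nz, Ho, Wo), dtype=dt)
        off = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    # direct strided copy; no temporary
                    cols[:, off] = xpn[
                        :,
                        dz + s * z0 : dz + s * (z1 - 1) + 1 : s,
                        dy : dy + s * (Ho - 1) + 1 : s,
                        dx : dx + s * (Wo - 1) + 1 : s,
                    ]
                    off += 1
        return cols.reshape(C * k * k * k, nz * Ho * Wo)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        if k == 1:
            x = self._cache
            N, C, D, H, W = x.shape
            cout = gy.shape[1]
            wmat = self.weight.value[:, :, 0, 0, 0]
            gx = np.empty_like(x)
            gw = np.zeros_like(wmat, dtype=np.float64)
            for n in range(N):
                go = gy[n].reshape(cout, -1)
                xf = x[n].reshape(C, -1)
                gw += go @ xf.T
                gx[n] = (wmat.T @ go).reshape(C, D, H, W)
            self.weight.grad[:, :, 0, 0, 0] += gw.astype(self.weight.grad.dtype)
            self.bias.grad += gy.sum(axis=(0, 2, 3, 4))
            self._cache = None
            return gx
        xp, xshape = self._cache
        N, C, D, H, W = xshape
        _, cout, Do, Ho, Wo = gy.shape
        dt = xp.dtype
        gxp = np.zeros_like(xp)
        wflat = self.weight.value.reshape(cout, -1)
        gwflat = np.zeros_like(wflat)
        kk = k * k * k
        for n in range(N):
            for z0, z1 in self._blocks(C, Do, Ho, Wo):
                go = gy[n, :, z0:z1].reshape(cout, -1)
                cols = self._im2col(xp[n], C, k, s, (Ho, Wo), z0, z1, dt)
                gwflat += go @ cols.T
                gcols = (wflat.T @ go).reshape(C, kk, z1 - z0, Ho, Wo)
                off = 0
                for dz in range(k):
                    for dy in range(k):
                        for dx in range(k):
                            gxp[n][
                                :,
                                dz + s * z0 : dz + s * (z1 - 1) + 1 : s,
                                dy : dy + s * (Ho - 1) + 1 : s,
                                dx : dx + s * (Wo - 1) + 1 : s,
                            ] += gcols[:, off]
                            off += 1
        self.weight.grad += gwflat.reshape(self.weight.grad.shape)
        self.bias.grad += gy.sum(axis=(0, 2, 3, 4))
        self._cache = None
        if p:
            return gxp[:, :, p:-p, p:-p, p:-p]
        return gxp


class InstanceNorm3d:
    """Per-sample, per-channel normalization over the spatial axes,
    with learnable affine scale/shift."""

    def __init__(self, c: int, eps: float = 1e-5, affine: bool = True, name: str = "in"):
        self.gamma = Param(np.ones(c)) if affine else None
        self.beta = Param(np.zeros(c)) if affine else None
        self.eps = eps
        self.affine = affine
        self.name = name
        self._cache = None

    def params(self):
        if not self.affine:
            return {}
        return {f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        ax = (2, 3, 4)
        mean = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        y = xhat
        if self.affine:
            y = xhat * self.gamma.value[None, :, None, None, None] + self.beta.value[None, :, None, None, None]
        if train:
            self._cache = (xhat, inv)
        return y.astype(x.dtype, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        ax = (2, 3, 4)
        if self.affine:
            self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3, 4))
            self.beta.grad += gy.sum(axis=(0, 2, 3, 4))
            gh = gy * self.gamma.value[None, :, None, None, None]
        else:
            gh = gy
        m1 = gh.mean(axis=ax, keepdims=True)
        m2 = (gh * xhat).mean(axis=ax, keepdims=True)
        return ((gh - m1 - xhat * m2) * inv).astype(gy.dtype, copy=False)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D linear-interpolation matrix (n_out x n_in), half-pixel-centered
    (the align_corners=False convention), edge-clamped."""
    key = (n_in, n_out)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    A = np.zeros((n_out, n_in), dtype=np.float64)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        w = src - i0
        A[i, i0] += 1.0 - w
        A[i, i1] += w
    _INTERP_CACHE[key] = A
    return A


def _apply_axis(x: np.ndarray, A: np.ndarray, axis: int) -> np.ndarray:
    y = np.tensordot(x, A.astype(x.dtype, copy=False), axes=([axis], [1]))
    return np.moveaxis(y, -1, axis)  # interpolated axis comes back in place


class TrilinearUpsample:
    """Trilinear resampling to an explicit target spatial shape.

    A fixed linear map (separable 1D interpolation per axis); the backward
    pass multiplies by the transposes, i.e. the exact adjoint.
    """

    def __init__(self):
        self._shapes = None

    def params(self):
        return {}

    def forward(self, x: np.ndarray, target: tuple[int, int, int], train: bool = True) -> np.ndarray:
        D, H, W = x.shape[2:]
        Do, Ho, Wo = target
        y = x
        for axis, (ni, no) in zip((2, 3, 4), ((D, Do), (H, Ho), (W, Wo))):
            if ni != no:
                y = _apply_axis(y, _interp_matrix(ni, no), axis)
        if train:
            self._shapes = ((D, H, W), target)
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        (D, H, W), (Do, Ho, Wo) = self._shapes
        self._shapes = None
        g = gy
        for axis, (ni, no) in zip((2, 3, 4), ((D, Do), (H, Ho), (W, Wo))):
            if ni != no:
                g = _apply_axis(g, _interp_matrix(ni, no).T, axis)
        return np.ascontiguousarray(g)


def concat_forward(parts: list[np.ndarray]) -> np.ndarray:
    return np.concatenate(parts, axis=1)


def concat_backward(gy: np.ndarray, channel_counts: list[int]) -> list[np.ndarray]:
    splits = np.cumsum(channel_counts)[:-1]
    return np.split(gy, splits, axis=1)
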