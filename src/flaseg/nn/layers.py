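"""Minimal define-by-hand layer framework (float32, channels-last).

Every layer implements ``forward(x, train)`` caching what its backward
needs, and ``backward(gy)`` returning the input gradient while accumulating
parameter gradients.  Feature maps are (N, H, W, C) internally; the public
network API converts from/to the (N, C, H, W) convention at its boundary.
Dense convolutions are im2col + one BLAS matmul.
"""

from __future__ import annotations

import numpy as np



class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Module:
    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers."""
        state: dict[str, np.ndarray] = {}
        for key, v in self.__dict__.items():
            if isinstance(v, Parameter):
                state[f"{prefix}{key}"] = v.data
            elif isinstance(v, Module):
                state.update(v.named_state(f"{prefix}{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.named_state(f"{prefix}{key}.{i}."))
        for name, buf in self.buffers():
            state[f"{prefix}{name}"] = buf
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for key, v in self.__dict__.items():
            if isinstance(v, Parameter):
                v.data[...] = state[f"{prefix}{key}"]
            elif isinstance(v, Module):
                v.load_state(state, f"{prefix}{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, f"{prefix}{key}.{i}.")
        for name, buf in self.buffers():
            buf[...] = state[f"{prefix}{name}"]


def kaiming_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


from .kernels import im2col  # noqa: E402  (numba-backed patch extraction)


class Conv2d(Module):
    """Stride-1 2-D convolution (cross-correlation), zero same-padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, pad: int | None = None):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2 if pad is None else pad
        self.weight = Parameter(kaiming_init(rng, (cout, cin, k, k), cin * k * k), "weight")
        self.bias = Parameter(np.zeros(cout, dtype=np.float32), "bias")
        self._x = None
        self._cols = None

    def _wmat(self) -> np.ndarray:
        # (k*k*C, Cout) matching im2col's (k, k, C) patch-flattening order
        return np.ascontiguousarray(
            self.weight.data.transpose(2, 3, 1, 0)).reshape(-1, self.cout)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        if self.k == 1:
            self._x = x if train else None
            y = x.reshape(-1, self.cin) @ self._wmat() + self.bias.data
        else:
            cols, (n, h, w) = im2col(x, self.k, self.pad)
            self._cols = cols if train else None
            y = cols @ self._wmat() + self.bias.data
        return y.reshape(n, h, w, self.cout)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, _ = gy.shape
        gmat = gy.reshape(-1, self.cout)
        self.bias.grad += gmat.sum(axis=0)
        if self.k == 1:
            x = self._x
            self.weight.grad += (x.reshape(-1, self.cin).T @ gmat).reshape(
                self.cin, 1, 1, self.cout).transpose(3, 0, 1, 2)
            return (gmat @ self._wmat().T).reshape(x.shape)
        cols, self._cols = self._cols, None  # cached by forward; freed here
        dwmat = cols.T @ gmat  # (k*k*C, Cout)
        self.weight.grad += dwmat.reshape(self.k, self.k, self.cin, self.cout).transpose(3, 2, 0, 1)
        # backward-data: full correlation of gy with the flipped, transposed kernel
        wrot = np.ascontiguousarray(
            self.weight.data[:, :, ::-1, ::-1].transpose(2, 3, 0, 1)).reshape(-1, self.cin)
        gcols, _ = im2col(gy, self.k, self.k - 1 - self.pad)
        return (gcols @ wrot).reshape(n, h, w, self.cin)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32), "gamma")
        self.beta = Parameter(np.zeros(c, dtype=np.float32), "beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None
        self._refresh = None  # (sum_mean, sum_var, count) during stat re-estimation

    def buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            m = x.mean(axis=(0, 1, 2))
            v = x.var(axis=(0, 1, 2))
            n = x.shape[0] * x.shape[1] * x.shape[2]
            unbiased = v * (n / max(n - 1, 1))
            if self._refresh is not None:
                self._refresh[0] += m
                self._refresh[1] += unbiased
                self._refresh[2] += 1
            else:
                self.running_mean += self.momentum * (m - self.running_mean)
                self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            m, v = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(v + self.eps)
        xhat = (x - m) * istd
        if train:
            self._cache = (xhat, istd.astype(np.float32))
        return self.gamma.data * xhat + self.beta.data

    def start_refresh(self) -> None:
        self._refresh = [np.zeros(self.c, dtype=np.float64),
                         np.zeros(self.c, dtype=np.float64), 0]

    def finish_refresh(self) -> None:
        s_mean, s_var, count = self._refresh
        if count:
            self.running_mean[...] = s_mean / count
            self.running_var[...] = s_var / count
        self._refresh = None

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, istd = self._cache
        axes = (0, 1, 2)
        dbeta = gy.sum(axis=axes)
        dgamma = (gy * xhat).sum(axis=axes)
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        m = gy.shape[0] * gy.shape[1] * gy.shape[2]
        return (self.gamma.data * istd) * (gy - dbeta / m - xhat * (dgamma / m))


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2x2(Module):
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        quads = (x[:, 0::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 0::2], x[:, 1::2, 1::2])
        y = quads[0].copy()
        if train:
            idx = np.zeros(y.shape, dtype=np.uint8)
        for j in (1, 2, 3):
            better = quads[j] > y
            np.copyto(y, quads[j], where=better)
            if train:
                idx[better] = j
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        dx = np.zeros(shape, dtype=gy.dtype)
        quads = (dx[:, 0::2, 0::2], dx[:, 0::2, 1::2], dx[:, 1::2, 0::2], dx[:, 1::2, 1::2])
        for j in range(4):
            np.copyto(quads[j], gy, where=idx == j)
        return dx


def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
    # 2x linear interpolation, align_corners=False, edge-clamped
    x = np.moveaxis(x, axis, 1)
    even = 0.75 * x
    even[:, 1:] += 0.25 * x[:, :-1]
    even[:, 0] += 0.25 * x[:, 0]
    odd = 0.75 * x
    odd[:, :-1] += 0.25 * x[:, 1:]
    odd[:, -1] += 0.25 * x[:, -1]
    out = np.empty((x.shape[0], 2 * x.shape[1]) + x.shape[2:], dtype=x.dtype)
    out[:, 0::2] = even
    out[:, 1::2] = odd
    return np.moveaxis(out, 1, axis)


def _up1d_adj(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, 1)
    ge, go = g[:, 0::2], g[:, 1::2]
    dx = 0.75 * (ge + go)
    dx[:, :-1] += 0.25 * ge[:, 1:]
    dx[:, 0] += 0.25 * ge[:, 0]
    dx[:, 1:] += 0.25 * go[:, :-1]
    dx[:, -1] += 0.25 * go[:, -1]
    return np.moveaxis(dx, 1, axis)


class BilinearUp2x(Module):
    """2x bilinear upsampling (align_corners=False); channel count unchanged."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return _up1d(_up1d(x, 1), 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return _up1d_adj(_up1d_adj(gy, 2), 1)


def stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Sigmoid(Module):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = stable_sigmoid(x)
        if train:
            self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._y * (1.0 - self._y)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for m in self.mods:
            x = m.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for m in reversed(self.mods):
            gy = m.backward(gy)
        return gy
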