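"""Feature-location attention block (FLAB).

Each channel of a concatenated decoder feature map is gated independently:
stride-1 sliding average/max pooling produces a two-map summary, a
1x1-conv -> ReLU -> 1x1-conv branch turns it into a feature weight, a 7x7
convolution turns it into a location weight, the two are added, squashed
through a sigmoid and multiplied back onto the channel.  A 3x3 projection
then halves the channel count.

Branch parameters are shared across channels by default (one attention
module applied to every channel); ``share_across_channels=False`` keeps a
separate parameter set per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import kernels
from .nn.layers import Conv2d, Module, Parameter, kaiming_init


@dataclass
class FlabConfig:
    """Hyperparameters of a FLAB (the learnable arrays live in :class:`FLAB`)."""

    pool_kernel: int = 3
    hidden_width: int = 2  # width r of the 1x1 -> ReLU -> 1x1 feature branch
    share_across_channels: bool = True

    def validate(self) -> None:
        if self.pool_kernel < 1 or self.pool_kernel % 2 == 0:
            raise ValueError(
                f"FLAB pool_kernel must be an odd positive integer, got {self.pool_kernel}")
        if self.hidden_width < 1:
            raise ValueError(f"FLAB hidden_width must be >= 1, got {self.hidden_width}")


@dataclass
class FlabParams:
    """Plain-array parameter bundle for the functional FLAB operations.

    ``feature_w1``/``feature_w2`` are the two 1x1 convolutions of the feature
    branch written as matrices (r, 2) and (1, r); ``location_w`` is the 7x7x2
    location kernel; ``proj_w``/``proj_b`` the 3x3 channel-halving projection
    in (Cout, Cin, 3, 3) layout.  With ``share_across_channels=False`` every
    array gains a leading channel axis.
    """

    pool_kernel: int
    feature_w1: np.ndarray
    feature_b1: np.ndarray
    feature_w2: np.ndarray
    feature_b2: np.ndarray
    location_w: np.ndarray
    location_b: float
    proj_w: np.ndarray | None = None
    proj_b: np.ndarray | None = None
    share_across_channels: bool = True

    def validate(self) -> None:
        if self.pool_kernel < 1 or self.pool_kernel % 2 == 0:
            raise ValueError(
                f"FLAB pool_kernel must be an odd positive integer, got {self.pool_kernel}")
        lw = np.asarray(self.location_w)
        if lw.shape[-3:-1] != (7, 7):
            raise ValueError(f"FLAB location kernel must be 7x7, got {lw.shape}")
        if self.proj_w is not None:
            pw = np.asarray(self.proj_w)
            if pw.shape[1] % 2 or pw.shape[0] * 2 != pw.shape[1]:
                raise ValueError(
                    "FLAB projection must halve an even channel count, got "
                    f"{pw.shape[1]} -> {pw.shape[0]}")


def pooled_pair(channel_slice: np.ndarray, pool_kernel: int) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 same-size sliding average and max pooling of one channel.

    Edge-replicate padding keeps the output at the input's height x width.
    This analysis-facing implementation is double precision and independent
    of the float32 training kernels.
    """
    if pool_kernel < 1 or pool_kernel % 2 == 0:
        raise ValueError(
            f"FLAB pool_kernel must be an odd positive integer, got {pool_kernel}")
    x = np.asarray(channel_slice, dtype=np.float64)
    if x.ndim != 2 or x.size == 0:
        raise ValueError(f"channel slice must be a non-empty 2-D array, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("channel slice contains non-finite values")
    p = pool_kernel // 2
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(np.pad(x, p, mode="edge"), (pool_kernel, pool_kernel))
    return win.mean(axis=(-2, -1)), win.max(axis=(-2, -1))


def feature_weight(channel_slice: np.ndarray, params: FlabParams) -> np.ndarray:
    """conv1x1(ReLU(conv1x1(concat(F_avg, F_max)))) for one channel."""
    params.validate()
    avg, mx = pooled_pair(channel_slice, params.pool_kernel)
    w1, b1, w2, b2 = (np.asarray(a, dtype=np.float64) for a in
                      (params.feature_w1, params.feature_b1,
                       params.feature_w2, params.feature_b2))
    s = np.stack([avg, mx], axis=-1).reshape(-1, 2)
    h = np.maximum(s @ w1.T + b1, 0.0)
    return (h @ w2.T + b2).reshape(channel_slice.shape)


def location_weight(channel_slice: np.ndarray, params: FlabParams) -> np.ndarray:
    """conv7x7(concat(F_avg, F_max)) for one channel, zero same-padding."""
    params.validate()
    avg, mx = pooled_pair(channel_slice, params.pool_kernel)
    w = np.asarray(params.location_w, dtype=np.float64)
    k = w.shape[0]
    p = k // 2
    from numpy.lib.stride_tricks import sliding_window_view
    stack = np.stack([np.pad(avg, p), np.pad(mx, p)], axis=-1)
    win = sliding_window_view(stack, (k, k), axis=(0, 1))  # (H, W, 2, k, k)
    out = np.einsum("hwcuv,uvc->hw", win, w)
    return out + float(np.asarray(params.location_b).reshape(-1)[0])


def flab_forward(features: np.ndarray, params: FlabParams) -> np.ndarray:
    """Full FLAB on a (N, C, H, W) feature map -> (N, C/2, H, W).

    Per channel: gate = sigmoid(feature_weight + location_weight), channel is
    multiplied by its gate, then the 3x3 projection halves the channels.
    """
    params.validate()
    x = np.asarray(features, dtype=np.float32)
    n, c, h, w = x.shape
    if c % 2:
        raise ValueError(f"FLAB requires an even channel count, got C={c}")
    block = FLAB.from_params(c, params)
    y = block.forward(np.ascontiguousarray(x.transpose(0, 2, 3, 1)), train=False)
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class FLAB(Module):
    """Learnable FLAB layer operating on channels-last (N, H, W, C) maps."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 config: FlabConfig | None = None):
        cfg = config or FlabConfig()
        cfg.validate()
        if channels % 2:
            raise ValueError(f"FLAB requires an even channel count, got C={channels}")
        self.channels = channels
        self.config = cfg
        r = cfg.hidden_width
        lead = () if cfg.share_across_channels else (channels,)
        self.fw1 = Parameter(kaiming_init(rng, lead + (r, 2), 2))
        # small positive bias keeps the ReLU of the feature branch alive at init
        self.fb1 = Parameter(np.full(lead + (r,), 0.01, dtype=np.float32))
        self.fw2 = Parameter(kaiming_init(rng, lead + (1, r), r))
        self.fb2 = Parameter(np.zeros(lead + (1,), dtype=np.float32))
        self.lw = Parameter(kaiming_init(rng, lead + (7, 7, 2), 7 * 7 * 2))
        self.lb = Parameter(np.zeros(lead + (1,), dtype=np.float32))
        self.proj = Conv2d(channels, channels // 2, 3, rng)
        self._cache = None

    @classmethod
    def from_params(cls, channels: int, params: FlabParams) -> "FLAB":
        cfg = FlabConfig(pool_kernel=params.pool_kernel,
                         hidden_width=np.asarray(params.feature_w1).shape[-2],
                         share_across_channels=params.share_across_channels)
        block = cls(channels, np.random.default_rng(0), cfg)
        block.fw1.data[...] = params.feature_w1
        block.fb1.data[...] = params.feature_b1
        block.fw2.data[...] = params.feature_w2
        block.fb2.data[...] = params.feature_b2
        block.lw.data[...] = params.location_w
        block.lb.data[...] = np.asarray(params.location_b, dtype=np.float32).reshape(
            block.lb.data.shape)
        if params.proj_w is not None:
            block.proj.weight.data[...] = params.proj_w
            block.proj.bias.data[...] = params.proj_b
        return block

    # -- helpers bridging shared (scalar) and per-channel ((C,)) coefficients

    def _coef(self, arr: np.ndarray, *ij):
        return arr[ij] if self.config.share_across_channels else arr[(slice(None),) + ij]

    def _accum(self, grad: np.ndarray, value: np.ndarray, *ij) -> None:
        if self.config.share_across_channels:
            grad[ij] += value.sum(dtype=np.float64)
        else:
            grad[(slice(None),) + ij] += value.sum(axis=(0, 1, 2))

    def _location_wvec(self) -> tuple[np.ndarray, np.ndarray]:
        if self.config.share_across_channels:
            wvec = np.broadcast_to(self.lw.data[..., None], (7, 7, 2, self.channels))
            bvec = np.broadcast_to(self.lb.data, (self.channels,))
        else:
            wvec = self.lw.data.transpose(1, 2, 3, 0)
            bvec = self.lb.data.reshape(-1)
        return wvec, bvec

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.channels:
            raise ValueError(f"FLAB built for C={self.channels}, got C={c}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        avg, mx, idx = kernels.sliding_pool_pair(x, self.config.pool_kernel)
        # feature branch, broadcasting scalar or (C,) coefficients
        wf = np.zeros_like(avg)
        hids, masks = [], []
        for j in range(self.config.hidden_width):
            pre = (avg * self._coef(self.fw1.data, j, 0)
                   + mx * self._coef(self.fw1.data, j, 1)
                   + self._coef(self.fb1.data, j))
            mask = pre > 0
            hid = np.where(mask, pre, np.float32(0.0))
            wf += hid * self._coef(self.fw2.data, 0, j)
            hids.append(hid)
            masks.append(mask)
        wf += self._coef(self.fb2.data, 0)
        wvec, bvec = self._location_wvec()
        wl = kernels.conv_pair(avg, mx, wvec, bvec)
        gate = _sigmoid(wf + wl)
        gated = gate * x
        if train:
            self._cache = (x, gate, avg, mx, idx, hids, masks)
        return self.proj.forward(gated, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, gate, avg, mx, idx, hids, masks = self._cache
        dgated = self.proj.backward(gy)
        dgate = dgated * x
        dx = dgated * gate
        dz = (dgate * gate * (1.0 - gate)).astype(np.float32)
        # location branch
        wvec, _ = self._location_wvec()
        davg, dmx, dwv, dbv = kernels.conv_pair_bwd(avg, mx, wvec, dz)
        if self.config.share_across_channels:
            self.lw.grad += dwv.sum(axis=-1)
            self.lb.grad += dbv.sum()
        else:
            self.lw.grad += dwv.transpose(3, 0, 1, 2)
            self.lb.grad += dbv[:, None]
        # feature branch
        self._accum(self.fb2.grad, dz, 0)
        for j in range(self.config.hidden_width):
            self._accum(self.fw2.grad, dz * hids[j], 0, j)
            dpre = dz * self._coef(self.fw2.data, 0, j) * masks[j]
            self._accum(self.fw1.grad, dpre * avg, j, 0)
            self._accum(self.fw1.grad, dpre * mx, j, 1)
            self._accum(self.fb1.grad, dpre, j)
            davg += dpre * self._coef(self.fw1.data, j, 0)
            dmx += dpre * self._coef(self.fw1.data, j, 1)
        dx += kernels.sliding_pool_pair_bwd(davg, dmx, idx, self.config.pool_kernel)
        return dx

    def export_params(self) -> FlabParams:
        return FlabParams(
            pool_kernel=self.config.pool_kernel,
            feature_w1=self.fw1.data.copy(), feature_b1=self.fb1.data.copy(),
            feature_w2=self.fw2.data.copy(), feature_b2=self.fb2.data.copy(),
            location_w=self.lw.data.copy(), location_b=self.lb.data.copy(),
            proj_w=self.proj.weight.data.copy(), proj_b=self.proj.bias.data.copy(),
            share_across_channels=self.config.share_across_channels)
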