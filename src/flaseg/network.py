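"""FLA-UNet backbone and its plain U-Net ablation baseline.

Five encoder stages (two conv-BN-ReLU blocks each, 2x2 max-pool between
stages, channel count doubling) feed four decoder stages.  Each decoder
bilinearly upsamples 2x, concatenates the matching encoder skip, runs the
concatenated map through a FLAB (which halves the channels) and two
conv-BN-ReLU blocks.  A 1x1 convolution plus softmax produces per-pixel
class probabilities.  With ``use_flab=False`` the decoder concatenation
goes straight into the conv blocks — the reference bilinear U-Net.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .attention import FLAB, FlabConfig
from .nn.layers import (
    BatchNorm2d,
    BilinearUp2x,
    Conv2d,
    MaxPool2x2,
    Module,
    ReLU,
    Sequential,
)

DEPTH = 5  # encoder stages; decoders = DEPTH - 1


@dataclass
class NetworkConfig:
    in_channels: int = 1
    num_classes: int = 2
    base_width: int = 64
    depth: int = DEPTH
    use_flab: bool = True
    flab: FlabConfig = field(default_factory=FlabConfig)
    pad_to_multiple: bool = False  # reflection-pad inputs not divisible by 16

    def validate(self) -> None:
        if self.depth != DEPTH:
            raise ValueError(f"architecture is fixed at {DEPTH} encoders, got depth={self.depth}")
        if self.base_width < 2 or self.base_width % 2:
            raise ValueError(f"base_width must be even and >= 2, got {self.base_width}")
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        self.flab.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "flab" in d and isinstance(d["flab"], dict):
            d["flab"] = FlabConfig(**d["flab"])
        return cls(**d)


@dataclass
class SegmentationOutput:
    probabilities: np.ndarray  # (N, num_classes, H, W), rows sum to 1
    predicted_mask: np.ndarray  # (N, H, W) argmax labels


class ConvBlock(Module):
    """3x3 conv -> batch norm -> ReLU, spatial dims preserved."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = Conv2d(cin, cout, 3, rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, gy):
        return self.conv.backward(self.bn.backward(self.relu.backward(gy)))


class DecoderStage(Module):
    def __init__(self, up_ch: int, skip_ch: int, out_ch: int, rng,
                 use_flab: bool, flab_cfg: FlabConfig):
        cat = up_ch + skip_ch
        self.up = BilinearUp2x()
        self.flab = FLAB(cat, rng, flab_cfg) if use_flab else None
        mid = cat // 2 if use_flab else cat
        self.block1 = ConvBlock(mid, out_ch, rng)
        self.block2 = ConvBlock(out_ch, out_ch, rng)

    def forward(self, bottom, skip, train=True):
        up = self.up.forward(bottom, train)
        if up.shape[1:3] != skip.shape[1:3]:
            raise ValueError(
                f"skip/upsample spatial mismatch: upsampled {up.shape} vs skip {skip.shape}")
        x = np.concatenate([up, skip], axis=-1)
        self._split = up.shape[-1]
        if self.flab is not None:
            x = self.flab.forward(x, train)
        return self.block2.forward(self.block1.forward(x, train), train)

    def backward(self, gy):
        g = self.block1.backward(self.block2.backward(gy))
        if self.flab is not None:
            g = self.flab.backward(g)
        g_up, g_skip = g[..., :self._split], g[..., self._split:]
        return self.up.backward(np.ascontiguousarray(g_up)), np.ascontiguousarray(g_skip)


class FLAUNet(Module):
    """Segmentation network; channels-first (N, C, H, W) public interface."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.config.validate()
        rng = np.random.default_rng(seed)
        bw = self.config.base_width
        widths = [bw * 2 ** s for s in range(DEPTH)]  # 64..1024 at base 64
        self.enc_widths = widths
        cin = self.config.in_channels
        self.encoders = []
        for w in widths:
            self.encoders.append(Sequential(ConvBlock(cin, w, rng), ConvBlock(w, w, rng)))
            cin = w
        self.pools = [MaxPool2x2() for _ in range(DEPTH - 1)]
        self.decoders = []
        for lvl in range(DEPTH - 2, -1, -1):  # deepest merge first
            up_ch = widths[lvl + 1]
            skip_ch = widths[lvl]
            self.decoders.append(DecoderStage(up_ch, skip_ch, widths[lvl], rng,
                                              self.config.use_flab, self.config.flab))
        self.head = Conv2d(bw, self.config.num_classes, 1, rng)

    # -- forward ----------------------------------------------------------

    def _check_input(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, config.in_channels={self.config.in_channels}")
        return x

    def encoder_forward(self, image: np.ndarray, train: bool = True) -> list[np.ndarray]:
        """Run the five encoder stages; returns channels-first stage outputs."""
        x = self._check_input(image)
        feats = self._encode(np.ascontiguousarray(x.transpose(0, 2, 3, 1)), train)
        return [np.ascontiguousarray(f.transpose(0, 3, 1, 2)) for f in feats]

    def _encode(self, x, train):
        h, w = x.shape[1:3]
        div = 2 ** (DEPTH - 1)
        if h % div or w % div:
            raise ValueError(
                f"input height/width must be divisible by {div}, got {h}x{w}")
        feats = []
        for s, enc in enumerate(self.encoders):
            if s:
                x = self.pools[s - 1].forward(x, train)
            x = enc.forward(x, train)
            feats.append(x)
        return feats

    def forward_logits(self, x_nhwc: np.ndarray, train: bool = True) -> np.ndarray:
        feats = self._encode(x_nhwc, train)
        y = feats[-1]
        for dec, skip in zip(self.decoders, feats[-2::-1]):
            y = dec.forward(y, skip, train)
        return self.head.forward(y, train)

    def backward_logits(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits)
        g_skips = []
        for dec in reversed(self.decoders):
            g, g_skip = dec.backward(g)
            g_skips.append(g_skip)
        g_skips.reverse()  # now ordered shallow..deep-1 matching feats[0..3]
        for s in range(DEPTH - 1, -1, -1):
            if s < DEPTH - 1:
                g = g + g_skips[DEPTH - 2 - s]
            g = self.encoders[s].backward(g)
            if s:
                g = self.pools[s - 1].backward(g)

    def forward(self, image: np.ndarray, train: bool = False) -> SegmentationOutput:
        x = self._check_input(image)
        n, _, h, w = x.shape
        div = 2 ** (DEPTH - 1)
        pad_h = pad_w = 0
        if (h % div or w % div) and self.config.pad_to_multiple:
            pad_h = (-h) % div
            pad_w = (-w) % div
            x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)), mode="reflect")
        logits = self.forward_logits(np.ascontiguousarray(x.transpose(0, 2, 3, 1)), train)
        if pad_h or pad_w:
            logits = logits[:, :h, :w, :]
        probs = softmax_lastaxis(logits)
        probs_ncHW = np.ascontiguousarray(probs.transpose(0, 3, 1, 2))
        return SegmentationOutput(probabilities=probs_ncHW,
                                  predicted_mask=probs_ncHW.argmax(axis=1))

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def softmax_lastaxis(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# -- checkpoint I/O -------------------------------------------------------

def save_checkpoint(path, model: FLAUNet, **meta) -> None:
    """Single-file .npz checkpoint: weights + config echo + metadata."""
    state = model.named_state()
    payload = {f"param/{k}": v for k, v in state.items()}
    payload["config_json"] = np.frombuffer(
        json.dumps({"config": model.config.to_dict(), **meta}).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[FLAUNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["config_json"].tobytes()).decode())
        config = NetworkConfig.from_dict(meta.pop("config"))
        model = FLAUNet(config)
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state(state)
    return model, meta
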