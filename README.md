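# flaseg

FLA-UNet: a U-Net variant with a per-channel **feature-location attention
block (FLAB)** in every decoder stage and a weighted Dice + cross-entropy
joint loss, built for foveal-avascular-zone (FAZ) segmentation in OCTA
en-face images. The package ships the full stack — network, attention
block, losses, hard-mask metrics (MIoU/ACC/Dice), a synthetic OCTA-like
data generator, and a training/evaluation/ablation pipeline with a CLI —
implemented in NumPy (forward *and* backward passes; BLAS via im2col for
dense convolutions, Numba kernels for the sliding pooling and the 7×7
location convolution). No deep-learning framework is required.

## Architecture

* **Encoder** — five stages of two (3×3 conv → BatchNorm → ReLU) blocks,
  2×2 max-pooling between stages; channels double per stage
  (64…1024 at the default base width).
* **Decoder** — four stages: 2× bilinear upsampling, concatenation with the
  matching encoder skip, a FLAB that gates each channel and halves the
  concatenated channel count with a 3×3 projection, then two conv blocks.
* **FLAB** — per channel, stride-1 sliding average/max pooling feeds two
  parallel branches: 1×1 conv → ReLU → 1×1 conv (feature weight) and a 7×7
  conv (location weight); their sum is passed through a sigmoid and
  multiplied back onto the channel. Branch parameters are shared across
  channels by default (`share_across_channels=False` keeps one set per
  channel).
* **Head** — 1×1 conv + softmax over {background, FAZ}.
* **Loss** — `0.8 · soft-Dice + 0.2 · binary cross-entropy`.
* **Protocol** — Adam (lr 0.01), batch 8, square crops divisible by 16,
  7:3 train/test split, best test-Dice model over three restarts. After
  training, BatchNorm statistics are re-estimated over the training set
  (precise-BN) before evaluation.

A plain bilinear U-Net baseline (`use_flab=False`) and a three-variant
ablation harness (U-Net / U-Net + FLABs / FLA-UNet) are included.

## CLI

```bash
# synthetic OCTA-like dataset (images/, masks/, manifest.csv)
fla-seg synth --config synth.yaml --out data/

# train (best-of-n restarts, checkpoint + JSON run record)
fla-seg train --config train.yaml --data data/ --out run/

# evaluate a checkpoint (per-image CSV, macro + micro rows, overlays)
fla-seg eval --checkpoint run/checkpoint.npz --data data/ --report report.csv

# Table-4-style ablation (U-Net / U-Net+FLABs / FLA-UNet)
fla-seg ablate --config train.yaml --data data/ --out table4.csv
```

`train.yaml` mirrors `flaseg.pipeline.TrainConfig` field for field
(`fla-seg`'s `TrainConfig.to_yaml` writes a template); `synth.yaml` mirrors
`flaseg.synthetic.SynthConfig`.

## Library quick start

```python
import numpy as np
from flaseg.network import FLAUNet, NetworkConfig
from flaseg.synthetic import SynthConfig, generate_mixed_dataset

pairs = generate_mixed_dataset(SynthConfig(n_images=8, size=160, seed=0))
net = FLAUNet(NetworkConfig(base_width=16), seed=0)
out = net.forward(pairs[0].image[None, None].astype(np.float32))
out.probabilities  # (1, 2, H, W), softmax
out.predicted_mask  # (1, H, W) in {0, 1}
```

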