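"""Synthetic OCTA-like en-face images with paired FAZ ground-truth masks.

The generator builds a star-convex, roughly elliptical dark region at the
image centre (the avascular zone) surrounded by bright band-pass "vessel"
texture with multiplicative speckle.  Presets for the three clinical states
encode only the qualitative ordering normal < myopic < diabetic in mean FAZ
area, with more irregular boundaries for the diseased states.  Rendered
intensities are quantised to 8-bit levels so PNG round-trips are exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

STATE_PRESETS = {
    # radius range (fraction of size), boundary irregularity, ellipticity range
    "normal": {"faz_radius_range": (0.10, 0.14), "boundary_irregularity": 0.06,
               "ellipticity_range": (0.80, 1.00)},
    "myopic": {"faz_radius_range": (0.12, 0.17), "boundary_irregularity": 0.14,
               "ellipticity_range": (0.70, 1.00)},
    "diabetic": {"faz_radius_range": (0.15, 0.22), "boundary_irregularity": 0.25,
                 "ellipticity_range": (0.60, 1.00)},
}

FAZ_FLOOR = 0.06
BG_FLOOR = 0.30
VESSEL_LEVEL = 0.85


@dataclass
class SynthConfig:
    n_images: int = 16
    size: int = 160
    faz_radius_range: tuple[float, float] = (0.10, 0.14)
    ellipticity_range: tuple[float, float] = (0.80, 1.00)
    boundary_irregularity: float = 0.06
    vessel_density: float = 0.35
    speckle_sigma: float = 0.08
    edge_softness: float = 1.0
    state: str = "normal"
    seed: int = 0

    def validate(self) -> None:
        rmin, rmax = self.faz_radius_range
        if not (0 < rmin <= rmax < 0.5):
            raise ValueError(f"need 0 < r_min <= r_max < 0.5, got {self.faz_radius_range}")
        if self.size < 32:
            raise ValueError(f"size must be >= 32, got {self.size}")
        if self.state not in STATE_PRESETS:
            raise ValueError(f"unknown state {self.state!r}; choose from {sorted(STATE_PRESETS)}")
        if not 0 <= self.vessel_density <= 1:
            raise ValueError(f"vessel_density must be in [0, 1], got {self.vessel_density}")
        if self.speckle_sigma < 0 or self.boundary_irregularity < 0:
            raise ValueError("speckle_sigma and boundary_irregularity must be >= 0")

    def with_state(self, state: str) -> "SynthConfig":
        """Copy with the state's radius/irregularity/ellipticity presets applied."""
        return replace(self, state=state, **STATE_PRESETS[state])


@dataclass
class SamplePair:
    image: np.ndarray  # 2-D float in [0, 1]
    mask: np.ndarray   # 2-D uint8 in {0, 1}
    metadata: dict = field(default_factory=dict)
    name: str = ""


def generate_faz_mask(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Star-convex FAZ mask about the image centre.

    The boundary is r(theta) = r0 * e(theta) * (1 + a * P(theta)) with e an
    equal-area ellipse profile and P a smooth periodic perturbation
    normalised to max |P| = 1, so the area stays within the configured
    radius band up to the perturbation bound.
    """
    config.validate()
    size = config.size
    rmin, rmax = config.faz_radius_range
    if rmax * size < 2:
        raise ValueError("degenerate radius range: FAZ smaller than 2 px")
    r0 = rng.uniform(rmin, rmax) * size
    q = rng.uniform(*config.ellipticity_range)
    phi = rng.uniform(0, np.pi)
    a_ax, b_ax = r0 / np.sqrt(q), r0 * np.sqrt(q)  # pi*a*b == pi*r0^2

    # smooth periodic radial perturbation, harmonics 2..5
    coeffs = rng.normal(size=(4, 2))
    theta_dense = np.linspace(0, 2 * np.pi, 720, endpoint=False)

    def perturb(theta):
        p = np.zeros_like(theta)
        for m, (cm, sm) in zip(range(2, 6), coeffs):
            p = p + cm * np.cos(m * theta) + sm * np.sin(m * theta)
        return p

    scale = np.abs(perturb(theta_dense)).max()
    amp = config.boundary_irregularity
    cy = cx = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    psi = theta - phi
    ell = a_ax * b_ax / np.sqrt((b_ax * np.cos(psi)) ** 2 + (a_ax * np.sin(psi)) ** 2)
    modulation = 1.0 + amp * (perturb(theta) / scale if scale > 0 else 0.0)
    r = ell * np.clip(modulation, 0.2, None)
    mask = (np.hypot(dy, dx) <= r)

    # guarantee a single 4-connected component containing the centre
    lab, _ = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    centre_label = lab[size // 2, size // 2]
    if centre_label == 0:
        mask = np.hypot(dy, dx) <= max(r0, 2.0)
    else:
        mask = lab == centre_label
    return ndimage.binary_fill_holes(mask).astype(np.uint8)


def render_octa_image(mask: np.ndarray, config: SynthConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Bright vessel texture outside the mask, dark floor inside, speckle on top."""
    config.validate()
    mask = np.asarray(mask)
    size = mask.shape[0]
    noise = rng.normal(size=mask.shape)
    band = ndimage.gaussian_filter(noise, 1.2) - ndimage.gaussian_filter(noise, 4.0)
    if config.vessel_density > 0:
        thr = np.quantile(band, 1.0 - config.vessel_density)
        vessels = band > thr
    else:
        vessels = np.zeros_like(mask, dtype=bool)
    background = np.where(vessels, VESSEL_LEVEL, BG_FLOOR)
    m = mask.astype(np.float64)
    if config.edge_softness > 0:
        m = ndimage.gaussian_filter(m, config.edge_softness)
    img = (1.0 - m) * background + m * FAZ_FLOOR
    if config.speckle_sigma > 0:
        img = img * (1.0 + config.speckle_sigma * rng.normal(size=mask.shape))
    img = np.clip(img, 0.0, 1.0)
    return np.round(img * 255.0) / 255.0  # 8-bit levels: PNG round-trip exact


def generate_dataset(config: SynthConfig) -> list[SamplePair]:
    """n_images deterministic samples; sample i uses substream (seed, i)."""
    config.validate()
    pairs = []
    for i in range(config.n_images):
        rng = np.random.default_rng((config.seed, i))
        mask = generate_faz_mask(config, rng)
        image = render_octa_image(mask, config, rng)
        pairs.append(SamplePair(
            image=image, mask=mask,
            metadata={"state": config.state, "seed": config.seed, "index": i},
            name=f"{config.state}_{config.seed:04d}_{i:04d}"))
    return pairs


def generate_mixed_dataset(config: SynthConfig,
                           states=("normal", "myopic", "diabetic")) -> list[SamplePair]:
    """Round-robin over clinical-state presets, n_images total."""
    per_state = {s: config.with_state(s) for s in states}
    pairs = []
    for i in range(config.n_images):
        state = states[i % len(states)]
        cfg = per_state[state]
        rng = np.random.default_rng((config.seed, i))
        mask = generate_faz_mask(cfg, rng)
        image = render_octa_image(mask, cfg, rng)
        pairs.append(SamplePair(
            image=image, mask=mask,
            metadata={"state": state, "seed": config.seed, "index": i},
            name=f"{state}_{config.seed:04d}_{i:04d}"))
    return pairs


# -- folder I/O -----------------------------------------------------------

def write_folder(pairs: list[SamplePair], out_dir, manifest: bool = True) -> None:
    """PNG pairs under out_dir/images and out_dir/masks plus a manifest CSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        img8 = np.round(np.clip(pair.image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out / "images" / f"{pair.name}.png")
        Image.fromarray((pair.mask * 255).astype(np.uint8), mode="L").save(
            out / "masks" / f"{pair.name}.png")
    if manifest:
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["filename", "state", "split"])
            for pair in pairs:
                w.writerow([f"{pair.name}.png", pair.metadata.get("state", ""), ""])


def load_folder_dataset(image_dir, mask_dir, strict_square: bool = False) -> list[SamplePair]:
    """Matched image/mask PNG folders -> SamplePairs sorted by filename."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    img_names = {p.name for p in image_dir.iterdir() if p.is_file()}
    mask_names = {p.name for p in mask_dir.iterdir() if p.is_file()}
    if not img_names and not mask_names:
        raise ValueError(f"no samples found in {image_dir} / {mask_dir}")
    unmatched = img_names ^ mask_names
    if unmatched:
        raise ValueError(f"unmatched image/mask filenames: {sorted(unmatched)[:5]}")
    pairs = []
    for name in sorted(img_names):
        img = Image.open(image_dir / name).convert("L")
        msk = Image.open(mask_dir / name).convert("L")
        image = np.asarray(img, dtype=np.float64) / 255.0
        mask = (np.asarray(msk) > 127).astype(np.uint8)
        if image.shape != mask.shape:
            raise ValueError(f"{name}: image shape {image.shape} != mask shape {mask.shape}")
        if strict_square and image.shape[0] != image.shape[1]:
            raise ValueError(f"{name}: non-square image {image.shape} with strict flag set")
        pairs.append(SamplePair(image=image, mask=mask, metadata={}, name=Path(name).stem))
    return pairs


def split_dataset(pairs: list, ratio: float, seed: int) -> tuple[list, list]:
    """Seeded shuffle then |train| = round(ratio * n) split."""
    if not 0 < ratio < 1:
        raise ValueError(f"split ratio must be in (0, 1), got {ratio}")
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need at least 2 samples to split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratio * n))
    train = [pairs[i] for i in order[:n_train]]
    test = [pairs[i] for i in order[n_train:]]
    return train, test
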