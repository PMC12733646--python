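"""Seeded synthetic histology-texture dataset in class-folder layout.

Generates five balanced classes of RGB patches that mimic the coarse visual
statistics of H&E-stained lung/colon tissue: an eosin-pink cytoplasm
background, hematoxylin-dark nuclei planted as soft-edged disks at a
class-specific Poisson density, and optional ring-shaped gland lumina. The
background distribution is shared across classes, so the only
class-discriminative signal lives in the planted structures (their density,
size, colour and gland content) — which makes the planted-structure mask a
ground-truth region for saliency checks.

This is a stand-in texture model for pipeline testing, with no claim of
biological realism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Texture statistics for one synthetic tissue class.

    nuclei_density is the expected nucleus count per 10^4 px^2; colours are
    RGB means in [0,1] with a uniform jitter half-width.
    """

    name: str
    nuclei_density: float
    nucleus_radius: tuple[float, float]
    nucleus_color: tuple[float, float, float]
    nucleus_jitter: float = 0.04
    cytoplasm_color: tuple[float, float, float] = (0.90, 0.76, 0.83)
    cytoplasm_jitter: float = 0.02
    gland_probability: float = 0.0
    gland_count: int = 2
    gland_radius: tuple[float, float] = (12.0, 20.0)
    noise_sd: float = 0.02

    def __post_init__(self):
        for p in (self.gland_probability,):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if min(self.nucleus_radius) <= 0 or min(self.gland_radius) <= 0:
            raise ValueError("radii must be positive")
        for col in (self.nucleus_color, self.cytoplasm_color):
            if not all(0.0 <= v <= 1.0 for v in col):
                raise ValueError(f"colors must lie in [0,1]^3, got {col}")
        if self.nuclei_density < 0 or self.noise_sd < 0:
            raise ValueError("density and noise_sd must be nonnegative")


def default_class_specs() -> tuple[SyntheticClassSpec, ...]:
    """Five classes echoing the benign/malignant contrasts of lung/colon patches.

    Two "benign-like" classes carry sparser, regular structure (ordered gland
    rings, small pale nuclei); three "malignant-like" classes carry dense,
    irregular, hyperchromatic nuclei. All share the same cytoplasm background.
    """
    return (
        SyntheticClassSpec(
            name="colon_adenocarcinoma", nuclei_density=55.0, nucleus_radius=(3.0, 5.0),
            nucleus_color=(0.32, 0.18, 0.52), gland_probability=0.9, gland_count=3,
            gland_radius=(10.0, 16.0)),
        SyntheticClassSpec(
            name="colon_benign", nuclei_density=22.0, nucleus_radius=(2.0, 3.0),
            nucleus_color=(0.48, 0.34, 0.62), gland_probability=1.0, gland_count=5,
            gland_radius=(14.0, 20.0)),
        SyntheticClassSpec(
            name="lung_adenocarcinoma", nuclei_density=45.0, nucleus_radius=(2.0, 3.5),
            nucleus_color=(0.22, 0.26, 0.60), gland_probability=0.4, gland_count=1,
            gland_radius=(8.0, 12.0)),
        SyntheticClassSpec(
            name="lung_benign", nuclei_density=18.0, nucleus_radius=(1.5, 2.5),
            nucleus_color=(0.55, 0.42, 0.68), gland_probability=0.0),
        SyntheticClassSpec(
            name="lung_squamous_cell_carcinoma", nuclei_density=75.0,
            nucleus_radius=(3.5, 6.0), nucleus_color=(0.42, 0.14, 0.44),
            gland_probability=0.0),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    class_specs: tuple[SyntheticClassSpec, ...] = field(default_factory=default_class_specs)
    images_per_class: int = 200
    image_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if len(self.class_specs) < 2:
            raise ValueError("need at least two class specs")


# ------------------------------------------------------------------ rendering

def _paint_disk(img, mask, cy, cx, radius, color, yy, xx):
    """Alpha-composite a soft-edged disk; mark its support in the mask."""
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    img *= (1 - alpha)[..., None]
    img += alpha[..., None] * np.asarray(color)
    mask |= alpha > 0.5


def _paint_ring(img, mask, cy, cx, radius, thickness, border_color, lumen_color, yy, xx):
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    lumen = np.clip(radius - thickness + 0.5 - dist, 0.0, 1.0)
    border = np.clip(radius + 0.5 - dist, 0.0, 1.0) - lumen
    for a, col in ((border, border_color), (lumen, lumen_color)):
        img *= (1 - a)[..., None]
        img += a[..., None] * np.asarray(col)
    mask |= (border + lumen) > 0.5


def generate_image(spec: SyntheticClassSpec, rng: np.random.Generator,
                   size: int = 128, return_mask: bool = False):
    """One H×W×3 float image in [0,1]; optionally also the structure mask."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    jitter = rng.uniform(-spec.cytoplasm_jitter, spec.cytoplasm_jitter, 3)
    bg = np.clip(np.asarray(spec.cytoplasm_color) + jitter, 0, 1)
    img = np.ones((size, size, 3), dtype=np.float64) * bg
    mask = np.zeros((size, size), dtype=bool)

    if spec.gland_probability > 0:
        for _ in range(spec.gland_count):
            if rng.random() < spec.gland_probability:
                r = min(rng.uniform(*spec.gland_radius), size / 2 - 1)
                cy, cx = rng.uniform(r, size - r, 2)
                border = np.clip(np.asarray(spec.nucleus_color) + 0.08, 0, 1)
                lumen = np.clip(bg + 0.07, 0, 1)
                _paint_ring(img, mask, cy, cx, r, 3.0, border, lumen, yy, xx)

    n_nuclei = rng.poisson(spec.nuclei_density * size * size / 1e4)
    for _ in range(n_nuclei):
        r = rng.uniform(*spec.nucleus_radius)
        cy, cx = rng.uniform(0, size, 2)
        col = np.clip(np.asarray(spec.nucleus_color)
                      + rng.uniform(-spec.nucleus_jitter, spec.nucleus_jitter, 3), 0, 1)
        _paint_disk(img, mask, cy, cx, r, col, yy, xx)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return (img, mask) if return_mask else img


# ----------------------------------------------------------------- generation

def _child_seeds(master_seed: int, n_classes: int, images_per_class: int) -> np.ndarray:
    """One independent child seed per image, derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([s.generate_state(1)[0] % (2 ** 31)
                     for s in ss.spawn(n_classes * images_per_class)],
                    dtype=np.int64).reshape(n_classes, images_per_class)


def generate_arrays(config: GeneratorConfig | None = None, return_masks: bool = False):
    """In-memory dataset: (images N×H×W×3, labels, class_names[, masks])."""
    config = config or GeneratorConfig()
    specs = config.class_specs
    seeds = _child_seeds(config.seed, len(specs), config.images_per_class)
    images, labels, masks = [], [], []
    for ci, spec in enumerate(specs):
        for j in range(config.images_per_class):
            rng = np.random.default_rng(int(seeds[ci, j]))
            img, msk = generate_image(spec, rng, config.image_size, return_mask=True)
            images.append(img)
            labels.append(ci)
            masks.append(msk)
    images = np.stack(images)
    labels = np.asarray(labels, dtype=np.int64)
    names = [s.name for s in specs]
    if return_masks:
        return images, labels, names, np.stack(masks)
    return images, labels, names


def generate_dataset(config: GeneratorConfig | None = None, out_root=".") -> Path:
    """Write class-named folders of PNGs plus a manifest CSV; returns the root."""
    config = config or GeneratorConfig()
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    specs = config.class_specs
    seeds = _child_seeds(config.seed, len(specs), config.images_per_class)
    manifest_rows = []
    for ci, spec in enumerate(specs):
        cls_dir = out_root / spec.name
        cls_dir.mkdir(exist_ok=True)
        for j in range(config.images_per_class):
            seed = int(seeds[ci, j])
            rng = np.random.default_rng(seed)
            img = generate_image(spec, rng, config.image_size)
            fname = f"{spec.name}_{j:04d}.png"
            Image.fromarray((img * 255 + 0.5).astype(np.uint8)).save(cls_dir / fname)
            manifest_rows.append({
                "path": f"{spec.name}/{fname}", "class_name": spec.name,
                "label": ci, "seed": seed,
                "nuclei_density": spec.nuclei_density,
                "gland_probability": spec.gland_probability,
                "noise_sd": spec.noise_sd,
            })
    with open(out_root / "manifest.csv", "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=list(manifest_rows[0].keys()))
        writer.writeheader()
        writer.writerows(manifest_rows)
    return out_root
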