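"""Class-folder image loading, preprocessing, and stratified splitting.

Datasets follow the common "one subdirectory per class" layout (as in the
public lung/colon histopathology patch collection): the class index of an
image is the lexicographic rank of its folder name, so label indices are
reproducible across machines. Images are decoded as 8-bit RGB, resized with
bilinear interpolation, and scaled by 1/255 into [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class LabeledImageSet:
    images: np.ndarray  # (N, H, W, 3) float32 in [0, 1]
    labels: np.ndarray  # (N,) int
    class_names: list[str]
    source_paths: list[str] = field(default_factory=list)
    skipped: int = 0  # undecodable files dropped during loading

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx)
        return LabeledImageSet(
            images=self.images[idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            source_paths=[self.source_paths[i] for i in idx] if self.source_paths else [],
        )


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(self.fractions)}")


def preprocess_image(img: Image.Image, target_size: tuple[int, int]) -> np.ndarray:
    """RGB decode, bilinear resize to (height, width), scale to [0, 1]."""
    if img.mode != "RGB":
        if img.mode in ("L", "I", "I;16", "1"):
            warnings.warn("grayscale source replicated to 3 channels")
        img = img.convert("RGB")
    h, w = target_size
    if img.size != (w, h):
        img = img.resize((w, h), Image.BILINEAR)
    return np.asarray(img, dtype=np.float32) / 255.0


def load_image_dir(root, target_size: tuple[int, int] = (128, 128)) -> LabeledImageSet:
    """Load a class-folder tree into a LabeledImageSet.

    Class index = lexicographic rank of the subdirectory name. Undecodable
    files are skipped with a warning and counted in the load report.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class subdirectories")
    images, labels, paths = [], [], []
    skipped = 0
    class_names = [d.name for d in class_dirs]
    for label, d in enumerate(class_dirs):
        for p in sorted(d.iterdir()):
            if p.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            try:
                with Image.open(p) as im:
                    arr = preprocess_image(im, target_size)
            except Exception as exc:  # undecodable file
                warnings.warn(f"skipping undecodable image {p}: {exc}")
                skipped += 1
                continue
            images.append(arr)
            labels.append(label)
            paths.append(str(p))
    if not images:
        raise ValueError(f"no decodable images under {root}")
    logger.info("loaded %d images (%d skipped) from %s", len(images), skipped, root)
    return LabeledImageSet(
        images=np.stack(images), labels=np.asarray(labels, dtype=np.int64),
        class_names=class_names, source_paths=paths, skipped=skipped)


def _largest_remainder(n: int, fractions) -> list[int]:
    """Allocate n items to len(fractions) bins by largest-remainder rounding."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    short = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def stratified_split(data: LabeledImageSet, spec: SplitSpec | None = None
                     ) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Per-class largest-remainder allocation into train/val/test.

    The within-class order is shuffled by the spec's seed; the three parts
    partition the input exactly.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    parts: list[list[int]] = [[], [], []]
    if spec.stratified:
        for label, name in enumerate(data.class_names):
            idx = np.flatnonzero(data.labels == label)
            if len(idx) == 0:
                continue
            counts = _largest_remainder(len(idx), spec.fractions)
            if any(c == 0 for c in counts):
                raise ValueError(
                    f"class {name!r} has only {len(idx)} members; too small to "
                    f"appear in all splits at fractions {spec.fractions}")
            idx = rng.permutation(idx)
            bounds = np.cumsum(counts)[:-1]
            for part, chunk in zip(parts, np.split(idx, bounds)):
                part.extend(chunk.tolist())
    else:
        idx = rng.permutation(len(data))
        counts = _largest_remainder(len(idx), spec.fractions)
        bounds = np.cumsum(counts)[:-1]
        for part, chunk in zip(parts, np.split(idx, bounds)):
            part.extend(chunk.tolist())
    return tuple(data.subset(sorted(p)) for p in parts)


# ------------------------------------------------------------------ manifests

def write_split_manifest(path, splits: dict[str, LabeledImageSet]) -> None:
    """CSV manifest (path, class_name, label, split) so splits are reconstructible."""
    rows = []
    for split_name, part in splits.items():
        for i in range(len(part)):
            rows.append({
                "path": part.source_paths[i] if part.source_paths else "",
                "class_name": part.class_names[part.labels[i]],
                "label": int(part.labels[i]),
                "split": split_name,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_split_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
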