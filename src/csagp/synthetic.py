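"""Synthetic paired-modality datasets with controllable class structure.

Each subject gets a smooth elliptical "brain" background (Gaussian-blurred
noise inside a brain-shaped mask) rendered into an MRI-like and a PET-like
image.  Class identity is carried by soft elliptical "lesion" intensity
offsets at class-specific loci; a configurable fraction of that signal is
common to both modalities and the remainder lives at modality-specific
loci, so the two modalities can be made complementary (``shared_fraction=0``
puts disjoint halves of the class signal in each modality).  Independent
per-modality pixel noise is added on top.

This emulates the *geometry* of paired axial neuroimage slices — shared
anatomy, localized class effects, modality-specific appearance — not the
physics of MR contrast or FDG uptake.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import ImagePair

__all__ = ["SynthConfig", "LESION_TABLE", "lesion_masks", "signal_region",
           "generate_dataset", "split", "to_png_dir", "from_png_dir",
           "to_npz", "from_npz"]


# Lesion geometry per class: (center_y, center_x, radius_y, radius_x, weight)
# in fractional image coordinates.  Loci and total mass differ across
# classes so the signal is recoverable both locally and in the image mean;
# the "mri"/"pet" entries are the modality-specific halves of the signal.
LESION_TABLE: dict[int, dict[str, list[tuple]]] = {
    0: {
        "shared": [(0.32, 0.35, 0.06, 0.05, 0.6)],
        "mri": [(0.62, 0.30, 0.06, 0.05, 0.6)],
        "pet": [(0.30, 0.62, 0.06, 0.05, 0.6)],
    },
    1: {
        "shared": [(0.60, 0.62, 0.13, 0.11, 1.2), (0.40, 0.55, 0.08, 0.08, 1.0)],
        "mri": [(0.35, 0.65, 0.12, 0.10, 1.2)],
        "pet": [(0.65, 0.38, 0.12, 0.10, 1.2)],
    },
    2: {
        "shared": [(0.50, 0.40, 0.15, 0.13, 1.4), (0.30, 0.60, 0.10, 0.08, 1.2)],
        "mri": [(0.68, 0.55, 0.13, 0.11, 1.4)],
        "pet": [(0.45, 0.70, 0.13, 0.11, 1.4)],
    },
}

_BRAIN_ELLIPSE = (0.5, 0.5, 0.44, 0.40)  # outline of the "slice"


@dataclass
class SynthConfig:
    """Generator settings; defaults give a strongly learnable 2-class task."""

    n_per_class: int = 30
    n_classes: int = 2
    img_size: tuple[int, int] = (64, 64)
    signal_amplitude: float = 1.0     # lesion intensity offset
    modality_noise: float = 0.1       # iid pixel noise std per modality
    shared_fraction: float = 0.5      # fraction of class signal common to both
    background_std: float = 0.05      # smooth background variation
    background_blur: float = 8.0      # blur sigma (px) of the background field
    lesion_blur: float = 1.5          # soft lesion edges (px)
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if min(self.signal_amplitude, self.modality_noise,
               self.background_std) < 0:
            raise ValueError("amplitudes and noise stds must be >= 0")
        self.img_size = tuple(self.img_size)


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float,
                  ry: float, rx: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ((((yy / h - cy) / ry) ** 2 + ((xx / w - cx) / rx) ** 2) <= 1.0
            ).astype(np.float64)


@lru_cache(maxsize=16)
def lesion_masks(img_size: tuple[int, int],
                 lesion_blur: float) -> dict[int, dict[str, np.ndarray]]:
    """Per-class, per-part soft lesion masks at the given image size."""
    masks: dict[int, dict[str, np.ndarray]] = {}
    for label, parts in LESION_TABLE.items():
        masks[label] = {}
        for part, ellipses in parts.items():
            m = np.zeros(img_size)
            for cy, cx, ry, rx, weight in ellipses:
                m += weight * _ellipse_mask(img_size, cy, cx, ry, rx)
            masks[label][part] = gaussian_filter(m, lesion_blur)
    return masks


def signal_region(img_size: tuple[int, int], n_classes: int,
                  lesion_blur: float = 1.5) -> np.ndarray:
    """Boolean union of all lesion loci used by the first n_classes classes."""
    masks = lesion_masks(tuple(img_size), lesion_blur)
    total = np.zeros(img_size)
    for label in range(n_classes):
        for part in masks[label].values():
            total += part
    return total > 1e-3


def _background(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal(cfg.img_size),
                            cfg.background_blur)
    sd = field.std()
    if sd > 0:
        field = field / sd * cfg.background_std
    return 0.5 + field


def _render_subject(rng: np.random.Generator, label: int,
                    cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    masks = lesion_masks(cfg.img_size, cfg.lesion_blur)[label]
    brain = gaussian_filter(_ellipse_mask(cfg.img_size, *_BRAIN_ELLIPSE), 1.0)
    sf, amp = cfg.shared_fraction, cfg.signal_amplitude
    images = []
    for modality in ("mri", "pet"):
        img = _background(rng, cfg)
        img += amp * (sf * masks["shared"] + (1.0 - sf) * masks[modality])
        img *= brain
        img += rng.normal(0.0, cfg.modality_noise, cfg.img_size)
        images.append(np.clip(img, 0.0, 1.0 + amp))
    return images[0], images[1]


def generate_dataset(cfg: SynthConfig) -> list[ImagePair]:
    """Deterministic (given cfg.seed) list of labelled image pairs,
    interleaved across classes."""
    rng = np.random.default_rng(cfg.seed)
    pairs: list[ImagePair] = []
    idx = 0
    for _ in range(cfg.n_per_class):
        for label in range(cfg.n_classes):
            mri, pet = _render_subject(rng, label, cfg)
            pairs.append(ImagePair(mri=mri, pet=pet, label=label,
                                   subject_id=f"s{idx:04d}"))
            idx += 1
    return pairs


def split(dataset: list[ImagePair],
          fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
          seed: int = 0) -> tuple[list[ImagePair], list[ImagePair], list[ImagePair]]:
    """Subject-level disjoint random train/val/test split (default 60/20/20)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n = len(dataset)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train = [dataset[i] for i in order[:n_train]]
    val = [dataset[i] for i in order[n_train:n_train + n_val]]
    test = [dataset[i] for i in order[n_train + n_val:]]
    return train, val, test


# -- disk round-trips ---------------------------------------------------------

def to_png_dir(dataset: list[ImagePair], out_dir: str | Path,
               scale: float | None = None) -> None:
    """class_<label>/<subject>_{mri,pet}.png, 8-bit grayscale."""
    from PIL import Image

    out_dir = Path(out_dir)
    if scale is None:
        scale = max(float(np.max([p.mri.max() for p in dataset])), 1.0)
    for pair in dataset:
        d = out_dir / f"class_{pair.label}"
        d.mkdir(parents=True, exist_ok=True)
        for name, img in (("mri", pair.mri), ("pet", pair.pet)):
            arr = np.clip(img / scale * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(
                d / f"{pair.subject_id}_{name}.png")


def from_png_dir(in_dir: str | Path) -> list[ImagePair]:
    from PIL import Image

    in_dir = Path(in_dir)
    pairs = []
    for class_dir in sorted(in_dir.glob("class_*")):
        label = int(class_dir.name.split("_")[1])
        for mri_path in sorted(class_dir.glob("*_mri.png")):
            subject = mri_path.name[:-len("_mri.png")]
            pet_path = class_dir / f"{subject}_pet.png"
            mri = np.asarray(Image.open(mri_path), dtype=np.float64) / 255.0
            pet = np.asarray(Image.open(pet_path), dtype=np.float64) / 255.0
            pairs.append(ImagePair(mri=mri, pet=pet, label=label,
                                   subject_id=subject))
    return pairs


def to_npz(dataset: list[ImagePair], path: str | Path) -> None:
    np.savez_compressed(
        path,
        mri=np.stack([p.mri for p in dataset]),
        pet=np.stack([p.pet for p in dataset]),
        labels=np.array([p.label for p in dataset]),
        subject_ids=np.array([p.subject_id for p in dataset]),
    )


def from_npz(path: str | Path) -> list[ImagePair]:
    with np.load(path, allow_pickle=False) as data:
        return [ImagePair(mri=m, pet=p, label=int(l), subject_id=str(s))
                for m, p, l, s in zip(data["mri"], data["pet"],
                                      data["labels"], data["subject_ids"])]
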