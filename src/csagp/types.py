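"""Core domain objects passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

__all__ = ["ImagePair", "TokenSequence", "Prediction"]


@dataclass
class ImagePair:
    """One supervised unit: an MRI-like and a PET-like slice plus a label.

    Both images must share spatial dimensions; arrays are (H, W) grayscale
    or (3, H, W) channel-first.
    """

    mri: np.ndarray
    pet: np.ndarray
    label: int
    subject_id: str = ""

    def __post_init__(self):
        self.mri = np.asarray(self.mri, dtype=np.float64)
        self.pet = np.asarray(self.pet, dtype=np.float64)
        if self._spatial(self.mri) != self._spatial(self.pet):
            raise ValueError(
                f"mri and pet spatial shapes differ: "
                f"{self._spatial(self.mri)} vs {self._spatial(self.pet)}")
        if not (np.isfinite(self.mri).all() and np.isfinite(self.pet).all()):
            raise ValueError("image intensities must be finite")
        self.label = int(self.label)

    @staticmethod
    def _spatial(img: np.ndarray) -> tuple[int, int]:
        if img.ndim == 2:
            return img.shape
        if img.ndim == 3 and img.shape[0] == 3:
            return img.shape[1:]
        raise ValueError(f"expected (H, W) or (3, H, W) image, got {img.shape}")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self._spatial(self.mri)


@dataclass
class TokenSequence:
    """A class token followed by N patch tokens, as one (N+1, D) tensor."""

    tokens: Tensor

    def __post_init__(self):
        if self.tokens.ndim != 2 or self.tokens.shape[0] < 1:
            raise ValueError(f"tokens must be (L, D) with L >= 1, "
                             f"got {self.tokens.shape}")

    @property
    def cls(self) -> Tensor:
        return self.tokens[0:1]

    @property
    def patches(self) -> Tensor:
        return self.tokens[1:]

    @property
    def length(self) -> int:
        return self.tokens.shape[0]

    @property
    def dim(self) -> int:
        return self.tokens.shape[1]


@dataclass
class Prediction:
    """Classifier output for one image pair."""

    logits: np.ndarray
    probabilities: np.ndarray = field(default=None)

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.probabilities is None:
            z = self.logits - self.logits.max()
            e = np.exp(z)
            self.probabilities = e / e.sum()
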