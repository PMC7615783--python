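"""Convolutional patch embedding: image -> positional-encoded token sequence.

Instead of the single linear projection of the original ViT, the stem is a
three-convolution pyramid — a 7x7 convolution with stride 4 and padding 3
followed by two 3x3 convolutions with stride 2 and padding 1 — giving an
overall downsampling factor of 16 and better low-level feature extraction
on medical slices.  The flattened D-channel grid becomes the patch-token
matrix; a learned class token is prepended and a learned positional
encoding is added.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Module, Tensor, concat, trunc_normal
from .types import TokenSequence

__all__ = ["ConvStem", "PatchEmbed", "stem_grid_shape", "prepare_image"]

STEM_FACTOR = 16  # 4 * 2 * 2


def stem_grid_shape(img_size: tuple[int, int]) -> tuple[int, int]:
    """Spatial grid of the stem output; raises if the strides do not tile."""
    h, w = img_size
    for side, name in ((h, "height"), (w, "width")):
        if side < STEM_FACTOR or side % STEM_FACTOR:
            raise ValueError(
                f"image {name} {side} must be >= {STEM_FACTOR} and divisible "
                f"by {STEM_FACTOR} (stem strides 4*2*2 must tile exactly)")
    return h // STEM_FACTOR, w // STEM_FACTOR


def prepare_image(img: np.ndarray) -> np.ndarray:
    """Coerce an (H, W) or (3, H, W) or (H, W, 3) image to (3, H, W).

    Grayscale slices are replicated across three channels so a single stem
    handles both photographic exports and raw slice arrays.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return np.repeat(img[None], 3, axis=0)
    if img.ndim == 3 and img.shape[0] == 3:
        return img
    if img.ndim == 3 and img.shape[-1] == 3:
        return img.transpose(2, 0, 1)
    raise ValueError(f"cannot interpret image of shape {img.shape}")


class ConvStem(Module):
    """ReLU(Conv3(ReLU(Conv2(ReLU(Conv1(x)))))) with channel widths
    doubling toward the embedding dimension D."""

    def __init__(self, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        c1 = max(embed_dim // 4, 4)
        c2 = max(embed_dim // 2, 8)
        self.conv1 = Conv2d(3, c1, 7, rng, stride=4, padding=3)
        self.conv2 = Conv2d(c1, c2, 3, rng, stride=2, padding=1)
        self.conv3 = Conv2d(c2, embed_dim, 3, rng, stride=2, padding=1)
        self.embed_dim = embed_dim

    def forward(self, img: np.ndarray | Tensor) -> Tensor:
        """(3, H, W) image -> (D, H/16, W/16) feature map."""
        if isinstance(img, Tensor):
            x = img
            h, w = x.shape[1:]
        else:
            img = prepare_image(img)
            h, w = img.shape[1:]
            x = Tensor(img)
        stem_grid_shape((h, w))
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        x = self.conv3(x).relu()
        return x


class PatchEmbed(Module):
    """Full tokenizer: stem, flatten, class token, positional encoding."""

    def __init__(self, img_size: tuple[int, int], embed_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.img_size = tuple(img_size)
        self.grid = stem_grid_shape(self.img_size)
        self.n_patches = self.grid[0] * self.grid[1]
        self.stem = ConvStem(embed_dim, rng)
        self.cls_token = Tensor(trunc_normal(rng, (1, embed_dim)),
                                requires_grad=True)
        self.pos_embed = Tensor(
            trunc_normal(rng, (self.n_patches + 1, embed_dim)),
            requires_grad=True)

    def flatten_grid(self, fmap: Tensor) -> Tensor:
        """(D, Gh, Gw) -> (N, D) in row-major raster order."""
        d = fmap.shape[0]
        return fmap.reshape(d, -1).transpose()

    def forward(self, img: np.ndarray) -> TokenSequence:
        img = prepare_image(img)
        if img.shape[1:] != self.img_size:
            raise ValueError(f"expected image of size {self.img_size}, "
                             f"got {img.shape[1:]}")
        fmap = self.stem(img)
        patches = self.flatten_grid(fmap)
        seq = concat([self.cls_token, patches], axis=0) + self.pos_embed
        return TokenSequence(seq)
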