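"""Loading photographic slice exports and NIfTI volumes.

Only a thin slice-extraction helper is provided for NIfTI input: volumes
are assumed already registered/skull-stripped upstream; axial slices are
taken by index (default 80-100, the mid-brain range of a 181-slice
resampled volume), min-max normalized and rescaled to the model's input
size.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["load_image", "extract_axial_slices", "DEFAULT_SLICE_RANGE"]

DEFAULT_SLICE_RANGE = range(80, 101)  # inclusive 80-100


def load_image(path: str | Path, size: tuple[int, int] | None = None,
               grayscale: bool = True) -> np.ndarray:
    """PNG/JPEG -> float array in [0, 1], optionally resized to (H, W)."""
    from PIL import Image

    img = Image.open(path)
    img = img.convert("L" if grayscale else "RGB")
    if size is not None:
        img = img.resize((size[1], size[0]), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float64) / 255.0
    if not grayscale:
        arr = arr.transpose(2, 0, 1)
    return arr


def _resize2d(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    from PIL import Image

    img = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(img.resize((size[1], size[0]), Image.BILINEAR),
                      dtype=np.float64)


def extract_axial_slices(path: str | Path,
                         indices=DEFAULT_SLICE_RANGE,
                         size: tuple[int, int] | None = None
                         ) -> list[np.ndarray]:
    """Axial (last-axis) slices of a NIfTI volume, each min-max normalized."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {vol.shape}")
    n_slices = vol.shape[2]
    out = []
    for i in indices:
        if not 0 <= i < n_slices:
            raise IndexError(f"slice index {i} out of range for volume "
                             f"with {n_slices} axial slices")
        sl = vol[:, :, i]
        lo, hi = sl.min(), sl.max()
        sl = (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)
        if size is not None:
            sl = _resize2d(sl, size)
        out.append(sl)
    return out
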