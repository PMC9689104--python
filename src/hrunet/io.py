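"""PNG I/O helpers: 8-bit grayscale images in [0,1], binary masks as 0/255."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def save_image(path, image: np.ndarray) -> None:
    """Write a float [0,1] grid as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float32), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * np.uint8(255)))


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float32 in [0,1] (RGB is averaged)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    arr = arr.astype(np.float32)
    if arr.max() > 1.0:
        arr /= 255.0
    return arr


def load_mask(path) -> np.ndarray:
    """Read a mask PNG as uint8 {0,1} (any nonzero pixel is foreground)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return (arr > 0).astype(np.uint8)
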