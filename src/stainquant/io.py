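"""Image file reading and writing (TIFF and PNG, 8/16-bit, gray and RGB).

The pipeline works on float arrays in [0, 1]; integer files are rescaled by
their dtype maximum on load and quantised back on save.
"""

from __future__ import annotations

import imageio.v3 as iio
import numpy as np


def read_image(path) -> np.ndarray:
    """Load an image as float64 in [0, 1] (alpha channel dropped if present)."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_image(path, image, bitdepth: int = 8) -> None:
    """Save a [0, 1] float image as 8- or 16-bit integer TIFF/PNG."""
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bitdepth == 8:
        out = np.round(img * 255).astype(np.uint8)
    elif bitdepth == 16:
        out = np.round(img * 65535).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    iio.imwrite(path, out)


def write_mask(path, mask) -> None:
    """Save a binary mask as an 8-bit image (0/255)."""
    iio.imwrite(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)
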