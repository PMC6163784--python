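"""Calibration-based illumination correction and shared raster utilities.

All images are NumPy arrays with floating-point values in the nominal range
[0, 1]: 2-D arrays for single-channel (grayscale) images and ``(H, W, 3)``
arrays for RGB.  Every normalisation step clips back into [0, 1].

Flat-field correction follows the standard brightfield/darkfield scheme: an
empty-slide brightfield reference captures the illumination profile of the
optical path, a closed-shutter darkfield reference captures the sensor
offset, and the corrected image is the per-pixel, per-channel ratio

    corrected = (original - darkfield) / (brightfield - darkfield)

The denominator is floored at ``EPS`` so that locally invalid calibration
pixels degrade gracefully instead of blowing up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

#: Floor for the flat-field denominator (and other divisions by intensity).
EPS = 1e-6

#: Rec. 601 luma weights used for the luminance channel.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def as_image(pixels) -> np.ndarray:
    """Coerce to a float image array and validate its layout.

    Accepts 2-D (gray) or ``(H, W, 3)`` (RGB) arrays with ``H, W >= 1``.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise ValueError(f"image must be 2-D or (H, W, 3), got shape {arr.shape}")
    if arr.ndim == 3 and arr.shape[2] != 3:
        raise ValueError(f"color images must have 3 channels, got {arr.shape[2]}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have height >= 1 and width >= 1")
    return arr


@dataclass(frozen=True)
class CalibrationPair:
    """Brightfield (empty slide) and darkfield (closed light path) references.

    Both references must match the dimensions and channel count of the images
    they correct.  A pair whose brightfield does not exceed its darkfield
    anywhere carries no illumination information and is rejected.
    """

    brightfield: np.ndarray
    darkfield: np.ndarray

    def __post_init__(self):
        bf = as_image(self.brightfield)
        df = as_image(self.darkfield)
        if bf.shape != df.shape:
            raise ValueError(
                f"brightfield shape {bf.shape} != darkfield shape {df.shape}"
            )
        if not np.any(bf > df):
            raise ValueError(
                "invalid calibration: brightfield <= darkfield everywhere"
            )
        object.__setattr__(self, "brightfield", bf)
        object.__setattr__(self, "darkfield", df)

    @classmethod
    def identity(cls, shape) -> "CalibrationPair":
        """Calibration that leaves images unchanged (flat field, zero offset)."""
        return cls(np.ones(shape), np.zeros(shape))


def correct_illumination(image, calib: CalibrationPair) -> np.ndarray:
    """Flat-field correct ``image`` with a brightfield/darkfield pair.

    Returns ``(image - darkfield) / (brightfield - darkfield)`` per pixel and
    channel, with the denominator floored at :data:`EPS` and the result
    clipped to [0, 1].
    """
    img = as_image(image)
    if img.shape != calib.brightfield.shape:
        raise ValueError(
            f"image shape {img.shape} does not match calibration "
            f"shape {calib.brightfield.shape}"
        )
    denom = np.maximum(calib.brightfield - calib.darkfield, EPS)
    return np.clip((img - calib.darkfield) / denom, 0.0, 1.0)


def to_luminance(image) -> np.ndarray:
    """Rec. 601 luminance of an RGB image (``0.299 R + 0.587 G + 0.114 B``).

    Single-channel input is returned unchanged (with a logged notice) so the
    function is safe to call on already-gray images.
    """
    img = as_image(image)
    if img.ndim == 2:
        logger.info("to_luminance called on a single-channel image; returned as-is")
        return img
    return np.clip(img @ LUMA_WEIGHTS, 0.0, 1.0)


def resize_to_width(image, target_width: int) -> np.ndarray:
    """Resize preserving aspect ratio so that the width equals ``target_width``.

    Height is rounded to the nearest integer (at least 1).  Downscaling is
    anti-aliased (area-averaging behaviour); upscaling is permitted but logged,
    since in this pipeline it only occurs on the mask path.
    """
    img = as_image(image)
    if target_width < 1:
        raise ValueError("target_width must be >= 1")
    h, w = img.shape[:2]
    if target_width == w:
        return img
    if target_width > w:
        logger.warning("upscaling image width %d -> %d", w, target_width)
    target_height = max(1, round(target_width / w * h))
    out_shape = (target_height, target_width) + img.shape[2:]
    out = _sk_resize(
        img,
        out_shape,
        order=1,
        mode="reflect",
        anti_aliasing=(target_width < w),
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def ensure_binary(mask) -> np.ndarray:
    """Validate a strictly binary mask and return it as a boolean array."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask is not binary (values other than 0/1 found)")
        arr = arr.astype(bool)
    return arr


def upscale_mask(mask, target_height: int, target_width: int) -> np.ndarray:
    """Resample a binary mask to ``(target_height, target_width)``.

    Nearest-neighbour semantics keep the output strictly binary.  Used to map
    masks computed at a reduced working resolution back onto the original
    image grid.
    """
    arr = ensure_binary(mask)
    if target_height < 1 or target_width < 1:
        raise ValueError("target dimensions must be >= 1")
    if arr.shape == (target_height, target_width):
        return arr.copy()
    out = _sk_resize(
        arr.astype(np.float64),
        (target_height, target_width),
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out > 0.5
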