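"""Binarization procedures: local-adaptive cell masks, global-Otsu pellet
masks with morphological cleanup, and mean-offset confluency masks.

Three different segmentation problems call for three different rules:

* scattered cells on a bright background are darker than their local
  surroundings, so a local-adaptive threshold on the negated luminance picks
  them out regardless of slow background variation;
* a single compact chondrogenic pellet on a bright background is well
  separated globally, so Otsu's between-class-variance threshold plus a
  morphological closing and a largest-component filter suffices;
* phase-contrast monolayers are brighter than the empty dish, and a fixed
  offset of 0.07 above the image mean is a consistent global threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label as _cc_label
from skimage.morphology import closing as _binary_closing, disk

from .preprocess import as_image, resize_to_width, upscale_mask

logger = logging.getLogger(__name__)

OTSU_BINS = 256


@dataclass(frozen=True)
class AdaptiveThresholdParams:
    """Parameters of the local-adaptive cell threshold.

    ``region_size`` is the side of the square local window at the working
    resolution: 30 px for 10x magnification images, 60 px for 20x.  A pixel
    (of the negated luminance) is foreground when its value exceeds
    ``gain_mu * mu - gain_sigma * sigma`` with ``mu``/``sigma`` the local
    mean and population standard deviation.  Images are processed at
    ``work_width`` pixels wide to keep the windowed statistics affordable.
    """

    region_size: int = 30
    gain_mu: float = 1.1
    gain_sigma: float = 0.3
    work_width: int = 512

    def __post_init__(self):
        if self.region_size <= 0:
            raise ValueError("region_size must be positive")
        if self.work_width <= 0:
            raise ValueError("work_width must be positive")

    @classmethod
    def for_magnification(cls, magnification: int, **kwargs) -> "AdaptiveThresholdParams":
        sizes = {10: 30, 20: 60}
        if magnification not in sizes:
            raise ValueError("magnification must be 10 or 20")
        return cls(region_size=sizes[magnification], **kwargs)


def local_mean_std(gray: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean and population standard deviation.

    Square window of side ``size`` (for even sizes the window extends one
    pixel further toward lower indices), reflective border padding.
    """
    g = np.asarray(gray, dtype=np.float64)
    mu = uniform_filter(g, size=size, mode="reflect")
    musq = uniform_filter(g * g, size=size, mode="reflect")
    var = np.maximum(musq - mu * mu, 0.0)
    return mu, np.sqrt(var)


def adaptive_cell_mask(gray, params: AdaptiveThresholdParams | None = None) -> np.ndarray:
    """Local-adaptive mask of (dark) cells on a luminance image.

    Pipeline: negate the luminance, downscale to ``params.work_width`` (images
    already narrower are left at native resolution), threshold each pixel at
    ``gain_mu * mu - gain_sigma * sigma`` over its local window, and upscale
    the binary mask back to the original dimensions.
    """
    params = params or AdaptiveThresholdParams()
    img = as_image(gray)
    if img.ndim != 2:
        raise ValueError("adaptive_cell_mask expects a single-channel image")
    h, w = img.shape
    negated = 1.0 - img
    work = resize_to_width(negated, min(params.work_width, w))
    if params.region_size > min(work.shape):
        raise ValueError(
            f"region_size {params.region_size} exceeds working image "
            f"dimensions {work.shape}"
        )
    mu, sigma = local_mean_std(work, params.region_size)
    mask = work > params.gain_mu * mu - params.gain_sigma * sigma
    return upscale_mask(mask, h, w)


def otsu_threshold(gray, nbins: int = OTSU_BINS) -> float:
    """Global threshold maximising between-class variance (Otsu).

    The value range [0, 1] is split into ``nbins`` uniform bins; each of the
    ``nbins - 1`` interior bin edges is a candidate threshold and class
    statistics are exact (per-bin value sums, not bin centres).  Ties take
    the lowest maximiser.  Foreground is ``value >= threshold``.
    """
    img = as_image(gray)
    if img.ndim != 2:
        raise ValueError("otsu_threshold expects a single-channel image")
    vals = img.ravel()
    if np.all(vals == vals[0]):
        raise ValueError("constant image: no separating threshold exists")
    edges = np.linspace(0.0, 1.0, nbins + 1)
    idx = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins).astype(np.float64)
    sums = np.bincount(idx, weights=vals, minlength=nbins)
    n0 = np.cumsum(counts)[:-1]  # class 0 = bins 0..t, t = 0..nbins-2
    s0 = np.cumsum(sums)[:-1]
    n1 = vals.size - n0
    s1 = sums.sum() - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(n0 > 0, s0 / n0, 0.0)
        mu1 = np.where(n1 > 0, s1 / n1, 0.0)
        between = n0 * n1 * (mu0 - mu1) ** 2
    between[(n0 == 0) | (n1 == 0)] = -np.inf
    t = int(np.argmax(between))  # first occurrence = lowest threshold on ties
    return float(edges[t + 1])


def pellet_mask(
    gray,
    *,
    downscale_factor: int = 3,
    closing_radius: int = 4,
) -> np.ndarray:
    """Mask of a single dark pellet on a bright background.

    Pipeline: downscale the luminance to a third of the original width,
    negate (pellet darker than background), Otsu-binarize, close with a disk
    of radius 4 (at the working scale) to fill small holes, keep only the
    largest 8-connected component (drops air bubbles and debris), and
    upscale to the original dimensions.  Degenerate images yield an empty
    mask with a warning rather than an error, so batch runs continue.
    """
    img = as_image(gray)
    if img.ndim != 2:
        raise ValueError("pellet_mask expects a single-channel image")
    h, w = img.shape
    work = resize_to_width(img, max(1, round(w / downscale_factor)))
    negated = 1.0 - work
    try:
        thr = otsu_threshold(negated)
    except ValueError:
        warnings.warn("pellet_mask: constant image, returning empty mask")
        return np.zeros((h, w), dtype=bool)
    fg = negated >= thr
    if not fg.any():
        warnings.warn("pellet_mask: empty foreground after thresholding")
        return np.zeros((h, w), dtype=bool)
    closed = _binary_closing(fg, disk(closing_radius))
    labels = _cc_label(closed, connectivity=2)
    if labels.max() == 0:
        warnings.warn("pellet_mask: no connected component found")
        return np.zeros((h, w), dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(np.argmax(sizes))  # first occurrence in scan order on ties
    return upscale_mask(labels == largest, h, w)


CONFLUENCY_OFFSET = 0.07


def confluency_mask(gray, offset: float = CONFLUENCY_OFFSET) -> np.ndarray:
    """Mask of bright cell area in a phase-contrast image.

    Foreground is every pixel strictly above ``mean(image) + offset``; the
    0.07 offset is a fixed, empirically consistent choice for standardized
    phase-contrast acquisitions.  No resizing is applied.
    """
    img = as_image(gray)
    if img.ndim != 2:
        raise ValueError("confluency_mask expects a single-channel image")
    return img > float(img.mean()) + offset
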