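"""Assay-level measurands for the differentiation, confluency, viability and
histology readouts.

Each function takes a raw image plus the relevant calibration/kernel objects
and returns an :class:`AssayMetrics` record holding the quantities that feed
the cohort statistics:

* adipogenic: cell-area fraction and the Oil Red O : hematoxylin
  concentration-mass ratio within the cell mask (lipid accumulation);
* chondrogenic: pellet-area fraction (micromass size) and the Alcian blue :
  nuclear fast red ratio within the pellet (cartilaginous matrix);
* osteogenic: 1 - mean corrected luminance (inverted brightness; von Kossa
  deposits darken the image);
* confluency: percent of the image above the mean + 0.07 threshold;
* viability: count of dead-cell spots in the red fluorescence channel.

Dye ratios are ratios of summed concentration mass (not means of per-pixel
ratios), which is robust to near-zero denominators.  Undefined quantities
propagate as NaN (never 0) into downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _cc_label

from .deconvolution import StainKernel, deconvolve
from .preprocess import CalibrationPair, as_image, correct_illumination, to_luminance
from .segmentation import (
    AdaptiveThresholdParams,
    adaptive_cell_mask,
    confluency_mask,
    otsu_threshold,
    pellet_mask,
)


class UnanalyzableImageError(ValueError):
    """Raised when an image cannot produce a meaningful metric at all."""


@dataclass
class AssayMetrics:
    """Per-image outputs of one assay.

    Fields that do not apply to an assay stay at their NaN/None defaults;
    ``area_pixels`` accompanies ``area_fraction`` where a raw pixel area is
    also of interest (pellet size).
    """

    assay: str
    area_fraction: float = float("nan")
    area_pixels: int | None = None
    dye_ratio: float = float("nan")
    concentration_percentage: float = float("nan")
    score: float = float("nan")
    dead_count: int | None = None
    mask: np.ndarray | None = field(default=None, repr=False)

    def as_row(self) -> dict:
        """Flat dict for tidy CSV export (mask omitted)."""
        return {
            "assay": self.assay,
            "area_fraction": self.area_fraction,
            "area_pixels": self.area_pixels,
            "dye_ratio": self.dye_ratio,
            "concentration_percentage": self.concentration_percentage,
            "score": self.score,
            "dead_count": self.dead_count,
        }


def _masked_dye_masses(maps, kernel: StainKernel, mask: np.ndarray) -> tuple[float, float]:
    a = float(maps[kernel.stains[0].name][mask].sum())
    b = float(maps[kernel.stains[1].name][mask].sum())
    return a, b


def _ratio_and_percentage(a: float, b: float, context: str) -> tuple[float, float]:
    if b <= 0.0:
        warnings.warn(f"{context}: denominator stain mass is zero; ratio undefined")
        ratio = float("nan")
    else:
        ratio = a / b
    total = a + b
    pct = 100.0 * a / total if total > 0 else float("nan")
    return ratio, pct


def adipogenic_metrics(
    image,
    calib: CalibrationPair,
    kernel: StainKernel,
    params: AdaptiveThresholdParams | None = None,
) -> AssayMetrics:
    """Cell-area fraction and Oil Red O : hematoxylin ratio within the cells.

    The image is flat-field corrected, a cell mask is computed on the negated
    luminance with the local-adaptive threshold, the corrected image is
    deconvolved with the two-dye kernel, and all dye statistics are
    restricted to the cell regions.  The kernel's first stain is the
    numerator dye.
    """
    corrected = correct_illumination(image, calib)
    mask = adaptive_cell_mask(to_luminance(corrected), params)
    area_fraction = float(mask.mean())
    metrics = AssayMetrics("adipogenic", area_fraction=area_fraction, mask=mask)
    if not mask.any():
        warnings.warn("adipogenic_metrics: empty cell mask; dye ratio undefined")
        return metrics
    maps = deconvolve(corrected, kernel)
    a, b = _masked_dye_masses(maps, kernel, mask)
    metrics.dye_ratio, metrics.concentration_percentage = _ratio_and_percentage(
        a, b, "adipogenic_metrics"
    )
    return metrics


def chondrogenic_metrics(image, calib: CalibrationPair, kernel: StainKernel) -> AssayMetrics:
    """Pellet-area fraction and Alcian blue : nuclear fast red ratio.

    Pellet area (micromass size) is reported both as a fraction of the image
    and in pixels; dye masses are restricted to the pellet mask.
    """
    corrected = correct_illumination(image, calib)
    mask = pellet_mask(to_luminance(corrected))
    metrics = AssayMetrics("chondrogenic", mask=mask)
    if not mask.any():
        warnings.warn("chondrogenic_metrics: no pellet found; metrics undefined")
        return metrics
    metrics.area_fraction = float(mask.mean())
    metrics.area_pixels = int(mask.sum())
    maps = deconvolve(corrected, kernel)
    a, b = _masked_dye_masses(maps, kernel, mask)
    metrics.dye_ratio, metrics.concentration_percentage = _ratio_and_percentage(
        a, b, "chondrogenic_metrics"
    )
    return metrics


def osteogenic_score(image, calib: CalibrationPair) -> AssayMetrics:
    """Inverted mean brightness of the corrected von Kossa image.

    The single-dye silver deposit darkens mineralised regions, so
    ``1 - mean(luminance)`` grows with mineralisation; no deconvolution and
    no masking are involved.  The score lies in [0, 1].
    """
    corrected = correct_illumination(image, calib)
    lum = to_luminance(corrected)
    return AssayMetrics("osteogenic", score=1.0 - float(lum.mean()))


def confluency(image) -> AssayMetrics:
    """Percent of a phase-contrast image covered by the bright cell mask."""
    img = as_image(image)
    gray = to_luminance(img) if img.ndim == 3 else img
    mask = confluency_mask(gray)
    return AssayMetrics(
        "confluency", area_fraction=float(mask.mean()), score=100.0 * float(mask.mean()),
        mask=mask,
    )


def count_dead_cells(
    red_channel,
    *,
    min_area: int = 10,
    min_threshold: float = 0.2,
    max_foreground: float = 0.5,
) -> AssayMetrics:
    """Count dead-cell spots in the red fluorescence channel.

    The channel is Otsu-binarized, 8-connected components smaller than
    ``min_area`` pixels are discarded, and the remaining component count is
    the dead-cell number.  Two guards make the count meaningful: an Otsu
    threshold at or below ``min_threshold`` indicates a spot-free background
    (pure noise would otherwise be split in half) and yields a count of 0,
    while a foreground fraction above ``max_foreground`` indicates a
    saturated, unanalyzable frame and raises.
    """
    img = as_image(red_channel)
    if img.ndim != 2:
        raise ValueError("count_dead_cells expects the red channel as a 2-D image")
    try:
        thr = otsu_threshold(img)
    except ValueError:
        return AssayMetrics("livedead", dead_count=0)
    bright = img >= max(thr, min_threshold)
    if bright.mean() > max_foreground:
        raise UnanalyzableImageError(
            f"foreground covers {100 * bright.mean():.0f}% of the frame; "
            "saturated signal cannot be counted"
        )
    if thr <= min_threshold:
        return AssayMetrics("livedead", dead_count=0, mask=np.zeros(img.shape, bool))
    fg = img >= thr
    labels = _cc_label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_area)
    keep = keep[keep != 0]
    mask = np.isin(labels, keep)
    return AssayMetrics(
        "livedead", dead_count=int(keep.size), area_fraction=float(mask.mean()),
        mask=mask,
    )


@dataclass(frozen=True)
class HistologyScore:
    """Manual scaffold-repopulation score (three categories, total 0-10).

    ``surface_distribution`` grades cell coverage of the seeded scaffold
    surface (0 = no cells ... 4 = constant multilayer), ``integration`` the
    fraction of cells integrated between the scaffold fibers (0-3), and
    ``opposite_surface`` the cell distribution on the far scaffold surface
    (0-3).
    """

    surface_distribution: int
    integration: int
    opposite_surface: int

    RANGES = {"surface_distribution": 4, "integration": 3, "opposite_surface": 3}

    def __post_init__(self):
        for name, top in self.RANGES.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= top):
                raise ValueError(f"{name} must be an integer in [0, {top}], got {v!r}")

    @property
    def total(self) -> int:
        return int(self.surface_distribution + self.integration + self.opposite_surface)


def total_histology_score(surface: int, integration: int, opposite: int) -> HistologyScore:
    """Validate the three category scores and return the aggregate record."""
    return HistologyScore(surface, integration, opposite)
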