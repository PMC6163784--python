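"""Synthetic microscopy and cohort generators with known ground truth.

Every input class the pipeline consumes can be generated here so that the
whole chain — illumination correction, deconvolution, segmentation, assay
metrics and cohort statistics — is testable end to end:

* stained brightfield fields are composed forward through the Beer-Lambert
  model (``I = 10**(-sum_s c_s v_s)``), multiplied by a smooth radial
  vignette ``1 - k r**2`` and optionally degraded with clipped Gaussian
  intensity noise;
* LIVE/DEAD fields place isotropic Gaussian spots (green = live, red = dead)
  with a minimum-separation constraint over a noisy background;
* cohorts follow a multiplicative random-effects model on positive metrics:
  ``value = baseline * donor_effect * condition_effect * day_effect * noise``
  with lognormal donor effects and residual noise.

Generation is fully deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import StainKernel, od_to_intensity
from .preprocess import CalibrationPair

#: Treatment-group labels of the monolayer arm of the study design
#: (control, single cytokines at two doses, combinations, leukocyte co-cultures).
DEFAULT_CONDITIONS = (
    "control",
    "IL1b-high",
    "TNFa-high",
    "IL1b-low",
    "TNFa-low",
    "IL1b-high+TNFa-high",
    "IL1b-low+TNFa-low",
    "Leuko-stim",
    "Leuko",
)


@dataclass(frozen=True)
class DiskSpec:
    """A circular object painted with fixed per-dye concentrations."""

    center: tuple[float, float]  # (row, col) in pixels
    radius: float
    concentrations: dict[str, float]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, stain chemistry, illumination and noise of one synthetic field."""

    height: int = 256
    width: int = 256
    objects: tuple[DiskSpec, ...] = ()
    background: dict[str, float] = field(default_factory=dict)
    vignette_strength: float = 0.0
    vignette_center: tuple[float, float] = (0.5, 0.5)  # fractional (row, col)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for obj in self.objects:
            if any(c < 0 for c in obj.concentrations.values()):
                raise ValueError("stain concentrations must be nonnegative")
        if any(c < 0 for c in self.background.values()):
            raise ValueError("background concentrations must be nonnegative")
        if not (0.0 <= self.vignette_strength <= 1.0):
            raise ValueError("vignette_strength must lie in [0, 1]")


def vignette_field(
    height: int,
    width: int,
    strength: float = 0.2,
    center: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """Radial quadratic illumination profile ``1 - k r**2``.

    ``r`` is the distance from the (fractional) center normalised by the
    farthest corner distance, so the field lies in ``[1 - k, 1]``.
    """
    rows = np.arange(height)[:, None] - center[0] * (height - 1)
    cols = np.arange(width)[None, :] - center[1] * (width - 1)
    r2 = rows**2 + cols**2
    corners = [
        (r - center[0] * (height - 1)) ** 2 + (c - center[1] * (width - 1)) ** 2
        for r in (0, height - 1)
        for c in (0, width - 1)
    ]
    r2max = max(corners) or 1.0
    return 1.0 - strength * r2 / r2max


def _disk_mask(height: int, width: int, center, radius: float) -> np.ndarray:
    rows = np.arange(height)[:, None] - center[0]
    cols = np.arange(width)[None, :] - center[1]
    return rows**2 + cols**2 <= radius**2


def concentration_images(spec: SceneSpec, stain_names) -> np.ndarray:
    """Ground-truth per-stain concentration maps, shape ``(H, W, n_stains)``.

    Overlapping objects add their dye amounts (co-localised absorbers are
    additive in OD).
    """
    conc = np.zeros((spec.height, spec.width, len(stain_names)))
    for i, name in enumerate(stain_names):
        conc[..., i] += spec.background.get(name, 0.0)
    for obj in spec.objects:
        mask = _disk_mask(spec.height, spec.width, obj.center, obj.radius)
        for i, name in enumerate(stain_names):
            conc[mask, i] += obj.concentrations.get(name, 0.0)
    return conc


@dataclass(frozen=True)
class RenderedScene:
    """A rendered field with its exact ground truth."""

    image: np.ndarray
    object_mask: np.ndarray
    concentrations: np.ndarray  # (H, W, n_stains), stain order of the kernel
    illumination: np.ndarray

    @property
    def calibration(self) -> CalibrationPair:
        """Calibration pair matching the rendered illumination (RGB)."""
        bf = np.repeat(self.illumination[..., None], 3, axis=-1)
        return CalibrationPair(bf, np.zeros_like(bf))


def render_stained_image(spec: SceneSpec, kernel: StainKernel) -> RenderedScene:
    """Render a stained brightfield image through the forward model.

    Per pixel, ``OD = sum_s c_s v_s`` over the kernel's stains, the
    transmitted intensity is ``10**(-OD)`` per channel, the illumination
    field multiplies all channels, and clipped Gaussian noise is added last.
    The exact object mask, concentration maps and field are returned for
    ground-truth comparisons.
    """
    names = [s.name for s in kernel.stains]
    conc = concentration_images(spec, names)
    vectors = np.vstack([s.od_vector for s in kernel.stains])  # (n, 3)
    od = conc @ vectors  # (H, W, 3)
    base = od_to_intensity(od)
    field = vignette_field(
        spec.height, spec.width, spec.vignette_strength, spec.vignette_center
    )
    image = base * field[..., None]
    if image.min() < -1e-12 or image.max() > 1 + 1e-12:
        raise ValueError("rendered intensities leave [0, 1] before noise")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)
    object_mask = np.zeros((spec.height, spec.width), dtype=bool)
    for obj in spec.objects:
        object_mask |= _disk_mask(spec.height, spec.width, obj.center, obj.radius)
    return RenderedScene(image, object_mask, conc, field)


# ---------------------------------------------------------------------------
# LIVE/DEAD fluorescence fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LiveDeadField:
    """Two-channel fluorescence field with ground-truth spot positions."""

    green: np.ndarray
    red: np.ndarray
    live_positions: np.ndarray
    dead_positions: np.ndarray

    @property
    def n_live(self) -> int:
        return len(self.live_positions)

    @property
    def n_dead(self) -> int:
        return len(self.dead_positions)


def _place_spots(rng, n, height, width, min_separation, margin, existing, max_tries):
    positions = list(existing)
    placed = []
    tries = 0
    while len(placed) < n:
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} spots with separation {min_separation} "
                f"in a {height}x{width} field (density too high)"
            )
        tries += 1
        p = np.array(
            [rng.uniform(margin, height - margin), rng.uniform(margin, width - margin)]
        )
        if all(np.hypot(*(p - q)) >= min_separation for q in positions):
            positions.append(p)
            placed.append(p)
    return placed


def _render_spots(height, width, positions, amplitude, sigma):
    img = np.zeros((height, width))
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    for p in positions:
        img += amplitude * np.exp(
            -((rows - p[0]) ** 2 + (cols - p[1]) ** 2) / (2 * sigma**2)
        )
    return img


def render_livedead_image(
    n_live: int,
    n_dead: int,
    *,
    height: int = 256,
    width: int = 256,
    spot_sigma: float = 2.5,
    amplitude: float = 0.8,
    min_separation: float | None = None,
    background: float = 0.05,
    background_sigma: float = 0.02,
    n_specks: int = 0,
    speck_amplitude: float = 0.9,
    seed: int = 0,
    max_tries: int = 20000,
) -> LiveDeadField:
    """Render a two-channel viability field with known spot counts.

    Live (green) and dead (red) cells are isotropic Gaussian spots of width
    ``spot_sigma`` placed by rejection sampling with a minimum pairwise
    separation (default ``5 * spot_sigma``: at ~4 sigma the flanks of two
    spots sum to near the detection threshold and noise can bridge them, so
    closer spots are not reliably resolvable by global thresholding) across
    both channels; densities too high for the constraint are rejected.  ``n_specks`` optional
    single-pixel bright artifacts are added to the red channel to exercise
    the minimum-area filter of the dead-cell counter.
    """
    if min_separation is None:
        min_separation = 5.0 * spot_sigma
    rng = np.random.default_rng(seed)
    margin = max(3.0 * spot_sigma, min_separation / 2.0)
    live = _place_spots(rng, n_live, height, width, min_separation, margin, [], max_tries)
    dead = _place_spots(
        rng, n_dead, height, width, min_separation, margin, live, max_tries
    )
    green = _render_spots(height, width, live, amplitude, spot_sigma)
    red = _render_spots(height, width, dead, amplitude, spot_sigma)
    for channel in (green, red):
        channel += background + rng.normal(0.0, background_sigma, channel.shape)
    for _ in range(n_specks):
        r = rng.integers(0, height)
        c = rng.integers(0, width)
        red[r, c] = speck_amplitude
    return LiveDeadField(
        green=np.clip(green, 0.0, 1.0),
        red=np.clip(red, 0.0, 1.0),
        live_positions=np.array(live).reshape(-1, 2),
        dead_positions=np.array(dead).reshape(-1, 2),
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Design and effect structure of a simulated donor cohort.

    Metrics are positive, so effects act multiplicatively and noise is
    lognormal: ``value = baseline * donor * condition * day * exp(N(0, s))``
    with ``s = sqrt(ln(1 + cv**2))`` so that ``cv`` is the residual
    coefficient of variation.  Donor effects are lognormal with log-scale
    standard deviation ``donor_sd`` (donors are the blocking factor and
    cancel in paired tests).  The control condition effect is pinned at 1.
    """

    n_donors: int = 7
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    culture_systems: tuple[str, ...] = ("monolayer",)
    days: tuple[int, ...] = (1, 3)
    baseline: float = 100.0
    condition_effects: dict[str, float] = field(default_factory=dict)
    day_effects: dict[int, float] = field(default_factory=dict)
    donor_sd: float = 0.25
    noise_cv: float = 0.2
    metric: str = "dead_count"
    seed: int = 0

    def __post_init__(self):
        if self.condition_effects.get("control", 1.0) != 1.0:
            raise ValueError("the control condition effect must be 1")
        if any(e <= 0 for e in self.condition_effects.values()):
            raise ValueError("condition effects must be positive")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table from the multiplicative random-effects model.

    Returns a tidy frame with columns ``donor, condition, culture_system,
    day, metric, value, condition_effect``; the generating effects are also
    attached under ``DataFrame.attrs["spec"]``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0
    donor_effects = (
        np.exp(rng.normal(0.0, spec.donor_sd, spec.n_donors))
        if spec.donor_sd > 0
        else np.ones(spec.n_donors)
    )
    rows = []
    for d in range(spec.n_donors):
        for system in spec.culture_systems:
            for cond in spec.conditions:
                for day in spec.days:
                    eff = spec.condition_effects.get(cond, 1.0)
                    noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                    value = (
                        spec.baseline
                        * donor_effects[d]
                        * eff
                        * spec.day_effects.get(day, 1.0)
                        * noise
                    )
                    rows.append(
                        {
                            "donor": d + 1,
                            "condition": cond,
                            "culture_system": system,
                            "day": day,
                            "metric": spec.metric,
                            "value": value,
                            "condition_effect": eff,
                        }
                    )
    df = pd.DataFrame(rows)
    df.attrs["spec"] = spec
    return df


# ---------------------------------------------------------------------------
# Ready-made scenes for the stain pipeline
# ---------------------------------------------------------------------------


def adipogenic_scene(
    kernel: StainKernel,
    *,
    height: int = 256,
    width: int = 256,
    n_cells: int = 25,
    cell_radius: float = 4.0,
    lipid_od: float = 0.8,
    nuclei_od: float = 0.2,
    vignette_strength: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SceneSpec:
    """Scattered small cells painted with a fixed lipid : nuclei OD mixture.

    Cells are kept smaller than the local-adaptive window and separated so
    the cell mask resolves them; the dye-mass ratio implied by the mixture is
    ``lipid_od / nuclei_od`` exactly.
    """
    rng = np.random.default_rng(seed)
    stain_a, stain_b = kernel.stains[0].name, kernel.stains[1].name
    margin = 3 * cell_radius
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > 50000:
            raise ValueError("could not place cells; lower n_cells or radius")
        p = np.array(
            [rng.uniform(margin, height - margin), rng.uniform(margin, width - margin)]
        )
        if all(np.hypot(*(p - q)) >= 4 * cell_radius for q in centers):
            centers.append(p)
    objects = tuple(
        DiskSpec(tuple(c), cell_radius, {stain_a: lipid_od, stain_b: nuclei_od})
        for c in centers
    )
    return SceneSpec(
        height=height,
        width=width,
        objects=objects,
        vignette_strength=vignette_strength,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def chondrogenic_scene(
    kernel: StainKernel,
    *,
    height: int = 900,
    width: int = 1200,
    radius: float = 250.0,
    matrix_od: float = 0.7,
    nuclei_od: float = 0.35,
    n_bubbles: int = 0,
    bubble_radius: float = 12.0,
    vignette_strength: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SceneSpec:
    """A single stained pellet, optionally with small dark bubble artifacts."""
    rng = np.random.default_rng(seed)
    stain_a, stain_b = kernel.stains[0].name, kernel.stains[1].name
    center = (height / 2.0, width / 2.0)
    objects = [DiskSpec(center, radius, {stain_a: matrix_od, stain_b: nuclei_od})]
    for _ in range(n_bubbles):
        while True:
            p = (rng.uniform(30, height - 30), rng.uniform(30, width - 30))
            if np.hypot(p[0] - center[0], p[1] - center[1]) > radius + 6 * bubble_radius:
                break
        objects.append(DiskSpec(p, bubble_radius, {stain_a: 1.0, stain_b: 1.0}))
    return SceneSpec(
        height=height,
        width=width,
        objects=tuple(objects),
        vignette_strength=vignette_strength,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def monolayer_scene(
    *,
    height: int = 256,
    width: int = 256,
    coverage: float = 0.3,
    cell_value: float = 0.8,
    background_value: float = 0.2,
    cell_radius: float = 6.0,
    seed: int = 0,
) -> np.ndarray:
    """Phase-contrast-like field: bright disks covering ``coverage`` of the area.

    Disk placement allows overlap; disks are added until the covered fraction
    reaches the target, and the realised mask fraction is exact by
    construction (the function returns the image; regenerate the mask as
    ``image > threshold`` midway between the two grey levels).
    """
    rng = np.random.default_rng(seed)
    covered = np.zeros((height, width), dtype=bool)
    target = int(round(coverage * height * width))
    tries = 0
    while covered.sum() < target:
        tries += 1
        if tries > 100000:
            break
        c = (rng.uniform(0, height), rng.uniform(0, width))
        covered |= _disk_mask(height, width, c, cell_radius)
    # trim overshoot pixel-by-pixel from the last row-major covered pixels
    overshoot = covered.sum() - target
    if overshoot > 0:
        idx = np.flatnonzero(covered.ravel())[-overshoot:]
        flat = covered.ravel()
        flat[idx] = False
        covered = flat.reshape(height, width)
    return np.where(covered, cell_value, background_value).astype(np.float64)


def stain_collage_scenes(
    kernel: StainKernel,
    *,
    n_images: int = 9,
    height: int = 64,
    width: int = 64,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Fields with spatially separated dye structures for kernel estimation.

    Each field holds disks of the first dye, disks of the second dye, and a
    few mixed disks, so both pure and mixed colors appear in a collage while
    the true concentration maps stay close to uncorrelated.
    """
    rng = np.random.default_rng(seed)
    stain_a, stain_b = kernel.stains[0].name, kernel.stains[1].name
    images = []
    for i in range(n_images):
        objects = []
        for _ in range(6):
            p = (rng.uniform(8, height - 8), rng.uniform(8, width - 8))
            r = rng.uniform(3, 7)
            kind = rng.integers(0, 3)
            if kind == 0:
                conc = {stain_a: rng.uniform(0.3, 0.9)}
            elif kind == 1:
                conc = {stain_b: rng.uniform(0.3, 0.9)}
            else:
                conc = {
                    stain_a: rng.uniform(0.2, 0.6),
                    stain_b: rng.uniform(0.2, 0.6),
                }
            objects.append(DiskSpec(p, r, conc))
        spec = SceneSpec(
            height=height,
            width=width,
            objects=tuple(objects),
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        images.append(render_stained_image(spec, kernel).image)
    return images
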