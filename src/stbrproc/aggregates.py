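"""Aggregate-size model, synthetic micrographs and equivalent-diameter sizing.

Suspension-cultured hPSCs grow as near-spherical cell-only aggregates. If
cell number in an aggregate grows exponentially at rate µ after the
aggregation phase (complete by day 1) and packing density is constant,
volume grows as :math:`e^{\\mu (t-1)}` and the diameter as its cube root:

.. math:: d(t) = d_1\\, e^{\\mu (t - 1)/3}, \\qquad t \\ge 1.

Measured size dispersion is modelled log-normally around the predicted
diameter (the predicted value is the population *median*; the population
mean carries the usual :math:`e^{\\sigma^2/2}` log-normal correction).

The measurement pipeline mirrors macro-based brightfield sizing: global
threshold, connected components, border-object exclusion, equivalent-circle
diameter :math:`d = 2\\sqrt{A/\\pi}` and a minimum-size debris filter. It is
validated on rendered synthetic images with known ground truth; it is not a
segmenter for real micrographs with halos or overlapping aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure
from skimage.filters import threshold_otsu

__all__ = [
    "AggregateError",
    "PlacementError",
    "AggregatePopulation",
    "AggregateGrowthParams",
    "SyntheticImageSpec",
    "PooledSummary",
    "predict_diameter",
    "expected_mean_diameter",
    "simulate_population",
    "render_image",
    "measure_diameters",
    "pooled_mean_diameter",
]

#: Default debris filter [µm] (≈ 3 cell diameters).
MIN_DIAMETER_UM = 30.0
#: Pooled-n threshold below which summaries warn (study-grade sizing pools
#: on the order of a thousand aggregates from ≥ 3 images).
POOLED_N_THRESHOLD = 900
MIN_IMAGES = 3


class AggregateError(ValueError):
    """Domain error in the aggregate-size model or measurement."""


class PlacementError(AggregateError):
    """Raised when circles cannot be placed without overlap."""


@dataclass(frozen=True)
class AggregatePopulation:
    """Pooled aggregate diameters [µm] for one sampling day."""

    diameters: tuple[float, ...]
    day: float = math.nan
    n_images: int = 1
    areas_px: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "diameters", tuple(float(d) for d in self.diameters))
        object.__setattr__(self, "areas_px", tuple(float(a) for a in self.areas_px))
        if any(d <= 0 for d in self.diameters):
            raise AggregateError("diameters must be > 0")

    @property
    def n(self) -> int:
        return len(self.diameters)

    @property
    def mean(self) -> float:
        if not self.diameters:
            raise AggregateError("mean undefined for an empty population")
        return float(np.mean(self.diameters))


@dataclass(frozen=True)
class AggregateGrowthParams:
    """Growth-model parameters: day-1 mean diameter [µm], log-normal CV,
    specific growth rate µ [d⁻¹], RNG seed."""

    d1_mean: float = 100.0
    d1_cv: float = 0.15
    mu: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d1_mean <= 0:
            raise AggregateError(f"d1_mean must be > 0, got {self.d1_mean}")
        if self.d1_cv < 0:
            raise AggregateError(f"d1_cv must be >= 0, got {self.d1_cv}")


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Rendering geometry: image size [px], scale [µm/px], 8-bit intensities
    for background/foreground, additive noise SD and non-overlap margin [px]."""

    width: int = 1024
    height: int = 1024
    scale: float = 1.0
    background: int = 200
    foreground: int = 60
    noise_sd: float = 0.0
    margin: int = 4

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise AggregateError(f"scale must be > 0, got {self.scale}")
        for name in ("background", "foreground"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise AggregateError(f"{name} must be in [0, 255], got {v}")
        if self.background == self.foreground:
            raise AggregateError("background and foreground must differ")


def predict_diameter(d1: float, mu: float, t: float) -> float:
    """Mean aggregate diameter [µm] on day ``t`` from the cube-root model.

    ``d1`` is the day-1 diameter; aggregation before day 1 is not modelled,
    so ``t < 1`` is a domain error.
    """
    if d1 <= 0:
        raise AggregateError(f"d1 must be > 0, got {d1}")
    if t < 1:
        raise AggregateError(
            f"the model starts at t = 1 (post-aggregation), got t = {t}")
    return d1 * math.exp(mu * (t - 1.0) / 3.0)


def _sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def expected_mean_diameter(params: AggregateGrowthParams, day: float) -> float:
    """Population mean under the log-normal dispersion:
    ``predict_diameter × exp(σ²/2)`` with σ² = ln(1 + cv²)."""
    s = _sigma(params.d1_cv)
    return predict_diameter(params.d1_mean, params.mu, day) * math.exp(s * s / 2.0)


def simulate_population(params: AggregateGrowthParams, day: float,
                        n: int) -> AggregatePopulation:
    """Draw ``n`` aggregate diameters for ``day``, log-normal about the
    growth-model prediction (which is the distribution median)."""
    if n < 1:
        raise AggregateError(f"n must be >= 1, got {n}")
    med = predict_diameter(params.d1_mean, params.mu, day)
    if params.d1_cv == 0:
        diam = np.full(n, med)
    else:
        rng = np.random.default_rng(params.seed)
        diam = med * np.exp(rng.normal(0.0, _sigma(params.d1_cv), size=n))
    return AggregatePopulation(diameters=tuple(diam), day=day)


def render_image(diameters: Sequence[float], spec: SyntheticImageSpec,
                 seed: int = 0,
                 max_attempts_per_circle: int = 500
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render non-overlapping dark circles on a light background.

    Returns the uint8 grayscale image and the ground-truth table
    (``object_id, cx_px, cy_px, diameter_um``; 0-based pixel-center
    coordinates, column = x). Placement is by seeded rejection sampling;
    impossible packings raise :class:`PlacementError`.
    """
    rng = np.random.default_rng(seed)
    H, W, m = spec.height, spec.width, spec.margin
    radii_px = [0.5 * float(d) / spec.scale for d in diameters]
    if any(r <= 0 for r in radii_px):
        raise AggregateError("diameters must be > 0")
    placed: list[tuple[float, float, float]] = []
    for r in sorted(radii_px, reverse=True):  # large first packs better
        lo_x, hi_x = r + m, W - 1 - r - m
        lo_y, hi_y = r + m, H - 1 - r - m
        if hi_x <= lo_x or hi_y <= lo_y:
            raise PlacementError(
                f"circle of radius {r:.1f} px does not fit a "
                f"{W}x{H} frame; use fewer or smaller objects")
        for _ in range(max_attempts_per_circle):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            if all((cx - x) ** 2 + (cy - y) ** 2 >= (r + r2 + m) ** 2
                   for x, y, r2 in placed):
                placed.append((cx, cy, r))
                break
        else:
            raise PlacementError(
                f"could not place {len(diameters)} circles without overlap "
                f"in a {W}x{H} frame; use fewer or smaller objects")

    img = np.full((H, W), spec.background, dtype=np.uint8)
    for cx, cy, r in placed:
        # rasterize into the circle's bounding window only
        x0, x1 = int(math.floor(cx - r)) - 1, int(math.ceil(cx + r)) + 2
        y0, y1 = int(math.floor(cy - r)) - 1, int(math.ceil(cy + r)) + 2
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, W), min(y1, H)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img[y0:y1, x0:x1][mask] = spec.foreground
    if spec.noise_sd > 0:
        noisy = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        [{"object_id": i, "cx_px": cx, "cy_px": cy,
          "diameter_um": 2.0 * r * spec.scale}
         for i, (cx, cy, r) in enumerate(placed)])
    if truth.empty:
        truth = pd.DataFrame(columns=["object_id", "cx_px", "cy_px", "diameter_um"])
    return img, truth


def measure_diameters(image: np.ndarray, scale: float,
                      min_diameter: float = MIN_DIAMETER_UM,
                      threshold: float | None = None,
                      auto_threshold: bool = False,
                      day: float = math.nan) -> AggregatePopulation:
    """Equivalent-circle diameters [µm] of dark objects in a grayscale image.

    Pipeline: global threshold (explicit value, Otsu when
    ``auto_threshold``, else the 8-bit midpoint 127.5), connected
    components, exclusion of border-touching objects (avoids truncation
    bias), ``d = 2·sqrt(A/π)·scale`` and the ``min_diameter`` debris
    filter. An empty image yields an empty population, not an error.
    """
    if image.ndim != 2:
        raise AggregateError(f"expected a single-channel image, got shape {image.shape}")
    if scale <= 0:
        raise AggregateError(f"scale must be > 0, got {scale}")
    img = np.asarray(image, dtype=float)
    if threshold is None:
        if auto_threshold:
            if np.ptp(img) == 0:
                return AggregatePopulation(diameters=(), day=day, n_images=1)
            threshold = float(threshold_otsu(img))
        else:
            threshold = 127.5
    binary = img < threshold
    labels = _skmeasure.label(binary, connectivity=1)
    H, W = labels.shape
    border = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :])) \
        | set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    diameters, areas = [], []
    for region in _skmeasure.regionprops(labels):
        if region.label in border:
            continue
        d_um = 2.0 * math.sqrt(region.area / math.pi) * scale
        if d_um >= min_diameter:
            diameters.append(d_um)
            areas.append(float(region.area))
    return AggregatePopulation(diameters=tuple(diameters), day=day,
                               n_images=1, areas_px=tuple(areas))


@dataclass(frozen=True)
class PooledSummary:
    """Arithmetic mean over the pooled diameter list of several images."""

    mean: float
    n: int
    per_image_counts: tuple[int, ...]
    warnings: tuple[str, ...] = ()


def pooled_mean_diameter(pops: Sequence[AggregatePopulation]) -> PooledSummary:
    """Pool populations (one per image) and report the arithmetic mean.

    Warns when fewer than 3 images or ≤ 900 pooled aggregates back the
    mean; an all-empty pool is an undefined-mean error.
    """
    if not pops:
        raise AggregateError("pooled mean needs at least one population")
    pooled = [d for p in pops for d in p.diameters]
    if not pooled:
        raise AggregateError("pooled mean undefined: all populations are empty")
    n_images = sum(p.n_images for p in pops)
    warns = []
    if n_images < MIN_IMAGES:
        warns.append(f"only {n_images} image(s); sizing protocols pool >= {MIN_IMAGES}")
    if len(pooled) <= POOLED_N_THRESHOLD:
        warns.append(f"pooled n = {len(pooled)} <= {POOLED_N_THRESHOLD} aggregates")
    return PooledSummary(mean=float(np.mean(pooled)), n=len(pooled),
                         per_image_counts=tuple(p.n for p in pops),
                         warnings=tuple(warns))
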