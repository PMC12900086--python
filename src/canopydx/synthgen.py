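"""Synthetic canopy scenes, calibration sets and growth series.

The generator produces inputs whose ground truth is known exactly, so
every pipeline stage can be verified without field data:

- :func:`render_canopy` draws an image in which exactly
  ``round(target_fraction * width * height)`` pixels come from a
  vegetation palette and the rest from a background palette.  The
  palettes keep a margin around the classification boundary (vegetation
  colours have discriminant index >= 140, background <= 128, threshold
  134), so segmenting the rendered image recovers the construction mask
  pixel for pixel and the measured cover equals the constructed
  fraction exactly.  Vegetation is clustered into a grid of blobs
  mimicking the 4 x 4 grid of transplanted hills a capture frames; the
  blobs are axis-aligned clusters, not botanically realistic leaves.
- :func:`simulate_calibration` draws (cover, tillers) pairs from a
  known quadratic plus i.i.d. Gaussian noise, for fit-recovery checks.
- :func:`simulate_growth` produces a linear daily tiller series at a
  fixed increase rate (reference range 12.0-24.3 tillers/m2/day), used
  to translate estimator bias into a shift of the day a cultivar target
  is crossed.

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import InputDomainError
from .estimation import QuadraticModel, default_model
from .imaging import discriminant_index

__all__ = [
    "SceneSpec",
    "CalibrationSpec",
    "GrowthSpec",
    "render_canopy",
    "simulate_calibration",
    "simulate_growth",
    "crossing_day",
    "DEFAULT_VEGETATION_PALETTE",
    "DEFAULT_BACKGROUND_PALETTE",
]

logger = logging.getLogger(__name__)

#: Greens with discriminant index >= 140 (comfortably above threshold 134).
DEFAULT_VEGETATION_PALETTE: Tuple[Tuple[int, int, int], ...] = (
    (30, 120, 40),   # dark leaf green
    (55, 160, 60),   # mid leaf green
    (80, 200, 90),   # sunlit leaf
    (20, 90, 35),    # shaded leaf
)

#: Water/soil/gray tones with index <= 128 (r >= g keeps them at or below neutral).
DEFAULT_BACKGROUND_PALETTE: Tuple[Tuple[int, int, int], ...] = (
    (120, 120, 120),  # gray water surface
    (140, 120, 100),  # turbid water / soil
    (90, 70, 50),     # wet soil
    (60, 60, 80),     # dark water with sky reflection
)

_VEG_INDEX_MIN = 140.0
_BG_INDEX_MAX = 128.0


def _check_palette(palette, low: Optional[float], high: Optional[float], kind: str):
    if not palette:
        raise InputDomainError(f"{kind} palette must be non-empty")
    for r, g, b in palette:
        idx = discriminant_index(r, g)
        if low is not None and idx < low:
            raise InputDomainError(
                f"{kind} colour {(r, g, b)} has index {idx:.1f} < {low}"
            )
        if high is not None and idx > high:
            raise InputDomainError(
                f"{kind} colour {(r, g, b)} has index {idx:.1f} > {high}"
            )


@dataclass(frozen=True)
class SceneSpec:
    """Specification of one synthetic canopy scene."""

    width: int
    height: int
    target_fraction: float
    grid_rows: int = 4
    grid_cols: int = 4
    vegetation_palette: Tuple[Tuple[int, int, int], ...] = DEFAULT_VEGETATION_PALETTE
    background_palette: Tuple[Tuple[int, int, int], ...] = DEFAULT_BACKGROUND_PALETTE
    seed: int = 0

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise InputDomainError("image dimensions must be >= 1")
        if not 0 <= self.target_fraction <= 1:
            raise InputDomainError("target_fraction must lie in [0, 1]")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise InputDomainError("grid dimensions must be >= 1")
        _check_palette(self.vegetation_palette, _VEG_INDEX_MIN, None, "vegetation")
        _check_palette(self.background_palette, None, _BG_INDEX_MAX, "background")


def _cell_quotas(areas: np.ndarray, k: int) -> np.ndarray:
    """Split k vegetation pixels over cells, proportional to area.

    Largest-remainder apportionment, then overflow (quota > area) pushed
    to cells with spare capacity so the total is preserved exactly.
    """
    total = int(areas.sum())
    raw = areas * (k / total)
    quotas = np.floor(raw).astype(np.int64)
    remainder = k - int(quotas.sum())
    order = np.argsort(-(raw - quotas), kind="stable")
    quotas[order[:remainder]] += 1
    # cap at cell area; redistribute any overflow
    overflow = int(np.maximum(quotas - areas, 0).sum())
    quotas = np.minimum(quotas, areas)
    while overflow > 0:
        spare = areas - quotas
        idx = np.argmax(spare)
        take = min(overflow, int(spare[idx]))
        quotas[idx] += take
        overflow -= take
    return quotas


def render_canopy(spec: SceneSpec):
    """Render a scene; returns ``(image, truth_mask, true_fraction)``.

    ``image`` is an ``(H, W, 3)`` uint8 array, ``truth_mask`` the boolean
    construction mask with exactly ``round(target_fraction * H * W)``
    true pixels, ``true_fraction`` that count divided by the pixel total.
    """
    h, w = spec.height, spec.width
    n = h * w
    k = int(round(spec.target_fraction * n))
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((h, w), dtype=bool)

    if spec.grid_rows > h or spec.grid_cols > w:
        logger.warning(
            "grid %dx%d infeasible for %dx%d image; falling back to "
            "pixel-wise placement",
            spec.grid_rows, spec.grid_cols, h, w,
        )
        flat = rng.permutation(n)[:k]
        mask.ravel()[flat] = True
    else:
        row_edges = np.linspace(0, h, spec.grid_rows + 1).astype(int)
        col_edges = np.linspace(0, w, spec.grid_cols + 1).astype(int)
        cells = [
            (row_edges[i], row_edges[i + 1], col_edges[j], col_edges[j + 1])
            for i in range(spec.grid_rows)
            for j in range(spec.grid_cols)
        ]
        areas = np.array([(r1 - r0) * (c1 - c0) for r0, r1, c0, c1 in cells])
        quotas = _cell_quotas(areas, k)
        for (r0, r1, c0, c1), quota in zip(cells, quotas):
            if quota == 0:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            cy, cx = (r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0
            d2 = (rr - cy) ** 2 + (cc - cx) ** 2
            # grow a blob outward from the hill centre; row-major tie-break
            order = np.argsort(d2.ravel(), kind="stable")[:quota]
            mask[rr.ravel()[order], cc.ravel()[order]] = True

    veg = np.asarray(spec.vegetation_palette, dtype=np.uint8)
    bg = np.asarray(spec.background_palette, dtype=np.uint8)
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[~mask] = bg[rng.integers(0, len(bg), size=int((~mask).sum()))]
    image[mask] = veg[rng.integers(0, len(veg), size=int(mask.sum()))]
    return image, mask, k / n


@dataclass(frozen=True)
class CalibrationSpec:
    """Specification of a synthetic calibration dataset."""

    true_model: QuadraticModel = field(default_factory=default_model)
    cover_min: float = 10.0
    cover_max: float = 70.0
    n_points: int = 50
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.cover_min < self.cover_max <= 100):
            raise InputDomainError("need 0 <= cover_min < cover_max <= 100")
        if self.n_points < 3:
            raise InputDomainError("n_points must be >= 3")
        if self.noise_sd < 0:
            raise InputDomainError("noise_sd must be >= 0")


def simulate_calibration(spec: CalibrationSpec) -> list:
    """Draw (cover %, tillers/m2) pairs from the true quadratic + noise.

    Covers are evenly spaced on ``[cover_min, cover_max]``; tiller
    values are the quadratic plus i.i.d. Gaussian(0, noise_sd^2).
    """
    rng = np.random.default_rng(spec.seed)
    covers = np.linspace(spec.cover_min, spec.cover_max, spec.n_points)
    tillers = spec.true_model.predict(covers)
    if spec.noise_sd > 0:
        tillers = tillers + rng.normal(0.0, spec.noise_sd, size=spec.n_points)
    return list(zip(covers.tolist(), np.asarray(tillers).tolist()))


@dataclass(frozen=True)
class GrowthSpec:
    """Linear tillering trajectory: initial count plus a daily rate."""

    initial_tillers: float = 300.0
    daily_rate: float = 20.0
    days: int = 7

    def __post_init__(self):
        if not self.daily_rate > 0:
            raise InputDomainError("daily_rate must be positive")
        if self.days < 1:
            raise InputDomainError("days must be >= 1")


def simulate_growth(spec: GrowthSpec) -> np.ndarray:
    """Daily tiller numbers ``initial + rate * day`` for day 0..days-1."""
    days = np.arange(spec.days, dtype=np.float64)
    return spec.initial_tillers + spec.daily_rate * days


def crossing_day(series: Sequence[float], target: float) -> Optional[int]:
    """First day index at which the series reaches the target, if any."""
    for day, value in enumerate(series):
        if value >= target:
            return day
    return None
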