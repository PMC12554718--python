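"""Seed counting from the segmented label map.

Touching seeds merge into a single connected component, so the seed count
cannot be the component count. Instead the areas of all components are
sorted ascending; single seeds of a dish have similar areas, so the sorted
area curve starts with a flat "stable" stretch (consecutive gaps below a
threshold) and jumps once merged multi-seed clusters begin. The mean area of
the stable prefix estimates the single-seed area s_opt, and each component
then contributes a multiplicity s_i / s_opt (floored, or rounded with a
floor of 1 in the alternative mode) to the total count.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from skimage import measure


@dataclasses.dataclass
class SeedComponent:
    """One connected region of seed-coat pixels."""

    area: int
    #: (x_min, y_min, x_max, y_max), 0-based, half-open
    bbox: tuple[int, int, int, int]
    #: (row, col) centroid
    centroid: tuple[float, float]
    #: boolean mask of the component within ``bbox`` (rows x cols)
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("component area must be >= 1")


@dataclasses.dataclass
class SingleSeedAreaEstimate:
    """Single-seed area estimated from the sorted area curve."""

    s_opt: float
    m: int
    areas: tuple[int, ...]
    deltas: tuple[int, ...]
    low_confidence: bool = False


@dataclasses.dataclass
class SeedCount:
    """Seed total with the per-component multiplicities that produced it."""

    n_seeds: int
    multiplicities: tuple[int, ...]


def extract_components(
    seed_coat_mask: np.ndarray,
    min_area: int = 200,
    connectivity: int = 8,
) -> list[SeedComponent]:
    """Connected seed-coat components with area >= ``min_area``, area-sorted.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    Regions below ``min_area`` are treated as noise (droplet highlights, awn
    fragments) and dropped.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(seed_coat_mask).astype(bool)
    labeled = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    components = []
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        components.append(
            SeedComponent(
                area=int(region.area),
                bbox=(c0, r0, c1, r1),
                centroid=tuple(region.centroid),
                mask=region.image.copy(),
            )
        )
    components.sort(key=lambda c: (c.area, c.bbox))
    return components


def estimate_single_seed_area(
    areas: Sequence[int],
    stability_gap: float = 30.0,
    min_run_length: int = 2,
) -> SingleSeedAreaEstimate:
    """Estimate s_opt from ascending component areas.

    Gaps Δ_i = s_{i+1} - s_i are scanned from the smallest component. The
    stable prefix is the set of components covered by the initial run of at
    least ``min_run_length`` consecutive gaps below ``stability_gap``; it
    ends at the first large gap after that run. s_opt is the mean of the
    stable prefix.

    Fallback: fewer than 3 areas, or no stable run at the start of the curve
    (e.g. the very first gap is already large), yields the median of all
    areas with the low-confidence flag set.
    """
    areas = tuple(int(a) for a in areas)
    if len(areas) == 0:
        raise ValueError("no component areas given")
    if any(a2 < a1 for a1, a2 in zip(areas, areas[1:])):
        raise ValueError("areas must be in ascending order")
    deltas = tuple(a2 - a1 for a1, a2 in zip(areas, areas[1:]))

    if len(areas) < 3:
        return SingleSeedAreaEstimate(
            s_opt=float(np.median(areas)),
            m=len(areas),
            areas=areas,
            deltas=deltas,
            low_confidence=True,
        )

    # initial run of small gaps
    run = 0
    for d in deltas:
        if d < stability_gap:
            run += 1
        else:
            break
    if run < min_run_length:
        return SingleSeedAreaEstimate(
            s_opt=float(np.median(areas)),
            m=len(areas),
            areas=areas,
            deltas=deltas,
            low_confidence=True,
        )
    m = run + 1  # gaps cover one more component than their count
    stable = areas[:m]
    return SingleSeedAreaEstimate(
        s_opt=float(np.mean(stable)),
        m=m,
        areas=areas,
        deltas=deltas,
    )


def count_seeds(
    components: Sequence[SeedComponent] | Sequence[int],
    s_opt: float,
    mode: str = "floor",
) -> SeedCount:
    """Total seed count from component areas and the single-seed area.

    ``floor`` mode (default) gives each component multiplicity
    floor(s_i / s_opt); a component slightly smaller than s_opt then counts
    zero. ``rounded`` mode uses max(1, round(s_i / s_opt)), which never
    discards a surviving component. Rounding is round-half-to-even (numpy
    convention).
    """
    if s_opt <= 0:
        raise ValueError("s_opt must be positive")
    if mode not in ("floor", "rounded"):
        raise ValueError("mode must be 'floor' or 'rounded'")
    areas = [c.area if isinstance(c, SeedComponent) else int(c) for c in components]
    if mode == "floor":
        mult = tuple(int(np.floor(a / s_opt)) for a in areas)
    else:
        mult = tuple(max(1, int(np.round(a / s_opt))) for a in areas)
    return SeedCount(n_seeds=int(sum(mult)), multiplicities=mult)
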