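"""Radicle detection and germination assessment.

A protruding radicle is near-white while the seed coat is yellowish and the
background dark, so radicle candidates are the pixels outside the seed-coat
cluster whose R, G and B all exceed a floor (160 by default). Candidate
regions are size-filtered and a seed counts as germinated when its radicle
region's pixel area exceeds the germination threshold T_g, or — in the
ratio-based classifier — when its radicle-to-seed area ratio reaches the
reference seed's ratio r_0.
"""

from __future__ import annotations

import dataclasses
from typing import Protocol, Sequence

import numpy as np
from skimage import measure

from .counting import SeedComponent
from .segmentation import (
    BACKGROUND_OR_RADICLE,
    ClusterLabelMap,
    color_features,
    kmeans_two_clusters,
)


@dataclasses.dataclass
class RadicleRegion:
    """One connected region of radicle-candidate pixels."""

    area: int
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), half-open


@dataclasses.dataclass
class GerminationStandard:
    """Which rule decides 'germinated'.

    AREA mode: radicle region area strictly greater than ``tg`` pixels.
    RATIO mode: seed's area ratio at least ``ratio`` (inclusive); the ratio
    is radicle/seed-body ("body" variant) or radicle/whole-seed ("whole"
    variant). ``provenance`` records whether the ratio came from a fixed
    setting or from a user-selected reference seed.
    """

    mode: str  # "area" | "ratio"
    tg: float | None = None
    ratio: float | None = None
    ratio_variant: str = "whole"
    provenance: str = "fixed"  # "fixed" | "reference_seed"

    def __post_init__(self) -> None:
        if self.mode == "area":
            if self.tg is None or self.tg <= 0:
                raise ValueError("AREA mode needs tg > 0")
        elif self.mode == "ratio":
            if self.ratio is None or not 0 < self.ratio <= 1:
                raise ValueError("RATIO mode needs ratio in (0, 1]")
        else:
            raise ValueError("mode must be 'area' or 'ratio'")


@dataclasses.dataclass
class SeedSegment:
    """A single seed's mask split into radicle and body pixels."""

    seed_mask: np.ndarray
    radicle_mask: np.ndarray
    body_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.radicle_mask & self.body_mask):
            raise ValueError("radicle and body masks must be disjoint")
        if not np.array_equal(self.radicle_mask | self.body_mask, self.seed_mask):
            raise ValueError("radicle and body must partition the seed mask")

    @property
    def radicle_area(self) -> int:
        return int(self.radicle_mask.sum())

    @property
    def seed_area(self) -> int:
        return int(self.seed_mask.sum())

    @property
    def ratio_whole(self) -> float:
        """Radicle area / whole-seed area, in [0, 1]."""
        return self.radicle_area / self.seed_area

    @property
    def ratio_body(self) -> float:
        """Radicle area / seed-body area (infinite for an all-radicle mask)."""
        body = int(self.body_mask.sum())
        if body == 0:
            return float("inf")
        return self.radicle_area / body


@dataclasses.dataclass
class GerminationSummary:
    """Per-image headline result: counts and the germination rate."""

    image_id: str
    n_seeds: int
    n_germinated: int
    rate: float
    standard: GerminationStandard


def detect_radicle_pixels(
    image: np.ndarray,
    labels: ClusterLabelMap | np.ndarray,
    rgb_floor: int = 160,
) -> np.ndarray:
    """Boolean mask of radicle candidates.

    True exactly where the pixel belongs to the background/radicle cluster
    and all three channels are strictly above ``rgb_floor``.
    """
    label_arr = labels.labels if isinstance(labels, ClusterLabelMap) else labels
    image = np.asarray(image)
    if image.shape[:2] != label_arr.shape:
        raise ValueError("image and label map shapes differ")
    bright = np.all(image > rgb_floor, axis=-1)
    return bright & (label_arr == BACKGROUND_OR_RADICLE)


def filter_radicle_regions(
    mask: np.ndarray,
    min_area: int = 20,
    max_area: float = np.inf,
    connectivity: int = 8,
) -> list[RadicleRegion]:
    """Connected mask regions with min_area <= area <= max_area, area-sorted.

    The bounds remove droplet highlights (tiny) and reflective dish rims or
    merged glare (huge); both bounds are inclusive.
    """
    labeled = measure.label(
        np.asarray(mask).astype(bool), connectivity=1 if connectivity == 4 else 2
    )
    regions = []
    for region in measure.regionprops(labeled):
        if not min_area <= region.area <= max_area:
            continue
        r0, c0, r1, c1 = region.bbox
        regions.append(RadicleRegion(area=int(region.area), bbox=(c0, r0, c1, r1)))
    regions.sort(key=lambda r: (r.area, r.bbox))
    return regions


def count_germinated_by_area(
    regions: Sequence[RadicleRegion] | Sequence[int], tg: float
) -> int:
    """Number of radicle regions with area strictly greater than T_g."""
    if tg <= 0:
        raise ValueError("tg must be positive")
    areas = (r.area if isinstance(r, RadicleRegion) else int(r) for r in regions)
    return sum(1 for a in areas if a > tg)


def germination_rate(n_germinated: int, n_seeds: int) -> float:
    """Fraction of germinated seeds, N_r / N_s."""
    if n_seeds <= 0:
        raise ValueError("no seeds found (N_s must be positive)")
    if not 0 <= n_germinated <= n_seeds:
        raise ValueError("need 0 <= N_r <= N_s")
    return n_germinated / n_seeds


def segment_seed(
    image: np.ndarray,
    seed_mask: np.ndarray,
    ratio_rgb_floor: int = 100,
) -> SeedSegment:
    """Split a seed mask into radicle (bright) and body pixels.

    Within the mask, pixels whose R, G and B all strictly exceed
    ``ratio_rgb_floor`` are radicle; the rest are body.
    """
    image = np.asarray(image)
    seed_mask = np.asarray(seed_mask).astype(bool)
    if image.shape[:2] != seed_mask.shape:
        raise ValueError("image and seed mask shapes differ")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    bright = np.all(image > ratio_rgb_floor, axis=-1)
    radicle = seed_mask & bright
    return SeedSegment(
        seed_mask=seed_mask, radicle_mask=radicle, body_mask=seed_mask & ~bright
    )


def classify_by_reference(segment: SeedSegment, reference: SeedSegment) -> bool:
    """Germinated iff the seed's whole-seed ratio reaches the reference's r_0.

    The comparison is inclusive, so the reference seed itself always
    classifies as germinated.
    """
    return segment.ratio_whole >= reference.ratio_whole


def classify_by_ratio(
    segment: SeedSegment, standard: GerminationStandard
) -> bool:
    """Apply a RATIO-mode standard to one seed segment."""
    if standard.mode != "ratio":
        raise ValueError("standard is not ratio-mode")
    r = (
        segment.ratio_body
        if standard.ratio_variant == "body"
        else segment.ratio_whole
    )
    return r >= standard.ratio


class MaskProvider(Protocol):
    """Produces a seed mask (body + radicle) for a bounding-box crop.

    The published system delegates this to a pretrained promptable
    segmenter; the default implementation below uses this package's own
    color clustering, so the ratio classifier has no model dependency. Any
    callable with this signature can be plugged in.
    """

    def __call__(self, image: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
        ...


class ColorMaskProvider:
    """Default mask provider: two-means coat clustering plus bright pixels.

    Within the crop, the seed mask is the union of the seed-coat cluster and
    near-white pixels (candidate radicle); everything else (dark dish
    background) is excluded. Returns a full-image-shaped boolean mask that
    is False outside the box.
    """

    def __init__(self, radicle_rgb_floor: int = 160):
        self.radicle_rgb_floor = radicle_rgb_floor

    def __call__(
        self, image: np.ndarray, bbox: tuple[int, int, int, int]
    ) -> np.ndarray:
        x0, y0, x1, y1 = (int(v) for v in bbox)
        image = np.asarray(image)
        crop = image[y0:y1, x0:x1]
        if crop.size == 0:
            raise ValueError("bounding box lies outside the image")
        labels = kmeans_two_clusters(color_features(crop))
        bright = np.all(crop > self.radicle_rgb_floor, axis=-1)
        mask = np.zeros(image.shape[:2], dtype=bool)
        mask[y0:y1, x0:x1] = labels.seed_coat_mask | bright
        return mask


def classify_seeds_by_reference(
    image: np.ndarray,
    boxes: Sequence[tuple[int, int, int, int]],
    reference_box: tuple[int, int, int, int],
    mask_provider: MaskProvider | None = None,
    ratio_rgb_floor: int = 100,
) -> tuple[list[bool], GerminationStandard]:
    """Ratio-classify every boxed seed against a reference seed.

    The reference box is segmented first and its whole-seed ratio becomes
    r_0; each seed is then germinated iff its own ratio is >= r_0.
    """
    provider = mask_provider or ColorMaskProvider()
    ref_segment = segment_seed(
        image, provider(image, reference_box), ratio_rgb_floor
    )
    r0 = ref_segment.ratio_whole
    standard = GerminationStandard(
        mode="ratio", ratio=max(r0, np.nextafter(0, 1)),
        ratio_variant="whole", provenance="reference_seed",
    )
    flags = []
    for box in boxes:
        seg = segment_seed(image, provider(image, box), ratio_rgb_floor)
        flags.append(seg.ratio_whole >= r0)
    return flags, standard


def seed_size(component: SeedComponent) -> tuple[float, float]:
    """Seed length and width from the component's moment ellipse.

    Length and width are the major and minor axis lengths of the ellipse
    with the same second central moments as the pixel set (the standard
    regionprops convention: 4 * sqrt(eigenvalue of the pixel covariance)).
    Degenerate (collinear) pixel sets return width 0.
    """
    if component.area < 5:
        raise ValueError("component too small for size measurement (area >= 5)")
    props = measure.regionprops(component.mask.astype(np.uint8))[0]
    length = float(props.axis_major_length)
    width = float(props.axis_minor_length)
    if width == 0.0:
        import warnings

        warnings.warn("degenerate (collinear) component: width is 0", stacklevel=2)
    return length, width
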