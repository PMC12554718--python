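"""Synthetic petri-dish image generator with exact ground truth.

Renders top-view dish images that mimic the imaging-box setup the pipeline
targets: yellowish ellipse seed bodies on a dark background, near-white
radicles protruding from the germinated seeds' tips, plus optional
impurities (thin awn/stalk fragments in coat-like colors, small droplet
highlights). Every rendered seed is recounted at render time, so the ground
truth (per-seed box, class, pixel areas, per-image counts and rate) is
exact by construction rather than approximate.

Germination is assigned by exact count — round(p * n) seeds of a dish get a
radicle — so end-to-end tests have deterministic expected rates. Touching
seeds are rendered as pairs whose bodies overlap by a few pixels; the
generator records which seeds merged so counting tests know the expected
component multiplicities.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .annotations import write_voc_xml, write_yolo_txt
from .metrics import DetectionBox

#: pixels two distinct (non-touching) objects must keep between them, so a
#: 3x3 smoothing kernel can never bridge them
_CLEARANCE = 4


@dataclasses.dataclass
class SynthSpec:
    """Parameters of one synthetic dish.

    Defaults emulate the reference acquisition setup: a 1920x1080 frame
    holding 30-60 rice-like seeds of ~500-900 px body area, radicle areas on
    the order of a few hundred pixels, dark dish background (all channels
    well below 80) and strongly yellowish seed coats (R - B and G - B large
    and positive for every coat pixel).
    """

    height: int = 1080
    width: int = 1920
    #: fixed count, or inclusive (lo, hi) range to draw from
    n_seeds: int | tuple[int, int] = (30, 60)
    germination_fraction: float = 0.6
    #: semi-axis ranges (px) of the ellipse seed body; a dish holds one
    #: variety, so the base size is drawn once per dish and individual
    #: seeds jitter around it by ``within_dish_size_cv``
    semi_major_range: tuple[float, float] = (18.0, 26.0)
    semi_minor_range: tuple[float, float] = (8.0, 12.0)
    #: per-seed relative size spread within a dish (single-variety dishes
    #: have near-uniform seed sizes)
    within_dish_size_cv: float = 0.03
    #: per-channel base-color ranges for the seed coat
    coat_red: tuple[int, int] = (185, 215)
    coat_green: tuple[int, int] = (150, 185)
    coat_blue: tuple[int, int] = (45, 75)
    #: per-pixel color jitter amplitude
    color_jitter: int = 8
    #: rendered radicle pixel-area range for germinated seeds
    radicle_area_range: tuple[int, int] = (200, 400)
    radicle_width: int = 7
    #: radicle channels drawn uniformly from this near-white range
    radicle_gray: tuple[int, int] = (225, 250)
    background_gray: tuple[int, int] = (22, 42)
    touching_probability: float = 0.0
    #: impurity toggles
    awns: bool = False
    droplets: bool = False
    n_impurities: int = 6
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.germination_fraction <= 1:
            raise ValueError("germination_fraction must lie in [0, 1]")
        if not 0 <= self.touching_probability <= 1:
            raise ValueError("touching_probability must lie in [0, 1]")
        for rng in (
            self.semi_major_range,
            self.semi_minor_range,
            self.radicle_area_range,
        ):
            if rng[1] < rng[0]:
                raise ValueError(f"empty range {rng}")

    @property
    def max_radicle_length(self) -> float:
        return self.radicle_area_range[1] / max(self.radicle_width - 2, 1) + 2 * self.radicle_width + 6


@dataclasses.dataclass
class SeedTruth:
    """Ground truth for one rendered seed."""

    #: (x_min, y_min, x_max, y_max), 0-based half-open, tight on rendered pixels
    bbox: tuple[int, int, int, int]
    label: str  # "yes" | "no"
    radicle_area: int
    seed_area: int
    centroid: tuple[float, float]


@dataclasses.dataclass
class GroundTruth:
    """Exact per-image ground truth of a generated dish."""

    image_name: str
    image_size: tuple[int, int]  # (H, W)
    seeds: list[SeedTruth]
    #: index groups of seeds rendered as one touching (merged) component
    merged_groups: list[tuple[int, ...]]
    coat_mask: np.ndarray
    radicle_mask: np.ndarray

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def n_germinated(self) -> int:
        return sum(1 for s in self.seeds if s.label == "yes")

    @property
    def rate(self) -> float:
        return self.n_germinated / self.n_seeds

    def boxes(self) -> list[DetectionBox]:
        return [
            DetectionBox(*s.bbox[:2], *s.bbox[2:], label=s.label, confidence=1.0)
            for s in self.seeds
        ]


@dataclasses.dataclass
class _Patch:
    """A rendered object as a boolean mask in a local window."""

    slices: tuple[slice, slice]
    body: np.ndarray
    radicle: np.ndarray
    truth: SeedTruth


def _window(
    center: tuple[float, float], half: float, shape: tuple[int, int]
) -> tuple[slice, slice] | None:
    r0 = int(np.floor(center[0] - half))
    r1 = int(np.ceil(center[0] + half)) + 1
    c0 = int(np.floor(center[1] - half))
    c1 = int(np.ceil(center[1] + half)) + 1
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        return None
    return slice(r0, r1), slice(c0, c1)


def _ellipse_local(
    slices: tuple[slice, slice],
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
) -> np.ndarray:
    """Boolean mask of a rotated ellipse within a window (center global)."""
    rr, cc = np.mgrid[slices]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _radicle_local(
    slices: tuple[slice, slice],
    body: np.ndarray,
    center: tuple[float, float],
    a: float,
    theta: float,
    direction: int,
    target_area: int,
    width: int,
    max_len: float,
) -> np.ndarray | None:
    """Exact-area radicle mask growing outward from the body tip.

    Candidate pixels lie in a band of the given width along the major axis
    beyond the tip; they are taken in order of axial distance (center of
    the band first), so the result is a connected capsule with exactly
    ``target_area`` pixels, or None if the window cannot hold it.
    """
    ux, uy = np.cos(theta), np.sin(theta)  # (col, row) unit vector
    tip = (center[0] + direction * a * uy, center[1] + direction * a * ux)
    rr, cc = np.mgrid[slices]
    dr = rr - tip[0]
    dc = cc - tip[1]
    t = direction * (dc * ux + dr * uy)  # axial distance beyond the tip
    s = np.abs(-dc * uy + dr * ux)  # lateral offset
    band = (t >= -2.5) & (t <= max_len) & (s <= width / 2) & ~body
    idx = np.flatnonzero(band)
    if idx.size < target_area:
        return None
    order = np.lexsort((s.flat[idx], np.round(t.flat[idx])))
    mask = np.zeros(body.shape, dtype=bool)
    mask.flat[idx[order[:target_area]]] = True
    return mask


def _propose_seed(
    spec: SynthSpec,
    rng: np.random.Generator,
    shape: tuple[int, int],
    center: tuple[float, float],
    germinated: bool,
    base_axes: tuple[float, float],
) -> _Patch | None:
    # single-variety dish: per-seed size jitters around the dish's base size
    scale = float(np.clip(rng.normal(1.0, spec.within_dish_size_cv), 0.88, 1.12))
    a = base_axes[0] * scale
    b = base_axes[1] * scale
    theta = rng.uniform(0, np.pi)
    half = a + (spec.max_radicle_length if germinated else 0) + _CLEARANCE + 2
    slices = _window(center, half, shape)
    if slices is None:
        return None
    body = _ellipse_local(slices, center, a, b, theta)
    area = int(body.sum())
    if area == 0:
        return None
    radicle = np.zeros(body.shape, dtype=bool)
    if germinated:
        target = int(
            rng.integers(spec.radicle_area_range[0], spec.radicle_area_range[1] + 1)
        )
        direction = int(rng.choice([-1, 1]))
        rad = _radicle_local(
            slices, body, center, a, theta, direction, target,
            spec.radicle_width, spec.max_radicle_length,
        )
        if rad is None:
            return None
        radicle = rad
    rows, cols = np.nonzero(body | radicle)
    r_off, c_off = slices[0].start, slices[1].start
    bbox = (
        int(cols.min()) + c_off,
        int(rows.min()) + r_off,
        int(cols.max()) + c_off + 1,
        int(rows.max()) + r_off + 1,
    )
    truth = SeedTruth(
        bbox=bbox,
        label="yes" if germinated else "no",
        radicle_area=int(radicle.sum()),
        seed_area=area,
        centroid=(float(rows.mean()) + r_off, float(cols.mean()) + c_off),
    )
    return _Patch(slices=slices, body=body, radicle=radicle, truth=truth)


def _merge_slices(
    patches: Sequence[_Patch], shape: tuple[int, int]
) -> tuple[slice, slice]:
    r0 = min(p.slices[0].start for p in patches)
    r1 = max(p.slices[0].stop for p in patches)
    c0 = min(p.slices[1].start for p in patches)
    c1 = max(p.slices[1].stop for p in patches)
    return slice(max(r0, 0), min(r1, shape[0])), slice(max(c0, 0), min(c1, shape[1]))


def _embed(patch_mask: np.ndarray, src: tuple[slice, slice], dst: tuple[slice, slice]) -> np.ndarray:
    out = np.zeros(
        (dst[0].stop - dst[0].start, dst[1].stop - dst[1].start), dtype=bool
    )
    out[
        src[0].start - dst[0].start : src[0].stop - dst[0].start,
        src[1].start - dst[1].start : src[1].stop - dst[1].start,
    ] = patch_mask
    return out


def _propose_cluster(
    spec: SynthSpec,
    rng: np.random.Generator,
    shape: tuple[int, int],
    pair: bool,
    germ_flags: Sequence[bool],
    base_axes: tuple[float, float],
) -> list[_Patch] | None:
    """Propose one seed, or a touching pair sharing a few boundary pixels."""
    margin = spec.semi_major_range[1] + spec.max_radicle_length + _CLEARANCE + 4
    if 2 * margin >= min(shape):
        raise ValueError("image too small for the configured seed geometry")
    cy = rng.uniform(margin, shape[0] - margin)
    cx = rng.uniform(margin, shape[1] - margin)
    first = _propose_seed(spec, rng, shape, (cy, cx), germ_flags[0], base_axes)
    if first is None:
        return None
    if not pair:
        return [first]
    # partner center at slightly less than the sum of effective radii, so
    # the two bodies overlap by a handful of pixels and merge
    phi = rng.uniform(0, 2 * np.pi)
    r_eff = np.sqrt(base_axes[0] * base_axes[1])
    dist = 2 * r_eff * 0.95
    c2 = (cy + dist * np.sin(phi), cx + dist * np.cos(phi))
    second = _propose_seed(spec, rng, shape, c2, germ_flags[1], base_axes)
    if second is None:
        return None
    union_sl = _merge_slices([first, second], shape)
    b1 = _embed(first.body, first.slices, union_sl)
    b2 = _embed(second.body, second.slices, union_sl)
    r1 = _embed(first.radicle, first.slices, union_sl)
    r2 = _embed(second.radicle, second.slices, union_sl)
    overlap = int((b1 & b2).sum())
    joined = ndimage.label(b1 | b2, structure=np.ones((3, 3)))[1] == 1
    if not joined or overlap > 0.15 * min(b1.sum(), b2.sum()):
        return None
    if (r1 & (b2 | r2)).any() or (r2 & (b1 | r1)).any():
        return None  # a radicle collides with the partner
    return [first, second]


def _paint(
    image: np.ndarray,
    slices: tuple[slice, slice],
    mask: np.ndarray,
    base: Sequence[int],
    jitter: int,
    rng: np.random.Generator,
) -> None:
    n = int(mask.sum())
    view = image[slices]
    for c in range(3):
        vals = base[c] + rng.integers(-jitter, jitter + 1, size=n)
        channel = view[..., c]
        channel[mask] = np.clip(vals, 0, 255)


def _draw(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def generate_dish(spec: SynthSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one dish and its exact ground truth.

    Deterministic given ``spec.random_seed``. Raises if the requested
    seeds cannot be placed without exceeding the overlap budget (the error
    lists the achieved count).
    """
    rng = np.random.default_rng(spec.random_seed)
    shape = (spec.height, spec.width)

    if isinstance(spec.n_seeds, tuple):
        n = int(rng.integers(spec.n_seeds[0], spec.n_seeds[1] + 1))
    else:
        n = int(spec.n_seeds)
    n_yes = int(round(spec.germination_fraction * n))
    germinated = np.zeros(n, dtype=bool)
    germinated[rng.permutation(n)[:n_yes]] = True
    base_axes = (
        rng.uniform(*spec.semi_major_range),
        rng.uniform(*spec.semi_minor_range),
    )

    image = np.empty((*shape, 3), dtype=np.uint8)
    bg = rng.integers(
        spec.background_gray[0], spec.background_gray[1] + 1, size=(*shape, 1)
    )
    image[:] = np.clip(
        bg + rng.integers(-4, 5, size=(*shape, 3)), 0, spec.background_gray[1] + 8
    )

    occupied = np.zeros(shape, dtype=bool)  # object pixels plus clearance
    coat_mask = np.zeros(shape, dtype=bool)
    radicle_mask = np.zeros(shape, dtype=bool)
    seeds: list[SeedTruth] = []
    merged_groups: list[tuple[int, ...]] = []

    max_attempts = 300 * n
    attempts = 0
    i = 0
    while i < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} seeds (achieved {i}); "
                "reduce n_seeds or seed size"
            )
        pair = (
            spec.touching_probability > 0
            and i + 1 < n
            and rng.random() < spec.touching_probability
        )
        flags = [bool(germinated[i]), bool(germinated[i + 1]) if i + 1 < n else False]
        members = _propose_cluster(spec, rng, shape, pair, flags, base_axes)
        if members is None:
            continue
        if any(
            (occupied[p.slices] & (p.body | p.radicle)).any() for p in members
        ):
            continue

        for p in members:
            base = [
                _draw(rng, *spec.coat_red),
                _draw(rng, *spec.coat_green),
                _draw(rng, *spec.coat_blue),
            ]
            _paint(image, p.slices, p.body, base, spec.color_jitter, rng)
            if p.radicle.any():
                gray = _draw(rng, *spec.radicle_gray)
                _paint(image, p.slices, p.radicle, [gray] * 3, 4, rng)
            coat_mask[p.slices] |= p.body
            radicle_mask[p.slices] |= p.radicle
            seeds.append(p.truth)
        if len(members) > 1:
            merged_groups.append(tuple(range(i, i + len(members))))
        for p in members:
            occupied[p.slices] |= ndimage.binary_dilation(
                p.body | p.radicle, iterations=_CLEARANCE
            )
        i += len(members)

    if spec.awns or spec.droplets:
        _render_impurities(spec, rng, image, occupied)

    return image, GroundTruth(
        image_name=f"dish_{spec.random_seed:05d}",
        image_size=shape,
        seeds=seeds,
        merged_groups=merged_groups,
        coat_mask=coat_mask,
        radicle_mask=radicle_mask,
    )


def _render_impurities(
    spec: SynthSpec,
    rng: np.random.Generator,
    image: np.ndarray,
    occupied: np.ndarray,
) -> None:
    """Thin awn/stalk fragments (coat-colored, area below the 200-px noise
    floor) and droplet highlights (near-white, below the radicle size
    filter)."""
    shape = image.shape[:2]
    keep_out = ndimage.binary_dilation(occupied, iterations=2)
    full = (slice(0, shape[0]), slice(0, shape[1]))
    for _ in range(spec.n_impurities):
        if spec.awns:
            length = _draw(rng, 30, 80)  # 1 px wide: area < 200
            theta = rng.uniform(0, np.pi)
            r0 = rng.uniform(20, shape[0] - 20)
            c0 = rng.uniform(20, shape[1] - 20)
            steps = np.arange(length)
            rr = np.clip(np.round(r0 + steps * np.sin(theta)).astype(int), 0, shape[0] - 1)
            cc = np.clip(np.round(c0 + steps * np.cos(theta)).astype(int), 0, shape[1] - 1)
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
            mask &= ~keep_out
            if mask.any():
                _paint(image, full, mask, [195, 165, 60], spec.color_jitter, rng)
        if spec.droplets:
            rad = rng.uniform(1.0, 1.8)  # area ~3-10 px, below min_area=20
            r0 = rng.uniform(10, shape[0] - 10)
            c0 = rng.uniform(10, shape[1] - 10)
            sl = _window((r0, c0), rad + 2, shape)
            if sl is None:
                continue
            mask = _ellipse_local(sl, (r0, c0), rad, rad, 0.0)
            mask &= ~keep_out[sl]
            if mask.any():
                _paint(image, sl, mask, [235, 235, 235], 6, rng)


def write_image(image: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(image, mode="RGB").save(path)


def write_annotations(
    truth: GroundTruth, out_dir: str | Path, fmt: str = "voc"
) -> Path:
    """Write the ground-truth boxes as VOC XML or YOLO txt; returns the path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    boxes = truth.boxes()
    if fmt == "voc":
        path = out_dir / f"{truth.image_name}.xml"
        write_voc_xml(path, truth.image_name + ".png", truth.image_size, boxes)
    elif fmt == "yolo":
        path = out_dir / f"{truth.image_name}.txt"
        write_yolo_txt(path, truth.image_size, boxes)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return path


def write_manifest(truths: Sequence[GroundTruth], path: str | Path) -> None:
    """CSV manifest: image, total seeds, germinated seeds, rate."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "n_seeds", "n_germinated", "rate"])
        for t in truths:
            writer.writerow([t.image_name, t.n_seeds, t.n_germinated, f"{t.rate:.4f}"])
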