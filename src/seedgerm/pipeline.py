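"""End-to-end germination analysis of dish images.

One image flows through: Gaussian smoothing -> (f1, f2) two-means
segmentation -> connected-component extraction with noise removal ->
single-seed area estimation and touching-aware counting -> radicle
detection and size filtering -> germination standard -> summary row.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import counting, germination, segmentation
from .config import PipelineConfig

logger = logging.getLogger(__name__)

#: stable CSV schema mirroring the platform's export fields
RESULT_COLUMNS = ("image_name", "germinated_count", "total_seeds", "germination_rate")


@dataclasses.dataclass
class ImageAnalysis:
    """Everything the pipeline computed for one image."""

    summary: germination.GerminationSummary
    components: list[counting.SeedComponent]
    area_estimate: counting.SingleSeedAreaEstimate
    seed_count: counting.SeedCount
    radicle_regions: list[germination.RadicleRegion]
    labels: segmentation.ClusterLabelMap


def analyze_image(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    image_id: str = "image",
) -> ImageAnalysis:
    """Run the full pipeline on one RGB array."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()

    smoothed, labels = segmentation.segment_image(
        image, sigma=config.gaussian_sigma
    )
    components = counting.extract_components(
        labels.seed_coat_mask,
        min_area=config.noise_min_area,
        connectivity=config.connectivity,
    )
    if not components:
        raise ValueError(f"{image_id}: no seed components found")
    estimate = counting.estimate_single_seed_area(
        [c.area for c in components],
        stability_gap=config.stability_gap,
        min_run_length=config.stability_run_length,
    )
    count = counting.count_seeds(components, estimate.s_opt, mode=config.counting_mode)

    radicle_mask = germination.detect_radicle_pixels(
        smoothed, labels, rgb_floor=config.radicle_rgb_floor
    )
    regions = germination.filter_radicle_regions(
        radicle_mask,
        min_area=config.radicle_min_area,
        max_area=config.radicle_max_area_factor * estimate.s_opt,
        connectivity=config.connectivity,
    )
    if config.standard_mode == "area":
        n_r = germination.count_germinated_by_area(regions, config.tg)
        standard = germination.GerminationStandard(mode="area", tg=config.tg)
    else:
        # ratio standard: each radicle region's area relative to the
        # single-seed area (body variant: radicle/body; whole variant:
        # radicle/(radicle + body)), compared inclusively
        standard = germination.GerminationStandard(
            mode="ratio",
            ratio=config.ratio_standard,
            ratio_variant=config.ratio_variant,
        )
        if config.ratio_variant == "body":
            n_r = sum(
                1 for r in regions if r.area / estimate.s_opt >= config.ratio_standard
            )
        else:
            n_r = sum(
                1
                for r in regions
                if r.area / (r.area + estimate.s_opt) >= config.ratio_standard
            )
    n_r = min(n_r, count.n_seeds)  # never report more germinated than seeds
    summary = germination.GerminationSummary(
        image_id=image_id,
        n_seeds=count.n_seeds,
        n_germinated=n_r,
        rate=germination.germination_rate(n_r, count.n_seeds),
        standard=standard,
    )
    logger.info(
        "%s: N_s=%d N_r=%d rate=%.4f s_opt=%.1f (%.2fs)",
        image_id, count.n_seeds, n_r, summary.rate, estimate.s_opt,
        time.perf_counter() - t0,
    )
    return ImageAnalysis(
        summary=summary,
        components=components,
        area_estimate=estimate,
        seed_count=count,
        radicle_regions=regions,
        labels=labels,
    )


@dataclasses.dataclass
class BatchResult:
    """Per-image summaries plus per-file error records."""

    analyses: dict[str, ImageAnalysis]
    errors: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "image_name": a.summary.image_id,
                "germinated_count": a.summary.n_germinated,
                "total_seeds": a.summary.n_seeds,
                "germination_rate": f"{a.summary.rate:.4f}",
            }
            for a in self.analyses.values()
        ]
        frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
        return frame.sort_values("image_name").reset_index(drop=True)


def analyze_batch(
    paths: Sequence[str | Path],
    config: PipelineConfig | None = None,
    csv_out: str | Path | None = None,
    overlay_dir: str | Path | None = None,
) -> BatchResult:
    """Analyze many images independently; individual failures are recorded,
    not fatal. Writes the result CSV if ``csv_out`` is given."""
    if not paths:
        raise ValueError("empty batch: no images given")
    config = config or PipelineConfig()
    analyses: dict[str, ImageAnalysis] = {}
    errors: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        try:
            image = segmentation.load_rgb(path)
            analysis = analyze_image(image, config, image_id=path.stem)
            analyses[path.stem] = analysis
            if overlay_dir is not None:
                Path(overlay_dir).mkdir(parents=True, exist_ok=True)
                write_overlay(
                    image, analysis, Path(overlay_dir) / f"{path.stem}_overlay.png"
                )
        except Exception as exc:  # per-file isolation
            logger.error("%s: %s", path, exc)
            errors[path.stem] = str(exc)
    result = BatchResult(analyses=analyses, errors=errors)
    if csv_out is not None and analyses:
        result.to_frame().to_csv(csv_out, index=False)
    return result


def write_overlay(
    image: np.ndarray,
    analysis: ImageAnalysis,
    path: str | Path,
    seed_color: tuple[int, int, int] = (0, 120, 255),
    radicle_color: tuple[int, int, int] = (255, 0, 0),
) -> None:
    """Debug rendering: seed component boxes and qualifying radicle boxes."""
    out = np.asarray(image).copy()
    for comp in analysis.components:
        _draw_box(out, comp.bbox, seed_color)
    tg = analysis.summary.standard.tg or 0
    for region in analysis.radicle_regions:
        if region.area > tg:
            _draw_box(out, region.bbox, radicle_color)
    from PIL import Image

    Image.fromarray(out, mode="RGB").save(path)


def _draw_box(
    image: np.ndarray, bbox: tuple[int, int, int, int], color: tuple[int, int, int]
) -> None:
    x0, y0, x1, y1 = bbox
    x1, y1 = min(x1, image.shape[1]) - 1, min(y1, image.shape[0]) - 1
    image[y0, x0 : x1 + 1] = color
    image[y1, x0 : x1 + 1] = color
    image[y0 : y1 + 1, x0] = color
    image[y0 : y1 + 1, x1] = color
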