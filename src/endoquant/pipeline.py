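"""End-to-end orchestration and non-interactive curation.

:func:`run_pipeline` chains the stages: overlapping inference tiling ->
per-tile detection -> stitching to global coordinates -> median-size
filtering -> overlap deduplication -> result file. Per-stage object counts
are logged so type I/II behavior of the filters can be audited.

Curation replaces an interactive review step with a batch
:class:`EditFile`: a JSON document listing detection indices to remove
(false positives) and polygon rings to add (false negatives). Removals are
applied before additions; edits are scriptable and reversible given the
inverse edit file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import DetectorConfig, detect_tile
from .geometry import Detection, polygon_to_mask
from .io import ResultFile
from .tiling import (
    DEDUP_IOU,
    INFERENCE_OVERLAP,
    MAX_MULT_OF_MEDIAN,
    MIN_FRAC_OF_MEDIAN,
    TILE_SIZE,
    dedup_overlap,
    size_filter,
    stitch,
    tile_inference,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the image and the detector."""

    tile_size: int = TILE_SIZE
    overlap: int = INFERENCE_OVERLAP
    min_frac_of_median: float = MIN_FRAC_OF_MEDIAN
    max_mult_of_median: float = MAX_MULT_OF_MEDIAN
    dedup_iou: float = DEDUP_IOU
    seed: int = 0
    detector: DetectorConfig = field(default_factory=DetectorConfig)


def run_pipeline(
    image: np.ndarray,
    detector,
    config: PipelineConfig | None = None,
    identifier: str = "",
    pixel_per_micron: float = 1.0,
) -> ResultFile:
    """Run the full detection pipeline on one image.

    Pure function of (image, detector, config): repeated runs with the same
    seed produce identical results.
    """
    config = config or PipelineConfig()
    spec, tiles = tile_inference(image, config.tile_size, config.overlap)
    logger.info("tiling: %d windows of %d px (overlap %d)", spec.n_tiles, config.tile_size, config.overlap)
    per_tile = [
        detect_tile(tile, detector, config.detector, tile_id=i) for i, tile in enumerate(tiles)
    ]
    stitched = stitch(per_tile, spec)
    logger.info("stitched: %d detections", len(stitched))
    filtered = size_filter(stitched, config.min_frac_of_median, config.max_mult_of_median)
    logger.info("size filter: %d -> %d detections", len(stitched), len(filtered))
    final = dedup_overlap(filtered, spec, seed=config.seed, iou_threshold=config.dedup_iou)
    logger.info("overlap dedup: %d -> %d detections", len(filtered), len(final))
    return ResultFile(
        identifier=identifier,
        image_shape=image.shape,  # type: ignore[arg-type]
        detections=final,
        pixel_per_micron=pixel_per_micron,
    )


@dataclass
class EditFile:
    """Batch curation edits for one result file.

    ``removals`` are 0-based indices into the result's detection list;
    ``additions`` are polygon rings (lists of (x, y) vertices) for missed
    objects. Removals are applied before additions, so output count =
    input - len(removals) + len(additions).
    """

    identifier: str
    removals: list[int] = field(default_factory=list)
    additions: list[list[tuple[float, float]]] = field(default_factory=list)

    @staticmethod
    def read(path: str | Path) -> "EditFile":
        doc = json.loads(Path(path).read_text())
        return EditFile(
            identifier=doc["identifier"],
            removals=list(doc.get("removals", [])),
            additions=[[(float(x), float(y)) for x, y in ring] for ring in doc.get("additions", [])],
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "identifier": self.identifier,
                    "removals": self.removals,
                    "additions": [[[x, y] for x, y in ring] for ring in self.additions],
                }
            )
        )


def apply_edits(result: ResultFile, edits: EditFile) -> ResultFile:
    """Apply a batch edit file: drop listed detections, add drawn polygons.

    Added polygons must lie inside the image; out-of-range removal indices
    are an error. Curated additions carry score 1.0 (human-validated).
    """
    if edits.identifier != result.identifier:
        raise ValueError(
            f"edit file is for {edits.identifier!r}, result is {result.identifier!r}"
        )
    n = len(result.detections)
    for i in edits.removals:
        if not (0 <= i < n):
            raise IndexError(f"removal index {i} out of range for {n} detections")
    keep = [d for i, d in enumerate(result.detections) if i not in set(edits.removals)]
    for ring in edits.additions:
        mask = polygon_to_mask(ring, result.image_shape)
        keep.append(Detection(mask, score=1.0))
    return ResultFile(
        identifier=result.identifier,
        image_shape=result.image_shape,
        detections=keep,
        pixel_per_micron=result.pixel_per_micron,
    )
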