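"""Tile-and-stitch machinery for running a fixed-size detector on large images.

Two tiling dialects:

* **training** — non-overlapping 512 x 512 grid; annotations are clipped to
  each tile so every image tile carries a paired annotation tile. Images not
  divisible by 512 are tiled from the origin and the right/bottom remainder
  is discarded.
* **inference** — overlapping windows with an 85-px default overlap
  (stride 427); the final window per axis is clamped to end at the image
  edge, which enlarges the last overlap. A 2,048 px side therefore yields
  exactly 5 windows, a 1,024 px side 3.

The backend translates per-tile detections back to global coordinates
(:func:`stitch`), removes size outliers relative to the image-wide median
(:func:`size_filter`: below 10% or above 5x the median area), and resolves
double counting inside the overlap strips by randomly dropping one of any
pair with IoU > 0.5 (:func:`dedup_overlap`, seeded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BBox, Detection, Mask, iou

TILE_SIZE = 512
INFERENCE_OVERLAP = 85
MIN_FRAC_OF_MEDIAN = 0.10
MAX_MULT_OF_MEDIAN = 5.0
DEDUP_IOU = 0.5
MIN_CLIP_PIXELS = 10  # training-tile annotation fragments below this are dropped


@dataclass
class TileSpec:
    """The window layout used to cut an image into tiles.

    ``windows`` is a row-major list of half-open (row_start, row_stop,
    col_start, col_stop) tuples covering every image pixel.
    """

    image_shape: tuple[int, int]
    tile_size: int = TILE_SIZE
    overlap: int = INFERENCE_OVERLAP
    windows: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def n_tiles(self) -> int:
        return len(self.windows)

    def overlap_strips(self) -> list[tuple[int, int, int, int]]:
        """Half-open regions where adjacent windows overlap (row strips span
        all columns and vice versa)."""
        h, w = self.image_shape
        row_starts = sorted({win[0] for win in self.windows})
        col_starts = sorted({win[2] for win in self.windows})
        strips = []
        for prev, nxt in zip(row_starts, row_starts[1:]):
            if nxt < prev + self.tile_size:
                strips.append((nxt, prev + self.tile_size, 0, w))
        for prev, nxt in zip(col_starts, col_starts[1:]):
            if nxt < prev + self.tile_size:
                strips.append((0, h, nxt, prev + self.tile_size))
        return strips


def _axis_starts(side: int, tile: int, overlap: int) -> list[int]:
    """Window starts along one axis: stride = tile - overlap, final window
    clamped to end at the image edge."""
    if side < tile:
        raise ValueError(f"image side {side} smaller than tile size {tile}")
    stride = tile - overlap
    if side == tile:
        return [0]
    n = int(np.ceil((side - tile) / stride)) + 1
    return [min(i * stride, side - tile) for i in range(n)]


def tile_inference(
    image: np.ndarray, tile_size: int = TILE_SIZE, overlap: int = INFERENCE_OVERLAP
) -> tuple[TileSpec, list[np.ndarray]]:
    """Cut an image into overlapping inference tiles.

    Returns the window layout and the tile rasters in the same order.
    """
    h, w = image.shape
    rows = _axis_starts(h, tile_size, overlap)
    cols = _axis_starts(w, tile_size, overlap)
    windows = [(r, r + tile_size, c, c + tile_size) for r in rows for c in cols]
    spec = TileSpec((h, w), tile_size, overlap, windows)
    tiles = [image[r0:r1, c0:c1] for r0, r1, c0, c1 in windows]
    return spec, tiles


def tile_training(
    image: np.ndarray,
    annotations: list[Mask],
    tile_size: int = TILE_SIZE,
    min_clip_pixels: int = MIN_CLIP_PIXELS,
) -> list[tuple[np.ndarray, list[Mask]]]:
    """Cut an image + annotations into the non-overlapping training grid.

    Each annotation is clipped to every tile it intersects and re-expressed
    in tile-local coordinates; fragments below ``min_clip_pixels`` are
    dropped. Right/bottom remainders of images not divisible by the tile
    size are discarded.
    """
    h, w = image.shape
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {h}x{w} smaller than tile size {tile_size}")
    out = []
    for r0 in range(0, h - tile_size + 1, tile_size):
        for c0 in range(0, w - tile_size + 1, tile_size):
            r1, c1 = r0 + tile_size, c0 + tile_size
            tile_anns = []
            for m in annotations:
                bb = m.bbox()
                if bb.row_max <= r0 or bb.row_min >= r1 or bb.col_max <= c0 or bb.col_min >= c1:
                    continue
                frag = _clip_mask(m, r0, r1, c0, c1)
                if frag is not None and frag.area >= min_clip_pixels:
                    tile_anns.append(frag)
            out.append((image[r0:r1, c0:c1], tile_anns))
    return out


def _clip_mask(m: Mask, r0: int, r1: int, c0: int, c1: int) -> Mask | None:
    """Intersect a mask with a window, re-expressed in window-local coordinates."""
    mr, mc = m.offset
    h, w = m.pixels.shape
    rr0, rr1 = max(mr, r0), min(mr + h, r1)
    cc0, cc1 = max(mc, c0), min(mc + w, c1)
    if rr1 <= rr0 or cc1 <= cc0:
        return None
    sub = m.pixels[rr0 - mr : rr1 - mr, cc0 - mc : cc1 - mc]
    if not sub.any():
        return None
    return Mask(sub, (rr0 - r0, cc0 - c0), m.label).crop_tight()


def stitch(tile_detections: list[list[Detection]], spec: TileSpec) -> list[Detection]:
    """Translate per-tile detections into global image coordinates.

    Nothing is dropped here; duplicate suppression happens later in
    :func:`dedup_overlap`. A detection whose mask exceeds its tile bounds is
    an error.
    """
    if len(tile_detections) != spec.n_tiles:
        raise ValueError(
            f"got detections for {len(tile_detections)} tiles, spec has {spec.n_tiles}"
        )
    out: list[Detection] = []
    for dets, (r0, r1, c0, c1) in zip(tile_detections, spec.windows):
        for d in dets:
            bb = d.bbox
            if bb.row_max > r1 - r0 or bb.col_max > c1 - c0:
                raise ValueError(
                    f"detection {bb} exceeds tile bounds {(r1 - r0, c1 - c0)}"
                )
            out.append(d.translated(r0, c0))
    return out


def size_filter(
    detections: list[Detection],
    min_frac: float = MIN_FRAC_OF_MEDIAN,
    max_mult: float = MAX_MULT_OF_MEDIAN,
) -> list[Detection]:
    """Drop detections smaller than ``min_frac`` or larger than ``max_mult``
    times the median mask area, computed over the full stitched image.

    Boundary areas exactly at the thresholds are kept (strict inequalities);
    survivor order is preserved.
    """
    if not detections:
        return []
    areas = np.array([d.mask.area for d in detections], dtype=float)
    med = float(np.median(areas))
    keep = ~((areas < min_frac * med) | (areas > max_mult * med))
    return [d for d, k in zip(detections, keep) if k]


def dedup_overlap(
    detections: list[Detection],
    spec: TileSpec,
    seed: int = 0,
    iou_threshold: float = DEDUP_IOU,
    restrict_to_overlap: bool = True,
) -> list[Detection]:
    """Suppress double counting in tile-overlap regions.

    Among candidate pairs with mask IoU > ``iou_threshold``, one member is
    dropped by a seeded coin flip. Candidates are the detections whose
    bounding box intersects an overlap strip (the only place tiling can
    duplicate an object); everything else passes through untouched. The
    survivor set is deterministic for a fixed seed and contains no candidate
    pair above the threshold.
    """
    if not detections:
        return []
    rng = np.random.default_rng(seed)
    strips = spec.overlap_strips() if restrict_to_overlap else []

    def in_strip(d: Detection) -> bool:
        if not restrict_to_overlap:
            return True
        bb = d.bbox
        for r0, r1, c0, c1 in strips:
            if bb.row_min < r1 and r0 < bb.row_max and bb.col_min < c1 and c0 < bb.col_max:
                return True
        return False

    candidates = [(i, d) for i, d in enumerate(detections) if in_strip(d)]
    # deterministic processing order: centroid (row, col)
    candidates.sort(key=lambda t: t[1].mask.centroid())
    kept: list[tuple[int, Detection]] = []
    for idx, det in candidates:
        survivor = det
        survivor_idx = idx
        dropped = False
        j = 0
        while j < len(kept):
            k_idx, k_det = kept[j]
            if k_det.bbox.intersects(survivor.bbox) and iou(k_det.mask, survivor.mask) > iou_threshold:
                if rng.random() < 0.5:  # drop the incoming detection
                    dropped = True
                    break
                kept.pop(j)  # drop the kept one, keep scanning with the incomer
                continue
            j += 1
        if not dropped:
            kept.append((survivor_idx, survivor))
    kept_indices = {i for i, _ in kept}
    out = []
    candidate_indices = {i for i, _ in candidates}
    for i, d in enumerate(detections):
        if i not in candidate_indices or i in kept_indices:
            out.append(d)
    return out
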