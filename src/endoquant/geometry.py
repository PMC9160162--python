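"""Pixel-mask geometry: masks, boxes, IoU, union area, polygon rasterization.

Every object in the pipeline — a hand-drawn annotation, a detector
prediction, a ground-truth disk from the synthetic generator — is a
:class:`Mask`: a cropped boolean raster plus the (row, col) offset of that
raster's origin in the global image frame. Keeping masks cropped makes the
tile-stitching arithmetic explicit (translation = changing the offset) and
keeps IoU computations local.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; boxes and windows are half-open
  ``[min, max)``.
* Polygon vertices are ``(x, y)`` points (x = column axis, y = row axis),
  matching the labelme/COCO convention. Pixel ``(r, c)`` covers the unit
  square ``[c, c+1) x [r, r+1)`` and its center is ``(c + 0.5, r + 0.5)``;
  a pixel belongs to a polygon iff its center lies strictly inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon


@dataclass(frozen=True)
class BBox:
    """Half-open axis-aligned box: rows in [row_min, row_max), cols in [col_min, col_max)."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.row_max > self.row_min and self.col_max > self.col_min):
            raise ValueError(f"degenerate bbox {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    def intersects(self, other: "BBox") -> bool:
        return (
            self.row_min < other.row_max
            and other.row_min < self.row_max
            and self.col_min < other.col_max
            and other.col_min < self.col_max
        )

    def to_coco(self) -> list[float]:
        """COCO [x, y, w, h]."""
        return [float(self.col_min), float(self.row_min), float(self.width), float(self.height)]

    @staticmethod
    def from_coco(xywh: list[float]) -> "BBox":
        x, y, w, h = xywh
        return BBox(int(round(y)), int(round(x)), int(round(y + h)), int(round(x + w)))


@dataclass(eq=False)
class Mask:
    """A detected or annotated object: cropped boolean raster + global offset.

    Parameters
    ----------
    pixels
        2-D boolean array; must contain at least one True pixel.
    offset
        (row, col) of ``pixels[0, 0]`` in global image coordinates; components >= 0.
    label
        Object class; endosymbiont detections default to ``"buchnera"``.
    """

    pixels: np.ndarray
    offset: tuple[int, int] = (0, 0)
    label: str = "buchnera"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mask raster must be a non-empty 2-D array")
        if not self.pixels.any():
            raise ValueError("mask must contain at least one true pixel")
        r, c = self.offset
        if r < 0 or c < 0:
            raise ValueError(f"offset components must be >= 0, got {self.offset}")
        self.offset = (int(r), int(c))

    @property
    def area(self) -> int:
        """Number of true pixels."""
        return int(self.pixels.sum())

    def bbox(self) -> BBox:
        """Tight half-open bounding box in global coordinates."""
        rows, cols = np.nonzero(self.pixels)
        r0, c0 = self.offset
        return BBox(
            r0 + int(rows.min()),
            c0 + int(cols.min()),
            r0 + int(rows.max()) + 1,
            c0 + int(cols.max()) + 1,
        )

    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.pixels)
        r0, c0 = self.offset
        return (r0 + float(rows.mean()), c0 + float(cols.mean()))

    def translated(self, drow: int, dcol: int) -> "Mask":
        r, c = self.offset
        return Mask(self.pixels, (r + drow, c + dcol), self.label)

    def crop_tight(self) -> "Mask":
        """Trim all-false border rows/cols, adjusting the offset."""
        rows, cols = np.nonzero(self.pixels)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        return Mask(
            self.pixels[r0:r1, c0:c1],
            (self.offset[0] + r0, self.offset[1] + c0),
            self.label,
        )

    def to_global(self, shape: tuple[int, int]) -> np.ndarray:
        """Paint this mask into a full-frame boolean array of the given shape."""
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.pixels.shape
        if r0 + h > shape[0] or c0 + w > shape[1]:
            raise ValueError("mask extends beyond the requested frame")
        out[r0 : r0 + h, c0 : c0 + w] = self.pixels
        return out

    def global_pixel_set(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.pixels)
        r0, c0 = self.offset
        return set(zip((rows + r0).tolist(), (cols + c0).tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Mask):
            return NotImplemented
        return (
            self.label == other.label
            and self.offset == other.offset
            and self.pixels.shape == other.pixels.shape
            and bool(np.array_equal(self.pixels, other.pixels))
        )


@dataclass
class Detection:
    """Detector output: mask, its tight bounding box, and a score in [0.01, 1]."""

    mask: Mask
    bbox: BBox = field(default=None)  # type: ignore[assignment]
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.bbox is None:
            self.bbox = self.mask.bbox()
        elif self.bbox != self.mask.bbox():
            raise ValueError("bbox is not the tight bounding box of the mask")
        if not (0.01 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0.01, 1]")

    def translated(self, drow: int, dcol: int) -> "Detection":
        return Detection(self.mask.translated(drow, dcol), score=self.score)


def _aligned_rasters(a: Mask, b: Mask) -> tuple[np.ndarray, np.ndarray]:
    """Paint both masks into the smallest common frame."""
    ar0, ac0 = a.offset
    br0, bc0 = b.offset
    r0 = min(ar0, br0)
    c0 = min(ac0, bc0)
    r1 = max(ar0 + a.pixels.shape[0], br0 + b.pixels.shape[0])
    c1 = max(ac0 + a.pixels.shape[1], bc0 + b.pixels.shape[1])
    fa = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    fb = np.zeros_like(fa)
    fa[ar0 - r0 : ar0 - r0 + a.pixels.shape[0], ac0 - c0 : ac0 - c0 + a.pixels.shape[1]] = a.pixels
    fb[br0 - r0 : br0 - r0 + b.pixels.shape[0], bc0 - c0 : bc0 - c0 + b.pixels.shape[1]] = b.pixels
    return fa, fb


def iou(a: Mask, b: Mask) -> float:
    """Intersection over union of two masks on their global pixel sets.

    Symmetric; disjoint masks give 0, identical masks give 1.
    """
    # cheap reject: disjoint bounding boxes cannot intersect
    if not a.bbox().intersects(b.bbox()):
        return 0.0
    fa, fb = _aligned_rasters(a, b)
    inter = int(np.logical_and(fa, fb).sum())
    if inter == 0:
        return 0.0
    union = int(np.logical_or(fa, fb).sum())
    return inter / union


def union_area(masks: list[Mask]) -> int:
    """Pixels covered by at least one mask (multi-way overlaps counted once)."""
    if not masks:
        return 0
    r0 = min(m.offset[0] for m in masks)
    c0 = min(m.offset[1] for m in masks)
    r1 = max(m.offset[0] + m.pixels.shape[0] for m in masks)
    c1 = max(m.offset[1] + m.pixels.shape[1] for m in masks)
    canvas = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for m in masks:
        mr, mc = m.offset
        h, w = m.pixels.shape
        canvas[mr - r0 : mr - r0 + h, mc - c0 : mc - c0 + w] |= m.pixels
    return int(canvas.sum())


def polygon_to_mask(
    vertices: list[tuple[float, float]],
    image_shape: tuple[int, int],
    label: str = "buchnera",
    holes: list[list[tuple[float, float]]] | None = None,
) -> Mask:
    """Rasterize a polygon with the pixel-center-inside rule.

    Pixel (r, c) is included iff its center (c + 0.5, r + 0.5) lies strictly
    inside the polygon; centers exactly on the boundary are excluded. The
    result is cropped tight around the filled region.

    Raises
    ------
    ValueError
        For < 3 vertices, zero-area polygons, vertices outside the image, or
        polygons that cover no pixel center.
    """
    if len(vertices) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon([(float(x), float(y)) for x, y in vertices], holes)
    if poly.area == 0:
        raise ValueError("degenerate polygon with zero area")
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.is_empty or poly.area == 0:
            raise ValueError("polygon is invalid and cannot be repaired")
    rows, cols = image_shape
    minx, miny, maxx, maxy = poly.bounds
    if minx < 0 or miny < 0 or maxx > cols or maxy > rows:
        raise ValueError("polygon vertices outside image bounds")
    c_lo = max(0, int(np.floor(minx)))
    c_hi = min(cols, int(np.ceil(maxx)))
    r_lo = max(0, int(np.floor(miny)))
    r_hi = min(rows, int(np.ceil(maxy)))
    if c_hi <= c_lo or r_hi <= r_lo:
        raise ValueError("polygon covers no pixel centers")
    cc, rr = np.meshgrid(
        np.arange(c_lo, c_hi, dtype=float) + 0.5,
        np.arange(r_lo, r_hi, dtype=float) + 0.5,
    )
    inside = shapely.contains_xy(poly, cc.ravel(), rr.ravel()).reshape(rr.shape)
    if not inside.any():
        raise ValueError("polygon covers no pixel centers")
    return Mask(inside, (r_lo, c_lo), label).crop_tight()


def mask_to_polygons(mask: Mask) -> list[dict]:
    """Trace the exact pixel-edge boundary of a mask as polygon rings.

    Returns one entry per connected component:
    ``{"exterior": [[x, y], ...], "holes": [[[x, y], ...], ...]}``.
    Rasterizing these rings with :func:`polygon_to_mask` reproduces the
    original pixel set exactly, which is what makes result files lossless.
    """
    from shapely.geometry import box as shapely_box
    from shapely.ops import unary_union

    rows, cols = np.nonzero(mask.pixels)
    r0, c0 = mask.offset
    squares = [
        shapely_box(c0 + int(c), r0 + int(r), c0 + int(c) + 1, r0 + int(r) + 1)
        for r, c in zip(rows, cols)
    ]
    merged = unary_union(squares)
    polys = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    out = []
    for p in polys:
        out.append(
            {
                "exterior": [[float(x), float(y)] for x, y in p.exterior.coords],
                "holes": [
                    [[float(x), float(y)] for x, y in ring.coords] for ring in p.interiors
                ],
            }
        )
    return out


def polygons_to_mask(
    polygons: list[dict], image_shape: tuple[int, int], label: str = "buchnera"
) -> Mask:
    """Inverse of :func:`mask_to_polygons`: rasterize rings back into one mask."""
    parts = [
        polygon_to_mask(
            [(x, y) for x, y in p["exterior"]],
            image_shape,
            label,
            holes=[[(x, y) for x, y in h] for h in p.get("holes", [])] or None,
        )
        for p in polygons
    ]
    if len(parts) == 1:
        return parts[0]
    r0 = min(m.offset[0] for m in parts)
    c0 = min(m.offset[1] for m in parts)
    r1 = max(m.offset[0] + m.pixels.shape[0] for m in parts)
    c1 = max(m.offset[1] + m.pixels.shape[1] for m in parts)
    canvas = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for m in parts:
        mr, mc = m.offset
        canvas[mr - r0 : mr - r0 + m.pixels.shape[0], mc - c0 : mc - c0 + m.pixels.shape[1]] |= m.pixels
    return Mask(canvas, (r0, c0), label)
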