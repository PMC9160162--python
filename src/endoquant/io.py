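"""Readers and writers: PNG micrographs, labelme JSON, COCO JSON, result files.

The on-disk lingua franca of the pipeline:

* **PNG/TIFF** single-channel micrographs (8- or 16-bit). Lossy formats
  (JPEG etc.) are refused because compression artifacts corrupt both
  annotation and detection; images must be at least 512 px on each side,
  the fixed tile size of the detector.
* **labelme JSON** — hand-drawn polygon annotations, one file per image.
* **COCO JSON** — the consolidated annotation format used for training and
  evaluation; segmentation is stored as polygon lists, symmetric with the
  labelme input.
* **result JSON** — the pipeline's output: per-image final detections as
  exact pixel-boundary polygon rings (lossless; see
  :func:`~endoquant.geometry.mask_to_polygons`), editable by curation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import BBox, Detection, Mask, mask_to_polygons, polygon_to_mask, polygons_to_mask

logger = logging.getLogger(__name__)

MIN_IMAGE_SIDE = 512

_LOSSLESS_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class AnnotatedImage:
    """A micrograph plus its ground-truth object masks and physical scale."""

    image: np.ndarray | None
    ground_truth: list[Mask] = field(default_factory=list)
    pixel_per_micron: float = 1.0
    identifier: str = ""
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if self.pixel_per_micron <= 0:
            raise ValueError("pixel_per_micron must be positive")
        if self.image is not None:
            self.image = np.asarray(self.image)
            if self.image.ndim != 2:
                raise ValueError("image must be a single-channel 2-D raster")
            h, w = self.image.shape
            if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
                raise ValueError(
                    f"image is {h}x{w}; images must be at least "
                    f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} pixels"
                )
            for m in self.ground_truth:
                bb = m.bbox()
                if bb.row_max > h or bb.col_max > w:
                    raise ValueError("ground-truth mask extends beyond the image")

    @property
    def shape(self) -> tuple[int, int]:
        if self.image is None:
            raise ValueError("no image raster attached")
        return self.image.shape  # type: ignore[return-value]


@dataclass
class ResultFile:
    """Final pipeline output for one image: one record per retained detection."""

    identifier: str
    image_shape: tuple[int, int]
    detections: list[Detection] = field(default_factory=list)
    pixel_per_micron: float = 1.0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        for d in self.detections:
            if d.bbox.row_max > h or d.bbox.col_max > w or d.bbox.row_min < 0 or d.bbox.col_min < 0:
                raise ValueError(f"detection at {d.bbox} outside image {self.image_shape}")


def read_image(path: str | Path) -> np.ndarray:
    """Load a single-channel lossless image (PNG/TIFF), 8- or 16-bit."""
    path = Path(path)
    if path.suffix.lower() not in _LOSSLESS_SUFFIXES:
        raise ValueError(
            f"refusing lossy/unsupported format {path.suffix!r}; use PNG or TIFF"
        )
    img = np.asarray(Image.open(path))
    if img.ndim == 3:  # take the first channel of an accidentally-RGB export
        img = img[..., 0]
    h, w = img.shape
    if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image is {h}x{w}; images must be at least {MIN_IMAGE_SIDE} px per side"
        )
    return img


def write_image(img: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _LOSSLESS_SUFFIXES:
        raise ValueError("refusing to write a lossy format; use PNG or TIFF")
    Image.fromarray(img).save(path)


# ---------------------------------------------------------------------------
# labelme
# ---------------------------------------------------------------------------

def read_labelme(path: str | Path) -> tuple[list[Mask], tuple[int, int], str]:
    """Read polygon annotations from a labelme JSON file.

    Returns (masks, image_shape, image_identifier). Non-polygon shapes are
    skipped with a warning; missing image dimensions are an error.
    """
    doc = json.loads(Path(path).read_text())
    if "imageHeight" not in doc or "imageWidth" not in doc:
        raise ValueError(f"{path}: labelme file lacks imageHeight/imageWidth")
    shape = (int(doc["imageHeight"]), int(doc["imageWidth"]))
    masks: list[Mask] = []
    for s in doc.get("shapes", []):
        if s.get("shape_type", "polygon") != "polygon":
            logger.warning("skipping non-polygon shape of type %r in %s", s.get("shape_type"), path)
            continue
        masks.append(
            polygon_to_mask(
                [(float(x), float(y)) for x, y in s["points"]],
                shape,
                label=s.get("label", "buchnera"),
            )
        )
    identifier = doc.get("imagePath") or Path(path).stem
    return masks, shape, identifier


# ---------------------------------------------------------------------------
# COCO
# ---------------------------------------------------------------------------

def labelme_to_coco(labelme_files: list[str | Path], out_path: str | Path | None = None) -> dict:
    """Consolidate labelme files into a single COCO document.

    One COCO image per file, one annotation per polygon shape, one category
    per distinct label. Annotation ids are unique and contiguous from 1.
    """
    images, annotations = [], []
    cat_ids: dict[str, int] = {}
    seen_ids: set[str] = set()
    ann_id = 1
    for img_idx, f in enumerate(labelme_files, start=1):
        doc = json.loads(Path(f).read_text())
        if "imageHeight" not in doc or "imageWidth" not in doc:
            raise ValueError(f"{f}: labelme file lacks imageHeight/imageWidth")
        shape = (int(doc["imageHeight"]), int(doc["imageWidth"]))
        identifier = doc.get("imagePath") or Path(f).stem
        if identifier in seen_ids:
            raise ValueError(f"duplicate image identifier {identifier!r}")
        seen_ids.add(identifier)
        images.append(
            {"id": img_idx, "file_name": identifier, "height": shape[0], "width": shape[1]}
        )
        for s in doc.get("shapes", []):
            if s.get("shape_type", "polygon") != "polygon":
                logger.warning("skipping non-polygon shape in %s", f)
                continue
            label = s.get("label", "buchnera")
            if label not in cat_ids:
                cat_ids[label] = len(cat_ids) + 1
            pts = [(float(x), float(y)) for x, y in s["points"]]
            mask = polygon_to_mask(pts, shape, label=label)
            bb = mask.bbox()
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_idx,
                    "category_id": cat_ids[label],
                    "segmentation": [[v for xy in pts for v in xy]],
                    "bbox": bb.to_coco(),
                    "area": mask.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": name} for name, i in cat_ids.items()],
    }
    if out_path is not None:
        write_coco(doc, out_path)
    return doc


def write_coco(doc: dict, path: str | Path) -> None:
    _validate_coco(doc)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    _validate_coco(doc)
    return doc


def _validate_coco(doc: dict) -> None:
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"COCO document missing {key!r}")
    image_ids = {im["id"] for im in doc["images"]}
    cat_ids = {c["id"] for c in doc["categories"]}
    ann_ids = [a["id"] for a in doc["annotations"]]
    if len(set(ann_ids)) != len(ann_ids):
        raise ValueError("duplicate annotation ids")
    for a in doc["annotations"]:
        if a["image_id"] not in image_ids:
            raise ValueError(f"annotation {a['id']} references unknown image_id {a['image_id']}")
        if a["category_id"] not in cat_ids:
            raise ValueError(f"annotation {a['id']} references unknown category_id")


def coco_to_masks(doc: dict, image_id: int) -> list[Mask]:
    """Rasterize the polygon annotations of one COCO image into masks."""
    img = next((im for im in doc["images"] if im["id"] == image_id), None)
    if img is None:
        raise ValueError(f"image_id {image_id} not in document")
    shape = (img["height"], img["width"])
    names = {c["id"]: c["name"] for c in doc["categories"]}
    masks = []
    for a in doc["annotations"]:
        if a["image_id"] != image_id:
            continue
        label = names[a["category_id"]]
        parts = []
        for flat in a["segmentation"]:
            pts = [(flat[i], flat[i + 1]) for i in range(0, len(flat), 2)]
            parts.append({"exterior": [[x, y] for x, y in pts], "holes": []})
        masks.append(polygons_to_mask(parts, shape, label=label))
    return masks


def masks_to_coco(
    per_image: list[tuple[str, tuple[int, int], list[Mask]]]
) -> dict:
    """Build a COCO document from (identifier, shape, masks) triples.

    Segmentations are exact pixel-boundary rings so rasterizing them back
    reproduces each mask's pixel set.
    """
    images, annotations = [], []
    cat_ids: dict[str, int] = {}
    ann_id = 1
    for img_idx, (identifier, shape, masks) in enumerate(per_image, start=1):
        images.append(
            {"id": img_idx, "file_name": identifier, "height": shape[0], "width": shape[1]}
        )
        for m in masks:
            if m.label not in cat_ids:
                cat_ids[m.label] = len(cat_ids) + 1
            rings = mask_to_polygons(m)
            seg = [[v for xy in ring["exterior"] for v in xy] for ring in rings]
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_idx,
                    "category_id": cat_ids[m.label],
                    "segmentation": seg,
                    "bbox": m.bbox().to_coco(),
                    "area": m.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": name} for name, i in cat_ids.items()],
    }


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------

def write_result(result: ResultFile, path: str | Path) -> None:
    """Serialize a result file as JSON with lossless polygon rings per mask."""
    records = []
    for d in result.detections:
        records.append(
            {
                "score": float(d.score),
                "label": d.mask.label,
                "polygons": mask_to_polygons(d.mask),
            }
        )
    doc = {
        "identifier": result.identifier,
        "image_shape": list(result.image_shape),
        "pixel_per_micron": result.pixel_per_micron,
        "detections": records,
    }
    Path(path).write_text(json.dumps(doc))


def read_result(path: str | Path) -> ResultFile:
    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["image_shape"])
    dets = []
    for rec in doc["detections"]:
        mask = polygons_to_mask(rec["polygons"], shape, label=rec.get("label", "buchnera"))
        dets.append(Detection(mask, score=rec["score"]))
    return ResultFile(
        identifier=doc["identifier"],
        image_shape=shape,  # type: ignore[arg-type]
        detections=dets,
        pixel_per_micron=doc.get("pixel_per_micron", 1.0),
    )
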