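"""Per-host-cell morphometrics: counts, densities, object sizes, occupancy.

Given the final detections for one bacteriocyte plus its hand-measured
whole-cell and nuclear areas, five metrics are computed:

1. cytoplasm area (um^2) = whole cell area - nuclear area
2. endosymbiont density (um^-2) = count / cytoplasm area
3. per-object area (um^2), converted from pixel area by the image scale
4. per-object "diameter" (um) = sqrt(area / pi) — the formula is applied
   verbatim; geometrically it is the radius of the equal-area circle, and
   the field name keeps the conventional "diameter" label (see docs)
5. occupied fraction = (union area of all object masks, overlaps counted
   once) / cytoplasm area — reported both as a fraction and as a percent

Outlier handling follows a single-pass z-score trim: values whose absolute
z-score (sample mean/SD of the full input) exceeds 3 are removed; the
boundary |z| = 3 is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Detection, union_area

Z_MAX = 3.0


@dataclass
class CellRecord:
    """One bacteriocyte: hand-measured areas + final detections + metadata."""

    cell_area_um2: float
    nucleus_area_um2: float
    pixel_per_micron: float
    detections: list[Detection] = field(default_factory=list)
    timepoint: str | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        if not (self.cell_area_um2 > self.nucleus_area_um2 > 0):
            raise ValueError("need cell area > nucleus area > 0")
        if self.pixel_per_micron <= 0:
            raise ValueError("pixel_per_micron must be positive")


@dataclass
class CellMetrics:
    """The five morphometric outputs for one cell."""

    identifier: str
    timepoint: str | None
    n_objects: int
    cytoplasm_area_um2: float
    density_per_um2: float
    object_areas_um2: list[float]
    object_diameters_um: list[float]
    occupied_fraction: float
    occupied_percent: float


def px_area_to_um2(area_px: float, pixel_per_micron: float) -> float:
    """Convert a pixel^2 area to um^2 given the px:um scale (px per micron)."""
    if pixel_per_micron <= 0:
        raise ValueError("pixel_per_micron must be positive")
    return area_px / pixel_per_micron**2


def compute_cell_metrics(rec: CellRecord) -> CellMetrics:
    """Compute all five morphometric quantities for one cell.

    The occupancy numerator is the union of the object masks so that
    multi-way overlaps between neighboring objects are counted once.
    """
    cytoplasm = rec.cell_area_um2 - rec.nucleus_area_um2
    if cytoplasm <= 0:
        raise ValueError("cytoplasm area must be positive")
    n = len(rec.detections)
    areas_px = [d.mask.area for d in rec.detections]
    areas_um2 = [px_area_to_um2(a, rec.pixel_per_micron) for a in areas_px]
    diameters = [float(np.sqrt(a / np.pi)) for a in areas_um2]
    union_px = union_area([d.mask for d in rec.detections])
    occupied = px_area_to_um2(union_px, rec.pixel_per_micron) / cytoplasm
    return CellMetrics(
        identifier=rec.identifier,
        timepoint=rec.timepoint,
        n_objects=n,
        cytoplasm_area_um2=cytoplasm,
        density_per_um2=n / cytoplasm,
        object_areas_um2=areas_um2,
        object_diameters_um=diameters,
        occupied_fraction=occupied,
        occupied_percent=100.0 * occupied,
    )


def trim_outliers_z(
    values, z_max: float = Z_MAX
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass z-score trim: drop values with |z| > z_max.

    z is computed from the sample mean and sample (n-1) standard deviation
    of the *full* input; the comparison is strict, so a value at exactly
    |z| = z_max is kept. Zero-variance inputs are returned untouched.

    Returns (kept, removed).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return x, np.array([])
    z = np.abs((x - x.mean()) / sd)
    keep = z <= z_max
    return x[keep], x[~keep]


def metrics_table(metrics: list[CellMetrics]) -> pd.DataFrame:
    """Tidy one-row-per-cell table of the scalar metrics."""
    return pd.DataFrame(
        {
            "identifier": [m.identifier for m in metrics],
            "timepoint": [m.timepoint for m in metrics],
            "n_objects": [m.n_objects for m in metrics],
            "cytoplasm_area_um2": [m.cytoplasm_area_um2 for m in metrics],
            "density_per_um2": [m.density_per_um2 for m in metrics],
            "occupied_fraction": [m.occupied_fraction for m in metrics],
            "occupied_percent": [m.occupied_percent for m in metrics],
        }
    )


def object_table(metrics: list[CellMetrics]) -> pd.DataFrame:
    """Long-format table: one row per detected object (area + diameter)."""
    rows = []
    for m in metrics:
        for a, d in zip(m.object_areas_um2, m.object_diameters_um):
            rows.append(
                {
                    "identifier": m.identifier,
                    "timepoint": m.timepoint,
                    "area_um2": a,
                    "diameter_um": d,
                }
            )
    return pd.DataFrame(rows, columns=["identifier", "timepoint", "area_um2", "diameter_um"])


def trim_object_areas_by_timepoint(table: pd.DataFrame, z_max: float = Z_MAX) -> pd.DataFrame:
    """Apply the z-score trim to per-object areas within each timepoint."""
    kept_parts = []
    for _, grp in table.groupby("timepoint", dropna=False, sort=False):
        if len(grp) < 2:
            kept_parts.append(grp)
            continue
        x = grp["area_um2"].to_numpy()
        sd = x.std(ddof=1)
        if sd == 0:
            kept_parts.append(grp)
            continue
        z = np.abs((x - x.mean()) / sd)
        kept_parts.append(grp[z <= z_max])
    return pd.concat(kept_parts, ignore_index=True)
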