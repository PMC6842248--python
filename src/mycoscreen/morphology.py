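"""Submerged-culture macromorphology from binary images.

Filamentous fungi grown in shake flasks form either compact pellets or
dispersed mycelial fragments. Each connected foreground structure is measured
with four Euclidean descriptors — area (µm²), maximum Feret diameter (µm),
aspect ratio (max/min Feret), and solidity (area / convex-hull area) — then
classified by area and condensed into the dimensionless Morphology Number

    MN = 2 * sqrt(Area) * Solidity / (sqrt(pi) * Feret * AspectRatio)

which equals 1 for a perfect circle and tends to 0 for a one-dimensional
line.

Conventions:

* connected components are 8-connected, so thin diagonal hyphae stay joined;
* the convex hull is built on pixel *corners* (each pixel contributes its
  four corners), so a 1-pixel-wide line has min Feret = 1 px rather than 0
  and aspect ratio never divides by zero;
* classification: area >= 500 µm² -> pellet; 95 µm² <= area < 500 µm² ->
  dispersed; smaller structures are excluded from summaries.

Under these conventions MN <= 1 holds exactly: pixel area never exceeds hull
area, and the isodiametric inequality bounds the hull area by
pi * Feret_max^2 / 4, giving MN <= Feret_min / Feret_max <= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull

__all__ = [
    "StructureMask",
    "StructureMetrics",
    "CultureMorphologySummary",
    "label_structures",
    "shape_descriptors",
    "classify_structure",
    "morphology_number",
    "summarize_culture",
    "measure_structures",
    "metrics_table",
    "PELLET_MIN_AREA_UM2",
    "DISPERSED_MIN_AREA_UM2",
]

PELLET_MIN_AREA_UM2 = 500.0
DISPERSED_MIN_AREA_UM2 = 95.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class StructureMask:
    """One connected foreground component in pixel coordinates."""

    object_id: int
    pixels: np.ndarray  # (n, 2) array of (row, col) indices
    pixel_size_um: float

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=int)
        object.__setattr__(self, "pixels", pixels)
        if pixels.ndim != 2 or pixels.shape[1] != 2 or pixels.shape[0] == 0:
            raise ValueError("pixels must be a nonempty (n, 2) index array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.shape[0])


@dataclass(frozen=True)
class StructureMetrics:
    """Euclidean descriptors of one structure, in µm-based units."""

    object_id: int
    area_um2: float
    feret_max_um: float
    feret_min_um: float
    aspect_ratio: float
    solidity: float
    size_class: str | None = None
    morphology_number: float | None = None

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("area must be positive")
        if not self.feret_max_um >= self.feret_min_um > 0:
            raise ValueError("require feret_max >= feret_min > 0")
        if self.aspect_ratio < 1 - 1e-12:
            raise ValueError("aspect ratio must be >= 1")
        if not 0 < self.solidity <= 1 + 1e-12:
            raise ValueError("solidity must lie in (0, 1]")


@dataclass(frozen=True)
class CultureMorphologySummary:
    """Image-level summary of pellet/dispersed composition.

    ``pellet_area_fraction_pct`` is the pellet share of total measured fungal
    area (pellets + dispersed; excluded structures count for neither side).
    It is NaN, not 0, when no measurable structure is present. MN statistics
    are over pellets only.
    """

    n_pellets: int
    n_dispersed: int
    n_excluded: int
    pellet_area_fraction_pct: float
    mn_values: tuple[float, ...]
    mn_mean: float
    mn_median: float


def label_structures(image: np.ndarray, pixel_size_um: float) -> list[StructureMask]:
    """Extract 8-connected foreground components from a binary image.

    Accepts a single-channel image whose values are exactly two levels
    {0, max} (or all zero); anything else is rejected as non-binary.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    levels = np.unique(img)
    if levels.size > 2 or (levels.size == 2 and levels[0] != 0):
        raise ValueError(
            f"image is not binary (distinct values {levels[:5].tolist()}); "
            "threshold upstream before quantification"
        )
    labels, n = ndimage.label(img > 0, structure=_EIGHT_CONNECTED)
    masks = []
    for obj_id in range(1, n + 1):
        rows, cols = np.nonzero(labels == obj_id)
        masks.append(
            StructureMask(
                object_id=obj_id,
                pixels=np.column_stack([rows, cols]),
                pixel_size_um=pixel_size_um,
            )
        )
    return masks


def _corner_hull(pixels: np.ndarray) -> ConvexHull:
    """Convex hull over the four corners of every pixel square."""
    base = pixels.astype(float)
    corners = np.concatenate(
        [base + offset for offset in ((0, 0), (0, 1), (1, 0), (1, 1))]
    )
    return ConvexHull(np.unique(corners, axis=0))


def _feret_diameters(hull_points: np.ndarray) -> tuple[float, float]:
    """(max, min) caliper widths of a convex polygon given its vertices.

    Max Feret is the polygon diameter; min Feret is the smallest width over
    directions normal to the hull edges (for convex polygons the minimum
    width is always attained flush with an edge).
    """
    pts = hull_points
    diffs = pts[:, None, :] - pts[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(axis=2)).max())

    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 0
    normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[
        keep, None
    ]
    projections = pts @ normals.T  # vertices x edges
    widths = projections.max(axis=0) - projections.min(axis=0)
    feret_min = float(widths.min())
    return feret_max, feret_min


def shape_descriptors(mask: StructureMask) -> StructureMetrics:
    """Area, Feret max/min, aspect ratio and solidity for one structure."""
    px = mask.pixel_size_um
    area_um2 = mask.n_pixels * px**2
    hull = _corner_hull(mask.pixels)
    vertices = hull.points[hull.vertices] * px
    feret_max, feret_min = _feret_diameters(vertices)
    hull_area_um2 = hull.volume * px**2
    solidity = min(area_um2 / hull_area_um2, 1.0)
    return StructureMetrics(
        object_id=mask.object_id,
        area_um2=area_um2,
        feret_max_um=feret_max,
        feret_min_um=feret_min,
        aspect_ratio=feret_max / feret_min,
        solidity=solidity,
    )


def classify_structure(
    area_um2: float,
    pellet_min_um2: float = PELLET_MIN_AREA_UM2,
    dispersed_min_um2: float = DISPERSED_MIN_AREA_UM2,
) -> str:
    """Pellet (area >= 500 µm²), dispersed (95 <= area < 500), else excluded."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if area_um2 >= pellet_min_um2:
        return "pellet"
    if area_um2 >= dispersed_min_um2:
        return "dispersed"
    return "excluded"


def morphology_number(
    area_um2: float, solidity: float, feret_max_um: float, aspect_ratio: float
) -> float:
    """Dimensionless Morphology Number of a structure.

    ``MN = 2 * sqrt(area) * solidity / (sqrt(pi) * feret_max * aspect_ratio)``
    with area in µm² and Feret diameter in µm (units cancel). Equals 1 for a
    perfect circle and approaches 0 for a line.
    """
    if min(area_um2, solidity, feret_max_um, aspect_ratio) <= 0:
        raise ValueError("all arguments must be positive")
    if solidity > 1 + 1e-12:
        raise ValueError("solidity cannot exceed 1")
    if aspect_ratio < 1 - 1e-12:
        raise ValueError("aspect ratio cannot be below 1")
    return (
        2.0
        * math.sqrt(area_um2)
        * solidity
        / (math.sqrt(math.pi) * feret_max_um * aspect_ratio)
    )


def measure_structures(
    image: np.ndarray, pixel_size_um: float
) -> list[StructureMetrics]:
    """Full per-structure pipeline: label, describe, classify, compute MN.

    MN is attached to measured (pellet or dispersed) structures; excluded
    fragments keep their descriptors but no MN.
    """
    metrics = []
    for mask in label_structures(image, pixel_size_um):
        desc = shape_descriptors(mask)
        size_class = classify_structure(desc.area_um2)
        mn = (
            morphology_number(
                desc.area_um2, desc.solidity, desc.feret_max_um, desc.aspect_ratio
            )
            if size_class != "excluded"
            else None
        )
        metrics.append(
            StructureMetrics(
                object_id=desc.object_id,
                area_um2=desc.area_um2,
                feret_max_um=desc.feret_max_um,
                feret_min_um=desc.feret_min_um,
                aspect_ratio=desc.aspect_ratio,
                solidity=desc.solidity,
                size_class=size_class,
                morphology_number=mn,
            )
        )
    return metrics


def summarize_culture(metrics: Sequence[StructureMetrics]) -> CultureMorphologySummary:
    """Condense per-structure metrics into an image-level summary."""
    classed = [
        (m, m.size_class if m.size_class is not None else classify_structure(m.area_um2))
        for m in metrics
    ]
    pellets = [m for m, c in classed if c == "pellet"]
    dispersed = [m for m, c in classed if c == "dispersed"]
    excluded = [m for m, c in classed if c == "excluded"]

    measured_area = sum(m.area_um2 for m in pellets) + sum(
        m.area_um2 for m in dispersed
    )
    if measured_area > 0:
        fraction = 100.0 * sum(m.area_um2 for m in pellets) / measured_area
    else:
        fraction = float("nan")

    mn_values = tuple(
        m.morphology_number
        if m.morphology_number is not None
        else morphology_number(
            m.area_um2, m.solidity, m.feret_max_um, m.aspect_ratio
        )
        for m in pellets
    )
    return CultureMorphologySummary(
        n_pellets=len(pellets),
        n_dispersed=len(dispersed),
        n_excluded=len(excluded),
        pellet_area_fraction_pct=fraction,
        mn_values=mn_values,
        mn_mean=float(np.mean(mn_values)) if mn_values else float("nan"),
        mn_median=float(np.median(mn_values)) if mn_values else float("nan"),
    )


def metrics_table(metrics: Sequence[StructureMetrics]) -> pd.DataFrame:
    """Per-structure metrics as the standard CSV columns."""
    return pd.DataFrame(
        [
            {
                "object_id": m.object_id,
                "area_um2": m.area_um2,
                "feret_max_um": m.feret_max_um,
                "feret_min_um": m.feret_min_um,
                "aspect_ratio": m.aspect_ratio,
                "solidity": m.solidity,
                "size_class": m.size_class,
                "morphology_number": m.morphology_number,
            }
            for m in metrics
        ],
        columns=[
            "object_id",
            "area_um2",
            "feret_max_um",
            "feret_min_um",
            "aspect_ratio",
            "solidity",
            "size_class",
            "morphology_number",
        ],
    )
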