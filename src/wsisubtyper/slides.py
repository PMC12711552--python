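"""Slide reading, patch-grid tiling and tumor-region restriction.

A whole-slide image (WSI) is represented by :class:`SlideRecord`, which
carries the pyramid geometry (level dimensions, objective magnification)
without holding pixel data.  Plain RGB images (PNG/TIFF) are accepted as
single-level slides with a declared magnification, which is what the
synthetic test bench produces; pyramidal SVS/TIFF files are handled through
the same interface when a pyramid-aware reader is registered.

Conventions used throughout the package: pixel coordinates are 0-based,
half-open windows ``[x, x+size) x [y, y+size)``, x = column and y = row,
expressed in the pixel frame of the tiling plane (level 0 for single-level
slides).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import box as shapely_box
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 512


@dataclass(frozen=True)
class PatchCoord:
    """Grid position of one square patch.

    ``x_px``/``y_px`` are the top-left corner in the tiling plane;
    ``row``/``col`` index the non-overlapping grid, so
    ``x_px == col * size_px`` and ``y_px == row * size_px``.
    """

    row: int
    col: int
    size_px: int = DEFAULT_PATCH_SIZE

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError("row/col must be non-negative")
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")

    @property
    def x_px(self) -> int:
        return self.col * self.size_px

    @property
    def y_px(self) -> int:
        return self.row * self.size_px

    def window(self):
        """Half-open pixel window ``(x0, y0, x1, y1)``."""
        return (self.x_px, self.y_px, self.x_px + self.size_px, self.y_px + self.size_px)


@dataclass
class SlideRecord:
    """Metadata for one slide: identity, label, pyramid geometry."""

    slide_id: str
    case_id: str
    level_dimensions: list  # [(width_px, height_px), ...] level 0 largest
    objective_magnification: float
    label: Optional[str] = None  # "SCC" | "AC" | None for pure inference
    path: Optional[str] = None
    annotation_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.objective_magnification is None or self.objective_magnification <= 0:
            raise ValueError(
                f"slide {self.slide_id!r}: objective magnification metadata missing or invalid"
            )
        dims = self.level_dimensions
        if not dims:
            raise ValueError(f"slide {self.slide_id!r}: no pyramid levels")
        for i in range(1, len(dims)):
            if dims[i][0] >= dims[i - 1][0] or dims[i][1] >= dims[i - 1][1]:
                raise ValueError(
                    f"slide {self.slide_id!r}: level dimensions must strictly decrease"
                )
        if self.label is not None and self.label not in ("SCC", "AC"):
            raise ValueError(f"slide {self.slide_id!r}: label must be SCC or AC")

    def level_magnification(self, level: int) -> float:
        """Magnification of a pyramid level, inferred from the downsample factor."""
        w0 = self.level_dimensions[0][0]
        wl = self.level_dimensions[level][0]
        return self.objective_magnification * wl / w0


@dataclass
class RegionSet:
    """Tumor-region polygons for one slide, in level-0 pixel coordinates."""

    slide_id: str
    polygons: list = field(default_factory=list)  # list of ShapelyPolygon

    def __post_init__(self) -> None:
        for i, p in enumerate(self.polygons):
            if len(p.exterior.coords) - 1 < 3:
                raise ValueError(f"polygon {i} has fewer than 3 vertices")

    def union(self):
        if not self.polygons:
            return None
        return unary_union([p.buffer(0) if not p.is_valid else p for p in self.polygons])

    def __len__(self) -> int:
        return len(self.polygons)


def select_level(slide: SlideRecord, target_magnification: float,
                 tol: float = 1.0, allow_resample: bool = True) -> tuple[int, float]:
    """Choose the pyramid level for a target magnification.

    Prefers a level whose inferred magnification is within ``tol`` of the
    target; otherwise returns the nearest higher-magnification level
    together with the downsample factor needed to reach the target.

    Returns ``(level, resample_factor)`` where factor 1.0 means no
    resampling is required.
    """
    mags = [slide.level_magnification(i) for i in range(len(slide.level_dimensions))]
    for i, m in enumerate(mags):
        if abs(m - target_magnification) <= tol:
            return i, 1.0
    higher = [(m, i) for i, m in enumerate(mags) if m > target_magnification]
    if not higher:
        raise ValueError(
            f"slide {slide.slide_id!r}: requested magnification {target_magnification}x "
            f"exceeds all available levels {mags}"
        )
    if not allow_resample:
        raise ValueError(
            f"slide {slide.slide_id!r}: magnification {target_magnification}x not available "
            f"in pyramid (levels: {mags}) and resampling is disabled"
        )
    m, i = min(higher)
    return i, m / target_magnification


def tile_slide(slide: SlideRecord, size_px: int = DEFAULT_PATCH_SIZE,
               target_magnification: float = 20.0,
               allow_resample: bool = True) -> list[PatchCoord]:
    """Tile a slide into the full non-overlapping patch grid.

    The grid covers the plane at ``target_magnification``; partial tiles at
    the right/bottom edges are dropped so every patch is exactly
    ``size_px`` square.  Ordering is row-major and deterministic.
    """
    if size_px < 32:
        raise ValueError("size_px must be at least 32")
    if target_magnification > slide.objective_magnification:
        raise ValueError(
            f"slide {slide.slide_id!r}: target magnification {target_magnification}x "
            f"exceeds objective {slide.objective_magnification}x"
        )
    level, factor = select_level(slide, target_magnification, allow_resample=allow_resample)
    w, h = slide.level_dimensions[level]
    w, h = int(w / factor), int(h / factor)
    n_cols, n_rows = w // size_px, h // size_px
    return [PatchCoord(row=r, col=c, size_px=size_px)
            for r in range(n_rows) for c in range(n_cols)]


def patches_in_regions(coords: Sequence[PatchCoord], regions: RegionSet,
                       min_overlap_fraction: float = 0.5) -> list[PatchCoord]:
    """Keep patches whose overlap with the annotated tumor regions is large enough.

    A patch is kept iff ``area(patch ∩ union(polygons)) / area(patch) >=
    min_overlap_fraction`` (boundary inclusive).  An empty region set
    signals an unannotated slide: every patch is dropped with a warning.
    """
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must lie in [0, 1]")
    union = regions.union()
    if union is None:
        logger.warning("slide %s: empty region set, no patches pass the region filter",
                       regions.slide_id)
        return []
    kept = []
    for pc in coords:
        x0, y0, x1, y1 = pc.window()
        window = shapely_box(x0, y0, x1, y1)
        frac = window.intersection(union).area / window.area
        if frac >= min_overlap_fraction or math.isclose(frac, min_overlap_fraction,
                                                        rel_tol=1e-12, abs_tol=1e-12):
            kept.append(pc)
    return kept


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks.

    Two empty masks agree perfectly by convention (1.0).  Used to flag
    annotation disagreement between observers (flag threshold 0.9).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def region_mask(regions: RegionSet, shape: tuple[int, int],
                scale: float = 1.0) -> np.ndarray:
    """Rasterize a region set to a binary mask of ``shape`` (rows, cols).

    ``scale`` maps level-0 coordinates to the raster frame (e.g. 1/downsample).
    """
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros(shape, dtype=np.uint8)
    for poly in regions.polygons:
        xs, ys = poly.exterior.coords.xy
        rr, cc = draw_polygon(np.asarray(ys) * scale, np.asarray(xs) * scale, shape)
        mask[rr, cc] = 1
    return mask


def read_annotation(path) -> RegionSet:
    """Parse a GeoJSON FeatureCollection of tumor polygons.

    Polygon and MultiPolygon features are accepted; multi-polygons are
    flattened.  Self-intersecting rings are accepted but flagged in the
    log.  Coordinates are level-0 pixels.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    slide_id = path.stem
    features = doc.get("features", [])
    polygons: list[ShapelyPolygon] = []
    for idx, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        try:
            if gtype == "Polygon":
                rings = [geom["coordinates"][0]]
            elif gtype == "MultiPolygon":
                rings = [part[0] for part in geom["coordinates"]]
            else:
                raise ValueError(f"unsupported geometry type {gtype!r}")
            for ring in rings:
                poly = ShapelyPolygon(ring)
                if len(poly.exterior.coords) - 1 < 3:
                    raise ValueError("fewer than 3 vertices")
                if not poly.is_valid:
                    logger.warning("%s: feature %d has invalid (e.g. self-intersecting) "
                                   "geometry; accepted as drawn", path.name, idx)
                polygons.append(poly)
        except (KeyError, IndexError, TypeError, ValueError) as exc:
            raise ValueError(f"{path.name}: malformed geometry in feature {idx}: {exc}") from exc
    if not polygons:
        logger.warning("%s: empty feature collection", path.name)
    return RegionSet(slide_id=slide_id, polygons=polygons)


def write_annotation(regions: RegionSet, path) -> None:
    """Write a region set as a GeoJSON FeatureCollection."""
    features = []
    for poly in regions.polygons:
        features.append({
            "type": "Feature",
            "properties": {"classification": "Tumor"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(xy) for xy in poly.exterior.coords]],
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_image_slide(path, slide_id: Optional[str] = None,
                     case_id: Optional[str] = None,
                     magnification: float = 20.0,
                     label: Optional[str] = None) -> tuple[SlideRecord, np.ndarray]:
    """Load a plain RGB image file as a single-level slide.

    Returns the slide record together with the uint8 HxWx3 pixel array.
    """
    img = np.asarray(Image.open(path).convert("RGB"))
    h, w = img.shape[:2]
    sid = slide_id or Path(path).stem
    rec = SlideRecord(slide_id=sid, case_id=case_id or sid,
                      level_dimensions=[(w, h)],
                      objective_magnification=magnification,
                      label=label, path=str(path))
    return rec, img


def extract_patch(image: np.ndarray, coord: PatchCoord) -> np.ndarray:
    """Crop one patch window out of a slide plane held in memory."""
    x0, y0, x1, y1 = coord.window()
    if y1 > image.shape[0] or x1 > image.shape[1]:
        raise ValueError(f"patch window {coord.window()} exceeds image shape {image.shape[:2]}")
    return image[y0:y1, x0:x1]


MANIFEST_COLUMNS = ["slide_id", "case_id", "label", "path", "annotation_path"]


def read_manifest(path) -> pd.DataFrame:
    """Read the slide manifest CSV (slide_id, case_id, label, path, annotation_path)."""
    df = pd.read_csv(path, dtype={"slide_id": str, "case_id": str})
    missing = [c for c in ("slide_id", "case_id") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing required columns {missing}")
    return df
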