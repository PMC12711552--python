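"""Synthetic slides, patches, artifacts and prediction bags with known truth.

The generator emulates the statistical structure the pipeline cares about
— two H&E-like tissue classes with controllable separability, the five
artifact families the QC cascade screens for, mosaicked slides with tumor
annotations, and per-slide streams of patch predictions with controllable
fidelity — without attempting morphological realism.  Squamous-carcinoma
("SCC") patches carry dense solid dark elliptical blobs; adenocarcinoma
("AC") patches carry ring/annulus structures with pale lumina.  The
contrast of the class-specific structures scales linearly with the
separability parameter δ, so at δ=0 the two classes are drawn from the
identical distribution; a shared layer of stromal speckle and chromatin
noise keeps every tissue patch above the edge-variance QC floor
regardless of δ.

Everything is driven by a single integer seed: identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .slides import RegionSet, SlideRecord
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

__all__ = [
    "GeneratorConfig", "make_tissue_patch", "make_artifact_patch",
    "make_slide", "make_prediction_bags", "ARTIFACT_KINDS",
]

ARTIFACT_KINDS = ("white", "black", "glare", "pen", "blank")

# Shared palette (uint8 RGB): eosin-pink background, hematoxylin-dark nuclei.
_BG = np.array([228.0, 178.0, 198.0])
_SPECKLE = np.array([90.0, 55.0, 120.0])      # stromal nuclei, class-independent
_CLASS_DARK = np.array([110.0, 95.0, 60.0])   # subtracted at full separability
_LUMEN_LIGHT = np.array([20.0, 35.0, 25.0])   # added inside AC gland lumina
_NOISE_SD = 40.0                              # chromatin/luminance speckle

_SPECKLE_DENSITY = 0.0095   # structures per pixel, shared layer
_CLASS_DENSITY = 0.0040     # class-specific structures per pixel


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study: one config describes one dataset."""

    seed: int = 0
    separability: float = 1.0          # δ; 0 means the classes are identical
    patch_size: int = 512
    artifact_mix: dict = field(default_factory=lambda: {
        "white": 0.05, "black": 0.05, "glare": 0.05, "pen": 0.05, "blank": 0.05})
    n_slides: int = 40
    patches_per_slide: int = 16        # perfect square for a square grid
    tumor_fraction: float = 0.5
    token_fidelity: float = 0.9        # q: P(token == slide label)

    def __post_init__(self) -> None:
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if sum(self.artifact_mix.values()) > 1:
            raise ValueError("artifact fractions must sum to <= 1")
        if not 0.5 <= self.token_fidelity <= 1.0:
            raise ValueError("token_fidelity must lie in [0.5, 1]")


def _stamp_disc(img: np.ndarray, r: int, c: int, ry: float, rx: float,
                delta_vec: np.ndarray, ring: float = 0.0,
                lumen_vec: Optional[np.ndarray] = None) -> None:
    """Add an ellipse (or annulus when ``ring``>0) to the canvas in-place."""
    h, w = img.shape[:2]
    rad = int(np.ceil(max(ry, rx))) + 1
    y0, y1 = max(0, r - rad), min(h, r + rad + 1)
    x0, x1 = max(0, c - rad), min(w, c + rad + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0 - r:y1 - r, x0 - c:x1 - c]
    d2 = (yy / ry) ** 2 + (xx / rx) ** 2
    if ring > 0:
        inner = 1.0 - ring
        band = (d2 <= 1.0) & (d2 >= inner * inner)
        img[y0:y1, x0:x1][band] -= delta_vec
        if lumen_vec is not None:
            lumen = d2 < inner * inner
            img[y0:y1, x0:x1][lumen] += lumen_vec
    else:
        img[y0:y1, x0:x1][d2 <= 1.0] -= delta_vec


def make_tissue_patch(label: str, delta: float, seed=None,
                      size: int = 64) -> np.ndarray:
    """One synthetic H&E-like tissue patch of the given class.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Class
    structure contrast scales with ``delta``; the shared stromal layer is
    identical across classes.
    """
    if label not in ("SCC", "AC"):
        raise ValueError(f"label must be SCC or AC, got {label!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.tile(_BG, (size, size, 1)).astype(np.float64)
    img += rng.normal(0.0, _NOISE_SD, (size, size))[..., None]

    n_speckle = int(round(_SPECKLE_DENSITY * size * size))
    for _ in range(n_speckle):
        r, c = rng.integers(0, size, 2)
        rad = rng.uniform(1.5, 3.5)
        img_delta = _BG - _SPECKLE
        _stamp_disc(img, int(r), int(c), rad, rad, img_delta)

    d = float(np.clip(delta, 0.0, 1.0))
    n_class = int(round(_CLASS_DENSITY * size * size))
    for _ in range(n_class):
        r, c = rng.integers(0, size, 2)
        if label == "SCC":
            ry, rx = rng.uniform(2.5, 5.5), rng.uniform(2.0, 4.0)
            _stamp_disc(img, int(r), int(c), ry, rx, d * _CLASS_DARK)
        else:
            rad = rng.uniform(4.0, 8.0)
            _stamp_disc(img, int(r), int(c), rad, rad, d * _CLASS_DARK,
                        ring=0.35, lumen_vec=d * _LUMEN_LIGHT)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def make_artifact_patch(kind: str, seed=None, size: int = 512) -> np.ndarray:
    """One artifact patch engineered to trip exactly one QC step.

    white/black → RGB background filter; glare → HSV filter (low
    saturation, high value, but mean intensity inside the RGB band);
    pen → eosin-loaded ink caught by the HED filter; blank → featureless
    pink texture caught by the Canny variance filter.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (size, size, 3)
    if kind == "white":
        img = rng.normal(248.0, 2.0, shape)
    elif kind == "black":
        img = rng.normal(15.0, 4.0, shape)
    elif kind == "glare":
        img = np.tile(np.array([212.0, 212.0, 233.0]), (size, size, 1))
        img += rng.normal(0.0, 1.0, (size, size))[..., None]
    elif kind == "pen":
        # forward-synthesized ink: eosin concentration 1.3 on the Ruifrok basis
        from .qc import RUIFROK_HED_BASIS, od_to_rgb
        od = 1.3 * RUIFROK_HED_BASIS[:, 1]
        base = od_to_rgb(od[None, :])[0].astype(np.float64)
        img = np.tile(base, (size, size, 1)) + rng.normal(0.0, 2.0, shape)
    elif kind == "blank":
        img = np.tile(_BG, (size, size, 1)) + rng.normal(0.0, 2.5, shape)
    else:
        raise ValueError(f"unknown artifact kind {kind!r}; expected one of {ARTIFACT_KINDS}")
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def make_slide(label: str, cfg: GeneratorConfig, slide_index: int = 0
               ) -> tuple[np.ndarray, RegionSet, dict, dict]:
    """Mosaic a synthetic slide: tumor tissue inside an annotated polygon,
    neutral tissue elsewhere, plus the configured artifact tiles.

    Returns ``(image, regions, manifest_row, planted)`` where ``planted``
    maps grid index (row-major) to the tile kind
    (``tumor``/``neutral``/artifact kind).
    """
    g = int(round(np.sqrt(cfg.patches_per_slide)))
    if g * g != cfg.patches_per_slide:
        raise ValueError("patches_per_slide must be a perfect square")
    ps = cfg.patch_size
    rng = np.random.default_rng((cfg.seed, 7919, slide_index))
    n_tiles = g * g

    # tumor region: first k tiles in row-major order, as one rectilinear polygon
    k = int(round(cfg.tumor_fraction * n_tiles))
    k = max(1, min(n_tiles, k))
    full_rows, rem = divmod(k, g)
    boxes = []
    if full_rows:
        boxes.append(shapely_box(0, 0, g * ps, full_rows * ps))
    if rem:
        boxes.append(shapely_box(0, full_rows * ps, rem * ps, (full_rows + 1) * ps))
    union = unary_union(boxes)
    slide_id = f"synth{slide_index:03d}"
    regions = RegionSet(slide_id=slide_id, polygons=[union])
    tumor_tiles = set(range(k))

    # artifact placement
    kinds = ["tumor" if i in tumor_tiles else "neutral" for i in range(n_tiles)]
    n_art = {kd: int(round(f * n_tiles)) for kd, f in cfg.artifact_mix.items()}
    art_slots = rng.permutation(n_tiles)[:sum(n_art.values())]
    it = iter(art_slots)
    for kd in ARTIFACT_KINDS:
        for _ in range(n_art.get(kd, 0)):
            try:
                kinds[next(it)] = kd
            except StopIteration:
                break

    img = np.empty((g * ps, g * ps, 3), dtype=np.uint8)
    for i in range(n_tiles):
        r, c = divmod(i, g)
        kd = kinds[i]
        if kd == "tumor":
            tile = make_tissue_patch(label, cfg.separability, rng, size=ps)
        elif kd == "neutral":
            tile = make_tissue_patch("SCC", 0.0, rng, size=ps)
        else:
            tile = make_artifact_patch(kd, rng, size=ps)
        img[r * ps:(r + 1) * ps, c * ps:(c + 1) * ps] = tile

    row = {"slide_id": slide_id, "case_id": f"case{slide_index:03d}",
           "label": label, "path": None, "annotation_path": None}
    planted = {i: kinds[i] for i in range(n_tiles)}
    return img, regions, row, planted


def slide_record_for(image: np.ndarray, row: dict,
                     magnification: float = 20.0) -> SlideRecord:
    """SlideRecord describing an in-memory synthetic slide plane."""
    h, w = image.shape[:2]
    return SlideRecord(slide_id=row["slide_id"], case_id=row["case_id"],
                       level_dimensions=[(w, h)],
                       objective_magnification=magnification,
                       label=row.get("label"))


def make_prediction_bags(n_slides: int, prevalence: float, q: float,
                         bag_size_range: tuple[int, int] = (30, 100),
                         seed: int = 0):
    """Per-slide streams of patch predictions with token fidelity ``q``.

    Each slide's label is Bernoulli(``prevalence``) for AC; each token
    equals the slide label with probability ``q`` and is flipped
    otherwise.  ``p_ac`` is drawn consistently with the token (above 0.5
    for AC tokens, below for SCC).  Returns ``(bags, truth)`` where truth
    is the list of slide labels.
    """
    from .aggregation import PredictionBag

    if not 0.5 <= q <= 1.0:
        raise ValueError("q must lie in [0.5, 1]")
    rng = np.random.default_rng(seed)
    bags, truth = [], []
    for i in range(n_slides):
        label = "AC" if rng.random() < prevalence else "SCC"
        n = int(rng.integers(bag_size_range[0], bag_size_range[1] + 1))
        agree = rng.random(n) < q
        tokens = np.where(agree, label, "AC" if label == "SCC" else "SCC")
        is_ac = tokens == "AC"
        probs = np.where(is_ac, rng.uniform(0.5, 1.0, n), rng.uniform(0.0, 0.5, n))
        bags.append(PredictionBag(slide_id=f"bag{i:04d}", case_id=f"case{i:04d}",
                                  tokens=list(tokens), probs=probs))
        truth.append(label)
    return bags, truth
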