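"""Five-step patch quality-control cascade and stain normalization.

Patches cut from an H&E slide are screened in a fixed order before any
classification: (1) white/black background by RGB intensity, (2) glass
glare and scanning artifacts by HSV saturation/value, (3) pen markings by
eosin concentration after stain deconvolution into the
hematoxylin-eosin-DAB (HED) space, (4) near-featureless texture by the
variance of the Canny edge map, and finally (5) Vahadane stain
normalization of the survivors.  A patch stops at its first rejecting
step, and the verdict records which step fired together with the measured
statistic, so per-step rejection counts can be audited.

Stain arithmetic uses optical density ``OD = -log10((I + 1) / 256)`` per
channel; a stain basis is a matrix whose unit-norm columns are the OD
vectors of the individual dyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import canny as _canny

__all__ = [
    "QcConfig", "QcVerdict", "RUIFROK_HED_BASIS",
    "rgb_background_filter", "hsv_artifact_filter", "hed_deconvolve",
    "hed_reconstruct", "hed_penmark_filter", "canny_variance_filter",
    "vahadane_fit", "vahadane_normalize", "VahadaneNormalizer", "run_qc",
]

# Ruifrok & Johnston H&E-DAB stain OD vectors (columns: H, E, DAB), unit norm.
RUIFROK_HED_BASIS = np.array([
    [0.65, 0.07, 0.27],
    [0.70, 0.99, 0.57],
    [0.29, 0.11, 0.78],
])
RUIFROK_HED_BASIS = RUIFROK_HED_BASIS / np.linalg.norm(RUIFROK_HED_BASIS, axis=0)

QC_STEPS = ("rgb", "hsv", "hed", "canny")


@dataclass
class QcConfig:
    """Thresholds for the QC cascade; every knob is overridable.

    Intensity thresholds are on the 8-bit scale.  ``rgb_fraction`` /
    ``hsv_fraction`` are the rejection fractions (a patch is rejected when
    the offending pixel fraction strictly exceeds them).  ``eosin_ref`` is
    the eosin concentration (OD units) treated as full ink saturation when
    rescaling the eosin plane to [0, 1].
    """

    rgb_high: int = 220
    rgb_low: int = 40
    rgb_fraction: float = 0.80
    hsv_fraction: float = 0.70
    hsv_sat_low: int = 25
    hsv_val_high: int = 230
    eosin_quantile: float = 0.90
    eosin_ref: float = 1.0
    canny_variance_min: float = 7000.0
    canny_sigma: float = 0.5
    canny_low: float = 100.0
    canny_high: float = 200.0
    normalize: bool = True
    rgb_enabled: bool = True
    hsv_enabled: bool = True
    hed_enabled: bool = True
    canny_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.rgb_low < self.rgb_high <= 255:
            raise ValueError("need 0 <= rgb_low < rgb_high <= 255")
        for name in ("rgb_fraction", "hsv_fraction", "eosin_quantile"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.canny_variance_min < 0:
            raise ValueError("canny_variance_min must be >= 0")


@dataclass
class QcVerdict:
    """Audit record for one patch: kept/rejected, the first failing step, stats."""

    kept: bool
    rejected_at: str = "none"  # none | rgb | hsv | hed | canny
    step_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kept != (self.rejected_at == "none"):
            raise ValueError("kept must agree with rejected_at")


def _check_rgb(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB patch, got shape {patch.shape}")
    return patch


def rgb_background_filter(patch: np.ndarray, cfg: QcConfig) -> QcVerdict:
    """Reject patches dominated by white background or black regions.

    A pixel counts as background when its mean channel intensity exceeds
    ``rgb_high`` (white) or falls below ``rgb_low`` (black); the patch is
    rejected when the background fraction strictly exceeds ``rgb_fraction``.
    """
    patch = _check_rgb(patch)
    mean = patch.astype(np.float64).mean(axis=2)
    frac = float(np.mean((mean > cfg.rgb_high) | (mean < cfg.rgb_low)))
    rejected = frac > cfg.rgb_fraction
    return QcVerdict(kept=not rejected, rejected_at="rgb" if rejected else "none",
                     step_stats={"rgb": frac})


def hsv_artifact_filter(patch: np.ndarray, cfg: QcConfig) -> QcVerdict:
    """Reject glare/debris patches: many pixels with low saturation AND high value."""
    patch = _check_rgb(patch)
    hsv = rgb2hsv(patch)
    glare = (hsv[..., 1] < cfg.hsv_sat_low / 255.0) & (hsv[..., 2] > cfg.hsv_val_high / 255.0)
    frac = float(glare.mean())
    rejected = frac > cfg.hsv_fraction
    return QcVerdict(kept=not rejected, rejected_at="hsv" if rejected else "none",
                     step_stats={"hsv": frac})


def optical_density(patch: np.ndarray) -> np.ndarray:
    """Per-channel optical density, ``-log10((I + 1) / 256)``."""
    patch = np.asarray(patch, dtype=np.float64)
    return -np.log10((patch + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`optical_density` back to uint8 RGB (clipped)."""
    intensity = 256.0 * np.power(10.0, -np.asarray(od)) - 1.0
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def hed_deconvolve(patch: np.ndarray, basis: Optional[np.ndarray] = None,
                   clip: bool = True) -> np.ndarray:
    """Unmix a patch into stain concentration planes.

    ``basis`` holds one stain OD vector per column (default: the Ruifrok
    H&E-DAB basis).  Returns an ``H x W x n_stains`` array of stain
    concentrations obtained through the pseudo-inverse of the basis,
    clipped at zero unless ``clip=False`` (the unclipped form inverts
    exactly for a square basis).
    """
    patch = _check_rgb(patch)
    basis = RUIFROK_HED_BASIS if basis is None else np.asarray(basis, dtype=np.float64)
    if basis.shape[0] != 3:
        raise ValueError("stain basis must have 3 rows (RGB optical densities)")
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValueError("stain basis is singular")
    od = optical_density(patch).reshape(-1, 3)
    conc = od @ np.linalg.pinv(basis).T
    if clip:
        conc = np.maximum(conc, 0.0)
    return conc.reshape(patch.shape[0], patch.shape[1], basis.shape[1])


def hed_reconstruct(concentrations: np.ndarray,
                    basis: Optional[np.ndarray] = None) -> np.ndarray:
    """Re-render stain concentration planes back to an 8-bit RGB patch."""
    basis = RUIFROK_HED_BASIS if basis is None else np.asarray(basis, dtype=np.float64)
    conc = np.asarray(concentrations, dtype=np.float64)
    od = conc.reshape(-1, conc.shape[-1]) @ basis.T
    return od_to_rgb(od).reshape(conc.shape[0], conc.shape[1], 3)


def hed_penmark_filter(patch: np.ndarray, cfg: QcConfig) -> QcVerdict:
    """Reject pen-marked patches: mean rescaled eosin concentration above 90%.

    The eosin plane is rescaled to [0, 1] against the fixed reference
    concentration ``cfg.eosin_ref`` (values above the reference saturate
    at 1); ink pigments load heavily on the eosin direction while real
    eosin-stained tissue sits far below the reference.
    """
    conc = hed_deconvolve(patch)
    eosin = np.clip(conc[..., 1] / cfg.eosin_ref, 0.0, 1.0)
    mean = float(eosin.mean())
    rejected = mean > cfg.eosin_quantile
    return QcVerdict(kept=not rejected, rejected_at="hed" if rejected else "none",
                     step_stats={"hed": mean})


def canny_edge_variance(patch: np.ndarray, cfg: QcConfig) -> float:
    """Variance of the {0, 255} Canny edge map of the grayscale patch.

    The grayscale image is kept on the 0-255 scale so the hysteresis
    thresholds (default 100/200) act on 8-bit-compatible gradient
    magnitudes; a map with edge-pixel fraction p has variance 255²·p(1−p).
    """
    patch = _check_rgb(patch)
    gray = rgb2gray(patch) * 255.0
    edges = _canny(gray, sigma=cfg.canny_sigma,
                   low_threshold=cfg.canny_low, high_threshold=cfg.canny_high)
    return float(np.where(edges, 255.0, 0.0).var())


def canny_variance_filter(patch: np.ndarray, cfg: QcConfig) -> QcVerdict:
    """Reject near-featureless patches whose edge-map variance is below the cutoff."""
    var = canny_edge_variance(patch, cfg)
    rejected = var < cfg.canny_variance_min
    return QcVerdict(kept=not rejected, rejected_at="canny" if rejected else "none",
                     step_stats={"canny": var})


# ---------------------------------------------------------------------------
# Vahadane stain normalization


def _od_pixels(patch: np.ndarray, od_threshold: float) -> np.ndarray:
    od = optical_density(patch).reshape(-1, 3)
    keep = np.linalg.norm(od, axis=1) > od_threshold
    return od[keep]


def vahadane_fit(reference_patch: np.ndarray, n_stains: int = 2,
                 sparsity: float = 0.1, seed: int = 0,
                 od_threshold: float = 0.15, max_pixels: int = 5000) -> np.ndarray:
    """Learn a stain basis by sparse non-negative factorization of optical density.

    Tissue pixels (OD norm above ``od_threshold``) are factorized as
    ``OD ≈ C · Bᵀ`` with non-negative concentrations ``C`` and dictionary
    ``B`` via sparse dictionary learning; the dictionary rows become the
    unit-norm stain columns, ordered hematoxylin-first (larger red-channel
    OD).  Deterministic for a fixed ``seed``.
    """
    from sklearn.decomposition import DictionaryLearning

    od = _od_pixels(_check_rgb(reference_patch), od_threshold)
    if od.shape[0] < 50:
        raise ValueError(
            "reference patch is nearly blank (too few tissue pixels above the OD "
            "threshold); supply a reference containing stained tissue"
        )
    rng = np.random.default_rng(seed)
    if od.shape[0] > max_pixels:
        od = od[rng.choice(od.shape[0], size=max_pixels, replace=False)]
    dl = DictionaryLearning(
        n_components=n_stains, alpha=sparsity, fit_algorithm="cd",
        transform_algorithm="lasso_cd", positive_code=True, positive_dict=True,
        random_state=seed, max_iter=500,
    )
    dl.fit(od)
    basis = dl.components_.T  # columns are stains
    norms = np.linalg.norm(basis, axis=0)
    if np.any(norms < 1e-8):
        raise ValueError("degenerate stain basis (zero column); try a different reference")
    basis = basis / norms
    order = np.argsort(-basis[0])  # hematoxylin absorbs more red light
    return basis[:, order]


def stain_concentrations(patch: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Least-squares stain concentrations (clipped at zero) for a fitted basis."""
    od = optical_density(_check_rgb(patch)).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(basis, od.T, rcond=None)
    return np.maximum(conc.T, 0.0)


def vahadane_normalize(patch: np.ndarray, source_basis: np.ndarray,
                       target_basis: np.ndarray,
                       target_concentration_scale: Optional[np.ndarray] = None
                       ) -> np.ndarray:
    """Re-render a patch through a target stain basis.

    Source concentrations are matched stain-by-stain to the target's
    99th-percentile concentration scale (no scaling when the scale is
    omitted), then recombined through the target basis.  Zero-OD (white)
    pixels are basis-invariant and stay white.
    """
    patch = _check_rgb(patch)
    conc = stain_concentrations(patch, source_basis)
    if target_concentration_scale is not None:
        src_p99 = np.percentile(conc, 99, axis=0)
        scale = np.where(src_p99 > 1e-8,
                         np.asarray(target_concentration_scale, dtype=float) /
                         np.maximum(src_p99, 1e-8), 1.0)
        conc = conc * scale
    od = conc @ np.asarray(target_basis, dtype=np.float64).T
    return od_to_rgb(od).reshape(patch.shape)


def concentration_scale(patch: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Per-stain 99th-percentile concentration of a patch under a basis."""
    return np.percentile(stain_concentrations(patch, basis), 99, axis=0)


class VahadaneNormalizer:
    """Fit a target stain appearance once, then normalize any patch to it.

    By default the source appearance of each incoming patch is described
    by the standard Ruifrok H&E columns (fast, closed-form); per-patch
    sparse basis fitting can be requested for slides with unusual stains.
    """

    def __init__(self, n_stains: int = 2, sparsity: float = 0.1, seed: int = 0,
                 fit_source_per_patch: bool = False):
        self.n_stains = n_stains
        self.sparsity = sparsity
        self.seed = seed
        self.fit_source_per_patch = fit_source_per_patch
        self.target_basis: Optional[np.ndarray] = None
        self.target_scale: Optional[np.ndarray] = None

    def fit(self, target_patch: np.ndarray) -> "VahadaneNormalizer":
        self.target_basis = vahadane_fit(target_patch, self.n_stains,
                                         self.sparsity, self.seed)
        self.target_scale = concentration_scale(target_patch, self.target_basis)
        return self

    def transform(self, patch: np.ndarray) -> np.ndarray:
        if self.target_basis is None:
            raise RuntimeError("normalizer is not fitted; call fit(target_patch) first")
        if self.fit_source_per_patch:
            source = vahadane_fit(patch, self.n_stains, self.sparsity, self.seed)
        else:
            source = RUIFROK_HED_BASIS[:, :self.n_stains]
        return vahadane_normalize(patch, source, self.target_basis, self.target_scale)


# ---------------------------------------------------------------------------
# Cascade driver


def run_qc(patches: Sequence[np.ndarray], cfg: Optional[QcConfig] = None,
           normalizer: Optional[VahadaneNormalizer] = None
           ) -> tuple[list[np.ndarray], list[QcVerdict], dict]:
    """Run the full cascade over a batch of patches.

    Steps run strictly in order rgb → hsv → hed → canny; a patch stops at
    its first rejecting step.  Survivors are stain-normalized when
    ``cfg.normalize`` is set and a fitted normalizer is supplied
    (normalization never changes a verdict).  Returns the kept patches,
    one verdict per input patch, and per-step rejection counts.
    """
    cfg = cfg or QcConfig()
    steps = [
        ("rgb", cfg.rgb_enabled, rgb_background_filter),
        ("hsv", cfg.hsv_enabled, hsv_artifact_filter),
        ("hed", cfg.hed_enabled, hed_penmark_filter),
        ("canny", cfg.canny_enabled, canny_variance_filter),
    ]
    kept_patches: list[np.ndarray] = []
    verdicts: list[QcVerdict] = []
    counts = {name: 0 for name in QC_STEPS}
    for patch in patches:
        stats: dict = {}
        rejected_at = "none"
        for name, enabled, step_fn in steps:
            if not enabled:
                continue
            frag = step_fn(patch, cfg)
            stats.update(frag.step_stats)
            if not frag.kept:
                rejected_at = name
                break
        if rejected_at == "none":
            out = patch
            if cfg.normalize and normalizer is not None:
                out = normalizer.transform(patch)
            kept_patches.append(out)
            verdicts.append(QcVerdict(kept=True, step_stats=stats))
        else:
            counts[rejected_at] += 1
            verdicts.append(QcVerdict(kept=False, rejected_at=rejected_at,
                                      step_stats=stats))
    return kept_patches, verdicts, counts
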