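"""Morphological segmentation of rosette µXRF scans into substructures.

The algorithm classifies every pixel as background, petiole, leaf margin,
vasculature (vein) or interveinal tissue:

1. Each metal raster (Zn, K, Ca, Ni) is binarized with Otsu's threshold;
   the union of the four masks is the plant-foreground mask.
2. Morphological opening with a square structuring element (default 15×15)
   removes the thin petioles, leaving the blade mask; the residual
   plant-minus-blade, filtered for tiny connected components, is the petiole.
3. The leaf margin is the internal gradient of the blade: blade minus its
   erosion (default 7×7 element, giving a 3-px band on straight edges).
4. Veins are ridges of the Compton scatter raster detected with a large-
   aperture Laplacian: a strongly negative threshold captures primary and
   secondary vasculature, and the skeleton of the weakly negative region
   captures thin tertiary vasculature; both are intersected with the blade
   interior to exclude margin detections.
5. Interveinal tissue is the blade minus margin minus vein.

Margin, vein and tissue partition the blade exactly; petiole is disjoint
from the blade; everything else is background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.special import comb
from skimage import morphology as skmorph

from .io_formats import (
    CLASS_CODES,
    METALS,
    STRUCTURE_8,
    IntensityRaster,
    ScanBundle,
)

logger = logging.getLogger(__name__)


def _check_odd_kernel(name: str, value: int) -> None:
    if value < 3 or value % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 3, got {value}")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation algorithm.

    opening_kernel
        Side of the square structuring element separating blade from petiole.
        Structures narrower than this survive as petiole.
    min_component_fraction
        Connected components of the petiole residual smaller than this
        fraction of the image area are discarded (default 0.001%).
    margin_erosion_kernel
        Side of the erosion element for the internal gradient; a side of
        ``2w+1`` yields a margin band of width ``w`` on straight edges
        (default 7 → 3 px, ~100 µm at 33 µm/px).
    laplacian_kernel
        Aperture of the Laplacian ridge detector on the Compton raster.
    vein1_threshold, vein2_threshold
        Thresholds on the (unnormalized) Laplacian response below which a
        pixel is primary/secondary vasculature, respectively part of the
        region whose skeleton is tertiary vasculature.  Bright ridges give
        negative responses, so both are ≤ 0.  The magnitudes are specific to
        the Laplacian dialect defined by :func:`laplacian` and should be
        re-tuned for other detectors or strongly different intensity scales.
    """

    opening_kernel: int = 15
    min_component_fraction: float = 1e-5
    margin_erosion_kernel: int = 7
    laplacian_kernel: int = 7
    vein1_threshold: float = -2500.0
    vein2_threshold: float = 0.0

    def __post_init__(self) -> None:
        _check_odd_kernel("opening_kernel", self.opening_kernel)
        _check_odd_kernel("margin_erosion_kernel", self.margin_erosion_kernel)
        _check_odd_kernel("laplacian_kernel", self.laplacian_kernel)
        if not (0.0 <= self.min_component_fraction < 1.0):
            raise ValueError(
                "min_component_fraction must be in [0, 1), got "
                f"{self.min_component_fraction}"
            )

    def with_(self, **kwargs) -> "SegmentationParams":
        return replace(self, **kwargs)


@dataclass
class SegmentationLabels:
    """Per-pixel class map over {background, petiole, margin, vein, tissue}."""

    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("label map must be 2-D")
        bad = set(np.unique(self.classes)) - set(CLASS_CODES.values())
        if bad:
            raise ValueError(f"unknown class code(s): {sorted(bad)}")
        self.classes = self.classes.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def mask(self, cls: str) -> np.ndarray:
        """Boolean mask of one class by name."""
        return self.classes == CLASS_CODES[cls]

    @property
    def plant(self) -> np.ndarray:
        """All non-background pixels."""
        return self.classes != CLASS_CODES["background"]

    def copy(self) -> "SegmentationLabels":
        return SegmentationLabels(self.classes.copy())


# ---------------------------------------------------------------------------
# Otsu thresholding


def _histogram_values(pixels: np.ndarray) -> np.ndarray:
    """Map pixel values onto the 0–255 histogram domain.

    8-bit rasters are used as-is; anything else is min–max scaled onto
    0–255 and floored to integer bins.
    """
    if pixels.dtype == np.uint8:
        return pixels
    pmin = float(pixels.min())
    pmax = float(pixels.max())
    if pmax == pmin:
        return np.zeros(pixels.shape, dtype=np.uint8)
    scaled = (pixels.astype(np.float64) - pmin) * (255.0 / (pmax - pmin))
    return np.minimum(scaled, 255.0).astype(np.uint8)


def otsu_threshold(raster: IntensityRaster) -> int | None:
    """Otsu threshold on the 256-bin histogram of a raster.

    Returns the threshold ``t*`` minimizing the weighted intra-class
    intensity variance of the split ``{v <= t}`` / ``{v > t}``; ties are
    broken by the smallest threshold.  Returns ``None`` for a constant
    raster (no separating threshold exists).
    """
    pixels = raster.pixels
    if pixels.min() == pixels.max():
        return None
    vals = _histogram_values(pixels)
    counts = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    total = counts.sum()
    levels = np.arange(256, dtype=np.float64)

    w0 = np.cumsum(counts)                       # pixels with value <= t
    s0 = np.cumsum(counts * levels)
    w1 = total - w0
    s1 = s0[-1] - s0

    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = s0 / w0
        m1 = s1 / w1
        # E[v^2] cumulative for per-class variances
        q0 = np.cumsum(counts * levels**2)
        q1 = q0[-1] - q0
        var0 = q0 / w0 - m0**2
        var1 = q1 / w1 - m1**2
    var0 = np.where(w0 > 0, var0, 0.0)
    var1 = np.where(w1 > 0, var1, 0.0)
    within = (w0 * var0 + w1 * var1) / total
    return int(np.argmin(within))  # argmin takes the first (smallest) tie


def otsu_mask(raster: IntensityRaster) -> np.ndarray:
    """Binarize a raster at its Otsu threshold (foreground: value > t*).

    A constant raster has no separating threshold and yields an all-false
    mask with a warning.
    """
    t = otsu_threshold(raster)
    if t is None:
        logger.warning(
            "constant %s raster: no Otsu threshold exists, returning empty mask",
            raster.element,
        )
        return np.zeros(raster.shape, dtype=bool)
    return _histogram_values(raster.pixels) > t


def plant_mask(bundle: ScanBundle) -> np.ndarray:
    """Plant-foreground mask: union of the four metal Otsu masks."""
    out = np.zeros(bundle.shape, dtype=bool)
    for element in METALS:
        out |= otsu_mask(bundle[element])
    return out


# ---------------------------------------------------------------------------
# Morphology

# Out-of-image pixels count as foreground for erosion and background for
# dilation, so a plant cropped at the image edge does not grow a phantom
# margin or lose blade area to the border.


def _erode(mask: np.ndarray, k: int) -> np.ndarray:
    return ndimage.binary_erosion(mask, structure=np.ones((k, k), bool),
                                  border_value=1)


def _dilate(mask: np.ndarray, k: int) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=np.ones((k, k), bool),
                                   border_value=0)


def blade_mask(plant: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Blade mask: opening of the plant mask with a square element.

    Structures narrower than ``opening_kernel`` (petioles) are removed,
    blades are kept.
    """
    k = params.opening_kernel
    return _dilate(_erode(np.asarray(plant, bool), k), k)


def petiole_mask(
    plant: np.ndarray, blade: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Petiole mask: plant minus blade, small components removed.

    Connected components (8-connectivity) of the residual with area below
    ``min_component_fraction`` of the image area are discarded; the pixel
    threshold is rounded up.
    """
    plant = np.asarray(plant, bool)
    blade = np.asarray(blade, bool)
    residual = plant & ~blade
    min_area = int(np.ceil(params.min_component_fraction * plant.size))
    if min_area <= 1 or not residual.any():
        if not residual.any():
            logger.warning("empty petiole mask (plant may equal its blade)")
        return residual
    lab, n = ndimage.label(residual, structure=STRUCTURE_8)
    areas = np.bincount(lab.ravel())
    keep = areas >= min_area
    keep[0] = False
    out = keep[lab]
    if not out.any():
        logger.warning("empty petiole mask after small-component filtering")
    return out


def margin_mask(blade: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Leaf-margin mask: internal gradient of the blade.

    blade minus erosion(blade); with the default 7×7 element the band is
    3 px wide on straight edges.
    """
    blade = np.asarray(blade, bool)
    return blade & ~_erode(blade, params.margin_erosion_kernel)


# ---------------------------------------------------------------------------
# Vein detection


def _pascal_row(n: int) -> np.ndarray:
    return comb(n - 1, np.arange(n)).astype(np.float64)


def laplacian_kernels(aperture: int) -> tuple[np.ndarray, np.ndarray]:
    """Separable 1-D kernels of the aperture-k Laplacian.

    The second-derivative kernel is ``[1, -2, 1]`` convolved with a binomial
    smoothing row of length ``aperture - 2``; the cross-direction smoothing
    kernel is the binomial row of length ``aperture``.  Both are
    unnormalized, so response magnitudes grow with aperture (the vein
    thresholds are expressed in this scale).
    """
    _check_odd_kernel("laplacian aperture", aperture)
    if aperture == 3:
        d2 = np.array([1.0, -2.0, 1.0])
    else:
        d2 = np.convolve([1.0, -2.0, 1.0], _pascal_row(aperture - 2))
    return d2, _pascal_row(aperture)


def laplacian(compton: IntensityRaster, params: SegmentationParams) -> np.ndarray:
    """Second-derivative response of the Compton raster (float64).

    Sum of the two directional second derivatives, each estimated with the
    separable extended-difference kernels of :func:`laplacian_kernels`;
    borders are handled by edge replication.  Bright ridges (veins) yield
    strongly negative responses.
    """
    k = params.laplacian_kernel
    img = compton.pixels.astype(np.float64)
    if k > min(img.shape):
        raise ValueError(
            f"laplacian aperture {k} exceeds image extent {img.shape}"
        )
    d2, sm = laplacian_kernels(k)
    dxx = ndimage.convolve1d(
        ndimage.convolve1d(img, d2, axis=1, mode="nearest"), sm, axis=0,
        mode="nearest",
    )
    dyy = ndimage.convolve1d(
        ndimage.convolve1d(img, d2, axis=0, mode="nearest"), sm, axis=1,
        mode="nearest",
    )
    return dxx + dyy


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px, 8-connected skeleton."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return mask.copy()
    return skmorph.skeletonize(mask)


def vein_mask(
    compton: IntensityRaster,
    blade: np.ndarray,
    margin: np.ndarray,
    params: SegmentationParams,
) -> np.ndarray:
    """Vasculature mask from the Compton scatter raster.

    Thick primary/secondary veins: Laplacian response strictly below
    ``vein1_threshold``.  Thin tertiary veins: skeleton of the region
    strictly below ``vein2_threshold``.  The union is intersected with
    blade-minus-margin to exclude detections on the leaf margin.
    """
    lap = laplacian(compton, params)
    vein1 = lap < params.vein1_threshold
    vein2 = skeletonize(lap < params.vein2_threshold)
    interior = np.asarray(blade, bool) & ~np.asarray(margin, bool)
    return (vein1 | vein2) & interior


# ---------------------------------------------------------------------------
# Full segmentation


def segment(
    bundle: ScanBundle, params: SegmentationParams | None = None
) -> SegmentationLabels:
    """Segment a scan bundle into the five classes.

    Deterministic for fixed inputs and parameters.  Margin, vein and tissue
    partition the blade; petiole is the filtered plant-minus-blade residual;
    the rest is background.  A plant whose blade mask is empty (too small
    for the opening kernel) is still processed — everything becomes petiole,
    with a warning.
    """
    if params is None:
        params = SegmentationParams()
    plant = plant_mask(bundle)
    blade = blade_mask(plant, params)
    if plant.any() and not blade.any():
        logger.warning(
            "%s: blade mask is empty; plant is classified entirely as petiole",
            bundle.sample_id,
        )
    petiole = petiole_mask(plant, blade, params)
    margin = margin_mask(blade, params)
    vein = vein_mask(bundle["Compton"], blade, margin, params)
    tissue = blade & ~margin & ~vein

    classes = np.zeros(bundle.shape, dtype=np.uint8)
    classes[petiole] = CLASS_CODES["petiole"]
    classes[margin] = CLASS_CODES["margin"]
    classes[vein] = CLASS_CODES["vein"]
    classes[tissue] = CLASS_CODES["tissue"]
    return SegmentationLabels(classes=classes)
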