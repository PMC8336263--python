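"""Synthetic rosette scans with known geometry and genotype structure.

The generator emulates the study design the pipeline targets: a diversity
panel of accessions (default 86) with a few replicate plants each (default
3), one multi-element scan bundle per plant.  A plant is a rosette of
elliptical leaf blades with thin petiole strips radiating from the centre;
each blade carries a midrib and branching secondary veins, and a 3-px rim
is the margin.  The Compton scatter raster renders veins (and petioles)
bright so the Laplacian ridge detector has signal.

Metal intensities are multiplicative: pixel intensity in substructure *s*
for element *e* is ``base_e × m_{e,s}`` plus Gaussian detector noise, where
the multiplier ``m`` carries an accession-level (genotype) log-effect with
standard deviation ``sigma_g`` and a plant-level (replicate) log-effect
with ``sigma_e``.  Because every latent effect — including the overall
plant-scale effect on geometry — splits its variance the same way, any
locally linear derived trait (CQ, plant size, colocalization r) inherits
the broad-sense heritability

    H² = sigma_g² / (sigma_g² + sigma_e²)

which is recorded in the panel manifest as the ground truth for estimator
checks.  Effects are drawn on the log scale so intensities stay positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import CLASS_CODES, METALS, SUBSTRUCTURES, \
    IntensityRaster, ScanBundle
from .segmentation import SegmentationLabels

logger = logging.getLogger(__name__)


def _default_base_intensity() -> dict[str, float]:
    return {"Zn": 90.0, "K": 110.0, "Ca": 100.0, "Ni": 70.0}


def _default_multipliers() -> dict[str, dict[str, float]]:
    # Mean enrichment per substructure: vasculature accumulates every metal
    # above the plant mean; petioles are metal-rich for the hyperaccumulated
    # Zn/Ni; margins are Ca/K-rich; interveinal tissue sits near or below 1.
    return {
        "Zn": {"petiole": 1.5, "margin": 0.85, "vein": 1.35, "tissue": 0.9},
        "K": {"petiole": 0.9, "margin": 1.2, "vein": 1.15, "tissue": 0.95},
        "Ca": {"petiole": 1.1, "margin": 1.3, "vein": 1.2, "tissue": 0.85},
        "Ni": {"petiole": 1.35, "margin": 0.9, "vein": 1.45, "tissue": 0.9},
    }


@dataclass
class PanelSpec:
    """Study-design and rendering parameters of a synthetic panel."""

    n_accessions: int = 86
    n_reps: int = 3
    image_shape: tuple[int, int] = (208, 208)
    n_leaves: int = 6
    blade_axes: tuple[float, float] = (26.0, 17.0)   # semi-major, semi-minor
    petiole_width: float = 5.0
    petiole_length: float = 56.0   # rosette centre to blade centre
    midrib_width: float = 3.0
    secondary_width: float = 2.0
    margin_width_kernel: int = 7   # rim = blade minus its (k×k) erosion
    base_intensity: dict[str, float] = field(default_factory=_default_base_intensity)
    multipliers: dict[str, dict[str, float]] = field(default_factory=_default_multipliers)
    sigma_g: float = 0.15          # genotype sd of log-multipliers
    sigma_e: float = 0.075         # replicate sd of log-multipliers
    #: sd of per-leaf log-intensity deviations (per element, drawn per
    #: plant).  Emulates leaf-age-driven within-plant heterogeneity: it
    #: barely moves substructure CQs (every substructure spans all leaves)
    #: but dominates the CQ of small random patches, which sample few
    #: leaves — the mechanism behind the random-substructure control.
    sigma_leaf: float = 0.15
    geom_sigma_g: float = 0.05     # genotype sd of log plant scale
    geom_sigma_e: float = 0.025    # replicate sd of log plant scale
    noise_sd: float = 5.0          # per-pixel Gaussian noise, metal rasters
    compton_noise_sd: float = 2.0
    background_level: float = 6.0
    compton_levels: dict[str, float] = field(
        default_factory=lambda: {
            "background": 10.0, "petiole": 170.0, "margin": 120.0,
            "vein": 200.0, "tissue": 120.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_g < 0 or self.sigma_e < 0:
            raise ValueError("sigma_g and sigma_e must be >= 0")
        if self.n_accessions < 1 or self.n_reps < 1:
            raise ValueError("panel must have >= 1 accession and replicate")

    @property
    def true_h2(self) -> float:
        """Heritability implied by the latent-effect variances."""
        total = self.sigma_g**2 + self.sigma_e**2
        return self.sigma_g**2 / total if total > 0 else float("nan")


@dataclass
class SyntheticPlantTruth:
    """Ground truth bookkeeping for one rendered plant."""

    labels: SegmentationLabels
    multipliers: dict[str, dict[str, float]]
    realized_cq: dict[str, dict[str, float]]   # element -> substructure -> CQ
    plant_area: int
    accession_id: str | None = None
    replicate: int | None = None
    scale: float = 1.0

    def mask(self, cls: str) -> np.ndarray:
        return self.labels.mask(cls)


# ---------------------------------------------------------------------------
# Geometry


def generate_geometry(
    spec: PanelSpec,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> dict[str, np.ndarray]:
    """Render the per-class ground-truth masks of one rosette.

    Leaves are filled ellipses around the image centre, each connected to
    the centre by a petiole strip narrower than the segmentation opening
    kernel; the margin is the blade rim (blade minus its erosion, matching
    the segmentation definition of the margin band); veins are a midrib
    plus branching secondary segments clipped to the blade interior;
    interveinal tissue is the remaining blade.  The masks partition the
    plant by construction.
    """
    h, w = spec.image_shape
    a = spec.blade_axes[0] * scale
    b = spec.blade_axes[1] * scale
    d = spec.petiole_length * scale
    if d + a + 4 > min(h, w) / 2:
        raise ValueError(
            f"rosette (radius ~{d + a:.0f}px) does not fit in a {h}x{w} image"
        )
    if 2 * b <= 15 or spec.petiole_width >= 15:
        raise ValueError(
            "geometry incompatible with blade/petiole separation: blades "
            "must be wider and petioles narrower than the opening kernel"
        )
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    blade = np.zeros((h, w), bool)
    petiole_render = np.zeros((h, w), bool)
    vein_render = np.zeros((h, w), bool)
    leaf_id = np.full((h, w), -1, dtype=np.int16)

    base_angles = np.linspace(0.0, 2 * np.pi, spec.n_leaves, endpoint=False)
    jitter = rng.uniform(-0.12, 0.12, size=spec.n_leaves)
    leaf_scales = np.exp(rng.normal(0.0, 0.02, size=spec.n_leaves))

    for il, (theta, ls) in enumerate(zip(base_angles + jitter, leaf_scales)):
        ur, uc = np.cos(theta), np.sin(theta)
        la, lb = a * ls, b * ls
        bc_r, bc_c = cy + d * ls * ur, cx + d * ls * uc
        X = rows - bc_r
        Y = cols - bc_c
        along = X * ur + Y * uc
        across = -X * uc + Y * ur
        ellipse = (along / la) ** 2 + (across / lb) ** 2 <= 1.0
        blade |= ellipse
        leaf_id[ellipse] = il

        # petiole strip from the rosette centre out to the blade centre
        Xc = rows - cy
        Yc = cols - cx
        along_c = Xc * ur + Yc * uc
        across_c = -Xc * uc + Yc * ur
        strip = (
            (along_c >= 0.0)
            & (along_c <= d * ls)
            & (np.abs(across_c) <= spec.petiole_width / 2.0)
        )
        petiole_render |= strip
        leaf_id[strip & ~blade] = il

        # midrib along the major axis
        half_mid = spec.midrib_width / 2.0
        vein_render |= (
            ellipse
            & (np.abs(across) <= half_mid)
            & (np.abs(along) <= 0.92 * la)
        )
        # secondary veins branching from the midrib towards the rim
        half_sec = spec.secondary_width / 2.0
        m_slope = 0.9
        for t in (-0.55, -0.15, 0.25, 0.6):
            t_along = t * la
            for sign in (1.0, -1.0):
                line = np.abs(sign * across - m_slope * (along - t_along))
                branch = (
                    ellipse
                    & (line <= half_sec)
                    & (sign * across >= 0.0)
                    & (sign * across <= 0.75 * lb)
                )
                vein_render |= branch

    k = spec.margin_width_kernel
    eroded = ndimage.binary_erosion(blade, structure=np.ones((k, k), bool),
                                    border_value=1)
    margin = blade & ~eroded
    vein = vein_render & eroded
    tissue = eroded & ~vein
    petiole = petiole_render & ~blade
    plant = blade | petiole

    leaf_id[~plant] = -1
    return {
        "plant": plant,
        "blade": blade,
        "petiole": petiole,
        "margin": margin,
        "vein": vein,
        "tissue": tissue,
        "leaf_id": leaf_id,
    }


def geometry_labels(geometry: dict[str, np.ndarray]) -> SegmentationLabels:
    """Pack ground-truth masks into a label map."""
    classes = np.zeros(geometry["plant"].shape, dtype=np.uint8)
    for s in SUBSTRUCTURES:
        classes[geometry[s]] = CLASS_CODES[s]
    return SegmentationLabels(classes=classes)


# ---------------------------------------------------------------------------
# Rendering


def render_bundle(
    geometry: dict[str, np.ndarray],
    multipliers: dict[str, dict[str, float]],
    spec: PanelSpec,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
    accession_id: str | None = None,
    replicate: int | None = None,
    scale: float = 1.0,
) -> tuple[ScanBundle, SyntheticPlantTruth]:
    """Render a scan bundle from ground-truth masks and realized multipliers.

    Each metal raster is ``base × multiplier`` per substructure plus
    Gaussian pixel noise, clipped to the 8-bit range (with a warning when a
    substructure mean leaves the dynamic range, since clipping biases CQ).
    The Compton raster uses fixed bright-vein levels.  The returned truth
    records the realized noiseless CQ of every metal × substructure.
    """
    labels = geometry_labels(geometry)
    plant = labels.plant
    h, w = labels.shape

    leaf_id = geometry.get("leaf_id")
    n_leaves = int(leaf_id.max()) + 1 if leaf_id is not None else 0

    rasters: dict[str, IntensityRaster] = {}
    realized_cq: dict[str, dict[str, float]] = {}
    for el in METALS:
        base = spec.base_intensity[el]
        clean = np.full((h, w), spec.background_level, dtype=np.float64)
        for s in SUBSTRUCTURES:
            level = base * multipliers[el][s]
            if level > 250.0 or level < 2.0 * spec.background_level:
                logger.warning(
                    "%s %s mean %.1f near dynamic-range limit; clipping "
                    "will bias CQ", el, s, level,
                )
            clean[geometry[s]] = level
        if n_leaves > 0 and spec.sigma_leaf > 0:
            # per-leaf within-plant heterogeneity (leaf age, position)
            eff = np.exp(rng.normal(0.0, spec.sigma_leaf, size=n_leaves))
            on_leaf = leaf_id >= 0
            clean[on_leaf] *= eff[leaf_id[on_leaf]]
        plant_mean = clean[plant].mean()
        realized_cq[el] = {
            s: float(clean[geometry[s]].mean() / plant_mean)
            if geometry[s].any() else float("nan")
            for s in SUBSTRUCTURES
        }
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=(h, w))
        rasters[el] = IntensityRaster(
            np.clip(np.rint(noisy), 0, 255).astype(np.uint8), el
        )

    compton = np.full((h, w), spec.compton_levels["background"], np.float64)
    for s in SUBSTRUCTURES:
        compton[geometry[s]] = spec.compton_levels[s]
    compton += rng.normal(0.0, spec.compton_noise_sd, size=(h, w))
    rasters["Compton"] = IntensityRaster(
        np.clip(np.rint(compton), 0, 255).astype(np.uint8), "Compton"
    )

    bundle = ScanBundle(
        rasters=rasters,
        sample_id=sample_id,
        accession_id=accession_id,
        replicate=replicate,
    )
    truth = SyntheticPlantTruth(
        labels=labels,
        multipliers=multipliers,
        realized_cq=realized_cq,
        plant_area=int(plant.sum()),
        accession_id=accession_id,
        replicate=replicate,
        scale=scale,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Panels


def generate_panel(
    spec: PanelSpec | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[ScanBundle, SyntheticPlantTruth]], pd.DataFrame]:
    """Generate a full accession × replicate panel.

    Accession-level log-effects (one per metal × substructure, plus one
    plant-scale effect) are drawn once per accession with sd ``sigma_g``;
    replicate-level deviations are drawn per plant with sd ``sigma_e``.
    Returns the plants and a manifest recording ids, the seed, the realized
    plant scale and the implied true H² per CQ trait.
    """
    if spec is None:
        spec = PanelSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    plants: list[tuple[ScanBundle, SyntheticPlantTruth]] = []
    manifest_rows = []
    n_digits = max(3, len(str(spec.n_accessions)))
    # largest plant scale the canvas can hold; extreme log-normal draws are
    # clamped here (≳3 sd out) rather than failing the whole panel
    max_scale = (min(spec.image_shape) / 2.0 - 5.0) / (
        spec.petiole_length + spec.blade_axes[0]
    )
    for ia in range(spec.n_accessions):
        accession = f"acc{ia + 1:0{n_digits}d}"
        g_geom = rng.normal(0.0, spec.geom_sigma_g)
        g_conc = {
            el: {s: rng.normal(0.0, spec.sigma_g) for s in SUBSTRUCTURES}
            for el in METALS
        }
        for rep in range(1, spec.n_reps + 1):
            e_geom = rng.normal(0.0, spec.geom_sigma_e)
            scale = float(np.exp(g_geom + e_geom))
            if scale > max_scale:
                logger.warning(
                    "clamping plant scale %.3f to %.3f for %s", scale,
                    max_scale, accession,
                )
                scale = max_scale
            mult = {
                el: {
                    s: spec.multipliers[el][s]
                    * float(np.exp(g_conc[el][s] + rng.normal(0.0, spec.sigma_e)))
                    for s in SUBSTRUCTURES
                }
                for el in METALS
            }
            sample_id = f"{accession}_r{rep}"
            geometry = generate_geometry(spec, rng, scale=scale)
            bundle, truth = render_bundle(
                geometry, mult, spec, rng,
                sample_id=sample_id, accession_id=accession,
                replicate=rep, scale=scale,
            )
            plants.append((bundle, truth))
            manifest_rows.append(
                {
                    "sample_id": sample_id,
                    "accession_id": accession,
                    "replicate": rep,
                    "scale": scale,
                    "plant_area": truth.plant_area,
                    "true_H2": spec.true_h2,
                    "seed": seed,
                }
            )
    return plants, pd.DataFrame(manifest_rows)
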