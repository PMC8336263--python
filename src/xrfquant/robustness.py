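"""Validation machinery: random substructures, label noise, parameter sweeps.

Three negative/robustness controls accompany the CQ-heritability pipeline:

* **Random substructures** — square patches placed at random on the plant
  surface stand in for a biologically meaningless substructure; their CQ
  should show near-zero heritability on a genotype-structured panel.
* **Label-noise injection** — a fraction of plant pixels is reassigned a
  uniformly random substructure class; CQ heritability should be nearly
  unchanged at moderate noise, because CQ averages over many pixels.
* **Sensitivity sweep** — segmentation quality (per-class precision /
  recall / F1 against a fixed set of ground-truth pixels) as a function of
  each of the four main segmentation parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CLASS_CODES, GroundTruthSample, ScanBundle, SUBSTRUCTURES
from .quantification import evaluate_predictions, plant_traits
from .segmentation import SegmentationLabels, SegmentationParams, segment
from .heritability import heritability_report

logger = logging.getLogger(__name__)

_SUB_CODES = np.array([CLASS_CODES[s] for s in SUBSTRUCTURES])


@dataclass(frozen=True)
class RandomSubstructureParams:
    """Random-substructure generator settings (5 squares of 30×30 px)."""

    n_squares: int = 5
    square_side: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_squares < 1:
            raise ValueError("n_squares must be >= 1")
        if self.square_side < 1:
            raise ValueError("square_side must be >= 1")


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter grid for the sensitivity sweep."""

    parameter: str
    values: tuple = ()

    _ALLOWED = (
        "opening_kernel",
        "laplacian_kernel",
        "vein1_threshold",
        "vein2_threshold",
    )

    def __post_init__(self) -> None:
        if self.parameter not in self._ALLOWED:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"expected one of {self._ALLOWED}"
            )
        object.__setattr__(self, "values", tuple(self.values))
        if not self.values:
            raise ValueError("sweep grid is empty")


def default_sweeps() -> dict[str, SweepSpec]:
    """The four default grids: two steps below to two steps above the
    default parameter values."""
    return {
        "opening_kernel": SweepSpec("opening_kernel", (7, 11, 15, 19, 23)),
        "laplacian_kernel": SweepSpec("laplacian_kernel", (3, 5, 7, 9, 11)),
        "vein1_threshold": SweepSpec(
            "vein1_threshold", (-3500.0, -3000.0, -2500.0, -2000.0, -1500.0)
        ),
        "vein2_threshold": SweepSpec(
            "vein2_threshold", (-200.0, -100.0, 0.0, 100.0, 200.0)
        ),
    }


def random_substructure(
    plant: np.ndarray,
    params: RandomSubstructureParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Union of random square patches, cropped to the plant mask.

    Square centres are drawn uniformly from plant-foreground pixels (which
    guarantees every square overlaps the plant); parts of a square falling
    on the background are cropped away, so the result is contained in the
    plant mask and has area at most ``n_squares * square_side**2``.
    """
    if params is None:
        params = RandomSubstructureParams()
    plant = np.asarray(plant, bool)
    if not plant.any():
        raise ValueError("plant mask is empty")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = plant.shape
    side = params.square_side
    if plant.sum() < side * side:
        logger.warning(
            "plant (%d px) smaller than one %dx%d square; "
            "result is whatever intersects", int(plant.sum()), side, side,
        )
    rows, cols = np.nonzero(plant)
    pick = rng.integers(0, rows.size, size=params.n_squares)
    half = side // 2
    out = np.zeros_like(plant)
    for i in pick:
        r0 = max(int(rows[i]) - half, 0)
        c0 = max(int(cols[i]) - half, 0)
        out[r0:r0 + side, c0:c0 + side] = True
    return out & plant


def inject_label_noise(
    labels: SegmentationLabels,
    fraction: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SegmentationLabels:
    """Reassign a random fraction of plant pixels to a random class.

    Exactly ``ceil(fraction * N_plant)`` non-background pixels are drawn
    without replacement and assigned a class uniform over the four
    substructures — the draw may repeat the original class, so the expected
    effective corruption rate is ``0.75 * fraction``.  Background pixels are
    never touched.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    out = labels.copy()
    if fraction == 0.0:
        return out
    if rng is None:
        rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(labels.plant)
    n_plant = rows.size
    if n_plant == 0:
        return out
    n_noise = math.ceil(fraction * n_plant)
    idx = rng.choice(n_plant, size=n_noise, replace=False)
    new_classes = rng.choice(_SUB_CODES, size=n_noise)
    out.classes[rows[idx], cols[idx]] = new_classes
    return out


def sensitivity_sweep(
    bundle: ScanBundle,
    truth: GroundTruthSample,
    spec: SweepSpec,
    base_params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Per-class segmentation quality along a one-parameter grid.

    The ground-truth pixel coordinates (and their true classes) stay fixed;
    for every grid value the bundle is re-segmented and the predictions at
    those coordinates are re-derived and scored.  The row at the base
    parameter value is flagged with ``is_base`` (the plotting convention of
    marking the production value with an asterisk).
    """
    if base_params is None:
        base_params = SegmentationParams()
    if not truth.is_labelled:
        raise ValueError("truth sample must have all true classes filled in")
    records = []
    base_value = getattr(base_params, spec.parameter)
    for value in spec.values:
        params = base_params.with_(**{spec.parameter: value})
        labels = segment(bundle, params)
        scores = evaluate_predictions(labels, truth)
        for cls, row in scores.iterrows():
            if np.isnan(row["f1"]) and np.isnan(row["precision"]):
                logger.warning(
                    "%s=%s: class %s degenerate, metrics missing",
                    spec.parameter, value, cls,
                )
            records.append(
                {
                    "parameter": spec.parameter,
                    "value": value,
                    "is_base": value == base_value,
                    "class": cls,
                    "precision": row["precision"],
                    "recall": row["recall"],
                    "f1": row["f1"],
                }
            )
    return pd.DataFrame(records)


def noise_robustness_curve(
    plants: Sequence[tuple[ScanBundle, SegmentationLabels]],
    fractions: Sequence[float],
    seed: int | None = None,
) -> pd.DataFrame:
    """H² of every CQ trait as a function of the label-noise fraction.

    For each fraction, every plant's labels are noise-injected (with a
    per-plant child seed derived from ``seed``, so the curve is reproducible
    and fractions are independent draws), CQ traits are re-derived, and the
    heritability report is recomputed.  Returns a long table
    ``(fraction, trait, H2, var_G, var_e)``.
    """
    root = np.random.default_rng(seed)
    out = []
    for fraction in fractions:
        rng = np.random.default_rng(root.integers(2**31))
        rows = []
        for bundle, labels in plants:
            noisy = inject_label_noise(labels, fraction, rng=rng)
            rows.append(plant_traits(bundle, noisy))
        table = pd.DataFrame(rows)
        cq_cols = [c for c in table.columns if c.startswith("CQ_")]
        report = heritability_report(table, trait_columns=cq_cols)
        for _, r in report.iterrows():
            out.append(
                {
                    "fraction": fraction,
                    "trait": r["trait"],
                    "H2": r["H2"],
                    "var_G": r["var_G"],
                    "var_e": r["var_e"],
                }
            )
    return pd.DataFrame(out)
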