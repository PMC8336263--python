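"""Concentration quotients, per-plant traits, colocalization and
segmentation-quality metrics.

The concentration quotient (CQ) of a substructure is the mean intensity
over the substructure's pixels divided by the mean over the whole plant
foreground:

    CQ_s = mean(P | A_s) / mean(P | A_p)

CQ is dimensionless, equals 1 when the substructure mean matches the plant
mean, and is invariant under global rescaling of the raster — which is what
makes it comparable across plants whose absolute count rates differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    GroundTruthSample,
    IntensityRaster,
    METALS,
    SUBSTRUCTURES,
    ScanBundle,
)
from .segmentation import SegmentationLabels

logger = logging.getLogger(__name__)

#: Metal pairs for pixel colocalization, in reporting order.
METAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("Zn", "K"), ("Zn", "Ca"), ("Zn", "Ni"),
    ("K", "Ca"), ("K", "Ni"), ("Ca", "Ni"),
)


@dataclass
class ConfusionMatrix:
    """4×4 confusion matrix; rows are ground-truth classes, columns are
    predicted classes, in the order (petiole, margin, vein, tissue)."""

    counts: np.ndarray
    classes: tuple[str, ...] = field(default=SUBSTRUCTURES)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected {n}×{n} counts, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion-matrix counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(sums > 0, self.counts / sums, np.nan)


# ---------------------------------------------------------------------------
# Concentration quotient and per-plant traits


def concentration_quotient(
    raster: IntensityRaster | np.ndarray,
    substructure: np.ndarray,
    plant: np.ndarray,
) -> float:
    """Mean intensity over the substructure divided by the plant mean.

    Returns NaN (a flagged missing value, never 0) for an empty
    substructure; raises for an empty plant or zero plant mean, where the
    quotient is undefined.
    """
    pixels = np.asarray(getattr(raster, "pixels", raster), dtype=np.float64)
    substructure = np.asarray(substructure, bool)
    plant = np.asarray(plant, bool)
    if substructure.shape != pixels.shape or plant.shape != pixels.shape:
        raise ValueError("masks must match the raster shape")
    if np.any(substructure & ~plant):
        raise ValueError("substructure mask must be a subset of the plant mask")
    if not plant.any():
        raise ValueError("plant mask is empty; CQ undefined")
    plant_mean = pixels[plant].mean()
    if plant_mean == 0:
        raise ValueError("plant mean intensity is zero; CQ undefined")
    if not substructure.any():
        logger.warning("empty substructure: CQ is a missing value")
        return float("nan")
    return float(pixels[substructure].mean() / plant_mean)


def colocalization(
    raster_a: IntensityRaster | np.ndarray,
    raster_b: IntensityRaster | np.ndarray,
    plant: np.ndarray,
) -> float:
    """Pearson correlation of two rasters over the plant-foreground pixels.

    NaN when either raster has zero variance over the plant (undefined).
    """
    a = np.asarray(getattr(raster_a, "pixels", raster_a), np.float64)
    b = np.asarray(getattr(raster_b, "pixels", raster_b), np.float64)
    plant = np.asarray(plant, bool)
    x = a[plant]
    y = b[plant]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        logger.warning("zero variance or too few pixels: colocalization undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def zscore_substructure_means(
    raster: IntensityRaster | np.ndarray,
    labels: SegmentationLabels,
    plant: np.ndarray | None = None,
) -> dict[str, float]:
    """Z-score of each substructure's mean intensity, normalized by the
    plant-foreground mean and standard deviation:

        z_s = (mean_s − mean_plant) / sd_plant

    All values NaN when the plant sd is zero.
    """
    pixels = np.asarray(getattr(raster, "pixels", raster), np.float64)
    if plant is None:
        plant = labels.plant
    plant = np.asarray(plant, bool)
    vals = pixels[plant]
    if vals.size == 0 or vals.std() == 0:
        logger.warning("zero plant sd: z-scores undefined")
        return {s: float("nan") for s in SUBSTRUCTURES}
    mean_p = vals.mean()
    sd_p = vals.std()
    out = {}
    for s in SUBSTRUCTURES:
        mask = labels.mask(s)
        out[s] = float((pixels[mask].mean() - mean_p) / sd_p) if mask.any() else float("nan")
    return out


def plant_traits(
    bundle: ScanBundle, labels: SegmentationLabels
) -> pd.Series:
    """Assemble the trait row of one plant.

    Traits: plant size (foreground pixel count); per-metal plant mean
    intensity; CQ for each metal × substructure (16 traits); relative
    substructure sizes; pairwise metal colocalization r.  The plant
    foreground used as CQ denominator is the set of classified
    (non-background) pixels, so the pixel-count-weighted mean of the four
    substructure CQs is exactly 1.
    """
    if labels.shape != bundle.shape:
        raise ValueError("labels do not match bundle dimensions")
    plant = labels.plant
    row: dict[str, float | str | None] = {
        "sample_id": bundle.sample_id,
        "accession_id": bundle.accession_id,
        "replicate": bundle.replicate,
    }
    n_plant = int(plant.sum())
    row["plant_size"] = n_plant
    if n_plant == 0:
        logger.warning("%s: all-background labels, traits are missing",
                       bundle.sample_id)
        for el in METALS:
            row[f"mean_{el}"] = np.nan
            for s in SUBSTRUCTURES:
                row[f"CQ_{el}_{s}"] = np.nan
        for s in SUBSTRUCTURES:
            row[f"relsize_{s}"] = np.nan
        for a, b in METAL_PAIRS:
            row[f"r_{a}_{b}"] = np.nan
        return pd.Series(row)

    for s in SUBSTRUCTURES:
        row[f"relsize_{s}"] = float(labels.mask(s).sum() / n_plant)
    for el in METALS:
        pixels = bundle[el].pixels.astype(np.float64)
        row[f"mean_{el}"] = float(pixels[plant].mean())
        for s in SUBSTRUCTURES:
            mask = labels.mask(s)
            if mask.any():
                row[f"CQ_{el}_{s}"] = concentration_quotient(pixels, mask, plant)
            else:
                logger.warning("%s: empty %s, CQ_%s_%s missing",
                               bundle.sample_id, s, el, s)
                row[f"CQ_{el}_{s}"] = np.nan
    for a, b in METAL_PAIRS:
        row[f"r_{a}_{b}"] = colocalization(bundle[a], bundle[b], plant)
    return pd.Series(row)


# ---------------------------------------------------------------------------
# Segmentation evaluation


def sample_ground_truth_pixels(
    labels: SegmentationLabels,
    n_per_class: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruthSample:
    """Sample predicted pixels for blind manual evaluation.

    For each substructure class, ``n_per_class`` pixels are drawn uniformly
    without replacement from that class's predicted pixels (all of them,
    with a warning, if fewer exist).  The output record order is shuffled so
    an annotator cannot infer the predicted class from position; the
    ``true_class`` column is left blank.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    records = []
    for s in SUBSTRUCTURES:
        rows, cols = np.nonzero(labels.mask(s))
        n_avail = rows.size
        if n_avail == 0:
            logger.warning("class %s has no predicted pixels; skipped", s)
            continue
        n_take = min(n_per_class, n_avail)
        if n_take < n_per_class:
            logger.warning(
                "class %s has only %d predicted pixels (< %d); taking all",
                s, n_avail, n_per_class,
            )
        idx = rng.choice(n_avail, size=n_take, replace=False)
        for i in idx:
            records.append((int(rows[i]), int(cols[i]), s, None))
    order = rng.permutation(len(records))
    frame = pd.DataFrame(
        [records[i] for i in order],
        columns=["row", "col", "predicted_class", "true_class"],
    )
    return GroundTruthSample(frame=frame)


def confusion_matrix(sample: GroundTruthSample) -> ConfusionMatrix:
    """Count records by (true class, predicted class).

    All ``true_class`` entries must be filled in.
    """
    frame = sample.frame
    blank = frame["true_class"].isna()
    if blank.any():
        raise ValueError(
            f"{int(blank.sum())} record(s) have no true class: "
            f"rows {frame.index[blank].tolist()[:10]}"
        )
    index = {s: i for i, s in enumerate(SUBSTRUCTURES)}
    counts = np.zeros((4, 4), dtype=np.int64)
    for t, p in zip(frame["true_class"], frame["predicted_class"]):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts)


def precision_recall_f1(matrix: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision, recall and F1.

    precision_i = M_ii / column-sum_i, recall_i = M_ii / row-sum_i,
    F1 the harmonic mean of the two; zero denominators give NaN.
    """
    counts = matrix.counts.astype(np.float64)
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    rowsum = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, np.nan)
        recall = np.where(rowsum > 0, diag / rowsum, np.nan)
        f1 = np.where(
            (precision + recall) > 0,
            2 * precision * recall / (precision + recall),
            np.nan,
        )
    return pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1},
        index=list(matrix.classes),
    )


def evaluate_predictions(
    labels: SegmentationLabels, truth: GroundTruthSample
) -> pd.DataFrame:
    """Re-derive predictions at the truth sample's coordinates from a label
    map and score them against the (filled-in) true classes.

    Used by the sensitivity sweep, where ground-truth coordinates stay fixed
    while segmentation parameters change.  Coordinates whose new prediction
    is background are dropped (no substructure class to score).
    """
    frame = truth.frame.copy()
    from .io_formats import CODE_TO_CLASS

    preds = [
        CODE_TO_CLASS[int(labels.classes[r, c])]
        for r, c in zip(frame["row"], frame["col"])
    ]
    frame["predicted_class"] = preds
    frame = frame[frame["predicted_class"] != "background"]
    sample = GroundTruthSample(frame=frame.reset_index(drop=True))
    return precision_recall_f1(confusion_matrix(sample))
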