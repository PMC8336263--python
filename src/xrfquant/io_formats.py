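"""Reading and writing rasters, label maps, ground truth and trait tables.

µXRF instruments export one greyscale intensity raster per element (sum of
counts at the element's K-line) plus a Compton scatter raster; the standard
interchange format is single-channel 8-bit TIFF.  All rasters of one scan are
co-registered, so a plant is represented as a :class:`ScanBundle` of five
co-sized rasters (Zn, K, Ca, Ni, Compton).

Pixel coordinates are ``(row, col)``, 0-based, row-major, shared by rasters,
masks and label maps throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Elements of a scan bundle.  "Compton" is the scatter channel used for
#: vein detection; the four metals are the quantified channels.
ELEMENTS: tuple[str, ...] = ("Zn", "K", "Ca", "Ni", "Compton")
METALS: tuple[str, ...] = ("Zn", "K", "Ca", "Ni")

#: Integer encoding of segmentation classes in label TIFFs.
CLASS_CODES: dict[str, int] = {
    "background": 0,
    "petiole": 1,
    "margin": 2,
    "vein": 3,
    "tissue": 4,
}
SUBSTRUCTURES: tuple[str, ...] = ("petiole", "margin", "vein", "tissue")
CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}

#: 8-connectivity structuring element for connected-component labelling.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


class FormatError(ValueError):
    """Raised when a file does not conform to the expected format."""


@dataclass
class IntensityRaster:
    """One element's 2-D intensity map (a concentration proxy).

    Values are non-negative; integer 0–255 as read from 8-bit TIFF, real
    valued after derived computations.
    """

    pixels: np.ndarray
    element: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"raster must be 2-D, got {self.pixels.ndim} dimensions"
            )
        if self.pixels.size == 0:
            raise FormatError("raster has zero size")
        if np.any(self.pixels < 0):
            raise FormatError("raster contains negative intensities")
        if self.element not in ELEMENTS:
            raise FormatError(
                f"unknown element {self.element!r}; expected one of {ELEMENTS}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ScanBundle:
    """Co-registered rasters for Zn, K, Ca, Ni and Compton scatter."""

    rasters: dict[str, IntensityRaster]
    sample_id: str
    accession_id: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        missing = [e for e in ELEMENTS if e not in self.rasters]
        if missing:
            raise FormatError(f"bundle is missing element(s): {missing}")
        extra = [e for e in self.rasters if e not in ELEMENTS]
        if extra:
            raise FormatError(f"bundle has unknown element(s): {extra}")
        shapes = {e: r.shape for e, r in self.rasters.items()}
        ref = shapes[ELEMENTS[0]]
        for e, s in shapes.items():
            if s != ref:
                raise FormatError(
                    f"dimension mismatch: {ELEMENTS[0]} is {ref} but {e} is {s}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.rasters[ELEMENTS[0]].shape

    def __getitem__(self, element: str) -> IntensityRaster:
        return self.rasters[element]


@dataclass
class GroundTruthSample:
    """Pixel sample for manual evaluation of a segmentation.

    ``frame`` has columns ``row, col, predicted_class, true_class``;
    ``true_class`` is empty until an annotator fills it in.  Record order is
    randomized at sampling time so the annotator is blind to the predicted
    class.
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["row", "col", "predicted_class", "true_class"]
        )
    )

    def __post_init__(self) -> None:
        required = ["row", "col", "predicted_class", "true_class"]
        for col in required:
            if col not in self.frame.columns:
                raise FormatError(f"ground-truth table missing column {col!r}")
        for col in ("predicted_class", "true_class"):
            vals = self.frame[col].dropna()
            bad = set(vals) - set(SUBSTRUCTURES)
            if bad:
                raise FormatError(f"invalid class label(s) in {col}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def is_labelled(self) -> bool:
        return bool(len(self.frame)) and self.frame["true_class"].notna().all()


# ---------------------------------------------------------------------------
# Raster I/O


def _check_single_channel(arr: np.ndarray, path: Path | str) -> np.ndarray:
    if arr.ndim == 3:
        raise FormatError(
            f"{path}: expected single-channel greyscale TIFF, "
            f"got {arr.shape[-1]} channels"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2-D image, got {arr.ndim}-D")
    return arr


def read_raster(path: str | Path, element: str) -> IntensityRaster:
    """Read a single-channel greyscale TIFF as an :class:`IntensityRaster`.

    8-bit files are the instrument export default; 16-bit files are accepted
    and used as-is, without rescaling.  No normalization is applied.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-TIFF
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    arr = _check_single_channel(np.asarray(arr), path)
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(
            f"{path}: expected 8-bit or 16-bit greyscale TIFF, got {arr.dtype}"
        )
    return IntensityRaster(pixels=arr, element=element)


def write_raster(raster: IntensityRaster, path: str | Path) -> None:
    """Write a raster as a single-channel TIFF (dtype preserved)."""
    arr = raster.pixels
    if arr.dtype not in (np.uint8, np.uint16):
        if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise FormatError(
                "only 8/16-bit integer rasters can be written; "
                f"got dtype {arr.dtype}"
            )
    tifffile.imwrite(Path(path), arr)


def load_bundle(
    paths: Mapping[str, str | Path],
    sample_id: str,
    accession_id: str | None = None,
    replicate: int | None = None,
) -> ScanBundle:
    """Load and validate the five element rasters of one scan."""
    missing = [e for e in ELEMENTS if e not in paths]
    if missing:
        raise FormatError(f"bundle is missing element(s): {missing}")
    rasters = {e: read_raster(paths[e], e) for e in ELEMENTS}
    return ScanBundle(
        rasters=rasters,
        sample_id=sample_id,
        accession_id=accession_id,
        replicate=replicate,
    )


def split_plants(
    bundle: ScanBundle,
    plant_mask: np.ndarray,
    pad: int = 5,
    min_area: int = 25,
) -> list[ScanBundle]:
    """Split a multi-plant batch scan into per-plant bundles.

    Plant instances are the 8-connected components of ``plant_mask`` (leaves
    of one rosette frequently touch diagonally).  Each instance is cropped to
    its bounding box padded by ``pad`` pixels (clipped to the image).
    Components smaller than ``min_area`` pixels are dropped with a warning.
    """
    plant_mask = np.asarray(plant_mask, bool)
    if plant_mask.shape != bundle.shape:
        raise FormatError(
            f"mask shape {plant_mask.shape} does not match bundle {bundle.shape}"
        )
    lab, n = ndimage.label(plant_mask, structure=STRUCTURE_8)
    if n == 0:
        return []
    slices = ndimage.find_objects(lab)
    areas = np.bincount(lab.ravel())[1:]
    out: list[ScanBundle] = []
    h, w = bundle.shape
    kept = 0
    for i, (sl, area) in enumerate(zip(slices, areas), start=1):
        if area < min_area:
            logger.warning(
                "dropping component %d of %s: area %d < min_area %d",
                i, bundle.sample_id, area, min_area,
            )
            continue
        kept += 1
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, h)
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, w)
        rasters = {
            e: IntensityRaster(bundle[e].pixels[r0:r1, c0:c1].copy(), e)
            for e in ELEMENTS
        }
        out.append(
            ScanBundle(
                rasters=rasters,
                sample_id=f"{bundle.sample_id}_p{kept}",
                accession_id=bundle.accession_id,
                replicate=bundle.replicate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Label map I/O


def write_labels(labels, path: str | Path) -> None:
    """Write a label map as a single-channel 8-bit TIFF.

    Class encoding: background=0, petiole=1, margin=2, vein=3, tissue=4.
    """
    arr = np.asarray(getattr(labels, "classes", labels))
    if arr.ndim != 2:
        raise FormatError(f"labels must be 2-D, got {arr.ndim}-D")
    bad = set(np.unique(arr)) - set(CLASS_CODES.values())
    if bad:
        raise FormatError(f"unknown class code(s): {sorted(bad)}")
    tifffile.imwrite(Path(path), arr.astype(np.uint8))


def read_labels(path: str | Path):
    """Read a label TIFF written by :func:`write_labels` (exact inverse)."""
    from .segmentation import SegmentationLabels  # local import: avoid cycle

    arr = _check_single_channel(np.asarray(tifffile.imread(Path(path))), path)
    bad = set(np.unique(arr)) - set(CLASS_CODES.values())
    if bad:
        raise FormatError(f"{path}: unknown class code(s): {sorted(bad)}")
    return SegmentationLabels(classes=arr.astype(np.uint8))


# ---------------------------------------------------------------------------
# Tables


def write_ground_truth(sample: GroundTruthSample, path: str | Path) -> None:
    sample.frame.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> GroundTruthSample:
    frame = pd.read_csv(path)
    return GroundTruthSample(frame=frame)


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a plants × traits table (CSV with header row)."""
    table.to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "accession_id" not in table.columns:
        raise FormatError("trait table must have an 'accession_id' column")
    return table


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a bundle manifest CSV.

    Columns: ``sample_id, accession_id, replicate, Zn, K, Ca, Ni, Compton``
    where the element columns hold raster paths (relative paths are resolved
    against the manifest's directory).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = ["sample_id", *ELEMENTS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"manifest missing column(s): {missing}")
    base = path.parent
    for e in ELEMENTS:
        frame[e] = [str((base / p)) if not Path(p).is_absolute() else str(p)
                    for p in frame[e]]
    return frame


def load_bundles_from_manifest(path: str | Path) -> list[ScanBundle]:
    frame = read_manifest(path)
    bundles = []
    for _, row in frame.iterrows():
        bundles.append(
            load_bundle(
                {e: row[e] for e in ELEMENTS},
                sample_id=str(row["sample_id"]),
                accession_id=(str(row["accession_id"])
                              if "accession_id" in row and pd.notna(row["accession_id"])
                              else None),
                replicate=(int(row["replicate"])
                           if "replicate" in row and pd.notna(row["replicate"])
                           else None),
            )
        )
    return bundles
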