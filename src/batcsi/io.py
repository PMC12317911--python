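"""Readers and writers for slice matrices, masks and cohort tables.

Supported slice formats: headerless CSV matrices, 16-bit grayscale
PNG/TIFF, and single-frame DICOM (optional, requires ``pydicom``).
Masks: 8-bit PNG (nonzero = in ROI) or CSV.  Values are clipped to the
12-bit range on read, with the clip count logged.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MAX_RAW_LEVEL, Channel, RawImageMatrix, RoiMask, make_roi_mask
from .phantom import PatientRecord

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".dicom"}

CLINICAL_COLUMNS = ["patient_id", "risk_group", "ipsa_ng_ml"]
MANIFEST_COLUMNS = ["patient_id", "slice_index", "water_path", "fat_path", "mask_path"]


# ---------------------------------------------------------------------------
# Low-level grid readers
# ---------------------------------------------------------------------------


def _read_csv_grid(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            try:
                rows.append([float(x) for x in row])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric entry in row {i}") from exc
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row {i} (expected {len(rows[0])} columns, "
                    f"got {len(rows[-1])})"
                )
    if not rows:
        raise ValueError(f"{path}: empty CSV matrix")
    return np.asarray(rows)


def _read_grid(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _read_csv_grid(path)
    if suffix in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse accidental RGB
            arr = arr[..., 0]
        return arr.astype(float)
    if suffix in _DICOM_SUFFIXES:
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                f"{path}: reading DICOM requires the optional 'pydicom' "
                "dependency (pip install batcsi[dicom])"
            ) from exc
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept
    raise ValueError(f"{path}: unsupported format {suffix!r}")


# ---------------------------------------------------------------------------
# Public readers
# ---------------------------------------------------------------------------


def read_image_matrix(path: str | Path, expected_channel: Channel) -> RawImageMatrix:
    """Read a water- or fat-channel slice and clip it to the 12-bit range."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"slice file not found: {path}")
    grid = _read_grid(path)
    if path.suffix.lower() == ".csv" and grid.min() < 0:
        raise ValueError(f"{path}: negative intensity values in CSV matrix")
    n_clipped = int(np.count_nonzero((grid < 0) | (grid > MAX_RAW_LEVEL)))
    if n_clipped:
        logger.warning("%s: clipped %d values to [0, %d]", path, n_clipped, MAX_RAW_LEVEL)
        grid = np.clip(grid, 0, MAX_RAW_LEVEL)
    return RawImageMatrix(np.rint(grid).astype(np.int32), expected_channel)


def read_mask(path: str | Path) -> RoiMask:
    """Read a binary ROI mask (nonzero = in ROI) and trace its contours.

    Multiple connected components are accepted with a warning; contours
    are traced over the union.
    """
    from scipy import ndimage

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    grid = _read_grid(path)
    in_roi = grid != 0
    if not in_roi.any():
        raise ValueError(f"{path}: mask is empty (no in-ROI pixels)")
    _, n_components = ndimage.label(in_roi)
    if n_components > 1:
        logger.warning(
            "%s: mask has %d connected components; contours traced per component",
            path,
            n_components,
        )
    return make_roi_mask(in_roi)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def load_cohort(
    manifest_path: str | Path, clinical_path: str | Path
) -> tuple[list[PatientRecord], dict[str, str]]:
    """Assemble patient records from a slice manifest and a clinical table.

    Returns (records, failures) where ``failures`` maps patient ids to
    error messages; patients that fail to load are excluded rather than
    aborting the whole cohort.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    clinical = read_clinical_table(clinical_path).set_index("patient_id")
    base = manifest_path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    records: list[PatientRecord] = []
    failures: dict[str, str] = {}
    for pid, rows in manifest.groupby("patient_id", sort=False):
        try:
            if pid not in clinical.index:
                raise KeyError(f"patient {pid!r} missing from clinical table")
            info = clinical.loc[pid]
            slices = []
            for _, row in rows.sort_values("slice_index").iterrows():
                water = read_image_matrix(_resolve(row["water_path"]), "water")
                fat = read_image_matrix(_resolve(row["fat_path"]), "fat")
                mask = read_mask(_resolve(row["mask_path"]))
                slices.append((water, fat, mask))
            records.append(
                PatientRecord(
                    patient_id=str(pid),
                    risk_group=str(info["risk_group"]),
                    ipsa=float(info["ipsa_ng_ml"]),
                    slices=slices,
                )
            )
        except Exception as exc:
            logger.error("patient %s failed to load: %s", pid, exc)
            failures[str(pid)] = str(exc)
    return records, failures


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_image_csv(path: str | Path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values), fmt="%d", delimiter=",")


def write_image_png16(path: str | Path, values: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(values).astype(np.uint16))


def write_image_png8(path: str | Path, values: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(values).astype(np.uint8))


def write_mask_png(path: str | Path, mask: RoiMask) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (mask.in_roi.astype(np.uint8) * 255))


def write_mask_csv(path: str | Path, mask: RoiMask) -> None:
    np.savetxt(path, mask.in_roi.astype(np.uint8), fmt="%d", delimiter=",")


def write_cohort(
    cohort: Sequence[PatientRecord],
    out_dir: str | Path,
    image_format: str = "csv",
) -> tuple[Path, Path]:
    """Write a cohort to disk: slices + masks, manifest CSV, clinical CSV.

    Returns (manifest_path, clinical_path).  ``image_format`` is ``csv``
    (plain text) or ``png`` (16-bit grayscale; masks always 8-bit PNG).
    """
    out_dir = Path(out_dir)
    slices_dir = out_dir / "slices"
    slices_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    clinical_rows = []
    for record in cohort:
        clinical_rows.append(
            {
                "patient_id": record.patient_id,
                "risk_group": record.risk_group,
                "ipsa_ng_ml": record.ipsa,
            }
        )
        for i, (water, fat, mask) in enumerate(record.slices):
            stem = f"{record.patient_id}_s{i:02d}"
            if image_format == "csv":
                wpath = slices_dir / f"{stem}_water.csv"
                fpath = slices_dir / f"{stem}_fat.csv"
                mpath = slices_dir / f"{stem}_mask.csv"
                write_image_csv(wpath, water.values)
                write_image_csv(fpath, fat.values)
                write_mask_csv(mpath, mask)
            elif image_format == "png":
                wpath = slices_dir / f"{stem}_water.png"
                fpath = slices_dir / f"{stem}_fat.png"
                mpath = slices_dir / f"{stem}_mask.png"
                write_image_png16(wpath, water.values)
                write_image_png16(fpath, fat.values)
                write_mask_png(mpath, mask)
            else:
                raise ValueError(f"unknown image format {image_format!r}")
            manifest_rows.append(
                {
                    "patient_id": record.patient_id,
                    "slice_index": i,
                    "water_path": str(wpath.relative_to(out_dir)),
                    "fat_path": str(fpath.relative_to(out_dir)),
                    "mask_path": str(mpath.relative_to(out_dir)),
                }
            )

    manifest_path = out_dir / "manifest.csv"
    clinical_path = out_dir / "clinical.csv"
    pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest_path, index=False
    )
    pd.DataFrame(clinical_rows, columns=CLINICAL_COLUMNS).to_csv(
        clinical_path, index=False
    )
    return manifest_path, clinical_path
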