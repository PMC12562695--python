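"""Reading and writing of on-disk artifacts.

Conventions (fixed so every other module can be format-agnostic):

* Volumes: multi-page TIFF, one page per B-scan; each page is a ``z``-by-``x``
  image, pages stacked along ``y``. NIfTI (``.nii``/``.nii.gz``) is also
  accepted with the array stored directly as ``(z, x, y)``.
* En face masks: 8-bit grayscale PNG, image width = ``x``, height = ``y``,
  origin top-left; any nonzero pixel is GA.
* nIR images: 8-bit grayscale PNG on the same axis convention.
* Cohort metadata: CSV with columns ``subject_id, eye, visit_index, device,
  quality_score, has_nAMD, has_GA, volume_path, mask_path`` and optional
  ``nir_path``; paths are relative to the cohort root directory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import CorruptStackError, FormatError, IntegrityError, SchemaError
from .types import EnFaceMask, NIRImage, OCTVolume, ScanRecord, check_unique_keys

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_nir",
    "write_nir",
    "read_cohort",
    "write_cohort",
]

_REQUIRED_COLUMNS = (
    "subject_id",
    "eye",
    "visit_index",
    "device",
    "quality_score",
    "has_nAMD",
    "has_GA",
    "volume_path",
    "mask_path",
)


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def read_volume(
    path: Union[str, Path],
    spacing_mm: tuple[float, float, float],
    record_id: str = "",
) -> OCTVolume:
    """Read an OCT volume from multi-page TIFF or NIfTI.

    Regardless of on-disk layout, the returned grid is indexed ``(z, x, y)``
    and cast to float32. TIFF pages are ``z``-by-``x`` images, one per B-scan.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    if _is_nifti(path):
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
        except Exception as exc:  # nibabel raises many types
            raise FormatError(f"unreadable NIfTI volume {path}: {exc}") from exc
        if data.ndim != 3:
            raise FormatError(f"NIfTI volume must be 3D, got shape {data.shape}")
    else:
        try:
            pages = tifffile.imread(str(path))
        except Exception as exc:
            raise FormatError(f"unreadable TIFF volume {path}: {exc}") from exc
        if pages.ndim == 2:  # single-page stack
            pages = pages[None]
        if pages.ndim != 3:
            raise CorruptStackError(
                f"TIFF pages of {path} do not form a uniform stack (shape {pages.shape})"
            )
        data = np.moveaxis(pages, 0, -1)  # (pages, z, x) -> (z, x, y)
    return OCTVolume(data=data.astype(np.float32), spacing_mm=spacing_mm, record_id=record_id)


def write_volume(path: Union[str, Path], vol: OCTVolume) -> None:
    """Write a volume as multi-page TIFF (or NIfTI by extension), losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(vol.data), affine=np.eye(4))
        nib.save(img, str(path))
    else:
        pages = np.moveaxis(np.asarray(vol.data), -1, 0)  # (z,x,y) -> (y,z,x)
        tifffile.imwrite(str(path), np.ascontiguousarray(pages))


def _read_gray_png(path: Path) -> np.ndarray:
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        img = Image.open(path)
    except Exception as exc:
        raise FormatError(f"unreadable image {path}: {exc}") from exc
    if img.mode not in ("L", "I", "I;16", "1"):
        raise FormatError(
            f"{path}: expected grayscale image, got mode {img.mode!r}"
        )
    return np.asarray(img)


def read_mask(path: Union[str, Path], pixel_area_mm2: Optional[float] = None) -> EnFaceMask:
    """Read an en face GA mask PNG; nonzero pixels map to 1."""
    arr = _read_gray_png(Path(path))
    grid = (arr > 0).astype(np.uint8).T  # (height=y, width=x) -> (x, y)
    return EnFaceMask(grid=grid, pixel_area_mm2=pixel_area_mm2, binary=True)


def write_mask(path: Union[str, Path], mask: EnFaceMask) -> None:
    """Write a binary en face mask as an 8-bit PNG (GA pixels = 255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = (np.asarray(mask.grid).T > 0).astype(np.uint8) * 255  # (x,y) -> (y,x)
    Image.fromarray(img, mode="L").save(path)


def read_nir(path: Union[str, Path], fov_deg: float = 30.0) -> NIRImage:
    """Read a near-infrared reflectance PNG; intensities scaled to [0, 1]."""
    arr = _read_gray_png(Path(path))
    grid = arr.astype(np.float32).T / 255.0
    return NIRImage(grid=grid, fov_deg=fov_deg)


def write_nir(path: Union[str, Path], nir: NIRImage) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = np.clip(np.asarray(nir.grid).T * 255.0, 0, 255).round().astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)):
        return bool(int(v))
    return str(v).strip().lower() in ("1", "true", "yes")


def read_cohort(metadata_path: Union[str, Path], root: Optional[Union[str, Path]] = None) -> list[ScanRecord]:
    """Read a cohort metadata CSV into a list of ScanRecords.

    ``root`` defaults to the CSV's directory; relative paths in the table are
    resolved against it so records carry absolute file locations.
    """
    metadata_path = Path(metadata_path)
    if not metadata_path.exists():
        raise FormatError(f"metadata file not found: {metadata_path}")
    root = Path(root) if root is not None else metadata_path.parent
    df = pd.read_csv(metadata_path, dtype={"subject_id": str, "eye": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata CSV missing required columns: {missing}")

    def _resolve(p) -> Optional[str]:
        if p is None or (isinstance(p, float) and np.isnan(p)) or str(p).strip() == "":
            return None
        return str(root / str(p))

    records = []
    for row in df.itertuples(index=False):
        records.append(
            ScanRecord(
                subject_id=str(row.subject_id),
                eye=str(row.eye),
                visit_index=int(row.visit_index),
                device=str(row.device),
                quality_score=float(row.quality_score),
                has_nAMD=_parse_bool(row.has_nAMD),
                has_GA=_parse_bool(row.has_GA),
                volume_path=_resolve(row.volume_path),
                mask_path=_resolve(row.mask_path),
                nir_path=_resolve(getattr(row, "nir_path", None)),
                area_true_mm2=(
                    float(row.area_true_mm2)
                    if "area_true_mm2" in df.columns and not pd.isna(row.area_true_mm2)
                    else None
                ),
                truncated=_parse_bool(getattr(row, "truncated", False)),
            )
        )
    check_unique_keys(records)
    return records


def write_cohort(metadata_path: Union[str, Path], records: list[ScanRecord], root: Optional[Union[str, Path]] = None) -> None:
    """Write cohort metadata to CSV with paths relative to ``root``."""
    metadata_path = Path(metadata_path)
    metadata_path.parent.mkdir(parents=True, exist_ok=True)
    root = Path(root) if root is not None else metadata_path.parent
    check_unique_keys(records)

    def _rel(p: Optional[str]) -> str:
        if p is None:
            return ""
        try:
            return str(Path(p).relative_to(root))
        except ValueError:
            return str(p)

    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "eye": [r.eye for r in records],
            "visit_index": [r.visit_index for r in records],
            "device": [r.device for r in records],
            "quality_score": [r.quality_score for r in records],
            "has_nAMD": [r.has_nAMD for r in records],
            "has_GA": [r.has_GA for r in records],
            "volume_path": [_rel(r.volume_path) for r in records],
            "mask_path": [_rel(r.mask_path) for r in records],
            "nir_path": [_rel(r.nir_path) for r in records],
            "area_true_mm2": [r.area_true_mm2 for r in records],
            "truncated": [r.truncated for r in records],
        }
    )
    df.to_csv(metadata_path, index=False)
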