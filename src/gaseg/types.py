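"""Core in-memory containers: OCT volumes, en face masks, nIR images, scan records."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import IntegrityError, ShapeError

__all__ = ["OCTVolume", "EnFaceMask", "NIRImage", "ScanRecord"]


@dataclass
class OCTVolume:
    """A 3D OCT intensity grid.

    ``data`` is indexed ``(z, x, y)``: axial depth, lateral position within a
    B-scan, and B-scan index. ``spacing_mm`` is the physical voxel pitch
    ``(dz, dx, dy)`` in mm/px.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    record_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or any(d < 1 for d in self.data.shape):
            raise ShapeError(f"volume must be 3D with all dims >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ShapeError("volume intensities must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ShapeError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def en_face_dims(self) -> tuple[int, int]:
        """(x, y) dimensions of the en face plane."""
        return self.data.shape[1], self.data.shape[2]


@dataclass
class EnFaceMask:
    """A 2D en face GA map on the (x, y) = (lateral, B-scan) plane.

    Values are probabilities in [0, 1]; when ``binary`` is set they are
    exactly 0 or 1. ``pixel_area_mm2`` is dx*dy of one en face pixel, so
    lesion area is simply ``grid.sum() * pixel_area_mm2``.
    """

    grid: np.ndarray
    pixel_area_mm2: Optional[float] = None
    binary: bool = True

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ShapeError(f"mask must be 2D, got shape {self.grid.shape}")
        if self.binary:
            vals = np.unique(self.grid)
            if not np.all(np.isin(vals, (0, 1))):
                raise ShapeError("binary mask must contain only values {0, 1}")
        else:
            if self.grid.size and (self.grid.min() < 0 or self.grid.max() > 1):
                raise ShapeError("mask values must lie in [0, 1]")
        if self.pixel_area_mm2 is not None and self.pixel_area_mm2 <= 0:
            raise ShapeError("pixel_area_mm2 must be positive")

    @property
    def dims(self) -> tuple[int, int]:
        return tuple(self.grid.shape)  # type: ignore[return-value]


@dataclass
class NIRImage:
    """A 2D near-infrared reflectance en face image."""

    grid: np.ndarray
    fov_deg: float = 30.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or any(d < 1 for d in self.grid.shape):
            raise ShapeError(f"nIR image must be 2D with dims >= 1, got {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ShapeError("nIR intensities must be finite")


@dataclass
class ScanRecord:
    """Metadata for a single scan of a subject's eye at one visit."""

    subject_id: str
    eye: str  # "OD" or "OS"
    visit_index: int
    device: str
    quality_score: float
    has_nAMD: bool
    has_GA: bool = True
    volume_path: Optional[str] = None
    mask_path: Optional[str] = None
    nir_path: Optional[str] = None
    #: generator-recorded ground-truth lesion area (synthetic cohorts only)
    area_true_mm2: Optional[float] = None
    #: set when programmed lesion growth had to be truncated at the FOV edge
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise IntegrityError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        if self.visit_index < 0:
            raise IntegrityError("visit_index must be >= 0")

    @property
    def key(self) -> tuple[str, str, int]:
        """(subject, eye, visit) — unique within a cohort."""
        return (self.subject_id, self.eye, self.visit_index)

    @property
    def record_id(self) -> str:
        return f"{self.subject_id}_{self.eye}_v{self.visit_index:02d}"


def check_unique_keys(records: list[ScanRecord]) -> None:
    """Raise IntegrityError when two records share a (subject, eye, visit) key."""
    seen: set[tuple[str, str, int]] = set()
    for r in records:
        if r.key in seen:
            raise IntegrityError(f"duplicate (subject, eye, visit) key: {r.key}")
        seen.add(r.key)
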