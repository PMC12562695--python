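"""OCT device acquisition profiles.

A :class:`DeviceProfile` captures everything downstream code needs to know
about how a device acquires a macular cube: the native voxel grid, the lateral
field of view, the resolution the network consumes, and the device-reported
quality score below which a scan is excluded.

Axis convention used throughout the package for volumes: ``(z, x, y)`` where
``z`` is axial depth (pixels within a B-scan column), ``x`` is the lateral
(fast) axis within a B-scan, and ``y`` indexes B-scans (the slow axis).
En face grids are indexed ``(x, y)``.

Two clinical profiles are registered:

* ``spectralis`` — Heidelberg Spectralis macular protocol: 49 B-scans of
  512x496 px over a ~20 degree (6 mm) field of view, near-infrared (nIR)
  reflectance available, minimum quality index 25.
* ``cirrus`` — Zeiss Cirrus macular protocol: 200 B-scans of 200x1024 px,
  no nIR channel, minimum signal score 5.

Two additional ``*_small`` profiles describe the same geometry at reduced
pixel counts; they exist so that full train/evaluate experiments run in
minutes on a single CPU and are used by the test-suite experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

__all__ = ["DeviceProfile", "get_profile", "register_profile", "PROFILES"]


@dataclass(frozen=True)
class DeviceProfile:
    """Acquisition geometry and inclusion rules for one OCT device."""

    name: str
    fov_mm: tuple[float, float] = (6.0, 6.0)
    #: native voxel grid (z, x, y)
    native_dims: tuple[int, int, int] = (496, 512, 49)
    #: grid fed to the network after subsampling (z, x, y)
    net_input_dims: tuple[int, int, int] = (128, 128, 64)
    #: en face output mask grid (x, y)
    mask_dims: tuple[int, int] = (128, 64)
    #: minimum device-reported quality score for inclusion (inclusive)
    quality_min: float = 25.0
    has_nir: bool = False

    def __post_init__(self) -> None:
        if self.mask_dims != (self.net_input_dims[1], self.net_input_dims[2]):
            raise ConfigError(
                f"profile {self.name!r}: mask_dims {self.mask_dims} must equal "
                f"(net_input_dims.x, net_input_dims.y) "
                f"{self.net_input_dims[1:]}"
            )
        if self.quality_min <= 0:
            raise ConfigError(f"profile {self.name!r}: quality_min must be > 0")
        if any(d < 1 for d in self.native_dims + self.net_input_dims):
            raise ConfigError(f"profile {self.name!r}: dimensions must be >= 1")

    @property
    def native_spacing_mm(self) -> tuple[float, float, float]:
        """(dz, dx, dy) in mm/px at native resolution.

        Axial depth extent is nominally ~1.9 mm for both devices; the axial
        spacing only matters for display, never for area computations.
        """
        z, x, y = self.native_dims
        return (1.9 / z, self.fov_mm[0] / x, self.fov_mm[1] / y)

    @property
    def native_pixel_area_mm2(self) -> float:
        """En face pixel area (dx * dy) at native resolution."""
        _, x, y = self.native_dims
        return (self.fov_mm[0] / x) * (self.fov_mm[1] / y)

    @property
    def mask_pixel_area_mm2(self) -> float:
        """En face pixel area at the network's output-mask resolution."""
        x, y = self.mask_dims
        return (self.fov_mm[0] / x) * (self.fov_mm[1] / y)


SPECTRALIS = DeviceProfile(
    name="spectralis",
    native_dims=(496, 512, 49),
    net_input_dims=(128, 128, 64),
    mask_dims=(128, 64),
    quality_min=25.0,
    has_nir=True,
)

CIRRUS = DeviceProfile(
    name="cirrus",
    native_dims=(1024, 200, 200),
    net_input_dims=(128, 128, 128),
    mask_dims=(128, 128),
    quality_min=5.0,
    has_nir=False,
)

# Reduced-pixel-count variants of the clinical protocols for CPU-scale
# experiments: same field of view and phenotype, half the network resolution.
SPECTRALIS_SMALL = DeviceProfile(
    name="spectralis_small",
    native_dims=(160, 128, 32),
    net_input_dims=(64, 64, 32),
    mask_dims=(64, 32),
    quality_min=25.0,
    has_nir=True,
)

CIRRUS_SMALL = DeviceProfile(
    name="cirrus_small",
    native_dims=(256, 64, 64),
    net_input_dims=(64, 64, 64),
    mask_dims=(64, 64),
    quality_min=5.0,
    has_nir=False,
)

PROFILES: dict[str, DeviceProfile] = {
    p.name: p for p in (SPECTRALIS, CIRRUS, SPECTRALIS_SMALL, CIRRUS_SMALL)
}


def get_profile(name: str) -> DeviceProfile:
    """Look up a registered device profile by name."""
    try:
        return PROFILES[name]
    except KeyError:
        raise ConfigError(
            f"unknown device profile {name!r}; known: {sorted(PROFILES)}"
        ) from None


def register_profile(profile: DeviceProfile) -> None:
    """Register a custom device profile (e.g. a different scan protocol)."""
    PROFILES[profile.name] = profile
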