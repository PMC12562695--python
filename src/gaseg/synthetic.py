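"""Synthetic OCT cohort generation.

Real GA cohorts are clinical data and cannot be redistributed, so every
downstream stage (preprocessing, training, evaluation) is exercised on
device-parameterized synthetic volumes that reproduce the imaging phenotype
of complete RPE and outer-retinal atrophy (cRORA):

* a normal macular background of smooth, bright horizontal bands (inner
  retina, ellipsoid zone, RPE) over a dim, decaying choroid;
* within the lesion footprint, loss of the RPE band (>= 70 % attenuation)
  and *hypertransmission* — amplified signal below the RPE, the cardinal
  en face signature of atrophy;
* multifocal lesions as unions of randomly deformed ellipses;
* monotone lesion growth across visits, calibrated in mm^2 per visit;
* optional neovascular-AMD confounders (fluid pockets, hyperreflective
  subretinal material) and multiplicative log-normal speckle.

All randomness flows from explicit seeds; identical parameters give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from . import io as gio
from .errors import CapabilityError, ParameterError, ShapeError
from .profiles import SPECTRALIS, DeviceProfile
from .types import EnFaceMask, NIRImage, OCTVolume, ScanRecord

__all__ = [
    "SyntheticParams",
    "make_background",
    "sample_lesion_mask",
    "apply_atrophy",
    "add_namd_features",
    "render_nir",
    "grow_mask",
    "add_speckle",
    "generate_cohort",
]

#: number of bright retinal bands in the synthetic background
N_BANDS = 3

#: fraction of axial extent used as the flat attenuation window half-width
#: around the detected RPE depth
_RPE_HALFWIN_FRAC = 0.035


@dataclass(frozen=True)
class SyntheticParams:
    """Cohort-level generation parameters.

    Defaults describe a longitudinal GA cohort of 20 subjects, one study eye
    each, three visits, with moderate speckle and 30 % of eyes carrying
    neovascular-AMD confounders — a desk-scale analogue of a routine-care
    GA data set in which most eyes show multifocal atrophy growing by about
    half a square millimetre per visit.
    """

    device: DeviceProfile = SPECTRALIS
    n_subjects: int = 20
    eyes_per_subject: int = 1
    visits_per_eye: int = 3
    n_foci_range: tuple[int, int] = (1, 4)
    focus_radius_range_mm: tuple[float, float] = (0.4, 1.2)
    growth_rate_mm2_per_visit: float = 0.5
    speckle_sigma: float = 0.2
    namd_fraction: float = 0.3
    quality_score_range: tuple[float, float] = (25.0, 45.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_foci_range", "focus_radius_range_mm", "quality_score_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name} must be ordered (low <= high)")
        if not (0.0 <= self.namd_fraction <= 1.0):
            raise ParameterError("namd_fraction must lie in [0, 1]")
        if self.growth_rate_mm2_per_visit < 0:
            raise ParameterError("growth_rate_mm2_per_visit must be >= 0")
        if self.speckle_sigma < 0:
            raise ParameterError("speckle_sigma must be >= 0")


def _smooth_field(rng: np.random.Generator, dims: tuple[int, int],
                  amplitude: float, n_modes: int = 3) -> np.ndarray:
    """A smooth random surface built from a few low-frequency cosine modes."""
    X, Y = dims
    xx = np.linspace(0, 1, X)[:, None]
    yy = np.linspace(0, 1, Y)[None, :]
    out = np.zeros((X, Y), np.float32)
    for _ in range(n_modes):
        fx, fy = rng.uniform(0.5, 1.5, 2)
        px, py = rng.uniform(0, 2 * np.pi, 2)
        out += rng.uniform(-1, 1) * np.cos(2 * np.pi * fx * xx + px) * np.cos(
            2 * np.pi * fy * yy + py
        ).astype(np.float32)
    return amplitude * out / max(n_modes, 1)


def make_background(profile: DeviceProfile, seed: int,
                    n_bands: int = N_BANDS) -> OCTVolume:
    """A normal-retina volume: dark vitreous, bright bands, dim choroid.

    Band depths vary smoothly across the en face plane; the RPE is the
    brightest band so it can be re-identified per A-scan by a simple argmax.
    Noise-free: speckle is applied separately.
    """
    Z, X, Y = profile.native_dims
    rng = np.random.default_rng(seed)
    z = np.arange(Z, dtype=np.float32)[:, None, None]

    # band depths as fractions of the axial extent, shallow to deep;
    # spacing chosen so each band is a distinct local maximum per column
    base_fracs = np.linspace(0.28, 0.62, n_bands)
    amps = np.linspace(0.55, 1.0, n_bands)  # RPE (deepest) is brightest
    sigma_px = max(1.5, 0.012 * Z)

    vol = np.full((Z, X, Y), 0.02, np.float32)
    tilt = _smooth_field(rng, (X, Y), amplitude=0.03 * Z)
    depth_last = None
    for frac, amp in zip(base_fracs, amps):
        wobble = _smooth_field(rng, (X, Y), amplitude=0.01 * Z)
        depth = frac * Z + tilt + wobble
        vol += amp * np.exp(-0.5 * ((z - depth[None]) / sigma_px) ** 2)
        depth_last = depth
    # choroid: dim signal decaying below the deepest (RPE) band
    below = z - depth_last[None]
    vol += np.where(below > 2 * sigma_px,
                    0.13 * np.exp(-np.maximum(below, 0) / (0.15 * Z)), 0.0)
    return OCTVolume(data=vol.astype(np.float32),
                     spacing_mm=profile.native_spacing_mm)


def sample_lesion_mask(profile: DeviceProfile, n_foci: int,
                       radius_range_mm: tuple[float, float], seed: int) -> EnFaceMask:
    """Union of ``n_foci`` randomly deformed elliptical blobs on the en face plane.

    Each focus has an equivalent radius drawn from ``radius_range_mm``; the
    boundary is modulated by low-order angular harmonics so blobs look like
    graded atrophy rather than perfect circles, with area within ~25 % of
    the circle of the drawn radius.
    """
    if n_foci < 0:
        raise ParameterError("n_foci must be >= 0")
    lo, hi = radius_range_mm
    fov_x, fov_y = profile.fov_mm
    if hi > min(fov_x, fov_y) / 2:
        raise ParameterError(
            f"focus radius {hi} mm exceeds half the field of view {profile.fov_mm}"
        )
    _, X, Y = profile.native_dims
    rng = np.random.default_rng(seed)
    dx, dy = fov_x / X, fov_y / Y
    # pixel-centre coordinates in mm
    xs = (np.arange(X) + 0.5) * dx
    ys = (np.arange(Y) + 0.5) * dy
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.zeros((X, Y), bool)
    for _ in range(n_foci):
        r0 = rng.uniform(lo, hi)
        margin = r0 * 1.3
        cx = rng.uniform(margin, fov_x - margin)
        cy = rng.uniform(margin, fov_y - margin)
        theta = np.arctan2(yy - cy, xx - cx)
        rad = np.hypot(xx - cx, yy - cy)
        rb = np.ones_like(theta) * r0
        for k in (2, 3, 5):
            rb += r0 * rng.uniform(0.0, 0.06) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        grid |= rad <= rb
    return EnFaceMask(grid=grid.astype(np.uint8),
                      pixel_area_mm2=dx * dy, binary=True)


def _rpe_depth(vol_data: np.ndarray) -> np.ndarray:
    """Per-column depth of the brightest band (the RPE in this phantom)."""
    return np.argmax(vol_data, axis=0).astype(np.float32)


def fit_rpe_surface(vol_data: np.ndarray, degree: int = 3) -> np.ndarray:
    """Robust smooth RPE depth surface for a possibly atrophic volume.

    Inside a lesion the RPE band is attenuated, so the per-column argmax
    lands on an inner band; a global weighted polynomial fit (weights are a
    high power of the column's peak brightness, which is low precisely where
    the RPE is lost) recovers the RPE plane from the healthy columns.
    Returns depth in px, shape (x, y).
    """
    Z, X, Y = vol_data.shape
    depth0 = np.argmax(vol_data, axis=0).astype(np.float64)
    peak = vol_data.max(axis=0)
    w = (peak / max(float(peak.max()), 1e-9)) ** 6
    xx = (np.arange(X) / max(X - 1, 1) - 0.5)[:, None] * np.ones((1, Y))
    yy = np.ones((X, 1)) * (np.arange(Y) / max(Y - 1, 1) - 0.5)[None, :]
    terms = [
        xx ** i * yy ** j
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
    ]
    A = np.stack([t.ravel() for t in terms], axis=1)
    sw = np.sqrt(w.ravel() + 1e-12)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], depth0.ravel() * sw, rcond=None)
    return (A @ coef).reshape(X, Y).astype(np.float32)


def _feather_weight(grid: np.ndarray, ramp_px: float = 2.0) -> np.ndarray:
    """Blend weight: 1 deep inside the lesion, ramping to 0 at its boundary.

    The ramp lives entirely *inside* the mask so pixels outside the lesion
    are untouched.
    """
    if not grid.any():
        return np.zeros_like(grid, np.float32)
    dist_in = ndimage.distance_transform_edt(grid > 0)
    return np.minimum(dist_in / ramp_px, 1.0).astype(np.float32)


def apply_atrophy(vol: OCTVolume, mask: EnFaceMask, profile: DeviceProfile,
                  rpe_attenuation: float = 0.8,
                  hypertransmission_boost: float = 2.5) -> OCTVolume:
    """Imprint the cRORA phenotype of ``mask`` into ``vol``.

    Within lesion columns the RPE band is attenuated by ``rpe_attenuation``
    (default 80 %) and everything below it is amplified by
    ``hypertransmission_boost`` (default 2.5x). The transition feathers over
    ~2 px inside the lesion boundary; columns outside the mask are returned
    bit-identical.
    """
    Z, X, Y = vol.data.shape
    if mask.grid.shape != (X, Y):
        raise ShapeError(
            f"mask dims {mask.grid.shape} do not match volume en face dims {(X, Y)}"
        )
    if not mask.grid.any():
        return OCTVolume(data=vol.data.copy(), spacing_mm=vol.spacing_mm,
                         record_id=vol.record_id)
    out = vol.data.copy()
    w = _feather_weight(mask.grid)[None]  # (1, X, Y)
    depth = _rpe_depth(vol.data)[None]  # (1, X, Y)
    z = np.arange(Z, dtype=np.float32)[:, None, None]
    halfwin = max(3.0, _RPE_HALFWIN_FRAC * Z)
    in_band = np.abs(z - depth) <= halfwin
    below = z > depth + halfwin
    factor = np.ones((Z, X, Y), np.float32)
    factor -= in_band * (rpe_attenuation * w)
    factor += below * ((hypertransmission_boost - 1.0) * w)
    out *= factor
    return OCTVolume(data=out, spacing_mm=vol.spacing_mm, record_id=vol.record_id)


def add_namd_features(vol: OCTVolume, seed: int,
                      ga_mask: Optional[EnFaceMask] = None) -> OCTVolume:
    """Add neovascular-AMD confounders: dark fluid pockets and bright
    subretinal hyperreflective patches at loci outside the GA footprint.

    Only the volume is perturbed; the ground-truth GA mask is never touched.
    """
    rng = np.random.default_rng(seed)
    Z, X, Y = vol.data.shape
    out = vol.data.copy()
    depth = _rpe_depth(vol.data)
    avoid = ga_mask.grid > 0 if ga_mask is not None else np.zeros((X, Y), bool)

    def _random_locus(max_r_frac: float):
        for _ in range(50):
            cx = rng.integers(X // 8, X - X // 8)
            cy = rng.integers(Y // 8, Y - Y // 8)
            if not avoid[cx, cy]:
                return int(cx), int(cy)
        return int(X // 2), int(Y // 2)

    zz = np.arange(Z, dtype=np.float32)[:, None, None]
    xx = np.arange(X, dtype=np.float32)[None, :, None]
    yy = np.arange(Y, dtype=np.float32)[None, None, :]

    n_fluid = int(rng.integers(1, 4))      # 1-3 dark fluid pockets
    n_bright = int(rng.integers(0, 3))     # 0-2 hyperreflective patches
    for kind, count in (("fluid", n_fluid), ("bright", n_bright)):
        for _ in range(count):
            cx, cy = _random_locus(0.1)
            cz = depth[cx, cy] - rng.uniform(0.06, 0.18) * Z  # intra/subretinal
            rz = rng.uniform(0.02, 0.05) * Z
            rx = rng.uniform(0.03, 0.10) * X
            ry = rng.uniform(0.03, 0.10) * Y
            blob = np.exp(-(((zz - cz) / rz) ** 2 + ((xx - cx) / rx) ** 2
                            + ((yy - cy) / ry) ** 2))
            if kind == "fluid":
                out *= (1.0 - 0.7 * blob).astype(np.float32)
            else:
                out += (0.45 * blob).astype(np.float32)
    return OCTVolume(data=out.astype(np.float32), spacing_mm=vol.spacing_mm,
                     record_id=vol.record_id)


def render_nir(vol: OCTVolume, mask: EnFaceMask,
               profile: Optional[DeviceProfile] = None) -> NIRImage:
    """Near-infrared reflectance facsimile: mean sub-RPE slab projection.

    Atrophic regions appear bright both through genuine hypertransmission in
    the volume and a mild additional reflectivity term driven by the lesion
    mask (atrophy is hyperreflective on real nIR). Output is resampled to a
    square grid of side equal to the lateral pixel count. Deterministic.
    """
    if profile is not None and not profile.has_nir:
        raise CapabilityError(f"device profile {profile.name!r} has no nIR channel")
    Z, X, Y = vol.data.shape
    if mask.grid.shape != (X, Y):
        raise ShapeError("mask dims must match volume en face dims")
    proj = sub_rpe_slab_projection(vol)
    proj = proj * (1.0 + 0.3 * (mask.grid > 0))
    side = X
    zoom = (side / proj.shape[0], side / proj.shape[1])
    sq = ndimage.zoom(proj, zoom, order=1, mode="nearest", grid_mode=True)
    return NIRImage(grid=np.clip(sq, 0.0, 1.0).astype(np.float32))


def sub_rpe_slab_projection(vol: OCTVolume) -> np.ndarray:
    """Mean intensity of the slab just below the fitted RPE surface.

    The classical en face readout of hypertransmission; shared by the nIR
    renderer and the slab-threshold baseline segmenter. The RPE plane comes
    from :func:`fit_rpe_surface` so that atrophic columns (where the band
    itself is gone) still get a sensible slab.
    """
    Z = vol.data.shape[0]
    depth = fit_rpe_surface(vol.data)
    halfwin = max(3.0, _RPE_HALFWIN_FRAC * Z)
    z = np.arange(Z, dtype=np.float32)[:, None, None]
    lo = depth[None] + halfwin
    hi = lo + 0.2 * Z
    slab = (z > lo) & (z <= hi)
    return ((vol.data * slab).sum(axis=0) / np.maximum(slab.sum(axis=0), 1)).astype(np.float32)


def grow_mask(mask: EnFaceMask, increment_mm2: float,
              spacing_mm: tuple[float, float]) -> tuple[EnFaceMask, bool]:
    """Isotropically dilate a lesion until its area grows by ``increment_mm2``.

    Growth is exact to the pixel: the ``k`` nearest outside pixels by
    Euclidean distance (in mm) are converted, where ``k`` is the increment
    divided by the pixel area. Returns (grown mask, truncated flag); the
    flag is set when the lesion met the field-of-view boundary and fewer
    pixels than requested could be added.
    """
    dx, dy = spacing_mm
    px_area = dx * dy
    grid = mask.grid > 0
    if not grid.any() or increment_mm2 <= 0:
        return EnFaceMask(grid=grid.astype(np.uint8), pixel_area_mm2=mask.pixel_area_mm2,
                          binary=True), False
    k = int(round(increment_mm2 / px_area))
    outside = ~grid
    dist = ndimage.distance_transform_edt(outside, sampling=(dx, dy))
    cand = np.argsort(dist[outside], kind="stable")[:k]
    truncated = cand.size < k
    new = grid.copy()
    ox, oy = np.nonzero(outside)
    new[ox[cand], oy[cand]] = True
    return EnFaceMask(grid=new.astype(np.uint8), pixel_area_mm2=mask.pixel_area_mm2,
                      binary=True), truncated


def add_speckle(vol: OCTVolume, sigma: float, seed: int) -> OCTVolume:
    """Multiplicative log-normal speckle with unit mean."""
    if sigma <= 0:
        return vol
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                          size=vol.data.shape).astype(np.float32)
    return OCTVolume(data=vol.data * noise, spacing_mm=vol.spacing_mm,
                     record_id=vol.record_id)


def generate_cohort(params: SyntheticParams, out_dir: Union[str, Path]) -> list[ScanRecord]:
    """Generate a full synthetic cohort on disk.

    For each subject/eye, visit ``v``'s lesion is visit ``v-1``'s dilated by
    ``growth_rate_mm2_per_visit`` (area growth is monotone by construction).
    A ``namd_fraction`` of eyes receive confounder features at every visit.
    Files are written in the io-module layout with a ``cohort.csv`` manifest;
    the returned records carry absolute paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profile = params.device
    root_ss = np.random.SeedSequence(params.seed)
    eye_names = ["OD", "OS"]
    records: list[ScanRecord] = []
    n_eyes_total = params.n_subjects * params.eyes_per_subject
    namd_rng = np.random.default_rng(root_ss.spawn(1)[0])
    namd_eyes = namd_rng.random(n_eyes_total) < params.namd_fraction

    eye_idx = 0
    for si in range(params.n_subjects):
        subject = f"S{si:03d}"
        for ei in range(params.eyes_per_subject):
            eye = eye_names[ei % 2]
            ss = np.random.SeedSequence((params.seed, si, ei))
            seeds = ss.generate_state(4 + 2 * params.visits_per_eye)
            bg = make_background(profile, int(seeds[0]))
            n_lo, n_hi = params.n_foci_range
            foci_rng = np.random.default_rng(int(seeds[1]))
            n_foci = int(foci_rng.integers(n_lo, n_hi + 1))
            mask = sample_lesion_mask(profile, n_foci,
                                      params.focus_radius_range_mm, int(seeds[2]))
            q_rng = np.random.default_rng(int(seeds[3]))
            has_namd = bool(namd_eyes[eye_idx])
            eye_idx += 1
            spacing_xy = (profile.fov_mm[0] / profile.native_dims[1],
                          profile.fov_mm[1] / profile.native_dims[2])
            truncated = False
            for v in range(params.visits_per_eye):
                if v > 0:
                    mask, trunc_v = grow_mask(mask, params.growth_rate_mm2_per_visit,
                                              spacing_xy)
                    truncated = truncated or trunc_v
                vol = apply_atrophy(bg, mask, profile)
                if has_namd:
                    vol = add_namd_features(vol, int(seeds[4 + 2 * v]), ga_mask=mask)
                nir = render_nir(vol, mask, profile) if profile.has_nir else None
                vol = add_speckle(vol, params.speckle_sigma, int(seeds[5 + 2 * v]))

                rid = f"{subject}_{eye}_v{v:02d}"
                vol_path = out_dir / f"{rid}_vol.tiff"
                mask_path = out_dir / f"{rid}_mask.png"
                gio.write_volume(vol_path, vol)
                gio.write_mask(mask_path, mask)
                nir_path = None
                if nir is not None:
                    nir_path = out_dir / f"{rid}_nir.png"
                    gio.write_nir(nir_path, nir)
                q_lo, q_hi = params.quality_score_range
                records.append(
                    ScanRecord(
                        subject_id=subject,
                        eye=eye,
                        visit_index=v,
                        device=profile.name,
                        quality_score=float(q_rng.uniform(q_lo, q_hi)),
                        has_nAMD=has_namd,
                        has_GA=bool(mask.grid.any()),
                        volume_path=str(vol_path),
                        mask_path=str(mask_path),
                        nir_path=str(nir_path) if nir_path else None,
                        area_true_mm2=float(mask.grid.sum() * mask.pixel_area_mm2),
                        truncated=truncated,
                    )
                )
    gio.write_cohort(out_dir / "cohort.csv", records, root=out_dir)
    return records
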