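"""Synthetic cohort generator: phenotype, determinism, growth, metadata."""

import filecmp

import numpy as np
import pytest
from scipy.signal import find_peaks

from gaseg import (EnFaceMask, SyntheticParams, add_namd_features, add_speckle,
                   apply_atrophy, dsc, generate_cohort, grow_mask,
                   make_background, render_nir, sample_lesion_mask)
from gaseg.baseline import SlabThresholdSegmenter
from gaseg.errors import CapabilityError, ParameterError, ShapeError
from gaseg.profiles import CIRRUS_SMALL, SPECTRALIS


class TestBackground:
    def test_native_dims_spectralis(self):
        """The Spectralis-profile phantom has the clinical 49x512x496 grid."""
        vol = make_background(SPECTRALIS, seed=0)
        assert vol.dims == (496, 512, 49)

    def test_deterministic(self, tiny_profile):
        a = make_background(tiny_profile, seed=5)
        b = make_background(tiny_profile, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_each_column_has_exactly_three_bands(self, tiny_profile):
        """Noise-free A-scans show one local maximum per retinal band."""
        vol = make_background(tiny_profile, seed=2)
        for (x, y) in [(0, 0), (7, 3), (15, 7), (4, 5)]:
            peaks, _ = find_peaks(vol.data[:, x, y])
            assert len(peaks) == 3


class TestLesionMask:
    def test_zero_foci_empty(self, tiny_profile):
        m = sample_lesion_mask(tiny_profile, 0, (0.4, 1.0), seed=0)
        assert m.grid.sum() == 0

    def test_single_focus_area_near_circle(self):
        """One blob of fixed equivalent radius r has area within 25 % of pi r^2."""
        r = 1.0
        for seed in range(5):
            m = sample_lesion_mask(SPECTRALIS, 1, (r, r), seed=seed)
            area = m.grid.sum() * m.pixel_area_mm2
            assert abs(area - np.pi * r ** 2) <= 0.25 * np.pi * r ** 2

    def test_deterministic(self, tiny_profile):
        a = sample_lesion_mask(tiny_profile, 3, (0.3, 1.0), seed=9)
        b = sample_lesion_mask(tiny_profile, 3, (0.3, 1.0), seed=9)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_radius_beyond_fov_rejected(self, tiny_profile):
        with pytest.raises(ParameterError):
            sample_lesion_mask(tiny_profile, 1, (0.5, 4.0), seed=0)


class TestAtrophy:
    def test_empty_mask_is_identity(self, tiny_profile):
        vol = make_background(tiny_profile, seed=1)
        empty = EnFaceMask(np.zeros(tiny_profile.native_dims[1:], np.uint8),
                           binary=True)
        out = apply_atrophy(vol, empty, tiny_profile)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_full_mask_brightens_sub_rpe(self, tiny_profile):
        vol = make_background(tiny_profile, seed=1)
        full = EnFaceMask(np.ones(tiny_profile.native_dims[1:], np.uint8),
                          binary=True)
        out = apply_atrophy(vol, full, tiny_profile)
        depth = np.argmax(vol.data, axis=0)
        Z = vol.data.shape[0]
        z = np.arange(Z)[:, None, None]
        below = z > depth[None] + 0.1 * Z
        assert out.data[below].mean() > vol.data[below].mean()

    def test_lesion_columns_separable(self, tiny_profile):
        """Sub-RPE brightness inside the lesion exceeds outside, every case."""
        for seed in range(4):
            vol = make_background(tiny_profile, seed=seed)
            mask = sample_lesion_mask(tiny_profile, 2, (0.5, 1.2), seed=seed + 50)
            if not mask.grid.any():
                continue
            out = apply_atrophy(vol, mask, tiny_profile)
            depth = np.argmax(vol.data, axis=0)
            Z = vol.data.shape[0]
            z = np.arange(Z)[:, None, None]
            below = z > depth[None] + 0.12 * Z
            sub = np.where(below, out.data, np.nan)
            col_mean = np.nanmean(sub, axis=0)
            inside = col_mean[mask.grid > 0].mean()
            outside = col_mean[mask.grid == 0].mean()
            assert inside > outside

    def test_outside_mask_untouched(self, tiny_profile):
        vol = make_background(tiny_profile, seed=3)
        mask = sample_lesion_mask(tiny_profile, 1, (0.5, 0.8), seed=3)
        out = apply_atrophy(vol, mask, tiny_profile)
        outside = mask.grid == 0
        np.testing.assert_array_equal(out.data[:, outside], vol.data[:, outside])

    def test_dim_mismatch(self, tiny_profile):
        vol = make_background(tiny_profile, seed=0)
        with pytest.raises(ShapeError):
            apply_atrophy(vol, EnFaceMask(np.zeros((3, 3), np.uint8)), tiny_profile)


class TestNamdAndNIR:
    def test_namd_deterministic_and_nontrivial(self, tiny_profile):
        vol = make_background(tiny_profile, seed=4)
        a = add_namd_features(vol, seed=7)
        b = add_namd_features(vol, seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        assert np.any(a.data != vol.data)

    def test_nir_homogeneous_without_lesion(self, tiny_profile):
        vol = make_background(tiny_profile, seed=5)
        empty = EnFaceMask(np.zeros(tiny_profile.native_dims[1:], np.uint8))
        nir = render_nir(vol, empty, tiny_profile)
        assert nir.grid.shape == (16, 16)  # square, side = lateral px
        assert nir.grid.std() < 0.05

    def test_nir_bright_inside_lesion(self, tiny_profile):
        vol = make_background(tiny_profile, seed=5)
        mask = sample_lesion_mask(tiny_profile, 1, (0.8, 1.2), seed=6)
        lesioned = apply_atrophy(vol, mask, tiny_profile)
        nir = render_nir(lesioned, mask, tiny_profile)
        from scipy.ndimage import zoom

        sq = zoom(mask.grid.astype(float),
                  (16 / mask.grid.shape[0], 16 / mask.grid.shape[1]),
                  order=0) > 0.5
        assert nir.grid[sq].mean() > nir.grid[~sq].mean()

    def test_nir_needs_capability(self):
        vol = make_background(CIRRUS_SMALL, seed=0)
        empty = EnFaceMask(np.zeros(CIRRUS_SMALL.native_dims[1:], np.uint8))
        with pytest.raises(CapabilityError):
            render_nir(vol, empty, CIRRUS_SMALL)


class TestGrowth:
    def test_exact_pixelwise_growth(self, tiny_profile):
        mask = sample_lesion_mask(tiny_profile, 1, (0.6, 0.8), seed=1)
        spacing = (6.0 / 16, 6.0 / 8)
        px = spacing[0] * spacing[1]
        grown, truncated = grow_mask(mask, 0.5, spacing)
        assert not truncated
        added = int(grown.grid.sum()) - int(mask.grid.sum())
        assert added == round(0.5 / px)
        assert np.all(grown.grid[mask.grid > 0] == 1)  # monotone

    def test_truncation_at_fov(self, tiny_profile):
        grid = np.ones(tiny_profile.native_dims[1:], np.uint8)
        grid[0, 0] = 0
        mask = EnFaceMask(grid, pixel_area_mm2=0.28, binary=True)
        _, truncated = grow_mask(mask, 5.0, (6.0 / 16, 6.0 / 8))
        assert truncated


class TestCohort:
    def test_counts_growth_and_metadata(self, tiny_profile, tmp_path):
        params = SyntheticParams(device=tiny_profile, n_subjects=5,
                                 eyes_per_subject=1, visits_per_eye=3,
                                 speckle_sigma=0.1, namd_fraction=0.4, seed=3)
        records = generate_cohort(params, tmp_path / "c")
        assert len(records) == 15
        assert len({r.subject_id for r in records}) == 5
        # per-eye areas never shrink; metadata area matches the stored mask
        from gaseg import read_mask

        for sub in {r.subject_id for r in records}:
            mine = sorted((r for r in records if r.subject_id == sub),
                          key=lambda r: r.visit_index)
            areas = [r.area_true_mm2 for r in mine]
            assert all(a2 >= a1 - 1e-9 for a1, a2 in zip(areas, areas[1:]))
            for r in mine:
                m = read_mask(r.mask_path,
                              pixel_area_mm2=tiny_profile.native_pixel_area_mm2)
                assert abs(m.grid.sum() * m.pixel_area_mm2 - r.area_true_mm2) \
                    <= m.pixel_area_mm2

    def test_same_seed_file_identical(self, tiny_profile, tmp_path):
        params = SyntheticParams(device=tiny_profile, n_subjects=2,
                                 eyes_per_subject=1, visits_per_eye=2, seed=8)
        r1 = generate_cohort(params, tmp_path / "a")
        r2 = generate_cohort(params, tmp_path / "b")
        for a, b in zip(r1, r2):
            assert filecmp.cmp(a.volume_path, b.volume_path, shallow=False)
            assert filecmp.cmp(a.mask_path, b.mask_path, shallow=False)
        assert (tmp_path / "a" / "cohort.csv").read_text() == \
            (tmp_path / "b" / "cohort.csv").read_text()


class TestWellPosedness:
    def test_slab_oracle_recovers_mask_noise_free(self, tiny_profile):
        """A trivial sub-RPE slab threshold reaches DSC >= 0.7 on clean data,
        so the learning task is well-posed by construction."""
        seg = SlabThresholdSegmenter()
        scores = []
        for seed in range(3):
            vol = make_background(tiny_profile, seed=seed)
            mask = sample_lesion_mask(tiny_profile, 2, (0.6, 1.2), seed=seed + 20)
            lesioned = apply_atrophy(vol, mask, tiny_profile)
            scores.append(dsc(seg.predict(lesioned),
                              EnFaceMask(mask.grid, binary=True)))
        assert np.median(scores) >= 0.7

    def test_speckle_deterministic_and_mean_preserving(self, tiny_profile):
        vol = make_background(tiny_profile, seed=0)
        a = add_speckle(vol, 0.3, seed=1)
        b = add_speckle(vol, 0.3, seed=1)
        np.testing.assert_array_equal(a.data, b.data)
        assert abs(a.data.mean() / vol.data.mean() - 1) < 0.05
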