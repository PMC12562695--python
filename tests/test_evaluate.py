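"""Agreement statistics, report assembly, cross-validation plumbing,
longitudinal series, coalescence diagnostic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gaseg import (EnFaceMask, NetConfig, TrainConfig, SyntheticParams,
                   area_mm2, bland_altman, coalescence_diagnostic,
                   compare_r2_between_strata, compute_report, cross_validate,
                   dsc, fisher_z_test, generate_cohort, longitudinal_report,
                   r2, ttest)
from gaseg.baseline import SlabThresholdSegmenter
from gaseg.errors import (ConfigError, InsufficientDataError, IntegrityError,
                          ShapeError)


def _mask(a, px=None):
    return EnFaceMask(np.asarray(a, np.uint8), pixel_area_mm2=px, binary=True)


class TestDSC:
    def test_identical_nonempty(self):
        m = _mask([[1, 0], [1, 1]])
        assert dsc(m, m) == 1.0

    def test_disjoint(self):
        assert dsc(_mask([[1, 0]]), _mask([[0, 1]])) == 0.0

    def test_half_overlap_closed_form(self):
        a = _mask([[1, 1, 1, 1, 0, 0, 0, 0]])
        b = _mask([[0, 0, 1, 1, 1, 1, 0, 0]])
        assert dsc(a, b) == 0.5

    def test_both_empty_is_perfect_agreement(self):
        assert dsc(_mask([[0, 0]]), _mask([[0, 0]])) == 1.0

    @given(st.integers(0, 50))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = _mask(rng.random((6, 4)) > 0.5)
        b = _mask(rng.random((6, 4)) > 0.5)
        assert dsc(a, b) == dsc(b, a)
        assert 0.0 <= dsc(a, b) <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            dsc(_mask([[1]]), _mask([[1, 0]]))


class TestArea:
    def test_full_fov_conservation(self):
        m = _mask(np.ones((128, 64)), px=(6 / 128) * (6 / 64))
        assert area_mm2(m) == pytest.approx(36.0)

    def test_single_pixel(self):
        g = np.zeros((128, 64))
        g[3, 7] = 1
        assert area_mm2(_mask(g, px=(6 / 128) * (6 / 64))) == pytest.approx(
            0.00439453125)

    def test_empty(self):
        assert area_mm2(_mask(np.zeros((4, 4)), px=1.0)) == 0.0

    def test_missing_metadata(self):
        with pytest.raises(ConfigError):
            area_mm2(_mask(np.ones((2, 2))))

    def test_additive_over_disjoint_masks(self, rng):
        g1 = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        g2 = ((rng.random((10, 10)) > 0.5) & (g1 == 0)).astype(np.uint8)
        px = 0.123
        assert area_mm2(_mask(g1 | g2, px=px)) == pytest.approx(
            area_mm2(_mask(g1, px=px)) + area_mm2(_mask(g2, px=px)))


class TestR2:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert r2(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_negative_slope_still_one(self):
        x = [1.0, 2.0, 3.0]
        assert r2(x, [-v for v in x]) == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        x, y = np.array([1.0, 2, 3]), np.array([1.0, 2, 4])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r2(x, y) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InsufficientDataError):
            r2([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_measurements(self):
        assert bland_altman([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        bias, lo, hi = bland_altman([1.0, 2.0], [1.5, 2.5])
        assert (bias, lo, hi) == (0.5, 0.5, 0.5)

    def test_hand_computed_loa(self):
        bias, lo, hi = bland_altman([1.0, -1.0], [0.0, 0.0])
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * math.sqrt(2.0))
        assert lo == pytest.approx(-1.96 * math.sqrt(2.0))

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [1.0])


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_degenerate_variance_unequal_means(self):
        t, p = ttest([0.0, 0.0], [1.0, 1.0])
        assert math.isinf(t) and p == 0.0

    def test_textbook_pooled_formula(self):
        a, b = [1.0, 2, 3], [2.0, 3, 4]
        t, p = ttest(a, b)
        from scipy import stats

        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)


class TestFisherZ:
    def test_equal_correlations_p_one(self):
        assert fisher_z_test(0.9, 50, 0.9, 200) == pytest.approx(1.0)

    def test_clinical_contrast_from_formula(self):
        """High vs moderate correlation (0.97 vs 0.85 pattern) at n=100/267."""
        r1, n1, r2_, n2 = 0.97, 100, 0.85, 267
        z = (math.atanh(r1) - math.atanh(r2_)) / math.sqrt(
            1 / (n1 - 3) + 1 / (n2 - 3))
        from scipy.stats import norm

        expect = 2 * norm.sf(abs(z))
        assert fisher_z_test(r1, n1, r2_, n2) == pytest.approx(expect, abs=1e-12)
        assert fisher_z_test(r1, n1, r2_, n2) < 0.05

    def test_boundary_and_small_n(self):
        with pytest.raises(InsufficientDataError):
            fisher_z_test(1.0, 10, 0.5, 10)
        with pytest.raises(InsufficientDataError):
            fisher_z_test(0.5, 3, 0.5, 10)


def _per_scan(rng, n=40, namd_noise=0.1):
    truth = rng.uniform(1, 10, n)
    namd = rng.random(n) < 0.4
    noise = np.where(namd, namd_noise, 0.05)
    auto = truth + rng.normal(0, 1, n) * noise * truth
    return pd.DataFrame({
        "record_id": [f"r{i}" for i in range(n)],
        "dsc": rng.uniform(0.7, 1.0, n),
        "area_manual_mm2": truth,
        "area_auto_mm2": auto,
        "has_nAMD": namd,
    })


class TestReport:
    def test_strata_partition_and_invariants(self, rng):
        df = _per_scan(np.random.default_rng(5))
        rep = compute_report(df, n_folds=5)
        assert rep.strata["GA_only"]["n"] + rep.strata["GA_nAMD"]["n"] == len(df)
        assert rep.loa_mm2[0] <= rep.bias_mm2 <= rep.loa_mm2[1]
        assert rep.p_dsc is not None and rep.p_r2 is not None
        assert rep.p_r2_method == "fisher-z"

    def test_json_round_trip_fields(self, tmp_path, rng):
        rep = compute_report(_per_scan(np.random.default_rng(2)))
        rep.to_json(tmp_path / "r.json")
        import json

        data = json.loads((tmp_path / "r.json").read_text())
        assert set(data) >= {"r2", "bias_mm2", "loa_mm2", "strata", "per_scan"}
        assert len(data["per_scan"]) == len(rep.per_scan)

    def test_compare_r2_between_strata_wraps_fisher(self):
        df = _per_scan(np.random.default_rng(9))
        p = compare_r2_between_strata(df)
        assert 0.0 <= p <= 1.0


class TestCoalescence:
    def test_empty_masks(self):
        assert coalescence_diagnostic(_mask(np.zeros((4, 4))),
                                      _mask(np.zeros((4, 4)))) == (0, 0)

    def test_single_blob_each(self):
        g = np.zeros((5, 5))
        g[1:3, 1:3] = 1
        assert coalescence_diagnostic(_mask(g), _mask(g)) == (1, 1)

    def test_merged_versus_separate_foci(self):
        """Two 1-px foci separated by one background px vs their filled union."""
        manual = np.zeros((3, 5))
        manual[1, 1] = manual[1, 3] = 1
        auto = np.zeros((3, 5))
        auto[1, 1:4] = 1
        assert coalescence_diagnostic(_mask(auto), _mask(manual)) == (1, 2)

    def test_diagonal_counts_as_connected(self):
        g = np.zeros((4, 4))
        g[0, 0] = g[1, 1] = 1
        assert coalescence_diagnostic(_mask(g), _mask(g)) == (1, 1)


class TestCrossValidatePlumbing:
    def test_partition_and_no_leakage_micro(self, tiny_profile, tmp_path):
        """A one-epoch micro cross-validation: every scan predicted exactly
        once and no subject crosses a fold boundary."""
        params = SyntheticParams(device=tiny_profile, n_subjects=6,
                                 eyes_per_subject=1, visits_per_eye=2,
                                 speckle_sigma=0.1, namd_fraction=0.5, seed=4)
        records = generate_cohort(params, tmp_path / "c")
        rep = cross_validate(
            records,
            NetConfig(input_dims=tiny_profile.net_input_dims, levels=2,
                      base_channels=2),
            TrainConfig(epochs=1, batch_size=4, patience=1,
                        learning_rate=1e-3),
            n_folds=3, seed=0, profile=tiny_profile)
        assert sorted(rep.per_scan["record_id"]) == sorted(
            r.record_id for r in records)
        fold_by_subject = rep.per_scan.groupby("subject_id")["fold"].nunique()
        assert (fold_by_subject == 1).all()
        assert rep.n_folds == 3


class TestLongitudinal:
    def test_order_invariance_and_eye_integrity(self, tiny_profile, tmp_path):
        params = SyntheticParams(device=tiny_profile, n_subjects=1,
                                 eyes_per_subject=2, visits_per_eye=3,
                                 speckle_sigma=0.0, seed=2)
        records = generate_cohort(params, tmp_path / "c")
        od = [r for r in records if r.eye == "OD"]
        seg = SlabThresholdSegmenter()
        a = longitudinal_report(od, seg, tiny_profile)
        b = longitudinal_report(list(reversed(od)), seg, tiny_profile)
        pd.testing.assert_frame_equal(a, b)
        assert list(a["visit_index"]) == [0, 1, 2]
        with pytest.raises(IntegrityError):
            longitudinal_report(records, seg, tiny_profile)
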