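"""Coverage arithmetic, cumulative CV and minimum image numbers."""

import itertools

import numpy as np
import pytest

from biofilmquant.errors import DataError, ValidationError
from biofilmquant.quantification import (
    CoverageRecord,
    CvCurve,
    bootstrap_cv_envelope,
    coupon_coverage,
    cumulative_cv,
    field_coverage,
    min_image_number,
)
from biofilmquant.segmentation import segment_field

from conftest import make_field


def rec(pct, tile=0, aref=10000, coupon="C", valid=True):
    return CoverageRecord(
        coupon_id=coupon,
        tile_index=tile,
        area_px=int(round(pct / 100 * aref)),
        aref_px=aref,
        pixel_area_um2=0.486**2,
        valid=valid,
    )


def series(*pcts, aref=10000):
    return [rec(p, tile=i, aref=aref) for i, p in enumerate(pcts)]


class TestFieldCoverage:
    def test_empty_and_full_masks(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[0, 0] = 1  # avoid a degenerate histogram
        field = make_field(img)
        res = segment_field(field)
        assert field_coverage(res, field).coverage_pct == 0.0
        full = rec(100.0)
        assert full.coverage_pct == 100.0

    def test_direct_pixel_count_example(self):
        # 12288 kept px on a 1280x960 raster is exactly 1%
        r = CoverageRecord("C", 0, area_px=12288, aref_px=1228800, pixel_area_um2=0.486**2)
        assert r.coverage_pct == pytest.approx(1.0)

    def test_invalid_field_carries_no_coverage(self, small_field):
        field, _, _ = small_field
        r = field_coverage(None, field, valid=False, invalid_reason="blur")
        assert not r.valid
        assert r.coverage_pct is None

    def test_pipeline_estimate_matches_ground_truth_without_artefacts(self, small_field):
        # no blur, no artefacts: estimated coverage == truth within 0.1 pct points
        field, cell_mask, _ = small_field
        res = segment_field(field)
        r = field_coverage(res, field)
        truth_pct = cell_mask.mean() * 100
        assert r.coverage_pct == pytest.approx(truth_pct, abs=0.1)


class TestCouponCoverage:
    def test_equal_aref_pooled_equals_mean(self):
        s = coupon_coverage(series(1.0, 2.0, 3.0))
        assert s.pooled_pct == pytest.approx(2.0)
        assert s.mean_pct == pytest.approx(2.0)

    def test_single_valid_field(self):
        s = coupon_coverage([rec(5.0)])
        assert s.pooled_pct == pytest.approx(5.0)
        assert s.n_valid == 1

    def test_unequal_aref_pools_by_area(self):
        n = 10000
        records = [rec(1.0, tile=0, aref=n), rec(4.0, tile=1, aref=n // 2)]
        s = coupon_coverage(records)
        expected = (0.01 * n + 0.04 * n / 2) / (1.5 * n) * 100
        assert s.pooled_pct == pytest.approx(expected)
        assert expected == pytest.approx(2.0)

    def test_pooled_lies_between_field_extremes(self):
        rng = np.random.default_rng(0)
        pcts = rng.uniform(0.1, 9.0, size=20)
        s = coupon_coverage(series(*pcts))
        assert pcts.min() <= s.pooled_pct <= pcts.max()

    def test_no_valid_fields_is_an_error(self):
        with pytest.raises(DataError, match="no valid images"):
            coupon_coverage([rec(1.0, valid=False)])

    def test_invalid_fields_are_skipped(self):
        records = series(1.0, 2.0, 3.0)
        records[2].valid = False
        s = coupon_coverage(records)
        assert s.pooled_pct == pytest.approx(1.5)
        assert (s.n_valid, s.n_total) == (2, 3)


class TestCumulativeCv:
    def test_constant_series_has_zero_cv(self):
        curve = cumulative_cv(series(2.0, 2.0, 2.0, 2.0))
        np.testing.assert_allclose(curve.cv_pct, 0.0, atol=1e-9)

    def test_two_point_series_matches_direct_formula(self):
        curve = cumulative_cv(series(1.0, 3.0))
        # sample sd(1,3) = sqrt(2), mean 2 -> CV = sqrt(2)/2 * 100 = 70.71%
        assert curve.cv_pct[0] == pytest.approx(np.sqrt(2) / 2 * 100, abs=1e-9)
        assert curve.cv_pct[0] == pytest.approx(70.71, abs=0.01)

    def test_population_denominator_option(self):
        curve = cumulative_cv(series(1.0, 3.0), ddof=0)
        assert curve.cv_pct[0] == pytest.approx(50.0)

    def test_full_sample_cv_is_permutation_invariant(self):
        rng = np.random.default_rng(1)
        pcts = rng.uniform(0.5, 5.0, size=12)
        base = cumulative_cv(series(*pcts)).cv_pct[-1]
        for _ in range(5):
            shuffled = rng.permutation(pcts)
            assert cumulative_cv(series(*shuffled)).cv_pct[-1] == pytest.approx(base)

    def test_converges_to_population_cv(self):
        # gamma(k) has CV = 1/sqrt(k); k=16 -> 25%
        rng = np.random.default_rng(11)
        x = rng.gamma(16.0, 0.1, size=4000)
        curve = cumulative_cv(series(*x))
        assert curve.cv_pct[-1] == pytest.approx(25.0, abs=2.0)

    def test_all_zero_series_is_explicit_error(self):
        with pytest.raises(DataError, match="all zero"):
            cumulative_cv(series(0.0, 0.0, 0.0))

    def test_needs_two_valid_fields(self):
        with pytest.raises(DataError):
            cumulative_cv([rec(1.0)])


class TestMinImageNumber:
    def _curve(self, values, target=13.0):
        values = np.asarray(values, dtype=float)
        return CvCurve("C", k=np.arange(2, values.size + 2), cv_pct=values,
                       target_cv_pct=target)

    def test_sustained_crossing_at_105(self):
        # curve stays <= 13% exactly from k = 105 onward
        ks = np.arange(2, 121)
        values = np.where(ks < 105, 13.0 + (105 - ks) * 0.05, 13.0 - (ks - 104) * 0.01)
        assert min_image_number(self._curve(values), 13.0) == 105

    def test_monotone_curve_crossing_20_at_75(self):
        ks = np.arange(2, 111)
        values = 20.0 + (75.0 - ks) * 0.1  # strictly decreasing, hits 20 at k=75
        curve = self._curve(values, target=20.0)
        assert min_image_number(curve, 20.0, mode="sustained") == 75
        assert min_image_number(curve, 20.0, mode="first-crossing") == 75

    def test_spurious_early_dip_only_fools_first_crossing(self):
        ks = np.arange(2, 101)
        values = np.where(ks < 75, 25.0, 18.0)
        values[ks == 50] = 19.0  # transient dip below 20
        curve = self._curve(values, target=20.0)
        assert min_image_number(curve, 20.0, mode="first-crossing") == 50
        assert min_image_number(curve, 20.0, mode="sustained") == 75

    def test_unreached_target_returns_sentinel(self):
        assert min_image_number(self._curve([30.0, 28.0, 27.0]), 13.0) is None

    def test_non_positive_target_rejected(self):
        with pytest.raises(ValidationError):
            min_image_number(self._curve([10.0]), 0.0)


class TestBootstrapEnvelope:
    def test_constant_series_gives_zero_envelope(self):
        env = bootstrap_cv_envelope(series(2.0, 2.0, 2.0), n_permutations=50, seed=0)
        np.testing.assert_allclose(env.to_numpy(), 0.0, atol=1e-12)

    def test_median_at_full_n_equals_full_sample_cv(self):
        records = series(1.0, 2.0, 4.0, 5.0)
        env = bootstrap_cv_envelope(records, n_permutations=200, seed=1)
        full_cv = cumulative_cv(records).cv_pct[-1]
        assert env.loc[4, "cv_p50"] == pytest.approx(full_cv)
        assert env.loc[4, "cv_p5"] == pytest.approx(full_cv)
        assert env.loc[4, "cv_p95"] == pytest.approx(full_cv)

    def test_matches_exhaustive_enumeration_on_four_elements(self):
        """Oracle: enumerate all 24 orderings of (1,1,1,10) and compare
        the 5/95% envelope of CV_k against 10,000 Monte-Carlo orderings."""
        values = [1.0, 1.0, 1.0, 10.0]
        curves = []
        for perm in itertools.permutations(values):
            x = np.asarray(perm)
            ks = np.arange(2, 5)
            cv = [np.std(x[:k], ddof=1) / np.mean(x[:k]) * 100 for k in ks]
            curves.append(cv)
        exhaustive = np.asarray(curves)
        env = bootstrap_cv_envelope(series(*values), n_permutations=10000, seed=3,
                                    quantiles=(5.0, 95.0))
        for j, k in enumerate((2, 3, 4)):
            assert env.loc[k, "cv_p5"] == pytest.approx(
                np.percentile(exhaustive[:, j], 5), abs=1e-9
            )
            assert env.loc[k, "cv_p95"] == pytest.approx(
                np.percentile(exhaustive[:, j], 95), abs=1e-9
            )

    def test_requires_at_least_one_permutation(self):
        with pytest.raises(ValidationError):
            bootstrap_cv_envelope(series(1.0, 2.0), n_permutations=0)
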