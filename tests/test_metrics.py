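import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from voxdose import (
    AbsorbedDoseMap,
    CDVH,
    CohortDoseProfile,
    LesionDoseRecord,
    LesionMask,
    build_cdvh,
    compare_treatments,
    d50,
    extract_records,
    fit_lognormal,
    peak_dose,
    percent_difference,
)
from voxdose.errors import MissingLesionError, ValidationError

FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def dose_map(values, voxel=4.67):
    return AbsorbedDoseMap(np.asarray(values, dtype=float), voxel)


def mask_of(labels, voxel=4.67, pid="P000"):
    return LesionMask(pid, np.asarray(labels, dtype=np.int32), voxel)


def brute_force_peak(dose: np.ndarray, labels: np.ndarray, lesion_id: int) -> float:
    """Exhaustive scan over lesion voxels, explicit neighbour loop."""
    best, best_idx = -math.inf, None
    for idx in np.ndindex(dose.shape):
        if labels[idx] == lesion_id and dose[idx] > best:
            best, best_idx = dose[idx], idx
    samples = [dose[best_idx]]
    for off in FACE_OFFSETS:
        pos = tuple(b + o for b, o in zip(best_idx, off))
        if all(0 <= p < n for p, n in zip(pos, dose.shape)):
            samples.append(dose[pos])
    return sum(samples) / len(samples)


class TestPeakDose:
    def test_uniform_dose_returns_the_uniform_value(self):
        labels = np.zeros((5, 5, 5), dtype=int)
        labels[1:4, 1:4, 1:4] = 1
        assert peak_dose(dose_map(np.full((5, 5, 5), 3.3)), mask_of(labels), 1) == (
            pytest.approx(3.3)
        )

    def test_isolated_hot_voxel_is_averaged_down_sevenfold(self):
        values = np.zeros((5, 5, 5))
        values[2, 2, 2] = 7.0
        labels = np.zeros((5, 5, 5), dtype=int)
        labels[2, 2, 2] = 1
        assert peak_dose(dose_map(values), mask_of(labels), 1) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_maps(self, rng):
        values = rng.random((7, 7, 7)) * 20.0
        labels = (rng.random((7, 7, 7)) < 0.4).astype(int)
        labels[3, 3, 3] = 1  # ensure non-empty
        result = peak_dose(dose_map(values), mask_of(labels), 1)
        assert result == pytest.approx(brute_force_peak(values, labels, 1), rel=1e-12)

    def test_edge_maximum_drops_off_volume_neighbours(self):
        values = np.zeros((3, 3, 3))
        values[0, 1, 1] = 5.0
        labels = np.ones((3, 3, 3), dtype=int)
        # 5 in-bounds neighbours (all zero) + centre -> 5/6
        assert peak_dose(dose_map(values), mask_of(labels), 1) == pytest.approx(5.0 / 6)

    def test_peak_bounded_by_lesion_maximum(self, rng):
        values = rng.random((6, 6, 6)) * 50.0
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[2:5, 2:5, 2:5] = 1
        pk = peak_dose(dose_map(values), mask_of(labels), 1)
        lesion_max = values[labels == 1].max()
        assert lesion_max / 7.0 <= pk <= lesion_max

    def test_missing_lesion_errors(self):
        with pytest.raises(MissingLesionError):
            peak_dose(dose_map(np.zeros((3, 3, 3))), mask_of(np.zeros((3, 3, 3), int)), 2)

    def test_records_report_mean_and_volume(self):
        values = np.zeros((4, 4, 4))
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, 0, :2] = 1
        values[0, 0, 0], values[0, 0, 1] = 2.0, 4.0
        (record,) = extract_records(dose_map(values, voxel=10.0), mask_of(labels, voxel=10.0))
        assert record.mean_dose_Gy == pytest.approx(3.0)
        assert record.volume_ml == pytest.approx(2.0)  # two 1 cm^3 voxels


class TestLognormalFit:
    def test_degenerate_equal_doses(self):
        mu, sigma = fit_lognormal([5.0, 5.0, 5.0])
        assert mu == pytest.approx(math.log(5.0))
        assert sigma == 0.0

    def test_two_point_logs(self):
        mu, sigma = fit_lognormal([math.e, math.e**3])
        assert mu == pytest.approx(2.0)
        assert sigma == pytest.approx(1.0)

    def test_recovers_simulation_truth_within_three_standard_errors(self, rng):
        true_mu, true_sigma, n = 2.8, 0.7, 379
        doses = rng.lognormal(true_mu, true_sigma, size=n)
        mu, sigma = fit_lognormal(doses)
        assert abs(mu - true_mu) < 3 * true_sigma / math.sqrt(n)
        assert abs(sigma - true_sigma) < 3 * true_sigma / math.sqrt(2 * n)

    def test_agrees_with_scipy_mle(self, rng):
        doses = rng.lognormal(1.0, 0.5, size=200)
        mu, sigma = fit_lognormal(doses)
        shape, loc, scale = stats.lognorm.fit(doses, floc=0)
        assert loc == 0
        assert mu == pytest.approx(math.log(scale), rel=1e-6)
        assert sigma == pytest.approx(shape, rel=1e-6)

    def test_nonpositive_doses_rejected(self):
        with pytest.raises(ValidationError):
            fit_lognormal([1.0, 0.0])
        with pytest.raises(ValidationError):
            fit_lognormal([3.0])


def uniform_lesion(shape, dose_value, voxel=10.0, pid="P000"):
    values = np.full(shape, float(dose_value))
    labels = np.ones(shape, dtype=int)
    return dose_map(values, voxel), mask_of(labels, voxel, pid)


class TestCDVH:
    def test_uniform_dose_is_a_step(self):
        cdvh = build_cdvh([uniform_lesion((2, 2, 2), 10.0)])
        assert cdvh.covered_fraction_at(0.0) == 1.0
        assert cdvh.covered_fraction_at(10.0) == 1.0
        assert cdvh.covered_fraction_at(10.0001) == 0.0
        assert d50(cdvh) == pytest.approx(10.0)

    def test_two_equal_volume_lesions(self):
        items = [
            uniform_lesion((2, 2, 2), 10.0, pid="P000"),
            uniform_lesion((2, 2, 2), 20.0, pid="P001"),
        ]
        cdvh = build_cdvh(items)
        assert cdvh.covered_fraction_at(5.0) == 1.0
        assert cdvh.covered_fraction_at(15.0) == 0.5
        assert cdvh.covered_fraction_at(25.0) == 0.0
        # half the volume reaches 20 Gy, so the D50 step convention gives 20
        assert d50(cdvh) == pytest.approx(20.0)

    def test_curve_monotone_and_anchored(self, rng):
        values = rng.random((6, 6, 6)) * 30.0
        labels = (rng.random((6, 6, 6)) < 0.5).astype(int)
        labels[0, 0, 0] = 1
        cdvh = build_cdvh([(dose_map(values), mask_of(labels))])
        assert np.all(np.diff(cdvh.covered_fraction) <= 1e-15)
        assert cdvh.covered_fraction[0] == 1.0
        assert cdvh.covered_fraction[-1] == 0.0

    def test_total_volume_sums_per_patient_lesions(self):
        items = [
            uniform_lesion((2, 2, 2), 5.0, voxel=10.0, pid="P000"),  # 8 ml
            uniform_lesion((3, 1, 1), 7.0, voxel=20.0, pid="P001"),  # 24 ml
        ]
        assert build_cdvh(items).total_volume_ml == pytest.approx(32.0)

    @settings(derandomize=True, max_examples=25)
    @given(doses=st.lists(st.floats(0.0, 100.0), min_size=1, max_size=40))
    def test_d50_matches_sort_oracle(self, doses):
        values = np.asarray(doses).reshape(-1, 1, 1)
        labels = np.ones_like(values, dtype=int)
        cdvh = build_cdvh([(dose_map(values, 10.0), mask_of(labels, 10.0))])
        arr = np.asarray(doses)
        candidates = sorted(set(doses), reverse=True)
        oracle = max(
            (d for d in candidates if np.mean(arr >= d) >= 0.5), default=min(doses)
        )
        assert d50(cdvh) == pytest.approx(oracle)

    def test_covered_fraction_matches_count_oracle(self, rng):
        doses = rng.random(50) * 40.0
        values = doses.reshape(-1, 1, 1)
        labels = np.ones_like(values, dtype=int)
        cdvh = build_cdvh([(dose_map(values, 10.0), mask_of(labels, 10.0))])
        for threshold in [0.0, 10.0, 25.0, 39.0, 41.0]:
            assert cdvh.covered_fraction_at(threshold) == pytest.approx(
                np.mean(doses >= threshold)
            )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            build_cdvh([(dose_map(np.zeros((2, 2, 2))), mask_of(np.zeros((2, 2, 2), int)))])


def record(pid, lid, peak, mean=1.0, vol=1.0):
    return LesionDoseRecord(pid, lid, peak, mean, vol)


class TestCompareTreatments:
    def plans_with_medians(self, medians):
        # single-lesion cohort: the median is the single record's peak
        return {
            plan: [record("P000", 1, m)] for plan, m in medians.items()
        }

    @pytest.mark.parametrize(
        "target_median, expected",
        [(10.4, -41), (2.7, -85), (6.3, -64)],
    )
    def test_percent_difference_from_printed_medians(self, target_median, expected):
        table = compare_treatments(
            self.plans_with_medians({"delivered": 17.7, "target": target_median}),
            "delivered",
        )
        row = table.set_index("plan").loc["target"]
        assert row["pct_diff_rounded"] == expected

    def test_identical_profiles_differ_by_zero(self):
        table = compare_treatments(
            self.plans_with_medians({"delivered": 17.7, "clone": 17.7}), "delivered"
        )
        assert table.set_index("plan").loc["clone", "pct_diff_rounded"] == 0

    def test_unrounded_difference_uses_unrounded_medians(self):
        assert percent_difference(21.8, 17.7) == pytest.approx(23.1638, abs=1e-3)

    def test_mismatched_lesion_sets_rejected(self):
        plans = {
            "delivered": [record("P000", 1, 5.0)],
            "target": [record("P000", 2, 5.0)],
        }
        with pytest.raises(ValidationError):
            compare_treatments(plans, "delivered")

    def test_profile_statistic_selection(self):
        records = [record("P", i, float(i), mean=2.0) for i in (1, 2, 3)]
        prof_peak = CohortDoseProfile.from_records(records, statistic="peak")
        prof_mean = CohortDoseProfile.from_records(records, statistic="mean")
        assert prof_peak.lognormal_sigma > 0
        assert prof_mean.lognormal_sigma == pytest.approx(0.0)
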