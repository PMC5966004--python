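import dataclasses

import numpy as np
import pytest

from voxdose import (
    IntegrationSettings,
    SyntheticCohortConfig,
    build_reference_kernels,
    convolve_dose,
    generate_cohort,
    ground_truth_dose,
    peak_dose,
)
from voxdose.cumulation import integrate_series
from voxdose.errors import PackingError, ParameterError
from voxdose.synthetic import exact_cumulated_map
from voxdose.units import DAY_S, LN2


def one_lesion_config(**overrides):
    base = dict(
        n_patients=1,
        grid_shape=(24, 24, 24),
        mean_lesions_per_patient=1.0,
        lesion_count_bounds=(1, 1),
        semi_axis_range_vox=(3.0, 3.0),  # sphere
        background_fraction=0.0,
        noise_cov=0.0,
        seed=11,
    )
    base.update(overrides)
    return SyntheticCohortConfig(**base)


class TestGeneration:
    def test_same_seed_is_bit_identical(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.series.maps, db.series.maps)
            np.testing.assert_array_equal(da.mask.labels, db.mask.labels)
        c = generate_cohort(dataclasses.replace(small_config, seed=small_config.seed + 1))
        assert any(
            not np.array_equal(da.series.maps, dc.series.maps) for da, dc in zip(a, c)
        )

    def test_single_lesion_voxels_follow_the_closed_form_curve(self):
        cfg = one_lesion_config()
        (ds,) = generate_cohort(cfg)
        lesion = ds.lesions[0]
        inside = ds.mask.labels == 1
        lam_h = LN2 / cfg.effective_half_life_d / 24.0
        for k, t in enumerate(cfg.schedule_h):
            if t < cfg.time_to_peak_h:
                expected = lesion.amplitude_MBq_per_voxel * t / cfg.time_to_peak_h
            else:
                expected = lesion.amplitude_MBq_per_voxel * np.exp(
                    -lam_h * (t - cfg.time_to_peak_h)
                )
            np.testing.assert_allclose(ds.series.maps[k][inside], expected, rtol=1e-12)
            assert np.all(ds.series.maps[k][~inside] == 0.0)

    def test_activity_bookkeeping_at_72h(self, small_config):
        """Whole-volume activity at the last scan equals the analytic value:
        uptake x administered x washout factor (no noise)."""
        for ds in generate_cohort(small_config):
            cfg = ds.config
            lam_h = LN2 / (cfg.effective_half_life_d * 24.0)
            expected = (
                cfg.uptake_fraction
                * cfg.administered_MBq
                * np.exp(-lam_h * (72.0 - cfg.time_to_peak_h))
            )
            assert ds.series.maps[-1].sum() == pytest.approx(expected, rel=0.005)

    def test_peak_amplitude_normalisation(self, small_config):
        for ds in generate_cohort(small_config):
            cfg = ds.config
            lesion_total = sum(
                les.amplitude_MBq_per_voxel * les.n_voxels for les in ds.lesions
            )
            bg_total = ds.background_MBq_per_voxel * (ds.mask.labels == 0).sum()
            assert lesion_total + bg_total == pytest.approx(
                cfg.uptake_fraction * cfg.administered_MBq, rel=1e-9
            )
            assert lesion_total == pytest.approx(
                (1 - cfg.background_fraction) * cfg.uptake_fraction * cfg.administered_MBq,
                rel=1e-9,
            )

    def test_lesions_do_not_overlap_and_are_labelled_consecutively(self, small_cohort):
        for ds in small_cohort:
            ids = sorted(set(ds.mask.labels.ravel()) - {0})
            assert ids == [les.lesion_id for les in ds.lesions]
            for les in ds.lesions:
                assert (ds.mask.labels == les.lesion_id).sum() == les.n_voxels

    def test_infeasible_packing_raises(self):
        cfg = SyntheticCohortConfig(
            n_patients=1,
            grid_shape=(12, 12, 12),
            mean_lesions_per_patient=30.0,
            lesion_count_bounds=(30, 40),
            semi_axis_range_vox=(3.0, 4.0),
            seed=0,
        )
        with pytest.raises(PackingError):
            generate_cohort(cfg)

    def test_noise_is_multiplicative_and_seeded(self):
        cfg = one_lesion_config(noise_cov=0.1)
        (a,) = generate_cohort(cfg)
        (b,) = generate_cohort(cfg)
        np.testing.assert_array_equal(a.series.maps, b.series.maps)
        (clean,) = generate_cohort(one_lesion_config())
        assert not np.array_equal(a.series.maps, clean.series.maps)
        assert np.all(a.series.maps >= 0)


class TestGroundTruth:
    def test_point_like_lesion_matches_pipeline_within_sampling_tolerance(self):
        cfg = one_lesion_config(semi_axis_range_vox=(0.9, 0.9))  # single voxel
        (ds,) = generate_cohort(cfg)
        assert ds.lesions[0].n_voxels == 1
        kernel = build_reference_kernels(size=7)["186Re"]
        truth = ground_truth_dose(ds, kernel)[1]
        cumulated = integrate_series(
            ds.series, lambda_eff_per_s=cfg.lambda_eff_per_s
        )
        pipeline = peak_dose(convolve_dose(cumulated, kernel), ds.mask, 1)
        assert pipeline == pytest.approx(truth, rel=0.02)

    def test_doubled_administration_doubles_ground_truth(self):
        cfg = one_lesion_config()
        (ds1,) = generate_cohort(cfg)
        (ds2,) = generate_cohort(
            dataclasses.replace(cfg, administered_MBq=2 * cfg.administered_MBq)
        )
        kernel = build_reference_kernels(size=7)["186Re"]
        t1 = ground_truth_dose(ds1, kernel)[1]
        t2 = ground_truth_dose(ds2, kernel)[1]
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_exact_cumulated_map_closed_form(self):
        cfg = one_lesion_config()
        (ds,) = generate_cohort(cfg)
        cmap = exact_cumulated_map(ds)
        tp_s = cfg.time_to_peak_h * 3600.0
        unit = tp_s / 2 + 1.0 / cfg.lambda_eff_per_s
        inside = ds.mask.labels == 1
        np.testing.assert_allclose(
            cmap.values[inside], ds.lesions[0].amplitude_MBq_per_voxel * unit, rtol=1e-12
        )

    def test_refuses_noisy_datasets(self):
        (ds,) = generate_cohort(one_lesion_config(noise_cov=0.05))
        kernel = build_reference_kernels(size=7)["186Re"]
        with pytest.raises(ParameterError):
            ground_truth_dose(ds, kernel)

    def test_pipeline_agrees_with_ground_truth_across_a_cohort(self, small_cohort, registry):
        """With the rise peaking at the first scan, trapezoid head + exponential
        phases + fitted tail integrate the generator's kinetics exactly, so the
        pipeline should track the analytic oracle closely."""
        kernel = build_reference_kernels(size=9)["186Re"]
        entry = registry["186Re-HEDP"]
        for ds in small_cohort:
            truth = ground_truth_dose(ds, kernel)
            cumulated = integrate_series(
                ds.series,
                IntegrationSettings(),
                lambda_eff_per_s=entry.lambda_eff_per_s,
                lambda_phys_per_s=entry.lambda_phys_per_s,
            )
            dose_map = convolve_dose(cumulated, kernel)
            for lesion_id, expected in truth.items():
                assert peak_dose(dose_map, ds.mask, lesion_id) == pytest.approx(
                    expected, rel=0.02
                )

    def test_lognormal_amplitudes_recovered_in_cohort_doses(self):
        """With uniform lesion sizes the peak doses inherit the amplitude
        distribution, so the fitted sigma tracks the configured value."""
        from voxdose import CohortDoseProfile, extract_records

        cfg = SyntheticCohortConfig(
            n_patients=6,
            grid_shape=(40, 40, 40),
            mean_lesions_per_patient=12.0,
            lesion_count_bounds=(8, 16),
            semi_axis_range_vox=(2.5, 2.5),
            amplitude_sigma_log=0.7,
            background_fraction=0.0,
            seed=42,
        )
        cohort = generate_cohort(cfg)
        kernel = build_reference_kernels(size=7)["186Re"]
        records = []
        for ds in cohort:
            cumulated = integrate_series(ds.series, lambda_eff_per_s=cfg.lambda_eff_per_s)
            records.extend(extract_records(convolve_dose(cumulated, kernel), ds.mask))
        profile = CohortDoseProfile.from_records(records)
        n = len(records)
        assert n >= 60
        assert abs(profile.lognormal_sigma - 0.7) < 3 * 0.7 / np.sqrt(2 * n)
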