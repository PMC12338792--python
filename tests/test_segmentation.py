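import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skinoct as sk
from skinoct.errors import SegmentationError
from skinoct.preprocess import CalibrationReference
from skinoct.segmentation import (
    detect_muscle_boundary,
    detect_peaks,
    measure_thickness,
    segment_column,
)

from conftest import analyze
from oracles import brute_peaks


class TestDetectPeaks:
    def test_two_clean_spikes_found_in_depth_order(self):
        col = np.full(40, -5.0)
        col[12] = 2.0
        col[18] = 1.0
        assert detect_peaks(col, noise_floor=-3.0, prominence=1.0) == [12, 18]

    def test_constant_profile_has_no_peaks(self):
        assert detect_peaks(np.zeros(30), noise_floor=-1.0, prominence=0.5) == []

    def test_spike_below_noise_floor_excluded(self):
        col = np.full(30, -5.0)
        col[10] = -4.0
        assert detect_peaks(col, noise_floor=-3.0, prominence=0.5) == []

    def test_plateau_reports_shallowest_index(self):
        col = np.full(30, 0.0)
        col[10:13] = 2.0
        assert detect_peaks(col, noise_floor=-1.0, prominence=1.0) == [10]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        prominence=st.sampled_from([0.3, 0.8, 1.5]),
        floor=st.sampled_from([-2.0, 0.0, 0.5]),
    )
    def test_matches_brute_force_prominence_scan(self, seed, prominence, floor):
        rng = np.random.default_rng(seed)
        # quantized values produce plateaus and prominence ties on purpose
        col = np.round(rng.normal(size=50) * 2) / 2
        assert detect_peaks(col, floor, prominence) == brute_peaks(
            col, floor, prominence
        )


class TestMuscleBoundary:
    def test_noiseless_boundary_within_one_pixel_of_truth(self, noiseless_phantom):
        spec, vol, truth, cal = noiseless_phantom
        col = vol.intensity[:, 0, 0].astype(float)
        surface = detect_peaks(col, cal.air_mean, cal.prominence_threshold)[0]
        idx = detect_muscle_boundary(
            col, surface, cal.muscle_mean, cal.prominence_threshold
        )
        truth_px = truth.muscle_depth[0, 0] / spec.axial_pitch
        assert abs(idx - truth_px) <= 1

    def test_profile_always_above_threshold_has_no_boundary(self):
        col = np.full(50, 1.0)
        col[5] = 3.0
        assert detect_muscle_boundary(col, 5, muscle_mean=-10.0, descent=0.5) is None

    def test_search_skips_the_dark_trough_below_the_surface_peak(self):
        # a dip right after the surface peak sits below the muscle mean but
        # above (peak - descent); it must not be mistaken for muscle
        col = np.full(60, 0.0)
        col[10] = 5.0
        col[11] = 4.6  # trough below muscle_mean but on the peak flank
        col[12:40] = 4.8
        col[40:] = 4.0
        idx = detect_muscle_boundary(col, 10, muscle_mean=4.7, descent=0.5)
        assert idx == 40


class TestSegmentColumn:
    def test_noiseless_phantom_landmarks_within_one_pixel(self, noiseless_phantom):
        spec, vol, truth, cal = noiseless_phantom
        col = vol.intensity[:, 3, 0].astype(float)
        profile = segment_column(col, cal)
        assert profile.valid
        pitch = spec.axial_pitch
        assert abs(profile.surface_idx - truth.surface_depth[3, 0] / pitch) <= 1
        assert abs(profile.dej_idx - truth.dej_depth[3, 0] / pitch) <= 1
        assert abs(profile.muscle_idx - truth.muscle_depth[3, 0] / pitch) <= 1

    def test_single_peak_column_is_invalid(self):
        cal = CalibrationReference(-23.0, -19.0, 1.0)
        col = np.full(80, -23.0)
        col[20] = 0.0
        col[21:60] = -5.0
        profile = segment_column(col, cal)
        assert profile.dej_idx is None and not profile.valid

    def test_shift_equivariance_of_all_detection_rules(self, noiseless_phantom):
        """Adding a constant to the log intensities and both thresholds
        leaves every landmark unchanged."""
        spec, vol, _, cal = noiseless_phantom
        col = vol.intensity[:, 7, 1].astype(float)
        shifted_cal = CalibrationReference(
            cal.air_mean + 11.0, cal.muscle_mean + 11.0, cal.prominence_threshold
        )
        assert segment_column(col, cal) == segment_column(col + 11.0, shifted_cal)


class TestMeasureThickness:
    def test_thickness_arithmetic(self):
        profiles = [sk.BoundaryProfile(10, 20, 110, True)]
        res = measure_thickness(profiles, axial_pitch=4.0)
        assert res.volume_mean == pytest.approx(400.0)

    def test_invalid_columns_excluded_from_mean_but_counted(self):
        profiles = [
            sk.BoundaryProfile(10, 20, 110, True),
            sk.BoundaryProfile(10, None, None, False),
        ]
        res = measure_thickness(profiles, 4.0)
        assert (res.n_valid, res.n_total) == (1, 2)
        assert res.volume_mean == pytest.approx(400.0)

    def test_all_invalid_raises_segmentation_error(self):
        with pytest.raises(SegmentationError):
            measure_thickness([sk.BoundaryProfile(None, None, None, False)], 4.0)

    def test_refractive_index_divides_optical_path(self):
        profiles = [sk.BoundaryProfile(0, 5, 100, True)]
        a = measure_thickness(profiles, 4.0, refractive_index=1.0)
        b = measure_thickness(profiles, 4.0, refractive_index=1.4)
        assert b.volume_mean == pytest.approx(a.volume_mean / 1.4)

    def test_noiseless_volume_recovers_flat_thickness_everywhere(
        self, noiseless_phantom
    ):
        spec, vol, truth, cal = noiseless_phantom
        thickness, _, profiles = analyze(vol, cal, trim=2)
        assert all(p.valid for p in profiles)
        true_um = truth.skin_thickness[0, 0]
        assert np.abs(thickness.per_ascan - true_um).max() <= spec.axial_pitch

    def test_thicker_dermis_measures_thicker_by_the_same_pixels(self):
        cals = {}
        means = {}
        for extra_px in (0, 5):
            spec = sk.default_phantom(
                30.0,
                dermis_thickness=400.0 + 4.0 * extra_px,
                speckle_shape=None,
                thickness_jitter=0.0,
                seed=2,
                n_ascans_per_bscan=60,
                n_bscans=2,
            )
            vol, _ = sk.generate_volume(spec)
            cal = sk.calibrate(
                [(vol, sk.reference_annotations(spec, "v"))], prominence_value=0.9
            )
            thickness, _, _ = analyze(vol, cal, trim=1)
            means[extra_px] = thickness.volume_mean
        assert means[5] - means[0] == pytest.approx(5 * 4.0, abs=4.0)
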