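"""Stress-fiber profiling: peak detection against a brute-force oracle,
reference statistics, densities and intensity ratios."""

import numpy as np
import pytest

from epimech.fibers import (ControlReference, LineProfile, PeakSet,
                            build_control_reference, detect_peaks,
                            extract_profile, local_maxima, peak_density,
                            relative_intensity)
from epimech.synth import ImageScene


def brute_force_peaks(positions, values, threshold, min_sep):
    """Independent oracle: exhaustive scan for local maxima (strict rise
    left, non-strict fall right), height >= threshold, greedy separation
    keeping the higher peak (leftmost on ties)."""
    cand = [i for i in range(1, len(values) - 1)
            if values[i - 1] < values[i] >= values[i + 1]
            and values[i] >= threshold]
    cand.sort(key=lambda i: (-values[i], positions[i]))
    accepted = []
    for i in cand:
        if all(abs(positions[i] - positions[j]) >= min_sep for j in accepted):
            accepted.append(i)
    return sorted(accepted, key=lambda i: positions[i])


def make_profile(values, spacing_um=0.25):
    values = np.asarray(values, dtype=float)
    return LineProfile(positions_um=np.arange(values.size) * spacing_um,
                       intensity=values, cell_id=1)


def bumpy_profile(n_bumps=5, height=100.0, baseline=10.0, gap=8):
    values = np.full(n_bumps * gap + gap, baseline)
    for k in range(n_bumps):
        values[gap // 2 + k * gap] = height
    return make_profile(values)


class TestDetectPeaks:
    def test_flat_profile_has_no_peaks(self):
        ref = ControlReference(100.0, 10.0, 5)
        assert len(detect_peaks(make_profile(np.full(50, 7.0)), ref)) == 0

    @pytest.mark.parametrize("ref_mean, ref_sd, expected", [
        (80.0, 20.0, 5),    # threshold 60 < bump height 100
        (150.0, 20.0, 0),   # threshold 130 > bump height
    ])
    def test_threshold_rule_on_bump_train(self, ref_mean, ref_sd, expected):
        prof = bumpy_profile()
        ref = ControlReference(ref_mean, ref_sd, 10)
        peaks = detect_peaks(prof, ref)
        oracle = brute_force_peaks(prof.positions_um, prof.intensity,
                                   ref_mean - ref_sd, 0.5)
        assert len(peaks) == len(oracle) == expected

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(42)
        ref = ControlReference(60.0, 15.0, 20)
        for _ in range(300):
            n = int(rng.integers(5, 200))
            values = rng.uniform(0, 100, n)
            if rng.random() < 0.3:     # inject plateaus
                idx = rng.integers(1, n - 1)
                values[idx] = values[idx - 1]
            prof = make_profile(values)
            got = detect_peaks(prof, ref)
            want = brute_force_peaks(prof.positions_um, prof.intensity,
                                     ref.threshold, 0.5)
            np.testing.assert_array_equal(got.peak_positions_um,
                                          prof.positions_um[want])

    def test_density_invariant_under_joint_rescaling(self):
        prof = bumpy_profile()
        ref = ControlReference(80.0, 20.0, 10)
        scaled = make_profile(prof.intensity * 3.5)
        ref_scaled = ControlReference(80.0 * 3.5, 20.0 * 3.5, 10)
        d1 = peak_density(detect_peaks(prof, ref), prof)
        d2 = peak_density(detect_peaks(scaled, ref_scaled), scaled)
        assert d1 == pytest.approx(d2)


class TestControlReference:
    def test_constant_peaks_give_zero_sd(self):
        profs = [bumpy_profile(height=100.0) for _ in range(3)]
        ref = build_control_reference(profs)
        assert ref.mean_peak_intensity == pytest.approx(100.0)
        assert ref.sd_peak_intensity == pytest.approx(0.0)

    def test_two_height_sample_sd(self):
        # oracle: sample SD of {80, 120} is 28.284
        p1 = make_profile([0, 80, 0])
        p2 = make_profile([0, 120, 0])
        ref = build_control_reference([p1, p2])
        assert ref.mean_peak_intensity == pytest.approx(100.0)
        assert ref.sd_peak_intensity == pytest.approx(28.284, abs=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_control_reference([])

    def test_maximaless_profiles_rejected(self):
        flat = [make_profile(np.full(20, 5.0)) for _ in range(2)]
        with pytest.raises(ValueError):
            build_control_reference(flat)


class TestPeakDensity:
    def test_six_peaks_over_ten_microns(self):
        prof = make_profile(np.zeros(41), spacing_um=0.25)  # 10 um line
        peaks = PeakSet(np.linspace(0, 9, 6), np.full(6, 50.0), 10.0)
        assert peak_density(peaks, prof) == pytest.approx(0.6)

    def test_empty_peakset_gives_zero(self):
        prof = make_profile(np.zeros(41))
        empty = PeakSet(np.array([]), np.array([]), 10.0)
        assert peak_density(empty, prof) == 0.0

    def test_zero_length_profile_rejected(self):
        prof = LineProfile(np.array([0.0, 0.25]), np.array([1.0, 1.0]), 1)
        prof.positions_um = np.array([0.0])
        prof.intensity = np.array([1.0])
        with pytest.raises(ValueError):
            peak_density(PeakSet(np.array([]), np.array([]), 0.0), prof)


def block_scene(width=64, height=48, n_fibers=5, intensity=100.0):
    """Hand-built one-cell scene with vertical fibers for profile tests."""
    image = np.zeros((height, width))
    labels = np.zeros((height, width), dtype=np.int32)
    labels[4:-4, 4:-4] = 1
    cols = [12 + 8 * k for k in range(n_fibers)]
    for c in cols:
        image[10:-10, c] = intensity
    return ImageScene(image=image, labels=labels, genotype={1: "control"},
                      tricellular_points=[], calibration=0.25), cols


class TestExtractProfile:
    def test_vertical_fibers_yield_matching_maxima(self):
        scene, cols = block_scene(n_fibers=5)
        prof = extract_profile(scene, 1)
        assert len(local_maxima(prof.intensity)) == 5

    def test_uniform_cell_gives_flat_profile(self):
        scene, _ = block_scene(n_fibers=0)
        scene.image[scene.labels == 1] = 42.0
        prof = extract_profile(scene, 1)
        interior = prof.intensity[2:-2]
        np.testing.assert_allclose(interior, 42.0)

    def test_profile_length_matches_geometric_chord(self):
        scene, _ = block_scene()
        prof = extract_profile(scene, 1, cortical_margin_um=1.0)
        # geometric oracle: width of the eroded cell along the chord row
        margin_px = 4
        interior_cols = np.arange(4 + margin_px, scene.labels.shape[1] - 4 - margin_px)
        chord_um = (interior_cols[-1] - interior_cols[0]) * scene.calibration
        assert prof.length_um == pytest.approx(chord_um, abs=scene.calibration)

    def test_missing_cell_rejected(self):
        scene, _ = block_scene()
        with pytest.raises(ValueError):
            extract_profile(scene, 99)

    def test_degenerate_cell_rejected(self):
        scene, _ = block_scene()
        with pytest.raises(ValueError):
            extract_profile(scene, 1, cortical_margin_um=10.0)


class TestRelativeIntensity:
    def test_identical_groups_give_unit_ratio(self, mosaic_scene):
        scene, truth = mosaic_scene
        ctrl = scene.cells_of("control")
        half = len(ctrl) // 2
        r = relative_intensity(scene, ctrl[:half], ctrl[half:],
                               "fiber-region", truth=truth)
        assert r == pytest.approx(1.0, rel=1e-9)

    def test_mutant_factin_reduced_sixty_percent(self, mosaic_scene):
        scene, truth = mosaic_scene
        r = relative_intensity(scene, scene.cells_of("mutant"),
                               scene.cells_of("control"),
                               "fiber-region", truth=truth)
        assert r == pytest.approx(0.40, rel=1e-6)

    def test_mutant_myosin_reduced_forty_percent(self, noiseless_config):
        from epimech.synth import generate_scene
        scene, truth = generate_scene(noiseless_config, "mutant", 16, seed=2,
                                      channel="myosin")
        r = relative_intensity(scene, scene.cells_of("mutant"),
                               scene.cells_of("control"),
                               "fiber-region", truth=truth)
        assert r == pytest.approx(0.60, rel=1e-6)

    def test_empty_group_rejected(self, mosaic_scene):
        scene, truth = mosaic_scene
        with pytest.raises(ValueError):
            relative_intensity(scene, [], scene.cells_of("control"))

    def test_noiseless_detected_counts_equal_truth(self, control_scene):
        scene, truth = control_scene
        profiles = {c: extract_profile(scene, c) for c in scene.cell_ids}
        ref = build_control_reference(list(profiles.values()))
        for cid, prof in profiles.items():
            n_crossing = sum(
                1 for f in truth.fibers if f.cell_id == cid)
            assert len(detect_peaks(prof, ref)) == n_crossing
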