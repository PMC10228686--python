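"""Line-profile extraction, derivatives and transition metrics."""

import numpy as np
import pytest

from nervebed import epithelium as epi
from nervebed import pipeline
from nervebed import synthetic as syn


def triangle_wave(n_periods=6, half=10, slope=3.0):
    """Piecewise-linear wave of slope +-s; one period = rise + fall."""
    rise = np.arange(half + 1) * slope
    fall = rise[::-1]
    one = np.concatenate([rise[:-1], fall[:-1]])
    return np.tile(one, n_periods)


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        out = epi.preprocess(np.full((10, 10), 42.0))
        assert (out == 0).all()

    def test_two_level_image_rescales_to_full_range(self):
        img = np.where(np.eye(8) > 0, 20.0, 10.0)
        out = epi.preprocess(img, epi.PreprocessSpec(gaussian_sigma_px=0))
        assert set(np.unique(out)) == {0.0, 255.0}

    def test_zero_sigma_is_identity_after_rescale(self, rng):
        img = rng.random((12, 12))
        a = epi.preprocess(img, epi.PreprocessSpec(gaussian_sigma_px=0))
        expected = (img - img.min()) / np.ptp(img) * 255
        np.testing.assert_allclose(a, expected)


class TestExtractProfiles:
    def test_default_scheme_yields_ten_profiles(self, rng):
        ps = epi.extract_profiles(rng.random((100, 80)))
        assert ps.n_profiles == 10
        assert sum(p.axis == "row" for p in ps.profiles) == 5
        assert sum(p.axis == "column" for p in ps.profiles) == 5

    def test_coordinates_evenly_spaced_excluding_borders(self):
        assert epi.profile_coords(600) == [100, 200, 300, 400, 500]

    def test_transposition_swaps_row_and_column_profiles(self, rng):
        img = rng.random((60, 60))
        a = epi.extract_profiles(img)
        b = epi.extract_profiles(img.T)
        rows_a = sorted((p.coord, tuple(p.values)) for p in a.profiles if p.axis == "row")
        cols_b = sorted((p.coord, tuple(p.values)) for p in b.profiles if p.axis == "column")
        assert rows_a == cols_b

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            epi.extract_profiles(np.zeros((4, 100)))


class TestFirstDerivative:
    def test_constant_profile_derivative_is_zero(self):
        assert (epi.first_derivative(np.full(10, 3.0)) == 0).all()

    def test_linear_ramp_has_unit_slope_everywhere(self):
        d = epi.first_derivative(np.array([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(d, 1.0)

    def test_sine_derivative_amplitude_approaches_closed_form(self):
        a, period = 5.0, 200.0
        x = np.arange(2000)
        d = epi.first_derivative(a * np.sin(2 * np.pi * x / period))
        assert np.max(np.abs(d)) == pytest.approx(2 * np.pi * a / period, rel=1e-3)

    def test_output_length_matches_and_short_profile_rejected(self):
        assert len(epi.first_derivative(np.arange(5.0))) == 5
        with pytest.raises(ValueError):
            epi.first_derivative(np.array([1.0, 2.0]))


class TestDetectTransitions:
    def test_flat_derivative_has_no_transitions(self):
        t = epi.detect_transitions(np.zeros(50), 0.1)
        assert t.n_transitions == 0

    def test_one_clean_nucleus_gives_one_peak_one_trough(self):
        x = np.linspace(-4, 4, 81)
        profile = np.exp(-x * x / 2.0)  # single bright bump
        t = epi.detect_transitions(epi.first_derivative(profile), "auto")
        assert len(t.peaks) == 1 and len(t.troughs) == 1
        assert t.peaks[0] < t.troughs[0]

    def test_k_equally_spaced_nuclei_give_k_peak_trough_pairs(self):
        k, spacing = 7, 30
        x = np.arange(k * spacing, dtype=float)
        profile = np.zeros_like(x)
        for c in range(spacing // 2, k * spacing, spacing):
            profile += 100 * np.exp(-((x - c) ** 2) / (2 * 9.0))
        t = epi.detect_transitions(epi.first_derivative(profile), "auto")
        assert len(t.peaks) == k and len(t.troughs) == k

    def test_plateau_resolved_to_leftmost_index(self):
        d = np.array([0.0, 2.0, 2.0, 2.0, 0.0, -2.0, -2.0, 0.0])
        t = epi.detect_transitions(d, 0.5)
        assert t.peaks.tolist() == [1]
        assert t.troughs.tolist() == [5]

    def test_same_sign_consecutive_extrema_keep_the_larger(self):
        # two peaks with only a shallow dip between them (dip above -p)
        d = np.array([0.0, 3.0, 1.0, 5.0, 0.0, -4.0, 0.0])
        t = epi.detect_transitions(d, 2.0)
        assert t.peaks.tolist() == [3]
        assert t.troughs.tolist() == [5]


class TestMetrics:
    def test_flat_image_metrics_all_zero(self):
        with pytest.warns(UserWarning):
            m = epi.compute_metrics([np.zeros(50)], 0.1)
        assert m.no_transitions
        assert m.transition_delta == m.auc == m.auc_per_transition == 0.0

    def test_triangular_wave_delta_is_twice_the_slope(self):
        s = 3.0
        m = epi.compute_metrics([triangle_wave(slope=s)], 0.5)
        assert m.transition_delta == pytest.approx(2 * s)
        assert m.n_peaks == m.n_troughs

    def test_auc_identity_holds_exactly(self, rng):
        img, _ = syn.generate_epithelium_image(syn.SyntheticEpitheliumParams(seed=11))
        m = epi.compute_metrics(epi.extract_profiles(epi.preprocess(img)))
        assert m.n_transitions > 0
        assert m.auc == pytest.approx(m.auc_per_transition * m.n_transitions, rel=1e-12)

    def test_metrics_invariant_to_intensity_offset_and_transpose(self):
        img, _ = syn.generate_epithelium_image(syn.SyntheticEpitheliumParams(seed=4))
        base = pipeline.analyze_epithelium_image(img)["metrics"]
        shifted = pipeline.analyze_epithelium_image(img + 37.0)["metrics"]
        transposed = pipeline.analyze_epithelium_image(img.T)["metrics"]
        for k in base:
            assert shifted[k] == pytest.approx(base[k], rel=1e-9)
            assert transposed[k] == pytest.approx(base[k], rel=1e-9)

    def test_degraded_epithelium_scores_lower_than_pristine(self):
        crisp, _ = syn.generate_epithelium_image(syn.SyntheticEpitheliumParams(seed=8, blur_sigma_px=0))
        hazy, _ = syn.generate_epithelium_image(syn.SyntheticEpitheliumParams(seed=8, blur_sigma_px=4))
        mc = pipeline.analyze_epithelium_image(crisp)["metrics"]
        mh = pipeline.analyze_epithelium_image(hazy)["metrics"]
        for k in ("transition_delta", "auc", "auc_per_transition"):
            assert mh[k] < mc[k]

    def test_average_first_pooling_runs_on_aligned_profiles(self):
        img, _ = syn.generate_epithelium_image(
            syn.SyntheticEpitheliumParams(seed=2, position_jitter_px=0, noise_sd=0)
        )
        m = epi.compute_metrics(epi.extract_profiles(epi.preprocess(img)), pool="average_first")
        assert m.n_transitions > 0
        assert len(m.per_profile) == 2  # one pooled row profile + one pooled column profile
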