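"""Generators: determinism, planted truth consistency, degradation behavior."""

import numpy as np
import pytest

from nervebed import synthetic as syn

from _oracles import bfs_component_count


class TestNerveStack:
    def test_empty_params_give_background_only(self):
        p = syn.SyntheticNerveParams(n_fibers=0, terminal_density=0, seed=1)
        stack, truth = syn.generate_nerve_stack(p)
        assert truth.true_fragment_count == 0
        assert not truth.true_coverage_mask.any()
        assert stack.voxels.shape == (p.n_planes, *p.image_size_px)

    def test_non_touching_layout_plants_exactly_n_fibers(self):
        p = syn.SyntheticNerveParams(
            n_fibers=5, break_rate=0, coverage_loss=0, terminal_density=0, non_touching=True, seed=7
        )
        _, truth = syn.generate_nerve_stack(p)
        assert truth.true_fragment_count == 5

    def test_same_seed_bitwise_identical(self):
        p = syn.SyntheticNerveParams(seed=7)
        s1, t1 = syn.generate_nerve_stack(p)
        s2, t2 = syn.generate_nerve_stack(p)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)
        np.testing.assert_array_equal(t1.true_coverage_mask, t2.true_coverage_mask)

    def test_truth_count_matches_bfs_oracle(self):
        for seed in range(5):
            p = syn.SyntheticNerveParams(seed=seed, break_rate=0.3, terminal_density=1.0)
            _, truth = syn.generate_nerve_stack(p)
            assert truth.true_fragment_count == bfs_component_count(truth.true_coverage_mask, 8)

    def test_sub_basal_and_terminal_bands_are_depth_separated(self):
        p = syn.SyntheticNerveParams(seed=3, noise_sd=0, curvature_tilt=2.0)
        stack, truth = syn.generate_nerve_stack(p)
        z_energy = stack.voxels.reshape(p.n_planes, -1).sum(axis=1)
        occupied = np.flatnonzero(z_energy)
        assert len(occupied) >= 2  # signal spreads over multiple planes via tilt

    def test_curvature_tilt_spreads_fiber_depth_across_image(self):
        p = syn.SyntheticNerveParams(seed=5, noise_sd=0, terminal_density=0, curvature_tilt=4.0)
        stack, truth = syn.generate_nerve_stack(p)
        zs, ys, xs = np.nonzero(stack.voxels)
        near = zs[(ys + xs) < np.percentile(ys + xs, 20)]
        far = zs[(ys + xs) > np.percentile(ys + xs, 80)]
        assert far.mean() > near.mean() + 1.0

    def test_validation_rejects_bad_params(self):
        with pytest.raises(ValueError):
            syn.SyntheticNerveParams(image_size_px=(32, 256))
        with pytest.raises(ValueError):
            syn.SyntheticNerveParams(curvature_tilt=12.0, n_planes=12)
        with pytest.raises(ValueError):
            syn.SyntheticNerveParams(break_rate=1.5)

    def test_coverage_loss_removes_whole_fibers(self):
        full = syn.SyntheticNerveParams(seed=9, terminal_density=0, noise_sd=0)
        lost = syn.SyntheticNerveParams(seed=9, terminal_density=0, noise_sd=0, coverage_loss=0.5)
        _, t_full = syn.generate_nerve_stack(full)
        _, t_lost = syn.generate_nerve_stack(lost)
        assert t_lost.true_coverage_mask.sum() < t_full.true_coverage_mask.sum()

    def test_degradation_monotone_in_break_rate(self):
        """Mean fragment count rises and coverage falls with the break rate."""
        counts, covers = [], []
        for rate in (0.0, 0.3, 0.6):
            c, a = [], []
            for s in range(10):
                p = syn.SyntheticNerveParams(seed=400 + s, break_rate=rate, terminal_density=0)
                _, t = syn.generate_nerve_stack(p)
                c.append(t.true_fragment_count)
                a.append(t.true_coverage_mask.sum())
            counts.append(np.mean(c))
            covers.append(np.mean(a))
        assert counts[0] < counts[1] < counts[2]
        assert covers[0] > covers[1] > covers[2]


class TestEpitheliumImage:
    def test_full_dropout_leaves_no_nuclei(self):
        img, truth = syn.generate_epithelium_image(syn.SyntheticEpitheliumParams(dropout=1.0, seed=2))
        assert truth.nucleus_centers == []

    def test_square_lattice_center_count(self):
        p = syn.SyntheticEpitheliumParams(
            image_size_px=(200, 200),
            nucleus_spacing_px=20,
            nucleus_radius_px=6,
            position_jitter_px=0,
            dropout=0.0,
            noise_sd=0.0,
        )
        _, truth = syn.generate_epithelium_image(p)
        assert len(truth.nucleus_centers) == 100

    def test_blur_strictly_lowers_row_profile_contrast(self):
        base = dict(position_jitter_px=0, dropout=0.0, noise_sd=0.0, seed=6)
        sharp, t = syn.generate_epithelium_image(syn.SyntheticEpitheliumParams(blur_sigma_px=0, **base))
        hazy, _ = syn.generate_epithelium_image(syn.SyntheticEpitheliumParams(blur_sigma_px=4, **base))
        row = int(round(t.nucleus_centers[0][0]))
        assert np.ptp(hazy[row]) < np.ptp(sharp[row])

    def test_guaranteed_overlap_rejected_possible_overlap_warns(self):
        with pytest.raises(ValueError):
            syn.SyntheticEpitheliumParams(nucleus_spacing_px=10, nucleus_radius_px=5)
        with pytest.warns(UserWarning):
            syn.SyntheticEpitheliumParams(
                nucleus_spacing_px=14, nucleus_radius_px=6, position_jitter_px=2
            )

    def test_same_seed_identical_image(self):
        p = syn.SyntheticEpitheliumParams(seed=9, dropout=0.2, blur_sigma_px=1.0)
        a, _ = syn.generate_epithelium_image(p)
        b, _ = syn.generate_epithelium_image(p)
        np.testing.assert_array_equal(a, b)


class TestCohort:
    def test_empty_cohort(self):
        wick, blink, _ = syn.generate_cohort(syn.CohortSpec(n_per_group=0))
        assert wick.empty and blink.empty

    def test_zero_sd_reproduces_group_day_means(self):
        spec = syn.CohortSpec(n_per_group=4, wick_sd_mm=0.0, seed=3)
        wick, _, truth = syn.generate_cohort(spec)
        means = wick.groupby(["group", "day"])["wick_mm"].mean()
        for gi, g in enumerate(spec.groups):
            for di, d in enumerate(spec.days):
                assert means[(g, d)] == pytest.approx(spec.wick_means_mm[gi, di])

    def test_wick_values_truncated_at_zero(self):
        spec = syn.CohortSpec(
            groups=("g",),
            n_per_group=50,
            days=(0,),
            wick_means_mm=np.array([[0.1]]),
            wick_sd_mm=2.0,
            threshold_means_mm=np.array([[1.0]]),
            seed=1,
        )
        wick, _, _ = syn.generate_cohort(spec)
        assert (wick["wick_mm"] >= 0).all()

    def test_same_seed_identical_tables(self):
        spec = syn.CohortSpec(seed=11, n_per_group=3)
        w1, b1, _ = syn.generate_cohort(spec)
        w2, b2, _ = syn.generate_cohort(spec)
        assert w1.equals(w2) and b1.equals(b2)

    def test_unsorted_days_rejected(self):
        with pytest.raises(ValueError):
            syn.CohortSpec(days=(5, 0))

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError):
            syn.CohortSpec(
                groups=("g",),
                days=(0,),
                wick_means_mm=np.array([[-1.0]]),
                threshold_means_mm=np.array([[1.0]]),
            )

    def test_blink_positives_within_tap_count(self):
        _, blink, _ = syn.generate_cohort(syn.CohortSpec(seed=5, n_per_group=4))
        assert blink["positives"].between(0, 6).all()
        assert set(blink["length_mm"]) == set(syn.TESTED_LENGTHS_MM)
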