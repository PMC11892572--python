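"""Semi-automatic boundary-detection labeler against phantom ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from octskin import (
    LayerROI,
    OCTVolume,
    SemiAutoParams,
    VoxelGeometry,
    despeckle_below,
    detect_upper_boundary,
    layer_threshold,
    render_phantom,
    rois_for_phantom,
    run_semiauto,
    smooth_surface,
)
from octskin.volume import BoundarySurface


def surface(z_map):
    return BoundarySurface(0, np.asarray(z_map, dtype=float))


class TestThreshold:
    def test_constant_roi_returns_value(self):
        g = VoxelGeometry(8, 8, 8)
        vol = OCTVolume(np.full((8, 8, 8), 50.0), g)
        roi = LayerROI(3, 0, 8, 0, 8, 0, 8)
        assert layer_threshold(vol, roi, alpha=7.0) == pytest.approx(50.0)

    def test_mean_minus_alpha_sd(self):
        g = VoxelGeometry(1, 1, 2)
        vol = OCTVolume(np.array([[[90.0, 110.0]]]), g)  # mean 100, pop SD 10
        roi = LayerROI(3, 0, 1, 0, 1, 0, 2)
        assert layer_threshold(vol, roi, alpha=2.0) == pytest.approx(80.0)
        assert layer_threshold(vol, roi, alpha=-2.0) == pytest.approx(120.0)

    def test_alpha_zero_is_roi_mean(self, speckled_phantom):
        ph = speckled_phantom
        roi = rois_for_phantom(ph.params)[3]
        expected = ph.volume.intensity[
            roi.z0 : roi.z1, roi.y0 : roi.y1, roi.x0 : roi.x1
        ].mean()
        assert layer_threshold(ph.volume, roi, 0.0) == pytest.approx(expected)

    def test_roi_outside_volume_rejected(self):
        g = VoxelGeometry(4, 4, 4)
        vol = OCTVolume(np.zeros((4, 4, 4)), g)
        with pytest.raises(ValueError):
            layer_threshold(vol, LayerROI(2, 0, 8, 0, 4, 0, 4), 1.0)


class TestDetect:
    def test_noise_free_step_found_exactly(self, noise_free_phantom):
        ph = noise_free_phantom
        thr = 0.5 * ph.params.layer_mean_intensity[2]
        found = detect_upper_boundary(ph.volume, thr, "rising")
        np.testing.assert_array_equal(found.rounded(), ph.boundaries[0].rounded())
        assert not found.flagged.any()

    def test_degenerate_threshold_hits_scan_start(self, noise_free_phantom):
        vol = noise_free_phantom.volume
        found = detect_upper_boundary(vol, -1e9, "rising")
        assert np.all(found.rounded() == 0)
        assert not found.flagged.any()  # first voxel qualifies, so no flags

    def test_no_crossing_flags_deepest_index(self, noise_free_phantom):
        vol = noise_free_phantom.volume
        found = detect_upper_boundary(vol, 1e9, "rising")
        assert np.all(found.rounded() == vol.shape[0] - 1)
        assert found.flagged.all()

    def test_speckled_detection_within_two_voxels(self, tiny_params):
        ph = render_phantom(replace(tiny_params, speckle=True, speckle_shape=16.0))
        thr = 0.3 * ph.params.layer_mean_intensity[2]
        found = detect_upper_boundary(ph.volume, thr, "rising")
        err = np.abs(found.z_of - ph.boundaries[0].z_of)
        assert np.median(err) <= 2.0


class TestSmooth:
    def test_constant_surface_unchanged(self):
        s = smooth_surface(surface(np.full((16, 16), 7.0)), 11)
        np.testing.assert_array_equal(s.z_of, 7.0)

    def test_spike_removed(self):
        z = np.full((21, 21), 10.0)
        z[10, 10] += 20
        s = smooth_surface(surface(z), 11)
        np.testing.assert_array_equal(s.z_of, 10.0)

    def test_matches_brute_force_median(self, rng):
        z = rng.integers(0, 50, size=(32, 32)).astype(float)
        w = 11
        got = smooth_surface(surface(z), w).z_of
        # brute force with reflected borders
        pad = w // 2
        zp = np.pad(z, pad, mode="symmetric")  # edge-including reflection
        expected = np.empty_like(z)
        for i in range(32):
            for j in range(32):
                expected[i, j] = np.median(zp[i : i + w, j : j + w])
        np.testing.assert_allclose(got, expected)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_surface(surface(np.zeros((4, 4))), 4)


class TestDespeckle:
    def test_surface_at_bottom_leaves_volume_unchanged(self, speckled_phantom):
        vol = speckled_phantom.volume
        n_z = vol.shape[0]
        s = surface(np.full(vol.shape[1:], n_z - 1))
        out = despeckle_below(vol, s, 3)
        np.testing.assert_array_equal(
            out.intensity[: n_z - 1], vol.intensity[: n_z - 1]
        )

    def test_constant_volume_unchanged(self):
        g = VoxelGeometry(8, 8, 8)
        vol = OCTVolume(np.full((8, 8, 8), 3.0), g)
        out = despeckle_below(vol, surface(np.zeros((8, 8))), 3)
        np.testing.assert_allclose(out.intensity, 3.0)

    def test_voxels_above_surface_untouched(self, speckled_phantom):
        vol = speckled_phantom.volume
        s = speckled_phantom.boundaries[0]
        out = despeckle_below(vol, s, 3)
        above = (
            np.arange(vol.shape[0])[:, None, None] < s.rounded()[None]
        )
        np.testing.assert_array_equal(out.intensity[above], vol.intensity[above])
        assert not np.array_equal(out.intensity, vol.intensity)

    def test_even_window_rejected(self, speckled_phantom):
        with pytest.raises(ValueError):
            despeckle_below(
                speckled_phantom.volume,
                surface(np.zeros(speckled_phantom.volume.shape[1:])),
                2,
            )


class TestRunSemiauto:
    def test_noise_free_recovery_is_exact(self, noise_free_phantom):
        ph = noise_free_phantom
        rois = rois_for_phantom(ph.params)
        labels, _ = run_semiauto(ph.volume, rois, SemiAutoParams.noise_free())
        np.testing.assert_array_equal(labels.labels, ph.truth.labels)

    def test_speckled_recovery(self, speckled_phantom):
        from octskin.evaluation import dice

        ph = speckled_phantom
        labels, surfs = run_semiauto(ph.volume, rois_for_phantom(ph.params))
        rep = dice(ph.truth, labels)
        for cls in (3, 4, 5):
            assert rep.dsc[cls] >= 0.9, rep.dsc
        for s, st in zip(surfs, ph.boundaries):
            assert np.median(np.abs(s.rounded() - st.rounded())) <= 2.0

    def test_output_is_depth_monotone(self, speckled_phantom):
        ph = speckled_phantom
        labels, surfs = run_semiauto(ph.volume, rois_for_phantom(ph.params))
        assert labels.is_depth_monotone()
        for a, b in zip(surfs, surfs[1:]):
            assert np.all(b.z_of >= a.z_of)

    def test_degradation_monotone_in_speckle(self, tiny_params):
        """Median boundary error at low speckle contrast (shape 16) does not
        exceed the error at high contrast (shape 2), averaged over seeds."""
        errs = {}
        for shape in (2.0, 16.0):
            per_seed = []
            for seed in range(5):
                p = replace(tiny_params, speckle_shape=shape, seed=100 + seed)
                ph = render_phantom(p)
                _, surfs = run_semiauto(ph.volume, rois_for_phantom(p))
                err = np.median(
                    [
                        np.median(np.abs(s.rounded() - st.rounded()))
                        for s, st in zip(surfs, ph.boundaries)
                    ]
                )
                per_seed.append(err)
            errs[shape] = np.mean(per_seed)
        assert errs[16.0] <= errs[2.0]

    def test_missing_roi_rejected(self, noise_free_phantom):
        rois = rois_for_phantom(noise_free_phantom.params)
        del rois[4]
        with pytest.raises(ValueError, match="missing ROI"):
            run_semiauto(noise_free_phantom.volume, rois)
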