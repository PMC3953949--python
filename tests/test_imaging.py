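import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomplast import imaging as im
from glomplast import synthetic_data as sd
from glomplast.imaging import GlomerularMap, GlomerulusROI, RoiParams, TrialStack

from conftest import disk_pixels


def constant_stack(level=4000.0, shape=(16, 16), n_frames=16, rate=2.0):
    return TrialStack(
        frames=np.full((n_frames,) + shape, level, dtype=np.float32),
        frame_rate_hz=rate,
    )


def matched_rois(rois, gt):
    """Match detected ROIs to ground-truth glomeruli by centroid distance."""
    hits = 0
    for g in gt.glomeruli:
        if any(
            np.hypot(r.centroid[0] - g.center[0], r.centroid[1] - g.center[1]) <= g.radius
            for r in rois
        ):
            hits += 1
    return hits


class TestDeltaMap:
    def test_constant_stack_gives_zero_map(self):
        dm = im.delta_map(constant_stack())
        assert np.all(dm.values == 0.0)

    def test_noiseless_blob_exact(self, noiseless_imaging_gt):
        stack = sd.generate_trial_stack(noiseless_imaging_gt, "A", 0, 1)
        dm = im.delta_map(stack)
        pix = disk_pixels((32, 32), (16.0, 16.0), 3.0)
        vals = dm.values[pix[:, 0], pix[:, 1]]
        np.testing.assert_allclose(vals, -2.0, atol=1e-9)
        outside = np.ones((32, 32), dtype=bool)
        outside[pix[:, 0], pix[:, 1]] = False
        assert np.all(dm.values[outside] == 0.0)

    def test_scale_invariance(self):
        gt = sd.sample_imaging_ground_truth(3, ["A"], seed=2, noise_sd_permil=0.5)
        s = sd.generate_trial_stack(gt, "A", 0, 1)
        s2 = TrialStack(frames=s.frames * 7.5, frame_rate_hz=s.frame_rate_hz,
                        odor_window_s=s.odor_window_s)
        # float32 storage quantizes the scaled frames; tolerance reflects that
        np.testing.assert_allclose(im.delta_map(s).values, im.delta_map(s2).values,
                                   atol=1e-3)

    def test_noisy_blob_within_analytic_se(self):
        noise = 1.0
        gt = sd.ImagingGroundTruth(
            field_shape=(32, 32),
            glomeruli=[sd.Glomerulus((16.0, 16.0), 3.0, {"A": -2.0})],
            noise_sd_permil=noise,
            seed=5,
        )
        stack = sd.generate_trial_stack(gt, "A", 0, 1)
        dm = im.delta_map(stack)
        pix = disk_pixels((32, 32), (16.0, 16.0), 3.0)
        est = dm.values[pix[:, 0], pix[:, 1]].mean()
        n_resp = len(stack.response_indices)
        n_base = len(stack.baseline_indices)
        # analytic SE of the blob mean over frames and pixels
        se = noise * np.sqrt(1.0 / n_resp + 1.0 / n_base) / np.sqrt(len(pix))
        assert abs(est - (-2.0)) < 3.0 * se

    def test_zero_baseline_pixel_masked(self):
        frames = np.full((8, 8, 8), 100.0, dtype=np.float32)
        frames[:, 3, 3] = 0.0
        s = TrialStack(frames=frames, frame_rate_hz=1.0, odor_window_s=(2.0, 7.0))
        with pytest.warns(UserWarning):
            dm = im.delta_map(s)
        assert dm.values[3, 3] == 0.0

    def test_noise_estimate_close_to_truth(self):
        gt = sd.ImagingGroundTruth(field_shape=(64, 64), noise_sd_permil=2.0,
                                   frame_rate_hz=4.0, seed=3)
        stack = sd.generate_trial_stack(gt, "A", 0, 1)
        dm = im.delta_map(stack)
        assert dm.noise_sd_frame_permil == pytest.approx(2.0, rel=0.15)


class TestAverageRepetitions:
    def test_identical_stacks_identity(self, noiseless_imaging_gt):
        stacks = [sd.generate_trial_stack(noiseless_imaging_gt, "A", 0, r) for r in (1, 2, 3, 4)]
        avg = im.average_repetitions(stacks)
        np.testing.assert_allclose(avg.values, im.delta_map(stacks[0]).values, atol=1e-9)

    def test_variance_reduction(self):
        gt = sd.ImagingGroundTruth(field_shape=(32, 32), noise_sd_permil=2.0, seed=9)
        stacks = [sd.generate_trial_stack(gt, "A", 0, r) for r in (1, 2, 3, 4)]
        single_var = np.var(im.delta_map(stacks[0]).values)
        avg_var = np.var(im.average_repetitions(stacks).values)
        assert avg_var == pytest.approx(single_var / 4.0, rel=0.25)

    def test_mse_beats_single_repetition(self):
        gt = sd.ImagingGroundTruth(
            field_shape=(32, 32),
            glomeruli=[sd.Glomerulus((16.0, 16.0), 3.0, {"A": -2.0})],
            noise_sd_permil=1.5,
            seed=17,
        )
        stacks = [sd.generate_trial_stack(gt, "A", 0, r) for r in (1, 2, 3, 4)]
        truth = sd.response_image(gt, "A", 0)
        mse_avg = np.mean((im.average_repetitions(stacks).values - truth) ** 2)
        for s in stacks:
            assert mse_avg < np.mean((im.delta_map(s).values - truth) ** 2)

    def test_mismatched_metadata_rejected(self, noiseless_imaging_gt):
        a = sd.generate_trial_stack(noiseless_imaging_gt, "A", 0, 1)
        b = sd.generate_trial_stack(noiseless_imaging_gt, "A", -2, 1)
        with pytest.raises(ValueError):
            im.average_repetitions([a, b])

    def test_order_invariant(self):
        gt = sd.ImagingGroundTruth(field_shape=(16, 16), noise_sd_permil=1.0, seed=2)
        stacks = [sd.generate_trial_stack(gt, "A", 0, r) for r in (1, 2, 3, 4)]
        a = im.average_repetitions(stacks)
        b = im.average_repetitions(stacks[::-1])
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestDetectRois:
    def test_recall_precision_on_clean_field(self):
        gt = sd.sample_imaging_ground_truth(
            10, ["A", "B"], seed=4, noise_sd_permil=1.0, n_vessels=0
        )
        stacks = [sd.generate_trial_stack(gt, od, 0, r) for od in ("A", "B") for r in (1, 2, 3, 4)]
        rois = im.detect_rois(stacks)
        assert matched_rois(rois, gt) == 10
        assert len(rois) == 10

    def test_vessels_excluded(self):
        gt = sd.sample_imaging_ground_truth(
            8, ["A"], seed=6, noise_sd_permil=1.0, n_vessels=2
        )
        stacks = [sd.generate_trial_stack(gt, "A", 0, r) for r in (1, 2, 3, 4)]
        rois = im.detect_rois(stacks)
        assert all(r.elongation <= 4.0 for r in rois)
        assert matched_rois(rois, gt) == 8
        assert len(rois) == 8

    def test_single_frame_transient_excluded(self):
        gt = sd.sample_imaging_ground_truth(6, ["A"], seed=7, noise_sd_permil=1.0)
        # drop the transient at the spot farthest from every glomerulus
        cand = [(r, c) for r in range(10, 55, 4) for c in range(10, 55, 4)]
        spot = max(
            cand,
            key=lambda p: min(np.hypot(p[0] - g.center[0], p[1] - g.center[1])
                              for g in gt.glomeruli),
        )
        gt.transients.append(sd.Transient((float(spot[0]), float(spot[1])), 2.5, -30.0,
                                          frame_index=8))
        stacks = [sd.generate_trial_stack(gt, "A", 0, r) for r in (1, 2, 3, 4)]
        rois = im.detect_rois(stacks)
        assert not any(
            np.hypot(r.centroid[0] - spot[0], r.centroid[1] - spot[1]) < 4 for r in rois
        )
        assert matched_rois(rois, gt) == 6

    def test_no_signal_warns_and_returns_empty(self):
        gt = sd.ImagingGroundTruth(field_shape=(32, 32), noise_sd_permil=1.0, seed=1)
        stacks = [sd.generate_trial_stack(gt, "A", 0, r) for r in (1, 2)]
        with pytest.warns(UserWarning):
            assert im.detect_rois(stacks) == []

    def test_deterministic(self):
        gt = sd.sample_imaging_ground_truth(5, ["A"], seed=8, noise_sd_permil=1.0)
        stacks = [sd.generate_trial_stack(gt, "A", 0, r) for r in (1, 2, 3, 4)]
        a = im.detect_rois(stacks)
        b = im.detect_rois(stacks)
        assert [tuple(map(tuple, r.pixels)) for r in a] == [tuple(map(tuple, r.pixels)) for r in b]


class TestQuantify:
    def _map_with_roi(self, gt):
        pix = disk_pixels(gt.field_shape, gt.glomeruli[0].center, gt.glomeruli[0].radius)
        roi = GlomerulusROI(id=0, pixels=pix, centroid=gt.glomeruli[0].center,
                            area=len(pix), elongation=1.0, n_frames_present=10)
        return GlomerularMap(mouse_id="m0", group="naive", rois=[roi])

    def test_noiseless_exact(self, noiseless_imaging_gt):
        gmap = self._map_with_roi(noiseless_imaging_gt)
        dm = im.delta_map(sd.generate_trial_stack(noiseless_imaging_gt, "A", 0, 1))
        amps = im.quantify(gmap, dm, "A", 0)
        assert amps[0] == pytest.approx(-2.0, abs=1e-9)

    def test_dilution_series_recovers_attenuation(self):
        gt = sd.ImagingGroundTruth(
            field_shape=(32, 32),
            glomeruli=[sd.Glomerulus((16.0, 16.0), 3.0, {"A": -2.0})],
            noise_sd_permil=0.3,
            seed=12,
        )
        gmap = self._map_with_roi(gt)
        for e in (0, -2, -3, -4, -5, -8):
            dm = im.average_repetitions(
                [sd.generate_trial_stack(gt, "A", e, r) for r in (1, 2, 3, 4)]
            )
            amps = im.quantify(gmap, dm, "A", e)
            truth = sd.injected_amplitude(gt, gt.glomeruli[0], "A", e)
            se = gmap.amplitude_se[(0, "A", e, None)]
            assert abs(amps[0] - truth) < 4.0 * se

    def test_blank_stimulus_near_zero(self):
        gt = sd.ImagingGroundTruth(
            field_shape=(32, 32),
            glomeruli=[sd.Glomerulus((16.0, 16.0), 3.0, {"A": -2.0})],
            noise_sd_permil=0.5,
            seed=13,
        )
        gmap = self._map_with_roi(gt)
        dm = im.delta_map(sd.generate_trial_stack(gt, "B", 0, 1))  # odorant B: no response
        amps = im.quantify(gmap, dm, "B", 0)
        assert abs(amps[0]) < 3.0 * gmap.amplitude_se[(0, "B", 0, None)]

    def test_roi_outside_image_rejected(self, noiseless_imaging_gt):
        roi = GlomerulusROI(id=0, pixels=np.array([[40, 40]]), centroid=(40.0, 40.0),
                            area=1, elongation=1.0, n_frames_present=2)
        gmap = GlomerularMap(mouse_id="m0", group="naive", rois=[roi])
        dm = im.delta_map(sd.generate_trial_stack(noiseless_imaging_gt, "A", 0, 1))
        with pytest.raises(ValueError):
            im.quantify(gmap, dm, "A", 0)


class TestCountActivated:
    def _quantified_map(self, amplitudes, seed=0):
        gloms = [
            sd.Glomerulus((8.0 + 10.0 * i, 8.0 + 10.0 * (i % 3)), 2.5, {"A": a})
            for i, a in enumerate(amplitudes)
        ]
        gt = sd.ImagingGroundTruth(field_shape=(40, 40), glomeruli=gloms,
                                   noise_sd_permil=0.3, seed=seed)
        rois = [
            GlomerulusROI(id=i, pixels=disk_pixels((40, 40), g.center, g.radius),
                          centroid=g.center, area=len(disk_pixels((40, 40), g.center, g.radius)),
                          elongation=1.0, n_frames_present=10)
            for i, g in enumerate(gloms)
        ]
        gmap = GlomerularMap(mouse_id="m0", group="naive", rois=rois)
        dm = im.average_repetitions([sd.generate_trial_stack(gt, "A", 0, r) for r in (1, 2, 3, 4)])
        im.quantify(gmap, dm, "A", 0)
        return gmap

    def test_all_zero_amplitudes_count_zero(self):
        gmap = self._quantified_map([-2.0, -1.5])
        # a stimulus never quantified counts zero
        assert im.count_activated(gmap, "B", 0) == 0

    def test_strong_amplitudes_all_counted(self):
        gmap = self._quantified_map([-2.0, -1.5, -1.8])
        assert im.count_activated(gmap, "A", 0) == 3

    def test_monotone_in_activation_k(self):
        gmap = self._quantified_map([-2.0, -0.1, -0.05, -1.0], seed=5)
        counts = [im.count_activated(gmap, "A", 0, activation_k=k) for k in (1, 2, 3, 5, 10, 50)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestGroupCountScale:
    def test_count_ratio_matches_ground_truth(self):
        # oracle: injected supra-threshold responder counts
        odorants = ["A", "B"]
        high = (-3, -2)
        counts = {}
        oracle = {}
        for group, cscale in (("trained", 3.0), ("naive", 1.0)):
            gt = sd.sample_imaging_ground_truth(
                24, odorants, seed=31, group=group, field_shape=(96, 96),
                noise_sd_permil=0.8, responder_fraction=0.25,
                group_count_scale=cscale, high_dilution_exponents=high,
            )
            stacks = [
                sd.generate_trial_stack(gt, od, e, r)
                for od in odorants for e in (0, -2) for r in (1, 2, 3, 4)
            ]
            _, _, count_rows = im.run_mouse_pipeline(stacks, reference_exponent=0)
            counts[group] = sum(
                r["count"] for r in count_rows if r["dilution_exponent"] == -2
            )
            oracle[group] = sum(
                g.responder[od]
                for g in gt.glomeruli for od in odorants if od in g.base_amplitude
            )
        assert counts["trained"] == pytest.approx(oracle["trained"], abs=2)
        assert counts["naive"] == pytest.approx(oracle["naive"], abs=2)
        assert oracle["trained"] / oracle["naive"] == pytest.approx(3.0, abs=0.3)


@given(st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=20, deadline=None)
def test_delta_map_gain_invariance_property(gain):
    frames = np.full((8, 6, 6), 1000.0)
    frames[4:, 2, 2] = 998.0
    s = TrialStack(frames=frames, frame_rate_hz=1.0, odor_window_s=(2.0, 7.0))
    s2 = TrialStack(frames=frames * gain, frame_rate_hz=1.0, odor_window_s=(2.0, 7.0))
    np.testing.assert_allclose(im.delta_map(s).values, im.delta_map(s2).values,
                               rtol=1e-9, atol=1e-9)
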