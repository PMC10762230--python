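"""Harris seeding, Lucas-Kanade tracking, orbit geometry, stagnation, fusion."""

import numpy as np
import pytest

from rotomo.errors import EmptyFeatureSet, FusionGap, OrbitDegenerate, ValidationError
from rotomo.phantom import ProjectionFrame, ProjectionStack
from rotomo.preprocess import CellMask, EnclosingCircle
from rotomo.rotation_tracking import (
    FeatureTrack,
    detect_stagnation,
    fit_orbit,
    fuse_tracks,
    harris_features,
    mean_angle_error,
    select_concordant,
    track_flow,
    track_to_angles,
)

AXIS = 63.5
CIRCLE = EnclosingCircle(63.5, 63.5, 50.0)


def sinusoid_track(r, phase_deg, angles_deg, row=40.0, axis=AXIS, quantize=False,
                   fid=0):
    cols = axis + r * np.sin(np.radians(phase_deg + angles_deg))
    if quantize:
        cols = np.round(cols)
    n = len(angles_deg)
    return FeatureTrack(
        fid, np.column_stack([np.full(n, row), cols]), np.ones(n, bool), 1.0
    )


class TestHarrisFeatures:
    def test_checkerboard_corner_location(self):
        img = np.zeros((96, 96))
        img[:40, :40] = 1.0
        img[40:, 40:] = 1.0  # single strong corner at (40, 40)
        mask = np.zeros((96, 96), dtype=bool)
        mask[10:86, 10:86] = True
        feats = harris_features(
            ProjectionFrame(img, 1.0), CellMask(mask), max_n=3, highpass_sigma=0
        )
        row, col, _ = feats[0]
        assert abs(row - 40) <= 1 and abs(col - 40) <= 1

    def test_uniform_frame_has_no_features(self):
        mask = np.ones((64, 64), dtype=bool)
        with pytest.raises(EmptyFeatureSet):
            harris_features(ProjectionFrame(np.ones((64, 64)), 1.0), CellMask(mask))

    def test_features_stay_inside_mask(self, mini_video):
        from rotomo.preprocess import segment_cell

        frame = mini_video.frames[0]
        mask = segment_cell(frame)
        feats = harris_features(frame, mask, max_n=8)
        for row, col, _ in feats:
            assert mask.pixels[int(round(row)), int(round(col))]


class TestTrackFlow:
    @staticmethod
    def gaussian_stack(n, shift_per_frame=(0.0, 0.0)):
        yy, xx = np.mgrid[:96, :96]
        frames = []
        for i in range(n):
            r0 = 40.0 + shift_per_frame[0] * i
            c0 = 30.0 + shift_per_frame[1] * i
            img = np.exp(-(((yy - r0) ** 2 + (xx - c0) ** 2) / 30.0))
            frames.append(ProjectionFrame(img, 1.0, i))
        return ProjectionStack(frames)

    def test_static_scene_zero_displacement(self):
        stack = self.gaussian_stack(6)
        tracks = track_flow(stack, [(40.0, 30.0, 1.0)], highpass_sigma=0)
        assert tracks[0].valid.all()
        disp = np.diff(tracks[0].positions, axis=0)
        assert np.abs(disp).max() < 0.05

    def test_translation_is_recovered(self):
        stack = self.gaussian_stack(6, shift_per_frame=(0.0, 2.0))
        tracks = track_flow(stack, [(40.0, 30.0, 1.0)], highpass_sigma=0)
        disp = np.diff(tracks[0].positions, axis=0)
        assert np.all(np.abs(disp[:, 1] - 2.0) <= 0.2)
        assert np.all(np.abs(disp[:, 0]) <= 0.2)

    def test_feature_leaving_frame_is_invalidated(self):
        stack = self.gaussian_stack(30, shift_per_frame=(0.0, 4.0))
        tracks = track_flow(stack, [(40.0, 30.0, 1.0)], highpass_sigma=0)
        assert not tracks[0].valid.all()
        # validity is a contiguous prefix
        first_bad = int(np.argmin(tracks[0].valid))
        assert not tracks[0].valid[first_bad:].any()


class TestFitOrbit:
    def test_exact_sinusoid_radius(self):
        th = np.arange(91.0)
        track = sinusoid_track(30.0, 0.0, th)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        assert orbit.orbit_radius == pytest.approx(30.0, abs=0.5)
        assert orbit.axis_col == pytest.approx(AXIS, abs=0.1)

    def test_constant_column_is_degenerate(self):
        n = 50
        track = FeatureTrack(
            0, np.column_stack([np.full(n, 40.0), np.full(n, AXIS)]), np.ones(n, bool), 1.0
        )
        with pytest.raises(OrbitDegenerate):
            fit_orbit(track, CIRCLE)

    def test_radius_clamped_to_circle(self):
        th = np.arange(180.0)
        track = sinusoid_track(70.0, 0.0, th)  # larger than the cell circle
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        assert orbit.orbit_radius <= CIRCLE.radius + 1.0


class TestTrackToAngles:
    def test_one_degree_steps_recovered_to_microdegrees(self):
        th = np.arange(91.0)
        track = sinusoid_track(30.0, 0.0, th)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        ang, _ = track_to_angles(track, orbit)
        assert np.abs(np.diff(ang) - 1.0).max() < 1e-6

    def test_arcsine_endpoint_has_zero_sensitivity(self):
        th = np.arange(91.0)
        track = sinusoid_track(30.0, 0.0, th)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        ang, sens = track_to_angles(track, orbit)
        assert ang[-1] == pytest.approx(90.0, abs=1e-6)
        assert sens[-1] == pytest.approx(0.0, abs=1e-9)

    def test_overshoot_is_clamped(self):
        th = np.arange(91.0)
        track = sinusoid_track(30.0, 0.0, th)
        track.positions[-1, 1] = AXIS + 32.0  # 2 px beyond the orbit radius
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        ang, sens = track_to_angles(track, orbit)
        assert ang[-1] <= 90.0 + 1e-9
        assert sens[-1] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("phase", [0.0, 20.0, 110.0, 250.0])
    def test_branch_continuation_crosses_the_limb(self, phase):
        th = np.arange(180.0)
        track = sinusoid_track(30.0, phase, th)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        ang, _ = track_to_angles(track, orbit)
        assert np.nanmax(np.abs(ang - th)) < 1e-5

    @pytest.mark.parametrize("lon", [0.0, 45.0, 120.0, 250.0])
    def test_reversed_rotation_direction(self, lon):
        th = np.arange(180.0)
        cols = AXIS + 30.0 * np.sin(np.radians(lon) - np.radians(th))
        track = FeatureTrack(
            0, np.column_stack([np.full(180, 40.0), cols]), np.ones(180, bool), 1.0
        )
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        ang, _ = track_to_angles(track, orbit, direction=-1)
        assert np.nanmax(np.abs(ang - th)) < 1e-5

    def test_prior_mode_matches_chaining_on_clean_data(self):
        th = np.arange(180.0)
        track = sinusoid_track(30.0, 20.0, th)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        chained, _ = track_to_angles(track, orbit)
        prior, _ = track_to_angles(track, orbit, nominal_angles=th)
        assert np.nanmax(np.abs(chained - prior)) < 1e-6


class TestDetectStagnation:
    def test_steady_rotation_has_no_stagnation(self):
        raw = np.arange(100.0)
        assert detect_stagnation(raw, window=5, tol=2.5) == []

    def test_flat_segment_is_found(self):
        raw = np.concatenate([np.arange(40.0), np.full(21, 39.0), np.arange(40.0, 159.0)])
        intervals = detect_stagnation(raw, window=5, tol=1.0)
        assert len(intervals) == 1
        start, end = intervals[0]
        assert abs(start - 40) <= 5 and abs(end - 60) <= 5

    def test_zero_tolerance_finds_nothing(self):
        raw = np.arange(50.0) * 0.01
        assert detect_stagnation(raw, window=5, tol=0.0) == []

    def test_quantized_orbit_stagnates_near_the_limb(self):
        # integer-pixel quantization of a 30 px orbit: the arcsine plateaus
        # where the feature crosses the silhouette (theta = 90 deg)
        th = np.arange(180.0)
        track = sinusoid_track(30.0, 0.0, th, quantize=True)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        ang, _ = track_to_angles(track, orbit)
        intervals = detect_stagnation(ang, window=5, tol=1.0)
        assert any(s <= 90 <= e or abs(s - 90) < 25 or abs(e - 90) < 25
                   for s, e in intervals)


class TestFuseTracks:
    def test_single_feature_identity(self):
        th = np.arange(180.0)
        track = sinusoid_track(30.0, 0.0, th)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        ang, sens = track_to_angles(track, orbit)
        fused = fuse_tracks({0: ang}, {0: sens})
        assert np.abs(fused.fused - ang).max() < 1e-6

    def test_two_features_beat_either_alone(self):
        th = np.arange(180.0)
        raws, sens, solo = {}, {}, []
        for fid, phase in enumerate((0.0, 90.0)):
            track = sinusoid_track(30.0, phase, th, quantize=True, fid=fid)
            orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
            a, s = track_to_angles(track, orbit)
            raws[fid], sens[fid] = a, s
            solo.append(np.nanmean(np.abs(a - th)))
        fused = fuse_tracks(raws, sens)
        fused_err = mean_angle_error(fused, th)
        assert fused_err <= min(solo)

    def test_empty_input_raises(self):
        with pytest.raises(FusionGap):
            fuse_tracks({}, {})

    def test_fused_series_is_monotone_and_anchored(self):
        th = np.arange(180.0)
        track = sinusoid_track(30.0, 10.0, th, quantize=True)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        a, s = track_to_angles(track, orbit)
        fused = fuse_tracks({0: a}, {0: s})
        assert fused.fused[0] == 0.0
        assert np.all(np.diff(fused.fused) >= 0.0)


class TestSensitivityErrorMonotonicity:
    def test_binned_error_decreases_with_sensitivity(self):
        """Quantization error of the arcsine conversion shrinks as the
        feature's geometric sensitivity grows (three-bin comparison)."""
        th = np.arange(180.0)
        track = sinusoid_track(30.0, 0.0, th, quantize=True)
        orbit = fit_orbit(track, CIRCLE, nominal_angles=th)
        ang, sens = track_to_angles(track, orbit)
        err = np.abs(ang - th)
        edges = np.quantile(sens, [0.0, 1 / 3, 2 / 3, 1.0])
        means = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (sens >= lo) & (sens <= hi)
            means.append(err[sel].mean())
        assert means[0] >= means[1] >= means[2]


class TestSelectConcordant:
    def test_discordant_feature_is_excluded(self, rng):
        th = np.arange(180.0)
        good_a = th + rng.normal(0, 0.3, 180)
        good_b = th + 5.0 + rng.normal(0, 0.3, 180)  # anchor offset is fine
        junk = np.linspace(0, 40, 180)  # wrong rate entirely
        ones = np.ones(180)
        keep = select_concordant(
            {0: good_a, 1: good_b, 2: junk}, {0: ones, 1: ones, 2: ones}
        )
        assert 0 in keep and 1 in keep and 2 not in keep


class TestMeanAngleError:
    def test_perfect_series(self):
        th = np.arange(10.0)
        assert mean_angle_error(th, th) == 0.0

    def test_constant_offset(self):
        th = np.arange(10.0)
        assert mean_angle_error(th + 2.0, th) == pytest.approx(2.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            mean_angle_error(np.arange(5.0), np.arange(6.0))
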