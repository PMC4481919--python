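"""Stage-by-stage and end-to-end checks of the I-VT fixation filter."""

import math

import numpy as np
import pytest

from gazelab.gaze_io import Fixation
from gazelab.ivt_filter import (
    FilterParams,
    SampleLabel,
    ScreenGeometry,
    classify_ivt,
    combine_eyes,
    compute_velocities,
    discard_short_fixations,
    fill_gaps,
    merge_fixations,
    reduce_noise,
    run_pipeline,
    visual_angle_deg,
)
from gazelab.synthetic_data import SessionProfile, simulate_session

from conftest import make_record, make_samples

DT = 1000.0 / 30.0


def mm_for_angle(deg, geometry):
    """Chord on screen subtending ``deg`` at the eye (inverse of the
    two-vector angle formula) — independent trigonometric oracle."""
    return 2.0 * geometry.eye_distance_mm * math.tan(math.radians(deg) / 2.0)


class TestFillGaps:
    def test_short_invalid_run_interpolated(self):
        # 60 ms invalid run (2 samples at 30 Hz) between valid flanks
        pos = [(10.0, 10.0)] * 3 + [(0, 0)] * 2 + [(40.0, 10.0)] * 3
        valid = [True] * 3 + [False] * 2 + [True] * 3
        samples = make_samples(pos, valid=valid)
        filled = fill_gaps(samples, max_gap_ms=75.0)
        assert all(s.left.is_valid for s in filled)
        # hand-computed linear interpolation between x=10 at t2 and x=40 at t5
        assert filled[3].left.x == pytest.approx(10 + 30 * (1 / 3))
        assert filled[4].left.x == pytest.approx(10 + 30 * (2 / 3))

    def test_long_run_left_as_gap(self):
        pos = [(10.0, 10.0)] * 2 + [(0, 0)] * 7 + [(10.0, 10.0)] * 2
        valid = [True] * 2 + [False] * 7 + [True] * 2
        filled = fill_gaps(make_samples(pos, valid=valid), max_gap_ms=75.0)
        assert not any(s.left.is_valid for s in filled[2:9])

    def test_valid_stream_unchanged(self):
        samples = make_samples([(5.0, 5.0)] * 10)
        assert fill_gaps(samples, 75.0) == samples

    def test_empty_input(self):
        assert fill_gaps([], 75.0) == []


class TestReduceNoise:
    def test_constant_stream_is_fixed_point(self):
        stream = combine_eyes(make_samples([(7.0, 3.0)] * 12))
        out = reduce_noise(stream)
        np.testing.assert_allclose(out.x, stream.x)
        np.testing.assert_allclose(out.y, stream.y)

    def test_impulse_reduced_to_third(self):
        pos = [(0.0, 0.0)] * 2 + [(9.0, 0.0)] + [(0.0, 0.0)] * 2
        out = reduce_noise(combine_eyes(make_samples(pos)))
        assert out.x[2] == pytest.approx(3.0)

    def test_alternating_noise_variance_reduced(self):
        pos = [((-1.0) ** k, 0.0) for k in range(40)]
        stream = combine_eyes(make_samples(pos))
        out = reduce_noise(stream)
        assert out.x.var() < stream.x.var()

    def test_never_averages_across_gaps(self):
        pos = [(0.0, 0.0)] * 3 + [(0, 0)] + [(100.0, 0.0)] * 3
        valid = [True] * 3 + [False] + [True] * 3
        out = reduce_noise(combine_eyes(make_samples(pos, valid=valid)))
        assert out.x[2] == pytest.approx(0.0)  # not pulled toward 100
        assert out.x[4] == pytest.approx(100.0)
        assert np.isnan(out.x[3])


class TestComputeVelocities:
    def test_stationary_gaze_zero_velocity(self, geometry):
        stream = combine_eyes(make_samples([(50.0, 50.0)] * 10))
        out = compute_velocities(stream, geometry)
        np.testing.assert_allclose(out.velocity, 0.0)

    def test_two_point_displacement_matches_trig_oracle(self, geometry):
        # 10 mm apart, 600 mm viewing distance, 33.33 ms apart
        dt = 1000.0 / 30.0
        stream = combine_eyes(make_samples([(0.0, 0.0), (10.0, 0.0)], dt_ms=dt))
        out = compute_velocities(stream, geometry)
        expected_deg = math.degrees(2 * math.atan(5.0 / 600.0))
        assert expected_deg == pytest.approx(0.9549, abs=1e-4)
        np.testing.assert_allclose(out.velocity, expected_deg / (dt / 1000.0), rtol=1e-12)
        assert out.velocity[0] == pytest.approx(28.65, abs=0.03)

    def test_velocity_scales_inversely_with_dt(self, geometry):
        s20 = combine_eyes(make_samples([(0.0, 0.0), (10.0, 0.0)], dt_ms=20.0))
        v20 = compute_velocities(s20, geometry).velocity[0]
        assert v20 == pytest.approx(47.7, abs=0.1)

    def test_single_sample_flagged_undefined(self, geometry):
        out = compute_velocities(combine_eyes(make_samples([(1.0, 1.0)])), geometry)
        assert np.isnan(out.velocity).all()


class TestClassifyIvt:
    def test_stationary_stream_single_fixation(self, geometry):
        n = 16  # ~500 ms at 30 Hz
        stream = compute_velocities(
            combine_eyes(make_samples([(50.0, 50.0)] * n)), geometry
        )
        labeled, fixations = classify_ivt(stream, geometry=geometry)
        assert (labeled.label == int(SampleLabel.FIXATION)).all()
        assert len(fixations) == 1
        assert fixations[0].duration == pytest.approx(500, abs=1.5 * DT)

    def test_two_holds_with_jump(self, geometry):
        far = mm_for_angle(5.0, geometry)
        pos = [(0.0, 0.0)] * 12 + [(far / 2, 0.0)] + [(far, 0.0)] * 12
        stream = compute_velocities(combine_eyes(make_samples(pos)), geometry)
        labeled, fixations = classify_ivt(stream, geometry=geometry)
        assert len(fixations) == 2
        assert (labeled.label == int(SampleLabel.SACCADE)).sum() >= 1

    def test_velocity_at_threshold_is_saccade(self, geometry):
        # exact dt and integer positions so every edge velocity is
        # bit-identical to the threshold: the >= rule must call it a saccade
        step, dt_ms = 10.0, 25.0
        pos = [(k * step, 0.0) for k in range(8)]
        stream = compute_velocities(
            combine_eyes(make_samples(pos, dt_ms=dt_ms)), geometry
        )
        edge_v = float(
            visual_angle_deg(0.0, 0.0, step, 0.0, geometry) / (dt_ms / 1000.0)
        )
        labeled, fixations = classify_ivt(
            stream, velocity_threshold_deg_s=edge_v, geometry=geometry
        )
        assert fixations == []
        assert (labeled.label == int(SampleLabel.SACCADE)).all()

    def test_every_sample_has_exactly_one_label(self, geometry):
        rec, _ = simulate_session(SessionProfile(), duration_s=10, seed=7)
        _, stream = run_pipeline(rec, geometry=geometry, return_stream=True)
        counts = [(stream.label == int(lab)).sum() for lab in SampleLabel]
        assert sum(counts) == len(stream)


class TestMergeFixations:
    def fix(self, start, dur, x, y=0.0):
        return Fixation(start_time=start, end_time=start + dur, duration=dur, x=x, y=y)

    def test_close_pair_merges(self, geometry):
        d = mm_for_angle(0.2, geometry)
        out = merge_fixations(
            [self.fix(0, 200, 0.0), self.fix(250, 200, d)], geometry
        )
        assert len(out) == 1
        assert out[0].duration == pytest.approx(450)
        # centroid is the duration-weighted mean
        assert out[0].x == pytest.approx(d / 2)

    def test_distant_pair_does_not_merge(self, geometry):
        d = mm_for_angle(1.0, geometry)
        out = merge_fixations(
            [self.fix(0, 200, 0.0), self.fix(250, 200, d)], geometry
        )
        assert len(out) == 2

    def test_chain_collapses_to_single_run(self, geometry):
        d = mm_for_angle(0.3, geometry)
        runs = [self.fix(0, 150, 0.0), self.fix(200, 150, d), self.fix(400, 150, 2 * d)]
        out = merge_fixations(runs, geometry)
        # brute-force pairwise closure oracle: repeat single merges until stable
        def brute(fs):
            fs = sorted(fs, key=lambda f: f.start_time)
            while True:
                for i in range(len(fs) - 1):
                    a, b = fs[i], fs[i + 1]
                    gap = b.start_time - a.end_time
                    ang = float(visual_angle_deg(a.x, a.y, b.x, b.y, geometry))
                    if gap <= 75.0 and ang <= 0.5:
                        merged = Fixation(
                            start_time=a.start_time,
                            end_time=b.end_time,
                            duration=b.end_time - a.start_time,
                            x=(a.x * a.duration + b.x * b.duration) / (a.duration + b.duration),
                            y=(a.y * a.duration + b.y * b.duration) / (a.duration + b.duration),
                        )
                        fs = fs[:i] + [merged] + fs[i + 2 :]
                        break
                else:
                    return fs
        expect = brute(runs)
        assert len(out) == len(expect) == 1
        assert out[0].start_time == expect[0].start_time
        assert out[0].end_time == expect[0].end_time

    def test_idempotent(self, geometry):
        rng = np.random.default_rng(4)
        t = 0.0
        runs = []
        for _ in range(30):
            dur = float(rng.uniform(60, 400))
            runs.append(self.fix(t, dur, float(rng.uniform(0, 376)), float(rng.uniform(0, 301))))
            t += dur + float(rng.uniform(5, 200))
        once = merge_fixations(runs, ScreenGeometry())
        twice = merge_fixations(once, ScreenGeometry())
        assert once == twice


class TestDiscardShort:
    @pytest.mark.parametrize(
        "duration,kept", [(90.0, False), (100.0, True), (250.0, True)]
    )
    def test_boundary_convention(self, duration, kept):
        f = Fixation(start_time=0, end_time=duration, duration=duration, x=0, y=0)
        out = discard_short_fixations([f], 100.0)
        assert (len(out) == 1) is kept

    def test_mixed_list_count(self):
        rng = np.random.default_rng(1)
        durs = rng.uniform(40, 400, 50)
        fs = [
            Fixation(start_time=1000.0 * i, end_time=1000.0 * i + d, duration=d, x=0, y=0)
            for i, d in enumerate(durs)
        ]
        out = discard_short_fixations(fs, 100.0)
        assert len(out) == int((durs >= 100.0).sum())


class TestRunPipeline:
    def test_empty_record(self, geometry):
        rec = make_record([])
        out = run_pipeline(rec, geometry=geometry)
        assert len(out) == 0
        assert out.meta == rec.meta

    def test_planted_fixations_recovered_within_one_sample(self, geometry):
        profile = SessionProfile(
            noise_sd_deg=0.0, blink_rate_hz=0.0, fixation_median_ms=320.0,
            fixation_sigma=0.12,
        )
        rec, truth = simulate_session(profile, seed=12, n_fixations=12)
        assert all(f.duration_ms >= 150 for f in truth.fixations)
        out = run_pipeline(rec, geometry=geometry)
        assert len(out) == 12
        t0 = rec.samples[0].timestamp_ms
        dt = 1000.0 / profile.sampling_rate_hz
        for planted, det in zip(truth.fixations, out.fixations):
            assert abs(det.start_time - t0 - planted.start_ms) <= dt + 1e-6
            assert abs(det.end_time - t0 - planted.end_ms) <= dt + 1e-6

    def test_short_blink_inside_fixation_yields_single_fixation(self, geometry):
        # 40 ms blink (1 sample at 30 Hz) in the middle of a 660 ms hold
        pos = [(80.0, 80.0)] * 20
        valid = [True] * 10 + [False] + [True] * 9
        rec = make_record(pos, valid=valid)
        out = run_pipeline(rec, geometry=geometry)
        assert len(out) == 1
        assert out.fixations[0].duration == pytest.approx(20 * DT, abs=2 * DT)

    def test_raising_threshold_never_decreases_fixation_time(self, geometry):
        rec, _ = simulate_session(SessionProfile(), duration_s=15, seed=21)
        totals = []
        for thr in (15.0, 30.0, 60.0, 120.0):
            out = run_pipeline(
                rec, FilterParams(velocity_threshold_deg_s=thr), geometry
            )
            totals.append(sum(f.duration for f in out.fixations))
        assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_raising_min_duration_never_increases_count(self, geometry):
        rec, _ = simulate_session(SessionProfile(), duration_s=15, seed=22)
        counts = [
            len(run_pipeline(rec, FilterParams(min_fixation_ms=m), geometry))
            for m in (60.0, 100.0, 150.0, 250.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_output_satisfies_record_invariants(self, geometry):
        rec, _ = simulate_session(SessionProfile(), duration_s=20, seed=23)
        out = run_pipeline(rec, geometry=geometry)
        starts = [f.start_time for f in out.fixations]
        assert starts == sorted(starts)
        for a, b in zip(out.fixations, out.fixations[1:]):
            assert b.start_time >= a.end_time - 0.5
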