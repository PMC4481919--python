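"""Heat-map rendering, alpha coverage, quadrants and the feature vector."""

import numpy as np
import pandas as pd
import pytest

from gazelab.gaze_io import Fixation, FixationRecord, SessionMeta, LEVELS
from gazelab.heatmap_features import (
    FEATURE_NAMES,
    HeatMap,
    QUADRANT_LABELS,
    alpha_coverage,
    assemble_features,
    features_frame,
    quadrant_of,
    quadrant_stats,
    render_heatmap,
)
from gazelab.ivt_filter import ScreenGeometry

GEO = ScreenGeometry(coordinate_unit="px")  # 1 unit = 1 px for easy placement


def fix(x, y, dur=200.0, start=0.0):
    return Fixation(start_time=start, end_time=start + dur, duration=dur, x=x, y=y)


class TestRenderHeatmap:
    def test_no_fixations_all_zero_alpha(self):
        hm = render_heatmap([], GEO)
        assert hm.alpha.sum() == 0

    def test_single_central_fixation_peaks_at_centre_and_decays(self):
        cx, cy = GEO.width_px // 2, GEO.height_px // 2
        hm = render_heatmap([fix(cx, cy)], GEO, kernel_radius_px=50)
        a = hm.alpha
        assert a[cy, cx] == a.max() == 255
        # monotone decay along a radius
        profile = a[cy, cx : cx + 51].astype(int)
        assert all(b <= x for x, b in zip(profile, profile[1:]))
        assert a[cy, cx + 60] == 0

    def test_coincident_fixations_double_intensity(self):
        one = render_heatmap([fix(300, 300)], GEO)
        two = render_heatmap([fix(300, 300)] * 2, GEO)
        np.testing.assert_allclose(two.intensity, 2.0 * one.intensity)

    def test_offscreen_fixation_clamped(self):
        hm = render_heatmap([fix(-500, -500)], GEO)
        assert hm.intensity[0, 0] == hm.intensity.max()


class TestAlphaCoverage:
    def test_zero_and_full(self):
        shape = (8, 8)
        assert alpha_coverage(HeatMap(np.zeros(shape))) == 0.0
        assert alpha_coverage(HeatMap(np.ones(shape))) == 100.0

    def test_half_saturated_is_fifty_percent(self):
        grid = np.zeros((10, 10))
        grid[:5] = 5.0  # saturates at 1.0
        assert alpha_coverage(HeatMap(grid)) == pytest.approx(50.0)

    def test_monotone_in_fixation_count(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(100, 900, size=(15, 2))
        cov = [
            alpha_coverage(render_heatmap([fix(x, y) for x, y in pts[:k]], GEO))
            for k in (0, 5, 10, 15)
        ]
        assert all(b >= a for a, b in zip(cov, cov[1:]))


class TestQuadrants:
    def test_exact_centre_is_B2(self):
        assert quadrant_of(GEO.width_px / 2, GEO.height_px / 2, GEO) == "B2"

    def test_origin_is_A1(self):
        assert quadrant_of(0.0, 0.0, GEO) == "A1"

    def test_boundary_belongs_to_lower_indexed_cell(self):
        assert quadrant_of(GEO.width_px / 3, 10.0, GEO) == "A1"
        assert quadrant_of(GEO.width_px / 3 + 0.5, 10.0, GEO) == "A2"

    def test_counts_match_brute_force_grouping(self):
        rng = np.random.default_rng(5)
        fs = [
            fix(float(x), float(y), dur=float(d))
            for x, y, d in zip(
                rng.uniform(0, GEO.width_px, 20),
                rng.uniform(0, GEO.height_px, 20),
                rng.uniform(100, 400, 20),
            )
        ]
        counts, means = quadrant_stats(fs, GEO)
        assert sum(counts.values()) == 20
        # brute force: independent row/col arithmetic
        for q in QUADRANT_LABELS:
            row, col = "ABC".index(q[0]), int(q[1]) - 1
            members = [
                f
                for f in fs
                if (0 if f.x <= GEO.width_px / 3 else 1 if f.x <= 2 * GEO.width_px / 3 else 2) == col
                and (0 if f.y <= GEO.height_px / 3 else 1 if f.y <= 2 * GEO.height_px / 3 else 2) == row
            ]
            assert counts[q] == len(members)
            expect = np.mean([f.duration for f in members]) if members else 0.0
            assert means[q] == pytest.approx(expect)


def _cohort_row(pid="7"):
    return {
        "participant_id": pid,
        "time_level1": 40.0, "time_level2": 35.0, "time_level3": 48.0,
        "time_level4": 45.0, "total_time": 168.0,
        "correct_level1": 4, "correct_level2": 3, "correct_level3": 2,
        "correct_level4": 3, "total_correct": 12,
    }


class TestAssembleFeatures:
    def records(self, rng):
        out = {}
        for level in LEVELS:
            n = int(rng.integers(3, 10))
            t = 0.0
            fs = []
            for _ in range(n):
                d = float(rng.uniform(100, 400))
                fs.append(
                    fix(float(rng.uniform(0, GEO.width_px)), float(rng.uniform(0, GEO.height_px)), d, t)
                )
                t += d + 50
            out[level] = FixationRecord(
                meta=SessionMeta(user_id="7", level=level), fixations=fs
            )
        return out

    def test_vector_has_exactly_34_named_features(self):
        rng = np.random.default_rng(9)
        vec = assemble_features(self.records(rng), _cohort_row(), geometry=GEO)
        assert len(vec) == len(FEATURE_NAMES) == 34
        assert list(vec.index) == list(FEATURE_NAMES)

    def test_empty_inputs_zero_counts_normal_flag(self):
        vec = assemble_features({}, _cohort_row(), geometry=GEO)
        assert vec["fix_total_count"] == 0
        assert vec["fix_avg_duration"] == 0
        assert vec["classification"] == 0
        assert vec["total_correct"] == 12

    def test_every_feature_matches_independent_recomputation(self):
        rng = np.random.default_rng(10)
        recs = self.records(rng)
        vec = assemble_features(recs, _cohort_row(), outlier=True, geometry=GEO)
        all_fix = [f for level in LEVELS for f in recs[level].fixations]
        durs = np.array([f.duration for f in all_fix])
        assert vec["classification"] == 1.0
        assert vec["fix_total_count"] == len(all_fix)
        assert vec["fix_avg_duration"] == pytest.approx(durs.mean())
        assert vec["fix_max_duration"] == pytest.approx(durs.max())
        assert vec["fix_min_duration"] == pytest.approx(durs.min())
        counts, means = quadrant_stats(all_fix, GEO)
        for q in QUADRANT_LABELS:
            assert vec[f"fix_count_{q}"] == counts[q]
            assert vec[f"fix_avgdur_{q}"] == pytest.approx(means[q])
        assert sum(vec[f"fix_count_{q}"] for q in QUADRANT_LABELS) == vec["fix_total_count"]
        # global alpha equals the mean of the four per-level coverages
        expect_alpha = np.mean(
            [
                alpha_coverage(render_heatmap(recs[level].fixations, GEO))
                for level in LEVELS
            ]
        )
        assert vec["global_alpha"] == pytest.approx(expect_alpha)

    def test_mismatched_participant_id_rejected(self):
        rng = np.random.default_rng(11)
        recs = self.records(rng)
        with pytest.raises(ValueError, match="does not\\s+match|match"):
            assemble_features(recs, _cohort_row(pid="99"), geometry=GEO)

    def test_features_frame_shape_and_order(self):
        rng = np.random.default_rng(12)
        vecs = [
            assemble_features(self.records(rng), _cohort_row(), geometry=GEO)
            for _ in range(3)
        ]
        frame = features_frame(vecs)
        assert frame.shape == (3, 34)
        assert list(frame.columns) == list(FEATURE_NAMES)
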