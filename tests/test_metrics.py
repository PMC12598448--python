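"""DLS family, exclusion rules, and subject aggregation."""

import math

import numpy as np
import pytest

from gazescratch.fixations import Fixation
from gazescratch.metrics import (TrialMetrics, aggregate_subjects,
                                 apply_trial_exclusions, compute_dls,
                                 exploratory_dls, looking_times,
                                 split_half_contingent)
from gazescratch.simulator import (CoverState, PhaseSchedule, TrialRecord,
                                   visible_object_region)

WINDOW = (0.0, 10000.0)


def fix_at(x, y, onset, duration):
    return Fixation(onset_ms=onset, offset_ms=onset + duration,
                    centroid_x=x, centroid_y=y, n_samples=max(int(duration // 8), 1))


def centers(layout, condition, which="object"):
    aois = (layout.object_aois(condition) if which == "object"
            else layout.nonobject_aois(condition))
    return [r.center for r in aois]


class TestComputeDls:
    def test_exclusive_object_looking_gives_one(self, layouts):
        lay = layouts["drop"]
        fx = [fix_at(x, y, 1000 * i, 400)
              for i, (x, y) in enumerate(centers(lay, "drop") * 2)]
        assert compute_dls(fx, lay, "drop", WINDOW) == 1.0

    def test_equal_time_per_quadrant_gives_zero(self, layouts):
        lay = layouts["drop"]
        fx = [fix_at(*rect.center, 1000 * i, 400)
              for i, rect in enumerate(lay.quadrants.values())]
        assert compute_dls(fx, lay, "drop", WINDOW) == 0.0

    def test_three_to_one_ratio(self, layouts):
        lay = layouts["rise"]
        (ox, oy), _ = centers(lay, "rise")
        (nx, ny), _ = centers(lay, "rise", "nonobject")
        fx = [fix_at(ox, oy, 0, 3000), fix_at(nx, ny, 4000, 1000)]
        assert compute_dls(fx, lay, "rise", WINDOW) == pytest.approx(0.5)

    def test_no_looking_is_undefined(self, layouts):
        assert math.isnan(compute_dls([], layouts["drop"], "drop", WINDOW))
        # fixation entirely outside the window
        fx = [fix_at(100, 100, 20000, 500)]
        assert math.isnan(compute_dls(fx, layouts["drop"], "drop", WINDOW))

    def test_offscreen_centroid_ignored(self, layouts):
        fx = [fix_at(-10, 100, 0, 500)]
        assert math.isnan(compute_dls(fx, layouts["drop"], "drop", WINDOW))

    def test_phase_straddling_fixation_clipped(self, layouts):
        lay = layouts["drop"]
        (ox, oy), _ = centers(lay, "drop")
        (nx, ny), _ = centers(lay, "drop", "nonobject")
        # object fixation half inside the window, non-object fully inside
        fx = [fix_at(ox, oy, 9000, 2000), fix_at(nx, ny, 0, 1000)]
        t_obj, t_non = looking_times(fx, lay, "drop", WINDOW)
        assert t_obj == 1000.0 and t_non == 1000.0
        assert compute_dls(fx, lay, "drop", WINDOW) == 0.0

    def test_rescaling_invariance(self, layouts, rng):
        lay = layouts["drop"]
        pts = rng.uniform([0, 0], [1920, 1080], size=(30, 2))
        for scale in (1.0, 3.7):
            fx = [fix_at(x, y, i * 1000 * scale, 300 * scale)
                  for i, (x, y) in enumerate(pts)]
            window = (0.0, 40000.0 * scale)
            dls = compute_dls(fx, lay, "drop", window)
            if scale == 1.0:
                base = dls
        assert dls == pytest.approx(base)

    def test_uniform_by_area_expectation(self, layouts, rng):
        """E[DLS] = 2 * object_area_fraction - 1 under uniform placement."""
        lay = layouts["rise"]
        vals = []
        for _ in range(300):
            pts = rng.uniform([0, 0], [1920, 1080], size=(10, 2))
            fx = [fix_at(x, y, i * 500, 400) for i, (x, y) in enumerate(pts)]
            vals.append(compute_dls(fx, lay, "rise", (0.0, 50000.0)))
        expected = 2 * 0.5572 - 1
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se


def _trial_record(stimulus, cover=None, t_stop=20000.0, end_reason="timeout"):
    if cover is None:
        cover = CoverState(1920, 1080, 25)
    return TrialRecord(stimulus=stimulus, schedule=PhaseSchedule(t_stop=t_stop),
                       cover_at_disruption=cover, end_reason=end_reason)


class TestExploratoryDls:
    def test_fresh_cover_equals_standard(self, layouts, drop_stimulus):
        lay = layouts["drop"]
        trial = _trial_record(drop_stimulus)
        window = trial.schedule.windows()["disruption"]
        fx = [fix_at(*c, window[0] + 500 * i, 400)
              for i, c in enumerate(centers(lay, "drop") + centers(lay, "drop", "nonobject"))]
        assert exploratory_dls(fx, lay, "drop", trial) == \
               compute_dls(fx, lay, "drop", window)

    def test_all_object_looks_on_visible_parts(self, layouts, drop_stimulus):
        lay = layouts["drop"]
        cover = CoverState(1920, 1080, 25)
        cover.grid[:] = False  # everything uncovered
        trial = _trial_record(drop_stimulus, cover)
        w0 = trial.schedule.windows()["disruption"][0]
        # object fixations on the (visible) object boxes, one non-object look
        obj_pts = [r.center for r in drop_stimulus.object_rects]
        (nx, ny), _ = centers(lay, "drop", "nonobject")
        fx = [fix_at(*obj_pts[0], w0, 1000), fix_at(*obj_pts[1], w0 + 1500, 1000),
              fix_at(nx, ny, w0 + 3000, 1000)]
        t_obj_raw = 2000.0
        t_non = 1000.0
        expected = (0.0 - t_non) / (t_obj_raw + t_non)
        assert exploratory_dls(fx, lay, "drop", trial) == pytest.approx(expected)

    def test_mixed_hand_built_case(self, layouts, drop_stimulus):
        lay = layouts["drop"]
        cover = CoverState(1920, 1080, 25)
        obj0 = drop_stimulus.object_rects[0]
        cx, cy = obj0.center
        cover.grid[int(cy // 25), int(cx // 25)] = False  # one visible cell
        trial = _trial_record(drop_stimulus, cover)
        w0 = trial.schedule.windows()["disruption"][0]
        (nx, ny), _ = centers(lay, "drop", "nonobject")
        qx, qy = obj0.x0 + 5, obj0.y0 + 5  # object part in a still-covered cell
        assert (int(qy // 25), int(qx // 25)) != (int(cy // 25), int(cx // 25))
        fx = [
            fix_at(cx, cy, w0, 800),          # on the visible object cell
            fix_at(qx, qy, w0 + 1000, 1200),  # object quadrant, covered area
            fix_at(nx, ny, w0 + 2500, 500),   # non-object quadrant
        ]
        # hand computation: T_obj = 2000, visible = 800, T_non = 500
        expected = (2000 - 800 - 500) / (2000 + 500)
        assert exploratory_dls(fx, lay, "drop", trial) == pytest.approx(expected)
        # with the denominator switch, visible time leaves the denominator too
        expected_alt = (2000 - 800 - 500) / (2000 + 500 - 800)
        assert exploratory_dls(fx, lay, "drop", trial,
                               denominator_excludes_visible=True) == \
               pytest.approx(expected_alt)

    def test_never_exceeds_standard_dls(self, layouts, drop_stimulus, rng):
        lay = layouts["drop"]
        cover = CoverState(1920, 1080, 25)
        mask = rng.random(cover.grid.shape) < 0.3
        cover.grid[mask] = False
        trial = _trial_record(drop_stimulus, cover)
        a, b = trial.schedule.windows()["disruption"]
        for _ in range(50):
            pts = rng.uniform([0, 0], [1920, 1080], size=(6, 2))
            fx = [fix_at(x, y, a + i * 700, 500) for i, (x, y) in enumerate(pts)]
            std = compute_dls(fx, lay, "drop", (a, b))
            exp = exploratory_dls(fx, lay, "drop", trial)
            assert exp <= std + 1e-12


def _metrics(baseline_look=2000.0, contingent_look=12000.0, end_reason="timeout",
             n_disruption=2, uncovered=0.1):
    m = TrialMetrics("p1", "t1", "drop")
    m.look_obj_baseline_ms = baseline_look / 2
    m.look_nonobj_baseline_ms = baseline_look / 2
    m.look_obj_contingent_ms = contingent_look / 2
    m.look_nonobj_contingent_ms = contingent_look / 2
    m.n_fixations_disruption = n_disruption
    m.end_reason = end_reason
    m.uncovered_fraction = uncovered
    return m


class TestExclusions:
    def test_short_baseline_excludes_whole_trial(self):
        m = apply_trial_exclusions(_metrics(baseline_look=500.0))
        assert m.excluded_baseline
        assert "baseline" in m.exclusion_reasons

    def test_fraction_reached_keeps_short_contingent(self):
        m = apply_trial_exclusions(
            _metrics(contingent_look=4000.0, end_reason="fraction_reached",
                     uncovered=0.21))
        assert not m.excluded_contingent_disruption

    def test_disengaged_contingent_excluded(self):
        m = apply_trial_exclusions(_metrics(contingent_look=5000.0, uncovered=0.10))
        assert m.excluded_contingent_disruption

    def test_no_disruption_fixation_excludes_disruption_only(self):
        m = apply_trial_exclusions(_metrics(n_disruption=0))
        assert m.excluded_disruption_only
        assert not m.excluded_baseline
        assert not m.excluded_contingent_disruption
        assert not m.phase_valid("disruption")
        assert m.phase_valid("contingent")

    def test_idempotent(self):
        m = apply_trial_exclusions(_metrics(baseline_look=500.0))
        state = (m.excluded_baseline, m.excluded_contingent_disruption,
                 m.excluded_disruption_only, m.exclusion_reasons)
        m = apply_trial_exclusions(m)
        assert state == (m.excluded_baseline, m.excluded_contingent_disruption,
                         m.excluded_disruption_only, m.exclusion_reasons)


class TestSplitHalf:
    def test_symmetric_trace_gives_equal_halves(self, layouts):
        lay = layouts["drop"]
        sched = PhaseSchedule(t_stop=28000.0)  # contingent 8000..28000, mid 18000
        (ox, oy), _ = centers(lay, "drop")
        (nx, ny), _ = centers(lay, "drop", "nonobject")
        fx = [
            fix_at(ox, oy, 9000, 1000), fix_at(nx, ny, 12000, 2000),
            fix_at(nx, ny, 22000, 2000), fix_at(ox, oy, 26000, 1000),
        ]
        first, second = split_half_contingent(fx, lay, "drop", sched)
        assert first == pytest.approx(second)

    def test_object_looking_in_second_half_only(self, layouts):
        lay = layouts["drop"]
        sched = PhaseSchedule(t_stop=28000.0)
        (ox, oy), _ = centers(lay, "drop")
        (nx, ny), _ = centers(lay, "drop", "nonobject")
        fx = [fix_at(nx, ny, 9000, 2000), fix_at(ox, oy, 20000, 2000)]
        first, second = split_half_contingent(fx, lay, "drop", sched)
        assert first == -1.0
        assert second == 1.0

    def test_midpoint_clips_straddling_fixation(self, layouts):
        lay = layouts["drop"]
        sched = PhaseSchedule(t_stop=28000.0)
        (ox, oy), _ = centers(lay, "drop")
        fx = [fix_at(ox, oy, 17000, 2000)]  # 1 s each side of the midpoint
        first, second = split_half_contingent(fx, lay, "drop", sched)
        assert first == 1.0 and second == 1.0


def _trial_metric(pid, tid, cond, dls_b, excluded_baseline=False, age=260):
    m = TrialMetrics(pid, tid, cond, age_days=age)
    m.dls_baseline = dls_b
    m.dls_contingent = dls_b
    m.look_obj_baseline_ms = 2000.0
    m.n_fixations_disruption = 1
    m.excluded_baseline = excluded_baseline
    return m


class TestAggregation:
    def test_mean_of_condition_means(self):
        trials = [
            _trial_metric("s1", "t1", "drop", 0.2),
            _trial_metric("s1", "t2", "drop", 0.4),
            _trial_metric("s1", "t3", "rise", 0.0),
            _trial_metric("s1", "t4", "rise", 0.2),
        ]
        [summary] = aggregate_subjects(trials)
        assert summary.dls_by_condition["dls_baseline"]["drop"] == pytest.approx(0.3)
        assert summary.dls_by_condition["dls_baseline"]["rise"] == pytest.approx(0.1)
        assert summary.dls["dls_baseline"] == pytest.approx(0.2)
        assert summary.included

    def test_insufficient_condition_trials_excludes_subject(self):
        trials = [_trial_metric("s1", f"t{i}", "drop", 0.1) for i in range(3)]
        trials.append(_trial_metric("s1", "t9", "rise", 0.1))
        [summary] = aggregate_subjects(trials)
        assert not summary.included
        assert summary.n_valid_trials_drop == 3
        assert summary.n_valid_trials_rise == 1

    def test_excluded_trials_do_not_count(self):
        trials = [
            _trial_metric("s1", "t1", "drop", 0.5),
            _trial_metric("s1", "t2", "drop", 0.1, excluded_baseline=True),
            _trial_metric("s1", "t3", "drop", 0.3),
            _trial_metric("s1", "t4", "rise", 0.0),
            _trial_metric("s1", "t5", "rise", 0.2),
        ]
        [summary] = aggregate_subjects(trials)
        assert summary.n_valid_trials_drop == 2
        assert summary.dls_by_condition["dls_baseline"]["drop"] == pytest.approx(0.4)

    def test_identical_subjects_give_common_value(self):
        trials = []
        for s in range(4):
            for i, cond in enumerate(["drop", "drop", "rise", "rise"]):
                trials.append(_trial_metric(f"s{s}", f"t{s}_{i}", cond, 0.25))
        summaries = aggregate_subjects(trials)
        assert all(x.dls["dls_baseline"] == pytest.approx(0.25) for x in summaries)

    def test_undefined_trials_drop_out_of_means(self):
        trials = [
            _trial_metric("s1", "t1", "drop", 0.2),
            _trial_metric("s1", "t2", "drop", math.nan),
            _trial_metric("s1", "t3", "rise", 0.4),
            _trial_metric("s1", "t4", "rise", 0.4),
        ]
        [summary] = aggregate_subjects(trials)
        assert summary.dls_by_condition["dls_baseline"]["drop"] == pytest.approx(0.2)
        assert summary.dls["dls_baseline"] == pytest.approx(0.3)
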