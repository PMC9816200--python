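"""AOI assignment, shift filtering, dwell rules, budgets and round-trips."""

import numpy as np
import pandas as pd
import pytest

from searchgain import gaze_analysis as ga
from searchgain import synthetic_data as sd
from searchgain.gaze_analysis import AOIVisit, BACKGROUND, GazeShift
from searchgain.task_core import ElementSpec, TrialDisplay, generate_display


@pytest.fixture(scope="module")
def display():
    """Hand-built two-element display (far apart, trivially valid geometry)."""
    elements = (
        ElementSpec(0, "easy", "target", 0.0, (-6.0, 0.0)),
        ElementSpec(1, "difficult", "distractor", 45.0, (6.0, 0.0)),
    )
    return TrialDisplay(1, 1, elements, "double_target")


def shift(onset, offset, p0, p1, kind="saccade"):
    return GazeShift(kind, onset, offset, p0, p1)


class TestAssignAoi:
    def test_center_and_radius(self, display):
        assert ga.assign_aoi((-6.0, 0.0), display) == 0
        assert ga.assign_aoi((-6.0, 2.4), display) == 0  # 2.4 deg inside
        assert ga.assign_aoi((-6.0, 2.5), display) == BACKGROUND  # boundary strict
        assert ga.assign_aoi((0.0, 0.0), display) == BACKGROUND

    def test_far_point_is_background(self, display):
        assert ga.assign_aoi((20.0, -12.0), display) == BACKGROUND


class TestFilterShifts:
    def test_each_rule_fires_with_one_primary_tag(self, display):
        shifts = [
            shift(0, 4, (0, 0), (1, 1)),  # 4 ms: duration rule
            shift(10, 40, (0, 0), (-6, 0)),  # valid, into AOI 0
            shift(100, 130, (-6, 0), (-5.5, 0.5)),  # corrective within AOI 0
            shift(200, 230, (-6, 0), (30.0, 0.0)),  # off-screen offset
            shift(300, 330, (-6, 0), (6, 0)),  # valid, into AOI 1
            shift(900, 1050, (6, 0), (6, 1)),  # offset after array offset
        ]
        kept, report = ga.filter_shifts(shifts, (0.0, 1000.0), display)
        assert [s.onset_t for s in kept] == [10, 300]
        reasons = dict(zip(report["onset_t"], report["reason"]))
        assert reasons == {
            0: "duration",
            100: "corrective",
            200: "off_screen",
            900: "after_array_offset",
        }

    def test_final_background_shift_dropped(self, display):
        shifts = [
            shift(10, 40, (0, 0), (-6, 0)),
            shift(500, 530, (-6, 0), (0.0, 8.0)),  # last, to background
        ]
        kept, report = ga.filter_shifts(shifts, (0.0, 1000.0), display)
        assert len(kept) == 1
        assert report["reason"].tolist() == ["final_background"]

    def test_filtering_is_idempotent(self, display):
        shifts = [
            shift(0, 4, (0, 0), (1, 1)),
            shift(10, 40, (0, 0), (-6, 0)),
            shift(300, 330, (-6, 0), (6, 0)),
        ]
        kept, _ = ga.filter_shifts(shifts, (0.0, 1000.0), display)
        kept2, report2 = ga.filter_shifts(kept, (0.0, 1000.0), display)
        assert kept2 == kept and report2.empty


class TestDetectVisits:
    def _samples(self, segs):
        rows = []
        for t0, t1, (x, y) in segs:
            for t in range(int(t0), int(t1)):
                rows.append({"t_ms": t, "x_deg": x, "y_deg": y, "valid_flag": True})
        return pd.DataFrame(rows)

    def test_single_visit_exit_by_response(self, display):
        shifts = [shift(10, 40, (0, 0), (-6, 0))]
        samples = self._samples([(40, 1000, (-6.0, 0.0))])
        visits = ga.detect_visits(shifts, samples, display, (0.0, 1000.0))
        assert len(visits) == 1
        v = visits[0]
        assert (v.element_id, v.exit_cause) == (0, "response")
        assert v.dwell == pytest.approx(960.0)

    def test_reentry_counts_as_independent_visit(self, display):
        shifts = [
            shift(10, 40, (0, 0), (-6, 0)),
            shift(240, 270, (-6, 0), (6, 0)),
            shift(470, 500, (6, 0), (-6, 0)),
        ]
        samples = self._samples(
            [(40, 240, (-6.0, 0.0)), (270, 470, (6.0, 0.0)), (500, 900, (-6.0, 0.0))]
        )
        visits = ga.detect_visits(shifts, samples, display, (0.0, 900.0))
        assert [v.element_id for v in visits] == [0, 1, 0]

    def test_boundary_mean_position_is_background(self, display):
        shifts = [shift(10, 40, (0, 0), (-6, 2.5))]
        samples = self._samples([(40, 500, (-6.0, 2.5))])
        visits = ga.detect_visits(shifts, samples, display, (0.0, 500.0))
        assert visits == []

    def test_overlapping_shifts_rejected(self, display):
        shifts = [shift(10, 40, (0, 0), (-6, 0)), shift(30, 60, (-6, 0), (6, 0))]
        with pytest.raises(ValueError):
            ga.detect_visits(shifts, pd.DataFrame({"t_ms": [], "x_deg": [], "y_deg": []}),
                             display, (0.0, 100.0))

    def test_blink_within_visit_is_subtracted(self, display):
        # enter offset 100; blink 250-400 with gaze in same AOI either side;
        # leaving saccade offset 600 -> dwell 500 - 150 = 350
        shifts = [
            shift(70, 100, (0, 0), (-6, 0)),
            shift(250, 400, (-6, 0), (-6, 0), kind="blink"),
            shift(570, 600, (-6, 0), (6, 0)),
        ]
        samples = self._samples([(100, 250, (-6.0, 0.0)), (400, 570, (-6.0, 0.0)),
                                 (600, 800, (6.0, 0.0))])
        visits = ga.detect_visits(shifts, samples, display, (0.0, 800.0))
        assert len(visits) == 2
        assert visits[0].within_visit_blink == pytest.approx(150.0)
        assert visits[0].dwell == pytest.approx(350.0)


class TestDwellRules:
    def test_exit_by_saccade_uses_saccade_offset(self):
        v = AOIVisit(0, 100.0, 350.0, "saccade", "saccade")
        assert ga.dwell_time(v) == pytest.approx(250.0)

    def test_exit_by_blink_uses_blink_onset(self):
        # detect_visits stores exit_t = blink onset for blink exits
        v = AOIVisit(0, 100.0, 300.0, "saccade", "blink")
        assert ga.dwell_time(v) == pytest.approx(200.0)

    def test_internal_blink_subtraction(self):
        v = AOIVisit(0, 100.0, 500.0, "saccade", "saccade", within_visit_blink=150.0)
        assert v.dwell == pytest.approx(250.0)

    def test_negative_dwell_rejected(self):
        v = AOIVisit(0, 100.0, 150.0, "saccade", "saccade")
        with pytest.raises(ValueError):
            ga.dwell_time(v, within_visit_blinks=100.0)


class TestViewingBudget:
    def test_single_long_visit_masks_at_budget(self):
        visits = [AOIVisit(3, 0.0, 600.0, "saccade", "saccade")]
        events = ga.viewing_budget(visits, 500.0)
        assert len(events) == 1
        assert events[0].t_masked == pytest.approx(500.0)

    def test_carryover_across_visits(self):
        visits = [
            AOIVisit(3, 0.0, 300.0, "saccade", "saccade"),
            AOIVisit(3, 1000.0, 1250.0, "saccade", "saccade"),
        ]
        events = ga.viewing_budget(visits, 500.0)
        assert len(events) == 1
        # 200 ms into the second visit
        assert events[0].t_masked == pytest.approx(1200.0)

    def test_under_budget_never_masks(self):
        visits = [
            AOIVisit(3, 0.0, 100.0, "saccade", "saccade"),
            AOIVisit(3, 500.0, 600.0, "saccade", "saccade"),
        ]
        assert ga.viewing_budget(visits, 500.0) == []


class TestExcludeTrial:
    def _samples(self, ts, devs):
        return pd.DataFrame({"t_ms": ts, "x_deg": devs, "y_deg": np.zeros(len(ts))})

    def test_deviation_inside_window_excludes(self):
        ts = np.arange(-50, 150)
        devs = np.where(ts == 0, 2.5, 0.0)
        assert ga.exclude_trial(self._samples(ts, devs)) is True

    def test_small_deviation_retained(self):
        ts = np.arange(-50, 150)
        assert ga.exclude_trial(self._samples(ts, np.full(len(ts), 1.9))) is False

    def test_deviation_outside_window_retained(self):
        ts = np.arange(-50, 150)
        devs = np.where(ts == 100, 2.5, 0.0)
        assert ga.exclude_trial(self._samples(ts, devs)) is False

    def test_uncovered_window_is_undetermined(self):
        ts = np.arange(0, 50)
        assert ga.exclude_trial(self._samples(ts, np.zeros(len(ts)))) is None


class TestRoundTrip:
    """Noiseless synthetic streams reproduce ground truth to <= 1 ms."""

    def _run(self, rng, **stream_kwargs):
        display = generate_display(5, 5, "double_target", rng)
        roles = {e.element_id: e.role for e in display.elements}
        easy_distractors = [e.element_id for e in display.elements
                            if e.set_label == "easy" and e.role == "distractor"]
        target = next(e.element_id for e in display.elements
                      if e.set_label == "easy" and e.role == "target")
        seq = [(easy_distractors[0], 480.0), (easy_distractors[1], 390.0),
               (target, 0.0)]
        stream = sd.simulate_gaze_stream(seq, display, rng=rng, **stream_kwargs)
        shifts = ga.shifts_from_frame(stream.events)
        bounds = (0.0, stream.truth["response_t"])
        metrics, visits = ga.trial_metrics(
            shifts, stream.samples, display, bounds,
            response_t=stream.truth["response_t"],
        )
        return stream, metrics, visits

    def test_noiseless_round_trip(self, rng):
        stream, metrics, visits = self._run(rng)
        truth = stream.truth
        assert metrics.excluded is False
        assert metrics.planning_time == pytest.approx(truth["planning_time"], abs=1.0)
        assert metrics.response_time == pytest.approx(truth["response_time"], abs=1.0)
        assert [v.element_id for v in visits] == [e for e, _ in truth["dwells"]]
        for v, (_, dwell) in zip(visits, truth["dwells"]):
            assert v.dwell == pytest.approx(dwell, abs=1.0)
        # inspection time averages the two distractor dwells plus the
        # (excluded) terminal target visit
        assert metrics.inspection_time == pytest.approx((480 + 390) / 2, abs=1.0)

    def test_injected_blink_is_subtracted(self, rng):
        stream, metrics, visits = self._run(rng, inject_blink=(1, 100.0, 120.0))
        truth_dwells = dict(stream.truth["dwells"])
        blink_visit = visits[1]
        assert blink_visit.within_visit_blink == pytest.approx(120.0, abs=1.0)
        assert blink_visit.dwell == pytest.approx(truth_dwells[blink_visit.element_id],
                                                  abs=1.0)

    def test_injected_spurious_shift_filtered(self, rng):
        stream, _, visits = self._run(rng, inject_spurious_shift=(0, 3.0))
        durations = stream.events["offset_t"] - stream.events["onset_t"]
        assert (durations < ga.MIN_SHIFT_DURATION_MS).any()  # present raw
        display_ids = [e for e, _ in stream.truth["dwells"]]
        assert [v.element_id for v in visits] == display_ids  # gone after filter

    def test_dwell_sum_bounded_by_trial_duration(self, rng):
        stream, _, visits = self._run(rng)
        total = sum(v.dwell for v in visits)
        assert total <= stream.truth["response_t"] + 1.0

    def test_jittered_samples_stay_on_screen(self, rng):
        stream, _, _ = self._run(rng, jitter_sd=0.2)
        assert stream.samples["x_deg"].abs().max() < ga.SCREEN_HALF_X_DEG
        assert stream.samples["y_deg"].abs().max() < ga.SCREEN_HALF_Y_DEG
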