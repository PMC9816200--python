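"""Eye-movement analysis: AOI visits, filtering, budgets and timing.

Saccades and blinks both shift gaze and are analyzed together as *gaze
shifts*.  Elements carry invisible circular areas of interest (AOIs,
diameter 5 deg).  The interval between two consecutive gaze shifts is
attributed to an element when the mean gaze position in that interval
falls inside its AOI; each (re-)entry is an independent visit.  Gaze
shifts are filtered (duration < 5 ms, offsets after array offset,
coordinates off screen, corrective shifts within one AOI, and a final
shift to the background), dwell times follow the saccade/blink exit
rules with within-visit blink subtraction, and per-trial planning,
inspection and response times are derived from the surviving events.

Event detection itself (saccade/blink on- and offsets) is taken as
input — recordings come with a tracker's event stream — but a simple
velocity-threshold detector is provided for synthetic fixture streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_core import TrialDisplay

#: AOI radius in degrees (diameter 5 deg); membership is strict (< radius)
AOI_RADIUS_DEG = 2.5
#: identifier for gaze positions outside every AOI
BACKGROUND = -1
#: minimum gaze-shift duration retained by the filter, ms
MIN_SHIFT_DURATION_MS = 5.0
#: screen half-extent in degrees (90.70 x 51.00 cm at 106 cm viewing distance)
SCREEN_HALF_X_DEG = 23.15
SCREEN_HALF_Y_DEG = 13.54
#: deviation threshold and window for the trial-start fixation check
FIXATION_CHECK_DEG = 2.0
FIXATION_CHECK_WINDOW_MS = (-20.0, 80.0)


@dataclass(frozen=True)
class GazeShift:
    kind: str  # saccade | blink
    onset_t: float
    offset_t: float
    onset_xy: tuple[float, float]
    offset_xy: tuple[float, float]

    def __post_init__(self) -> None:
        if self.offset_t <= self.onset_t:
            raise ValueError("gaze shift must have positive duration")

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t


@dataclass
class AOIVisit:
    element_id: int
    enter_t: float  # offset of the entering shift
    exit_t: float  # offset of leaving saccade / onset of leaving blink / response
    enter_cause: str
    exit_cause: str  # saccade | blink | response | array_offset
    within_visit_blink: float = 0.0  # ms subtracted

    @property
    def dwell(self) -> float:
        return self.exit_t - self.enter_t - self.within_visit_blink


@dataclass
class MaskEvent:
    element_id: int
    t_masked: float  # absolute time at which the viewing budget elapsed


@dataclass
class TrialEyeMetrics:
    planning_time: float | None  # ms
    inspection_time: float | None  # ms, mean over eligible visits
    response_time: float | None  # ms, None when last shift landed on a distractor
    viewed_element_ids: tuple[int, ...]
    masked_elements: tuple[int, ...]
    excluded: bool
    exclusion_reason: str = ""


def shifts_from_frame(events: pd.DataFrame) -> list[GazeShift]:
    """Build gaze-shift objects from an event table."""
    return [
        GazeShift(
            str(r.kind), float(r.onset_t), float(r.offset_t),
            (float(r.onset_x), float(r.onset_y)),
            (float(r.offset_x), float(r.offset_y)),
        )
        for r in events.itertuples()
    ]


def assign_aoi(point: tuple[float, float], display: TrialDisplay) -> int:
    """Element whose AOI contains the point, or BACKGROUND.

    Membership is strict: a point exactly on the 2.5-deg boundary is
    background.  Display geometry guarantees AOIs cannot overlap.
    """
    x, y = point
    for e in display.elements:
        ex, ey = e.position
        if np.hypot(x - ex, y - ey) < AOI_RADIUS_DEG:
            return e.element_id
    return BACKGROUND


def filter_shifts(
    shifts: list[GazeShift],
    trial_bounds: tuple[float, float],
    display: TrialDisplay,
    screen_bounds: tuple[float, float] = (SCREEN_HALF_X_DEG, SCREEN_HALF_Y_DEG),
) -> tuple[list[GazeShift], pd.DataFrame]:
    """Apply the gaze-shift exclusion rules.

    Rules, in priority order (each excluded shift gets exactly one
    primary tag): duration below 5 ms; offset after stimulus-array
    offset; onset or offset coordinates outside the screen; corrective
    shifts that start and end inside the same AOI.  Additionally the
    last remaining shift of the trial is dropped when it targets the
    background.

    Returns the surviving shifts and an exclusion table
    (onset_t, reason).
    """
    _, array_offset = trial_bounds
    hx, hy = screen_bounds
    kept: list[GazeShift] = []
    excluded: list[tuple[float, str]] = []
    for s in sorted(shifts, key=lambda s: s.onset_t):
        if s.duration < MIN_SHIFT_DURATION_MS:
            excluded.append((s.onset_t, "duration"))
        elif s.offset_t > array_offset:
            excluded.append((s.onset_t, "after_array_offset"))
        elif any(abs(p[0]) > hx or abs(p[1]) > hy for p in (s.onset_xy, s.offset_xy)):
            excluded.append((s.onset_t, "off_screen"))
        elif (s.kind == "saccade"
              and assign_aoi(s.onset_xy, display) == assign_aoi(s.offset_xy, display)
              != BACKGROUND):
            # corrective saccades only: a blink staying within one AOI is
            # part of the visit (its duration is subtracted from the dwell)
            excluded.append((s.onset_t, "corrective"))
        else:
            kept.append(s)
    if kept and assign_aoi(kept[-1].offset_xy, display) == BACKGROUND:
        excluded.append((kept[-1].onset_t, "final_background"))
        kept = kept[:-1]
    report = pd.DataFrame(excluded, columns=["onset_t", "reason"])
    return kept, report


def _mean_position(samples: pd.DataFrame, t0: float, t1: float) -> tuple[float, float] | None:
    m = (samples["t_ms"] >= t0) & (samples["t_ms"] < t1)
    if "valid_flag" in samples:
        m &= samples["valid_flag"].astype(bool)
    if not m.any():
        return None
    return float(samples.loc[m, "x_deg"].mean()), float(samples.loc[m, "y_deg"].mean())


def detect_visits(
    shifts: list[GazeShift],
    samples: pd.DataFrame,
    display: TrialDisplay,
    trial_bounds: tuple[float, float],
) -> list[AOIVisit]:
    """Classify inter-shift intervals into AOI visits.

    The mean (valid) gaze position between the offset of one shift and
    the onset of the next decides whether the interval belongs to an
    AOI.  A blink separating two intervals on the same AOI does not end
    the visit; its duration is subtracted from the dwell.  The interval
    after the last shift runs to the array offset/response.
    """
    shifts = sorted(shifts, key=lambda s: s.onset_t)
    for a, b in zip(shifts, shifts[1:]):
        if b.onset_t < a.offset_t:
            raise ValueError("overlapping gaze shifts")
    _, array_offset = trial_bounds
    # raw intervals: (aoi, entering shift, leaving shift or None)
    raw: list[tuple[int, GazeShift, GazeShift | None]] = []
    for i, s in enumerate(shifts):
        t0 = s.offset_t
        t1 = shifts[i + 1].onset_t if i + 1 < len(shifts) else array_offset
        if t1 <= t0:
            continue
        pos = _mean_position(samples, t0, t1)
        if pos is None:
            continue
        aoi = assign_aoi(pos, display)
        raw.append((aoi, s, shifts[i + 1] if i + 1 < len(shifts) else None))

    visits: list[AOIVisit] = []
    i = 0
    while i < len(raw):
        aoi, enter, leave = raw[i]
        if aoi == BACKGROUND:
            i += 1
            continue
        blink_ms = 0.0
        # merge across blinks that stay within the same AOI
        while (leave is not None and leave.kind == "blink"
               and i + 1 < len(raw) and raw[i + 1][0] == aoi
               and raw[i + 1][1] is leave):
            blink_ms += leave.duration
            i += 1
            leave = raw[i][2]
        if leave is None:
            exit_t, exit_cause = array_offset, "response"
        elif leave.kind == "blink":
            exit_t, exit_cause = leave.onset_t, "blink"
        else:
            exit_t, exit_cause = leave.offset_t, "saccade"
        visit = AOIVisit(aoi, enter.offset_t, exit_t, enter.kind, exit_cause, blink_ms)
        if visit.dwell < 0:
            raise ValueError("negative dwell time; malformed input")
        visits.append(visit)
        i += 1
    return visits


def dwell_time(visit: AOIVisit, within_visit_blinks: float = 0.0) -> float:
    """Dwell of one visit, ms, with optional extra blink subtraction."""
    d = visit.dwell - within_visit_blinks
    if d < 0:
        raise ValueError("negative dwell time; malformed input")
    return d


def viewing_budget(
    visits: list[AOIVisit], budget: float = 500.0
) -> list[MaskEvent]:
    """Track cumulative per-element dwell against the viewing budget.

    Unused budget from earlier visits carries over; an element is
    flagged masked at the moment its cumulative dwell reaches the
    budget.
    """
    by_element: dict[int, list[AOIVisit]] = {}
    for v in sorted(visits, key=lambda v: v.enter_t):
        by_element.setdefault(v.element_id, []).append(v)
    events: list[MaskEvent] = []
    for eid, vs in by_element.items():
        cum = 0.0
        for v in vs:
            if cum + v.dwell >= budget:
                events.append(MaskEvent(eid, v.enter_t + (budget - cum)))
                break
            cum += v.dwell
    return sorted(events, key=lambda e: e.t_masked)


def exclude_trial(
    samples: pd.DataFrame,
    window: tuple[float, float] = FIXATION_CHECK_WINDOW_MS,
    threshold: float = FIXATION_CHECK_DEG,
) -> bool | None:
    """Trial-start fixation check.

    True when any sample between -20 and +80 ms around stimulus onset
    deviates more than 2 deg from the fixation cross; None when the
    samples do not cover the window (undetermined).
    """
    t = samples["t_ms"]
    if t.min() > window[0] or t.max() < window[1]:
        return None
    m = (t >= window[0]) & (t <= window[1])
    dev = np.hypot(samples.loc[m, "x_deg"], samples.loc[m, "y_deg"])
    return bool((dev > threshold).any())


def trial_metrics(
    shifts: list[GazeShift],
    samples: pd.DataFrame,
    display: TrialDisplay,
    trial_bounds: tuple[float, float],
    response_t: float | None = None,
    mode: str = "double_target",
    budget: float = 500.0,
) -> tuple[TrialEyeMetrics, list[AOIVisit]]:
    """Full per-trial pipeline: filter, detect visits, compute timings.

    Planning time is stimulus onset to the offset of the first valid
    shift.  Inspection time averages visit dwells, excluding target
    visits in single-target mode and the terminal (response-exited)
    target visit in double-target mode.  Response time runs from the
    last shift's offset to the response and is undefined when that
    shift landed on a distractor.
    """
    onset, array_offset = trial_bounds
    response_t = array_offset if response_t is None else response_t
    fix_check = exclude_trial(samples)
    excluded = bool(fix_check) if fix_check is not None else False
    reason = "fixation_error" if excluded else ("undetermined" if fix_check is None else "")

    kept, _ = filter_shifts(shifts, trial_bounds, display)
    visits = detect_visits(kept, samples, display, trial_bounds)

    planning = kept[0].offset_t - onset if kept else None

    roles = {e.element_id: e.role for e in display.elements}
    eligible: list[float] = []
    for i, v in enumerate(visits):
        is_target = roles.get(v.element_id) == "target"
        terminal = v.exit_cause == "response"
        if is_target and (mode == "single_target" or terminal):
            continue
        eligible.append(v.dwell)
    inspection = float(np.mean(eligible)) if eligible else None

    response = None
    if kept:
        last = kept[-1]
        landing = assign_aoi(last.offset_xy, display)
        if landing != BACKGROUND and roles.get(landing) == "target":
            response = response_t - last.offset_t
    masked = tuple(e.element_id for e in viewing_budget(visits, budget))
    metrics = TrialEyeMetrics(
        planning_time=planning,
        inspection_time=inspection,
        response_time=response,
        viewed_element_ids=tuple(v.element_id for v in visits),
        masked_elements=masked,
        excluded=excluded,
        exclusion_reason=reason,
    )
    return metrics, visits


def detect_shifts_from_samples(
    samples: pd.DataFrame, velocity_threshold: float = 30.0
) -> list[GazeShift]:
    """Minimal velocity-threshold saccade detector for fixture streams.

    Consecutive samples moving faster than ``velocity_threshold`` deg/s
    are grouped into one saccade; invalid-sample runs become blinks.
    Intended for synthetic traces only, not as a replacement for a
    tracker's event stream.
    """
    t = samples["t_ms"].to_numpy(dtype=float)
    x = samples["x_deg"].to_numpy(dtype=float)
    y = samples["y_deg"].to_numpy(dtype=float)
    valid = samples["valid_flag"].to_numpy(dtype=bool) if "valid_flag" in samples \
        else np.ones_like(t, dtype=bool)
    dt = np.diff(t) / 1000.0  # s
    speed = np.hypot(np.diff(x), np.diff(y)) / np.maximum(dt, 1e-9)
    moving = (speed > velocity_threshold) & valid[:-1] & valid[1:]
    blink = ~valid[:-1] | ~valid[1:]
    events: list[GazeShift] = []

    def flush(kind: str, i0: int, i1: int) -> None:
        events.append(GazeShift(
            kind, t[i0], t[i1], (x[i0], y[i0]), (x[i1], y[i1])
        ))

    state, start = None, 0
    for i in range(len(moving)):
        lab = "blink" if blink[i] else ("saccade" if moving[i] else None)
        if lab != state:
            if state is not None:
                flush(state, start, i)
            state, start = lab, i
    if state is not None:
        flush(state, start, len(moving))
    return events
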