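"""Synthetic sessions and raw gaze streams.

Simulates complete experimental sessions in place of human
participants: trials are drawn miniblock-wise, fixation sequences come
from the generative model, per-fixation dwell times follow a truncated
normal under the 500-ms per-element viewing budget, responses are
Bernoulli with the found target's accuracy, and the 390-s session
clock is decremented by each trial's stimulus-onset-to-response
duration (the final trial may overshoot, matching the update-after-
trial bookkeeping of the task).

``simulate_gaze_stream`` additionally renders one trial's fixation
sequence as a 1-kHz raw gaze-sample trace with saccade events and
(optionally) injected blinks and sub-threshold spurious shifts; it is
the ground-truth generator against which the gaze-analysis pipeline is
validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import generative_model as gm
from .ideal_observer import delta_g_vector
from .task_core import (
    Mode,
    ParticipantProfile,
    SessionConfig,
    SetLabel,
    TrialDisplay,
    displays_to_frame,
    generate_display,
    make_miniblock,
)

#: fixed duration of simulated saccade segments, ms
SACCADE_DURATION_MS = 30.0


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    condition_ne: int
    n_distractors: int  # distractors on screen (8 in double-target trials)
    chosen_target: SetLabel
    n_fixations: int
    fixations_on_easy: int
    fixations_on_chosen: int
    correct: bool
    points: float
    planning_time: float  # s
    search_time: float  # s, stimulus onset to response
    response_time: float  # s
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class FixationRecord:
    trial_id: int
    fixation_index: int  # 1-based
    element_id: int
    set_label: SetLabel
    role: str
    dwell: float  # ms
    enter_cause: str = "saccade"
    exit_cause: str = "saccade"


@dataclass
class SessionLog:
    config: SessionConfig
    profile: ParticipantProfile
    trials: list[TrialRecord] = field(default_factory=list)
    remaining_time_trace: list[float] = field(default_factory=list)

    @property
    def accumulated_points(self) -> float:
        return float(sum(t.points for t in self.trials))

    @property
    def gain_rate(self) -> float:
        """Realized session gain, cents per second of session time."""
        return 100.0 * self.accumulated_points / self.config.session_time

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "config": asdict(self.config),
            "profile": asdict(self.profile),
            "n_trials": len(self.trials),
            "accumulated_points": self.accumulated_points,
            "gain_rate_cents_per_s": self.gain_rate,
            "remaining_time_trace": self.remaining_time_trace,
        }


@dataclass
class SessionResult:
    """Everything one simulated session produced."""

    log: SessionLog
    fixations: list[FixationRecord]
    displays: dict[int, TrialDisplay]

    def trials_frame(self) -> pd.DataFrame:
        from dataclasses import asdict

        return pd.DataFrame([asdict(t) for t in self.log.trials])

    def fixations_frame(self) -> pd.DataFrame:
        from dataclasses import asdict

        return pd.DataFrame([asdict(f) for f in self.fixations])

    def displays_frame(self) -> pd.DataFrame:
        return displays_to_frame(self.displays)


def _draw_dwells(n: int, profile: ParticipantProfile, config: SessionConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal dwell times in seconds, support (0, budget]."""
    mu, sd = profile.t_insp, profile.dwell_sd
    hi = config.viewing_budget / 1000.0
    a, b = (0.0 - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def _sequence_to_elements(
    sequence: tuple[tuple[SetLabel, str], ...],
    display: TrialDisplay,
    rng: np.random.Generator,
) -> list[int]:
    """Attach concrete element ids to a set-level fixation sequence.

    The generative model is position-blind, so distractor identities
    within a set are exchangeable; they are assigned in a random order
    without replacement.
    """
    pools: dict[SetLabel, list[int]] = {}
    targets: dict[SetLabel, int] = {}
    for e in display.elements:
        if e.role == "target":
            targets[e.set_label] = e.element_id
        else:
            pools.setdefault(e.set_label, []).append(e.element_id)
    for ids in pools.values():
        rng.shuffle(ids)
    out = []
    for set_label, role in sequence:
        if role == "target":
            out.append(targets[set_label])
        else:
            out.append(pools[set_label].pop())
    return out


def _simulate_single_target_sequence(
    set_label: SetLabel, n_set: int, rng: np.random.Generator
) -> tuple[tuple[SetLabel, str], ...]:
    """Uniform random inspection order without replacement within one set."""
    target_pos = int(rng.integers(n_set))  # 0-based position of the target
    seq = [(set_label, "distractor")] * target_pos + [(set_label, "target")]
    return tuple(seq)


def simulate_session(
    profile: ParticipantProfile,
    config: SessionConfig | None = None,
    rng: np.random.Generator | None = None,
    fixation_error_rate: float = 0.0,
) -> SessionResult:
    """Simulate one complete session against the session clock.

    Trials are drawn miniblock-wise (every condition once per block, in
    random order); a new trial starts as long as remaining time is
    positive.  Trial duration is planning + the sum of distractor dwell
    times + response.  On an injected fixation error the trial is
    flagged excluded and scored as a loss, as in the task.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    log = SessionLog(config, profile)
    fixations: list[FixationRecord] = []
    displays: dict[int, TrialDisplay] = {}
    dg = delta_g_vector(profile, config)

    remaining = config.session_time
    trial_id = 0
    block: list = []
    while remaining > 0:
        if not block:
            block = make_miniblock(config.mode, rng)
        cond = block.pop(0)
        if config.mode == "double_target":
            ne, nd = cond, 10 - cond
            display = generate_display(ne, nd, "double_target", rng)
            sim = gm.simulate_trial((ne, nd), profile, rng=rng, config=config,
                                    delta_g=float(dg[ne - 1]))
            sequence = sim.sequence
            chosen = sim.chosen_target
            condition_ne = ne
        else:
            set_label, k = cond
            ne, nd = (k + 1, 0) if set_label == "easy" else (0, k + 1)
            display = generate_display(ne, nd, "single_target", rng)
            sequence = _simulate_single_target_sequence(set_label, k + 1, rng)
            chosen = set_label
            condition_ne = ne

        element_ids = _sequence_to_elements(sequence, display, rng)
        dwells_s = _draw_dwells(len(sequence), profile, config, rng)
        fixation_error = rng.random() < fixation_error_rate
        n_distractor_fix = len(sequence) - 1
        duration = profile.t_plan + float(dwells_s[:n_distractor_fix].sum()) \
            + profile.t_resp
        correct = bool(rng.random() < profile.accuracy(chosen))
        if fixation_error:
            points = config.reward_incorrect
        else:
            points = config.reward_correct if correct else config.reward_incorrect

        record = TrialRecord(
            trial_id=trial_id,
            condition_ne=condition_ne,
            n_distractors=len(display.elements) - len(display.targets),
            chosen_target=chosen,
            n_fixations=len(sequence),
            fixations_on_easy=sum(s == "easy" for s, _ in sequence),
            fixations_on_chosen=sum(s == chosen for s, _ in sequence),
            correct=correct,
            points=float(points),
            planning_time=profile.t_plan,
            search_time=duration,
            response_time=profile.t_resp,
            excluded=fixation_error,
            exclusion_reason="fixation_error" if fixation_error else "",
        )
        log.trials.append(record)
        displays[trial_id] = display
        for idx, ((set_label_i, role), eid) in enumerate(zip(sequence, element_ids)):
            is_last = idx == len(sequence) - 1
            dwell_ms = profile.t_resp * 1000.0 if is_last else dwells_s[idx] * 1000.0
            fixations.append(FixationRecord(
                trial_id=trial_id,
                fixation_index=idx + 1,
                element_id=eid,
                set_label=set_label_i,
                role=role,
                dwell=float(dwell_ms),
                exit_cause="response" if is_last else "saccade",
            ))
        remaining -= duration
        log.remaining_time_trace.append(remaining)
        trial_id += 1
    return SessionResult(log, fixations, displays)


@dataclass
class GazeStream:
    """A 1-kHz gaze trace plus ground-truth events and metrics."""

    samples: pd.DataFrame  # t_ms, x_deg, y_deg, valid_flag
    events: pd.DataFrame  # kind, onset_t, offset_t, onset_x, onset_y, offset_x, offset_y
    truth: dict  # planning_time, dwells (per element visit), response_time, response_t


def simulate_gaze_stream(
    fixation_sequence: list[tuple[int, float]],
    display: TrialDisplay,
    config: SessionConfig | None = None,
    rng: np.random.Generator | None = None,
    planning_time_ms: float = 237.0,
    response_time_ms: float = 1052.0,
    jitter_sd: float = 0.0,
    pre_onset_ms: float = 100.0,
    saccade_duration_ms: float = SACCADE_DURATION_MS,
    inject_blink: tuple[int, float, float] | None = None,
    inject_spurious_shift: tuple[int, float] | None = None,
) -> GazeStream:
    """Render a fixation sequence as raw gaze samples plus shift events.

    Parameters
    ----------
    fixation_sequence
        ``(element_id, dwell_ms)`` per fixation, in order.  Dwell is on
        the offline definition: entering-shift offset to leaving-shift
        offset; the stationary period is therefore ``dwell - saccade``.
        The last fixation is held until the response (its dwell entry is
        ignored and replaced by ``response_time_ms``).
    inject_blink
        ``(fixation_index, onset_offset_ms, duration_ms)``: a blink
        fully inside that fixation's stationary period (samples
        invalid); ground-truth dwell for that visit is reduced by the
        blink duration, per the blink-subtraction rule.
    inject_spurious_shift
        ``(fixation_index, duration_ms)``: a sub-threshold "shift"
        event of the given duration inserted mid-fixation that does not
        move gaze; it must be removed by the 5-ms duration filter.
    """
    if not fixation_sequence:
        raise ValueError("fixation sequence must be non-empty")
    config = config or SessionConfig()
    rng = np.random.default_rng() if rng is None else rng

    events_rows = []
    seg: list[tuple[float, float, np.ndarray, bool]] = []  # t0, t1, pos, valid
    truth_dwells: list[tuple[int, float]] = []

    def pos_of(eid: int) -> np.ndarray:
        return np.asarray(display.element(eid).position, dtype=float)

    # pre-onset fixation on the cross, then the first (planning) saccade
    origin = np.zeros(2)
    first_onset = planning_time_ms - saccade_duration_ms
    if first_onset <= 0:
        raise ValueError("planning time must exceed the saccade duration")
    seg.append((-pre_onset_ms, first_onset, origin, True))
    prev_pos = origin
    t = first_onset
    for idx, (eid, dwell_ms) in enumerate(fixation_sequence):
        p = pos_of(eid)
        events_rows.append(("saccade", t, t + saccade_duration_ms, prev_pos, p))
        t += saccade_duration_ms  # entering-shift offset
        enter_offset = t
        is_last = idx == len(fixation_sequence) - 1
        if is_last:
            stationary = response_time_ms
        else:
            stationary = dwell_ms - saccade_duration_ms
            if stationary <= 0:
                raise ValueError("dwell must exceed the saccade duration")
        blink_ms = 0.0
        if inject_blink is not None and inject_blink[0] == idx:
            b_rel, b_dur = inject_blink[1], inject_blink[2]
            if b_rel + b_dur >= stationary:
                raise ValueError("blink must fit inside the stationary period")
            seg.append((t, t + b_rel, p, True))
            seg.append((t + b_rel, t + b_rel + b_dur, p, False))
            events_rows.append(("blink", t + b_rel, t + b_rel + b_dur, p, p))
            seg.append((t + b_rel + b_dur, t + stationary, p, True))
            blink_ms = b_dur
        else:
            seg.append((t, t + stationary, p, True))
        if inject_spurious_shift is not None and inject_spurious_shift[0] == idx:
            s_dur = inject_spurious_shift[1]
            s_on = t + stationary / 2
            events_rows.append(("saccade", s_on, s_on + s_dur, p, p))
        t += stationary
        if is_last:
            truth_dwells.append((eid, response_time_ms))
        else:
            # offline dwell: enter offset to leaving-saccade offset
            truth_dwells.append(
                (eid, (t + saccade_duration_ms) - enter_offset - blink_ms)
            )
        prev_pos = p
    response_t = t  # response at last-shift offset + response interval

    # rasterize segments at 1 ms
    t_ms = np.arange(-pre_onset_ms, np.ceil(response_t) + 1)
    x = np.empty_like(t_ms, dtype=float)
    y = np.empty_like(t_ms, dtype=float)
    valid = np.ones_like(t_ms, dtype=bool)
    for t0, t1, p, ok in seg:
        m = (t_ms >= t0) & (t_ms < t1)
        x[m], y[m] = p[0], p[1]
        valid[m] &= ok
    # saccade samples: linear interpolation
    for kind, on, off, p0, p1 in events_rows:
        if kind != "saccade" or off <= on:
            continue
        m = (t_ms >= on) & (t_ms < off)
        frac = (t_ms[m] - on) / (off - on)
        x[m] = p0[0] + frac * (np.asarray(p1)[0] - np.asarray(p0)[0])
        y[m] = p0[1] + frac * (np.asarray(p1)[1] - np.asarray(p0)[1])
    m_after = t_ms >= response_t
    x[m_after], y[m_after] = prev_pos
    if jitter_sd > 0:
        stationary_mask = np.ones_like(valid)
        for kind, on, off, _, _ in events_rows:
            stationary_mask &= ~((t_ms >= on) & (t_ms < off))
        x = x + np.where(stationary_mask, rng.normal(0, jitter_sd, x.shape), 0.0)
        y = y + np.where(stationary_mask, rng.normal(0, jitter_sd, y.shape), 0.0)

    samples = pd.DataFrame(
        {"t_ms": t_ms, "x_deg": x, "y_deg": y, "valid_flag": valid}
    )
    events = pd.DataFrame(
        [
            {
                "kind": kind,
                "onset_t": on,
                "offset_t": off,
                "onset_x": float(np.asarray(p0)[0]),
                "onset_y": float(np.asarray(p0)[1]),
                "offset_x": float(np.asarray(p1)[0]),
                "offset_y": float(np.asarray(p1)[1]),
            }
            for kind, on, off, p0, p1 in events_rows
        ]
    ).sort_values("onset_t", ignore_index=True)
    truth = {
        "planning_time": planning_time_ms,
        "dwells": truth_dwells,
        "response_time": response_time_ms,
        "response_t": response_t,
        "stimulus_onset": 0.0,
    }
    return GazeStream(samples, events, truth)
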