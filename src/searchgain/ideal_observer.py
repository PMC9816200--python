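"""Ideal-observer expected gain per unit of time for each target option.

In the double-target condition an observer can pursue either the easy
or the difficult target.  Pursuing the target of a set with ``n``
elements under serial self-terminating search costs, in expectation,
``(n - 1) / 2`` distractor inspections before the target is fixated.
The expected monetary gain of a target option is its expected reward
per trial (driven by that set's discrimination accuracy and the
symmetric +/-2-cent payoff) divided by the expected trial time
(planning + inspections + response).  The option with the larger gain
rate is the one an ideal observer searches for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_core import ParticipantProfile, SessionConfig, SetLabel

CONDITIONS = tuple(range(1, 10))  # N_E = 1..9, N_D = 10 - N_E


@dataclass(frozen=True)
class ConditionGain:
    """Gain per unit time of both target options in one set-size condition."""

    condition_ne: int
    g_easy: float  # cents/s
    g_difficult: float  # cents/s

    @property
    def delta_g(self) -> float:
        return self.g_easy - self.g_difficult

    @property
    def optimal_target(self) -> SetLabel:
        # tie broken toward the easy target
        return "easy" if self.delta_g >= 0 else "difficult"


def expected_inspections(n_set: int) -> float:
    """Expected distractor inspections before the target, set size ``n_set``.

    Under a uniformly random inspection order without replacement the
    target's position is uniform on 1..n, so on average ``(n - 1) / 2``
    distractors are fixated first.
    """
    if n_set < 1:
        raise ValueError("n_set must be at least 1")
    return (n_set - 1) / 2


def _set_size(target: SetLabel, ne: int, nd: int) -> int:
    return ne if target == "easy" else nd


def expected_trial_time(
    target: SetLabel, condition: tuple[int, int], profile: ParticipantProfile
) -> float:
    """Expected seconds to complete a trial pursuing ``target``.

    Planning plus one inspection per expected distractor fixation plus
    the response interval.  The target's own viewing time is part of the
    response interval (response time is measured from the offset of the
    last gaze shift), so no separate target-dwell term appears.
    """
    ne, nd = condition
    n = _set_size(target, ne, nd)
    return profile.t_plan + expected_inspections(n) * profile.t_insp + profile.t_resp


def expected_reward(
    target: SetLabel,
    profile: ParticipantProfile,
    config: SessionConfig | None = None,
) -> float:
    """Expected cents per trial when discriminating ``target``."""
    config = config or SessionConfig()
    p = profile.accuracy(target)
    return 100.0 * (p * config.reward_correct + (1 - p) * config.reward_incorrect)


def gain_table(
    profile: ParticipantProfile, config: SessionConfig | None = None
) -> list[ConditionGain]:
    """Per-condition gain rates of both target options, N_E = 1..9."""
    config = config or SessionConfig()
    out = []
    for ne in CONDITIONS:
        nd = 10 - ne
        g = {
            t: expected_reward(t, profile, config)
            / expected_trial_time(t, (ne, nd), profile)
            for t in ("easy", "difficult")
        }
        out.append(ConditionGain(ne, g["easy"], g["difficult"]))
    return out


def gain_frame(profile: ParticipantProfile,
               config: SessionConfig | None = None) -> pd.DataFrame:
    """Gain table in the on-disk schema."""
    rows = gain_table(profile, config)
    return pd.DataFrame(
        {
            "condition_ne": [r.condition_ne for r in rows],
            "g_easy": [r.g_easy for r in rows],
            "g_difficult": [r.g_difficult for r in rows],
            "delta_g": [r.delta_g for r in rows],
            "optimal_target": [r.optimal_target for r in rows],
        }
    )


def delta_g_vector(profile: ParticipantProfile,
                   config: SessionConfig | None = None) -> np.ndarray:
    """Easy-minus-difficult gain difference per condition, cents/s."""
    return np.array([r.delta_g for r in gain_table(profile, config)])


def theoretical_max_gain(
    profile: ParticipantProfile, config: SessionConfig | None = None
) -> float:
    """Best achievable session gain rate, cents/s.

    An equal mix of the nine conditions, always pursuing the per-
    condition optimal target and never fixating the other set.  The
    session-level rate is total expected reward over total expected
    time (a ratio of sums, matching how empirical gain is computed from
    accumulated reward and the session clock), not a mean of
    per-condition rates.
    """
    config = config or SessionConfig()
    reward = time = 0.0
    for row in gain_table(profile, config):
        t = row.optimal_target
        reward += expected_reward(t, profile, config)
        time += expected_trial_time(t, (row.condition_ne, 10 - row.condition_ne), profile)
    return reward / time
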