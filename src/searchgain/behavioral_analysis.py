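"""Results-level computations on trial and fixation tables.

Regression of search time on distractor count, the normalized choice
regression, gaze-shift proportion metrics against their chance levels,
the condition-then-participant averaging rule, gain summaries and
paired comparisons.  All operations consume the delimited-text trial /
fixation / display tables produced by the session simulator (or any
table with the same schema).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import generative_model as gm
from . import ideal_observer
from .task_core import ParticipantProfile, SessionConfig, chance_levels


@dataclass(frozen=True)
class ChoiceCurve:
    """Per-condition proportion of easy-target choices and its regression.

    Proportions are indexed by the number of easy distractors (0..8,
    i.e. ``N_E - 1``).  The regression is on centered variables:
    chance (0.5) is subtracted from the proportions and 4 from the easy
    distractor count, so a zero intercept means balanced choice in the
    4-vs-4 condition.
    """

    proportions: tuple[float, ...]
    n_per_condition: tuple[int, ...]
    intercept: float
    slope: float


@dataclass(frozen=True)
class GainSummary:
    empirical_gain: float  # cents/s
    theoretical_gain: float  # cents/s
    predicted_gain: float  # cents/s


@dataclass(frozen=True)
class PairedComparison:
    mean_difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    correlation: float
    n: int
    zero_variance: bool


def _valid(trials: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in trials:
        return trials[~trials["excluded"].astype(bool)]
    return trials


def search_time_slope(trials: pd.DataFrame) -> tuple[float, float]:
    """OLS slope (ms per distractor) and intercept (ms) of search time.

    Following the averaging rule, trial search times are first averaged
    within each set-size condition (distractor count) and the line is
    fitted to the condition means.
    """
    t = _valid(trials)
    means = t.groupby("n_distractors")["search_time"].mean()
    if len(means) < 2:
        raise ValueError("need at least two distinct distractor counts")
    slope, intercept = np.polyfit(means.index.to_numpy(dtype=float),
                                  means.to_numpy() * 1000.0, 1)
    return float(slope), float(intercept)


def choice_regression(trials: pd.DataFrame) -> ChoiceCurve:
    """Normalized linear regression of easy-target choices.

    Expects double-target trials (``condition_ne`` in 1..9).
    """
    t = _valid(trials)
    props = np.full(9, np.nan)
    ns = np.zeros(9, dtype=int)
    for ne, g in t.groupby("condition_ne"):
        k = int(ne) - 1  # easy distractors
        props[k] = (g["chosen_target"] == "easy").mean()
        ns[k] = len(g)
    mask = ns > 0
    if mask.sum() < 2:
        raise ValueError("need at least two observed conditions")
    x = np.flatnonzero(mask).astype(float) - 4.0
    y = props[mask] - 0.5
    slope, intercept = np.polyfit(x, y, 1)
    return ChoiceCurve(tuple(props), tuple(int(n) for n in ns),
                       float(intercept), float(slope))


def _closest_element_id(display_rows: pd.DataFrame,
                        reference: tuple[float, float],
                        exclude: int | None = None) -> int:
    d = display_rows
    if exclude is not None:
        d = d[d["element_id"] != exclude]
    dist = np.hypot(d["x_deg"] - reference[0], d["y_deg"] - reference[1])
    return int(d.loc[dist.idxmin(), "element_id"])


def gaze_shift_proportions(
    fixations: pd.DataFrame,
    displays: pd.DataFrame,
    trials: pd.DataFrame,
    shift_index: int = 1,
    per_condition: bool = True,
) -> dict[str, float]:
    """Proportion metrics for the first or second gaze shift in trials.

    Computes, over non-excluded trials with a gaze shift at the given
    index, the proportion landing on (a) the set of the eventually
    chosen target, (b) the easy set, (c) the smaller set (equal-set
    conditions excluded), and (d) the element closest to the current
    fixation location (the fixation cross for the first shift, the
    previously fixated element for the second).  By default each
    proportion is first computed per set-size condition and then
    averaged (the condition-then-participant rule); ``per_condition=
    False`` pools all trials.  Chance levels are attached with a
    ``chance_`` prefix.
    """
    if shift_index not in (1, 2):
        raise ValueError("shift_index must be 1 or 2")
    t = _valid(trials).set_index("trial_id")
    fx = fixations[fixations["trial_id"].isin(t.index)]
    first = fx[fx["fixation_index"] == 1].set_index("trial_id")
    at_idx = fx[fx["fixation_index"] == shift_index].set_index("trial_id")

    rows = []
    for trial_id, f in at_idx.iterrows():
        tr = t.loc[trial_id]
        ne = int(tr["condition_ne"])
        nd = 10 - ne
        d = displays[displays["trial_id"] == trial_id]
        if shift_index == 1:
            ref: tuple[float, float] = (0.0, 0.0)
            exclude = None
        else:
            prev = first.loc[trial_id]
            prow = d[d["element_id"] == prev["element_id"]].iloc[0]
            ref = (float(prow["x_deg"]), float(prow["y_deg"]))
            exclude = int(prev["element_id"])
        rows.append(
            {
                "condition_ne": ne,
                "chosen_set": float(f["set_label"] == tr["chosen_target"]),
                "easy_set": float(f["set_label"] == "easy"),
                "smaller_set": np.nan if ne == nd else
                    float(f["set_label"] == ("easy" if ne < nd else "difficult")),
                "closest_element":
                    float(int(f["element_id"]) == _closest_element_id(d, ref, exclude)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no trials with a gaze shift at the requested index")
    out: dict[str, float] = {}
    for metric in ("chosen_set", "easy_set", "smaller_set", "closest_element"):
        vals = df[["condition_ne", metric]].dropna()
        if per_condition:
            out[metric] = float(vals.groupby("condition_ne")[metric].mean().mean())
        else:
            out[metric] = float(vals[metric].mean())
    ch = chance_levels()
    out["chance_chosen_set"] = 0.5
    out["chance_easy_set"] = ch["easy_set"]
    out["chance_smaller_set"] = ch["smaller_set"]
    out["chance_closest_element"] = ch["closest_element"]
    return out


def condition_then_participant_mean(values_by_condition: dict) -> float:
    """Unweighted mean of per-condition means (the averaging rule)."""
    if not values_by_condition:
        raise ValueError("need at least one condition")
    return float(np.mean([np.mean(v) for v in values_by_condition.values()]))


def gain_summary(
    session_log,
    profile: ParticipantProfile,
    sigma_d: float | None = None,
    sigma_f: float | None = None,
    config: SessionConfig | None = None,
) -> GainSummary:
    """Empirical, theoretical-maximum and model-predicted session gain.

    Empirical gain is accumulated points (in cents) over the session
    time; the theoretical maximum assumes per-condition optimal target
    choice with search confined to its set; the prediction evaluates
    the generative model at the supplied (or profile) noise levels,
    aggregated as a ratio of sums over the equal condition mix.
    """
    config = config or (session_log.config if session_log is not None else SessionConfig())
    empirical = session_log.gain_rate if session_log is not None else np.nan
    theoretical = ideal_observer.theoretical_max_gain(profile, config)
    predicted = gm.predicted_gain_rate(profile, sigma_d, sigma_f, config)
    return GainSummary(float(empirical), float(theoretical), float(predicted))


def paired_comparison(x, y) -> PairedComparison:
    """Paired-sample comparison: mean difference, 95% CI, t, Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = x - y
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    zero_var = sd == 0.0
    se = sd / np.sqrt(n)
    if zero_var:
        tstat = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        ci = (mean, mean)
    else:
        tstat = mean / se
        p = float(2 * stats.t.sf(abs(tstat), n - 1))
        half = float(stats.t.ppf(0.975, n - 1) * se)
        ci = (mean - half, mean + half)
    if x.std() == 0 or y.std() == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return PairedComparison(mean, ci[0], ci[1], float(tstat), p, r, n, zero_var)
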