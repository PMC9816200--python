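"""Generative stochastic model of fixation sequences during search.

The model receives the ideal-observer gain difference between the easy
and difficult target option (``delta_g``, cents/s) for one set-size
condition and turns it into behavior in three stages:

1. *Decision noise*: the gain difference is corrupted by additive
   Gaussian noise with SD ``sigma_d``, allowing occasional pursuit of
   the lower-gain target.
2. *Fixation bias*: the noisy gain difference is squashed through a
   cumulative Gaussian with SD ``sigma_f`` into a bias ``b`` in [0, 1]
   toward the easy set, allowing occasional fixations on the non-chosen
   set.  The bias acts as an odds weight ``w = b / (1 - b)`` on the
   remaining easy-element count when sampling the next fixated set.
3. *Search*: fixations are generated by a binary decision tree.  At
   each step the easy set is fixated with probability
   ``w e / (w e + d)``, where ``e`` and ``d`` are the remaining easy
   and difficult element counts (targets included); the fixation lands
   on that set's target with probability 1/size, otherwise one
   distractor is removed from the set.  The recursion terminates when
   either target is fixated.

``enumerate_tree`` evaluates the tree exactly (all terminal paths); the
noise marginal over stage 1 is evaluated with fixed-order Gauss-Hermite
quadrature so predictions are deterministic.  ``simulate_trial`` draws
one ancestral sample from the same process and is used both for
synthetic sessions and as a Monte-Carlo oracle for the enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .ideal_observer import delta_g_vector, expected_reward, expected_trial_time
from .task_core import ParticipantProfile, SessionConfig, SetLabel

#: number of Gauss-Hermite nodes used to marginalize over decision noise
GAUSS_HERMITE_ORDER = 61


@dataclass(frozen=True)
class FixationBias:
    """Bias toward the easy set, on probability and odds scales."""

    b: float  # cumulative-Gaussian output in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("bias must lie in [0, 1]")

    @property
    def w(self) -> float:
        """Odds-scale weight b / (1 - b); infinite at b = 1."""
        return np.inf if self.b == 1.0 else self.b / (1.0 - self.b)


@dataclass(frozen=True)
class TreePrediction:
    """Exact expectations of the decision tree for one condition and weight."""

    p_choose_easy: float
    expected_fixations: float
    expected_fix_easy: float
    expected_fix_difficult: float
    expected_fix_chosen: float  # E[fixations on the found-target's set], target included
    p_fix_chosen: float  # E[fixations on found-target's set / total], target included
    expected_search_time: float = np.nan  # s, filled when a profile is supplied
    expected_reward: float = np.nan  # cents, likewise

    @property
    def gain_rate(self) -> float:
        """Expected cents per second for this condition."""
        return self.expected_reward / self.expected_search_time


def bias_from_noisy_gain(delta_g_noisy: float, sigma_f: float) -> FixationBias:
    """Map a noisy gain difference to a fixation bias via a Gaussian CDF.

    ``b = Phi(delta_g_noisy / sigma_f)``.  At ``sigma_f = 0`` the CDF
    degenerates to a step: b is 0, 0.5 or 1 by the sign of the input.
    """
    if sigma_f < 0:
        raise ValueError("sigma_f must be non-negative")
    if sigma_f == 0:
        b = 0.5 if delta_g_noisy == 0 else float(delta_g_noisy > 0)
    else:
        b = float(ndtr(delta_g_noisy / sigma_f))
    return FixationBias(b)


def _tree_expectations(e0: int, d0: int, w: np.ndarray) -> dict[str, np.ndarray]:
    """Exact tree expectations, vectorized over an array of odds weights.

    Reaching the state with ``i`` easy and ``j`` difficult distractors
    removed fixes the fixation counts along every path into it, so the
    full-path expectations reduce to a dynamic program over the
    (e0 x d0) state grid; each state contributes its two terminal
    branches (easy target hit, difficult target hit).
    """
    w = np.asarray(w, dtype=float)
    finite = ~np.isinf(w)
    acc = {k: np.zeros_like(w) for k in
           ("p_total", "p_easy", "e_fix", "e_fix_easy", "e_fix_diff",
            "e_fix_chosen", "p_fix_chosen")}
    prob = np.zeros((e0, d0) + w.shape)
    prob[0, 0] = 1.0
    for s in range(e0 + d0 - 1):  # total distractors removed so far
        for i in range(max(0, s - d0 + 1), min(s, e0 - 1) + 1):
            j = s - i
            p = prob[i, j]
            if not np.any(p):
                continue
            e, d = e0 - i, d0 - j  # remaining counts, targets included
            q = np.empty_like(w)
            q[finite] = w[finite] * e / (w[finite] * e + d)
            q[~finite] = 1.0
            hit_easy = p * q / e
            hit_diff = p * (1.0 - q) / d
            nfix = s + 1  # the terminating target fixation
            acc["p_total"] += hit_easy + hit_diff
            acc["p_easy"] += hit_easy
            acc["e_fix"] += (hit_easy + hit_diff) * nfix
            acc["e_fix_easy"] += hit_easy * (i + 1) + hit_diff * i
            acc["e_fix_diff"] += hit_easy * j + hit_diff * (j + 1)
            fix_chosen = hit_easy * (i + 1) + hit_diff * (j + 1)
            acc["e_fix_chosen"] += fix_chosen
            acc["p_fix_chosen"] += fix_chosen / nfix
            if i + 1 < e0:
                prob[i + 1, j] += p * q * (e - 1) / e
            if j + 1 < d0:
                prob[i, j + 1] += p * (1.0 - q) * (d - 1) / d
    return acc


def enumerate_tree(
    e: int,
    d: int,
    w: float,
    profile: ParticipantProfile | None = None,
    config: SessionConfig | None = None,
) -> TreePrediction:
    """Exhaustively enumerate the fixation decision tree.

    Parameters
    ----------
    e, d
        Remaining easy and difficult element counts, targets included
        (both at least 1 in the double-target condition).
    w
        Odds weight toward the easy set; ``np.inf`` confines search to
        the easy set, 0 to the difficult set.
    profile, config
        If given, expected search time and reward are attached using the
        profile's timing and the found target's accuracy.
    """
    if e < 1 or d < 1:
        raise ValueError("both sets must contain at least their target")
    if w < 0:
        raise ValueError("odds weight must be non-negative")
    acc = _tree_expectations(e, d, np.array([float(w)]))
    p_easy = float(acc["p_easy"][0])
    pred = dict(
        p_choose_easy=p_easy,
        expected_fixations=float(acc["e_fix"][0]),
        expected_fix_easy=float(acc["e_fix_easy"][0]),
        expected_fix_difficult=float(acc["e_fix_diff"][0]),
        expected_fix_chosen=float(acc["e_fix_chosen"][0]),
        p_fix_chosen=float(acc["p_fix_chosen"][0]),
    )
    if profile is not None:
        config = config or SessionConfig()
        t = profile.t_plan + (pred["expected_fixations"] - 1) * profile.t_insp \
            + profile.t_resp
        r = p_easy * expected_reward("easy", profile, config) \
            + (1 - p_easy) * expected_reward("difficult", profile, config)
        pred.update(expected_search_time=t, expected_reward=r)
    return TreePrediction(**pred)


def _hermite_nodes(order: int = GAUSS_HERMITE_ORDER) -> tuple[np.ndarray, np.ndarray]:
    x, wq = np.polynomial.hermite.hermgauss(order)
    return x, wq / np.sqrt(np.pi)


def marginal_predictions(
    condition: tuple[int, int],
    profile: ParticipantProfile,
    sigma_d: float | None = None,
    sigma_f: float | None = None,
    config: SessionConfig | None = None,
    delta_g: float | None = None,
) -> TreePrediction:
    """Model predictions for one condition, marginal over decision noise.

    Evaluates ``E_eps[tree(ne, nd, w(delta_g + eps))]`` with
    ``eps ~ Normal(0, sigma_d)`` by Gauss-Hermite quadrature
    (:data:`GAUSS_HERMITE_ORDER` nodes); ``sigma_d = 0`` collapses to a
    single tree evaluation.  Noise SDs default to the profile's.
    """
    ne, nd = condition
    sigma_d = profile.sigma_d if sigma_d is None else sigma_d
    sigma_f = profile.sigma_f if sigma_f is None else sigma_f
    if sigma_d < 0 or sigma_f < 0:
        raise ValueError("noise SDs must be non-negative")
    config = config or SessionConfig()
    if delta_g is None:
        delta_g = float(delta_g_vector(profile, config)[ne - 1])
    if sigma_d == 0:
        noisy = np.array([delta_g])
        wq = np.array([1.0])
    else:
        x, wq = _hermite_nodes()
        noisy = delta_g + np.sqrt(2.0) * sigma_d * x
    w_arr = _weights_from_noisy(noisy, sigma_f)
    acc = _tree_expectations(ne, nd, w_arr)
    out = {k: float(np.dot(wq, v)) for k, v in acc.items()}
    t = profile.t_plan + (out["e_fix"] - 1) * profile.t_insp + profile.t_resp
    r = out["p_easy"] * expected_reward("easy", profile, config) \
        + (1 - out["p_easy"]) * expected_reward("difficult", profile, config)
    return TreePrediction(
        p_choose_easy=out["p_easy"],
        expected_fixations=out["e_fix"],
        expected_fix_easy=out["e_fix_easy"],
        expected_fix_difficult=out["e_fix_diff"],
        expected_fix_chosen=out["e_fix_chosen"],
        p_fix_chosen=out["p_fix_chosen"],
        expected_search_time=t,
        expected_reward=r,
    )


def _weights_from_noisy(noisy: np.ndarray, sigma_f: float) -> np.ndarray:
    if sigma_f == 0:
        b = np.where(noisy == 0, 0.5, (noisy > 0).astype(float))
    else:
        b = ndtr(noisy / sigma_f)
    with np.errstate(divide="ignore"):
        return np.where(b == 1.0, np.inf, b / (1.0 - b))


@dataclass(frozen=True)
class SimulatedTrial:
    """One ancestral draw from the generative model."""

    condition_ne: int
    sequence: tuple[tuple[SetLabel, str], ...]  # (set_label, role) per fixation
    chosen_target: SetLabel  # set of the found target
    correct: bool
    duration: float  # s: planning + distractor inspections + response

    @property
    def n_fixations(self) -> int:
        return len(self.sequence)

    @property
    def fixations_on_easy(self) -> int:
        return sum(s == "easy" for s, _ in self.sequence)

    @property
    def fixations_on_chosen(self) -> int:
        return sum(s == self.chosen_target for s, _ in self.sequence)


def simulate_trial(
    condition: tuple[int, int],
    profile: ParticipantProfile,
    sigma_d: float | None = None,
    sigma_f: float | None = None,
    rng: np.random.Generator | None = None,
    config: SessionConfig | None = None,
    delta_g: float | None = None,
) -> SimulatedTrial:
    """Sample one fixation sequence, found target and response.

    Draws a single decision-noise perturbation, derives the fixation
    bias, then walks the tree stochastically: sets are sampled with the
    odds-weighted probability, elements uniformly within the sampled
    set, distractors are removed once fixated, and the walk stops at
    the first target.  The response is Bernoulli with the found
    target's discrimination accuracy.
    """
    rng = np.random.default_rng() if rng is None else rng
    ne, nd = condition
    if ne < 1 or nd < 1:
        raise ValueError("double-target condition requires both targets present")
    sigma_d = profile.sigma_d if sigma_d is None else sigma_d
    sigma_f = profile.sigma_f if sigma_f is None else sigma_f
    config = config or SessionConfig()
    if delta_g is None:
        delta_g = float(delta_g_vector(profile, config)[ne - 1])
    noisy = delta_g + (sigma_d * rng.standard_normal() if sigma_d > 0 else 0.0)
    w = bias_from_noisy_gain(noisy, sigma_f).w

    e, d = ne, nd
    sequence: list[tuple[SetLabel, str]] = []
    while True:
        if np.isinf(w):
            q = 1.0
        else:
            q = w * e / (w * e + d)
        pick_easy = rng.random() < q
        size = e if pick_easy else d
        label: SetLabel = "easy" if pick_easy else "difficult"
        if rng.random() < 1.0 / size:
            sequence.append((label, "target"))
            chosen = label
            break
        sequence.append((label, "distractor"))
        if pick_easy:
            e -= 1
        else:
            d -= 1
    correct = rng.random() < profile.accuracy(chosen)
    duration = profile.t_plan + (len(sequence) - 1) * profile.t_insp + profile.t_resp
    return SimulatedTrial(ne, tuple(sequence), chosen, bool(correct), duration)


def prediction_frame(
    profile: ParticipantProfile,
    sigma_d: float | None = None,
    sigma_f: float | None = None,
    config: SessionConfig | None = None,
):
    """Per-condition prediction table (delimited-text export schema)."""
    import pandas as pd

    rows = []
    for ne in range(1, 10):
        p = marginal_predictions((ne, 10 - ne), profile, sigma_d, sigma_f, config)
        rows.append(
            {
                "condition_ne": ne,
                "p_choose_easy": p.p_choose_easy,
                "p_fix_chosen": p.p_fix_chosen,
                "expected_fixations": p.expected_fixations,
                "expected_gain": p.gain_rate,
            }
        )
    return pd.DataFrame(rows)


def predicted_gain_rate(
    profile: ParticipantProfile,
    sigma_d: float | None = None,
    sigma_f: float | None = None,
    config: SessionConfig | None = None,
) -> float:
    """Session-level predicted gain, cents/s, over an equal condition mix.

    Ratio of summed expected rewards to summed expected trial times
    across the nine conditions (same aggregation as the theoretical
    maximum and the empirical session gain).
    """
    preds = [
        marginal_predictions((ne, 10 - ne), profile, sigma_d, sigma_f, config)
        for ne in range(1, 10)
    ]
    return sum(p.expected_reward for p in preds) / sum(p.expected_search_time for p in preds)
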