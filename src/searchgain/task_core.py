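"""Domain types and stimulus-display generation.

The task is a combined visual search and perceptual discrimination
experiment.  Stimulus elements belong to one of two sets that differ in
how hard their target is to discriminate (gap size on the target's
rectangle): an *easy* set and a *difficult* set.  In the double-target
condition every display holds 10 elements — one easy target among
``N_E`` easy elements and one difficult target among ``N_D = 10 - N_E``
difficult elements — scattered over a 20 deg x 20 deg area around a
central fixation cross, with a minimum center-to-center spacing of
5 deg (fixation cross included) and an equal number of elements in each
screen half.  The single-target condition shows one target plus 0-8
same-set distractors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

SetLabel = Literal["easy", "difficult"]
Role = Literal["target", "distractor"]
Mode = Literal["single_target", "double_target"]

#: side length of the square placement area, degrees of visual angle
AREA_DEG = 20.0
#: minimum pairwise distance between element centers and the fixation cross
MIN_DISTANCE_DEG = 5.0
#: number of elements in every double-target display
DOUBLE_TARGET_N = 10

TARGET_ORIENTATIONS = (0.0, 90.0)
DISTRACTOR_ORIENTATIONS = (45.0, 135.0)


class PlacementError(RuntimeError):
    """Raised when no display satisfying the geometry can be found."""


@dataclass(frozen=True)
class StimulusSet:
    """One of the two stimulus sets, identified by its discrimination difficulty."""

    label: SetLabel
    gap_size: float  # degrees; easy 0.08, difficult 0.05
    ring_color_tag: str = ""

    def __post_init__(self) -> None:
        if self.gap_size <= 0:
            raise ValueError("gap_size must be positive")


EASY_SET = StimulusSet("easy", 0.08, "ring_a")
DIFFICULT_SET = StimulusSet("difficult", 0.05, "ring_b")
assert EASY_SET.gap_size > DIFFICULT_SET.gap_size


@dataclass(frozen=True)
class ElementSpec:
    """A single element on the screen."""

    element_id: int
    set_label: SetLabel
    role: Role
    orientation: float  # degrees from vertical
    position: tuple[float, float]  # (x, y) degrees relative to fixation cross

    def __post_init__(self) -> None:
        allowed = TARGET_ORIENTATIONS if self.role == "target" else DISTRACTOR_ORIENTATIONS
        if self.orientation not in allowed:
            raise ValueError(
                f"{self.role} orientation must be one of {allowed}, got {self.orientation}"
            )


@dataclass(frozen=True)
class TrialDisplay:
    """Composition and geometry of one stimulus array."""

    condition_ne: int
    condition_nd: int
    elements: tuple[ElementSpec, ...]
    mode: Mode

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.elements], dtype=float)

    @property
    def targets(self) -> tuple[ElementSpec, ...]:
        return tuple(e for e in self.elements if e.role == "target")

    def element(self, element_id: int) -> ElementSpec:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)

    def min_pairwise_distance(self) -> float:
        """Minimum Euclidean distance among element centers and the origin."""
        pts = np.vstack([self.positions, [0.0, 0.0]])
        diffs = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(diffs[..., 0], diffs[..., 1])
        iu = np.triu_indices(len(pts), k=1)
        return float(dist[iu].min())

    def validate(self) -> None:
        ne = sum(e.set_label == "easy" for e in self.elements)
        nd = sum(e.set_label == "difficult" for e in self.elements)
        if (ne, nd) != (self.condition_ne, self.condition_nd):
            raise ValueError("set counts do not match condition")
        n_targets = {s: sum(e.role == "target" and e.set_label == s for e in self.elements)
                     for s in ("easy", "difficult")}
        if self.mode == "double_target":
            if len(self.elements) != DOUBLE_TARGET_N or ne + nd != DOUBLE_TARGET_N:
                raise ValueError("double-target display must hold 10 elements")
            if n_targets["easy"] != 1 or n_targets["difficult"] != 1:
                raise ValueError("double-target display needs one target per set")
            t_easy, t_diff = (t for t in self.targets)
            if t_easy.orientation == t_diff.orientation:
                raise ValueError("the two targets may not share an orientation")
        else:
            if sum(n_targets.values()) != 1:
                raise ValueError("single-target display needs exactly one target")
            target_set = self.targets[0].set_label
            if any(e.set_label != target_set for e in self.elements):
                raise ValueError("single-target distractors must come from the target's set")
        pos = self.positions
        if np.any(np.abs(pos) > AREA_DEG / 2 + 1e-12):
            raise ValueError("element outside the placement area")
        if self.min_pairwise_distance() < MIN_DISTANCE_DEG - 1e-12:
            raise ValueError("minimum pairwise distance violated")
        tol = 0 if self.mode == "double_target" else 1
        for axis in (0, 1):
            lo = int(np.sum(pos[:, axis] < 0))
            hi = len(pos) - lo
            if abs(lo - hi) > tol:
                raise ValueError("elements not balanced across screen halves")

    def to_frame(self, trial_id: int = 0) -> pd.DataFrame:
        """One row per element, in the on-disk display-table schema."""
        return pd.DataFrame(
            {
                "trial_id": trial_id,
                "condition_ne": self.condition_ne,
                "element_id": [e.element_id for e in self.elements],
                "set_label": [e.set_label for e in self.elements],
                "role": [e.role for e in self.elements],
                "orientation": [e.orientation for e in self.elements],
                "x_deg": [e.position[0] for e in self.elements],
                "y_deg": [e.position[1] for e in self.elements],
            }
        )


@dataclass(frozen=True)
class SessionConfig:
    """Clock, viewing budget and reward scheme for one session."""

    session_time: float = 390.0  # s; 6 min 30 s
    viewing_budget: float = 500.0  # ms per element before masking
    reward_correct: float = 0.02  # points
    reward_incorrect: float = -0.02  # points
    rng_seed: int = 0
    mode: Mode = "double_target"

    def __post_init__(self) -> None:
        if self.session_time <= 0 or self.viewing_budget <= 0:
            raise ValueError("session_time and viewing_budget must be positive")
        if self.reward_correct != -self.reward_incorrect:
            raise ValueError("reward scheme must be symmetric (+x / -x)")


@dataclass(frozen=True)
class ParticipantProfile:
    """An individual's discrimination accuracies, timing and noise levels.

    Defaults are group means from the single-target condition of the
    reference experiment (accuracies 0.79 / 0.70; planning 237 ms,
    inspection 486 ms, response 1052 ms) and the group-mean fitted noise
    levels (decision noise 0.31, fixation noise 0.58, both in cents/s).
    ``dwell_sd`` is the spread of simulated dwell times; it defaults to a
    small value so that the mean simulated dwell stays at ``t_insp``
    under the truncation imposed by the per-element viewing budget.
    """

    acc_easy: float = 0.79
    acc_difficult: float = 0.70
    t_plan: float = 0.237  # s
    t_insp: float = 0.486  # s per inspected element
    t_resp: float = 1.052  # s
    dwell_sd: float = 0.004  # s
    sigma_d: float = 0.31  # decision-noise SD, cents/s
    sigma_f: float = 0.58  # fixation-noise SD, cents/s

    def __post_init__(self) -> None:
        for name in ("acc_easy", "acc_difficult"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("t_plan", "t_insp", "t_resp", "dwell_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_d < 0 or self.sigma_f < 0:
            raise ValueError("noise SDs must be non-negative")

    def accuracy(self, set_label: SetLabel) -> float:
        return self.acc_easy if set_label == "easy" else self.acc_difficult


def _single_target_conditions() -> list[tuple[SetLabel, int]]:
    return [(s, k) for s in ("easy", "difficult") for k in range(9)]


def _propose_positions(n: int, rng: np.random.Generator,
                       max_proposals: int = 10_000) -> np.ndarray | None:
    """Sequential rejection sampling of n points with the spacing constraint."""
    accepted: list[np.ndarray] = []
    half = AREA_DEG / 2
    proposals = 0
    while len(accepted) < n:
        if proposals >= max_proposals:
            return None
        p = rng.uniform(-half, half, size=2)
        proposals += 1
        pts = [np.zeros(2)] + accepted  # fixation cross counts
        if all(np.hypot(*(p - q)) >= MIN_DISTANCE_DEG for q in pts):
            accepted.append(p)
    return np.array(accepted)


def _balanced(pos: np.ndarray, tol: int) -> bool:
    for axis in (0, 1):
        lo = int(np.sum(pos[:, axis] < 0))
        if abs(len(pos) - 2 * lo) > tol:
            return False
    return True


def generate_display(
    ne: int,
    nd: int,
    mode: Mode = "double_target",
    rng: np.random.Generator | None = None,
    max_restarts: int = 1_000,
) -> TrialDisplay:
    """Draw one stimulus display satisfying all geometric constraints.

    Positions are sampled uniformly over the placement area with
    sequential rejection against the 5-deg minimum-distance rule; whole
    displays are re-drawn until element counts balance across the
    left/right and upper/lower screen halves (exactly for 10 elements,
    within one element per axis for the odd counts of the single-target
    condition).

    Parameters
    ----------
    ne, nd
        Easy and difficult element counts (targets included).  In
        double-target mode ``ne + nd`` must equal 10 with ``ne`` in 1-9;
        in single-target mode one of the two counts must be zero and the
        other in 1-9.
    """
    rng = np.random.default_rng() if rng is None else rng
    if mode == "double_target":
        if not (1 <= ne <= 9 and ne + nd == DOUBLE_TARGET_N):
            raise ValueError(f"invalid double-target condition ({ne}, {nd})")
        n = DOUBLE_TARGET_N
        tol = 0
    elif mode == "single_target":
        if not ((ne == 0) ^ (nd == 0)) or not 1 <= ne + nd <= 9:
            raise ValueError(f"invalid single-target condition ({ne}, {nd})")
        n = ne + nd
        tol = 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for _ in range(max_restarts):
        pos = _propose_positions(n, rng)
        if pos is None or not _balanced(pos, tol):
            continue
        return _assemble(ne, nd, mode, pos, rng)
    raise PlacementError(
        f"could not place {n} elements after {max_restarts} restarts"
    )


def _assemble(ne: int, nd: int, mode: Mode, pos: np.ndarray,
              rng: np.random.Generator) -> TrialDisplay:
    labels: list[SetLabel] = ["easy"] * ne + ["difficult"] * nd
    roles: list[Role] = ["distractor"] * len(labels)
    orientations = [float(rng.choice(DISTRACTOR_ORIENTATIONS)) for _ in labels]
    # targets: one per present set; double-target orientations never coincide
    easy_orient = float(rng.choice(TARGET_ORIENTATIONS))
    if ne:
        i = int(rng.integers(ne))
        roles[i], orientations[i] = "target", easy_orient
    if nd:
        j = ne + int(rng.integers(nd))
        roles[j] = "target"
        if mode == "double_target":
            orientations[j] = TARGET_ORIENTATIONS[1] if easy_orient == TARGET_ORIENTATIONS[0] \
                else TARGET_ORIENTATIONS[0]
        else:
            orientations[j] = float(rng.choice(TARGET_ORIENTATIONS))
    # positions were drawn exchangeably; assign in order
    elements = tuple(
        ElementSpec(i, labels[i], roles[i], orientations[i], (float(x), float(y)))
        for i, (x, y) in enumerate(pos)
    )
    display = TrialDisplay(ne, nd, elements, mode)
    display.validate()
    return display


def make_miniblock(mode: Mode, rng: np.random.Generator) -> list:
    """Random ordering of all conditions of one miniblock.

    Double-target miniblocks hold the nine set-size conditions
    ``N_E = 1..9`` once each; single-target miniblocks hold the 18
    combinations of target difficulty and 0-8 distractors.
    """
    if mode == "double_target":
        conditions: list = list(range(1, 10))
    elif mode == "single_target":
        conditions = _single_target_conditions()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    order = rng.permutation(len(conditions))
    return [conditions[i] for i in order]


def chance_levels() -> dict[str, float]:
    """Chance proportions for the three reference gaze-shift metrics.

    A gaze shift made by set-blind uniform sampling of the 10 elements
    lands on the easy set with probability ``N_E/10``; averaged evenly
    over the nine conditions this is 0.50.  The smaller-set chance
    averages ``min(N_E, N_D)/10`` over the eight unequal conditions
    (0.25), and the closest-element chance is 1/10.
    """
    easy = float(np.mean([ne / 10 for ne in range(1, 10)]))
    unequal = [ne for ne in range(1, 10) if ne != 5]
    smaller = float(np.mean([min(ne, 10 - ne) / 10 for ne in unequal]))
    return {"easy_set": easy, "smaller_set": smaller, "closest_element": 0.1}


def display_from_frame(df: pd.DataFrame, mode: Mode = "double_target",
                       validate: bool = True) -> TrialDisplay:
    """Rebuild one TrialDisplay from its rows of a display table."""
    elements = tuple(
        ElementSpec(int(r.element_id), str(r.set_label), str(r.role),
                    float(r.orientation), (float(r.x_deg), float(r.y_deg)))
        for r in df.itertuples()
    )
    ne = sum(e.set_label == "easy" for e in elements)
    display = TrialDisplay(ne, len(elements) - ne, elements, mode)
    if validate:
        display.validate()
    return display


def displays_to_frame(displays: dict[int, TrialDisplay]) -> pd.DataFrame:
    """Concatenate display tables keyed by trial id."""
    if not displays:
        return pd.DataFrame(
            columns=["trial_id", "condition_ne", "element_id", "set_label",
                     "role", "orientation", "x_deg", "y_deg"]
        )
    return pd.concat(
        [d.to_frame(tid) for tid, d in displays.items()], ignore_index=True
    )
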