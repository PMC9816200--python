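"""Maximum-likelihood estimation of the two noise parameters.

The generative model has two free parameters per participant: the
decision-noise SD ``sigma_d`` and the fixation-noise SD ``sigma_f``
(both in cents/s).  They are estimated from per-condition counts of
easy-target choices and fixations on the chosen set by maximizing a
binomial pseudo-likelihood: within-trial fixations are treated as
independent draws, an approximation documented in the methods note.

The public surface follows the model/results idiom of statsmodels::

    model = ChoiceFixationModel.from_dataframe(df, profile)
    res = model.fit()
    print(res.summary())

``negative_log_likelihood``, ``fit`` and ``parameter_recovery`` are
thin functional wrappers over the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import generative_model as gm
from .ideal_observer import delta_g_vector
from .task_core import ParticipantProfile, SessionConfig

_PROB_CLIP = 1e-9


@dataclass(frozen=True)
class ObservedCondition:
    """Choice and fixation counts for one set-size condition."""

    condition_ne: int
    n_trials: int
    n_easy_choices: int
    n_fix_total: int
    n_fix_chosen: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_easy_choices <= self.n_trials:
            raise ValueError("n_easy_choices must lie in [0, n_trials]")
        if not 0 <= self.n_fix_chosen <= self.n_fix_total:
            raise ValueError("n_fix_chosen must lie in [0, n_fix_total]")


@dataclass(frozen=True)
class SearchSpec:
    """Grid-then-refine search strategy for the two noise parameters.

    A coarse log-spaced grid brackets the plausible range by more than
    an order of magnitude on each side, then a Nelder-Mead polish (in
    log-parameter space) refines the grid optimum.  Deterministic.
    """

    lower: float = 1e-4
    upper: float = 10.0
    grid_points: int = 25
    refine: bool = True
    xatol: float = 1e-4
    fatol: float = 1e-6

    def grid(self) -> np.ndarray:
        return np.geomspace(self.lower, self.upper, self.grid_points)


@dataclass(frozen=True)
class FitResult:
    """Point estimates of the noise parameters with fit diagnostics."""

    sigma_d_hat: float
    sigma_f_hat: float
    neg_log_likelihood: float
    converged: bool
    predicted_choice_curve: tuple[float, ...]
    predicted_fix_curve: tuple[float, ...]
    conditions: tuple[int, ...]
    sigma_d_se: float = np.nan
    sigma_f_se: float = np.nan


@lru_cache(maxsize=100_000)
def _curves(sigma_d: float, sigma_f: float, delta_gs: tuple[float, ...],
            conditions: tuple[int, ...]) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Predicted (choice, fixation) probability curves; cached.

    The fixation probability is the ratio of expected fixations on the
    chosen set to expected total fixations, matching the pooled-count
    observable the likelihood binds to.
    """
    if sigma_d == 0:
        wq = np.array([1.0])
    else:
        x, wq = gm._hermite_nodes()
    p_choice, p_fix = [], []
    for ne, dg in zip(conditions, delta_gs):
        noisy = np.array([dg]) if sigma_d == 0 else dg + np.sqrt(2.0) * sigma_d * x
        w_arr = gm._weights_from_noisy(noisy, sigma_f)
        acc = gm._tree_expectations(ne, 10 - ne, w_arr)
        p_choice.append(float(np.dot(wq, acc["p_easy"])))
        e_fix = float(np.dot(wq, acc["e_fix"]))
        e_chosen = float(np.dot(wq, acc["e_fix_chosen"]))
        p_fix.append(e_chosen / e_fix)
    return tuple(p_choice), tuple(p_fix)


def _nll_from_curves(observed, p_choice, p_fix, choice_only: bool) -> float:
    k = np.array([o.n_easy_choices for o in observed], dtype=float)
    n = np.array([o.n_trials for o in observed], dtype=float)
    p = np.clip(np.asarray(p_choice), _PROB_CLIP, 1 - _PROB_CLIP)
    if not choice_only:
        k = np.concatenate([k, [o.n_fix_chosen for o in observed]])
        n = np.concatenate([n, [o.n_fix_total for o in observed]])
        p = np.concatenate([p, np.clip(np.asarray(p_fix), _PROB_CLIP, 1 - _PROB_CLIP)])
    keep = n > 0
    return float(-stats.binom.logpmf(k[keep], n[keep], p[keep]).sum())


class ChoiceFixationModel:
    """Binomial pseudo-likelihood model for per-condition choice and fixation counts.

    Parameters
    ----------
    observed
        One :class:`ObservedCondition` per set-size condition with
        ``n_trials > 0``.
    profile
        Participant timing and accuracy parameters; these fix the
        ideal-observer gain differences that enter the generative model,
        only the two noise SDs are estimated.
    choice_only
        If true, fixation counts do not enter the likelihood.
    """

    def __init__(
        self,
        observed: list[ObservedCondition],
        profile: ParticipantProfile,
        config: SessionConfig | None = None,
        choice_only: bool = False,
    ) -> None:
        observed = [o for o in observed if o.n_trials > 0]
        if not observed:
            raise ValueError("need at least one condition with trials")
        self.observed = sorted(observed, key=lambda o: o.condition_ne)
        self.profile = profile
        self.config = config or SessionConfig()
        self.choice_only = choice_only
        self.conditions = tuple(o.condition_ne for o in self.observed)
        dg = delta_g_vector(profile, self.config)
        self.delta_gs = tuple(float(dg[ne - 1]) for ne in self.conditions)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        profile: ParticipantProfile,
        config: SessionConfig | None = None,
        **kwargs,
    ) -> "ChoiceFixationModel":
        """Build from a table with the ObservedCondition columns."""
        observed = [
            ObservedCondition(
                int(r.condition_ne), int(r.n_trials), int(r.n_easy_choices),
                int(r.n_fix_total), int(r.n_fix_chosen),
            )
            for r in df.itertuples()
        ]
        return cls(observed, profile, config, **kwargs)

    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        profile: ParticipantProfile,
        config: SessionConfig | None = None,
        **kwargs,
    ) -> "ChoiceFixationModel":
        """Aggregate a per-trial table (as written by the session simulator)."""
        t = trials[~trials.get("excluded", pd.Series(False, index=trials.index))]
        grouped = t.groupby("condition_ne")
        rows = []
        for ne, g in grouped:
            rows.append(ObservedCondition(
                int(ne), len(g), int((g["chosen_target"] == "easy").sum()),
                int(g["n_fixations"].sum()), int(g["fixations_on_chosen"].sum()),
            ))
        return cls(rows, profile, config, **kwargs)

    def loglike(self, sigma_d: float, sigma_f: float) -> float:
        return -self.nll(sigma_d, sigma_f)

    def nll(self, sigma_d: float, sigma_f: float) -> float:
        if sigma_d < 0 or sigma_f < 0:
            raise ValueError("noise SDs must be non-negative")
        p_choice, p_fix = _curves(float(sigma_d), float(sigma_f),
                                  self.delta_gs, self.conditions)
        return _nll_from_curves(self.observed, p_choice, p_fix, self.choice_only)

    def fit(self, search_spec: SearchSpec | None = None) -> "ChoiceFixationResults":
        """Grid search plus derivative-free refinement of the two SDs."""
        spec = search_spec or SearchSpec()
        grid = spec.grid()
        best = (np.inf, grid[0], grid[0])
        for sd in grid:
            for sf in grid:
                v = self.nll(sd, sf)
                if v < best[0]:
                    best = (v, sd, sf)
        nll0, sd0, sf0 = best
        if not np.isfinite(nll0):
            raise RuntimeError("likelihood not finite anywhere on the search grid")
        converged = True
        if spec.refine:
            def obj(logp: np.ndarray) -> float:
                sd, sf = np.exp(np.clip(logp, np.log(spec.lower), np.log(spec.upper)))
                return self.nll(sd, sf)

            res = optimize.minimize(
                obj, np.log([sd0, sf0]), method="Nelder-Mead",
                options={"xatol": spec.xatol, "fatol": spec.fatol, "maxiter": 500},
            )
            if res.fun <= nll0:
                sd0, sf0 = np.exp(np.clip(res.x, np.log(spec.lower), np.log(spec.upper)))
                nll0 = float(res.fun)
            converged = bool(res.success)
        p_choice, p_fix = _curves(float(sd0), float(sf0), self.delta_gs, self.conditions)
        se_d, se_f = self._standard_errors(float(sd0), float(sf0), spec)
        return ChoiceFixationResults(
            self,
            FitResult(float(sd0), float(sf0), float(nll0), converged,
                      p_choice, p_fix, self.conditions, se_d, se_f),
        )

    def _standard_errors(self, sd: float, sf: float,
                         spec: SearchSpec) -> tuple[float, float]:
        """Observed-information SEs from a finite-difference Hessian."""
        h = 1e-3

        def f(a: float, b: float) -> float:
            return self.nll(max(a, spec.lower), max(b, spec.lower))

        try:
            f0 = f(sd, sf)
            hdd = (f(sd + h, sf) - 2 * f0 + f(sd - h, sf)) / h**2
            hff = (f(sd, sf + h) - 2 * f0 + f(sd, sf - h)) / h**2
            hdf = (f(sd + h, sf + h) - f(sd + h, sf - h)
                   - f(sd - h, sf + h) + f(sd - h, sf - h)) / (4 * h**2)
            hess = np.array([[hdd, hdf], [hdf, hff]])
            cov = np.linalg.inv(hess)
            if np.any(np.diag(cov) <= 0):
                return np.nan, np.nan
            return tuple(np.sqrt(np.diag(cov)))
        except (np.linalg.LinAlgError, ValueError):
            return np.nan, np.nan


class ChoiceFixationResults:
    """Results wrapper with estimates, uncertainty and predicted curves."""

    def __init__(self, model: ChoiceFixationModel, result: FitResult) -> None:
        self.model = model
        self._result = result

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"sigma_d": self._result.sigma_d_hat, "sigma_f": self._result.sigma_f_hat}
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {"sigma_d": self._result.sigma_d_se, "sigma_f": self._result.sigma_f_se}
        )

    @property
    def sigma_d_hat(self) -> float:
        return self._result.sigma_d_hat

    @property
    def sigma_f_hat(self) -> float:
        return self._result.sigma_f_hat

    @property
    def neg_log_likelihood(self) -> float:
        return self._result.neg_log_likelihood

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def fit_result(self) -> FitResult:
        return self._result

    def predicted_curves(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_ne": self._result.conditions,
                "p_choose_easy": self._result.predicted_choice_curve,
                "p_fix_chosen": self._result.predicted_fix_curve,
            }
        )

    def expected_counts(self) -> list[ObservedCondition]:
        """Model-expected counts at the fitted parameters (rounded)."""
        out = []
        for obs, pc, pf in zip(self.model.observed,
                               self._result.predicted_choice_curve,
                               self._result.predicted_fix_curve):
            out.append(ObservedCondition(
                obs.condition_ne, obs.n_trials,
                int(round(pc * obs.n_trials)),
                obs.n_fix_total, int(round(pf * obs.n_fix_total)),
            ))
        return out

    def simulate(self, n_trials_per_condition: int,
                 rng: np.random.Generator) -> list[ObservedCondition]:
        """Draw a synthetic dataset at the fitted parameters."""
        return simulate_observed(
            self.model.profile, self.sigma_d_hat, self.sigma_f_hat,
            n_trials_per_condition, rng, self.model.config,
        )

    def summary(self) -> str:
        r = self._result
        lines = [
            "Choice/fixation noise model (binomial pseudo-likelihood)",
            "=" * 58,
            f"conditions:          {len(r.conditions)}",
            f"trials:              {sum(o.n_trials for o in self.model.observed)}",
            f"-log L:              {r.neg_log_likelihood:.3f}",
            f"converged:           {r.converged}",
            "-" * 58,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
            f"{'sigma_d':<12}{r.sigma_d_hat:>12.4f}{r.sigma_d_se:>12.4f}",
            f"{'sigma_f':<12}{r.sigma_f_hat:>12.4f}{r.sigma_f_se:>12.4f}",
            "-" * 58,
            "units: cents/s (SD of decision / fixation noise)",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers and simulation helpers

def negative_log_likelihood(
    sigma_d: float,
    sigma_f: float,
    observed: list[ObservedCondition],
    profile: ParticipantProfile,
    config: SessionConfig | None = None,
    choice_only: bool = False,
) -> float:
    """Joint binomial NLL of choice and fixation counts, in nats."""
    return ChoiceFixationModel(observed, profile, config, choice_only).nll(
        sigma_d, sigma_f
    )


def fit(
    observed: list[ObservedCondition],
    profile: ParticipantProfile,
    search_spec: SearchSpec | None = None,
    config: SessionConfig | None = None,
    choice_only: bool = False,
) -> FitResult:
    """Estimate (sigma_d, sigma_f) from observed counts."""
    model = ChoiceFixationModel(observed, profile, config, choice_only)
    return model.fit(search_spec).fit_result


def simulate_observed(
    profile: ParticipantProfile,
    sigma_d: float,
    sigma_f: float,
    n_trials_per_condition: int,
    rng: np.random.Generator,
    config: SessionConfig | None = None,
) -> list[ObservedCondition]:
    """Simulate per-condition counts from the generative model."""
    config = config or SessionConfig()
    dg = delta_g_vector(profile, config)
    out = []
    for ne in range(1, 10):
        n_easy = fix_total = fix_chosen = 0
        for _ in range(n_trials_per_condition):
            t = gm.simulate_trial((ne, 10 - ne), profile, sigma_d, sigma_f,
                                  rng, config, delta_g=float(dg[ne - 1]))
            n_easy += t.chosen_target == "easy"
            fix_total += t.n_fixations
            fix_chosen += t.fixations_on_chosen
        out.append(ObservedCondition(ne, n_trials_per_condition, n_easy,
                                     fix_total, fix_chosen))
    return out


def parameter_recovery(
    true_params: tuple[float, float],
    profile: ParticipantProfile,
    n_trials_per_condition: int = 200,
    n_replicates: int = 20,
    seed: int = 0,
    search_spec: SearchSpec | None = None,
    config: SessionConfig | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit study of estimator quality.

    Returns one row per replicate with the true and recovered
    parameters; summary statistics (bias, RMSE, median) are attached in
    ``DataFrame.attrs['summary']``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    sigma_d, sigma_f = true_params
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        observed = simulate_observed(profile, sigma_d, sigma_f,
                                     n_trials_per_condition, rng, config)
        res = fit(observed, profile, search_spec, config)
        rows.append(
            {
                "replicate": rep,
                "sigma_d_true": sigma_d,
                "sigma_f_true": sigma_f,
                "sigma_d_hat": res.sigma_d_hat,
                "sigma_f_hat": res.sigma_f_hat,
                "neg_log_likelihood": res.neg_log_likelihood,
                "converged": res.converged,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["summary"] = {
        "bias_sigma_d": float(df["sigma_d_hat"].mean() - sigma_d),
        "bias_sigma_f": float(df["sigma_f_hat"].mean() - sigma_f),
        "rmse_sigma_d": float(np.sqrt(((df["sigma_d_hat"] - sigma_d) ** 2).mean())),
        "rmse_sigma_f": float(np.sqrt(((df["sigma_f_hat"] - sigma_f) ** 2).mean())),
        "median_sigma_d": float(df["sigma_d_hat"].median()),
        "median_sigma_f": float(df["sigma_f_hat"].median()),
    }
    return df
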