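"""Full simulated sessions: 11 interleaved staircases, catch trials, QC rules.

A session presents 48 staircase trials for each of 11 conditions (no surround,
near surround at 5 relative orientations, far surround at 5 relative
orientations) plus 48 catch trials (reference fixed at 30% contrast, i.e. a
-50 percentage-point decrement, evenly split between parallel and orthogonal
surrounds and randomly assigned near/far), for 576 trials total.  Conditions
are interleaved by a uniform shuffle; each condition owns an independent Psi
staircase, so the trial schedule does not alter any staircase's trajectory.

Per-condition perceived-contrast estimates are the mean of the last three
per-trial threshold estimates.  Participants are excluded when catch accuracy
is not better than 75% or when the near 0/20-degree estimates fail to show
reduced perceived contrast; a 5-standard-deviation rule flags per-condition
outliers for analyses using that condition as a dependent variable.

Randomness is organized so results are reproducible and schedule-invariant:
the per-observer seed spawns one child stream per condition (in canonical
condition order), one for catch-trial responses, and one for the trial
shuffle.  ``run_session`` and the vectorized cohort runner in
:mod:`surrsupp.pipeline` therefore produce bit-identical estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .observer_model import (
    ObserverParams,
    TARGET_HIGHER,
    perceived_decrement,
    respond_trial,
)
from .psi_staircase import (
    PsiConfig,
    PsiState,
    init_psi,
    select_intensity,
    update_posterior,
)

__all__ = [
    "NEAR_THETAS",
    "CONDITIONS",
    "TaskConfig",
    "TrialSlot",
    "SessionPlan",
    "TrialRecord",
    "SessionResult",
    "condition_surround",
    "condition_rngs",
    "build_session",
    "run_session",
    "extract_condition_estimate",
    "apply_exclusions",
    "flag_outliers",
]

NEAR_THETAS = (0, 20, 45, 70, 90)

#: Canonical condition order; also the order of per-condition RNG streams.
CONDITIONS = ("no_surround",) + tuple(f"near_{t}" for t in NEAR_THETAS) \
    + tuple(f"far_{t}" for t in NEAR_THETAS)

TARGET_ORIENTATIONS = (0, 45, 90, 135)


def condition_surround(condition: str) -> tuple[str, float]:
    """Map a condition id to (surround_class, relative orientation degrees)."""
    if condition == "no_surround":
        return "none", 0.0
    kind, _, theta = condition.partition("_")
    if kind not in ("near", "far") or not theta:
        raise ValueError(f"unknown condition {condition!r}")
    return kind, float(theta)


@dataclass(frozen=True)
class TaskConfig:
    """Session structure: trial counts and the catch-trial contrast."""

    trials_per_condition: int = 48
    n_catch: int = 48
    catch_decrement: float = -50.0  # reference fixed at 30% vs the 80% target
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.n_catch < 0 or self.n_catch % 2:
            raise ValueError("n_catch must be a nonnegative even count")

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions) + self.n_catch


@dataclass(frozen=True)
class TrialSlot:
    """One planned trial: a staircase slot for ``condition`` or a catch slot."""

    condition: str | None          # None for catch trials
    is_catch: bool
    catch_surround: str | None     # "near" / "far" for catch trials
    catch_theta: float | None      # 0 (parallel) or 90 (orthogonal)
    target_orientation: int
    reference_side: str            # "left" / "right"


@dataclass
class SessionPlan:
    slots: list[TrialSlot]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.slots])


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    condition: str
    is_catch: bool
    decrement: float
    response: str
    correct: bool | None  # catch trials only


@dataclass
class SessionResult:
    """Per-condition estimates and QC summary for one participant."""

    observer_id: str
    group: str
    logmar: float
    estimates: dict[str, float]
    catch_accuracy: float
    convergence_sd: dict[str, float] = field(default_factory=dict)
    included: bool | None = None
    exclusion_reason: str = "none"


def build_session(task: TaskConfig, rng: np.random.Generator) -> SessionPlan:
    """Lay out and shuffle all trial slots of one session."""
    n = task.n_trials
    orientations = rng.choice(TARGET_ORIENTATIONS, size=n)
    sides = np.where(rng.random(n) < 0.5, "left", "right")
    near_catch = rng.random(task.n_catch) < 0.5

    slots: list[TrialSlot] = []
    i = 0
    for cond in task.conditions:
        for _ in range(task.trials_per_condition):
            slots.append(TrialSlot(cond, False, None, None,
                                   int(orientations[i]), str(sides[i])))
            i += 1
    # Catch trials: evenly split parallel/orthogonal, near/far random.
    catch_thetas = [0.0] * (task.n_catch // 2) + [90.0] * (task.n_catch // 2)
    for j, theta in enumerate(catch_thetas):
        slots.append(TrialSlot(None, True,
                               "near" if near_catch[j] else "far", theta,
                               int(orientations[i]), str(sides[i])))
        i += 1
    order = rng.permutation(len(slots))
    return SessionPlan([slots[k] for k in order])


def condition_rngs(obs: ObserverParams, conditions: Sequence[str]) -> dict:
    """Per-observer child RNG streams, independent of trial schedule.

    Streams 0..(n_conditions-1) drive the per-condition staircase responses
    (canonical condition order), stream n_conditions the catch responses and
    stream n_conditions + 1 the session plan.
    """
    def child(i: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(obs.seed, spawn_key=(i,)))

    rngs = {cond: child(i) for i, cond in enumerate(conditions)}
    rngs["__catch__"] = child(len(conditions))
    rngs["__plan__"] = child(len(conditions) + 1)
    return rngs


def true_pses(obs: ObserverParams, conditions: Sequence[str]) -> dict[str, float]:
    return {c: perceived_decrement(obs, *condition_surround(c)) for c in conditions}


def extract_condition_estimate(estimate_history: Sequence[float]) -> float:
    """Perceived-contrast estimate: mean of the final three threshold estimates."""
    if len(estimate_history) < 3:
        raise ValueError("estimate history must contain at least 3 entries")
    return float(np.mean(estimate_history[-3:]))


def run_session(obs: ObserverParams, plan: SessionPlan,
                psi_config: PsiConfig | None = None,
                task: TaskConfig | None = None,
                rng: np.random.Generator | None = None,
                ) -> tuple[list[TrialRecord], SessionResult]:
    """Run one observer through a planned session.

    Staircase slots run one select/respond/update cycle of their condition's
    staircase; catch slots draw a response at the fixed catch decrement and do
    not touch any posterior.  With ``rng=None`` (default) the per-condition
    streams are derived from ``obs.seed``, making the outcome independent of
    the slot order in ``plan``.
    """
    psi_config = psi_config or PsiConfig()
    task = task or TaskConfig()
    if rng is None:
        rngs = condition_rngs(obs, task.conditions)
    else:
        children = rng.spawn(len(task.conditions) + 1)
        rngs = dict(zip(task.conditions, children[:-1]))
        rngs["__catch__"] = children[-1]

    states: dict[str, PsiState] = {c: init_psi(psi_config) for c in task.conditions}
    pses = true_pses(obs, task.conditions)

    log: list[TrialRecord] = []
    n_catch = n_catch_correct = 0
    for i, slot in enumerate(plan.slots):
        if slot.is_catch:
            pse = perceived_decrement(obs, slot.catch_surround, slot.catch_theta)
            response = respond_trial(obs, task.catch_decrement, pse, rngs["__catch__"])
            correct = response == TARGET_HIGHER
            n_catch += 1
            n_catch_correct += correct
            log.append(TrialRecord(i, f"catch_{slot.catch_surround}_{slot.catch_theta:g}",
                                   True, task.catch_decrement, response, correct))
        else:
            cond = slot.condition
            state = states[cond]
            x = select_intensity(state, psi_config)
            response = respond_trial(obs, x, pses[cond], rngs[cond])
            states[cond] = update_posterior(state, x, response, psi_config)
            log.append(TrialRecord(i, cond, False, x, response, None))

    estimates, conv = {}, {}
    for cond in task.conditions:
        hist = states[cond].estimate_history
        estimates[cond] = extract_condition_estimate(hist)
        conv[cond] = float(np.std(hist[-3:]))
    result = SessionResult(
        observer_id=obs.observer_id, group=obs.group, logmar=obs.logmar,
        estimates=estimates,
        catch_accuracy=n_catch_correct / n_catch if n_catch else 1.0,
        convergence_sd=conv,
    )
    return log, result


def apply_exclusions(result: SessionResult, catch_threshold: float = 0.75) -> SessionResult:
    """QC rule: include iff catch accuracy is strictly better than the threshold
    AND the near 0/20-degree estimates indicate reduced perceived contrast
    (strictly negative).  Catch accuracy is checked first."""
    out = replace_result(result)
    if not out.catch_accuracy > catch_threshold:
        out.included, out.exclusion_reason = False, "catch_fail"
    elif not (out.estimates.get("near_0", np.inf) < 0 and out.estimates.get("near_20", np.inf) < 0):
        out.included, out.exclusion_reason = False, "no_suppression"
    else:
        out.included, out.exclusion_reason = True, "none"
    return out


def replace_result(result: SessionResult) -> SessionResult:
    return SessionResult(
        observer_id=result.observer_id, group=result.group, logmar=result.logmar,
        estimates=dict(result.estimates), catch_accuracy=result.catch_accuracy,
        convergence_sd=dict(result.convergence_sd), included=result.included,
        exclusion_reason=result.exclusion_reason,
    )


def flag_outliers(values: np.ndarray, included: np.ndarray | None = None,
                  n_sd: float = 5.0) -> np.ndarray:
    """Flag values more than ``n_sd`` standard deviations from the condition
    mean (mean/SD over included observers).  Returns a boolean array; values of
    excluded observers are never flagged (they are already out of analyses)."""
    values = np.asarray(values, dtype=float)
    if included is None:
        included = np.ones(values.shape, dtype=bool)
    included = np.asarray(included, dtype=bool)
    if included.sum() < 3:
        raise ValueError("need at least 3 included observers to flag outliers")
    pool = values[included]
    sd = float(np.std(pool))
    if sd == 0.0:
        return np.zeros(values.shape, dtype=bool)
    flags = np.abs(values - pool.mean()) > n_sd * sd
    return flags & included
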