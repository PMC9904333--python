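"""Synthetic observers for the contrast-matching surround-suppression task.

The generative core is a divisive normalization model of the response to a
central grating embedded in an iso-contrast surround,

    R(theta) = A_c * C_c / (A_c * C_c + C_s * exp(-theta / w_obs) + sigma),

where ``A_c`` amplifies the center following segmentation (focal attention
and/or good visual acuity), ``C_c`` and ``C_s`` are the center and surround
drives (both 0.8 for the 80%-contrast stimuli used in the task), ``w_obs``
is the orientation tuning width of surround suppression in degrees, and
``sigma`` is the semi-saturation constant representing untuned
(orientation-insensitive) gain control.  ``theta`` is the center-surround
relative orientation in degrees.

An observer's perceived contrast of the target is read out linearly from R,
anchored at the canonical no-surround operating point R0 = 0.8 (the response
of the baseline A_c = 2.0, sigma = 0.4 observer with no surround), so the
matched contrast decrement in percentage points is

    delta = (80 / 0.8) * (R_cond - 0.8).

Conditions whose effective surround drive is zero (the no-surround condition,
or a far surround with ``far_gain = 0``) present physically identical stimuli
on both sides of the screen, so their point of subjective equality is exactly
0 regardless of the observer's internal parameters.

Trial-level behavior follows a logistic decision rule with a symmetric lapse:
P(report reference higher) = lapse/2 + (1 - lapse) * F(x; pse, beta) where x
is the contrast decrement applied to the reference grating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "GROUPS",
    "TARGET_CONTRAST",
    "CANONICAL_NO_SURROUND_RESPONSE",
    "REFERENCE_HIGHER",
    "TARGET_HIGHER",
    "InvalidParameterError",
    "NormParams",
    "ObserverParams",
    "GroupSpec",
    "CohortSpec",
    "norm_response",
    "perceived_decrement",
    "prob_reference_higher",
    "respond_trial",
    "sample_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
]

#: Canonical group labels, in reporting order.
GROUPS = ("PSZ", "PBD", "HC", "PSZrel", "PBDrel")

#: Luminance contrast of the target grating, in percent.
TARGET_CONTRAST = 80.0

#: No-surround normalized response of the baseline observer (A_c=2, sigma=0.4);
#: the anchor of the linear perceived-contrast read-out.
CANONICAL_NO_SURROUND_RESPONSE = 0.8

REFERENCE_HIGHER = "reference_higher"
TARGET_HIGHER = "target_higher"

SURROUND_CLASSES = ("none", "near", "far")


class InvalidParameterError(ValueError):
    """A model parameter is non-finite or outside its allowed range."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class NormParams:
    """Divisive-normalization parameters of one observer.

    a_c : center amplification (> 0), segmentation / attention / acuity.
    c_c, c_s : center and surround drive, proportional to contrast (0-1).
    w_obs : orientation tuning width of surround suppression, degrees (> 0).
    sigma : semi-saturation constant, untuned gain control (> 0).
    """

    a_c: float = 2.0
    c_c: float = 0.8
    c_s: float = 0.8
    w_obs: float = 30.0
    sigma: float = 0.4

    def __post_init__(self) -> None:
        for name in ("a_c", "c_c", "c_s", "w_obs", "sigma"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")
        _require(self.a_c > 0, "a_c must be > 0")
        _require(0.0 <= self.c_c <= 1.0, "c_c must be in [0, 1]")
        _require(0.0 <= self.c_s <= 1.0, "c_s must be in [0, 1]")
        _require(self.w_obs > 0, "w_obs must be > 0")
        _require(self.sigma > 0, "sigma must be > 0")


@dataclass(frozen=True)
class ObserverParams:
    """Generative description of one simulated participant."""

    norm: NormParams
    far_gain: float = 0.15
    beta_true: float = 0.5
    lapse_true: float = 0.04
    logmar: float = 0.0
    group: str = "HC"
    observer_id: str = "obs0"
    seed: int = 0

    def __post_init__(self) -> None:
        # beta_true may be +inf (step-function observer limit)
        _require(not math.isnan(self.beta_true) and self.beta_true > 0, "beta_true must be > 0")
        _require(0.0 <= self.lapse_true < 0.5, "lapse_true must be in [0, 0.5)")
        _require(0.0 <= self.far_gain <= 1.0, "far_gain must be in [0, 1]")
        _require(math.isfinite(self.logmar), "logmar must be finite")


def norm_response(p: NormParams, theta) -> np.ndarray | float:
    """Normalized response R to the central target at relative orientation theta.

    R = a_c*c_c / (a_c*c_c + c_s*exp(-theta/w_obs) + sigma).  Vectorized over
    ``theta`` (degrees, >= 0).
    """
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(~np.isfinite(theta_arr)) or np.any(theta_arr < 0):
        raise InvalidParameterError("theta must be finite and >= 0")
    drive = p.a_c * p.c_c
    r = drive / (drive + p.c_s * np.exp(-theta_arr / p.w_obs) + p.sigma)
    return float(r) if np.isscalar(theta) or theta_arr.ndim == 0 else r


def perceived_decrement(obs: ObserverParams, surround_class: str, theta: float = 0.0) -> float:
    """Model-true matched contrast decrement (percentage points) for a condition.

    The read-out is linear in R with slope TARGET_CONTRAST / R0 anchored at the
    canonical no-surround response R0 = 0.8, matching the convention that R
    predicts perceived contrast on a common scale across observers.  Conditions
    with zero effective surround drive return exactly 0 (identical stimuli on
    both sides of the screen).
    """
    if surround_class not in SURROUND_CLASSES:
        raise ValueError(f"unknown surround_class {surround_class!r}; expected one of {SURROUND_CLASSES}")
    if surround_class == "none":
        return 0.0
    gain = 1.0 if surround_class == "near" else obs.far_gain
    c_s_eff = gain * obs.norm.c_s
    if c_s_eff == 0.0:
        return 0.0
    r_cond = norm_response(replace(obs.norm, c_s=c_s_eff), theta)
    r0 = CANONICAL_NO_SURROUND_RESPONSE
    return (TARGET_CONTRAST / r0) * (r_cond - r0)


def prob_reference_higher(obs: ObserverParams, reference_decrement: float, true_pse: float) -> float:
    """P(observer reports the reference side as higher contrast).

    Logistic decision rule with symmetric lapse:
    p = lapse/2 + (1 - lapse) * F(x; pse, beta).  An infinite slope gives the
    step-function limit (0.5 exactly at the PSE).
    """
    x = float(reference_decrement)
    if math.isinf(obs.beta_true):
        f = 0.5 if x == true_pse else (1.0 if x > true_pse else 0.0)
    else:
        f = float(expit(obs.beta_true * (x - true_pse)))
    return obs.lapse_true / 2.0 + (1.0 - obs.lapse_true) * f


def respond_trial(obs: ObserverParams, reference_decrement: float, true_pse: float,
                  rng: np.random.Generator) -> str:
    """Draw one 2AFC response (one Bernoulli sample from the decision rule)."""
    p = prob_reference_higher(obs, reference_decrement, true_pse)
    return REFERENCE_HIGHER if rng.random() < p else TARGET_HIGHER


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Per-group generative settings: size, acuity distribution, gain control.

    ``sigma_poor`` applies to observers whose logMAR exceeds the cohort's
    acuity cutoff (weakened untuned gain control confined to the low-acuity
    sub-group); equal values make sigma acuity-independent.
    """

    size: int
    logmar_mean: float
    logmar_sd: float
    sigma_good: float
    sigma_poor: float

    def __post_init__(self) -> None:
        _require(self.size >= 0, "group size must be >= 0")
        _require(self.logmar_sd >= 0, "logmar_sd must be >= 0")
        for name in ("logmar_mean", "logmar_sd", "sigma_good", "sigma_poor"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")
        _require(self.sigma_good > 0 and self.sigma_poor > 0, "sigma values must be > 0")


def _default_groups() -> dict[str, GroupSpec]:
    # Sizes and logMAR mean (sd) follow the study demographics; sigma encodes
    # the gain-control hypothesis: controls & PBDrel intact (0.4), PBD & PSZrel
    # intermediate (0.25), PSZ weakened (0.1) in the low-acuity sub-group.
    return {
        "PSZ": GroupSpec(31, 0.14, 0.15, sigma_good=0.4, sigma_poor=0.1),
        "PBD": GroupSpec(29, 0.12, 0.12, sigma_good=0.25, sigma_poor=0.25),
        "HC": GroupSpec(29, 0.08, 0.13, sigma_good=0.4, sigma_poor=0.4),
        "PSZrel": GroupSpec(28, 0.10, 0.12, sigma_good=0.25, sigma_poor=0.25),
        "PBDrel": GroupSpec(21, 0.04, 0.10, sigma_good=0.4, sigma_poor=0.4),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative settings.

    acuity_cutoff : logMAR threshold of the acuity split (0.1 ~ Snellen 20/25).
    a_c_good / a_c_poor : center amplification for observers at/below vs above
        the cutoff (segmentation aided by good acuity).
    logmar_floor : lower truncation of the acuity distribution.
    """

    groups: Mapping[str, GroupSpec] = field(default_factory=_default_groups)
    acuity_cutoff: float = 0.1
    a_c_good: float = 2.0
    a_c_poor: float = 1.0
    logmar_floor: float = -0.3
    c_c: float = 0.8
    c_s: float = 0.8
    w_obs: float = 30.0
    beta_true: float = 0.5
    lapse_true: float = 0.04
    far_gain: float = 0.15

    def __post_init__(self) -> None:
        for name in ("acuity_cutoff", "a_c_good", "a_c_poor", "logmar_floor",
                     "c_c", "c_s", "w_obs", "beta_true", "lapse_true", "far_gain"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")

    @property
    def n_total(self) -> int:
        return sum(g.size for g in self.groups.values())


def _sample_logmar(g: GroupSpec, floor: float, rng: np.random.Generator) -> np.ndarray:
    if g.size == 0:
        return np.empty(0)
    if g.logmar_sd == 0:
        return np.full(g.size, max(g.logmar_mean, floor))
    a = (floor - g.logmar_mean) / g.logmar_sd
    return truncnorm.rvs(a, np.inf, loc=g.logmar_mean, scale=g.logmar_sd,
                         size=g.size, random_state=rng)


def sample_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[ObserverParams]:
    """Draw a cohort of observers: acuity per group, then the acuity-dependent
    center amplification and the group's gain-control rule.

    Deterministic given ``rng``'s state; per-observer seeds (used downstream to
    derive session randomness) are drawn from the same stream.
    """
    observers: list[ObserverParams] = []
    for group, g in spec.groups.items():
        logmars = _sample_logmar(g, spec.logmar_floor, rng)
        seeds = rng.integers(0, 2**31 - 1, size=g.size)
        for i in range(g.size):
            lm = float(logmars[i])
            poor = lm > spec.acuity_cutoff
            norm = NormParams(
                a_c=spec.a_c_poor if poor else spec.a_c_good,
                c_c=spec.c_c, c_s=spec.c_s, w_obs=spec.w_obs,
                sigma=g.sigma_poor if poor else g.sigma_good,
            )
            observers.append(ObserverParams(
                norm=norm, far_gain=spec.far_gain, beta_true=spec.beta_true,
                lapse_true=spec.lapse_true, logmar=lm, group=group,
                observer_id=f"{group}_{i:03d}", seed=int(seeds[i]),
            ))
    return observers


def cohort_to_frame(observers: Iterable[ObserverParams]) -> pd.DataFrame:
    """One row per observer; round-trips through :func:`frame_to_cohort`."""
    rows = [{
        "observer_id": o.observer_id, "group": o.group, "logmar": o.logmar,
        "a_c": o.norm.a_c, "c_c": o.norm.c_c, "c_s": o.norm.c_s,
        "sigma": o.norm.sigma, "w_obs": o.norm.w_obs, "far_gain": o.far_gain,
        "beta_true": o.beta_true, "lapse_true": o.lapse_true, "seed": o.seed,
    } for o in observers]
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[ObserverParams]:
    observers = []
    for row in frame.itertuples(index=False):
        norm = NormParams(a_c=row.a_c, c_c=row.c_c, c_s=row.c_s,
                          w_obs=row.w_obs, sigma=row.sigma)
        observers.append(ObserverParams(
            norm=norm, far_gain=row.far_gain, beta_true=row.beta_true,
            lapse_true=row.lapse_true, logmar=row.logmar, group=row.group,
            observer_id=row.observer_id, seed=int(row.seed),
        ))
    return observers
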