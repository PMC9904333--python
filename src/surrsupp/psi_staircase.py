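"""Psi adaptive staircase: Bayesian threshold estimation on a parameter grid.

The Psi method maintains a discrete posterior over the threshold (alpha) and
slope (beta) of a psychometric function and places each trial at the stimulus
intensity that minimizes the expected posterior entropy over the two possible
responses.  Grids follow the task configuration used in the contrast-matching
experiment: alpha in [-40, 20] step 1 (percentage-point contrast decrement),
beta in [0.1, 5] step 0.05, candidate intensities in [-75, 15] step 1, total
lapse delta = 0.08 split half per tail.

Stimulus placement uses the mutual-information identity

    E[H_post](x) = H(prior) - h(p(r=1|x)) + sum_j p_j h(L_{x,j}),

where h is the binary entropy, p(r=1|x) = sum_j p_j L_{x,j} and L is the
per-cell probability of a "reference higher" response.  This is algebraically
identical to averaging the entropy of the two candidate posteriors and costs
two matrix-vector products per trial.  The expected-entropy surface and the
argmin (ties broken toward the smallest intensity) match a brute-force
enumeration oracle; see the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import expit, ndtr, xlogy

if TYPE_CHECKING:  # pragma: no cover
    from .observer_model import ObserverParams

from .observer_model import REFERENCE_HIGHER, TARGET_HIGHER, respond_trial

__all__ = [
    "PsiConfig",
    "PsiState",
    "DegeneratePosteriorError",
    "init_psi",
    "select_intensity",
    "update_posterior",
    "threshold_estimate",
    "run_staircase",
    "expected_entropies",
    "selection_scores",
    "argmin_intensity",
]


class DegeneratePosteriorError(RuntimeError):
    """The posterior mass vanished (zero normalizing constant)."""


def _default_alpha() -> np.ndarray:
    return np.arange(-40.0, 21.0, 1.0)


def _default_beta() -> np.ndarray:
    return np.linspace(0.1, 5.0, 99)


def _default_intensity() -> np.ndarray:
    return np.arange(-75.0, 16.0, 1.0)


@dataclass
class PsiConfig:
    """Grids and psychometric family of one staircase.

    delta is the total lapse (probability of a stimulus-independent error),
    applied as delta/2 on each asymptote.  family is "logistic" or "cnorm".
    """

    alpha_grid: np.ndarray = field(default_factory=_default_alpha)
    beta_grid: np.ndarray = field(default_factory=_default_beta)
    intensity_grid: np.ndarray = field(default_factory=_default_intensity)
    delta: float = 0.08
    family: str = "logistic"

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        self.beta_grid = np.asarray(self.beta_grid, dtype=float)
        self.intensity_grid = np.asarray(self.intensity_grid, dtype=float)
        for name in ("alpha_grid", "beta_grid", "intensity_grid"):
            g = getattr(self, name)
            if g.ndim != 1 or g.size == 0:
                raise ValueError(f"{name} must be a nonempty 1-d grid")
            if g.size > 1:
                steps = np.diff(g)
                if np.any(steps <= 0):
                    raise ValueError(f"{name} must be strictly increasing")
                if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
                    raise ValueError(f"{name} must be uniformly spaced")
        if not 0.0 <= self.delta < 0.5:
            raise ValueError("delta must be in [0, 0.5)")
        if self.family not in ("logistic", "cnorm"):
            raise ValueError("family must be 'logistic' or 'cnorm'")
        self._tables: dict | None = None

    # -- cached response tables ------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.alpha_grid.size * self.beta_grid.size

    def tables(self) -> dict:
        """Per-(intensity, cell) response probabilities and entropy table.

        L[x, j] = delta/2 + (1 - delta) * F(x; alpha_j, beta_j), cells in
        alpha-major order; HB[x, j] = binary entropy of L[x, j].
        """
        if self._tables is None:
            a = self.alpha_grid[:, None]            # (na, 1)
            b = self.beta_grid[None, :]             # (1, nb)
            x = self.intensity_grid[:, None, None]  # (nx, 1, 1)
            z = b * (x - a)                         # (nx, na, nb)
            f = expit(z) if self.family == "logistic" else ndtr(z)
            like = self.delta / 2.0 + (1.0 - self.delta) * f
            like = like.reshape(self.intensity_grid.size, -1)
            hb = _binary_entropy(like)
            self._tables = {"L": like, "HB": hb}
        return self._tables


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p))


@dataclass
class PsiState:
    """Posterior over (alpha, beta), flattened alpha-major, plus the running
    per-trial history of posterior-mean threshold estimates."""

    posterior: np.ndarray
    trial_count: int = 0
    estimate_history: list[float] = field(default_factory=list)

    def copy(self) -> "PsiState":
        return PsiState(self.posterior.copy(), self.trial_count,
                        list(self.estimate_history))


def init_psi(config: PsiConfig) -> PsiState:
    """Uniform prior over the (alpha, beta) grid, empty history."""
    n = config.n_cells
    return PsiState(posterior=np.full(n, 1.0 / n))


def threshold_estimate(state: PsiState, config: PsiConfig) -> float:
    """Posterior mean of alpha (marginalized over beta)."""
    marg = state.posterior.reshape(config.alpha_grid.size, config.beta_grid.size).sum(axis=1)
    return float(marg @ config.alpha_grid)


def selection_scores(posteriors: np.ndarray, config: PsiConfig) -> np.ndarray:
    """Expected posterior entropy minus the (per-posterior constant) prior
    entropy, for every candidate intensity: -h(p(r|x)) + E_cells[h(L_x)].
    Minimizing this over x is equivalent to minimizing the expected entropy."""
    p = np.atleast_2d(np.asarray(posteriors, dtype=float))
    t = config.tables()
    c1 = np.clip(t["L"] @ p.T, 0.0, 1.0)        # (nx, n) P(reference_higher | x)
    cond = t["HB"] @ p.T                        # (nx, n) E_cells[h(L)]
    scores = (cond - _binary_entropy(c1)).T
    return scores[0] if np.asarray(posteriors).ndim == 1 else scores


def expected_entropies(posteriors: np.ndarray, config: PsiConfig) -> np.ndarray:
    """Expected posterior entropy E[H](x) for every candidate intensity.

    posteriors: (n, n_cells) batch of normalized posteriors (a single state's
    posterior may be passed as shape (n_cells,)).  Returns (n, n_x), or (n_x,)
    for 1-d input.
    """
    p = np.atleast_2d(np.asarray(posteriors, dtype=float))
    h_prior = -np.sum(xlogy(p, p), axis=1)      # (n,)
    eh = h_prior[:, None] + np.atleast_2d(selection_scores(p, config))
    return eh[0] if np.asarray(posteriors).ndim == 1 else eh


def argmin_intensity(eh: np.ndarray) -> np.ndarray:
    """Index of the entropy-minimizing intensity per row; ties (within a tiny
    absolute-scale tolerance, so exact symmetric ties resolve identically
    regardless of summation order) break toward the smallest intensity."""
    eh2 = np.atleast_2d(eh)
    m = eh2.min(axis=1, keepdims=True)
    tol = 1e-12 * np.maximum(1.0, np.abs(m))
    idx = np.argmax(eh2 <= m + tol, axis=1)
    return idx if np.asarray(eh).ndim == 2 else idx[0]


def select_intensity(state: PsiState, config: PsiConfig) -> float:
    """Intensity minimizing expected posterior entropy; ties -> smallest x."""
    total = state.posterior.sum()
    if not np.isfinite(total) or total <= 0:
        raise DegeneratePosteriorError("posterior has no mass")
    scores = selection_scores(state.posterior, config)
    return float(config.intensity_grid[int(argmin_intensity(scores))])


def _intensity_index(x: float, config: PsiConfig) -> int:
    idx = int(np.argmin(np.abs(config.intensity_grid - x)))
    if abs(config.intensity_grid[idx] - x) > 1e-9:
        raise ValueError(f"intensity {x} is not on the intensity grid")
    return idx


def update_posterior(state: PsiState, x: float, response: str, config: PsiConfig) -> PsiState:
    """Bayes update on one observed response; returns a new state with the
    posterior-mean threshold appended to the history."""
    if response not in (REFERENCE_HIGHER, TARGET_HIGHER):
        raise ValueError(f"unknown response {response!r}")
    like = config.tables()["L"][_intensity_index(x, config)]
    if response == TARGET_HIGHER:
        like = 1.0 - like
    post = state.posterior * like
    z = post.sum()
    if not np.isfinite(z) or z <= 0.0:
        raise DegeneratePosteriorError("zero normalizing constant in posterior update")
    post /= z
    new = PsiState(posterior=post, trial_count=state.trial_count + 1,
                   estimate_history=list(state.estimate_history))
    new.estimate_history.append(threshold_estimate(new, config))
    return new


def run_staircase(obs: "ObserverParams", true_pse: float, n_trials: int,
                  config: PsiConfig, rng: np.random.Generator) -> PsiState:
    """Run one staircase against a simulated observer with the given true PSE."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    state = init_psi(config)
    for _ in range(n_trials):
        x = select_intensity(state, config)
        response = respond_trial(obs, x, true_pse, rng)
        state = update_posterior(state, x, response, config)
    return state
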