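"""Orchestration: cohort simulation, batched sessions, fits, statistics, I/O.

``run_pipeline`` executes the full study simulation:

    cohort -> sessions (11 staircases x 48 trials + 48 catch trials each)
           -> exclusions and per-condition 5-SD outlier flags
           -> exponential tuning fits (inadequate fits dropped from parameter
              analyses)
           -> group statistics (mixed-design rmANCOVA with Huynh-Feldt
              correction, one-way ANCOVAs on M/w/o with and without the
              acuity covariate, moderation of M by acuity, BH-FDR pairwise
              contrasts on o)

and writes plain-text artifacts plus a manifest (config, seed, per-filter
counts, content hash per artifact).  All randomness descends from the master
seed; per-observer child streams make cohorts reproducible regardless of
execution order.

``run_cohort_sessions`` is a vectorized execution engine for the session
semantics defined in :mod:`surrsupp.session_engine`: because every condition
owns an independent staircase and an independent response stream, staircases
can be advanced for all observers in lock-step with batched linear algebra.
It produces bit-identical estimates to per-observer ``run_session`` calls
(asserted in the test suite).

``reproduce_figure4`` evaluates the four printed normalization-model
parameter sets (A_c in {2.0, 1.0} x sigma in {0.4, 0.1}, C_c = C_s = 0.8,
w = 30 deg) on a 0..90 degree grid and checks the qualitative orderings:
distributed attention below baseline everywhere, reduced sigma above baseline
everywhere, and the combined set showing the largest parallel-vs-orthogonal
modulation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .observer_model import (
    CohortSpec,
    GroupSpec,
    NormParams,
    ObserverParams,
    REFERENCE_HIGHER,
    TARGET_HIGHER,
    cohort_to_frame,
    frame_to_cohort,
    norm_response,
    perceived_decrement,
    prob_reference_higher,
    sample_cohort,
)
from .psi_staircase import PsiConfig, argmin_intensity, selection_scores
from .session_engine import (
    CONDITIONS,
    NEAR_THETAS,
    SessionResult,
    TaskConfig,
    apply_exclusions,
    build_session,
    condition_rngs,
    condition_surround,
    extract_condition_estimate,
    flag_outliers,
)
from .tuning_fit import fit_exponential

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "FIGURE4_PARAM_SETS",
    "run_cohort_sessions",
    "run_pipeline",
    "reproduce_figure4",
    "sessions_to_frame",
    "fit_cohort",
    "analyze_cohort",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    psi: PsiConfig = field(default_factory=PsiConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0
    out_dir: Path | None = None

    def to_dict(self) -> dict:
        cohort = dataclasses.asdict(self.cohort)
        cohort["groups"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else dict(v)
                            for k, v in self.cohort.groups.items()}
        return {
            "seed": self.seed,
            "cohort": cohort,
            "psi": {
                "alpha": [float(self.psi.alpha_grid[0]), float(self.psi.alpha_grid[-1]),
                          float(self.psi.alpha_grid[1] - self.psi.alpha_grid[0])
                          if self.psi.alpha_grid.size > 1 else 1.0],
                "beta": [float(self.psi.beta_grid[0]), float(self.psi.beta_grid[-1]),
                         float(self.psi.beta_grid[1] - self.psi.beta_grid[0])
                         if self.psi.beta_grid.size > 1 else 1.0],
                "intensity": [float(self.psi.intensity_grid[0]), float(self.psi.intensity_grid[-1]),
                              float(self.psi.intensity_grid[1] - self.psi.intensity_grid[0])
                              if self.psi.intensity_grid.size > 1 else 1.0],
                "delta": self.psi.delta,
                "family": self.psi.family,
            },
            "task": {
                "trials_per_condition": self.task.trials_per_condition,
                "n_catch": self.task.n_catch,
                "catch_decrement": self.task.catch_decrement,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cohort = CohortSpec()
        if "cohort" in d:
            cd = dict(d["cohort"])
            groups = cd.pop("groups", None)
            if groups is not None:
                cd["groups"] = {k: GroupSpec(**v) for k, v in groups.items()}
            cohort = CohortSpec(**cd)
        psi = PsiConfig()
        if "psi" in d:
            pd_ = d["psi"]
            def grid(lohistep):
                lo, hi, step = lohistep
                return np.arange(lo, hi + step / 2, step)
            kwargs = {}
            if "alpha" in pd_:
                kwargs["alpha_grid"] = grid(pd_["alpha"])
            if "beta" in pd_:
                kwargs["beta_grid"] = grid(pd_["beta"])
            if "intensity" in pd_:
                kwargs["intensity_grid"] = grid(pd_["intensity"])
            for key in ("delta", "family"):
                if key in pd_:
                    kwargs[key] = pd_[key]
            psi = PsiConfig(**kwargs)
        task = TaskConfig(**d.get("task", {}))
        return cls(cohort=cohort, psi=psi, task=task, seed=int(d.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Vectorized session execution
# ---------------------------------------------------------------------------

def run_cohort_sessions(observers: Sequence[ObserverParams],
                        psi_config: PsiConfig | None = None,
                        task: TaskConfig | None = None,
                        log_trials: bool = False,
                        ) -> tuple[list[SessionResult], pd.DataFrame | None]:
    """Run one session per observer, advancing each condition's staircases for
    all observers in lock-step (batched posterior updates and intensity
    selection).  Estimates equal per-observer :func:`run_session` exactly.

    Returns (results, trial_log or None).  The trial log is in canonical order
    (observer, condition, within-staircase trial, then catch trials); the
    shuffled presentation order lives in each observer's session plan.
    """
    psi_config = psi_config or PsiConfig()
    task = task or TaskConfig()
    n_obs = len(observers)
    conditions = task.conditions
    rngsets = [condition_rngs(o, conditions) for o in observers]
    plans = [build_session(task, rs["__plan__"]) for rs in rngsets]

    tables = psi_config.tables()
    like = tables["L"]
    x_grid = psi_config.intensity_grid
    n_cells = psi_config.n_cells
    na, nb = psi_config.alpha_grid.size, psi_config.beta_grid.size

    estimates: dict[str, np.ndarray] = {}
    conv: dict[str, np.ndarray] = {}
    log_rows: list[tuple] = [] if log_trials else None

    for cond in conditions:
        surround, theta = condition_surround(cond)
        pses = np.array([perceived_decrement(o, surround, theta) for o in observers])
        cond_rngs = [rs[cond] for rs in rngsets]
        posteriors = np.full((n_obs, n_cells), 1.0 / n_cells)
        history = np.empty((n_obs, task.trials_per_condition))
        for t in range(task.trials_per_condition):
            scores = selection_scores(posteriors, psi_config)   # (n_obs, nx)
            xi = argmin_intensity(scores)
            xs = x_grid[xi]
            p_ref = np.array([prob_reference_higher(obs, xs[i], pses[i])
                              for i, obs in enumerate(observers)])
            draws = np.array([r.random() for r in cond_rngs])
            ref_higher = draws < p_ref
            lk = np.where(ref_higher[:, None], like[xi], 1.0 - like[xi])
            # normalization and alpha-marginal per row, with the same
            # operation order as update_posterior / threshold_estimate, so
            # estimates are bit-identical to sequential run_session calls
            for i in range(n_obs):
                post = posteriors[i] * lk[i]
                posteriors[i] = post / post.sum()
                history[i, t] = (posteriors[i].reshape(na, nb).sum(axis=1)
                                 @ psi_config.alpha_grid)
            if log_trials:
                for i, obs in enumerate(observers):
                    log_rows.append((obs.observer_id, cond, t, False, float(xs[i]),
                                     REFERENCE_HIGHER if ref_higher[i] else TARGET_HIGHER,
                                     None))
        estimates[cond] = history[:, -3:].mean(axis=1)
        conv[cond] = history[:, -3:].std(axis=1)

    results: list[SessionResult] = []
    for i, obs in enumerate(observers):
        n_catch = n_correct = 0
        catch_rng = rngsets[i]["__catch__"]
        for slot in plans[i].slots:
            if not slot.is_catch:
                continue
            pse = perceived_decrement(obs, slot.catch_surround, slot.catch_theta)
            p_ref = prob_reference_higher(obs, task.catch_decrement, pse)
            response_ref = catch_rng.random() < p_ref
            correct = not response_ref
            n_catch += 1
            n_correct += correct
            if log_trials:
                log_rows.append((obs.observer_id,
                                 f"catch_{slot.catch_surround}_{slot.catch_theta:g}",
                                 n_catch - 1, True, task.catch_decrement,
                                 REFERENCE_HIGHER if response_ref else TARGET_HIGHER,
                                 bool(correct)))
        results.append(SessionResult(
            observer_id=obs.observer_id, group=obs.group, logmar=obs.logmar,
            estimates={c: float(estimates[c][i]) for c in conditions},
            catch_accuracy=n_correct / n_catch if n_catch else 1.0,
            convergence_sd={c: float(conv[c][i]) for c in conditions},
        ))

    log = None
    if log_trials:
        log = pd.DataFrame(log_rows, columns=[
            "observer_id", "condition", "trial", "is_catch", "decrement",
            "response", "correct"])
    return results, log


def sessions_to_frame(results: Sequence[SessionResult]) -> pd.DataFrame:
    """Wide summary: one row per observer with per-condition estimates and QC."""
    rows = []
    for r in results:
        row = {"observer_id": r.observer_id, "group": r.group, "logmar": r.logmar,
               "catch_accuracy": r.catch_accuracy, "included": r.included,
               "exclusion_reason": r.exclusion_reason}
        row.update(r.estimates)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fits and statistics over a simulated cohort
# ---------------------------------------------------------------------------

def add_outlier_flags(sessions: pd.DataFrame,
                      conditions: Sequence[str] = CONDITIONS) -> pd.DataFrame:
    """Per-condition 5-SD outlier flags (columns ``outlier_<condition>``),
    computed over included observers."""
    out = sessions.copy()
    included = out["included"].fillna(True).to_numpy(dtype=bool)
    for cond in conditions:
        out[f"outlier_{cond}"] = flag_outliers(out[cond].to_numpy(), included)
    return out


def fit_cohort(sessions: pd.DataFrame,
               thetas: Sequence[float] = NEAR_THETAS) -> pd.DataFrame:
    """Exponential tuning fit of the near-surround estimates of every included
    observer whose near-condition values carry no outlier flag."""
    near_cols = [f"near_{int(t)}" for t in thetas]
    rows = []
    for _, row in sessions.iterrows():
        if not row["included"]:
            continue
        if any(row.get(f"outlier_{c}", False) for c in near_cols):
            continue
        fit = fit_exponential(np.asarray(thetas, dtype=float),
                              row[near_cols].to_numpy(dtype=float))
        rows.append({"observer_id": row["observer_id"], "group": row["group"],
                     "logmar": row["logmar"], "M": fit.m, "w": fit.w, "o": fit.o,
                     "residual_variance": fit.residual_variance,
                     "data_variance": fit.data_variance,
                     "adequate": fit.adequate, "converged": fit.converged})
    return pd.DataFrame(rows)


def analyze_cohort(sessions: pd.DataFrame, fits: pd.DataFrame,
                   rm_conditions: Sequence[str] = ("no_surround", "near_0", "near_90"),
                   ) -> dict:
    """Group statistics of one simulated cohort.

    Returns a dict with the rmANCOVA table, one-way ANCOVA tables for M/w/o
    (with and without the acuity covariate), the moderation test on M and the
    BH-FDR pairwise contrasts on o.
    """
    from .group_stats import ancova_oneway, moderation_test, pairwise_fdr, rm_ancova_hf

    keep = sessions["included"].fillna(False).to_numpy(dtype=bool)
    for cond in rm_conditions:
        col = f"outlier_{cond}"
        if col in sessions:
            keep &= ~sessions[col].to_numpy(dtype=bool)
    rm_data = sessions.loc[keep, ["observer_id", "group", "logmar", *rm_conditions]]
    long = rm_data.melt(id_vars=["observer_id", "group", "logmar"],
                        var_name="condition", value_name="estimate")
    out = {"rm_ancova": rm_ancova_hf(long, conditions=rm_conditions)}

    ok = fits[fits["adequate"]]
    for param in ("M", "w", "o"):
        out[f"ancova_{param}"] = ancova_oneway(ok[param], ok["group"], ok["logmar"])
        out[f"ancova_{param}_nocov"] = ancova_oneway(ok[param], ok["group"])
    out["moderation_M"] = moderation_test(ok["M"], ok["group"], ok["logmar"])
    out["pairwise_o"] = pairwise_fdr(ok["o"], ok["group"], ok["logmar"])
    out["group_means_o"] = ok.groupby("group", sort=False)["o"].mean()
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    sessions: pd.DataFrame
    fits: pd.DataFrame
    stats: dict
    manifest: dict
    trial_log: pd.DataFrame | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, log_trials: bool = True) -> PipelineResult:
    """Execute every stage on one simulated cohort; write artifacts when
    ``config.out_dir`` is set.  Identical seeds yield identical manifests."""
    t0 = time.time()
    stage = "sample_cohort"
    try:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        observers = sample_cohort(config.cohort, rng)
        cohort_frame = cohort_to_frame(observers)

        stage = "run_sessions"
        results, trial_log = run_cohort_sessions(
            observers, config.psi, config.task, log_trials=log_trials)

        stage = "exclusions"
        results = [apply_exclusions(r) for r in results]
        sessions = sessions_to_frame(results)
        sessions = add_outlier_flags(sessions, config.task.conditions)

        stage = "tuning_fits"
        fits = fit_cohort(sessions)

        stage = "group_stats"
        stats_out = analyze_cohort(sessions, fits)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    n = len(sessions)
    counts = {
        "simulated": n,
        "excluded_catch": int((sessions["exclusion_reason"] == "catch_fail").sum()),
        "excluded_no_suppression": int((sessions["exclusion_reason"] == "no_suppression").sum()),
        "included": int(sessions["included"].sum()),
        "outlier_flags": int(sessions.filter(like="outlier_").to_numpy().sum()),
        "fitted": len(fits),
        "inadequate_fit": int((~fits["adequate"]).sum()) if len(fits) else 0,
        "analyzed_parameters": int(fits["adequate"].sum()) if len(fits) else 0,
    }
    manifest = {"config": config.to_dict(), "seed": config.seed, "counts": counts,
                "elapsed_s": round(time.time() - t0, 2)}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        artifacts = {"cohort.tsv": cohort_frame, "sessions.tsv": sessions,
                     "fits.tsv": fits}
        if trial_log is not None:
            artifacts["trials.tsv"] = trial_log
        stats_text = []
        for name, obj in stats_out.items():
            stats_text.append(f"== {name} ==")
            stats_text.append(repr(obj))
            stats_text.append("")
        (out / "stats.txt").write_text("\n".join(stats_text))
        hashes = {}
        for fname, frame in artifacts.items():
            frame.to_csv(out / fname, sep="\t", index=False)
            hashes[fname] = _sha256(out / fname)
        hashes["stats.txt"] = _sha256(out / "stats.txt")
        manifest["artifacts"] = hashes
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(cohort=cohort_frame, sessions=sessions, fits=fits,
                          stats=stats_out, manifest=manifest, trial_log=trial_log)


# ---------------------------------------------------------------------------
# Normalization-model tuning curves (four printed parameter sets)
# ---------------------------------------------------------------------------

FIGURE4_PARAM_SETS = {
    "baseline": {"a_c": 2.0, "sigma": 0.4},           # focal attention, strong gain control
    "distributed": {"a_c": 1.0, "sigma": 0.4},        # distributed attention / low acuity
    "reduced_sigma": {"a_c": 2.0, "sigma": 0.1},      # weakened untuned gain control
    "combined": {"a_c": 1.0, "sigma": 0.1},           # both factors
}


def reproduce_figure4(param_sets: dict | None = None, w_obs: float = 30.0,
                      thetas: np.ndarray | None = None,
                      check: bool = True) -> pd.DataFrame:
    """Normalized-response tuning curves R(theta) for the four model variants.

    With ``check=True`` asserts the qualitative orderings: the distributed
    curve lies below baseline at every theta, the reduced-sigma curve above
    baseline at every theta, and the combined set has the largest
    R(90) - R(0) modulation.
    """
    param_sets = param_sets or FIGURE4_PARAM_SETS
    thetas = np.arange(0.0, 91.0) if thetas is None else np.asarray(thetas, dtype=float)
    frames = []
    curves = {}
    for name, p in param_sets.items():
        norm = NormParams(a_c=p["a_c"], c_c=0.8, c_s=0.8, w_obs=w_obs, sigma=p["sigma"])
        r = norm_response(norm, thetas)
        curves[name] = np.asarray(r)
        frames.append(pd.DataFrame({"set": name, "a_c": p["a_c"], "sigma": p["sigma"],
                                    "theta": thetas, "R": r}))
    table = pd.concat(frames, ignore_index=True)
    if check and set(FIGURE4_PARAM_SETS) <= set(curves):
        base = curves["baseline"]
        if not np.all(curves["distributed"] < base):
            raise AssertionError("distributed-attention curve not below baseline everywhere")
        if not np.all(curves["reduced_sigma"] > base):
            raise AssertionError("reduced-sigma curve not above baseline everywhere")
        mods = {k: v[-1] - v[0] for k, v in curves.items()}
        if max(mods, key=mods.get) != "combined":
            raise AssertionError("combined set does not have the largest modulation")
    return table
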