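"""Group-level inference for the surround-suppression pipeline.

Implements the study's inferential toolbox:

* a mixed-design (split-plot) repeated-measures ANCOVA on three conditions
  with a between-subjects group factor and visual acuity (logMAR) as
  covariate, with Huynh-Feldt sphericity correction of the within-subject
  degrees of freedom;
* the Greenhouse-Geisser -> Huynh-Feldt epsilon computation from a pooled
  within-group covariance matrix;
* one-way ANCOVAs on the fitted tuning parameters (with and without the
  covariate);
* a moderation test (group x acuity interaction on M) plus a descriptive
  acuity split at logMAR 0.1;
* covariate-adjusted pairwise group contrasts with Benjamini-Hochberg FDR
  adjustment;
* an optional BIC-based Bayes-factor approximation (explicitly *not* the JZS
  Bayes factors used in the original analyses).

One-way models are fit with statsmodels OLS; the split-plot decomposition is
computed directly (sum-of-squares by model comparison on orthonormalized
contrast scores, effect-coded group, centered covariate) because no installed
package provides a mixed ANOVA with a between-subjects covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaTable",
    "hf_epsilon",
    "rm_ancova_hf",
    "ancova_oneway",
    "moderation_test",
    "pairwise_fdr",
    "bic_bayes_factor",
    "orthonormal_contrasts",
]


@dataclass
class AnovaTable:
    """Per-effect F table; ``epsilon`` is the Huynh-Feldt epsilon applied to
    within-subject effects (None for purely between-subjects models)."""

    table: pd.DataFrame
    epsilon: float | None = None

    def row(self, effect: str) -> pd.Series:
        hit = self.table[self.table["effect"] == effect]
        if hit.empty:
            raise KeyError(f"no effect {effect!r} in table")
        return hit.iloc[0]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        eps = f", epsilon={self.epsilon:.4g}" if self.epsilon is not None else ""
        return f"AnovaTable({len(self.table)} effects{eps})\n{self.table.to_string(index=False)}"


# ---------------------------------------------------------------------------
# Sphericity correction
# ---------------------------------------------------------------------------

def orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) matrix of orthonormal contrasts (normalized Helmert)."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def hf_epsilon(within_covariance: np.ndarray, n: int, g: int = 1) -> float:
    """Huynh-Feldt epsilon from a k x k within-subject covariance matrix.

    Greenhouse-Geisser epsilon is computed from the covariance of orthonormal
    contrasts, then adjusted by the Huynh-Feldt formula for ``n`` subjects in
    ``g`` groups and clipped to [1/(k-1), 1].
    """
    s = np.asarray(within_covariance, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("within_covariance must be square")
    if not np.allclose(s, s.T, rtol=1e-8, atol=1e-10):
        raise ValueError("within_covariance must be symmetric")
    k = s.shape[0]
    c = orthonormal_contrasts(k)
    sc = c.T @ s @ c
    tr = np.trace(sc)
    tr2 = np.trace(sc @ sc)
    if tr2 <= 0:
        return 1.0
    gg = tr**2 / ((k - 1) * tr2)
    hf = (((n - g + 1) * (k - 1) * gg - 2)
          / ((k - 1) * (n - g - (k - 1) * gg)))
    return float(np.clip(hf, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _group_levels(groups: Sequence) -> list:
    seen: dict = {}
    for g in groups:
        seen.setdefault(g, None)
    return list(seen)


def _effect_code(groups: Sequence, levels: list) -> np.ndarray:
    """Sum-to-zero (effect) coding, last level as the negative row."""
    n, g = len(groups), len(levels)
    x = np.zeros((n, g - 1))
    for i, grp in enumerate(groups):
        j = levels.index(grp)
        if j == g - 1:
            x[i, :] = -1.0
        else:
            x[i, j] = 1.0
    return x


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# Mixed-design rmANCOVA
# ---------------------------------------------------------------------------

def rm_ancova_hf(data: pd.DataFrame, dv: str = "estimate",
                 within: str = "condition", subject: str = "observer_id",
                 between: str = "group", covariate: str | None = "logmar",
                 conditions: Sequence[str] | None = None,
                 covariate_by_condition: bool = True) -> AnovaTable:
    """Split-plot ANCOVA: within-subject condition, between-subject group,
    optional between-subject covariate (entered per orthonormal contrast when
    ``covariate_by_condition``; the covariate is centered, group effect-coded).

    ``data`` is long-format with one row per subject x condition; subjects
    with incomplete condition data are dropped (complete-case analysis).
    Within-effect p-values use Huynh-Feldt-corrected degrees of freedom.
    """
    cols = [subject, between, within, dv] + ([covariate] if covariate else [])
    d = data[cols].dropna()
    wide = d.pivot_table(index=subject, columns=within, values=dv)
    if conditions is not None:
        wide = wide[list(conditions)]
    wide = wide.dropna()
    n, k = wide.shape
    meta = d.drop_duplicates(subject).set_index(subject).loc[wide.index]
    groups = meta[between].tolist()
    levels = _group_levels(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if min(groups.count(l) for l in levels) == 0:  # pragma: no cover
        raise ValueError("empty group")
    if n <= g + (1 if covariate else 0):
        raise ValueError("too few subjects for the between-subjects design")

    y = wide.to_numpy()
    geff = _effect_code(groups, levels)
    ones = np.ones((n, 1))
    z = None
    if covariate:
        z = meta[covariate].to_numpy(dtype=float)
        z = (z - z.mean()).reshape(-1, 1)

    rows = []

    # ---- between-subjects part: subject means ----
    ybar = y.mean(axis=1)
    xb_parts = [ones, geff] + ([z] if z is not None else [])
    xb = np.hstack(xb_parts)
    rss_full_b = _rss(xb, ybar)
    df_err_b = n - g - (1 if z is not None else 0)
    ss_group = _rss(np.hstack([p for p in xb_parts if p is not geff]), ybar) - rss_full_b
    f_group = (ss_group / (g - 1)) / (rss_full_b / df_err_b)
    rows.append(("group", f_group, g - 1.0, float(df_err_b),
                 float(stats.f.sf(f_group, g - 1, df_err_b)),
                 ss_group / (ss_group + rss_full_b)))
    if z is not None:
        ss_cov = _rss(np.hstack([ones, geff]), ybar) - rss_full_b
        f_cov = ss_cov / (rss_full_b / df_err_b)
        rows.append(("covariate", f_cov, 1.0, float(df_err_b),
                     float(stats.f.sf(f_cov, 1, df_err_b)),
                     ss_cov / (ss_cov + rss_full_b)))

    # ---- within-subjects part: orthonormal contrast scores ----
    c = orthonormal_contrasts(k)
    w = y @ c                                   # (n, k-1)
    xw_parts = [ones, geff]
    if z is not None and covariate_by_condition:
        xw_parts.append(z)
    xw = np.hstack(xw_parts)
    p_w = xw.shape[1]
    if n <= p_w:
        raise ValueError("too few subjects for the within-subjects design")

    def block_ss(drop) -> float:
        reduced = np.hstack([p for p in xw_parts if p is not drop])
        return sum(_rss(reduced, w[:, j]) - _rss(xw, w[:, j]) for j in range(k - 1))

    rss_w = sum(_rss(xw, w[:, j]) for j in range(k - 1))
    df_err_w = (n - p_w) * (k - 1)
    ss_cond = block_ss(ones)
    ss_gxc = block_ss(geff)
    mse_w = rss_w / df_err_w

    # Pooled covariance of within residuals -> sphericity correction.
    resid = y - xw @ np.linalg.lstsq(xw, y, rcond=None)[0]
    s_pooled = resid.T @ resid / (n - p_w)
    eps = hf_epsilon(s_pooled, n=n, g=g)

    def within_row(name: str, ss: float, df1: float):
        f = (ss / df1) / mse_w
        p = float(stats.f.sf(f, eps * df1, eps * df_err_w))
        rows.append((name, f, eps * df1, eps * df_err_w, p, ss / (ss + rss_w)))

    within_row("condition", ss_cond, k - 1.0)
    within_row("group:condition", ss_gxc, (g - 1.0) * (k - 1.0))
    if z is not None and covariate_by_condition:
        within_row("covariate:condition", block_ss(z), k - 1.0)

    table = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p", "partial_eta_sq"])
    return AnovaTable(table=table, epsilon=eps)


# ---------------------------------------------------------------------------
# One-way ANCOVA, moderation, pairwise contrasts
# ---------------------------------------------------------------------------

def _design(groups: Sequence, levels: list, covariate=None, interaction: bool = False):
    """Dummy-coded design with intercept; optional centered covariate and
    group x covariate interaction columns."""
    n = len(groups)
    x = [np.ones((n, 1))]
    dummies = np.zeros((n, len(levels) - 1))
    for i, grp in enumerate(groups):
        j = levels.index(grp)
        if j > 0:
            dummies[i, j - 1] = 1.0
    x.append(dummies)
    if covariate is not None:
        zc = np.asarray(covariate, dtype=float)
        zc = (zc - zc.mean()).reshape(-1, 1)
        x.append(zc)
        if interaction:
            x.append(dummies * zc)
    return np.hstack(x)


def ancova_oneway(values, groups, covariate=None) -> AnovaTable:
    """F test of the group effect on one dependent variable, optionally
    adjusting for a covariate.  Fit with statsmodels OLS; reports partial
    eta squared per effect."""
    y = np.asarray(values, dtype=float)
    groups = list(groups)
    levels = _group_levels(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if min(groups.count(l) for l in levels) < 2:
        raise ValueError("each group needs at least 2 observers")

    x_full = _design(groups, levels, covariate)
    full = sm.OLS(y, x_full).fit()
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("collinear (degenerate) design")
    rows = []
    # group effect: drop the g-1 dummy columns
    x_red = np.delete(x_full, np.s_[1:g], axis=1)
    red = sm.OLS(y, x_red).fit()
    f, p, df1 = full.compare_f_test(red)
    ss_g = red.ssr - full.ssr
    rows.append(("group", float(f), float(df1), float(full.df_resid), float(p),
                 ss_g / (ss_g + full.ssr)))
    if covariate is not None:
        x_red = x_full[:, :-1]
        red = sm.OLS(y, x_red).fit()
        f, p, df1 = full.compare_f_test(red)
        ss_c = red.ssr - full.ssr
        rows.append(("covariate", float(f), float(df1), float(full.df_resid), float(p),
                     ss_c / (ss_c + full.ssr)))
    table = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p", "partial_eta_sq"])
    return AnovaTable(table=table)


@dataclass
class ModerationResult:
    """Interaction F test plus the descriptive acuity split."""

    table: pd.DataFrame
    subgroup_means: pd.DataFrame
    epsilon: None = None

    def row(self, effect: str) -> pd.Series:
        return AnovaTable(self.table).row(effect)


def moderation_test(values, groups, logmar, split_at: float = 0.1) -> ModerationResult:
    """Does acuity moderate the group effect?  Linear model with group,
    centered logMAR and group x logMAR terms; F test on the interaction block
    (g - 1 numerator df).  Also returns per-group mean values split at
    ``split_at`` logMAR for descriptive reporting."""
    y = np.asarray(values, dtype=float)
    groups = list(groups)
    z = np.asarray(logmar, dtype=float)
    levels = _group_levels(groups)
    g = len(levels)
    for lev in levels:
        zg = z[[i for i, grp in enumerate(groups) if grp == lev]]
        if zg.size < 2 or np.var(zg) == 0:
            raise ValueError(f"group {lev!r} has no acuity variance; interaction inestimable")

    x_full = _design(groups, levels, z, interaction=True)
    x_red = _design(groups, levels, z, interaction=False)
    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    f, p, df1 = full.compare_f_test(red)
    ss_i = red.ssr - full.ssr
    table = pd.DataFrame(
        [("group:logmar", float(f), float(df1), float(full.df_resid), float(p),
          ss_i / (ss_i + full.ssr))],
        columns=["effect", "F", "df1", "df2", "p", "partial_eta_sq"])

    d = pd.DataFrame({"group": groups, "value": y,
                      "acuity": np.where(z <= split_at, "good", "poor")})
    sub = (d.groupby(["group", "acuity"], sort=False)["value"]
           .agg(["mean", "count"]).reset_index())
    return ModerationResult(table=table, subgroup_means=sub)


def pairwise_fdr(values, groups, covariate=None) -> pd.DataFrame:
    """All pairwise covariate-adjusted group contrasts with BH-FDR adjustment.

    Contrasts use the pooled error of the one-way (AN)COVA model.  Returns one
    row per pair: adjusted difference, t, raw and BH-adjusted p.
    """
    y = np.asarray(values, dtype=float)
    groups = list(groups)
    levels = _group_levels(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    x = _design(groups, levels, covariate)
    fit = sm.OLS(y, x).fit()
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            contrast = np.zeros(x.shape[1])
            if i > 0:
                contrast[i] = 1.0
            if j > 0:
                contrast[j] = -1.0
            tt = fit.t_test(contrast)
            rows.append((levels[i], levels[j], float(np.squeeze(tt.effect)),
                         float(np.squeeze(tt.tvalue)), float(np.squeeze(tt.pvalue))))
    out = pd.DataFrame(rows, columns=["group1", "group2", "difference", "t", "p"])
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def bic_bayes_factor(values, groups, covariate=None) -> float:
    """BIC-approximate Bayes factor for the group effect (alternative over
    null; the covariate is in both models).  A coarse large-sample surrogate,
    not comparable to JZS/anovaBF Bayes factors."""
    y = np.asarray(values, dtype=float)
    groups = list(groups)
    levels = _group_levels(groups)
    x_full = _design(groups, levels, covariate)
    x_null = np.delete(x_full, np.s_[1:len(levels)], axis=1)
    bic_full = sm.OLS(y, x_full).fit().bic
    bic_null = sm.OLS(y, x_null).fit().bic
    return float(np.exp((bic_null - bic_full) / 2.0))
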