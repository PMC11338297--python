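"""Condition-effect and mediation models on the per-participant table.

All models are fixed-effects fits on per-participant aggregates (each
participant's mean alignment, categoricality, and estimated cluster count):
OLS for continuous outcomes, Poisson regression for cluster counts, and
logistic regression for the 2-cluster indicator.  Condition predictors are
centered, which leaves slopes unchanged but makes intercepts interpretable
as grand means.  Mediation is assessed by covariate entry: the condition
effect on alignment is re-estimated with bridged categoricality in the
model, and the verdict is *complete* when the adjusted condition term is no
longer significant (alpha = .05), *partial* when it is reduced but still
significant while the covariate itself predicts the outcome, and *none*
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr


class FitError(ValueError):
    """Degenerate or singular model fit."""


@dataclass(frozen=True)
class Term:
    name: str
    coef: float
    se: float
    stat: float  # t (OLS) or z (GLM)
    p: float


@dataclass(frozen=True)
class FitResult:
    model_kind: str  # linear | poisson | logistic
    terms: tuple[Term, ...]
    r_squared: float | None = None
    n: int = 0

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "n": self.n,
            "r_squared": self.r_squared,
            "terms": [vars(t) for t in self.terms],
        }


@dataclass(frozen=True)
class MediationResult:
    condition_coef_raw: float
    condition_p_raw: float
    condition_coef_adjusted: float
    condition_p_adjusted: float
    covariate_coef: float
    covariate_se: float
    covariate_stat: float
    covariate_p: float
    variance_accounted: float  # squared partial correlation of the covariate
    model_r_squared: float
    verdict: str  # complete | partial | none

    def to_dict(self) -> dict:
        return dict(vars(self))


def _centered_indicator(cond: pd.Series, contrast: Sequence[str]) -> np.ndarray:
    ind = (cond == contrast[1]).astype(float)
    return np.asarray(ind - ind.mean())


def _pair_table(table: pd.DataFrame, contrast: Sequence[str] | None) -> tuple[pd.DataFrame, tuple[str, str]]:
    conds = sorted(table["condition"].unique())
    if contrast is None:
        if len(conds) != 2:
            raise FitError(f"contrast must be named when conditions != 2 (got {conds})")
        contrast = tuple(conds)
    sub = table[table["condition"].isin(contrast)].copy()
    for c in contrast:
        if (sub["condition"] == c).sum() < 2:
            raise FitError(f"condition {c!r} has fewer than 2 participants")
    return sub, tuple(contrast)


def condition_effect(
    table: pd.DataFrame,
    outcome: str = "mean_alignment",
    contrast: Sequence[str] | None = None,
) -> FitResult:
    """OLS of ``outcome`` on a centered condition indicator for one pair of
    conditions; the slope is the second-minus-first condition difference."""
    sub, contrast = _pair_table(table, contrast)
    y = np.asarray(sub[outcome], dtype=float)
    if np.allclose(y, y[0]):
        raise FitError(f"outcome {outcome!r} is constant; degenerate fit")
    x = sm.add_constant(_centered_indicator(sub["condition"], contrast))
    fit = sm.OLS(y, x).fit()
    name = f"condition[{contrast[1]}-{contrast[0]}]"
    terms = (
        Term("intercept", float(fit.params[0]), float(fit.bse[0]),
             float(fit.tvalues[0]), float(fit.pvalues[0])),
        Term(name, float(fit.params[1]), float(fit.bse[1]),
             float(fit.tvalues[1]), float(fit.pvalues[1])),
    )
    return FitResult("linear", terms, r_squared=float(fit.rsquared), n=int(fit.nobs))


def mediation(
    table: pd.DataFrame,
    covariate: str = "categoricality",
    outcome: str = "mean_alignment",
    contrast: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> MediationResult:
    """Covariate-entry mediation: compare the condition effect on
    ``outcome`` with and without ``covariate`` in the model.

    ``variance_accounted`` is the squared partial correlation of the
    covariate in the adjusted model (t^2 / (t^2 + df_resid)); the full
    adjusted-model R^2 is reported alongside.
    """
    sub, contrast = _pair_table(table, contrast)
    y = np.asarray(sub[outcome], dtype=float)
    cond = _centered_indicator(sub["condition"], contrast)
    cov = np.asarray(sub[covariate], dtype=float)
    cov = cov - cov.mean()
    if np.allclose(cov, 0):
        raise FitError(f"covariate {covariate!r} has zero variance")
    raw = sm.OLS(y, sm.add_constant(cond)).fit()
    X = sm.add_constant(np.column_stack([cond, cov]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("covariate is collinear with the design")
    adj = sm.OLS(y, X).fit()
    if adj.df_resid < 1 or not np.isfinite(adj.bse).all() or adj.bse[2] <= 0:
        raise FitError("degenerate adjusted fit (collinear or saturated)")
    if adj.rsquared > 1 - 1e-10:
        raise FitError("covariate reproduces the outcome exactly; degenerate fit")
    t_cov = float(adj.tvalues[2])
    partial_r2 = t_cov**2 / (t_cov**2 + float(adj.df_resid))
    p_raw, p_adj = float(raw.pvalues[1]), float(adj.pvalues[1])
    b_raw, b_adj = float(raw.params[1]), float(adj.params[1])
    if p_raw < alpha and p_adj >= alpha:
        verdict = "complete"
    elif (
        p_adj < alpha
        and float(adj.pvalues[2]) < alpha  # the mediator must itself matter
        and abs(b_adj) < abs(b_raw)
    ):
        verdict = "partial"
    else:
        verdict = "none"
    return MediationResult(
        condition_coef_raw=b_raw,
        condition_p_raw=p_raw,
        condition_coef_adjusted=b_adj,
        condition_p_adjusted=p_adj,
        covariate_coef=float(adj.params[2]),
        covariate_se=float(adj.bse[2]),
        covariate_stat=t_cov,
        covariate_p=float(adj.pvalues[2]),
        variance_accounted=float(partial_r2),
        model_r_squared=float(adj.rsquared),
        verdict=verdict,
    )


def cluster_count_model(
    table: pd.DataFrame, contrast: Sequence[str] | None = None
) -> FitResult:
    """Poisson regression (log link) of cluster counts on condition."""
    sub, contrast = _pair_table(table, contrast)
    counts = np.asarray(sub["n_clusters"], dtype=float)
    if (counts < 1).any():
        raise ValueError("cluster counts must be >= 1")
    x = sm.add_constant(_centered_indicator(sub["condition"], contrast))
    fit = sm.GLM(counts, x, family=sm.families.Poisson()).fit()
    name = f"condition[{contrast[1]}-{contrast[0]}]"
    terms = (
        Term("intercept", float(fit.params[0]), float(fit.bse[0]),
             float(fit.tvalues[0]), float(fit.pvalues[0])),
        Term(name, float(fit.params[1]), float(fit.bse[1]),
             float(fit.tvalues[1]), float(fit.pvalues[1])),
    )
    return FitResult("poisson", terms, n=int(fit.nobs))


def two_cluster_model(
    table: pd.DataFrame, contrast: Sequence[str] | None = None
) -> FitResult:
    """Logistic regression of the (n_clusters == 2) indicator on condition;
    perfect separation is flagged as a degenerate fit."""
    sub, contrast = _pair_table(table, contrast)
    y = (np.asarray(sub["n_clusters"]) == 2).astype(float)
    if y.min() == y.max():
        raise FitError("2-cluster indicator is constant; degenerate fit")
    by_cond = [y[np.asarray(sub["condition"] == c)] for c in contrast]
    if any(g.min() == g.max() for g in by_cond):
        raise FitError("perfect separation: a condition is all-0 or all-1")
    x = sm.add_constant(_centered_indicator(sub["condition"], contrast))
    fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    name = f"condition[{contrast[1]}-{contrast[0]}]"
    terms = (
        Term("intercept", float(fit.params[0]), float(fit.bse[0]),
             float(fit.tvalues[0]), float(fit.pvalues[0])),
        Term(name, float(fit.params[1]), float(fit.bse[1]),
             float(fit.tvalues[1]), float(fit.pvalues[1])),
    )
    return FitResult("logistic", terms, n=int(fit.nobs))


def bridge_correlations(
    dyads: pd.DataFrame, table: pd.DataFrame
) -> dict[str, float]:
    """Pearson correlations between per-participant mean alignment and the
    per-participant means of each bridged dyad covariate.

    ``dyads`` needs columns id_i, id_j, z_alignment, cat_min, cat_max,
    cat_absdiff; ``table`` needs participant_id and mean_alignment (and
    n_clusters for ``r_nclusters``, if present).
    """
    per = {}
    for col in ("cat_min", "cat_max", "cat_absdiff"):
        agg: dict[str, list[float]] = {}
        for _, row in dyads.iterrows():
            for pid in (row["id_i"], row["id_j"]):
                agg.setdefault(pid, []).append(float(row[col]))
        per[col] = {pid: float(np.mean(v)) for pid, v in agg.items()}
    out: dict[str, float] = {}
    align = table.set_index("participant_id")["mean_alignment"]
    for col, label in (("cat_min", "r_min"), ("cat_max", "r_max"), ("cat_absdiff", "r_absdiff")):
        bridged = pd.Series(per[col]).reindex(align.index)
        if align.std() == 0 or bridged.std() == 0:
            raise FitError("zero variance; correlation undefined")
        out[label] = float(pearsonr(align, bridged)[0])
    if "n_clusters" in table.columns:
        ncl = table.set_index("participant_id")["n_clusters"].astype(float)
        out["r_nclusters"] = (
            float(pearsonr(align, ncl)[0]) if ncl.std() > 0 else float("nan")
        )
    return out
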