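"""Survival evaluation of module and signature scores.

Per score vector: continuous Cox hazard ratio per unit index, median-split
Kaplan-Meier curves with log-rank test, group-coded Cox HR, and 10-year
(120-month) survival per group. Also signature comparison by p-value score
and univariate/multivariate covariate models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, SurvivalData
from .errors import InputError
from .scoring import median_split, score_cohort
from .survstats import (
    CoxFit,
    CoxResult,
    KMEstimate,
    fit_cox,
    kaplan_meier,
    logrank_test,
    pvalue_score,
    survival_at,
)

logger = logging.getLogger(__name__)

TEN_YEARS = 120.0  # months


@dataclass
class ModuleEvaluation:
    cox: CoxResult  # continuous, per unit index
    groups: pd.Series  # 'high' / 'low'
    logrank_chi2: float
    logrank_p: float
    hr_groups: CoxResult  # Cox on the high-vs-low indicator
    km_by_group: dict[str, KMEstimate]
    surv10: dict[str, float]  # S(120 months) per group

    def to_dict(self) -> dict:
        return {
            "hr_per_unit": self.cox.hazard_ratio,
            "p_per_unit": self.cox.p_value,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "hr_groups": self.hr_groups.hazard_ratio,
            "p_groups": self.hr_groups.p_value,
            "surv10": dict(self.surv10),
            "n": self.cox.n,
            "n_events": self.cox.n_events,
        }


def _aligned(scores: pd.Series, surv: SurvivalData) -> tuple[pd.Series, SurvivalData]:
    scores = pd.Series(scores, dtype=float)
    if set(scores.index) != set(surv.sample_ids):
        shared = [s for s in scores.index if s in set(surv.sample_ids)]
        if not shared:
            raise InputError("no shared samples between scores and survival data")
        logger.info("evaluate: restricting to %d shared samples", len(shared))
        scores = scores.loc[shared]
        surv = surv.subset(shared)
    else:
        surv = surv.subset(list(scores.index))
    return scores, surv


def evaluate_module(scores, surv: SurvivalData) -> ModuleEvaluation:
    """Full survival evaluation of one per-sample score vector."""
    scores, surv = _aligned(pd.Series(scores, dtype=float), surv)
    cox = fit_cox(scores.to_numpy(), surv, names=["score"]).result
    groups = median_split(scores)
    indicator = (groups == "high").astype(float).to_numpy()
    if indicator.min() == indicator.max():
        raise InputError("median split produced a single group")
    lr = logrank_test(surv, groups.to_numpy())
    hr_groups = fit_cox(indicator, surv, names=["high_vs_low"]).result
    km_by_group: dict[str, KMEstimate] = {}
    surv10: dict[str, float] = {}
    for label in ("low", "high"):
        mask = (groups == label).to_numpy()
        km = kaplan_meier((surv.time[mask], surv.event[mask]))
        km_by_group[label] = km
        if surv.time[mask].max() < TEN_YEARS:
            logger.warning(
                "evaluate_module: max observed time %.1f < %.0f months in %s "
                "group; S(10y) extrapolates the last step",
                surv.time[mask].max(), TEN_YEARS, label,
            )
        surv10[label] = survival_at(km, TEN_YEARS)
    return ModuleEvaluation(
        cox, groups, lr.chi_square, lr.p_value, hr_groups, km_by_group, surv10
    )


def compare_signatures(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    signatures: dict,
    agg: str = "geometric",
) -> pd.DataFrame:
    """Rank signatures by the p-value score of a continuous Cox fit on
    their cohort score. Unresolvable signatures are skipped with a
    warning."""
    rows = []
    for name, sets in signatures.items():
        try:
            scores = score_cohort(expr, [sets], agg=agg).iloc[:, 0]
            scores, surv_a = _aligned(scores, surv)
            res = fit_cox(scores.to_numpy(), surv_a).result
            rows.append((name, pvalue_score(res.p_value), res.hazard_ratio, res.p_value))
        except InputError as exc:
            logger.warning("compare_signatures: skipping %r: %s", name, exc)
    if not rows:
        raise InputError("no signature could be evaluated")
    table = pd.DataFrame(
        rows, columns=["signature", "pvalue_score", "hazard_ratio", "p_value"]
    ).set_index("signature")
    return table.sort_values("pvalue_score", ascending=False)


def covariate_models(
    surv: SurvivalData,
    scores,
    covariates: list[str] | None = None,
    score_name: str = "score",
) -> dict:
    """Univariate Cox per covariate and for the score, plus one
    multivariate fit on the selected covariates + score.

    Rows with missing covariate values are dropped with a logged count.
    """
    scores = pd.Series(scores, dtype=float)
    covariates = covariates if covariates is not None else surv.covariate_names
    unknown = [c for c in covariates if c not in surv.covariate_names]
    if unknown:
        raise InputError(f"unknown covariates: {unknown}")
    table = surv.table.loc[[s for s in scores.index if s in surv.table.index]].copy()
    table[score_name] = scores.loc[table.index]
    complete = table[covariates + [score_name, "time", "event"]].notna().all(axis=1)
    if (~complete).any():
        logger.info("covariate_models: dropped %d incomplete row(s)", int((~complete).sum()))
        table = table.loc[complete]
    surv_c = SurvivalData(table[["time", "event"]])

    univariate = {}
    for name in covariates + [score_name]:
        x = table[name].to_numpy(dtype=float)
        univariate[name] = fit_cox(x, surv_c, names=[name]).result

    X = table[covariates + [score_name]].to_numpy(dtype=float)
    multivariate: CoxFit = fit_cox(X, surv_c, names=covariates + [score_name])
    if not multivariate.converged:
        logger.warning("covariate_models: multivariate fit did not converge "
                       "(possible collinearity)")
    return {"univariate": univariate, "multivariate": multivariate, "n": len(table)}
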