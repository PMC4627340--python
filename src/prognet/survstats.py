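"""Survival statistics implemented from first principles.

Cox proportional-hazards fitting (Newton-Raphson on the partial likelihood,
Efron or Breslow tie handling), the Cox score test, Kaplan-Meier estimation
with Greenwood variance, the multi-group log-rank test, and p-value scores.

These are re-implemented rather than wrapped so that the score-test /
log-rank identity can be verified across two independent code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
from scipy import stats

from .dataio import SurvivalData
from .errors import ConvergenceError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "CoxFit",
    "KMEstimate",
    "fit_cox",
    "cox_score_test",
    "kaplan_meier",
    "survival_at",
    "logrank_test",
    "pvalue_score",
]


@dataclass
class CoxResult:
    """Per-covariate summary of a Cox proportional-hazards fit."""

    name: str
    beta: float
    se: float
    hazard_ratio: float
    wald_z: float
    p_value: float
    n: int
    n_events: int
    converged: bool
    iterations: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for beta."""
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se


@dataclass
class CoxFit:
    """Full multivariate fit: per-covariate results plus fit diagnostics."""

    results: list[CoxResult]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    iterations: int

    def __getitem__(self, i: int) -> CoxResult:
        return self.results[i]

    @property
    def result(self) -> CoxResult:
        if len(self.results) != 1:
            raise InputError("`.result` is only defined for univariate fits")
        return self.results[0]


def _as_survival_arrays(surv) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(surv, SurvivalData):
        return surv.time, surv.event
    time, event = surv
    return np.asarray(time, dtype=float), np.asarray(event, dtype=int)


def _prepare(X, surv):
    time, event = _as_survival_arrays(surv)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != time.shape[0]:
        raise InputError(
            f"covariate rows ({X.shape[0]}) != survival rows ({time.shape[0]})"
        )
    if not np.isfinite(X).all():
        raise InputError("non-finite covariate values")
    if event.sum() == 0:
        raise InputError("no events in survival data")
    if (time < 0).any():
        raise InputError("negative survival times")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise InputError(f"constant covariate at column(s) {np.flatnonzero(const).tolist()}")
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order]


def _partial_loglik(beta, X, time, event, ties):
    """Log partial likelihood with gradient and information matrix.

    Inputs must be sorted by ascending time. Vectorized over untied event
    times; tied groups (d > 1) are handled in a short loop.
    """
    n, k = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; PL is invariant to this shift
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,il->ijl", w, X, X)

    # reverse cumulative risk-set sums: position i -> sum over j >= i
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum(wx[::-1], axis=0)[::-1]
    c2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(event == 1)
    ev_times = time[ev_idx]
    # first index of each tied event-time group
    uniq_times, group_start, group_sizes = np.unique(
        ev_times, return_index=True, return_counts=True
    )
    # index into the sorted arrays of the first at-risk element per event time
    risk_start = np.searchsorted(time, uniq_times, side="left")

    loglik = float(eta[ev_idx].sum())
    grad = X[ev_idx].sum(axis=0)
    info = np.zeros((k, k))

    # vectorized over groups handled as Breslow (all untied groups, or
    # every group when ties == 'breslow')
    breslow_mask = (group_sizes == 1) if ties == "efron" else np.ones_like(group_sizes, dtype=bool)
    if breslow_mask.any():
        gi = risk_start[breslow_mask]
        d = group_sizes[breslow_mask].astype(float)
        s0 = c0[gi]
        s1 = c1[gi]
        s2 = c2[gi]
        loglik -= float((d * np.log(s0)).sum())
        grad -= (d[:, None] * s1 / s0[:, None]).sum(axis=0)
        info += np.einsum("g,gjl->jl", d / s0, s2)
        info -= np.einsum("g,gj,gl->jl", d / s0**2, s1, s1)

    for g in np.flatnonzero(~breslow_mask):
        d = int(group_sizes[g])
        members = ev_idx[group_start[g] : group_start[g] + d]
        s0, s1, s2 = c0[risk_start[g]], c1[risk_start[g]], c2[risk_start[g]]
        d0 = w[members].sum()
        d1 = wx[members].sum(axis=0)
        d2 = wxx[members].sum(axis=0)
        for ell in range(d):  # efron correction within the tied group
            f = ell / d
            e0 = s0 - f * d0
            e1 = s1 - f * d1
            e2 = s2 - f * d2
            loglik -= np.log(e0)
            grad -= e1 / e0
            info += e2 / e0 - np.outer(e1, e1) / e0**2
    return loglik, grad, info


def fit_cox(
    covariates,
    surv,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
    names: list[str] | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    covariates
        (n,) or (n, k) array of covariate values.
    surv
        ``SurvivalData`` or a ``(time, event)`` pair of arrays.
    ties
        ``"efron"`` (default, matches the R ``coxph`` default) or
        ``"breslow"``.

    Monotone partial likelihoods (perfect separation) are returned flagged
    ``converged=False`` rather than raised, with the diverged estimate.
    """
    if ties not in ("efron", "breslow"):
        raise InputError(f"unknown tie method {ties!r}")
    X, time, event = _prepare(covariates, surv)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if len(names) != k:
        raise InputError("names length mismatch")

    # center columns for numerical stability (shifts eta, not beta)
    mean = X.mean(axis=0)
    Xc = X - mean

    beta = np.zeros(k)
    loglik, grad, info = _partial_loglik(beta, Xc, time, event, ties)
    converged = False
    diverged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            diverged = True
            break
        # step-halving if the likelihood does not improve
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            new_beta = beta + step
            new_ll, new_grad, new_info = _partial_loglik(new_beta, Xc, time, event, ties)
            halvings = 0
            while not (new_ll >= loglik - 1e-12) and halvings < 30:
                step = step / 2
                new_beta = beta + step
                new_ll, new_grad, new_info = _partial_loglik(new_beta, Xc, time, event, ties)
                halvings += 1
        if not (np.isfinite(new_ll) and np.isfinite(new_grad).all()):
            diverged = True
            break
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if np.abs(grad).max() < tol or np.abs(step).max() < tol:
            converged = True
            break
        if np.abs(beta).max() > 40:  # monotone likelihood / separation
            diverged = True
            break

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
        diverged = True
    # monotone likelihood (perfect separation): the gradient vanishes as
    # |beta| grows, so Newton "converges" with a degenerate information
    # matrix; flag it rather than report a spurious fit
    if np.any(~np.isfinite(se)) or np.any(se <= 1e-8 * np.maximum(1.0, np.abs(beta))):
        diverged = True
        logger.warning("fit_cox: degenerate standard error; monotone likelihood suspected")
    if diverged:
        converged = False

    results = []
    for j in range(k):
        z = beta[j] / se[j] if se[j] > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        results.append(
            CoxResult(
                name=names[j],
                beta=float(beta[j]),
                se=float(se[j]),
                hazard_ratio=float(np.exp(beta[j])),
                wald_z=float(z),
                p_value=float(p),
                n=n,
                n_events=int(event.sum()),
                converged=converged,
                iterations=iterations,
            )
        )
    return CoxFit(results, beta, cov, float(loglik), converged, iterations)


def cox_score_test(binary_group, surv) -> tuple[float, float]:
    """Score test of the Cox partial likelihood at beta=0 (Breslow ties)
    for a binary group covariate. Equals the 2-group log-rank chi-square
    in the absence of tied event times.
    """
    group = np.asarray(binary_group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise InputError(f"binary group required, got {len(levels)} level(s)")
    x = (group == levels[1]).astype(float)
    X, time, event = _prepare(x, surv)
    _, grad, info = _partial_loglik(np.zeros(1), X, time, event, ties="breslow")
    if info[0, 0] <= 0:
        raise InputError("degenerate score-test information")
    chi2 = float(grad[0] ** 2 / info[0, 0])
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


@dataclass
class KMEstimate:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    greenwood_var: np.ndarray

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (nan if never reached)."""
        below = self.survival <= 0.5
        if not below.any():
            return float("nan")
        return float(self.times[np.argmax(below)])


def kaplan_meier(surv) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    Censored observations at an event time remain at risk for that time
    (events processed before censorings at tied times — the standard
    convention).
    """
    time, event = _as_survival_arrays(surv)
    if time.shape[0] == 0:
        raise InputError("empty survival data")
    if (time < 0).any():
        raise InputError("negative survival times")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = time.shape[0]

    event_times = np.unique(time[event == 1])
    n_risk = n - np.searchsorted(time, event_times, side="left")
    n_events = np.array(
        [int(((time == t) & (event == 1)).sum()) for t in event_times]
    )
    frac = 1.0 - n_events / n_risk
    survival = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * cumsum(d / (r (r - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_events / (n_risk * (n_risk - n_events))
        terms = np.where(n_risk == n_events, np.inf, terms)
    with np.errstate(invalid="ignore"):
        greenwood = survival**2 * np.cumsum(terms)
    greenwood = np.where(np.isfinite(greenwood), greenwood, 0.0)
    return KMEstimate(event_times, n_risk, n_events, survival, greenwood)


def survival_at(km: KMEstimate, t: float) -> float:
    """Right-continuous step-function value S(t)."""
    if t < 0:
        raise InputError("t must be non-negative")
    idx = np.searchsorted(km.times, t, side="right")
    if idx == 0:
        return 1.0
    return float(km.survival[idx - 1])


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    df: int
    observed: np.ndarray  # per group
    expected: np.ndarray


def logrank_test(surv, groups) -> LogrankResult:
    """Mantel-Haenszel log-rank test across >= 2 groups (df = k - 1)."""
    time, event = _as_survival_arrays(surv)
    groups = np.asarray(groups)
    if groups.shape[0] != time.shape[0]:
        raise InputError("group labels length mismatch")
    levels, gidx = np.unique(groups, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise InputError("log-rank requires >= 2 groups")

    event_times = np.unique(time[event == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = int(((time == t) & (event == 1)).sum())
        n_j = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_j = np.bincount(
            gidx[(time == t) & (event == 1)], minlength=k
        ).astype(float)
        observed += d_j
        expected += d_t * n_j / n_t
        if n_t > 1:
            hyper = d_t * (n_t - d_t) / (n_t - 1)
            p_j = n_j / n_t
            var += hyper * (np.diag(p_j) - np.outer(p_j, p_j))
    diff = (observed - expected)[: k - 1]
    v = var[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return LogrankResult(chi2, p, k - 1, observed, expected)


def pvalue_score(p: float, base: float = 10.0) -> float:
    """Negative logarithm of a p-value (base 10 by default)."""
    if not 0 < p <= 1:
        raise InputError(f"p-value must be in (0, 1], got {p}")
    return float(-np.log(p) / np.log(base))
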