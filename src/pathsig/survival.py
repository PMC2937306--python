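"""Survival analysis: Kaplan-Meier curves, area between curves, optimal
two-group stratification, and Cox proportional hazards.

The stratification objective follows the study design this package
reimplements: candidate thresholds are the midpoints between consecutive
distinct scores; for each admissible split (both groups at least
``min_group_frac`` of the cohort) the two Kaplan-Meier curves are estimated
and the area between them integrated exactly on the merged step grid; the
threshold maximizing that area defines the high/low groups, ties broken
toward the lower threshold.  Significance comes from a Cox
proportional-hazards fit — the partial likelihood is maximized by Newton's
method with Breslow handling of tied event times — reported both for the
binary group indicator and for the continuous score.

Note the group-based p-value after an optimized cutpoint is subject to the
usual selection optimism; the continuous-score p-value is the calibrated
one under the null and both are carried in the result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "KMCurve",
    "CoxResult",
    "StratificationResult",
    "km_estimate",
    "area_between",
    "cox_fit",
    "optimal_stratify",
    "stratify_by_gene",
]

logger = logging.getLogger(__name__)

#: |coefficient| at which the Cox fit is declared monotone-likelihood divergent
COX_COEF_CAP = 15.0


def _check_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in table.columns:
            raise ValidationError(f"survival table must have a {col!r} column")
    if len(table) < 1:
        raise ValidationError("survival table is empty")
    if table.index.has_duplicates:
        raise ValidationError("duplicate sample ids in survival table")
    if (table["time"] < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not table["event"].isin([0, 1]).all():
        raise ValidationError("event flags must be 0 or 1")
    return table


@dataclass
class KMCurve:
    """Product-limit estimate: a right-continuous step function.

    ``times`` are the distinct event times; ``survival[j]`` is S(t) for
    ``times[j] <= t < times[j+1]``.  S is 1 before the first event.
    ``max_observed`` is the largest observed time, censored or not, and
    bounds the region where the curve is supported by data.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int
    max_observed: float

    def survival_at(self, t) -> np.ndarray:
        """Evaluate S(t) (right-continuous) at scalar or array t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def km_estimate(table: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time t_j with d_j events and n_j subjects at
    risk, S is multiplied by (1 - d_j / n_j); times at which only censoring
    occurs change the at-risk count but not S.
    """
    table = _check_survival_table(table)
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    event_times = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in event_times], dtype=int)
    d = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk) if len(event_times) else np.array([])
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=at_risk,
        n_events=d,
        n=len(table),
        max_observed=float(time.max()),
    )


def area_between(c1: KMCurve, c2: KMCurve, horizon: float | None = None) -> float:
    """Integral of |S1(t) - S2(t)| from 0 to the horizon.

    The default horizon is the smaller of the two curves' largest observed
    times (each curve is carried flat to that point, never extrapolated
    beyond its data).  Computed exactly on the merged step grid.
    """
    if horizon is None:
        horizon = min(c1.max_observed, c2.max_observed)
    if horizon <= 0:
        raise ValidationError(f"horizon must be > 0, got {horizon}")
    knots = np.concatenate([[0.0], c1.times, c2.times, [horizon]])
    grid = np.unique(knots[knots <= horizon])
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    left = grid[:-1]
    widths = np.diff(grid)
    gap = np.abs(c1.survival_at(left) - c2.survival_at(left))
    return float(np.sum(gap * widths))


@dataclass
class CoxResult:
    """Single-covariate Cox proportional-hazards fit (Breslow ties)."""

    coef: float
    se: float
    p: float
    loglik: float
    n: int
    n_events: int
    converged: bool
    diverged: bool = False

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.coef))


def _cox_ll_grad_hess(beta, time, event, x):
    """Breslow partial log-likelihood and derivatives at ``beta``.

    Inputs must be sorted by ascending time.  Risk-set sums are reverse
    cumulative sums; tied event times share a risk set and each event
    contributes the full denominator (Breslow).
    """
    eta = beta * x
    eta = eta - eta.max()  # rescale for overflow safety; cancels in ratios
    theta = np.exp(eta)
    r0 = np.cumsum(theta[::-1])[::-1]
    r1 = np.cumsum((theta * x)[::-1])[::-1]
    r2 = np.cumsum((theta * x * x)[::-1])[::-1]
    first = np.searchsorted(time, time, side="left")  # first index of each time
    ev = event == 1
    s0 = r0[first[ev]]
    s1 = r1[first[ev]]
    s2 = r2[first[ev]]
    ll = float(np.sum(eta[ev]) - np.sum(np.log(s0)))
    grad = float(np.sum(x[ev]) - np.sum(s1 / s0))
    hess = float(-np.sum(s2 / s0 - (s1 / s0) ** 2))
    return ll, grad, hess


def cox_fit(covariate, table: pd.DataFrame, tol: float = 1e-9,
            max_iter: int = 50) -> CoxResult:
    """Maximize the Cox partial likelihood for a single covariate.

    Newton's method with step halving; convergence when the log-likelihood
    change drops below ``tol``.  A monotone partial likelihood (perfect
    separation of event order by the covariate) is flagged ``diverged``
    with the coefficient capped at +/-15.
    """
    table = _check_survival_table(table)
    cov = getattr(covariate, "scores", covariate)
    if isinstance(cov, pd.Series):
        cov = cov.reindex(table.index)
        if cov.isna().any():
            raise ValidationError(
                "covariate does not cover all survival samples"
            )
        x = cov.to_numpy(dtype=float)
    else:
        x = np.asarray(cov, dtype=float)
        if len(x) != len(table):
            raise ValidationError(
                f"covariate length {len(x)} != table length {len(table)}"
            )
    if np.std(x) == 0:
        raise ValidationError("covariate is constant")
    n_events = int(table["event"].sum())
    if n_events == 0:
        raise ValidationError("no events in survival table")

    order = np.argsort(table["time"].to_numpy(), kind="mergesort")
    time = table["time"].to_numpy(dtype=float)[order]
    event = table["event"].to_numpy(dtype=int)[order]
    xs = x[order] - x.mean()  # centering: numerical stability only

    beta = 0.0
    ll, grad, hess = _cox_ll_grad_hess(beta, time, event, xs)
    converged = False
    diverged = False
    for _ in range(max_iter):
        if hess >= 0 or not np.isfinite(hess):
            break
        step = -grad / hess
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_ll_grad_hess(new_beta, time, event, xs)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_ll_grad_hess(
                new_beta, time, event, xs
            )
            halvings += 1
        delta = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if abs(beta) > COX_COEF_CAP:
            diverged = True
            beta = math.copysign(COX_COEF_CAP, beta)
            ll, grad, hess = _cox_ll_grad_hess(beta, time, event, xs)
            logger.warning(
                "cox_fit: monotone partial likelihood, coefficient capped at "
                "%+g", beta,
            )
            break
        if abs(delta) < tol:
            converged = True
            break
    info = -hess
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(
        coef=float(beta),
        se=se,
        p=p,
        loglik=ll,
        n=len(table),
        n_events=n_events,
        converged=converged,
        diverged=diverged,
    )


@dataclass
class StratificationResult:
    """Optimal two-group split of a cohort by a per-sample score."""

    threshold: float
    groups: pd.Series            # "high" / "low" per sample
    area: float
    cox_group: CoxResult         # binary high-vs-low indicator
    cox_score: CoxResult         # continuous score (null-calibrated p)
    group_sizes: dict
    curve_high: KMCurve
    curve_low: KMCurve
    n_candidates: int = 0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "area_between_curves": self.area,
            "group_sizes": self.group_sizes,
            "n_candidate_thresholds": self.n_candidates,
            "cox_group": {
                "coef": self.cox_group.coef,
                "se": self.cox_group.se,
                "p": self.cox_group.p,
                "hazard_ratio": self.cox_group.hazard_ratio,
                "diverged": self.cox_group.diverged,
            },
            "cox_score": {
                "coef": self.cox_score.coef,
                "se": self.cox_score.se,
                "p": self.cox_score.p,
                "diverged": self.cox_score.diverged,
            },
            "groups": {str(k): v for k, v in self.groups.items()},
        }


def optimal_stratify(
    scores, table: pd.DataFrame, min_group_frac: float = 0.1
) -> StratificationResult:
    """Split a cohort at the score threshold maximizing the area between
    the two groups' Kaplan-Meier curves.

    Candidate thresholds are midpoints between consecutive distinct sorted
    scores; only splits leaving each group at least ``min_group_frac`` of
    the cohort are admissible (an unconstrained scan degenerates to
    single-sample groups).  Ties in area go to the lower threshold.
    """
    if not 0 < min_group_frac <= 0.5:
        raise ValidationError(
            f"min_group_frac must be in (0, 0.5], got {min_group_frac}"
        )
    table = _check_survival_table(table)
    s = getattr(scores, "scores", scores)
    if isinstance(s, pd.Series):
        s = s.reindex(table.index)
        if s.isna().any():
            raise ValidationError("scores do not cover all survival samples")
    else:
        s = np.asarray(s, dtype=float)
        if len(s) != len(table):
            raise ValidationError(
                f"scores length {len(s)} != table length {len(table)}"
            )
        s = pd.Series(s, index=table.index)
    x = s.to_numpy(dtype=float)
    n = len(x)
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValidationError("no admissible split: scores are constant")
    min_size = int(math.ceil(min_group_frac * n))
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    logger.info(
        "optimal_stratify: %d candidate thresholds, min group size %d, "
        "ties broken toward the lower threshold", len(candidates), min_size,
    )

    best = None  # (area, threshold, curves, mask)
    n_admissible = 0
    for thr in candidates:
        high = x > thr
        n_high = int(high.sum())
        if n_high < min_size or n - n_high < min_size:
            continue
        n_admissible += 1
        c_high = km_estimate(table.loc[high])
        c_low = km_estimate(table.loc[~high])
        area = area_between(c_high, c_low)
        if best is None or area > best[0]:
            best = (area, float(thr), c_high, c_low, high)
    if best is None:
        raise ValidationError(
            "no admissible split: every threshold violates the minimum "
            f"group size {min_size}"
        )
    area, threshold, c_high, c_low, high = best
    groups = pd.Series(np.where(high, "high", "low"), index=table.index)
    cox_group = cox_fit(
        pd.Series(high.astype(float), index=table.index), table
    )
    cox_score = cox_fit(s, table)
    return StratificationResult(
        threshold=threshold,
        groups=groups,
        area=area,
        cox_group=cox_group,
        cox_score=cox_score,
        group_sizes={"high": int(high.sum()), "low": int(n - high.sum())},
        curve_high=c_high,
        curve_low=c_low,
        n_candidates=n_admissible,
    )


def stratify_by_gene(
    expr: pd.DataFrame, probe, table: pd.DataFrame,
    min_group_frac: float = 0.1,
) -> StratificationResult:
    """Optimal stratification using one probe's expression as the score."""
    if probe not in expr.index:
        raise ValidationError(f"unknown probe {probe!r}")
    return optimal_stratify(expr.loc[probe], table, min_group_frac)
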