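"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately use naive Python loops and textbook
formulas, independent of the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import pathsig as ps


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def tiny_expr_annot():
    """2 probes x (2 control + 2 treated) at one time point, hand values."""
    expr = pd.DataFrame(
        {
            "control_4h_r1": [5.0, 8.0],
            "control_4h_r2": [5.0, 6.0],
            "treated_4h_r1": [7.0, 6.5],
            "treated_4h_r2": [6.0, 7.5],
        },
        index=pd.Index(["pA", "pB"], name="probe_id"),
    )
    annot = pd.DataFrame(
        {
            "arm": ["control", "control", "treated", "treated"],
            "time_point": ["4h"] * 4,
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(expr.columns, name="sample_id"),
    )
    return expr, annot


def make_signature(pis, betas, sigma2s, label="sig", ids=None):
    ids = ids or [f"g{i}" for i in range(len(pis))]
    table = pd.DataFrame(
        {"pi": pis, "beta": betas, "sigma2": sigma2s},
        index=pd.Index(ids, name="probe_id"),
    )
    return ps.SignatureModel(label, table)


def random_survival_table(rng, n, censor_frac=0.3, tie_decimals=1):
    """Random survival table with occasional tied times."""
    time = np.round(rng.exponential(5.0, size=n), tie_decimals)
    time = np.maximum(time, 0.1)
    event = (rng.random(n) > censor_frac).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )


# ------------------------------------------------------- survival oracles

def naive_km(times, events):
    """Textbook product-limit computed with explicit loops.

    Returns (event_times, survival) lists.
    """
    pairs = sorted(zip(times, events))
    distinct = sorted({t for t, e in pairs if e == 1})
    surv = []
    s = 1.0
    for t in distinct:
        n_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        s *= 1.0 - d / n_risk
        surv.append(s)
    return distinct, surv


def naive_step_eval(event_times, surv, t):
    """Right-continuous step lookup by linear scan."""
    s = 1.0
    for et, sv in zip(event_times, surv):
        if et <= t:
            s = sv
        else:
            break
    return s


def naive_area(times1, surv1, times2, surv2, horizon):
    """Rectangle sum of |S1 - S2| over the merged knot grid."""
    knots = sorted({0.0, horizon} | {t for t in times1 if t < horizon}
                   | {t for t in times2 if t < horizon})
    if knots[-1] < horizon:
        knots.append(horizon)
    total = 0.0
    for a, b in zip(knots[:-1], knots[1:]):
        s1 = naive_step_eval(times1, surv1, a)
        s2 = naive_step_eval(times2, surv2, a)
        total += abs(s1 - s2) * (b - a)
    return total


def naive_optimal_stratify(scores, table, min_group_frac):
    """Exhaustive threshold scan with the naive KM/area helpers.

    Returns (threshold, area); ties go to the lower threshold.
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    uniq = np.unique(x)
    min_size = math.ceil(min_group_frac * n)
    best = None
    times = table["time"].to_numpy()
    events = table["event"].to_numpy()
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        thr = (lo + hi) / 2.0
        high = x > thr
        if high.sum() < min_size or (n - high.sum()) < min_size:
            continue
        t1, s1 = naive_km(times[high], events[high])
        t2, s2 = naive_km(times[~high], events[~high])
        horizon = min(times[high].max(), times[~high].max())
        area = naive_area(t1, s1, t2, s2, horizon)
        if best is None or area > best[1]:
            best = (thr, area)
    return best


def naive_cox_loglik(beta, times, events, x):
    """Breslow partial log-likelihood via an O(n^2) double loop."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        denom = sum(
            math.exp(beta * x[j]) for j in range(len(times))
            if times[j] >= times[i]
        )
        ll += beta * x[i] - math.log(denom)
    return ll


# ------------------------------------------------ selection-screen oracles

def naive_fold_filter(matrix, fold, min_obs):
    """Double-loop scan for the fold-change filter."""
    cutoff = math.log2(fold)
    kept = []
    for probe in matrix.index:
        count = 0
        for v in matrix.loc[probe]:
            if abs(v) >= cutoff:
                count += 1
        if count >= min_obs:
            kept.append(probe)
    return kept


def naive_discordant(model_a, model_b, top_frac):
    """Enumerate every shared probe and rank by pi_a*pi_b*opposite-sign."""
    shared = [p for p in model_a.table.index if p in model_b.table.index]
    d = {}
    for p in shared:
        ba = model_a.table.at[p, "beta"]
        bb = model_b.table.at[p, "beta"]
        opposite = (ba > 0 > bb) or (ba < 0 < bb)
        d[p] = (
            model_a.table.at[p, "pi"] * model_b.table.at[p, "pi"]
            if opposite else 0.0
        )
    ranked = sorted(shared, key=lambda p: (-d[p], str(p)))
    k = math.ceil(top_frac * len(shared))
    cutoff = d[ranked[k - 1]]
    if cutoff > 0:
        return [p for p in ranked if d[p] >= cutoff]
    return [p for p in ranked if d[p] > 0]
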