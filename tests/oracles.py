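"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (explicit loops, no shared
code with the package) so that package results can be checked against a
second, independent route.
"""

from __future__ import annotations

import numpy as np

ORANGE_PLUS = {"HEMOPTYSIS", "FEVER", "TOO_SICK_FOR_ACTIVITIES"}
RED_PLUS = {
    "VERY_DYSPNEIC", "CHEST_PAIN", "CONFUSED", "FORGETFULNESS",
    "DIZZINESS", "COLLAPSE_TENDENCY", "LOSS_OF_CONSCIOUSNESS",
}


def poisson_irls(X, y, offset, tol=1e-12, maxiter=200):
    """Hand-coded IRLS for a log-link Poisson regression with offset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta + offset
        mu = np.exp(eta)
        W = mu  # Poisson: var = mu, weight = mu for log link
        z = eta - offset + (y - mu) / mu
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def replay_bruteforce(rows, goal_factor=1.0):
    """Naive day-by-day rule walk over a patient log.

    ``rows`` is a list of dicts with keys day, answered, worse, plus,
    steps.  Returns (list of overall-zone ints per row, number of
    overall-zone changes, list of advice strings for changes).
    GREEN=0, YELLOW=1, ORANGE=2, RED=3.
    """
    baseline_vals = [None] * 21
    goal = None
    sym = 0
    run = 0
    red_via_plus = False
    step = 0
    overall_prev = 0
    series = []
    n_changes = 0
    advices = []
    for row in rows:
        day = row["day"]
        if day < 21:
            if row["steps"] is not None:
                baseline_vals[day] = row["steps"]
        elif goal is None:
            present = [v for v in baseline_vals if v is not None]
            if present:
                goal = goal_factor * sum(present) / len(present)
        if row["answered"]:
            if row["worse"]:
                run += 1
                if sym == 0:
                    sym = 1
                if run >= 3 and sym < 2:
                    sym = 2
            else:
                run = 0
                sym = 0
                red_via_plus = False
        if row["plus"] is not None:
            if row["plus"] in ORANGE_PLUS and sym < 2:
                sym = 2
            elif row["plus"] in RED_PLUS and sym < 3:
                sym = 3
                red_via_plus = True
        if row["steps"] is not None and day >= 21 and goal is not None and goal > 0:
            if row["steps"] <= 0.6 * goal:
                step = 3
            elif row["steps"] <= 0.8 * goal:
                step = 2
            else:
                step = 0
        overall = max(sym, step)
        if overall != overall_prev:
            n_changes += 1
            if overall == 0:
                advices.append("NONE")
            elif overall == 1:
                advices.append("READ_PLAN_ADAPT_MEDICATION")
            elif overall == 3 and red_via_plus and sym == 3:
                advices.append("CALL_AMBULANCE")
            else:
                advices.append("EMERGENCY_MEDICATION_OR_CONTACT_HCP")
        overall_prev = overall
        series.append(overall)
    return series, n_changes, advices


def quantiles_bruteforce(values, q):
    """Linear-interpolation quantile from sorted order statistics."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = q * (n - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def random_log(rng, n_days=60, p_answer=0.6, p_worse=0.35, p_plus=0.1,
               p_steps=0.7, patient_id=1):
    """Random daily log both as DailyRecords and as plain oracle rows."""
    from copdwatch.cohort import DailyRecord

    plus_choices = sorted(ORANGE_PLUS | RED_PLUS | {"NONE"})
    records, rows = [], []
    for day in range(n_days):
        answered = rng.random() < p_answer
        worse = bool(rng.random() < p_worse) if answered else None
        plus = plus_choices[rng.integers(len(plus_choices))] if rng.random() < p_plus else None
        steps = int(rng.integers(0, 8000)) if rng.random() < p_steps else None
        records.append(DailyRecord(patient_id, day, answered, worse, plus, steps, None))
        rows.append({
            "day": day, "answered": answered, "worse": bool(worse) if worse is not None else False,
            "plus": plus, "steps": steps,
        })
    return records, rows
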