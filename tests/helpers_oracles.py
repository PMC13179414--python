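"""Naive double-loop reference implementations used as independent oracles.

Everything here deliberately re-derives the estimators from their
definitions with explicit Python loops over pairs, independent of the
vectorized code paths under test.
"""

from __future__ import annotations

import math

import numpy as np

from winodds import SubjectRecord, compare_hierarchical


def naive_score_matrix(records, rule=compare_hierarchical):
    n = len(records)
    S = np.full((n, n), 0.5)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            S[i, j] = 0.5 * (1 + rule(records[i], records[j]))
    return S


def naive_win_statistics(records, rule=compare_hierarchical):
    """Pair counts over (control i, treated j) by direct enumeration."""
    wins = losses = ties = 0
    n0 = n1 = 0
    for r in records:
        if r.arm == 0:
            n0 += 1
        else:
            n1 += 1
    for a in records:
        if a.arm != 0:
            continue
        for b in records:
            if b.arm != 1:
                continue
            v = rule(a, b)
            if v == 1:
                wins += 1
            elif v == -1:
                losses += 1
            else:
                ties += 1
    nu = (wins + 0.5 * ties) / (n0 * n1)
    return wins, losses, ties, nu


def naive_delta_variance(records, rule=compare_hierarchical):
    """Two-sample U-statistic projection variance of the net benefit."""
    ctrl = [r for r in records if r.arm == 0]
    trt = [r for r in records if r.arm == 1]
    row_means = [np.mean([rule(a, b) for b in trt]) for a in ctrl]
    col_means = [np.mean([rule(a, b) for a in ctrl]) for b in trt]
    return (
        np.var(row_means, ddof=1) / len(ctrl)
        + np.var(col_means, ddof=1) / len(trt)
    )


def expit(t):
    return 1.0 / (1.0 + math.exp(-t))


def naive_standardize(tau_a, tau_x, X):
    n = X.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total += expit(tau_a + float(np.dot(tau_x, X[j] - X[i])))
    return total / (n * (n - 1))


def naive_augment(S, arms, tau_a, tau_x, X):
    n = len(arms)
    n0 = int(np.sum(arms == 0))
    n1 = int(np.sum(arms == 1))
    nu_direct = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and arms[i] == 0 and arms[j] == 1:
                nu_direct += S[i, j]
    nu_direct /= n0 * n1
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            h = expit(tau_a + float(np.dot(tau_x, X[j] - X[i])))
            w = 1.0 / (n * (n - 1)) - (1 - arms[i]) * arms[j] / (n0 * n1)
            total += w * h
    return nu_direct + total


def naive_pim_score(S, arms, X, beta):
    """Estimating-equation value at beta, summed pair by pair."""
    n = len(arms)
    q = 1 + X.shape[1]
    score = np.zeros(q)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.concatenate(([arms[j] - arms[i]], X[j] - X[i]))
            score += d * (S[i, j] - expit(float(d @ beta)))
    return score


def random_records(rng, n, p=2, tie_prob=0.2):
    """Random censored composite outcomes exercising every comparison branch."""
    records = []
    times = rng.integers(1, 8, size=n).astype(float)  # ties likely
    for k in range(n):
        t1 = float(times[k])
        d1 = int(rng.random() < 0.5)
        if rng.random() < tie_prob:
            t2, d2 = t1, 0
        else:
            t2 = float(rng.integers(1, 8))
            if t2 >= t1:
                t2, d2 = t1, 0
            else:
                d2 = 1
        records.append(
            SubjectRecord(
                subject_id=k,
                arm=int(rng.random() < 0.5),
                covariates=rng.standard_normal(p),
                terminal_time=t1,
                terminal_event=d1,
                nonfatal_time=t2,
                nonfatal_event=d2,
            )
        )
    # guarantee both arms occupied
    records[0].arm = 0
    records[1].arm = 1
    return records
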