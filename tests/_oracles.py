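"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal, loop-based translations of the
defining formulas, deliberately sharing no code with the package, so each
serves as an independent oracle for the optimized implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def efron_partial_loglik(beta_vec, times, events, design):
    """Efron-tie partial log-likelihood, literal definition with loops."""
    beta_vec = np.atleast_1d(np.asarray(beta_vec, dtype=float))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != len(times):
        design = design.T
    eta = design @ beta_vec
    loglik = 0.0
    for t in sorted(set(times[events == 1])):
        dead = [i for i in range(len(times)) if times[i] == t and events[i] == 1]
        risk = [i for i in range(len(times)) if times[i] >= t]
        d = len(dead)
        sum_risk = sum(np.exp(eta[i]) for i in risk)
        sum_dead = sum(np.exp(eta[i]) for i in dead)
        for i in dead:
            loglik += eta[i]
        for ell in range(d):
            loglik -= np.log(sum_risk - (ell / d) * sum_dead)
    return loglik


def brute_force_cox_binary(times, events, group_high):
    """Maximize the binary-covariate Efron partial likelihood numerically."""
    z = np.asarray(group_high, dtype=float).reshape(-1, 1)
    result = minimize_scalar(
        lambda b: -efron_partial_loglik([b], times, events, z),
        bounds=(-15.0, 15.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(result.x)


def brute_force_cox_multivariate(times, events, design):
    """Maximize the multivariate Efron partial likelihood numerically."""
    design = np.asarray(design, dtype=float)
    p = design.shape[1]
    result = minimize(
        lambda b: -efron_partial_loglik(b, times, events, design),
        x0=np.zeros(p),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return np.asarray(result.x, dtype=float)


def logrank_o_e_v(times, events, group_high):
    """Hand-rolled two-group log-rank test: (O - E)^2 / V and its p-value."""
    from scipy.stats import chi2

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    z = np.asarray(group_high, dtype=bool)
    o_minus_e = 0.0
    variance = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & z).sum())
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        d1 = int((dead & z).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / variance
    return stat, float(chi2.sf(stat, 1))


def bh_stepup(p_values):
    """Literal Benjamini-Hochberg step-up adjusted p-values."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, value)
        q[i] = running_min
    return q


def kaplan_meier_table(times, events):
    """Hand product-limit estimator: (event_times, survival, at_risk)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    out_t, out_s, out_n = [], [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / n
        out_t.append(t)
        out_s.append(s)
        out_n.append(n)
    return out_t, out_s, out_n


def running_sum_es(ordered_genes, ordered_metric, members, weight_p=1.0):
    """Literal weighted KS running-sum enrichment score."""
    members = set(members)
    n = len(ordered_genes)
    n_hits = sum(1 for g in ordered_genes if g in members)
    total_hit_weight = sum(
        abs(m) ** weight_p for g, m in zip(ordered_genes, ordered_metric) if g in members
    )
    running = []
    value = 0.0
    for gene, metric in zip(ordered_genes, ordered_metric):
        if gene in members:
            if total_hit_weight > 0:
                value += abs(metric) ** weight_p / total_hit_weight
            else:
                value += 1.0 / n_hits
        else:
            value -= 1.0 / (n - n_hits)
        running.append(value)
    peak = max(running)
    trough = min(running)
    # magnitude ties (to float tolerance) go positive
    es = peak if peak + trough >= -1e-9 else trough
    return es, running
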