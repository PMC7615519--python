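"""Independent, deliberately naive re-implementations used as test oracles.

Everything here evaluates closed-form level formulas non-incrementally
(full sums re-done at every step) with explicit candidate/selection
bookkeeping, so it shares no code path with the package's incremental
schedule machinery.
"""

from __future__ import annotations

import numpy as np


def gamma_fn(weights_from_start, start):
    """Lookup gamma_k with zero outside the tabulated range."""

    def g(k):
        i = k - start
        if 0 <= i < len(weights_from_start):
            return float(weights_from_start[i])
        return 0.0

    return g


def lord_original_levels(pvals, alpha, w0, b0, gamma1):
    g = gamma_fn(gamma1, 1)
    levels, rejects, taus = [], [], []
    for t in range(1, len(pvals) + 2):
        a = w0 * g(t) + b0 * sum(g(t - tau) for tau in taus)
        a = min(a, 1.0)
        levels.append(a)
        if t <= len(pvals):
            r = pvals[t - 1] <= a
            rejects.append(r)
            if r:
                taus.append(t)
    return np.array(levels), np.array(rejects)


def lordpp_levels(pvals, alpha, w0, gamma1):
    g = gamma_fn(gamma1, 1)
    levels, rejects, taus = [], [], []
    for t in range(1, len(pvals) + 2):
        a = w0 * g(t)
        if taus:
            a += (alpha - w0) * g(t - taus[0])
            a += alpha * sum(g(t - tau) for tau in taus[1:])
        a = min(a, 1.0)
        levels.append(a)
        if t <= len(pvals):
            r = pvals[t - 1] <= a
            rejects.append(r)
            if r:
                taus.append(t)
    return np.array(levels), np.array(rejects)


def saffron_levels(pvals, alpha, w0, lam, gamma1):
    g = gamma_fn(gamma1, 1)
    levels, rejects, taus, cand = [], [], [], []
    for t in range(1, len(pvals) + 2):
        c0 = sum(cand[: t - 1])
        term = w0 * g(t - c0)
        if taus:
            t1 = taus[0]
            c1 = sum(cand[t1 : t - 1])
            term += (alpha - w0) * g(t - t1 - c1)
            for tj in taus[1:]:
                cj = sum(cand[tj : t - 1])
                term += alpha * g(t - tj - cj)
        a = min(lam, (1.0 - lam) * term)
        levels.append(a)
        if t <= len(pvals):
            p = pvals[t - 1]
            r = p <= a
            rejects.append(r)
            if r:
                taus.append(t)
            cand.append(p <= lam)
    return np.array(levels), np.array(rejects)


def addis_levels(pvals, alpha, w0, lam, eta, gamma0):
    g = gamma_fn(gamma0, 0)
    levels, rejects, taus, sel, cand = [], [], [], [], []
    for t in range(1, len(pvals) + 2):
        s_t = sum(sel[: t - 1])
        c0 = sum(1 for j in range(t - 1) if sel[j] and cand[j])
        term = w0 * g(s_t - c0)
        if taus:
            t1 = taus[0]
            s_t1 = sum(sel[:t1])
            c1 = sum(1 for j in range(t1, t - 1) if sel[j] and cand[j])
            term += (alpha - w0) * g(s_t - s_t1 - c1)
            for tj in taus[1:]:
                s_tj = sum(sel[:tj])
                cj = sum(1 for j in range(tj, t - 1) if sel[j] and cand[j])
                term += alpha * g(s_t - s_tj - cj)
        a = min(lam, (eta - lam) * term)
        levels.append(a)
        if t <= len(pvals):
            p = pvals[t - 1]
            r = p <= a
            rejects.append(r)
            if r:
                taus.append(t)
            sel.append(p <= eta)
            cand.append(p <= lam)
    return np.array(levels), np.array(rejects)


def monotone_ai_levels(pvals, alpha, w0, gamma1):
    """Self-candidacy recursion; each level solves x = (1 - x) * B."""
    g = gamma_fn(gamma1, 1)
    levels, rejects, taus, cand = [], [], [], []
    for t in range(1, len(pvals) + 2):
        c0 = sum(cand[: t - 1])
        bracket = w0 * g(t - c0)
        if taus:
            t1 = taus[0]
            c1 = sum(cand[t1 : t - 1])
            bracket += (alpha - w0) * g(t - t1 - c1)
            for tj in taus[1:]:
                cj = sum(cand[tj : t - 1])
                bracket += alpha * g(t - tj - cj)
        a = bracket / (1.0 + bracket)
        levels.append(a)
        if t <= len(pvals):
            p = pvals[t - 1]
            r = p <= a
            rejects.append(r)
            if r:
                taus.append(t)
            cand.append(p <= a)
    return np.array(levels), np.array(rejects)


def bh_threshold_scan(pvals, alpha):
    """Brute-force BH: try every observed p-value as the fixed threshold
    and keep the largest one whose FDP overestimate stays at or below alpha."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    best = None
    for s in sorted(set(p)):
        n_rej = int((p <= s).sum())
        if n_rej > 0 and n * s / n_rej <= alpha:
            best = s
    if best is None:
        return set()
    return {int(i) for i in np.nonzero(p <= best)[0]}
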