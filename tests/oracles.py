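"""Independent brute-force oracles used to validate the implementation.

Each oracle is a direct transcription of the defining formula or an
exhaustive enumeration, deliberately naive and independent of the code
paths it checks.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar


def bh_stepup_bruteforce(pvalues):
    """BH q-values straight from the step-up definition, O(m^2)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def mannwhitney_exact_twosided(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free inputs).

    Enumerates every assignment of the pooled values into groups of the
    observed sizes; the p-value is the probability of a U at least as far
    from its null mean as the observed U.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n1, n2 = len(x), len(y)

    def u_stat(group1, group2):
        return sum(1 for a in group1 for b in group2 if a > b)

    u_obs = u_stat(x, y)
    centre = n1 * n2 / 2.0
    extreme = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(n1 + n2) if i not in combo]
        u = u_stat(g1, g2)
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            extreme += 1
        total += 1
    return u_obs, extreme / total


def cox_partial_loglik(beta, time, event, x):
    """Written-out Cox partial log-likelihood, single covariate, no ties."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return ll


def cox_mle_bruteforce(time, event, x):
    """Maximise the written-out partial likelihood over a scalar beta."""
    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, time, event, x),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def logrank_bruteforce(time, event, groups):
    """Two-group log-rank chi-square from the observed-vs-expected tables."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert labels.size == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var
    from scipy.stats import chi2

    return float(stat), float(chi2.sf(stat, 1))


def hypergeom_uppertail(k, big_m, n_term, n_draw):
    """P(X >= k) from the closed-form hypergeometric pmf."""
    total = 0.0
    for j in range(k, min(n_term, n_draw) + 1):
        total += (
            math.comb(n_term, j)
            * math.comb(big_m - n_term, n_draw - j)
            / math.comb(big_m, n_draw)
        )
    return total
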