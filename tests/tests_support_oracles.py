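"""Brute-force statistical oracles, independent of the package internals."""

import numpy as np


def oracle_logrank_two_group(times, events, group):
    """Two-group log-rank chi2 recomputed from first-principles risk tables."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group, bool)
    O1 = E1 = V = 0.0
    for t in sorted(set(times[events])):
        at = times >= t
        d = float((events & (times == t)).sum())
        d1 = float((events & (times == t) & group).sum())
        n = float(at.sum())
        n1 = float((at & group).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


def oracle_chi_square(obs):
    """Pearson chi-square by explicit sum of (O-E)^2 / E."""
    obs = np.asarray(obs, float)
    row = obs.sum(1, keepdims=True)
    col = obs.sum(0, keepdims=True)
    expected = row @ col / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def oracle_efron_loglik(beta, x, times, events):
    """Efron-tie Cox partial log-likelihood for a single covariate."""
    eta = beta * np.asarray(x, float)
    r = np.exp(eta)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    ll = 0.0
    for t in sorted(set(times[events])):
        D = np.flatnonzero(events & (times == t))
        R = np.flatnonzero(times >= t)
        sum_r = r[R].sum()
        sum_rd = r[D].sum()
        d = len(D)
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(sum_r - (l / d) * sum_rd)
    return ll
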