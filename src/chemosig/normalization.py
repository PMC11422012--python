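"""Trimmed Mean of M-values (TMM) scaling and log2-CPM normalization.

TMM estimates one relative scaling factor per sample that corrects for
composition bias between RNA-seq libraries before any cross-sample analysis.
For a sample *s* against a reference *r*, genes expressed in both libraries
contribute an M-value (log2 ratio of library-normalized counts) and an
A-value (average log2 abundance). The most extreme M- and A-values are
trimmed, and the factor is 2 to the precision-weighted mean of the surviving
M-values. Factors are recentered so their geometric mean is 1, which keeps
the overall scale of the data unchanged.

The implementation follows the standard algorithm: reference chosen as the
sample whose upper quartile of non-zero CPM is closest to the mean upper
quartile, 30% two-sided trim on M, 5% on A, and inverse-asymptotic-variance
precision weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, NormalizationState

__all__ = ["tmm_factors", "normalize_log2"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (pre-centering)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic variance of M (binomial delta method)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    keep = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[keep], a[keep], v[keep]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any():
        return 1.0
    w = 1.0 / v[sel]
    f = 2.0 ** (np.sum(w * m[sel]) / np.sum(w))
    if not np.isfinite(f):
        return 1.0
    return float(f)


def tmm_factors(
    counts: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors.

    Parameters
    ----------
    counts
        Raw-count matrix (``state == raw_counts``) with >= 2 samples.
    trim_m, trim_a
        Two-sided trim fractions for the M-values (log-ratios) and A-values
        (log-abundances).

    Returns
    -------
    pandas.Series
        Strictly positive factors indexed by sample, geometric mean 1. The
        effective library size of sample *s* is ``libsize(s) * factor(s)``.
    """
    if counts.state is not NormalizationState.RAW_COUNTS:
        raise ValueError("tmm_factors requires a raw_counts matrix")
    if counts.n_samples < 2:
        raise ValueError("tmm_factors requires at least two samples")
    x = counts.values
    lib = x.sum(axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        names = [counts.sample_ids[i] for i in zero]
        raise ValueError(f"all-zero sample(s): {', '.join(names)}")

    # reference: upper quartile of non-zero CPM closest to the mean upper quartile
    uq = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        cpm = x[:, j] / lib[j] * 1e6
        nz = cpm[cpm > 0]
        uq[j] = np.percentile(nz, 75)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    raw = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref_idx:
            raw[j] = 1.0
        else:
            raw[j] = _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
    # recenter to geometric mean 1
    factors = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def normalize_log2(
    counts: ExpressionMatrix,
    factors: pd.Series | None = None,
    prior: float = 1.0,
) -> ExpressionMatrix:
    """log2-CPM on TMM-effective library sizes.

    value(g, s) = log2( count(g, s) / (libsize(s) * factor(s)) * 1e6 + prior )

    With the default pseudocount of 1, a zero count maps to exactly 0.
    """
    if counts.state is not NormalizationState.RAW_COUNTS:
        raise ValueError("normalize_log2 requires a raw_counts matrix")
    if factors is None:
        factors = tmm_factors(counts)
    if set(factors.index) != set(counts.sample_ids):
        raise ValueError("factors do not cover the same samples as the count matrix")
    f = factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("scaling factors must be finite and positive")
    x = counts.values
    lib = x.sum(axis=0)
    cpm = x / (lib * f)[None, :] * 1e6
    out = pd.DataFrame(
        np.log2(cpm + prior), index=counts.gene_ids, columns=counts.sample_ids
    )
    return ExpressionMatrix(out, NormalizationState.TMM_LOG2)
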