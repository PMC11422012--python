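"""Survival and categorical-response statistics for signature validation.

Patients are scored by signature projection and dichotomized at the score
cutpoint giving the best survival separation (lowest log-rank p subject to a
minimum group-size proportion). Because the cutpoint is chosen to minimize
p, the module reports both the raw log-rank p at the chosen cutpoint and a
selection-adjusted p (Lausen-Schumacher approximation for maximally selected
rank statistics); significance claims should use the adjusted value.

Kaplan-Meier estimation, Cox proportional-hazards fits (Efron ties) and
IPTW-weighted curves are delegated to lifelines behind this module's
interface; the log-rank statistic is computed directly from the risk tables
so the cutpoint scan stays vectorized and exactly reproducible.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

__all__ = [
    "ClinicalCohort",
    "KMCurve",
    "StratificationResult",
    "CombinationProfile",
    "km_estimate",
    "logrank_test",
    "best_cutpoint",
    "cox_fit",
    "iptw_adjusted_km",
    "combine_drug_labels",
    "orr_exact",
    "chi_square",
]

logger = logging.getLogger(__name__)

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass
class ClinicalCohort:
    """Per-patient clinical table.

    Required columns: ``id``, ``arm`` (e.g. mFFX / GEM), ``os_time`` (months,
    > 0), ``os_event`` (bool). Optional: ``pfs_time``/``pfs_event``,
    ``response`` (CR/PR/SD/PD), ``purist`` (classical / basal-like) and any
    further covariate columns.
    """

    data: pd.DataFrame

    REQUIRED = ("id", "arm", "os_time", "os_event")

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate patient ids: {dups}")
        if (df["os_time"].astype(float) <= 0).any():
            raise ValueError("os_time must be > 0")
        df["os_event"] = df["os_event"].astype(bool)
        if "pfs_event" in df.columns:
            df["pfs_event"] = df["pfs_event"].astype(bool)
        if "pfs_time" in df.columns and (df["pfs_time"].dropna().astype(float) <= 0).any():
            raise ValueError("pfs_time must be > 0")
        if "response" in df.columns:
            bad = set(df["response"].dropna()) - set(RESPONSE_CATEGORIES)
            if bad:
                raise ValueError(f"unknown response categories: {sorted(bad)}")
        self.data = df.set_index("id", drop=False)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def arm_subset(self, arm: str) -> "ClinicalCohort":
        sub = self.data[self.data["arm"] == arm].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no patients in arm {arm!r}")
        return ClinicalCohort(sub)


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk counts and Greenwood SE."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_se: np.ndarray
    median: float  # nan = not reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median_label(self) -> str:
        return "not reached" if np.isnan(self.median) else f"{self.median:.3g}"


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    weights: Sequence[float] | None = None,
) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Median survival is the first time with S(t) <= 0.5 (NaN when never
    reached). Optional case weights give the weighted estimator used by
    IPTW adjustment.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e, weights=None if weights is None else np.asarray(weights, float))
    sf = kmf.survival_function_.iloc[:, 0]
    # drop the t=0 anchor row unless 0 is an observed time
    obs_times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    if obs_times[0] == 0 and 0 not in t:
        obs_times, surv = obs_times[1:], surv[1:]
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)
    at_risk = np.array([w[t >= tt].sum() for tt in obs_times])
    d_at = np.array([w[(t == tt) & e].sum() for tt in obs_times])
    # Greenwood variance: S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d_at, d_at / (at_risk * (at_risk - d_at)), np.nan)
    se = surv * np.sqrt(np.cumsum(terms))
    median = kmf.median_survival_time_
    median = float("nan") if np.isinf(median) else float(median)
    return KMCurve(
        times=obs_times, survival=surv, at_risk=at_risk, greenwood_se=se, median=median
    )


def _risk_table(times: np.ndarray, events: np.ndarray, group: np.ndarray):
    """Per-event-time (d_total, n_total, d_g, n_g) arrays for each group label."""
    uniq = np.unique(times[events])
    labels = np.unique(group)
    n_t = np.array([(times >= t).sum() for t in uniq], dtype=float)
    d_t = np.array([((times == t) & events).sum() for t in uniq], dtype=float)
    n_g = np.stack([[((times >= t) & (group == g)).sum() for t in uniq] for g in labels]).astype(float)
    d_g = np.stack(
        [[((times == t) & events & (group == g)).sum() for t in uniq] for g in labels]
    ).astype(float)
    return uniq, n_t, d_t, n_g, d_g, labels


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence,
) -> tuple[float, int, float]:
    """Multi-group log-rank test: (chi2, df, p).

    Standard observed-minus-expected statistic with hypergeometric variance;
    df = number of groups - 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if not e.any():
        raise ValueError("log-rank test needs >= 1 event")
    _, n_t, d_t, n_g, d_g, labels = _risk_table(t, e, g)

    O = d_g.sum(axis=1)
    E = (d_t[None, :] * n_g / n_t[None, :]).sum(axis=1)
    k = labels.size
    # covariance of (O - E) over the first k-1 groups
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
    V = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            pi = n_g[i] / n_t
            pj = n_g[j] / n_t
            V[i, j] = np.sum(mult * (pi * ((i == j) - pj)))
    z = (O - E)[: k - 1]
    Vs = V[: k - 1, : k - 1]
    chi2 = float(z @ np.linalg.pinv(Vs) @ z)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _two_group_logrank_chi2(
    n_t: np.ndarray, d_t: np.ndarray, n1_t: np.ndarray, d1_t: np.ndarray
) -> float:
    """Scalar two-group log-rank chi2 from risk-table vectors."""
    E1 = np.sum(d_t * n1_t / n_t)
    O1 = np.sum(d1_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n_t > 1,
            d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1),
            0.0,
        )
    V = float(np.sum(var))
    if V <= 0:
        return 0.0
    return float((O1 - E1) ** 2 / V)


def lausen_schumacher_p(max_chi2: float, minprop: float) -> float:
    """Selection-adjusted p for a maximally selected log-rank statistic.

    Improved-Bonferroni approximation for the supremum of the standardized
    two-sample statistic over cutpoints keeping each group above ``minprop``
    of the cohort. Conservative for small b; clipped to [0, 1].
    """
    b = float(np.sqrt(max(max_chi2, 0.0)))
    if b <= 1.0:  # approximation only valid in the tail
        return 1.0
    e1, e2 = minprop, 1.0 - minprop
    phi = stats.norm.pdf(b)
    p = phi * (b - 1.0 / b) * np.log((e2 * (1 - e1)) / ((1 - e2) * e1)) + 4 * phi / b
    return float(np.clip(p, 0.0, 1.0))


@dataclass
class StratificationResult:
    """Optimal-cutpoint dichotomization of a score against survival."""

    cutpoint: float
    labels: pd.Series  # patient -> bool (True = positive = score > cutpoint)
    logrank_chi2: float
    logrank_p: float
    p_adjusted: float  # Lausen-Schumacher selection-adjusted
    n_candidates: int
    km_positive: KMCurve
    km_negative: KMCurve
    hr: float
    hr_ci: tuple[float, float]
    hr_p: float

    def summary(self) -> str:
        pos = int(self.labels.sum())
        neg = int((~self.labels).sum())
        return "\n".join(
            [
                "Optimal-cutpoint stratification",
                "=" * 40,
                f"cutpoint:          {self.cutpoint:.4g} ({self.n_candidates} candidates scanned)",
                f"groups:            {pos} positive / {neg} negative",
                f"median OS +/-:     {self.km_positive.median_label} / {self.km_negative.median_label}",
                f"log-rank:          chi2 {self.logrank_chi2:.3f}, p {self.logrank_p:.3g}"
                f" (selection-adjusted p {self.p_adjusted:.3g})",
                f"hazard ratio (+):  {self.hr:.3f} (95% CI {self.hr_ci[0]:.3f}-{self.hr_ci[1]:.3f},"
                f" p {self.hr_p:.3g})",
            ]
        )


def _scan_chi2(
    score_arr: np.ndarray,
    candidates: np.ndarray,
    at_risk_mask: np.ndarray,
    event_mask: np.ndarray,
    n_t: np.ndarray,
    d_t: np.ndarray,
) -> np.ndarray:
    """Two-group log-rank chi2 for every candidate cutpoint, vectorized.

    ``at_risk_mask``/``event_mask`` are (event-times x patients) boolean
    tables; group membership for all candidates is a (patients x candidates)
    matrix, so the per-cutpoint risk tables reduce to two matmuls.
    """
    hi = score_arr[:, None] > candidates[None, :]  # patients x candidates
    n1 = at_risk_mask.astype(float) @ hi  # times x candidates
    d1 = event_mask.astype(float) @ hi
    E1 = (d_t[:, None] * n1 / n_t[:, None]).sum(axis=0)
    O1 = d1.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            (n_t[:, None] > 1),
            d_t[:, None] * (n1 / n_t[:, None]) * (1 - n1 / n_t[:, None])
            * (n_t[:, None] - d_t[:, None]) / (n_t[:, None] - 1),
            0.0,
        )
    V = var.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, (O1 - E1) ** 2 / V, 0.0)
    return chi2


def best_cutpoint(
    scores: pd.Series | Mapping[str, float],
    times: Sequence[float],
    events: Sequence[bool],
    min_group_proportion: float = 0.10,
    n_permutations: int = 199,
    permutation_seed: int = 0,
) -> StratificationResult:
    """Scan score cutpoints for the best survival separation.

    Candidates are midpoints between consecutive distinct sorted scores
    whose induced groups each hold at least ``min_group_proportion`` of
    patients. The cutpoint minimizing the two-group log-rank p is returned
    (ties: larger minority group, then lower cutpoint). Positive label =
    score > cutpoint.

    ``p_adjusted`` accounts for the minimum-p selection: with
    ``n_permutations > 0`` it is the exact permutation p of the maximal
    statistic (score labels shuffled, deterministic given
    ``permutation_seed``); with 0 it falls back to the Lausen-Schumacher
    approximation.
    """
    s = pd.Series(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(s) != len(t) or len(s) != len(e):
        raise ValueError("scores, times and events must align")
    if len(s) < 10:
        raise ValueError("need >= 10 patients for cutpoint selection")
    if not 0 < min_group_proportion < 0.5:
        raise ValueError("min_group_proportion must be in (0, 0.5)")
    distinct = np.unique(s.to_numpy())
    if distinct.size < 2:
        raise ValueError("scores are constant; no cutpoint exists")

    n = len(s)
    min_n = int(np.ceil(min_group_proportion * n))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    score_arr = s.to_numpy()
    sizes_hi = (score_arr[:, None] > mids[None, :]).sum(axis=0)
    ok = (sizes_hi >= min_n) & ((n - sizes_hi) >= min_n)
    candidates = mids[ok]
    if candidates.size == 0:
        raise ValueError(
            f"no cutpoint leaves both groups with >= {min_n} patients "
            f"(min_group_proportion={min_group_proportion})"
        )
    logger.info("best_cutpoint: scanning %d candidate cutpoints", candidates.size)

    # shared risk-table backbone over event times
    uniq = np.unique(t[e])
    at_risk_mask = t[None, :] >= uniq[:, None]  # times x patients
    event_mask = (t[None, :] == uniq[:, None]) & e[None, :]
    n_t = at_risk_mask.sum(axis=1).astype(float)
    d_t = event_mask.sum(axis=1).astype(float)

    chi2s = _scan_chi2(score_arr, candidates, at_risk_mask, event_mask, n_t, d_t)
    ps = stats.chi2.sf(chi2s, 1)
    minority = np.minimum(sizes_hi[ok], n - sizes_hi[ok])
    order = sorted(range(candidates.size), key=lambda i: (ps[i], -minority[i], candidates[i]))
    i_best = order[0]
    cut, chi2, p = float(candidates[i_best]), float(chi2s[i_best]), float(ps[i_best])
    hi = score_arr > cut
    labels = pd.Series(hi, index=s.index, name="positive")

    if n_permutations > 0:
        rng = np.random.default_rng(permutation_seed)
        max_obs = chi2s.max()
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(score_arr)
            sizes_p = (perm[:, None] > mids[None, :]).sum(axis=0)
            ok_p = (sizes_p >= min_n) & ((n - sizes_p) >= min_n)
            if not ok_p.any():
                continue
            chi2_p = _scan_chi2(perm, mids[ok_p], at_risk_mask, event_mask, n_t, d_t)
            exceed += chi2_p.max() >= max_obs
        p_adj = (1 + exceed) / (n_permutations + 1)
    else:
        p_adj = lausen_schumacher_p(chi2, min_group_proportion)

    km_pos = km_estimate(t[hi], e[hi])
    km_neg = km_estimate(t[~hi], e[~hi])
    try:
        row = cox_fit(pd.DataFrame({"positive": hi.astype(float)}), t, e).loc["positive"]
        hr, hr_ci, hr_p = float(row["hr"]), (float(row["ci_low"]), float(row["ci_high"])), float(row["p"])
    except ValueError as exc:
        # perfect separation at the chosen cutpoint: the HR is unbounded
        logger.warning("cutpoint Cox fit not identifiable: %s", exc)
        hr, hr_ci, hr_p = float("nan"), (float("nan"), float("nan")), float("nan")
    return StratificationResult(
        cutpoint=float(cut),
        labels=labels,
        logrank_chi2=chi2,
        logrank_p=p,
        p_adjusted=float(p_adj),
        n_candidates=int(candidates.size),
        km_positive=km_pos,
        km_negative=km_neg,
        hr=hr,
        hr_ci=hr_ci,
        hr_p=hr_p,
    )


def cox_fit(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) via partial likelihood.

    Returns one row per covariate with columns beta, se, hr, ci_low,
    ci_high, p. Monotone likelihood (separation) is reported as an error
    rather than a silently diverging estimate.
    """
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    const = [c for c in cov.columns if cov[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    n_events = int(np.asarray(events, bool).sum())
    if n_events < cov.shape[1]:
        raise ValueError(f"{n_events} events for {cov.shape[1]} covariates")
    df = cov.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=bool).astype(int)
    cph = CoxPHFitter()
    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            cph.fit(df, duration_col="_time", event_col="_event",
                    fit_options={"precision": 1e-12})
        sep_warned = any(
            "complete separation" in str(w.message).lower()
            or "monotone" in str(w.message).lower()
            for w in caught
        )
        # a drifting Newton step at a huge |beta| is the monotone-likelihood signature
        drifting = any("norm(delta) is still high" in str(w.message) for w in caught)
        diverged = np.any(np.abs(cph.params_.to_numpy()) > 10) or drifting
        if diverged:
            raise ValueError(
                "monotone partial likelihood (separation) detected; the hazard "
                "ratio is not identifiable for at least one covariate"
            )
        if sep_warned:
            # lifelines' heuristic fires on strong but identifiable effects too;
            # surface it without refusing the finite estimate
            logger.warning("possible separation reported by the fitter; estimates are finite")
    except ConvergenceError as exc:
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    out = pd.DataFrame(
        {
            "beta": cph.params_,
            "se": cph.standard_errors_,
            "hr": np.exp(cph.params_),
            "ci_low": np.exp(cph.params_ - 1.959963984540054 * cph.standard_errors_),
            "ci_high": np.exp(cph.params_ + 1.959963984540054 * cph.standard_errors_),
            "p": cph.summary["p"],
        }
    )
    out.index.name = "covariate"
    return out


def iptw_adjusted_km(
    group: Sequence,
    times: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame,
    truncate: tuple[float, float] = (1.0, 99.0),
) -> dict:
    """IPTW-weighted Kaplan-Meier curves per group.

    Propensity of group membership is estimated by logistic regression on
    the covariates; stabilized weights P(G=g) / P(G=g | X) are truncated at
    the given percentiles. Returns ``{group: {"weighted": KMCurve,
    "unweighted": KMCurve}}`` plus the weights under ``"weights"``.
    """
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("IPTW adjustment implemented for exactly 2 groups")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    X = pd.DataFrame(covariates).reset_index(drop=True)
    if X.isna().any().any():
        raise ValueError("covariates must be observed for all patients")
    y = (g == labels[1]).astype(float)

    import statsmodels.api as sm

    design = sm.add_constant(X.to_numpy(dtype=float))
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        except Exception as exc:
            raise ValueError(f"propensity model failed: {exc}") from exc
    ps = np.clip(res.predict(design), 1e-12, 1 - 1e-12)
    if np.any(ps > 1 - 1e-8) or np.any(ps < 1e-8):
        raise ValueError("perfect propensity separation: weights are unbounded")

    marginal = y.mean()
    w = np.where(y == 1, marginal / ps, (1 - marginal) / (1 - ps))
    lo, hi = np.percentile(w, truncate)
    w = np.clip(w, lo, hi)

    out: dict = {"weights": pd.Series(w, name="iptw_weight"), "propensity": pd.Series(ps)}
    for lab in labels:
        m = g == lab
        out[lab] = {
            "weighted": km_estimate(t[m], e[m], weights=w[m]),
            "unweighted": km_estimate(t[m], e[m]),
        }
    return out


@dataclass
class CombinationProfile:
    """Per-patient count of drugs predicted sensitive (0-3)."""

    per_drug: pd.DataFrame  # patients x drugs, bool
    sensitive_count: pd.Series

    def counts_table(self) -> pd.Series:
        return self.sensitive_count.value_counts().sort_index()


def combine_drug_labels(strat: Mapping[str, StratificationResult]) -> CombinationProfile:
    """Combine per-drug positive labels into a sensitive-drug count.

    The count (0 as reference) is the covariate for downstream Cox models of
    combination benefit.
    """
    drugs = list(strat)
    if not drugs:
        raise ValueError("no stratification results supplied")
    idx = strat[drugs[0]].labels.index
    for d in drugs[1:]:
        if not strat[d].labels.index.equals(idx):
            raise ValueError(f"patient sets differ between drugs {drugs[0]!r} and {d!r}")
    per_drug = pd.DataFrame({d: strat[d].labels.astype(bool) for d in drugs}, index=idx)
    count = per_drug.sum(axis=1).astype(int)
    count.name = "sensitive_count"
    return CombinationProfile(per_drug=per_drug, sensitive_count=count)


def orr_exact(
    responses: Sequence[str],
    p0: float = 0.5,
) -> tuple[float, float, float, float]:
    """Objective response rate with exact binomial inference.

    ORR = (#CR + #PR) / n; 95% Clopper-Pearson interval; two-sided exact
    binomial p against the null proportion ``p0``.
    """
    resp = [r for r in responses if isinstance(r, str)]
    if not resp:
        raise ValueError("empty response group")
    bad = set(resp) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories: {sorted(bad)}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    n = len(resp)
    k = sum(r in ("CR", "PR") for r in resp)
    orr = k / n
    ci_low = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    ci_high = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    p = float(stats.binomtest(k, n, p0).pvalue)
    return orr, ci_low, ci_high, p


def chi_square(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction. A warning is logged when any expected count is
    below 5; a zero row/column marginal is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if np.any(expected < 5):
        logger.warning("chi-square: %d expected counts below 5", int((expected < 5).sum()))
    return float(chi2), int(df), float(p)
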