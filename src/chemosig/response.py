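"""Preclinical drug-response quantification.

Two readouts feed signature derivation:

* **Viability AUC** (PDC/PDO): viability fraction-of-control is measured
  across a log-spaced concentration range (1 nmol/L to 1 mmol/L), fitted to
  a four-parameter logistic in log10(dose), and summarised as the area under
  the fitted curve normalized by the width of the log-dose range. Lower AUC
  = more sensitive. An optional growth-rate correction maps viability to a
  division-rate-normalized response before integration, removing the
  confound between proliferation speed and apparent sensitivity.
* **POR, percentage of resistance** (PDX): per-arm tumor-volume growth
  curves are fitted with a three-parameter logistic in time; POR is the
  treated growth AUC divided by the control growth AUC over an identical day
  interval. POR 1 = no effect, 0 = complete regression.

Discovery cohorts are assembled from the AUC distribution: models inside the
[P10, P25] percentile band form the sensitive pool and [P75, P90] the
resistant pool (six each), leaving the extremes out so the contrast is not
driven by outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import ResponseScore

__all__ = [
    "DoseResponsePanel",
    "SigmoidFit",
    "GrowthCurveSet",
    "GrowthCurveFit",
    "tumor_volume",
    "fit_dose_response",
    "viability_auc",
    "fit_growth_curve",
    "por",
    "select_discovery_samples",
]

logger = logging.getLogger(__name__)

DOSE_RANGE = (1e-9, 1e-3)  # mol/L, 1 nmol/L .. 1 mmol/L


def tumor_volume(length: np.ndarray, width: np.ndarray) -> np.ndarray:
    """Ellipsoid caliper volume: v = length * width^2 / 2 (mm^3)."""
    return np.asarray(length, float) * np.asarray(width, float) ** 2 / 2.0


@dataclass
class DoseResponsePanel:
    """Viability panel for one (model, drug) pair.

    ``viability`` is a long-form array aligned with ``doses``: one row per
    (dose, replicate) observation.
    """

    model_id: str
    drug: str
    doses: np.ndarray  # mol/L, one per observation row
    viability: np.ndarray  # fraction of control, one per observation row
    replication_rate: float | None = None  # divisions per assay window

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses.shape != self.viability.shape or self.doses.ndim != 1:
            raise ValueError("doses and viability must be aligned 1-D arrays")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive concentrations (mol/L)")
        if np.any(self.viability < 0) or not np.all(np.isfinite(self.viability)):
            raise ValueError("viability must be finite and >= 0")
        if np.unique(self.doses).size < 5:
            raise ValueError("panel needs at least 5 distinct doses")


@dataclass
class SigmoidFit:
    """Four-parameter logistic fit in log10(dose).

    viability(d) = lower + (upper - lower) / (1 + (d / ec50)^hill)

    with hill > 0, so viability decreases with dose.
    """

    upper: float
    lower: float
    ec50: float
    hill: float
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.converged and self.upper < self.lower:
            raise ValueError("upper asymptote below lower on a converged fit")

    def __call__(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return _four_pl(d, self.upper, self.lower, self.ec50, self.hill)


def _four_pl(d: np.ndarray, upper: float, lower: float, ec50: float, hill: float) -> np.ndarray:
    # computed in log-space for numerical stability at extreme hill slopes
    t = hill * (np.log10(d) - np.log10(ec50))
    t = np.clip(t, -500, 500)
    return lower + (upper - lower) / (1.0 + 10.0 ** t)


def fit_dose_response(panel: DoseResponsePanel) -> SigmoidFit:
    """Least-squares 4PL fit with a multi-start grid over EC50 and slope.

    The fit minimizes squared error over all replicate observations jointly.
    Starts cover a log-spaced EC50 grid across the observed dose range and
    Hill slopes {0.5, 1, 2}; the best local optimum is kept. ``converged``
    reflects the optimizer status of that best start.
    """
    d, v = panel.doses, panel.viability
    lo_d, hi_d = d.min(), d.max()
    v_hi, v_lo = float(np.percentile(v, 90)), float(np.percentile(v, 10))

    def resid(p: np.ndarray) -> np.ndarray:
        upper, lower, lec50, hill = p
        return _four_pl(d, upper, lower, 10.0 ** lec50, hill) - v

    bounds = (
        [0.0, 0.0, np.log10(lo_d) - 2, 0.05],
        [max(2.0, 2 * v.max() + 0.1), max(1.0, v.max()), np.log10(hi_d) + 2, 20.0],
    )
    best = None
    for lec0 in np.linspace(np.log10(lo_d), np.log10(hi_d), 7):
        for hill0 in (0.5, 1.0, 2.0):
            p0 = np.array([max(v_hi, 1e-3), max(v_lo, 0.0), lec0, hill0])
            p0 = np.clip(p0, bounds[0], bounds[1])
            try:
                sol = least_squares(resid, p0, bounds=bounds, method="trf")
            except Exception:  # pragma: no cover - pathological start
                continue
            if best is None or sol.cost < best.cost - 1e-12:
                best = sol
    if best is None:
        raise RuntimeError("dose-response fit failed from every start")
    upper, lower, lec50, hill = best.x
    if upper < lower:  # enforce the asymptote ordering the bounds allow
        upper, lower = lower, upper
    return SigmoidFit(
        upper=float(upper),
        lower=float(lower),
        ec50=float(10.0 ** lec50),
        hill=float(hill),
        rss=float(2 * best.cost),
        converged=bool(best.success),
    )


def _gr_transform(viability: np.ndarray, replication_rate: float) -> np.ndarray:
    """Growth-rate-normalized response, rescaled to [0, 1].

    GR(x) = 2^(1 + log2(x)/k) - 1 for viability x (fraction of control) and
    k control divisions per assay window: the ratio of treated to control
    growth rate re-expressed on a doubling scale. GR = 1 means no effect,
    0 complete cytostasis, < 0 cell loss; the [-1, 1] range is mapped
    affinely to [0, 1] so the integral stays comparable with the
    raw-viability AUC (full viability still integrates to 1).
    """
    if replication_rate <= 0:
        raise ValueError("replication_rate must be positive")
    x = np.clip(viability, 1e-12, None)
    gr = 2.0 ** (1.0 + np.log2(x) / replication_rate) - 1.0
    return np.clip((gr + 1.0) / 2.0, 0.0, None)


def viability_auc(
    fit: SigmoidFit,
    model_id: str,
    drug: str,
    dose_range: tuple[float, float] = DOSE_RANGE,
    replication_rate: float | None = None,
    n_grid: int = 201,
) -> ResponseScore:
    """Range-normalized area under the fitted viability curve.

    Trapezoid integration of the fitted curve over log10(dose) on an
    ``n_grid``-point grid, divided by the width of the log-dose range, so a
    fully resistant model (viability 1 everywhere) has AUC exactly 1.
    """
    if not fit.converged:
        raise ValueError(
            "non-converged fit: recompute the AUC by raw trapezoid on the "
            "observed viabilities instead of the fitted curve"
        )
    lo, hi = dose_range
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    y = fit(grid)
    if replication_rate is not None:
        y = _gr_transform(y, replication_rate)
    auc = np.trapezoid(y, np.log10(grid)) / (np.log10(hi) - np.log10(lo))
    return ResponseScore(model_id=model_id, drug=drug, metric="viability_auc", value=float(auc))


@dataclass
class GrowthCurveSet:
    """Tumor-volume time series for one PDX arm.

    ``series`` maps mouse id -> (days, volumes mm^3) arrays. Volumes above
    the 2000 mm^3 sacrifice threshold are censored (dropped with a log
    message) from that day onward.
    """

    pdx_id: str
    arm: str  # "control" | "treated"
    series: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    sacrifice_volume: float = 2000.0

    def __post_init__(self) -> None:
        if self.arm not in ("control", "treated"):
            raise ValueError("arm must be 'control' or 'treated'")
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for mouse, (days, vols) in self.series.items():
            days = np.asarray(days, dtype=float)
            vols = np.asarray(vols, dtype=float)
            if days.shape != vols.shape or days.ndim != 1:
                raise ValueError(f"mouse {mouse!r}: days and volumes must align")
            if np.any(np.diff(days) < 0):
                raise ValueError(f"mouse {mouse!r}: days must be nondecreasing")
            if np.any(vols < 0):
                raise ValueError(f"mouse {mouse!r}: volumes must be >= 0")
            over = np.nonzero(vols > self.sacrifice_volume)[0]
            if over.size:
                cut = over[0]
                logger.info(
                    "pdx %s mouse %s censored from day %g (volume %.0f > %.0f)",
                    self.pdx_id, mouse, days[cut], vols[cut], self.sacrifice_volume,
                )
                days, vols = days[:cut], vols[:cut]
            if days.size:
                clean[mouse] = (days, vols)
        self.series = clean

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        days = np.concatenate([d for d, _ in self.series.values()])
        vols = np.concatenate([v for _, v in self.series.values()])
        return days, vols

    @property
    def last_common_day(self) -> float:
        return min(float(d[-1]) for d, _ in self.series.values())


@dataclass
class GrowthCurveFit:
    """Three-parameter logistic V(t) = vmax / (1 + exp(-k (t - t0)))."""

    vmax: float
    k: float
    t0: float
    rss: float
    flagged: bool  # set on degenerate (e.g. shrinking) data

    def __call__(self, t: np.ndarray) -> np.ndarray:
        z = np.clip(-self.k * (np.asarray(t, float) - self.t0), -500, 500)
        return self.vmax / (1.0 + np.exp(z))


def fit_growth_curve(curves: GrowthCurveSet) -> GrowthCurveFit:
    """Joint logistic fit to all replicate mice of one arm.

    All (day, volume) points are pooled and fitted by least squares; with
    replicate mice this is the curve through the replicate cloud, so
    duplicating a mouse leaves the fit unchanged.
    """
    t, v = curves.pooled()
    if np.unique(t).size < 3:
        raise ValueError("growth-curve fit needs >= 3 distinct observation days")
    vmax0 = max(v.max(), 1.0)

    # detect non-growing data: best monotone description is a flat/declining line
    day_means = pd.Series(v).groupby(pd.Series(t)).mean()
    declining = day_means.iloc[-1] < day_means.iloc[0]

    def resid(p: np.ndarray) -> np.ndarray:
        vmax, k, t0 = p
        z = np.clip(-k * (t - t0), -500, 500)
        return vmax / (1.0 + np.exp(z)) - v

    span = max(t.max() - t.min(), 1.0)
    best = None
    for k0 in (0.05, 0.15, 0.5):
        for t0_0 in np.linspace(t.min(), t.max(), 4):
            sol = least_squares(
                resid,
                np.array([vmax0 * 1.2, k0, t0_0]),
                bounds=([1e-9, 1e-4, t.min() - 5 * span], [10 * vmax0 + 10, 10.0, t.max() + 5 * span]),
                method="trf",
            )
            if best is None or sol.cost < best.cost - 1e-12:
                best = sol
    vmax, k, t0 = best.x
    if declining:
        # shrinking tumors: report a flat curve at the initial volume, flagged
        v0 = float(day_means.iloc[0])
        return GrowthCurveFit(vmax=v0, k=1e-6, t0=float(t.min() - span), rss=float(2 * best.cost), flagged=True)
    return GrowthCurveFit(
        vmax=float(vmax), k=float(k), t0=float(t0), rss=float(2 * best.cost), flagged=False
    )


def _growth_auc(fn: Callable[[np.ndarray], np.ndarray], t_max: float, n_grid: int = 201) -> float:
    grid = np.linspace(0.0, t_max, n_grid)
    return float(np.trapezoid(fn(grid), grid))


def por(
    treated: GrowthCurveSet,
    control: GrowthCurveSet,
    t_max: float | None = None,
    drug: str = "",
    fitted: bool = True,
) -> ResponseScore:
    """Percentage of resistance: treated / control growth AUC over [0, t_max].

    Both AUCs are evaluated on the identical day interval. With
    ``fitted=True`` (default) AUCs come from the per-arm logistic fits; the
    raw mode trapezoids the per-day mean volumes instead.
    """
    if treated.pdx_id != control.pdx_id:
        raise ValueError(
            f"arms from different PDX: {treated.pdx_id!r} vs {control.pdx_id!r}"
        )
    last_common = min(treated.last_common_day, control.last_common_day)
    if t_max is None:
        t_max = last_common
    if t_max > last_common + 1e-9:
        raise ValueError(f"t_max {t_max} exceeds last common day {last_common}")

    if fitted:
        fit_t = fit_growth_curve(treated)
        fit_c = fit_growth_curve(control)
        auc_t = _growth_auc(fit_t, t_max)
        auc_c = _growth_auc(fit_c, t_max)
    else:
        def raw_auc(cs: GrowthCurveSet) -> float:
            t, v = cs.pooled()
            means = pd.Series(v).groupby(pd.Series(t)).mean()
            days = means.index.to_numpy(dtype=float)
            keep = days <= t_max + 1e-9
            return float(np.trapezoid(means.to_numpy()[keep], days[keep]))

        auc_t = raw_auc(treated)
        auc_c = raw_auc(control)
    if auc_c <= 0:
        raise ValueError("control growth AUC is zero; POR undefined")
    return ResponseScore(
        model_id=treated.pdx_id, drug=drug, metric="por", value=float(auc_t / auc_c)
    )


def select_discovery_samples(
    aucs: pd.Series | dict[str, float],
    n_per_group: int = 6,
    bands: tuple[float, float, float, float] = (10.0, 25.0, 75.0, 90.0),
) -> tuple[list[str], list[str]]:
    """Pick the sensitive and resistant discovery models from the AUC spread.

    Sensitive pool: AUC in [P10, P25]; resistant pool: AUC in [P75, P90]
    (linear-interpolation / type-7 percentiles). If a band holds more than
    ``n_per_group`` models, the ones closest to the band midpoint are kept;
    fewer is an error.
    """
    s = pd.Series(aucs, dtype=float).sort_index()
    if s.size < 2 * n_per_group:
        raise ValueError(f"need at least {2 * n_per_group} models, got {s.size}")
    if s.nunique() == 1:
        raise ValueError("all AUCs identical: percentile bands are degenerate")
    if s.duplicated().any():
        logger.info("tied AUC values present; ties broken by model id order")

    lo_s, hi_s, lo_r, hi_r = np.percentile(s.to_numpy(), bands)  # type-7 default

    def pick(lo: float, hi: float, label: str) -> list[str]:
        in_band = s[(s >= lo) & (s <= hi)]
        if in_band.size < n_per_group:
            raise ValueError(
                f"{label} band [{lo:.4g}, {hi:.4g}] holds {in_band.size} models, "
                f"need {n_per_group}; enlarge the cohort"
            )
        mid = (lo + hi) / 2.0
        order = (in_band - mid).abs().sort_values(kind="stable")
        return sorted(order.index[:n_per_group].tolist(), key=lambda m: s.index.get_loc(m))

    sensitive = pick(lo_s, hi_s, "sensitive")
    resistant = pick(lo_r, hi_r, "resistant")
    return sensitive, resistant
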