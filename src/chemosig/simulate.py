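"""Synthetic study generator with planted, recoverable ground truth.

Every input the pipeline consumes can be simulated here: paired PDC/PDX
count matrices driven by shared patient-level latent programs, viability
dose-response panels and PDX growth curves whose response metrics are
monotone noisy functions of the planted drug latents, an independent
validation PDC cohort, and a two-arm clinical cohort whose survival depends
on the planted sensitivities in the mFFX arm only.

Generative model
----------------
* Each patient carries ``n_latent`` latent activities z ~ Laplace(0, 1/sqrt 2)
  (unit variance, leptokurtic — the non-Gaussianity ICA requires). The first
  three latents are the drug-response programs (5FU, oxaliplatin,
  irinotecan); the rest are background biology.
* A sparse loading matrix maps latents to genes: each drug program touches
  its planted support (disjoint across drugs by default), each background
  program a random gene set. log-scale expression is
  ``baseline + loadings @ z + noise`` and counts are Poisson around the
  exp-scaled mean with log-normal library sizes, so TMM has real work to do.
* A patient's PDC and PDX share z up to independent model-system noise, so
  homologous ICA components exist by construction.
* Viability AUC (and PDX POR) are linked to the drug latent through a
  Gaussian copula calibrated to a target Spearman correlation
  (``effect_rho``), then realized as full dose-response panels / growth
  curves that the response module re-fits.
* Clinical overall and progression-free survival are Weibull with
  log-hazard ``sum_d beta_d [z_d > 0]`` for mFFX patients only — the
  arm-exclusive effect structure the pipeline is meant to detect. Objective
  response is Bernoulli with logit linear in the sensitive-drug count, and
  the PurIST-like subtype label is correlated with the oxaliplatin and
  irinotecan programs but not the 5FU one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri
from scipy import stats

from .containers import DrugSignature, ExpressionMatrix, NormalizationState
from .clinical import ClinicalCohort
from .response import DOSE_RANGE, DoseResponsePanel, GrowthCurveSet

__all__ = [
    "DRUGS",
    "SimulationSpec",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_paired_expression",
    "simulate_response",
    "simulate_clinical_cohort",
    "simulate_study",
    "overdispersion",
]

DRUGS = ("5FU", "oxaliplatin", "irinotecan")

_LN_035 = float(np.log(0.35))


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design parameters of the synthetic cohort generator."""

    n_genes: int = 2000
    n_discovery_pool: int = 40       # paired PDC/PDX models to select 12 from
    n_patients_discovery: int = 12   # selected discovery models (6 + 6)
    n_validation_pdc: int = 30
    n_patients_clinical: int = 170
    n_latent: int = 6
    planted_support_size: dict = field(
        default_factory=lambda: {"5FU": 39, "oxaliplatin": 277, "irinotecan": 25}
    )
    support_overlap: int = 0         # genes shared between consecutive drug supports
    background_support_size: int = 150
    effect_rho: float = 0.8          # target |Spearman| latent vs AUC / POR
    noise_sd: float = 0.3            # model-system + gene-level log noise
    loading_scale: float = 1.0       # magnitude of planted gene weights
    baseline_log_mean: float = 4.5   # natural-log mean count scale (~90 counts/gene)
    library_sd: float = 0.2          # log-normal library-size spread
    viability_noise_sd: float = 0.05
    n_doses: int = 9
    n_replicates: int = 3
    n_pdx_response: int = 7          # PDXs per drug with growth-curve data
    n_mice: int = 5
    growth_vmax: float = 1500.0      # mm^3
    growth_k: float = 0.12
    growth_t0: float = 25.0          # days
    growth_noise_sd: float = 0.10
    mffx_fraction: float = 0.563
    # log hazard per sensitive-drug count (mFFX arm only); additive per drug
    # at the per-signature scale the clinical cohorts report (HR ~ 0.35)
    hazard_beta: dict = field(
        default_factory=lambda: {0: 0.0, 1: -1.35, 2: -2.70, 3: -4.05}
    )
    os_median_mffx: float = 4.5      # months, count-0 mFFX baseline (arm median ~10)
    os_median_gem: float = 4.7
    pfs_median_mffx: float = 2.6     # count-0 baseline (arm median ~5)
    pfs_median_gem: float = 2.4
    weibull_shape: float = 1.3
    censor_low: float = 24.0         # months, uniform censoring window
    censor_high: float = 96.0        # ~8-year retrospective accrual + follow-up
    orr_intercept: float = -2.8      # mFFX logit of response vs sensitive count
    orr_slope: float = 1.15
    gem_orr: float = 0.08
    purist_assoc: float = 0.9        # logit scale of subtype/latent association
    seed: int = 0

    def __post_init__(self) -> None:
        for d, n in self.planted_support_size.items():
            if n <= 0:
                raise ValueError(f"planted support for {d!r} must be positive")
            if n > self.n_genes:
                raise ValueError(f"planted support for {d!r} exceeds n_genes")
        if not 0 < self.effect_rho <= 1:
            raise ValueError("effect_rho must be in (0, 1]")
        for name in ("n_genes", "n_discovery_pool", "n_validation_pdc",
                     "n_patients_clinical", "n_latent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted parameters serialized alongside every simulated dataset."""

    spec: SimulationSpec
    supports: dict            # drug -> list of gene ids
    loadings: pd.DataFrame    # genes x latents
    baseline: pd.Series       # per-gene natural-log baseline
    latents: dict             # cohort name -> DataFrame (latents x samples)
    auc_targets: dict         # cohort -> {drug: Series per sample}
    por_targets: dict         # drug -> Series per pdx
    sensitive: pd.DataFrame | None = None   # clinical patients x drugs, bool
    hazard_lp: pd.Series | None = None      # clinical log-hazard (mFFX effect)

    def true_signature(self, drug: str) -> DrugSignature:
        """Planted signature: support genes with their loading weights.

        Oriented so a higher projection score means more sensitive (the
        drug latent raises expression of positively loaded genes).
        """
        genes = self.supports[drug]
        j = DRUGS.index(drug)
        w = self.loadings.loc[genes].iloc[:, j].to_numpy()
        return DrugSignature(drug=drug, gene_ids=genes, weights=w,
                             provenance={"planted": True})

    def to_json_dict(self) -> dict:
        return {
            "seed": self.spec.seed,
            "supports": {d: list(g) for d, g in self.supports.items()},
            "effect_rho": self.spec.effect_rho,
            "hazard_beta": {str(k): v for k, v in self.spec.hazard_beta.items()},
        }


def _copula_mix(z: np.ndarray, rho_s: float, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal variate with Spearman correlation ~ rho_s to z.

    z is rank-transformed to normal scores, then mixed with independent
    Gaussian noise at the Pearson level 2 sin(pi rho_s / 6) that yields the
    requested Spearman correlation for a bivariate Gaussian copula.
    """
    n = z.size
    ranks = stats.rankdata(z)
    zn = ndtri(ranks / (n + 1))
    zn = zn / max(zn.std(), 1e-12)
    a = 2 * np.sin(np.pi * rho_s / 6)
    a = min(a, 1.0)
    return a * zn + np.sqrt(max(1 - a**2, 0.0)) * rng.standard_normal(n)


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _build_loadings(spec: SimulationSpec, rng: np.random.Generator):
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    loadings = np.zeros((spec.n_genes, spec.n_latent))
    supports: dict[str, list[str]] = {}
    available = np.arange(spec.n_genes)
    rng.shuffle(available)
    cursor = 0
    for j, drug in enumerate(DRUGS):
        size = spec.planted_support_size[drug]
        start = max(cursor - spec.support_overlap, 0)
        idx = available[start:start + size]
        if idx.size < size:
            raise ValueError("drug supports exhaust the gene universe")
        cursor = start + size
        w = rng.uniform(0.8, 1.2, size=size) * rng.choice([-1.0, 1.0], size=size)
        loadings[idx, j] = w * spec.loading_scale
        supports[drug] = [genes[i] for i in idx]
    for j in range(len(DRUGS), spec.n_latent):
        idx = rng.choice(spec.n_genes, size=spec.background_support_size, replace=False)
        w = rng.uniform(0.8, 1.2, size=idx.size) * rng.choice([-1.0, 1.0], size=idx.size)
        loadings[idx, j] = w * spec.loading_scale
    baseline = rng.normal(spec.baseline_log_mean, 1.0, size=spec.n_genes)
    return (
        supports,
        pd.DataFrame(loadings, index=genes, columns=[f"L{j}" for j in range(spec.n_latent)]),
        pd.Series(baseline, index=genes, name="baseline"),
    )


def _counts_cohort(
    truth_loadings: pd.DataFrame,
    baseline: pd.Series,
    latents: pd.DataFrame,
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Poisson counts around exp-scaled means for one cohort."""
    A = truth_loadings.to_numpy()
    Z = latents.to_numpy()  # latents x samples
    log_mu = baseline.to_numpy()[:, None] + A @ Z
    log_mu = log_mu + rng.normal(0.0, spec.noise_sd, size=log_mu.shape)
    lib = np.exp(rng.normal(0.0, spec.library_sd, size=Z.shape[1]))
    counts = rng.poisson(np.exp(np.clip(log_mu, -20, 20)) * lib[None, :])
    return ExpressionMatrix.from_arrays(
        counts.astype(float), truth_loadings.index, latents.columns,
        NormalizationState.RAW_COUNTS,
    )


def simulate_paired_expression(spec: SimulationSpec):
    """Paired PDC/PDX discovery-pool counts plus the validation PDC cohort.

    Returns ``(pdc, pdx, truth)``; the validation cohort's counts live in
    ``truth`` via :func:`simulate_study` (which wires everything together).
    Per patient, the latent vector is drawn once and shared by that
    patient's PDC and PDX profiles up to independent model-system noise.
    """
    rng = _spawn(spec.seed, 0)
    supports, loadings, baseline = _build_loadings(spec, rng)

    n_pool = spec.n_discovery_pool
    patient_ids = [f"P{i:02d}" for i in range(n_pool)]
    z_patient = rng.laplace(0.0, 1 / np.sqrt(2), size=(spec.n_latent, n_pool))

    def model_latents(prefix: str, stream: int) -> pd.DataFrame:
        r = _spawn(spec.seed, stream)
        z = z_patient + r.normal(0.0, spec.noise_sd, size=z_patient.shape)
        cols = [f"{prefix}{i:02d}" for i in range(n_pool)]
        return pd.DataFrame(z, index=loadings.columns, columns=cols)

    z_pdc = model_latents("PDC", 1)
    z_pdx = model_latents("PDX", 2)

    pdc = _counts_cohort(loadings, baseline, z_pdc, spec, _spawn(spec.seed, 3))
    pdx = _counts_cohort(loadings, baseline, z_pdx, spec, _spawn(spec.seed, 4))

    # independent validation PDC cohort (its own patients)
    rv = _spawn(spec.seed, 5)
    z_val = pd.DataFrame(
        rv.laplace(0.0, 1 / np.sqrt(2), size=(spec.n_latent, spec.n_validation_pdc)),
        index=loadings.columns,
        columns=[f"VAL{i:02d}" for i in range(spec.n_validation_pdc)],
    )

    truth = GroundTruth(
        spec=spec,
        supports=supports,
        loadings=loadings,
        baseline=baseline,
        latents={
            "patient": pd.DataFrame(z_patient, index=loadings.columns, columns=patient_ids),
            "pdc": z_pdc,
            "pdx": z_pdx,
            "validation": z_val,
        },
        auc_targets={},
        por_targets={},
    )
    return pdc, pdx, truth


def _auc_targets_for(
    latents: pd.DataFrame, drug: str, spec: SimulationSpec, rng: np.random.Generator
) -> pd.Series:
    j = DRUGS.index(drug)
    z = latents.iloc[j].to_numpy()
    y = _copula_mix(z, spec.effect_rho, rng)
    # higher latent activity -> more sensitive -> lower AUC
    auc = 0.55 - 0.35 * np.tanh(y / 1.5)
    return pd.Series(auc, index=latents.columns, name=f"auc_{drug}")


def _panel_from_target(
    model_id: str, drug: str, target_auc: float, spec: SimulationSpec,
    rng: np.random.Generator,
) -> DoseResponsePanel:
    """Dose-response panel whose fitted, range-normalized AUC ~ target."""
    lo, hi = np.log10(DOSE_RANGE[0]), np.log10(DOSE_RANGE[1])
    hill = 1.2
    grid = np.linspace(lo, hi, 201)

    def auc_of(m: float) -> float:
        y = 1.0 / (1.0 + 10.0 ** (hill * (grid - m)))
        return float(np.trapezoid(y, grid) / (hi - lo))

    t = float(np.clip(target_auc, auc_of(lo - 3) + 1e-3, auc_of(hi + 3) - 1e-3))
    m = brentq(lambda mm: auc_of(mm) - t, lo - 3, hi + 3)
    doses = np.repeat(np.logspace(lo, hi, spec.n_doses), spec.n_replicates)
    clean = 1.0 / (1.0 + 10.0 ** (hill * (np.log10(doses) - m)))
    viability = np.clip(clean + rng.normal(0, spec.viability_noise_sd, doses.size), 0, None)
    return DoseResponsePanel(model_id=model_id, drug=drug, doses=doses, viability=viability)


def _growth_curves_for(
    pdx_id: str, arm: str, ratio: float, spec: SimulationSpec, rng: np.random.Generator
) -> GrowthCurveSet:
    days = np.arange(0.0, 46.0, 3.5)
    vmax = spec.growth_vmax * (ratio if arm == "treated" else 1.0)
    series = {}
    for mm in range(spec.n_mice):
        z = np.clip(-spec.growth_k * (days - spec.growth_t0), -500, 500)
        clean = vmax / (1.0 + np.exp(z))
        noisy = clean * np.exp(rng.normal(0, spec.growth_noise_sd, days.size))
        series[f"{pdx_id}_{arm}_m{mm}"] = (days, noisy)
    return GrowthCurveSet(pdx_id=pdx_id, arm=arm, series=series)


def simulate_response(truth: GroundTruth, drugs=DRUGS, null_drugs=()):
    """Dose-response panels (PDC pool + validation) and PDX growth curves.

    Viability AUC targets follow the planted latent through the calibrated
    copula; panels realize those targets so the response module can re-fit
    them. ``null_drugs`` get a POR target of exactly 1 (no planted growth
    effect) regardless of the latent — the negative control for POR
    calibration.

    Returns ``(panels, growth_curves)`` where panels maps cohort ->
    {(model_id, drug): DoseResponsePanel} and growth_curves maps
    drug -> {pdx_id: (treated, control)}.
    """
    spec = truth.spec
    panels: dict[str, dict] = {"pool": {}, "validation": {}}
    for c_idx, (cohort, latents) in enumerate(
        [("pool", truth.latents["pdc"]), ("validation", truth.latents["validation"])]
    ):
        for drug in drugs:
            rng = _spawn(spec.seed, 10 + 10 * c_idx + DRUGS.index(drug))
            targets = _auc_targets_for(latents, drug, spec, rng)
            truth.auc_targets.setdefault(cohort, {})[drug] = targets
            for model_id in latents.columns:
                panels[cohort][(model_id, drug)] = _panel_from_target(
                    model_id, drug, float(targets[model_id]), spec, rng
                )

    growth: dict[str, dict] = {}
    z_pdx = truth.latents["pdx"]
    for drug in drugs:
        rng = _spawn(spec.seed, 40 + DRUGS.index(drug))
        pdx_ids = list(z_pdx.columns[: spec.n_pdx_response])
        j = DRUGS.index(drug)
        z = z_pdx.loc[:, pdx_ids].iloc[j].to_numpy()
        if drug in null_drugs:
            ratios = np.ones(len(pdx_ids))
        else:
            y = _copula_mix(z, spec.effect_rho, rng)
            ratios = 1.0 - 0.7 * expit(1.2 * y)  # sensitive -> low POR
        truth.por_targets[drug] = pd.Series(ratios, index=pdx_ids)
        growth[drug] = {}
        for pid, r in zip(pdx_ids, ratios):
            growth[drug][pid] = (
                _growth_curves_for(pid, "treated", float(r), spec, rng),
                _growth_curves_for(pid, "control", 1.0, spec, rng),
            )
    return panels, growth


def simulate_clinical_cohort(truth: GroundTruth) -> tuple[ClinicalCohort, ExpressionMatrix]:
    """Two-arm clinical cohort with score-dependent Weibull survival.

    mFFX patients' log-hazard is the sum of the per-count effect from
    ``spec.hazard_beta`` evaluated on the planted sensitive-drug count; GEM
    patients carry no signature effect (arm-exclusive structure). Expression
    is generated from the same loading matrix so derived or planted
    signatures can be projected onto the cohort.
    """
    spec = truth.spec
    rng = _spawn(spec.seed, 60)
    n = spec.n_patients_clinical
    ids = [f"PT{i:03d}" for i in range(n)]
    z = pd.DataFrame(
        rng.laplace(0.0, 1 / np.sqrt(2), size=(spec.n_latent, n)),
        index=truth.loadings.columns, columns=ids,
    )
    expr = _counts_cohort(truth.loadings, truth.baseline, z, spec, _spawn(spec.seed, 61))

    sens = pd.DataFrame(
        {d: z.iloc[j].to_numpy() > 0 for j, d in enumerate(DRUGS)}, index=ids
    )
    count = sens.sum(axis=1).astype(int)
    beta = pd.Series({int(k): float(v) for k, v in spec.hazard_beta.items()})
    lp_all = count.map(beta).astype(float)

    arm = np.where(rng.random(n) < spec.mffx_fraction, "mFFX", "GEM")
    lp = np.where(arm == "mFFX", lp_all.to_numpy(), 0.0)

    shape = spec.weibull_shape

    def weibull_times(median_mffx: float, median_gem: float, r: np.random.Generator):
        scale = np.where(
            arm == "mFFX",
            median_mffx / np.log(2) ** (1 / shape),
            median_gem / np.log(2) ** (1 / shape),
        )
        u = r.random(n)
        return scale * (-np.log(u) / np.exp(lp)) ** (1 / shape)

    r_os = _spawn(spec.seed, 62)
    r_pfs = _spawn(spec.seed, 63)
    t_os = weibull_times(spec.os_median_mffx, spec.os_median_gem, r_os)
    t_pfs = np.minimum(weibull_times(spec.pfs_median_mffx, spec.pfs_median_gem, r_pfs), t_os)
    censor = r_os.uniform(spec.censor_low, spec.censor_high, n)

    os_time = np.minimum(t_os, censor)
    os_event = t_os <= censor
    pfs_time = np.minimum(t_pfs, censor)
    pfs_event = t_pfs <= censor

    # objective response: logit linear in sensitive count (mFFX), flat in GEM
    p_resp = np.where(
        arm == "mFFX",
        expit(spec.orr_intercept + spec.orr_slope * count.to_numpy()),
        spec.gem_orr,
    )
    responded = rng.random(n) < p_resp
    non_resp = rng.choice(["SD", "PD"], size=n)
    response = np.where(responded, "PR", non_resp)

    # subtype label correlated with the oxaliplatin + irinotecan programs
    z_oi = (z.iloc[1].to_numpy() + z.iloc[2].to_numpy()) / np.sqrt(2)
    classical = rng.random(n) < expit(spec.purist_assoc * z_oi)
    purist = np.where(classical, "classical", "basal-like")

    df = pd.DataFrame(
        {
            "id": ids,
            "arm": arm,
            "os_time": np.maximum(os_time, 1e-3),
            "os_event": os_event,
            "pfs_time": np.maximum(pfs_time, 1e-3),
            "pfs_event": pfs_event,
            "response": response,
            "purist": purist,
            "age": np.round(rng.normal(63, 8, n), 1),
            "sex": rng.choice(["F", "M"], size=n),
        }
    )
    truth.sensitive = sens
    truth.hazard_lp = pd.Series(lp, index=ids, name="log_hazard")
    truth.latents["clinical"] = z
    return ClinicalCohort(df), expr


@dataclass
class SimulatedStudy:
    """Everything one seed of the generator produces, with its truth."""

    spec: SimulationSpec
    truth: GroundTruth
    pdc: ExpressionMatrix
    pdx: ExpressionMatrix
    validation: ExpressionMatrix
    panels: dict
    growth: dict
    clinical: ClinicalCohort
    clinical_expr: ExpressionMatrix
    pairing: dict


def simulate_study(
    spec: SimulationSpec | None = None,
    seed: int | None = None,
    drugs=DRUGS,
    with_clinical: bool = True,
) -> SimulatedStudy:
    """Generate a full synthetic study: expression, response and clinic."""
    spec = spec or SimulationSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    pdc, pdx, truth = simulate_paired_expression(spec)
    validation = _counts_cohort(
        truth.loadings, truth.baseline, truth.latents["validation"], spec,
        _spawn(spec.seed, 6),
    )
    panels, growth = simulate_response(truth, drugs=drugs)
    if with_clinical:
        clinical, clinical_expr = simulate_clinical_cohort(truth)
    else:
        clinical, clinical_expr = None, None
    pairing = {
        f"PDC{i:02d}": f"PDX{i:02d}" for i in range(spec.n_discovery_pool)
    }
    return SimulatedStudy(
        spec=spec, truth=truth, pdc=pdc, pdx=pdx, validation=validation,
        panels=panels, growth=growth, clinical=clinical,
        clinical_expr=clinical_expr, pairing=pairing,
    )


def overdispersion(counts: ExpressionMatrix) -> pd.Series:
    """Per-gene variance/mean ratio across samples (sanity diagnostic)."""
    x = counts.values
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > 0, var / mean, np.nan)
    return pd.Series(ratio, index=counts.gene_ids, name="var_over_mean")
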