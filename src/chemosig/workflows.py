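"""End-to-end convenience workflows over simulated or on-disk studies.

These helpers wire the individual stages (normalization, dose-response
fitting, signature derivation, projection, stratification) the way the CLI
and the reproduction script run them, so every consumer executes the
identical pipeline.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .containers import ExpressionMatrix
from .extraction import SignatureModel, SignatureResults
from .normalization import normalize_log2, tmm_factors
from .projection import project_signature
from .response import fit_dose_response, viability_auc
from .simulate import SimulatedStudy

__all__ = ["fitted_aucs", "derive_from_study", "project_on_clinical"]


def fitted_aucs(study: SimulatedStudy, cohort: str, drug: str) -> dict[str, float]:
    """Fit every (model, drug) panel of one cohort and return viability AUCs."""
    out: dict[str, float] = {}
    for (model_id, d), panel in study.panels[cohort].items():
        if d != drug:
            continue
        fit = fit_dose_response(panel)
        out[model_id] = viability_auc(fit, model_id, drug).value
    return out


def derive_from_study(
    study: SimulatedStudy,
    drug: str,
    seed: int,
    pdc_aucs: Mapping[str, float] | None = None,
    validation_aucs: Mapping[str, float] | None = None,
    **model_kwargs,
) -> SignatureResults:
    """Normalize, fit response panels and derive one drug's signature."""
    pdc = normalize_log2(study.pdc, tmm_factors(study.pdc))
    pdx = normalize_log2(study.pdx, tmm_factors(study.pdx))
    val = normalize_log2(study.validation, tmm_factors(study.validation))
    if pdc_aucs is None:
        pdc_aucs = fitted_aucs(study, "pool", drug)
    if validation_aucs is None:
        validation_aucs = fitted_aucs(study, "validation", drug)
    model = SignatureModel(
        pdc_expr=pdc,
        pdx_expr=pdx,
        pdc_aucs=pdc_aucs,
        validation_expr=val,
        validation_aucs=validation_aucs,
        patient_pairing=study.pairing,
        drug=drug,
        **model_kwargs,
    )
    return model.fit(seed=seed)


def project_on_clinical(
    signature, clinical_expr: ExpressionMatrix, min_overlap: float = 0.80
) -> pd.Series:
    """TMM-log2 normalize a clinical count matrix and project a signature."""
    norm = normalize_log2(clinical_expr, tmm_factors(clinical_expr))
    return project_signature(signature, norm, min_overlap=min_overlap).sample_scores
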