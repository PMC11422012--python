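# chemosig

Drug-specific transcriptomic chemosensitivity signatures for the drugs of
the mFOLFIRINOX (mFFX) regimen — 5-fluorouracil, oxaliplatin and
irinotecan — in pancreatic ductal adenocarcinoma (PDAC).

The package is for computational biologists who want to derive a per-drug
expression signature from paired patient-derived model systems (primary
cell cultures, PDC, and xenografts, PDX), score new samples with it, and
test whether the score stratifies patient survival arm-specifically. A
synthetic-study generator with planted, serialized ground truth makes every
stage verifiable by parameter recovery, so the whole pipeline runs and is
tested without any external data.

## The method

**Response quantification.** PDC viability is measured across a log-spaced
dose range (1 nmol/L–1 mmol/L), fitted with a four-parameter logistic in
log10(dose), and summarised as the range-normalized area under the fitted
curve (viability AUC; lower = more sensitive), optionally growth-rate
corrected. PDX response is the POR (percentage of resistance): the ratio of
treated to control tumor-growth AUC over a common day window, from
three-parameter logistic fits of caliper volumes (v = length·width²/2).

**Signature derivation.** Twelve discovery models are selected from the PDC
AUC distribution (percentile bands [P10, P25] and [P75, P90], six each).
Expression of the 12 PDCs and the 12 matched PDXs is each deconvolved by
ICA into gene-contribution (S) and sample-contribution (A) matrices,
X ≈ S·A. Components whose sample contributions correlate across the shared
patients in both model systems are matched one-to-one (homology); among
the homologous components, the one whose PDC contribution correlates
significantly with viability AUC is the drug-response component, oriented
so higher contribution = more sensitive. Its gene weights are thresholded
at multiples of their standard deviation; each candidate gene set is
projected onto an independent validation PDC cohort and the smallest set
within tolerance of the best |Spearman ρ| against validation AUC becomes
the signature. A final gate requires that validation correlation to be
significant — a component that only fit the discovery responses by chance
is rejected.

**Projection scoring.** A sample is scored by the Moore–Penrose
pseudoinverse cross-product of the signature weight vector w with its
(gene-centered) expression: score = wᵀx/‖w‖², the least-squares amount of
the signature program in the sample.

**Clinical validation.** Patients are dichotomized at the score cutpoint
with the lowest log-rank p (subject to a minimum group proportion);
reported alongside the raw p is a selection-adjusted p (permutation of the
maximal statistic). Kaplan–Meier curves, Cox proportional-hazards fits
(Efron ties), IPTW-weighted curves, sensitive-drug-count combination
analysis, exact binomial ORR and chi-square tests complete the clinical
toolbox.

## Worked example

```python
import chemosig as cs
from chemosig.workflows import derive_from_study, project_on_clinical

# a full synthetic study: paired PDC/PDX counts, dose-response panels,
# growth curves, a validation cohort and a 170-patient clinical cohort
study = cs.simulate_study(seed=1)

res = derive_from_study(study, "irinotecan", seed=1)
print(res.summary())
```

```
Drug-signature derivation: irinotecan
==============================================
discovery PDCs (sensitive): PDC07, PDC10, PDC26, PDC27, PDC32, PDC38
discovery PDCs (resistant): PDC01, PDC05, PDC08, PDC16, PDC31, PDC33
ICA components (k):         11  [seed 1]
homologous matches:         8
response component:         PDC IC5 ~ PDX IC5 (homology rho 0.965)
AUC correlation:            rho 0.706, p 0.0102
signature size:             25 genes (|w| > 3.0 SD)
validation |rho|:           0.869 (n=30)
```

The derived 25-gene signature is exactly the planted irinotecan program of
this study (support Jaccard 1.00). Projecting it onto the simulated
clinical cohort and stratifying the mFFX arm:

```python
scores = project_on_clinical(res.signature, study.clinical_expr)
mffx = study.clinical.data[study.clinical.data["arm"] == "mFFX"]
strat = cs.best_cutpoint(scores.loc[mffx["id"]],
                         mffx["os_time"].to_numpy(), mffx["os_event"].to_numpy())
print(strat.summary())
```

```
Optimal-cutpoint stratification
========================================
cutpoint:          -0.07553 (73 candidates scanned)
groups:            66 positive / 24 negative
median OS +/-:     30.3 / 9.49
log-rank:          chi2 36.851, p 1.27e-09 (selection-adjusted p 0.005)
hazard ratio (+):  0.199 (95% CI 0.113-0.352, p 2.81e-08)
```

Signature-positive (predicted sensitive) patients live far longer under
mFFX — median 30.3 vs 9.5 months, hazard ratio 0.20 — and the same
stratification stays non-significant in the gemcitabine arm, where the
generator plants no effect.

A command-line interface chains the same stages
(`chemosig simulate | derive | project | stratify | combine | report`);
every output table carries its config hash and seed.

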