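"""Published clinical-validation cohort composition.

Patient counts of the pooled advanced/metastatic PDAC validation cohorts
(COMPASS plus the two-hospital Angers-Strasbourg series) as reported with
the 5FUCore/OxaCore/IriCore signatures. These are inputs for cohort
arithmetic (arm shares, positivity rates, exclusion rates); no patient-level
data is bundled.
"""

from __future__ import annotations

# pooled OS analysis set
N_COMPASS = 94
N_ANGERS_STRASBOURG_ENROLLED = 87
N_ANGERS_STRASBOURG_EXCLUDED = 14  # poor RNA quality
N_ANGERS_STRASBOURG_ASSESSABLE = N_ANGERS_STRASBOURG_ENROLLED - N_ANGERS_STRASBOURG_EXCLUDED
N_POOLED = N_COMPASS + N_ANGERS_STRASBOURG_ASSESSABLE  # 167

N_MFFX = 94       # mFOLFIRINOX arm of the pooled cohort
N_GEM = N_POOLED - N_MFFX

# signature positivity in the mFFX arm (OS analysis)
N_OXACORE_POS = 43
N_OXACORE_NEG = 51
N_IRICORE_POS = 48
N_IRICORE_NEG = 46

# PFS analysis set
N_PFS_ASSESSABLE = 111
N_PFS_MFFX = 63
N_PFS_GEM = N_PFS_ASSESSABLE - N_PFS_MFFX
N_5FUCORE_POS_PFS = 15


def pct(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage rounded to the reported precision."""
    return round(100.0 * numerator / denominator, digits)


def cohort_arithmetic() -> dict[str, float]:
    """Derived cohort shares, on the percent scale the reports print."""
    return {
        "mffx_arm_pct": pct(N_MFFX, N_POOLED),                      # 56.3
        "gem_arm_pct": pct(N_GEM, N_POOLED),                        # 43.7
        "excluded_pct": pct(N_ANGERS_STRASBOURG_EXCLUDED,
                            N_ANGERS_STRASBOURG_ENROLLED),          # 16.1
        "oxacore_pos_pct": pct(N_OXACORE_POS, N_MFFX),              # 45.7
        "iricore_pos_pct": pct(N_IRICORE_POS, N_MFFX),              # 51.1
        "pfs_mffx_pct": pct(N_PFS_MFFX, N_PFS_ASSESSABLE),          # 56.8
        "fucore_pos_pfs_pct": pct(N_5FUCORE_POS_PFS, N_PFS_MFFX),   # 23.8
        "assessable_angers_strasbourg": float(N_ANGERS_STRASBOURG_ASSESSABLE),  # 73
    }
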