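"""Published summary statistics of the Italian ITQ validation cohort.

These are printed summary tables (counts, percentages, chi-square statistics
and CFA fit triples) from the validation study of the Italian ITQ in ~1,000
late adolescents.  The raw cohort is not deposited, so these summaries serve
two purposes: as *inputs* when rebuilding contingency tables (the percent
columns identify the gender-group denominators) and as external checks that
this package's statistics reproduce the published values from those inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class GenderContrast:
    """One row of the lifetime-exposure/prevalence table: per-gender count
    and percent plus the published uncorrected chi-square."""

    label: str
    male_count: int
    male_percent: float
    female_count: int
    female_percent: float
    published_chi2: float


#: Gender contrasts with published chi-square statistics (count, %, chi2),
#: male column first.  Percentages are as printed; group denominators are
#: reconstructed from each count/percent pair.
GENDER_CONTRASTS = (
    GenderContrast("someone_close_died", 91, 18.20, 154, 30.99, 21.983),
    GenderContrast("assault_nonparent", 84, 16.80, 45, 9.05, 13.274),
    GenderContrast("sexually_harassed", 14, 2.80, 66, 13.25, 36.972),
    GenderContrast("bullied", 60, 12.07, 88, 17.71, 6.224),
    GenderContrast("made_feel_unloved", 162, 32.60, 249, 50.20, 31.720),
    GenderContrast("lifetime_intentional", 269, 53.69, 336, 67.47, 19.847),
    GenderContrast("ptsd", 28, 5.63, 63, 12.96, 15.712),
    GenderContrast("cptsd", 10, 2.01, 30, 6.17, 10.897),
)


#: Published diagnostic prevalence figures.  The abstract-level prevalences
#: (9.11% / 4.06%) and the gender-table totals (9.26% / 4.07%) imply
#: slightly different denominators; each is reproduced under its own.
PREVALENCE_FIGURES = (
    {"label": "ptsd_overall", "count": 91, "percent": 9.11},
    {"label": "ptsd_table", "count": 91, "percent": 9.26},
    {"label": "cptsd_table", "count": 40, "percent": 4.07},
    {"label": "cptsd_overall", "count": 40, "percent": 4.06},
)


#: Published CFA chi-square / df / n triples and fit indices per model.
CFA_PUBLISHED = pd.DataFrame(
    [
        {"model": "M1", "chi2": 1903.43, "df": 54, "n": 992,
         "rmsea": 0.188, "cfi": 0.619, "tli": 0.535, "srmr": 0.109},
        {"model": "M2", "chi2": 175.18, "df": 39, "n": 992,
         "rmsea": 0.06, "cfi": 0.972, "tli": 0.953, "srmr": 0.036},
        {"model": "M3", "chi2": 517.447, "df": 48, "n": 992,
         "rmsea": 0.101, "cfi": 0.903, "tli": 0.867, "srmr": 0.076},
        {"model": "M4", "chi2": 256.186, "df": 47, "n": 992,
         "rmsea": 0.068, "cfi": 0.957, "tli": 0.94, "srmr": 0.055},
    ]
).set_index("model")

#: Published network summary: 46 nonzero edges among the 66 item pairs,
#: printed sparsity 0.31.
NETWORK_NONZERO_EDGES = 46
NETWORK_SPARSITY = 0.31

#: Published subscale reliabilities.
ALPHA_PTSD = 0.88
ALPHA_DSO = 0.88


#: Contrast labels whose 2x2 tables share gender denominators (the two
#: diagnostic-prevalence rows come from the same scored subsample, so the
#: intersection of their feasible denominator sets pins the true one).
SHARED_DENOMINATOR_GROUPS = (("ptsd", "cptsd"),)


def gender_table(contrast: GenderContrast) -> tuple:
    """Rebuild the 2x2 (gender x indicator) table behind one contrast.

    Denominators come from the printed count/percent pairs via
    ``reconstruct_denominator``; for contrasts in a shared-denominator group
    the feasible sets of the group's rows are intersected first, which
    resolves rounding ambiguity (a printed percent only pins the denominator
    to an interval).  Returns ((male_yes, male_no), (female_yes, female_no))
    plus the implied denominators.
    """
    from itqnet.epi import feasible_denominators, reconstruct_denominator

    group = next(
        (g for g in SHARED_DENOMINATOR_GROUPS if contrast.label in g), None
    )
    if group is not None:
        members = [c for c in GENDER_CONTRASTS if c.label in group]
        denoms = []
        for side in ("male", "female"):
            sets = [
                set(feasible_denominators(getattr(c, f"{side}_count"),
                                          getattr(c, f"{side}_percent")))
                for c in members
            ]
            common = sorted(set.intersection(*sets))
            fallback = reconstruct_denominator(
                getattr(contrast, f"{side}_count"), getattr(contrast, f"{side}_percent")
            )[0]
            denoms.append(common[0] if len(common) == 1 else fallback)
        n_m, n_f = denoms
    else:
        n_m, _ = reconstruct_denominator(contrast.male_count, contrast.male_percent)
        n_f, _ = reconstruct_denominator(contrast.female_count, contrast.female_percent)
    table = (
        (contrast.male_count, n_m - contrast.male_count),
        (contrast.female_count, n_f - contrast.female_count),
    )
    return table, (n_m, n_f)
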