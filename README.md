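# itqnet

Analysis toolkit for the **International Trauma Questionnaire (ITQ)**: the
complete statistical pipeline used to validate the Italian ITQ in a
community cohort of late adolescents, re-implemented as a tested,
reusable Python package.

The ITQ is the standard self-report screen for ICD-11 post-traumatic
stress disorder (PTSD) and complex PTSD (cPTSD): 12 symptom items — two
per cluster of re-experiencing (Re), avoidance (Av), sense of current
threat (Th), affective dysregulation (AD), negative self-concept (NSC) and
disturbed relationships (DR) — plus 6 functional-impairment items, all on
a 0–4 Likert scale.  `itqnet` covers, for cohorts assessed with the ITQ
and a 21-event lifetime trauma checklist:

* **Diagnostic scoring** — the ICD-11 screening algorithm (endorsement at
  score ≥ 2; one symptom per cluster plus impairment; cPTSD supersedes
  PTSD), subscale sums, Cronbach's α, and intentional/unintentional
  exposure classification by developmental period.
* **Ordinal factor analysis** — polychoric correlations and thresholds,
  bootstrap WLS weight matrices, and weighted-least-squares confirmatory
  factor analysis of the four standard candidate structures (one-factor;
  correlated six-factor; six factors under one or two second-order
  factors), with RMSEA/CFI/TLI/SRMR/CD/BIC and ΔBIC > 10 model selection.
* **Symptom networks** — EBIC-selected graphical lasso (γ = 0.5) over the
  12 symptom items: partial-correlation edge weights, sparsity, and raw +
  z-standardized centrality (strength, closeness, betweenness, expected
  influence).
* **Epidemiology** — prevalence with Wilson intervals, uncorrected Pearson
  χ² gender contrasts (including rebuilding 2×2 tables from published
  count/percent pairs), and multinomial logistic regression of diagnosis
  on intentional/unintentional exposure per period, unadjusted and
  adjusted.
* **Synthetic cohorts** — a calibrated graded-response generator
  (correlated six-factor latent structure, gender-differential exposure,
  exposure-dependent symptom elevation) so every stage is testable without
  the original cohort.

The core estimators follow scikit-learn conventions (`fit`, trailing-
underscore attributes, `get_params`) and compose with sklearn tooling:
`PolychoricCorrelation`, `WlsCfa`, `EbicGlassoNetwork`, `ItqScorer`,
`MultinomialDiagnosisRegression`.

## Worked example

```python
from itqnet import (
    ItqScorer, WlsCfa, EbicGlassoNetwork,
    default_config, generate_cohort, cronbach_alpha, PTSD_ITEMS,
)
from itqnet.cfa import (build_standard_models, fit_wls, fit_independence,
                        fit_indices, compare_models)
from itqnet.polychoric import polychoric_matrix
from itqnet.constants import SYMPTOM_ITEMS

cohort = generate_cohort(default_config(n_subjects=2000, seed=5))
scored = ItqScorer().fit(cohort).transform(cohort)
print(scored["diagnosis"].value_counts())
#   none     1730
#   PTSD      194
#   cPTSD      76

print(round(cronbach_alpha(cohort[list(PTSD_ITEMS)].to_numpy()).alpha, 3))
#   0.884

est = polychoric_matrix(cohort[list(SYMPTOM_ITEMS)].to_numpy(),
                        item_labels=list(SYMPTOM_ITEMS))
baseline = fit_independence(est, weight="identity")
indexed = {mid: fit_indices(fit_wls(est, spec, weight="identity"), baseline, est)
           for mid, spec in build_standard_models().items()}
cmp = compare_models(indexed)
print(cmp.table[["model", "chi2", "df", "RMSEA", "CFI", "BIC"]].round(3))
#     model      chi2  df  RMSEA    CFI        BIC
#   0    M2    12.815  39  0.000  1.000   7713.190
#   1    M4    75.156  47  0.017  0.999   7798.635
#   2    M3  1147.167  48  0.107  0.966   8843.163
#   3    M1  2250.214  54  0.143  0.933  13163.657
print(cmp.selected, round(cmp.delta_bic, 1), cmp.decisive)
#   M2 85.4 True

net = EbicGlassoNetwork().fit(cohort[list(SYMPTOM_ITEMS)])
print(round(net.sparsity_, 3), round(net.lambda_, 4))
#   0.212 0.0094
```

Reading the output: ~9.7 % of the synthetic cohort screens positive for
PTSD and ~3.8 % for cPTSD (calibration targets ≈9 %/4 %); the
PTSD-subscale α of 0.884 matches the published 0.88; the correlated
six-factor model (M2) decisively wins the BIC comparison (ΔBIC 85 > 10)
over the hierarchical two-factor model (M4), replicating the published
ordering; and the EBIC-selected symptom network retains 52 of 66 possible
edges (sparsity 0.21 at n = 2,000; at the study's n ≈ 1,000 the same
pipeline typically selects sparser networks, around the published 0.31).

A command-line interface wraps the same pipeline:

```bash
itqnet simulate --n 1000 --seed 5 --out cohort.csv
itqnet run-all --input cohort.csv --out results/ --seed 5
itqnet network --input cohort.csv --out results/ --gamma 0.5
```

Each run writes CSV tables (diagnoses, prevalence, fit indices, edge
lists, centrality, odds ratios) plus a `manifest.json` recording seed,
options and stage status; identical config + seed reproduces every output
byte-for-byte.

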