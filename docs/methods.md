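# Methods

`itqnet` re-implements, as a reusable and tested pipeline, the complete
statistical analysis used to validate the Italian International Trauma
Questionnaire (ITQ) in a community cohort of late adolescents: ICD-11
PTSD/complex-PTSD screening, ordinal confirmatory factor analysis of four
competing measurement models, EBIC-regularized partial-correlation symptom
networks, and trauma-exposure epidemiology.  Because the original cohort is
not publicly deposited, the package ships a synthetic cohort generator that
emulates the cohort's data structure; all simulation-based validation runs
against that generator or against published summary tables.

## Diagnostic algorithm

The ITQ scores 12 symptom items (two per cluster: re-experiencing,
avoidance, sense of current threat; affective dysregulation, negative
self-concept, disturbed relationships) and 6 functional-impairment items on
a 0–4 Likert scale.  An item is *endorsed* at a score ≥ 2 ("Moderately").
PTSD screening requires trauma exposure, one endorsed symptom in each of
the three core clusters, and one endorsed PTSD-impairment item; cPTSD
additionally requires one endorsed symptom per DSO cluster and one endorsed
DSO-impairment item.  The categories are mutually exclusive (cPTSD
supersedes PTSD).  Records with any missing diagnostic item receive a
missing diagnosis and drop out of prevalence denominators — mirroring the
original cohort handling, where fully missing ITQ protocols were excluded.

The trauma-exposure gate defaults to "any endorsement of a non-excluded
checklist event" since the data record only the 21-item checklist, not the
index event; `require_exposure=False` disables the gate.  The checklist's
intentional/unintentional classification follows the itemized adjudicated
map (events 1, 2, 3, 14, 15, 16 unintentional; 12 and 13 excluded; the rest
intentional).  The prose of the source materials mentions *three* excluded
events while the itemized table marks two; the itemized table is taken as
authoritative.

## Synthetic cohort generator

Per subject the generator draws, in order: gender and covariates; checklist
exposure flags (independent Bernoulli per item × period, gender- and
class-specific probabilities back-solved from the published any-lifetime
exposure rates, 67.5 % female / 53.7 % male intentional, 84.5 % / 80.6 %
unintentional); latent factor scores from N(shift, Φ) where the mean shift
adds the configured effect of any lifetime intentional (+0.45 SD on all six
factors) and unintentional (+0.2 SD core, +0.1 SD DSO) exposure; two
impairment composites built from the standardized block means of the
(shifted) factors (composite loading 0.8); and finally ordinal items via a
cumulative-probit (graded-response) measurement model,
`y*_j = λ_j η + √(1−λ_j²) ε`, scored as the number of thresholds below
`y*_j`.  This measurement model matches the polychoric/WLS assumptions of
the analysis stage exactly, which is what makes the generator a usable
truth source for parameter-recovery studies.

Key default parameters:

| parameter | default | rationale |
|---|---|---|
| `n_subjects` | 1,000 | cohort size of the validation study (992 scored) |
| `loadings` | 0.87 (all 12 items) | reproduces subscale α ≈ 0.88 |
| `factor_corr` | ≈0.80 within core-PTSD, ≈0.65 within DSO, ≈0.45 cross, heterogeneous | a generic correlated six-factor truth; an exactly block-uniform matrix is second-order-representable and would make the six-factor and hierarchical models empirically indistinguishable |
| symptom thresholds | normal quantiles of the published item category distributions + block offsets (+0.60 core, +0.10 DSO) | anchors marginals to the published item table while calibrating prevalence |
| impairment thresholds | (0.4, 1.0, 1.6, 2.2) | not published; moderately skewed |
| `female_share` | 0.5 | cohort composition |

The block offsets were calibrated once, by simulation over a grid, so the
default cohort reproduces the published screening prevalences (≈9 % PTSD,
≈4 % cPTSD at large n) and PTSD-subscale α ≈ 0.88; they were then frozen.
The generator does **not** emulate: clustered school/geography sampling,
event-specific exposure profiles (all items of a class share one
probability), differential item functioning by gender (gender affects items
only through exposure), or structured missingness (missingness is uniform
at a configurable rate).  Passing tests therefore validate the estimators
under a clean graded-response world, not robustness to those real-data
features.

## Polychoric correlations and the WLS weight

Two-step estimation: thresholds are normal quantiles of the observed
margins (so thresholds pushed back through the normal CDF reproduce the
margins exactly), then the latent correlation maximizes the
bivariate-normal orthant likelihood of the cross-table.  Cell probabilities
are evaluated by 24-point Gauss–Legendre quadrature of
φ(x)·[Φ((b₂−ρx)/s) − Φ((b₁−ρx)/s)] per row interval (accurate to ~1e−10,
fully vectorized), and the scalar likelihood is maximized by bounded Brent
search on ρ ∈ (−0.999, 0.999).  Boundary cumulative proportions map to a
finite sentinel (±8).  The pairwise matrix gets an eigenvalue-clipping PSD
repair (flagged) when sampling noise pushes it indefinite.

The weight matrix W for WLS factor analysis is the covariance of the
q = 66 unique correlations, estimated by a nonparametric bootstrap over
subjects (default B = 200, seeded, ridge-stabilized with 1e−3 relative
diagonal inflation; B < 50 is refused).  Bootstrapping was chosen over
analytic fourth-moment formulas as simpler to verify and asymptotically
equivalent.  Because the full 66×66 W is near-singular below roughly
n = 500·B-dependent thresholds, the fitting layer offers `weight="diag"`
(default for data analysis) and `weight="identity"` (unweighted least
squares, used in the simulation studies where the chi-square calibration is
irrelevant and BIC — which does not involve W — drives model selection).

## WLS confirmatory factor analysis

Four candidate structures over the 12 symptom items: one factor (df 54);
six correlated factors, two items each (df 39); six factors under a single
second-order factor (df 48); six factors under correlated second-order
PTSD and DSO factors (df 47).  Identification fixes factor variances to 1;
the implied matrix is Σ(θ) = ΛΦΛᵀ with a unit diagonal enforced through
unique variances.  The discrepancy F(θ) = (s − σ(θ))ᵀ Γ⁻¹ (s − σ(θ)) is
minimized by bounded L-BFGS-B with multi-start (one structured start plus
seeded perturbations; ties broken by lowest F then fewest parameters),
where Γ = n·W is the n-stable metric (so W itself shrinks as 1/n while
chi² = (n−1)·F_min is calibrated).  Correlation parameters are kept in
(−0.999, 0.999) by box bounds; the quadratic discrepancy needs no
positive-definiteness during search.

Fit indices use the standard normal-theory formulas — RMSEA =
√(max(χ²−df,0)/(df(n−1))), CFI and TLI against the zero-correlation
independence baseline fitted under the same metric, SRMR as the RMS of the
66 residual correlations, CD = 1 − det(Θ̂)/det(Σ̂), and BIC = −2ℓ_G +
q·ln n with ℓ_G the Gaussian pseudo-log-likelihood of the sample
correlation matrix under Σ̂ (additive constants dropped; only BIC
*differences* are meaningful, and absolute BIC values are software-specific
and not comparable across implementations).  The (n−1) chi-square
convention is the one under which the published six-factor RMSEA
reconstructs (χ²=175.18, df=39, n=992 → 0.0594, printed 0.06); the printed
one-factor RMSEA (0.188) differs from the reconstruction (0.186) by more
than rounding, an unexplained convention difference of the original
software, covered by a documented 0.003 tolerance.  A BIC gap above 10 is
reported as decisive, matching the selection rule of the study.

## Symptom network

The 12-node Gaussian graphical model is estimated by graphical lasso along
a log-spaced path of 100 penalties from λ_max (largest absolute
off-diagonal correlation) down to 0.01·λ_max, with the Extended BIC
(γ = 0.5) selecting the penalty: EBIC = −n(log det K − tr(SK)) + E ln n +
4γE ln p.  The input correlation defaults to polychoric (items are
five-category ordinal); Pearson is available.  Edge weights are partial
correlations −K_ij/√(K_ii K_jj).  Sparsity is the share of absent edges
among the 66 pairs.

Centrality follows psychometric-network conventions: distance = 1/|weight|;
betweenness by Brandes' algorithm with fractional counting over tied
shortest paths; closeness as the reciprocal of summed distances, restricted
to reachable nodes with a disconnection flag (the verbal definition does
not cover disconnected graphs); strength = Σ|w|; expected influence = Σw.
Values are reported raw and z-standardized across the 12 nodes (the
published centrality values are z-scores).

**Known limitation** (documented operating characteristic, visible in the
edge-recovery study): when true partial correlations are strong, the
EBIC-selected penalty slides toward the bottom of the path — the likelihood
gain from debiasing strong edges dominates the per-edge penalty — and weak
spurious edges enter the selected network.  The edge-recovery study
therefore generates truth with partials of ±0.1, where the selected
penalty separates signal from noise; with ±0.3 truths the same estimator
keeps perfect sensitivity but admits 30–45 % spurious (weak) edges.
Substantive conclusions should rest on edge weights, not on bare
presence/absence of weak edges.

## Epidemiology

Gender contrasts use the uncorrected Pearson chi-square — the convention
under which the eight published statistics reproduce to three decimals from
the printed counts; with continuity correction none of them do.  Group
denominators are rebuilt from printed count/percent pairs as
round(100·k/%); since a printed percentage only pins the denominator to an
interval, rows known to share a denominator (the PTSD and cPTSD prevalence
rows) intersect their feasible sets, which resolves the one ambiguous case.
Prevalence intervals use the Wilson score method; the published interval
bounds match no standard method we tested (Wilson, Wald, exact) and are
deliberately not used as checks, while the published *point* estimates
reproduce exactly under their own implied denominators (which are
internally inconsistent in the source: 9.11 % ⇒ n = 999, 9.26 % ⇒ n = 983 —
each figure is reproduced under its own denominator, never averaged).

The exposure regression is a maximum-likelihood multinomial logit
(diagnosis none/PTSD/cPTSD, reference none) on the six class × period
indicators, optionally adjusted for gender, non-Italian nationality and
parental education (a single ordinal covariate; the original coding is
unpublished).  Odds ratios and 95 % CIs are Wald-based; coefficients above
|15| raise a separation flag.

## Validation studies and problem sizes

`itqnet.studies` packages the simulation studies used for acceptance:

* **Model recovery** — 100 replicates, n = 2,000, truth = generic correlated
  six-factor structures (loadings U(0.7, 0.85), factor correlations in
  (0.3, 0.8)); the six-factor model should win BIC in ≥ 90 replicates with
  loadings recovered within 0.07.
* **Edge recovery** — 20 seeds, p = 12, 20 true edges of ±0.1, n = 5,000;
  plus a two-block contrast (12 items on two factors correlated 0.4)
  checking that within-block edges outweigh between-block edges, the
  structural analogue of the separation between core-PTSD and DSO symptom
  clusters.
* **OR coverage** — 100 replicates, n = 2,000, generating effects anchored
  at the published unadjusted odds ratios; the Wald CI for the strongest
  intentional-exposure effect on cPTSD (OR 3.53) should cover truth in
  ≥ 90 replicates.

These sizes are the package's chosen operating points for routine
verification; all are re-run end-to-end by `scripts/acceptance.py`.

## Numerical choices

Polychoric Brent tolerance 1e−7 on ρ; quadrature sentinel ±8; glasso path
solved coarsely (tol 1e−5) for EBIC ranking with a tight re-solve (1e−7) at
the selected penalty; CFA optimizer ftol 1e−12 with 5 default restarts (2
in bulk simulations); partial-correlation entries below 1e−10 treated as
absent edges; z-standardization uses the ddof = 1 standard deviation across
nodes.  All randomness flows through explicit integer seeds; identical
config + seed reproduces outputs byte-for-byte.
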