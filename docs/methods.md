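# Methods

## Data model

One row per twin pair: zygosity (MZ, DZss, DZos), per-twin affection,
per-twin proband flag (independently ascertained, e.g. survey self-report),
per-twin sex, optional per-affected-twin ACPA status, optional discordance
time. Within-pair order is meaningless and every operation symmetrizes over
it. A proband must be affected; ACPA status is defined only for affected
twins; same-sexed zygosity groups must have equal sexes.

Pairs are classified as C2 (concordant, two probands), C1 (concordant, one
proband), D1 (discordant, affected twin a proband), U (unaffected pair) or
*remainder* — affected pairs without the proband configuration the
concordance estimators require (a concordant pair with no proband, or a
discordant pair whose case never self-reported). Remainder pairs are
counted and reported, never silently dropped, and the five classes
partition the cohort exactly.

The ACPA-positive stratum admits a pair when *every affected member* is
ACPA-positive (an affected member with unknown status excludes the pair).
Requiring only the proband to be positive is equally defensible on the
published wording; the all-affected rule was chosen because it makes the
stratum an analysis of purely seropositive disease, and it is a one-line
predicate a user can replace.

## Concordance estimators

Casewise (2C1+2C2)/(2C1+2C2+D1), probandwise (C1+2C2)/(C1+2C2+D1),
pairwise (C1+C2)/(C1+C2+D1). Confidence intervals are Clopper–Pearson on
the estimator's integer numerator and denominator: this choice reproduces,
to one decimal in percent, the published 95% intervals of a nationwide RA
twin table (e.g. 3/33 → 1.9–24.3), which is how the otherwise-unstated CI
method was pinned down. The casewise interval treats the 2(C1+C2) affected
individuals in concordant pairs as independent trials; within a pair they
are not, so that interval is mildly anti-conservative — a known
approximation implied by the estimator's printed denominators.

Sex adjustment is direct standardization: the weighted mean of
stratum-specific rates, weights defaulting to each stratum's share of
probands, with a seeded stratified bootstrap (multinomial resampling of
each stratum's (C1, C2, D1), 2000 replicates by default) for the interval.
Published sex-adjusted values cannot be reproduced exactly because the
published adjustment procedure and stratum counts are unavailable; the
operation is validated by arithmetic identities instead (equal stratum
rates leave the rate unchanged; degenerate weights select a stratum).

Report rendering rounds percentages half-up to one decimal; raw
proportions are always retained in the JSON.

## Liability-threshold model

Liability is standard normal per individual; disease occurs above
t = Φ⁻¹(1−K). The bivariate normal CDF is evaluated through Owen's T
function (vectorized, validated against scipy's multivariate normal CDF to
1e-10 and against direct 2-D quadrature to 1e-8); exact zero thresholds
are nudged by 1e-13, far below the evaluation's own accuracy.

The tetrachoric correlation is estimated from the symmetric three-cell
table (both / exactly one / neither affected) — cotwin order carries no
information, so nothing is lost relative to the ordered 2×2 table — by
maximizing the multinomial likelihood over (ρ, t) with Nelder–Mead from
four deterministic starts, ρ mapped through tanh to stay in (−1, 1).
Confidence intervals are profile likelihood at the χ²(1) cutoff. When no
unaffected pairs are available the threshold is unidentified and must be
supplied via an external prevalence. An independent iteratively-refined
grid search over (ρ, t) serves as an oracle in the tests; the two agree to
1e-4 in ρ on random tables.

ACE-family fits maximize the joint multinomial likelihood over all
zygosity-group tables under ρ_MZ = a²+c²+d², ρ_DZ = ½a²+c²+¼d², with DZss
and DZos sharing ρ_DZ (no sex-limitation structure; sex enters only
through thresholds). C and D are never simultaneously free: MZ/DZ data
identify only two correlation contrasts. Free components are parameterized
as squared path weights normalized onto the unit simplex with E as the
residual weight, so e² > 0 always and boundary optima (a² = 0, expected in
weakly informative data) are reachable. The optimizer is Nelder–Mead from
five deterministic starts; convergence tolerance 1e-9 on the
log-likelihood. AIC = −2 lnL + 2k with k counting free components plus
thresholds (one common, or one per sex with `sex_layout="per-sex"`).
Published Mx-convention AIC values differ by a data-dependent offset and
are not comparable in absolute value; only AIC *differences* are
meaningful here, and those are what the comparison reports.

Component confidence intervals are profile likelihood on the component
scale (root-finding tolerance 1e-6), truncated to [0, 1]; at realistic
cohort sizes the a² interval reaches 0, matching the wide published
intervals for this design. Likelihood-ratio tests for nested pairs report
both the naive χ²(df) p-value and the boundary-corrected mixture p-value
(½χ²(df) + ½χ²(df−1), with the df = 1 case a 50:50 mixture with a point
mass at zero), since a dropped variance component lies on the boundary of
its space.

## Capture–recapture and registry confirmation

Two-source ascertainment: p(source A) = overlap / n_B and symmetrically,
matching the arithmetic used in registry validation studies (69 of 86
registry cases found by a survey → 80.2%). The total-case estimate is
Chapman's bias-corrected (n_A+1)(n_B+1)/(m+1) − 1, preferred over
Lincoln–Petersen for counts near 100 (both are reported); its CI is the
standard log-normal interval on the unseen-case count, degenerating to a
point when the overlap is complete. Registry strata with partial diagnostic
validity contribute n_registered × confirmation_rate to the expected true
case count.

## Prevalence and recurrence risk

Crude prevalence is cases over responders with a Clopper–Pearson interval.
Direct standardization takes user-supplied reference weights — no national
age–sex table is bundled, so nationally adjusted published figures are
approximated, not reproduced. Recurrence-risk ratios divide a concordance
rate by prevalence, with CI endpoints scaled by the same constant (the
prevalence, estimated on ~45,000 individuals, is treated as fixed relative
to a rate estimated on tens of pairs). When reproducing published ratios
the inputs are the published one-decimal rates, because those ratios were
themselves computed from printed precision (9.1/0.37 = 24.6); full-precision
ratios are reported alongside.

## Synthetic cohorts

Each twin's liability is a weighted sum of independent standard normal
components — additive genetic (cross-twin correlation 1 MZ / ½ DZ),
dominance (1 / ¼), shared environment (1), unique environment (0) — with
weights √a², √d², √c², √e²: exactly the construction the ACE algebra
assumes, so generated cohorts have the model's correlation structure by
construction rather than approximately. Affection is liability > t(K);
each affected twin is independently a proband with probability π; ACPA is
an independent Bernoulli per affected twin. All draws come from one
`numpy.random.Generator`, so a seed fixes the cohort byte-for-byte.

Defaults are the study conditions of the motivating RA survey: a² = 0.12,
c² = 0.50, e² = 0.38, K = 0.37%, π = 0.80, ACPA probability 0.78 (the
observed seropositive fraction among confirmed cases), ~16,800 intact
pairs split 1:1.5:1.5 across MZ:DZss:DZos. Parameter-recovery tests run at
K = 0.05 instead of 0.37%: at the true prevalence a desk-scale cohort
contains a handful of affected pairs and no estimator is informative; the
rare-prevalence regime is exercised where it matters, in the
orthant-probability and forward-model (expected-count) checks. Recovery
problem sizes: 10⁶ expected-count pairs per group for the forward-model
check (±0.02 per component), 500,000 simulated pairs for the end-to-end
check (±0.05).

The generator does not model questionnaire non-response, mortality
attrition, zygosity misclassification or age structure. Passing recovery
tests therefore show that the estimators invert the generating model
correctly — not that real registry data are free of those biases.

## Known limitations

- Tetrachoric and component estimates from rare-trait tables are highly
  imprecise; profile intervals routinely touch the boundary. This mirrors
  the design's intrinsic power, not a numerical defect.
- The casewise CI's independence approximation (above).
- No sex-limitation models (qualitative or quantitative), no GxE, no
  multivariate extensions; DZos informs ρ_DZ only.
- Discordance time is carried through ingest but no time-to-event model is
  fitted.
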