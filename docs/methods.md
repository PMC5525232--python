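# Methods

`equiuse` implements a multi-stage analysis of income-related inequality in
the use of public health services across two cross-sectional survey waves
(a pre-crisis wave labelled 2006 and a crisis wave labelled 2011). This note
documents the statistical model at each stage, the numerical choices, what
the synthetic generator does and does not emulate, and the known
limitations.

## 1. The two-part hurdle model

Utilization of each service (primary care, specialist care, emergencies,
hospitalizations; plus the medicine count) is a non-negative integer with
many zeros. The model separates the two decisions involved:

**Part 1 — any use.** A logistic regression for the probability of at least
one annual contact,

    mu1_i = P(y_i > 0 | X1_i) ,   logit(mu1_i) = X1_i' b1 ,

with the Bernoulli variance mu1(1 - mu1) taken as exact: a binary response
identifies only its mean, so no part-1 dispersion parameter exists and the
code never estimates one.

**Part 2 — frequency among users.** A zero-truncated negative binomial with
NB1-style dispersion,

    f2(y | y > 0) = [ G(y+psi) / (G(psi) G(y+1)) * (mu2/(mu2+psi))^y ]
                    / ( ((mu2+psi)/psi)^psi - 1 ),
    mu2_i = exp(X2_i' b2),   psi_i = mu2_i / phi ,

so the untruncated variance is mu2 (1 + phi). Note this is the NB1
convention (psi proportional to mu), not the more common NB2; the limit
phi -> 0 recovers the zero-truncated Poisson.

The two parts enter the likelihood multiplicatively and are estimated
**jointly** (one optimization over b1, b2, log phi). With no shared
parameters and no random effects the likelihood separates, and the joint
maximum provably equals the two independent part maxima — this is asserted
numerically in the tests rather than assumed.

**Random effects.** Unobserved heterogeneity is a Gaussian random intercept
u_j ~ N(0, sigma_u^2) shared by both linear predictors within a grouping
declared at fit time. An individual-level effect is unidentified with one
observation per respondent per part, so the grouping is a column (households
in the synthetic data, mean size 2.5). Group contributions are integrated
out with Gauss–Hermite quadrature (default 25 nodes, non-adaptive). For
household-sized groups and sigma_u up to about 1 the non-adaptive rule is
accurate far below estimation error, and it avoids a per-group mode search
inside every objective evaluation; this is a deliberate trade of formal
adaptivity for speed and simplicity.

**Shrinkage on sigma_u.** In random-effects mode the fit is penalized
maximum likelihood with an exponential-tail penalty lambda * sigma_u,
lambda = -log(alpha)/u, calibrated through P(sigma_u > u) = alpha (defaults
u = 1, alpha = 0.01, hence lambda ≈ 4.6). This emulates a
penalised-complexity prior: zero flexibility (sigma_u = 0) is the base
model and deviations pay an exponential price.

**Numerics.** The ZTNB log-pmf is computed on the log scale; the truncation
denominator uses a stable log(expm1(a)) with a = psi * log1p(phi), switching
to a + log1p(-exp(-a)) for large a. For psi > 1e6 (the Poisson-limit
regime) the difference of two log-gamma calls loses all precision and the
product form sum_{j<y} log(psi + j) is used instead. Optimization is
L-BFGS-B with analytic gradients in the fixed-effects case (finite
differences under quadrature), gradient tolerance 1e-6, step tolerance
1e-8, at most 500 iterations. Starting values: part 1 from a plain logistic
fit, part 2 from a Poisson fit on users, phi from the method-of-moments
excess variance floored at 1e-3. Standard errors come from the inverse
observed information (numerical Hessian at the optimum); phi and sigma_u
are estimated on the log scale. Non-convergence is flagged on the fit
object, never silent.

Quartile effects are reported as exp(contrast) with delta-method intervals:
odds ratios for part 1, rate ratios for part 2, always against quartile 1
(the poorest).

## 2. Income harmonization

The two waves report net family income in incompatible interval schemes:
8 annual bands (2006) versus 10 monthly bands (2011), with different ranges.
A per-wave ordered probit with covariates sex, age band, occupation,
education and household size places both dialects on one latent scale:

    y*_i = X_i' gamma + eps_i,  eps ~ N(0,1),
    band k observed  iff  c_{k-1} < y*_i <= c_k ,

with strictly increasing thresholds enforced by reparameterization
(statsmodels' ordered model does the estimation; this package adds band
validation and scoring).

**The score.** The standardized income of respondent i is by default the
interval-censored conditional mean

    E[y* | X_i, band k] = eta_i + (phi(a) - phi(b)) / (Phi(b) - Phi(a)),
    a = c_{k-1} - eta_i,  b = c_k - eta_i ,

the truncated-normal mean of the latent index inside the observed band's
interval. This uses both the demographics and the reported band, and is
strictly increasing in each at the other fixed. A covariate-only
alternative — the bare index X'gamma-hat — is available
(`score_method="index"`), but it makes "income" a demographic composite:
respondents reporting the lowest and highest bands get the same score if
their covariates match, and any covariate correlated with actual income
(private insurance above all) then absorbs the income-quartile effect in the
adjusted models. The conditional-mean default was adopted after exactly this
failure mode appeared in end-to-end recovery experiments.

**Quartiles.** Within each wave, scores are cut at the left-continuous
(inverted-CDF) empirical quartiles; a score tied with a cut point goes to
the lower quartile. Quartile labels are invariant to any strictly monotone
transform of the score — the only downstream use — which is asserted as a
property test (restricted to score ranges where the transforms remain
injective in float arithmetic).

## 3. Ownership split and annualization

**Public vs private.** The surveys record only the ownership of the last
contact. Respondents with exactly one contact reveal that contact's
ownership; a logistic regression on that single-visit subsample (sex, age
band, self-perceived health with 'very good' as reference,
chronic-condition count; one fit per service per wave) predicts the
probability p-hat that a contact was private. Multi-visit totals are split
as private = round(total * p-hat) with round-half-to-even, public the
remainder, so public + private = total exactly, for every respondent.

The deterministic rounding keeps counts integral and is reproducible, but
it is only unbiased in aggregate when total * p-hat varies over more than
one integer (covariate heterogeneity in p-hat, or larger totals). With
near-homogeneous p-hat around 0.1 and window totals of 1–3, round(total *
p-hat) is 0 almost surely and the aggregate private share is biased low.
This is a property of the discretization, accepted deliberately; the
recovery test quantifies the regime where the rule is unbiased and the bias
outside it is stated here rather than hidden.

Quasi-separation deserves a note: single-visit subsamples can contain a
covariate cell with no private contact at all, driving that one dummy
coefficient to the boundary. The fit tolerates this (the implied p-hat of
~0 in that cell is the cell's empirical rate, exactly what imputation
needs); a single-class response, non-convergence or runaway coefficients
still raise a fit error.

**Annualization.** Hospitalizations and emergencies are asked per 12
months and pass through. Primary/specialist counts are asked per 4 weeks
and are multiplied by 12 — but only for respondents reporting at least one
contact. For zero reporters, a delay model (same covariates, fitted on
users only) predicts the probability that care was sought more than 4 weeks
after a problem was perceived; a **single** annual contact is imputed when
that probability strictly exceeds 0.5 (p = 0.5 exactly imputes nothing).
The imputed contact is recorded as 1, not 12: the model assumes one delayed
contact and multiplying it would fabricate frequency. Its ownership is
assigned by the same rounding rule from the ownership model's p-hat.
Consequently annualized 4-week counts are multiples of 12 except the
imputed singletons — asserted exactly.

**Medicines.** The count of distinct medicines is the sum of positive
responses over the 22 listed items excluding contraceptives: range 0–21,
total utilization only (no public/private split).

## 4. The model sequence and descriptive tables

For each service, ownership (total/public/private; medicines total only)
and wave, three nested hurdle models are fitted: Model 1 income quartiles
only; Model 2 adds gender and age band; Model 3 adds private insurance and
GHQ-12 (0–12 mental-health score). Reading the quartile effects across the
sequence separates the raw association from what survives adjustment for
need and double cover. Per-model failures on degenerate cells (e.g. no
private hospitalizations in a wave) are reported as structured errors and
leave the remaining cells intact.

Descriptive tables summarize each utilization variable by wave within
income quartile (and overall): n, mean, SD, percent change of the mean
((post - pre)/pre * 100; -100% when use vanishes; undefined when the
baseline is 0), and a wave-comparison p-value — Wilcoxon rank-sum for
counts, Fisher exact for binary variables. No multiple-testing correction
is applied; raw p-values are printed (3 decimals; means/SDs 3, percent
changes 1). Cells are pure functions of the input records.

## 5. The synthetic generator

The generator inverts the analysis model, so every stage is testable
without restricted microdata. Per wave it draws household groups (size 1 +
Poisson(1.5), mean 2.5), demographics (wave-specific sex/age/occupation
mixes; the crisis wave has more long-term unemployment), latent annual log
income (log-normal around e^9.6 ≈ €15k with education/occupation/age
effects, SD 0.7 total), discretized through the wave's dialect — annual
cut points for 2006, monthly cut points x 12 for 2011, half-open so a
value at a cut point goes to the upper band. Need proxies (self-perceived
health, chronic conditions, GHQ-12) depend on age and each other;
insurance is driven by latent income.

Utilization then follows the hurdle process exactly: Bernoulli use with the
household effect in the predictor, ZTNB1 annual frequency, per-contact
ownership i.i.d. from the ownership model (the last contact's draw is what
the survey records), a delay indicator for users. Annual counts of
4-week-recall services are thinned contact-by-contact into the window with
probability 4/52, making the x12 rule an approximate inverse of the recall
truncation (the annualized mean tracks the generated annual mean within
10% at 20,000 respondents; the residual gap is the recall-thinning
variance plus the zero-reporter imputation, not a bug). Default
income-quartile effects mirror the qualitative pattern the analysis
targets — pro-poor emergencies and hospitalizations, pro-rich specialist
care — with part-1 log-odds taken from the reported relative probabilities
(e.g. emergencies Q2..Q4 at -0.40, -0.69, -0.76).

Default sample sizes are the surveyed populations (29,712 and 19,935).
Tests and the acceptance script run the same process at the sizes their
properties state (1,500–10,000 per wave; 400 groups of 10 for
random-effect recovery; 200 replicates for coverage, 100 for sign
recovery) — chosen as the scales at which the Monte-Carlo bounds are
already sharp.

What the generator does **not** emulate: questionnaire wording and the
indirect emergency questions; survey design weights and nonresponse;
panel structure (none exists; the surveys are cross-sections);
within-household covariate correlation (members share only the random
effect); wave-specific changes in the utilization coefficients. Passing
tests therefore certify the estimators and the pipeline's accounting, not
the substantive findings on the real surveys.

## 6. Calibration caveats and limitations

- **Clustered rank tests.** With the household effect active
  (sigma_u = 0.5), observations within a descriptive cell are correlated
  and the rank-sum test is mildly anti-conservative (empirical level
  ~0.057 at nominal 0.05). The null-calibration test therefore switches
  clustering off, matching the test's independence assumption; on real
  clustered data the descriptive p-values inherit this caveat.
- **Rounding bias** in the ownership split at small totals (see §3).
- **Inference engine.** The estimators are penalized maximum likelihood
  with quadrature, not a full Bayesian treatment: intervals are
  delta-method Wald intervals, not posterior credible intervals, and the
  PC-style penalty enters as a mode-shrinking term rather than a prior to
  be integrated.
- The income ordered probit is unpenalized and per-wave; a group-level
  random intercept for it is not implemented (one income response per
  household member makes it weakly identified at best).
- Emergency counts derived indirectly from hospitalization questions are
  out of scope; the schema carries one direct emergency count.
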