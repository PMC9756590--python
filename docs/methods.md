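# Methods

`trialpref` simulates and analyses an adaptive stated-preference survey on
willingness to participate in clinical trials. This note documents the
models, the synthetic-data generator, the numerical choices, and the known
limitations.

## The elicitation design

A hypothetical clinical study is described by 17 attributes in five
categories (payment/support, administration/procedures, treatment-related,
location/time commitment, data collection/feedback). Each attribute has two
or three levels stored worst-to-best; the last level is the designated
"best" level. Payment levels are localised per country at a constant
fraction of average salary ($0/$500/$2,000; 0/450/1,800 zł; ¥0/500/2,000).

The survey is single-profile and adaptive. The initial task fixes every
three-level attribute at its middle level and randomises two-level
attributes uniformly between participants (the recorded arm of the first
two-level attribute, study hours, is carried as the binary "survey version"
covariate). A respondent who declines the initial profile sees five
follow-up tasks in which one attribute at a time — drawn uniformly without
replacement — is improved to its best level; a respondent who accepts sees
five one-at-a-time deteriorations to the worst level. An attribute already
at its target level is excluded from the sampling pool, since modifying it
would produce no visible change; because the nine three-level attributes
start at their middle level, at least nine attributes are always eligible.
Where deteriorations should land is genuinely open for three-level
attributes (one-step-worse vs worst); we deteriorate to the worst level,
mirroring the improvement rule, for maximal signal.

## Stage 1 — initial-decision logistic regressions

The initial accept/decline decision is modelled by maximum-likelihood
logistic regression on respondent-characteristic dummies (reference levels
follow the published coding; the constant is the all-references cell).
Three covariate variants are compared: all dummies (Model 1); disease
dummies plus country (Model 2); everything except disease and country
(Model 3; also excludes COVID vaccination, trial experience and the QoL
classification, which are reported only under Model 1). Candidate columns
are screened pairwise: |Pearson r| > 0.8 drops the later column, and the
report labels magnitudes Cohen-style (≥0.5 "large"). Model comparison uses
BIC = k·ln(n) − 2·logL and out-of-sample predictive validity: stratified
tenfold cross-validation (seeded folds, 0.5 probability cutoff, percent of
held-out decisions correctly predicted). The paper does not state the
cutoff, stratification, or whether CV was repeated; we use a single
stratified split at cutoff 0.5. Training folds that separate perfectly are
fit with the separation guard disabled (saturated probabilities still rank
held-out cases); a single-class training fold falls back to the majority
rule and is logged. No multiple-testing adjustment is applied. Stars: *
p<0.1, ** p<0.05, *** p<0.01 (two-sided Wald).

## Stage 2 — latent-class switch logit

The five follow-up responses per respondent are collapsed to switch
indicators (decision differs from the respondent's initial decision).
Because each respondent sees a single direction (improve xor deteriorate),
a direction main effect is confounded with the initial decision and is
deliberately excluded: the model is a mixture over respondents of
attribute-indicator logits,

  P(switch | class c, attribute m) = σ(α_c + β_cm),

with transport provision as the omitted reference (β ≡ 0), so exp(β_cm) is
the odds ratio of switching when attribute m changes relative to a change
in transport provision. The respondent-level likelihood is the π-weighted
mixture of the five Bernoulli terms; the total log-likelihood uses
log-sum-exp stabilisation.

Estimation is EM. The E-step computes responsibilities; the M-step updates
shares as mean responsibilities and the class logits by
responsibility-weighted maximum likelihood. Because the design matrix is a
saturated set of attribute indicators, the weighted-logistic M-step has a
closed form — each (class, attribute) cell logit is the logit of the
responsibility-weighted empirical switch rate — which is exactly the
converged weighted-IRLS solution, guarantees monotone EM steps, and makes
each iteration O(n). Cell probabilities are clipped to [1e−10, 1−1e−10]
(pure weighted cells would otherwise diverge); class shares are floored at
1e−4 and renormalised, flagged in the convergence log if active.

Starts: per-respondent responsibilities from a symmetric Dirichlet(1)
followed by one M-step; 20 random starts by default, best final
log-likelihood kept; an error is raised only if no start converges.
Convergence: relative log-likelihood change < 1e−8 or 1,000 iterations
(tests that run many cheap starts allow 2,000 so a slow plateau start
cannot exhaust the cap). Classes are relabelled in increasing share order,
so class 1 is always the smaller class and repeated fits with one seed are
identical. The number of classes is chosen by BIC over 2–5 candidates with
k = (C−1) + 17C and n = respondents (the independent units), ties toward
fewer classes. Wald standard errors for the odds ratios come from the
numerically observed information of the full mixture likelihood at the MLE
(shares parameterised by multinomial logit); CIs are delta-method on the
log scale. Posterior membership is the Bayes posterior per respondent.

## Stage 3 — membership beta regression

Posterior probabilities of the larger class (class 2) are regressed on the
same characteristic dummies by beta regression: logit mean link, constant
precision φ. Posteriors can touch 0/1, so outcomes are first compressed by
y′ = (y(n−1) + ½)/n, the standard order-preserving shrink to the open
interval. Fitting is BFGS followed by a Newton polish so the full-sample
score norm at the optimum is below 1e−6; standard errors come from the
inverse observed information. This is the naive three-step approach — the
posterior is treated as data, with no correction for its estimation error —
matching the published analysis; coefficients are therefore attenuated
relative to a bias-adjusted three-step estimator.

## The synthetic cohort

No survey data are available, so all stages run on simulated cohorts with
known truth (shipped in `data/default_truth.json`):

- **Size and quotas.** 487 respondents by default; per-indication counts
  are met exactly, using the published sample counts (87 higher-mortality
  cancer, 96 lower-mortality cancer, 122 heart disease, 178 migraine, 51
  multiple sclerosis, 134 rheumatoid arthritis; comorbidities: 93 anemia,
  111 anxiety, 106 depression, 106 diabetes). Every respondent carries at
  least one screening indication; extra memberships land uniformly; the two
  cancer groups are disjoint. Quotas scale proportionally with n.
- **Covariates.** Country, age and employment are drawn jointly through a
  Gaussian copula whose latent correlations are inverted analytically
  (bivariate-normal rectangle probabilities + Brent root-finding) so the
  Pearson correlations of the ordinal codes hit the published values (0.63
  country–age, 0.61 age–employment, 0.54 country–employment). Age is a
  truncated normal (mean 47, sd 17, min 18) binned into 18–35/36–50/51–65/
  ≥66; the implied group shares (~20/31/27/21%) differ somewhat from the
  published 31/28/17/24% — the continuous-age model was preferred. All
  other covariates are independent draws from the published marginals; the
  six 0–4 quality-of-life items reproduce the published three-band
  marginals (outer bands split 60/40) and sum to the 0–24 total. Marginals
  without a published value (living alone 25%, dependents 40%, COVID
  vaccination 70%, time since diagnosis ≥6y 45%, QoL worse vs last year
  80%) were fixed once at plausible rates.
- **Decisions and classes.** The initial decision follows a logistic model
  whose dummy coefficients are the published Model-1 estimates; the
  membership model uses the published class-allocation coefficients. Both
  intercepts were solved numerically once so the marginal acceptance rate
  is 0.71 and the marginal class-2 share 0.639 under the default marginals.
  Switches follow σ(α_c + β_cm) with reference switch odds 0.25 (class 1)
  and 0.05 (class 2) and the published odds ratios; the nine attributes
  without a published OR carry fixed plausible defaults flagged
  `non_paper_odds_ratios`.

What the generator does **not** emulate: item nonresponse and attrition,
response-time behaviour, correlations among covariates beyond the three
published pairs (so real-data collinearity is understated), any dependence
of QoL items on indication, and measurement error in self-reports. Passing
recovery tests therefore show the estimators work under the published
two-class structure, not that the published estimates would replicate on
new survey data.

## Problem sizes and reproducibility

The recovery study simulates 10 seeds × 2,000 respondents and refits the
2-class model with 20 starts per seed (medians reported); BIC selection is
exercised at n = 700 with 5 starts × 10 seeds and EM monotonicity at
n = 200 across 2–5 classes. The full pipeline is bit-reproducible from
(config, seed): all randomness flows from one `numpy` SeedSequence, every
output file carries the seed and config hash in a header line, and
repeated runs produce identical file hashes.

## Known limitations

- Class intercepts α_c and the nine non-published ORs have no external
  reference values; only internal recovery is checked.
- The mixture's observed information is computed by finite differences;
  with thin (class, attribute) cells standard errors can be large or the
  information near-singular (logged, SEs omitted).
- Magnitude coding for three-level attributes (middle→best spans vs
  middle→worst) is not modelled; the switch model uses pure
  modified-attribute indicators, so improvement and deterioration magnitudes
  are pooled into one effect per attribute.
- The membership regression inherits the three-step attenuation noted
  above.
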