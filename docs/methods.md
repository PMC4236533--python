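# Methods

## The study design being emulated

The analysis treats a three-year pharmacy-claims extract (2003-06-03 to
2006-07-21) for primary-care patients of prescribers who were offered
standalone e-prescribing with formulary decision support (FDS).  Two
brand-only medication classes are analyzed — angiotensin receptor
blockers (ARB) and inhaled steroids (IS) — so that generic-substitution
policies cannot contaminate the tier signal.  The design is a
difference in differences: prescribers who adopted e-prescribing during
2005 (split into low users, <30% of prescriptions, and high users, ≥30%)
are compared with non-adopters across three periods per prescriber —
before activation, after activation with non-interruptive FDS only (tier
symbols shown passively), and after 2005-09-16 when interruptive
preferred-alternative alerts were added.  Non-adopters have no activation
date, so each is assigned a *synthetic* one drawn with replacement from
adopters' real dates; this splits control claims into the same periods
and absorbs the secular trend toward preferred-tier prescribing.

## Cohort construction

The exclusion cascade runs in a fixed order:

1. **Supply filter.** Claims with fewer than 15 days supplied are dropped
   (trial starts, data errors).  Because this runs first, a sub-15-day
   fill can never block a later claim from being an index claim; the
   filter threshold and washout are arguments if a different convention
   is wanted.
2. **New-user washout.** A claim is an *index* claim iff the patient has
   no same-class claim in the prior 180 days ("six months" is
   implemented as 180 days, matching the adherence window; calendar-month
   arithmetic is ambiguous).  Cross-class claims never block.  Claims
   before the extract start are unobservable, so the washout is
   left-censored at the extract boundary, exactly as in a real one-shot
   extract.
3. **Follow-up flag.** Index claims from 2006 are retained for the tier
   analyses but flagged ineligible for adherence (no full 180-day
   follow-up inside the extract).

Boundary dates are inclusive on the exposed side: a fill on the
activation day counts as post-activation and a fill on the go-live day
counts as interruptive-exposed, since activation enables e-prescribing
that same day.  The usage threshold resolves ties upward (high iff usage
≥ 0.30).  Monthly copayment is standardized as `copayment × 30 /
days_supplied` — the 30-day convention usual in claims work; the claim's
recorded patient-paid amount is taken at face value (coinsurance and
heterogeneous plans simply appear as copayment dispersion).

## PDC engine

For each adherence-eligible index claim, the proportion of days covered
is computed over the 180 days starting at the index fill (the fill day is
covered day 1).  Every same-class fill — any tier, any product —
contributes its days supplied.  Overlapping supply is *shifted forward*
(stockpiling) by default: a refill dispensed while supply remains starts
contributing when the prior supply runs out.  A `truncate` mode discards
the overlap instead; both modes are tested against a literal day-by-day
simulation and agree exactly on all randomized fill patterns.  Coverage
past the window end is not counted; windows extending past the extract
end are computed anyway and flagged right-censored.

## The three links

* **FDS:tier** — GEE logistic regression of preferred tier on class,
  usage-group and period main effects and all group × period
  interactions, clustered on prescriber.  The working correlation is
  exchangeable (the clustering unit is named by the design; the structure
  is not, and exchangeable is the conventional default), with robust
  sandwich standard errors.  Empty group × period cells have their
  columns dropped with a warning naming the cell.
* **tier:copayment** — OLS of monthly copayment on tier × class, so each
  class × tier cell mean is exactly representable and per-class tier
  differences are linear contrasts.  Standard errors are
  heteroscedasticity-robust (HC1): cost noise is multiplicative, so
  residual variance differs sharply between cells, and classical OLS
  errors undercover the IS contrast.
* **copayment:adherence** — linear mixed model of PDC (absolute
  proportion) on copay^λ, class, income stratum and dosing frequency,
  with a Gaussian prescriber random intercept, fitted by REML.
  Coefficients are absolute PDC changes; the copayment coefficient is per
  unit of copay^0.25 and is deliberately not back-transformed.

**Box-Cox selection.** The exponent λ ∈ {0, 0.25, 0.5, 1} (0 = log) is
chosen to minimize the RMSE of the regression of PDC on copay^λ *plus the
adjustment covariates*; omitting the covariates lets the class offset —
which is correlated with copayment through the class-specific centers —
distort the marginal shape the transform is fit to.  Without a response
the function falls back to the classic profile-likelihood normality
criterion.  Ranking is invariant to rescaling copayments by a positive
constant.  Note that over a narrow copayment range (roughly $5–$35 in
the default configuration) the candidate transforms are nearly
collinear, so the selected exponent is weakly identified; the selection
property is therefore tested on a wide-spread harness where the exponent
is identifiable, and the recovery models fix λ = 0.25.

**Backward elimination.** Starting from the full specification, the least
significant removable term (joint Wald p-value) with p above the
threshold (0.05) is dropped only if the fit criterion does not worsen —
QIC for the GEE link, ML-based AIC for the mixed model, AIC for OLS.
Exposure interactions and their main effects (and tier/class in the
copayment model) are protected.  The procedure is deterministic given
the data; a threshold of 1.0 with the criterion check disabled empties
the unprotected set, which is used as a degenerate-input test.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions.

* **Rosters.** 1570/187/74 prescribers (non/low/high), 8 patients each by
  default.  Low-user usage is uniform on (0.01, 0.30); high-user usage is
  0.30 + 0.70·Beta(2, 2.515), giving mean 0.61.  Activation dates are
  sampled from an empirical 2005 distribution interpolated through the
  adoption-date quartiles (Jun 2 / Aug 4 / Sep 29).  Prescribers carry
  specialty and practice-size categories drawn from per-group marginals;
  specialty has no effect on generated tier choice, but the tier model
  exposes a default-off `include_pediatric` sensitivity flag that adds a
  pediatric-prescriber indicator.  Patient income
  strata follow the marginal mix 18/58/24 (<45k / 45–75k / ≥75k); age is
  N(45.8, 19.5²) truncated to [2, 95]; 52% female; 12% of episodes dose
  more than once daily.  The generator assigns non-adopters their
  synthetic activation dates itself (from the same empirical
  distribution), because tier draws depend on the period label at
  generation time; the cohort stage keeps pre-assigned synthetic dates
  and only fills in missing ones, so analysis labels match generation
  labels.
* **Tier choice** is Bernoulli per (group, period, class) cell.  Two
  calibrations are provided.  The default builds the 18 cells from the
  published odds ratios (class OR 4.1; main effects 0.9/0.8/1.1/1.0;
  interactions 0.9/0.8/0.9/1.9) on the logit scale with the intercept
  solved so the pooled non-user pre-FDS share is 63% at a 73% ARB mix —
  under it the generator's true odds ratios are exactly the configured
  ones.  The alternative (`tier_cells_from_pooled`) solves each cell so
  the pooled class mixture reproduces the unadjusted percent-preferred
  table exactly.  The two cannot coincide: the published unadjusted cells
  imply a pooled high-user interaction odds ratio of about 2.0 rather
  than the adjusted 1.9, an ordinary unadjusted-versus-adjusted gap.
* **Copayments** are the class × tier centers $10.60/$11.81 (ARB) and
  $14.86/$16.42 (IS) times a mean-one log-normal multiplier
  exp(σZ − σ²/2), σ = 0.25 — right-skewed as cost data are, with the
  center equal to the cell mean so the linear tier model is unbiased for
  the configured centers; σ = 0 degenerates to the centers exactly.
* **Adherence.** Target PDC is linear: intercept 0.8945 (placing the
  ARB / non-preferred copayment / lowest-income / once-daily profile at
  74.62%, the ARB projection baseline), slope −0.08 per unit copay^0.25,
  IS offset −0.49, income offsets +0.06/+0.08, more-than-daily dosing
  −0.04, Gaussian prescriber intercepts (SD 0.05) and residual SD 0.10
  (both unpublished; chosen once as realistic claims-PDC noise).  The
  residual is truncated *symmetrically* to ±min(m, 1−m) around the
  conditional mean m, so PDC stays in [0, 1] while the conditional mean
  remains exactly linear — one-sided clipping would make the generator a
  censored-normal model whose true slope is attenuated relative to the
  configured −0.08 (about 8% at these noise levels), defeating recovery
  testing.  The cost of the choice is mild heteroscedasticity near the
  bounds.
* **Claims realization.** One index episode per patient per class by
  default (configurable).  Supplies are 30-day units; the drawn PDC
  target is realized exactly at day resolution by back-to-back 30-day
  fills plus one final fill placed so that only the remainder of its
  days falls inside the 180-day window — partial adherence comes from
  gaps between refills, never short supplies.  Because the index fill
  itself always exists, claims-realized PDC is floored at 30/180; the
  record-level generator (`generate_adherence_records`) has no such
  floor and is the direct route for copayment:adherence recovery.
  Refills dated past the extract end are dropped, mirroring a one-shot
  extract; adherence-eligible (pre-2006) episodes are never affected.

### What the generator does not emulate

Real claims features deliberately out of scope: generic-tier
medications, benefit-plan mechanics (deductibles, out-of-pocket maxima,
flex-spend, gap coverage, pay-and-submit), hospitalization/death
censoring, within-prescriber correlation of tier choice beyond the cell
structure, seasonality of IS starts, prescriber specialty effects (the
pediatric-prescriber covariate is behind a default-off flag), and any
per-prescription attribution of e-prescribing.  Passing tests therefore
demonstrate that the *estimators recover the generating process* under
the assumed structure — not that the assumed structure captures every
feature of real claims.

## Projections

`expected_copay_change(Δp, c_pref, c_non)` = Δp·(c_non − c_pref), the
expected-copayment identity, rounded to cents.
`pdc_change_from_copay(slope, base, new)` moves PDC along the fitted
quartic-root slope.  `net_probability_shift(OR, p₀)` converts an odds
ratio into an absolute probability shift; the pipeline uses as baseline
the joint model's counterfactual prediction for the high-user both-FDS
cell with the interaction removed, which lands the per-class net effects
at ≈15% (ARB) and ≈8% (IS).  The external route uses the survey tier
copayments ($29/$52 in 2013; $23/$40 era-matched to 2005) and a
cost-sharing elasticity (midrange 0.4, range 0.2–0.6) applied to a 60%
baseline PDC; the relative copayment change is taken against the
era-matched preferred survey copayment ($23), under which the chain
$3.45 → 3.45/23 → 0.60 × 0.4 × 0.15 yields +3.6 PDC percentage points.
The computed $3.45 (= 0.15 × $23) is reported as such and not forced to
any externally rounded figure.

## Problem sizes and numerical choices

* Recovery runs: the diff-in-diff uses 1,400 prescribers × 10 patients
  (~14,000 index claims) so the high-user × both-FDS cell holds ~1,500
  claims and the interaction log-OR has simulation SE ≈ 0.09; the
  copayment:adherence model uses 50,000 records across 1,000
  prescribers (slope SE ≈ 0.004); the calibration check uses 1,150
  prescribers × 40 patients (~5,000 claims in the target cell).  The
  acceptance script averages three independent replicates per stochastic
  quantity, cutting the Monte-Carlo SE by √3 so a single unlucky stream
  cannot dominate a reported value.
* The CI-coverage experiment runs 200 replicates at reduced size (120
  prescribers, ~1,200 claims, 1,500 adherence records) with the go-live
  shifted to 2006-02-01 so both post-activation periods are comfortably
  populated at that scale; coverage of generator truth is required to be
  ≥ 90% for each checked coefficient.
* All randomness flows through one `numpy.random.Generator` per run;
  identical config + seed reproduces every table byte-for-byte.
  Money is rounded to cents only at the reporting boundary; internal
  arithmetic is unrounded.  Ties: usage 0.30 is "high"; boundary fill
  dates are exposed; λ ties keep the earlier grid point (coarsest
  transform wins only via strict RMSE improvement).

## Known limitations

* Unadjusted-table and odds-ratio calibrations cannot both hold exactly
  (see above); choose the calibration matching the question.
* The Box-Cox exponent is weakly identified at the study's narrow
  copayment spread — faithfully so; selection is exercised where it is
  identifiable.
* The claims-realized PDC floor (one fill = 30/180) slightly compresses
  the low-adherence tail at the claims level; record-level generation is
  the unbiased route to the adherence model.
* GEE assumes the usage group is stable over the study, as the design
  did; the generator has no usage drift.
* The study-scale default roster (74 high users × 8 patients) leaves the
  key interaction cell with only ~160 claims; with those sizes the
  interaction is estimated with a CI about as wide as 1.0–3.4, so
  recovery-style checks require the enlarged designs above.
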