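# Methods

This note documents the statistical methods, the synthetic-cohort model and
the numerical and design choices in `ctctrack`, in the package's own terms.

## Expression scoring

Ct values live in [0, 40] cycles; 40 is the assay limit and encodes an
undetected well, so expression `40 − Ct` lives in [0, 40] expression units
with 0 meaning undetected. Thresholding is done on raw `40 − Ct` levels,
not housekeeping-normalized ones: raw levels keep the EM score's ±1
boundary statements exact, and the positivity rule is itself a calibration
against healthy donors processed identically, which absorbs global
efficiency differences. An optional ΔCt mode
(`expression.normalize_delta_ct`) shifts each sample by its mean
housekeeping Ct against a 25-cycle reference for users who prefer
within-sample normalization; it is off by default.

Per (gene, processing arm), the positivity threshold is the HD mean plus
one sample standard deviation (n−1 divisor; appropriate for arms of ~50
donors). Positivity is strict (`>`): a sample exactly at threshold is
negative. The positive-gene count considers only the 17 CTC-related genes;
the leukocyte control (PTPRC), erythroid control (GYPA) and housekeeping
genes are never part of patient-facing scores. Gene symbols are normalized
to uppercase on input.

Missing wells are recorded as undetected and logged; a sample missing more
than 25% of panel wells is flagged and excluded from score computations.
The 25% figure is a package choice: at that point more than five wells of
22 are absent and per-sample summaries (totals, positive counts) are no
longer comparable across samples.

The EM score divides the mesenchymal-minus-epithelial contrast by the sum
over all 8 EM genes, giving a scale-free polarity in [−1, +1]. A zero
denominator (no EM gene detected) leaves the score undefined rather than
zero: an all-undetected sample carries no polarity information, and
coercing it to 0 would pull group medians toward the center exactly in the
low-burden samples where the score is least meaningful. Undefined scores
are excluded from downstream EM analyses.

## Survival machinery

**Cox engine.** The counting-process partial likelihood over `(start,
stop]` rows (left truncation via `start > 0`, stratum-specific baseline
hazards) is maximized by Newton–Raphson with step-halving, to a gradient
max-norm of 1e−8 within 100 iterations. Ties are handled by Breslow's
method by default — the default of the major commercial survival package,
so published coefficients are comparable — with Efron's method behind an
option. Monotone likelihoods (perfect separation) are detected two ways: a
runaway coefficient during iteration, and a post-convergence check that
`|beta| × range(x)` stays below 15 (a hazard-ratio span above e^15 means
the gradient only vanished numerically); both raise naming the covariate.

**Robust variance.** The sandwich estimator aggregates score residuals
within clusters (patients), `V = I⁻¹ (Σ_g U_g U_gᵀ) I⁻¹`, with no
small-sample multiplier; it reproduces lifelines and R `survival::coxph`
clustered standard errors to ~1e−7 (verified in the test suite against
lifelines). Score residuals are implemented for Breslow ties; requesting a
robust variance with Efron ties raises rather than silently approximating.
Wald confidence intervals and p-values, 95% throughout.

**LVCF construction.** A covariate measured at visit time t applies from t
forward until the next measurement; the first measurement is carried back
to the consent date (the baseline draw effectively is the consent-time
value). An event coinciding with a measurement time uses the preceding
interval's value — the new measurement takes effect just after its own
time, so a covariate cannot "explain" an event simultaneous with it.
Measurements at or after the end of follow-up are ignored with a log entry;
patients with no usable measurement are excluded with a warning. Continuous
CTC counts are truncated at 40 before entering any model. When calendar
dates are converted, months = days / 30.4375.

**PWP recurrent-event model.** Total-time variant: every stratum's clock
runs from consent, rows split additionally at each progression event, and
the k-th-event stratum contains only patients who have had k−1 events.
Strata without events are dropped with a warning. The fit is the Cox engine
stratified on event number with patient-clustered sandwich variance.

**Endpoints.** A death without documented progression is treated as a
progression at the death date, both for the single-event
progression-free-survival (PFS) endpoint and as a terminal recurrent event.
An imputation flag is carried so analyses can also target the
progression-specific hazard (deaths censor instead); the parameter-recovery
suite uses that cause-specific form, because the imputed composite's hazard
is by construction a mixture of the progression and death hazards and its
multiplier for a shared covariate lies between the two processes'
multipliers — recovery of the progression-specific truth must not be judged
against a composite estimand.

**Nelson MCF.** Mean cumulative progression events: at each event time,
events divided by the number of subjects still under observation
(experiencing an event does not remove a subject; censoring or death does).

**Incidence rates.** Events per 100 person-years with exact Poisson
(chi-square) intervals; zero events yield a one-sided interval. The
incidence-rate ratio uses the log-normal interval with
`SE = sqrt(1/a + 1/b)`. Exact-Poisson intervals were chosen over Wald
because subgroup event counts can be small.

**Landmark convention.** Per-visit prognostic models measure survival from
the visit's sample time and exclude patients whose event or censoring
precedes it, avoiding immortal-time bias; the alternative (enrollment
origin for every visit) is deliberately not offered.

## Cutoff analysis

`counts.cutoff_sweep` reports, for each candidate cutoff c, the
landmark-Cox hazard ratio of `count ≥ c` with confidence interval and
per-stratum Kaplan–Meier medians, flagging the max-HR cutoff among those
with ≥ 5 high-group patients (smallest-cutoff tie-break). That table
mirrors the conventional figure, but simulation shows the max-HR flag is
noise-dominated: above the true change-point adjacent indicators differ in
only a few patients, expected hazard ratios are nearly flat, and small high
groups produce inflated estimates, so the arg-max wanders. The package
therefore also provides `counts.profile_cutoff`, which profiles the Cox
partial likelihood of the *time-dependent* indicator across cutoffs,
summing the recurrent-progression likelihood (common baseline hazard
across event numbers, to pool all events) and the death likelihood — the
change-point estimate is the likelihood maximizer. This is the estimator
the recovery suite tests; the sweep table remains available for
visual/reporting use.

## Synthetic cohort model

The generator produces the joint structure the analyses assume, with
defaults chosen as the study conditions:

- **Cohort layout**: 184 patients, up to 9 visits at exactly 3-month
  spacing, administrative censoring at 24 months plus exponential dropout
  (0.01/month). HD calibration sets of 54 (lysis) and 55 (no lysis)
  samples.
- **Subtype mix** (metastatic site): HR+/HER2− 0.576, HR−/HER2+ 0.054,
  HR+/HER2+ 0.076, TNBC 0.201, unknown 0.092 (renormalized to sum to 1).
- **Counts**: baseline counts are zero-inflated negative binomial,
  calibrated at construction so P(0) = 0.39 and P(<5) = 0.84. With NB size
  0.7 this gives π₀ ≈ 0.041 and mean ≈ 2.27. The calibration is solved
  numerically and raises when the two targets are unreachable at the given
  size — below size ≈ 0.65 the NB cannot place 45% of its mass on counts
  1–4. Consequence: the generator does not reproduce extreme count
  outliers (counts in the thousands); the truncation-at-40 rule is
  therefore exercised by direct unit tests, not by the cohort tails.
  Trajectories share a patient-level gamma burden thinned by 0.75 per
  visit (counts decline over follow-up, Poisson around the decaying
  burden).
- **Hazards**: piecewise-constant per month between visits, driven by the
  *current* CTC state — exactly the LVCF structure the fits assume. Base
  progression hazard 0.045/month and death hazard 0.010/month (set so the
  cohort's median time to first progression is ≈ 10 months and most
  patients are alive at the 24-month cutoff). Multipliers: CTC ≥ 5 — 2.251
  on progression and 4.894 on death; TNBC — 1.725 and 3.389; FGFR1-high —
  1.470 on progression. Progressions form a Poisson process (recurrent);
  death is terminal.
- **Expression**: gene Ct = HD background − weight × slope × log1p(count)
  + N(0, 1), clipped to [0, 40]; slope 2.5 cycles per log-count unit. HD
  background 36.5 cycles for CTC-related genes (SD 1.0), housekeeping 24,
  leukocyte control 21 in HDs and 26 in leukocyte-depleted patient
  samples; the no-lysis arm is offset +0.5 cycles. The EM polarity state θ
  starts at N(−0.4, 0.25) clipped to [−1, 1] (epithelial-leaning baseline)
  and drifts +0.05/visit in patients who progress, −0.03/visit otherwise;
  epithelial-class genes carry weight (1−θ)/2 and mesenchymal/stem genes
  (1+θ)/2. FGFR1 status (high in 30% of patients) shifts FGFR1 Ct 4
  cycles below HD background when high and 1 cycle above when low, so the
  expression-derived high/low call misclassifies ≈ 2% of visits while the
  hazard uses the true flag. ERBB2 couples to a latent HER2-positive CTC
  state (probability 0.6 given HER2+ tissue, 0.1 otherwise) to exercise
  the tissue-vs-CTC concordance utility.
- **Ordering**: counts are generated first, events are drawn from hazards
  conditional on the counts, and the EM drift is then assigned from the
  realized progressor status — trajectory → hazard → event, no
  circularity.
- **Clusters**: Poisson(0.15 × max(0, count − 2)) clusters per sample
  (≈ 4% of samples cluster-positive at defaults), each cluster holding at
  least 2 cells.

Same config and seed give byte-identical tables.

**What passing tests do and do not show.** The generator realizes the
proportional-hazards, LVCF-consistent world the models assume, so recovery
there validates the estimators and plumbing — not that real CTC data obey
proportional hazards, that real counts are negative binomial, or that EM
drift is linear per visit. Features deliberately absent: measurement error
in counts, visit-time jitter and missed visits, inter-plate batch effects
beyond the single arm offset, informative dropout, and the extreme count
tail.

## Numerical details and edge cases

- Sample SD uses the n−1 divisor everywhere; a calibration arm with fewer
  than 2 HD samples raises naming the arm.
- `hd_zscore` reports NaN with a QC note when an HD SD is zero.
- Kaplan–Meier median is the first time the curve reaches 0.5, reported
  missing when it never does; bands are the exponential-Greenwood
  (log-log) intervals.
- Exact rank tests switch to normal approximations (with tie and
  continuity corrections) above 25 per-group observations (rank-sum) or 20
  nonzero pairs (signed-rank), or whenever ties make enumeration invalid.
- The Welch (unequal-variance) t-test is used for per-visit EM group
  comparisons; group sizes and variances differ substantially between
  progressors and non-progressors.
- Per-visit progressor labels are patient-level ("progressed at some point
  on protocol") applied to all of that patient's visits.
- Simulation suite sizes — 25 replicates of 400 patients for
  hazard-ratio recovery, 200 replicates for type-I error, 50 replicates of
  200 patients for change-point recovery, 500 HD draws per arm for
  calibration checks — were chosen to keep Monte-Carlo error comfortably
  inside the assertion tolerances.

## Known limitations

- The recurrent-progression and death processes are conditionally
  independent given covariates; no frailty or joint modeling.
- The robust sandwich has no small-sample correction; with very few
  clusters its intervals can undercover.
- The profile change-point estimator assumes a single jump in the hazard
  as a function of count; it is not a general change-point test.
- HER2 tissue/CTC concordance is a thresholding-and-cross-tabulation
  utility; it does not model assay sensitivity.
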