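# ctctrack

Longitudinal liquid-biopsy analysis of circulating tumor cells (CTCs) in
metastatic breast cancer: healthy-donor-calibrated qRT-PCR expression
scoring, CTC-count thresholding, and the survival machinery for
time-dependent and recurrent-event prognosis modeling.

## Who this is for

Groups running serial CTC monitoring programs — imaging-based CTC counts
plus a targeted qRT-PCR panel on CTC-enriched blood — who need a tested,
reproducible path from raw cycle-threshold (Ct) values and per-visit counts
to calibrated positivity calls, epithelial–mesenchymal (EM) scores, and
Cox/recurrent-event survival models with time-varying biomarker covariates.

## The model at the core

**Expression scoring.** Expression is measured on the `40 − Ct` scale
(Ct = 40 encodes undetected). For each gene *g* and processing arm (with or
without red-blood-cell lysis), healthy-donor (HD) blood defines a positivity
threshold *m·g + s·g* (mean plus one standard deviation); a patient sample is
positive for *g* when its expression strictly exceeds that threshold. The EM
score contrasts four mesenchymal/stem genes (*ALDH1A1, CDH2, FN1, ZEB2*)
with four epithelial genes (*CDH1, EPCAM, KRT7, KRT18*):

```
EM = ( Σ_mes (40 − Ct) − Σ_epi (40 − Ct) ) / Σ_all 8 (40 − Ct)
```

so EM = +1 when only mesenchymal/stem genes are detected and −1 when only
epithelial genes are detected; it is undefined when none of the 8 genes is
detected.

**Survival machinery.** Counts and expression groups enter Cox proportional
hazards models as time-dependent covariates on counting-process
`(start, stop]` data built by last-value-carried-forward (LVCF) splitting at
measurement times; continuous counts are truncated at 40. The partial
likelihood (Breslow ties) is maximized by Newton–Raphson; variance is the
robust sandwich clustered on patient. Recurrent progression events use the
Prentice–Williams–Peterson (PWP) total-time model (stratified by event
number). Mean cumulative progression is the Nelson estimator; incidence is
reported per 100 person-years with exact Poisson intervals. Death without
documented progression counts as progression at the death date.

**Synthetic cohorts.** Because no patient-level data are distributed, a
seeded generator emulates the study structure (zero-inflated
negative-binomial baseline counts with 39% zeros and 84% below 5, counts
declining across up to 9 visits, HD-anchored Ct background with tumor signal
scaled to burden, mesenchymal EM drift in progressors, and
progression/death hazards multiplied by CTC ≥ 5, TNBC subtype and
FGFR1-high status). Every analysis stage is validated end-to-end against
this generator's known truth.

## Worked example

```python
from ctctrack import (
    CohortConfig, generate_cohort, calibrate_thresholds, score_samples,
)
from ctctrack.pipeline import time_dependent_multivariate

cohort = generate_cohort(CohortConfig(), seed=1)       # 184 patients
thresholds = calibrate_thresholds(cohort.hd_samples)   # per (gene, arm)
scores = score_samples(cohort.samples, thresholds)
print(scores[["sample_id", "positive_count", "em_score"]].head(5))

fits = time_dependent_multivariate(cohort, thresholds)
print(fits["progression"])
```

prints

```
sample_id  positive_count  em_score
  P0001V1               2 -0.141788
  P0001V2              10 -0.218630
  P0001V3               5 -0.071617
  P0001V4               7 -0.132035
  P0001V5               5 -0.063195

CoxPH fit: n=184, events=143, variance=robust_sandwich, logPL=-631.5287
           coef    hr     se  hr_ci_low  hr_ci_high         p
ctc_high  1.143 3.136 0.2533      1.909       5.153 6.419e-06
tnbc     0.4775 1.612 0.2007      1.088       2.389   0.01733
fgfr1    0.2751 1.317 0.1611       0.96       1.806   0.08783
```

`positive_count` is the number of the 17 CTC-related genes above their HD
thresholds; `em_score` is the sample's EM polarity in [−1, 1]. The fit is
the time-dependent multivariate progression model: at any given timepoint a
patient whose current CTC count is ≥ 5 has about 3.1 times the progression
hazard of one below 5 in this particular replicate (the generator's true
hazard ratio is 2.251; single replicates scatter around it), with TNBC
subtype and FGFR1-high expression as the other covariates.

The same workflows are available from the shell:

```bash
ctctrack synth --seed 1 --outdir cohort/
ctctrack all --synthetic --seed 1 --outdir results/
```

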