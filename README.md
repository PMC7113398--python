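# hlasurv

Survival association and risk prediction from HLA "superalleles" in
cancer cohorts, with skin cutaneous melanoma as the motivating setting.

Typed four-digit HLA alleles (e.g. `HLA-A*01:01`) are individually too
rare for reliable survival contrasts, so they are collapsed to their
allele group — the two-digit *superallele* `HLA-A*01` (gene + field1 of
the IMGT name). The package then:

1. **screens** every superallele carried by ≥ 10 patients: carriers vs
   non-carriers are compared on mean overall survival (MOS, months)
   with a two-sample t-test; a positive significant difference marks
   the superallele *survival-favorable* (SF), a negative one
   *survival-unfavorable* (SU);
2. **scores** each patient with the cumulative risk score
   RS = #SU carried − #SF carried, and stratifies the cohort at integer
   thresholds (high-risk ⇔ RS ≥ t), measuring each split by the Cox
   proportional-hazards ratio (HR, 95% CI) and the log-rank test;
3. **predicts** OS months with regression models (lasso, ridge, random
   forest, decision tree) over clinical covariates (age, gender, tumor
   stage, tumor status, Breslow depth) and superallele carriage,
   scoring a model by the HR between patients whose pooled out-of-fold
   5-fold-CV prediction falls below vs above the prediction median;
4. **selects features** with a greedy wrapper: superalleles are added
   one at a time, keeping the addition that most increases the HR,
   until no addition improves it;
5. **simulates** cohorts with known ground truth (Weibull
   proportional-hazards survival, independent censoring, configurable
   carriage frequencies and planted log-HRs) so every stage is testable
   without controlled-access patient data.

Kaplan–Meier estimation, the two-group log-rank test and Cox partial
likelihood maximization (Newton–Raphson, Efron tie correction by
default, Breslow by flag) are implemented in `hlasurv.survstats` and
cross-checked in the test suite against brute-force risk-set
enumeration and `lifelines`.

## Worked example

A 401-patient synthetic cohort (mean follow-up 54.3 months, 67%
censored) with known planted effects:

```sh
hlasurv simulate --out demo --seed 5
hlasurv screen --clinical demo/clinical.tsv --alleles demo/alleles.tsv --out demo/screen.tsv
hlasurv riskscore --clinical demo/clinical.tsv --alleles demo/alleles.tsv --out-dir demo/rs
hlasurv wrapper --clinical demo/clinical.tsv --alleles demo/alleles.tsv --out-dir demo/wrap --model lasso --seed 7
```

The significant rows of `demo/screen.tsv` (columns: superallele,
carriers, non-carriers, group MOS, difference, p, class):

```
superallele  n_present  n_absent  mos_present  mos_absent  mean_diff       p  klass
HLA-DPB1*01         29       372        83.43       51.98      31.45   0.017     SF
   HLA-B*08         76       325        70.77       50.39      20.37   0.011     SF
HLA-DQB1*06        140       261        64.89       48.55      16.34  0.0073     SF
   HLA-C*07        216       185        60.90       46.50      14.40  0.0094     SF
HLA-DRB1*03        102       299        64.57       50.74      13.84   0.041     SF
   HLA-B*07        124       277        45.33       58.25     -12.92   0.021     SU
   HLA-A*24         92       309        43.63       57.42     -13.79   0.023     SU
   HLA-C*01         42       359        41.29       55.77     -14.48   0.047     SU
HLA-DRB1*07        106       295        40.40       59.23     -18.83 0.00066     SU
   HLA-B*14         29       372        30.98       56.07     -25.09   0.002     SU
   HLA-B*50         13       388        28.32       55.12     -26.80 0.00026     SU
   HLA-B*13         17       384        26.21       55.50     -29.29   0.024     SU
```

Carriers of `HLA-DPB1*01` live on average 31 months longer than
non-carriers (SF); `HLA-B*50` carriers live 27 months shorter (SU).
Ten of the twelve calls are planted effects; `HLA-DQB1*06` and
`HLA-B*07` are chance hits of the kind an uncorrected 26-way screen
produces. The risk-score sweep (`demo/rs/threshold_sweep.tsv`) then
shows, e.g., that the 102 patients with RS ≥ 1 die at 3.2 times the
rate of the rest (HR 3.25, 95% CI 2.28–4.63, log-rank p = 2e-08), with
the high-risk group shrinking monotonically as the threshold rises
(102, 37, 7 for RS ≥ 1, 2, 3).  The greedy wrapper starting from the
five clinical features raises the cross-validated median-split HR from
1.58 to 5.37 while adopting eight superalleles:

```
 step       added    hr
    0      <base> 1.579
    1 HLA-DRB1*07 3.626
    2    HLA-C*07 4.337
    ...
    8 HLA-DRB1*03 5.370
```

Every command writes a JSON manifest from which the run can be
reproduced exactly.

The same pipeline runs unchanged on real data: a clinical TSV
(`patient_id, age, gender, stage, tumor_status, breslow_depth,
os_months, event`) plus a long-format allele TSV (`patient_id,
allele`).

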