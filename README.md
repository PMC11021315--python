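# tlscreen

Standardization toolkit for a telephone-administered language screener
(TLS): deterministic scoring of its nine language subtasks (total range
0–68) plus backward digit span, **Equivalent-Score (ES) regression-based
norming** with non-parametric tolerance limits, **2-PL IRT** item
calibration, a reliability/validity suite (Spearman with Bonferroni control,
ICC, McDonald's ω, item-rest correlations, PCA), **ROC** case-finding
analysis, and the study-design **sample-size planners**. A synthetic-cohort
module emulates the normative sample (N = 480 Italian adults, age
51.79 ± 18.61 years, education 12.88 ± 3.96 years) so every pipeline stage
is testable without access to the restricted raw data; the published norm
table ships as a versioned JSON fixture for scoring real records.

It is written for clinical neuropsychologists and psychometricians who
either apply published telephone-screener norms or standardize a new
instrument with the same methodology.

## The model

**Demographic adjustment.** For each measure, raw scores RS are regressed
on candidate demographic transforms (age, age², age³, ln(100−age);
education, 1/education, √education, log₁₀(education); sex) by forward
stepwise OLS with entry α = 0.05, at most one term per demographic
variable. The adjusted score is

```
AS = RS + Σ_t c_t · (t(x) − center_t),   c_t = −β̂_t,
```

with `center_t` the normative mean of the transform, so AS = RS exactly at
the centering demographics. For example, the published total-score
equation is `AS = RS + 0.000009·(age³ − 191433.997917) +
50.82466·(1/education − 0.088235)`.

**Tolerance limits.** On the ascending adjusted scores of n examinees, the
outer tolerance limit oTL is the order statistic at the largest rank r with
P(Binomial(n, 0.05) ≥ r) ≥ 0.95, and the inner limit iTL at the smallest
rank s with P(Binomial(n, 0.05) ≤ s−1) ≥ 0.95 — a one-sided non-parametric
interval estimate of the population 5th centile (feasible for n ≥ 59; at
n = 100 the ranks are 2 and 10).

**Equivalent Scores.** AS ≤ oTL ⇒ ES = 0 (impaired); AS ≥ median ⇒ ES = 4
(high-end normal); the region in between is split into ES = 1/2/3 at the
empirical quantiles matching an equal three-way split of the z interval
[−1.6449, 0] (cuts at z = −1.0966 and −0.5483, i.e. the ≈13.6th and ≈29.2th
centiles). Scores in (oTL, iTL] are ES = 1 but flagged non-classifiable.

**Item calibration.** P(correct | θ) = logistic(a(θ − b)) with a standard
normal ability prior, fitted by Bock–Aitkin EM (marginal maximum
likelihood, 61-node quadrature on [−6, 6]); items are banded as
extremely easy / typical / extremely difficult (|b| vs 3) and
low / moderate / high / extremely high discrimination
(0.65, 1.35, 1.7 cuts).

**Case finding and planning.** Patient-vs-norm discrimination uses the
Mann–Whitney AUC with DeLong standard errors; the planners reproduce the
noncentral-F minimum-N search for the norming regression and Obuchowski's
binormal single-test ROC sizes.

## Worked example

Score a 70-year-old with 8 years of education who obtained a raw total
of 55, against the published norm table:

```python
from tlscreen import PUBLISHED_NORM_TABLE, score_record

as_value, res = score_record(55, 70, 8, "female", PUBLISHED_NORM_TABLE["total"])
print(f"AS={as_value:.2f}, ES={res.es}, non_classifiable={res.non_classifiable}")
```

```
AS=58.23, ES=2, non_classifiable=False
```

The raw 55 is adjusted upward by ≈3.2 points (older age and low education
are compensated), landing in the ES = 2 band (low-end normal,
56.42–58.79). The same call with RS = 53.5 unadjusted would fall between
the tolerance limits (52.64, 54.9] and return ES = 1 with
`non_classifiable=True` — below-median but not inferentially judgeable
against the impairment cut-off.

The planners from the shell:

```sh
$ tls power regression           # norming-stage minimum N
{"min_total_n": 193}
$ tls pipeline --out-dir out --seed 1   # simulate -> norm-fit -> score -> irt-fit -> roc
```

Other subcommands: `simulate`, `norm-fit`, `score`, `irt-fit`,
`reliability`, `consistency`, `validity`, `roc`.

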