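# Methods

This note records the statistical model behind `tlscreen`, the design
decisions taken where the methodology leaves room, and what the synthetic
cohorts do and do not establish.

## Instrument model

The screener is declared, not hard-coded: `InstrumentSpec` (shipped as
`data/instrument_spec.json`) lists the nine total-contributing subtasks —
informative units (0–11), spelling (0–10), semantic association (0–6),
naming to description of nouns and of verbs (0–6 each), the six-command
comprehension task (0–15), repetition of words (0–6), non-words (0–5) and
sentences (0–3), summing to 68 — plus the backward digit span, which never
enters the total. Missing subtask scores raise; prorating is deliberately
not offered as a default behaviour.

Two fixture conventions are package choices, editable in the spec file:

- **Command point allocation.** Only the per-task total (15) and one item's
  range (0–3) are fixed by the instrument; the allocation across the six
  commands defaults to (3, 2, 3, 2, 3, 2), alternating commands that carry
  a serial-order point (components + 1) with commands that do not. The
  scorer accepts either structure per item: one point per correct
  component, plus the order point only when every component is correct and
  the order respected.
- **Digit-span trial list.** Eight sequences of lengths (2, 2, 3, 3, 4, 4,
  5, 6), bounding the total at 8 and the longest-recalled outcome at 6.
  Discontinuation rules are not modelled; scoring consumes the full trial
  record.

The ceiling rate uses the linear-interpolation empirical quantile
(`numpy.percentile` default) and counts scores **at or above** the 95th
percentile; the quantile convention is stated because none is canonical.

## Synthetic cohorts

The generator emulates the normative sample's structure, not its data:

- Age ~ truncated normal (51.79, 18.61) on [18, 96], rounded to years;
  education ~ truncated normal (12.88, 3.96) on [4, 25], discretised;
  P(female) = 289/480.
- One latent ability per person,
  `theta = beta_age*(age^3 - E[age^3]) + beta_edu*(1/edu - E[1/edu]) + eps`,
  with defaults `beta_age = -3e-6`, `beta_edu = -10`, `eps ~ N(0, 0.85)`.
  The transform moments are computed by quadrature on the continuous
  truncated normals. These defaults place roughly 0.45 SD of ability on
  age and 0.25 SD on education (older worse, educated better), totalling
  an ability SD near 1 — chosen once as a realistic demographic footprint
  for a language screener and not revisited.
- Each subtask score is `Binomial(max_k, logistic(theta + c_k))` with
  `c_k = logit(published subtask mean / max)`. The binomial-logistic link,
  rather than truncated Gaussians, makes ceiling effects emerge naturally
  near the maxima (the simulated total shows a ceiling rate near 6–9%) and
  the single shared factor mirrors the instrument's mono-component
  structure.
- Patients are the same generator with ability shifted down by a constant
  delta; `shift_for_auc` inverts the equal-variance binormal identity
  AUC = Φ(delta/(sd·√2)) on the **latent** scale. Observed-score AUC is
  attenuated by binomial measurement noise: at a latent target of 0.80 the
  empirical total-score AUC averages ≈0.78–0.80 at 480 controls vs 37
  patients, which is the property the acceptance test asserts.
- Retest/second-rater pairs regress the first occasion toward the mean by
  the target reliability and restore the variance with fresh noise, giving
  a population absolute-agreement ICC equal to the target.
- All draws flow from one master seed through `SeedSequence.spawn` child
  streams (fixed order: age, education, sex, ability, scores), so cohorts
  are bitwise reproducible and locale-independent.

What passing these simulations does **not** show: real cohorts have
subtype-specific deficit profiles, non-binomial overdispersion,
interviewer effects and item-level local dependence; recovery on the
simulator validates the estimators under the model's own assumptions, not
the instrument's field behaviour.

## Equivalent-Score norming

- **Stepwise rule.** Forward selection with entry α = 0.05 over the
  candidate pools (age, age², age³, ln(100−age); education, 1/education,
  √education, log₁₀(education); male indicator), at most one term per
  demographic variable, smallest entry p-value first. Candidates within a
  family are nearly collinear, so under a true null the family-wise
  spurious-entry rate is ≈20% rather than 3×5%; the unit tests assert the
  empty-equation retention rate the procedure actually delivers (≈80%).
  Saturated fits returning non-finite p-values are skipped.
- **Adjustment convention.** Coefficients are the negated OLS slopes and
  centers the cohort means of the selected transforms, so AS = RS at the
  centering point and the correction direction compensates (older age and
  lower education are adjusted upward when they depress raw scores).
- **Tolerance limits.** Exact binomial rank search; one-sided 95%
  confidence that the outer (inner) order statistic lies below (above) the
  population 5th centile. The smallest feasible sample is n = 59, where
  the outer rank is 1.
- **Interior bands.** The method tradition specifies only "a z-score-based
  approach" between the 5th centile and the median. This package splits
  the z interval [z_{0.05}, 0] into three equal widths (cuts −1.0966,
  −0.5483 ⇒ centiles ≈13.64% and ≈29.17%) and takes the corresponding
  empirical quantiles of the adjusted scores. The choice is isolated
  behind the `interior_z` parameter of `es_thresholds`.
- **Tie handling.** ES 0 uses ≤ oTL and ES 4 uses ≥ its lower bound,
  matching the published table's printed inequalities; interior bands are
  half-open on the left, so every adjusted score receives exactly one
  band.
- **Partial published rows.** A measure whose table row prints only the
  impairment bound (word repetition) is represented with absent interior
  bounds: scores at the ceiling map to ES 4, scores within the tolerance
  interval to a non-classifiable ES 1, and anything else in the middle
  region returns `es=None` (unavailable) rather than a fabricated band.
- **Fixture precision.** The published thresholds are stored and compared
  at the printed precision; fitted thresholds keep full float precision
  and round only in reports. `save`/`load` round-trips are bit-exact.

## 2-PL calibration

Bock–Aitkin EM with a fixed standard-normal ability prior (identification),
61 equally spaced quadrature nodes on [−6, 6] weighted by the normal
density, and a damped per-item Newton M-step with step-halving — a
generalized EM whose marginal log-likelihood is asserted non-decreasing at
every iteration. Convergence is declared when the largest change in any
(a, b) falls below `tol` (default 1e-4). Standard errors come from the
expected complete-data information of the M-step objective via the delta
method (slope–intercept to slope–location); they ignore cross-item
dependence and are therefore mildly optimistic, which is acceptable for
the flagging role they play here. Missing responses are omitted from the
likelihood (assumed ignorable). All-constant items are excluded and
reported "n.a."; items with |b| > 8 and SE(b) > 10 are flagged unstable but
retained. No prior or ridge penalty is placed on the discriminations by
default. Dichotomization of polytomous items marks scores at or above the
empirical 5th percentile as passes; with an all-constant column the cut
equals the common value and every response passes (documented edge — the
strictly-above variant would instead zero the column and always produce a
degenerate item).

Parameter recovery at the scale used in the tests (2000 persons, 20 items,
a ∈ [0.8, 2], b ∈ [−2, 1]) achieves mean absolute errors around 0.07 for a
and 0.04 for b, comfortably inside the asserted 0.2/0.15 bounds; estimates
move by < 1e-6 when the quadrature is refined from 61 to 81 nodes.

## Reliability, validity, structure

- Spearman correlations use midranks and the t-approximation p-value,
  with pairwise missing-data exclusion; multiplicity control is plain
  Bonferroni (α/m).
- The ICC is the two-way random-effects, absolute-agreement,
  single-measure form — the standard choice for crossed test-retest and
  inter-rater designs — delegated to `pingouin.intraclass_corr` and
  cross-checked in the tests against a mean-squares oracle. Zero
  between-subject variance raises rather than returning a meaningless
  coefficient.
- McDonald's ω uses a one-factor maximum-likelihood factor solution
  (scikit-learn's `FactorAnalysis`) with ω = (Σλ)²/((Σλ)² + Σψ); Heywood
  cases are reported by subtest via a warning. The equal-loading closed
  form (kλ)²/((kλ)² + kψ) is exposed as `omega_from_loadings`.
- The structure check is a correlation-matrix PCA (subtests have
  heterogeneous ranges); the leading loadings are the eigenvector scaled
  by √eigenvalue with the sign fixed to a positive mean.

## ROC and planners

AUC is the tie-corrected Mann–Whitney probability computed from placement
values, with DeLong's variance by default (Hanley–McNeil behind a flag)
and a normal CI clipped to [0, 1]. The orientation flag states which side
of the scale disease occupies (screener totals: lower).

`regression_min_n` searches integers under the convention
λ = f²·(u + v + 1): with f² = 0.075, u = 3, power 0.90, α = 0.05 it returns
N = 193. `roc_min_n` implements the Obuchowski binormal-exponential
variance V(A) = 0.0099·e^(−A²/4)·[(5A² + 8) + (A² + 8)/k]; the variance
variant is an explicit parameter because several variants circulate, and
no specific published pair of case/control sizes is asserted against it.
The one-sided α (testing AUC > 0.5) is the default. Degenerate power
requests floor at one case.

## Problem sizes in the test suite

The acceptance tests run the pipeline at the study's own scale: 50
replicates of n = 480 for stepwise-selection recovery, one 2000 × 20
calibration, 100 replicates of 480 vs 37 for the AUC calibration, and an
exhaustive tolerance-rank check over n ∈ [59, 1000]. The whole suite
completes in well under a minute on one CPU.

## Known limitations

- The interior z-cut choice and the command point allocation are
  documented conventions, not published facts; both are configurable.
- Simulator patients differ from controls only by a global ability shift;
  no clinical-subtype profiles.
- IRT standard errors omit cross-item information (see above); no 1-PL/
  3-PL, multidimensional models or DIF.
- Norming assumes the cohort is representative; no continuous-norming or
  quantile-regression alternative is provided.
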