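"""Synthetic cohorts with the statistical structure the norming pipeline assumes.

The normative study population is emulated as follows. Demographics follow
the published normative-sample margins: age from a truncated normal
(mean 51.79, sd 18.61, bounds [18, 96], rounded to whole years), education
from a discretised truncated normal (mean 12.88, sd 3.96, bounds [4, 25]),
sex female with probability 289/480. Each person carries a single latent
language ability

    theta_i = beta_age * (age_i^3 - E[age^3]) + beta_edu * (1/edu_i - E[1/edu]) + eps_i

(one shared factor across subtasks, mirroring the screener's mono-component
structure), and every subtask raw score is a bounded count

    RS_k ~ Binomial(max_k, logistic(theta_i + c_k)),

so ceiling effects arise naturally near the subtask maxima. The per-subtask
offsets ``c_k`` default to the logits of the published normative subtask
means over their maxima. Default effect sizes put roughly 0.45 SD of ability
on the age term and 0.25 SD on the education term (older age worsens,
education improves scores), with residual sd 0.85.

Patient cohorts reuse the generator with ability shifted down by ``delta``;
``shift_for_auc`` converts a target theoretical AUC into that shift via the
binormal identity AUC = Phi(delta / (sd(theta) * sqrt(2))).

All generators draw from child streams of a single master seed (fixed
offsets via `numpy.random.SeedSequence(seed).spawn`), so runs are bitwise
reproducible.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats
from scipy.special import expit, logit

from .instrument import DEFAULT_SPEC, InstrumentSpec

#: Normative subtask means / maxima (published normative sample), used as
#: default difficulty offsets c_k = logit(mean_k / max_k).
_NORMATIVE_MEANS = {
    "informative_units": 8.37,
    "spelling": 8.92,
    "semantic_association": 5.87,
    "naming_nouns": 5.45,
    "naming_verbs": 5.53,
    "repetition_words": 5.85,
    "repetition_nonwords": 4.28,
    "repetition_sentences": 2.72,
    "cml": 14.13,
    "bds_total": 4.79,
    "bds_wm": 4.68,
}


def _default_links(spec: InstrumentSpec) -> dict[str, float]:
    return {
        s.name: float(logit(_NORMATIVE_MEANS[s.name] / s.max_score))
        for s in spec.subtests
        if s.name in _NORMATIVE_MEANS
    }


class TruncNormSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(gt=0)
    low: float
    high: float

    def _frozen(self):
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(n, random_state=rng)

    def moments_of(self, fn) -> tuple[float, float]:
        """(mean, variance) of fn(X) under the continuous truncated normal,
        by Gauss-Legendre quadrature on the support."""
        dist = self._frozen()
        nodes, weights = np.polynomial.legendre.leggauss(201)
        x = 0.5 * (self.high - self.low) * nodes + 0.5 * (self.high + self.low)
        w = 0.5 * (self.high - self.low) * weights * dist.pdf(x)
        fx = np.array([fn(v) for v in x])
        m1 = float(np.sum(w * fx))
        m2 = float(np.sum(w * fx**2))
        return m1, m2 - m1**2


class CohortConfig(BaseModel):
    """Generating conditions for a normative cohort (defaults emulate the
    published normative sample of 480 adults)."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=480, ge=1)
    seed: int = 0
    age_dist: TruncNormSpec = TruncNormSpec(mean=51.79, sd=18.61, low=18, high=96)
    edu_dist: TruncNormSpec = TruncNormSpec(mean=12.88, sd=3.96, low=4, high=25)
    p_female: float = Field(default=289 / 480, ge=0, le=1)
    beta_age: float = -3.0e-6  # ability per unit centered age^3 (older worse)
    beta_edu: float = -10.0  # ability per unit centered 1/education
    noise_sd: float = Field(default=0.85, gt=0)
    subtest_links: Optional[dict[str, float]] = None

    def links(self, spec: InstrumentSpec = DEFAULT_SPEC) -> dict[str, float]:
        return dict(self.subtest_links or _default_links(spec))


class PatientConfig(BaseModel):
    """Patient cohort: the normative generator with latent ability shifted
    down by ``ability_shift`` (a global deficit, no subtype profiles)."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=37, ge=1)
    ability_shift: float = Field(default=0.0, ge=0)
    seed: int = 0


@lru_cache(maxsize=32)
def _transform_moments(age_dist: TruncNormSpec, edu_dist: TruncNormSpec):
    age_m, age_v = age_dist.moments_of(lambda a: a**3)
    edu_m, edu_v = edu_dist.moments_of(lambda e: 1.0 / e)
    return age_m, age_v, edu_m, edu_v


def ability_sd(config: CohortConfig) -> float:
    """Population SD of latent ability under the continuous demographic
    distributions (binomial measurement noise excluded)."""
    _, age_v, _, edu_v = _transform_moments(config.age_dist, config.edu_dist)
    return math.sqrt(
        config.beta_age**2 * age_v + config.beta_edu**2 * edu_v + config.noise_sd**2
    )


def shift_for_auc(auc: float, config: CohortConfig) -> float:
    """Ability shift giving theoretical (latent-scale, equal-variance
    binormal) patient-vs-control AUC: delta = sqrt(2) * Phi^-1(auc) * sd."""
    if not (0.5 < auc < 1.0):
        raise ValueError("target AUC must lie in (0.5, 1)")
    return float(math.sqrt(2.0) * stats.norm.ppf(auc) * ability_sd(config))


def _child_rngs(seed: int, k: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(k)]


def _latent_theta(
    config: CohortConfig,
    age: np.ndarray,
    edu: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    age_m, _, edu_m, _ = _transform_moments(config.age_dist, config.edu_dist)
    eps = rng.normal(0.0, config.noise_sd, size=len(age))
    return (
        config.beta_age * (age.astype(float) ** 3 - age_m)
        + config.beta_edu * (1.0 / edu.astype(float) - edu_m)
        + eps
    )


def _draw_cohort(
    config: CohortConfig,
    spec: InstrumentSpec,
    seed: int,
    theta_shift: float,
    id_prefix: str,
) -> pd.DataFrame:
    rng_age, rng_edu, rng_sex, rng_theta, rng_scores = _child_rngs(seed, 5)
    age = np.clip(np.rint(config.age_dist.rvs(config.n, rng_age)), 18, 96).astype(int)
    edu = np.clip(np.rint(config.edu_dist.rvs(config.n, rng_edu)), 4, 25).astype(int)
    sex = np.where(rng_sex.random(config.n) < config.p_female, "female", "male")
    theta = _latent_theta(config, age, edu, rng_theta) - theta_shift
    data: dict[str, object] = {
        "id": [f"{id_prefix}{i:04d}" for i in range(config.n)],
        "age": age,
        "education_years": edu,
        "sex": sex,
    }
    links = config.links(spec)
    for s in spec.subtests:
        p = expit(theta + links[s.name])
        data[s.name] = rng_scores.binomial(s.max_score, p)
    return pd.DataFrame(data)


def generate_normative(
    config: CohortConfig, spec: InstrumentSpec = DEFAULT_SPEC
) -> pd.DataFrame:
    """Normative cohort as a frame with columns id, age, education_years,
    sex and one raw-score column per subtask. Reproducible given the seed;
    every row passes instrument validation."""
    return _draw_cohort(config, spec, config.seed, 0.0, "hp")


def generate_patients(
    config: PatientConfig,
    base: CohortConfig,
    spec: InstrumentSpec = DEFAULT_SPEC,
) -> pd.DataFrame:
    """Patient cohort: identical generator with theta shifted by -delta."""
    patient_base = base.model_copy(update={"n": config.n})
    return _draw_cohort(patient_base, spec, config.seed, config.ability_shift, "pt")


def generate_retest(
    scores: np.ndarray | pd.Series, reliability_target: float, seed: int = 0
) -> pd.DataFrame:
    """Paired measurements with population ICC equal to ``reliability_target``.

    The second occasion regresses the first toward the sample mean by the
    target reliability and adds fresh error restoring the variance:
    y = mu + rho*(x - mu) + sqrt(1 - rho^2)*sd*z, which has the same mean and
    variance as x and inter-occasion correlation rho, hence a population
    two-way absolute-agreement ICC of rho. A target of 1 returns identical
    pairs; also used for second-rater replicates.
    """
    if not (0.0 < reliability_target <= 1.0):
        raise ValueError("reliability_target must lie in (0, 1]")
    x = np.asarray(scores, dtype=float)
    rho = reliability_target
    mu, sd = x.mean(), x.std(ddof=1)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    z = rng.normal(0.0, 1.0, size=x.shape)
    y = mu + rho * (x - mu) + math.sqrt(1.0 - rho**2) * sd * z
    return pd.DataFrame({"occasion_1": x, "occasion_2": y})


def generate_item_matrix(
    n: int, a: np.ndarray, b: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Binary person x item responses under the two-parameter logistic model
    with standard-normal abilities: x_ij ~ Bernoulli(logistic(a_j*(theta_i - b_j)))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("discrimination and difficulty vectors must match in length")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng_theta, rng_resp = _child_rngs(seed, 2)
    theta = rng_theta.normal(0.0, 1.0, size=n)
    p = expit(a[None, :] * (theta[:, None] - b[None, :]))
    x = (rng_resp.random(p.shape) < p).astype(int)
    return pd.DataFrame(x, columns=[f"item_{j + 1}" for j in range(len(a))])
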