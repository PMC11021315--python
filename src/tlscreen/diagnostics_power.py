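"""ROC discrimination and the study-design sample-size planners.

``auc_mann_whitney`` estimates the probability that a randomly chosen
patient scores on the disease side of a randomly chosen control (the
Mann-Whitney AUC, ties counted one half) with DeLong's distribution-free
standard error (Hanley-McNeil available by flag).

``regression_min_n`` reproduces the norming-stage power computation: the
smallest total N = u + v + 1 for which the level-alpha F(u, v) test of a
multiple regression with effect size f^2 reaches the target power, under the
noncentrality convention lambda = f^2 * (u + v + 1).

``roc_min_n`` is the Obuchowski single-test ROC planner under the
binormal-exponential variance approximation
V(A) = 0.0099 * exp(-A^2/4) * [(5A^2 + 8) + (A^2 + 8)/k], A = Phi^-1(AUC)*sqrt(2),
with n_cases = ceil[(z_{1-alpha} sqrt(V0) + z_{1-beta} sqrt(V1))^2 / (AUC - 0.5)^2]
and n_controls = k * n_cases. The variance variant is an explicit parameter.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats


class DiagnosticsError(ValueError):
    pass


class RocResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    auc: float = Field(ge=0, le=1)
    se: float = Field(ge=0)
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


class PowerSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    f2: float = Field(gt=0)
    u: int = Field(gt=0, description="numerator df (number of predictors)")
    power: float = Field(gt=0, lt=1)
    alpha: float = Field(gt=0, lt=1)


class RocSizeSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    auc_alt: float = Field(gt=0.5, lt=1)
    k: float = Field(gt=0, description="control-to-case allocation ratio")
    power: float = Field(gt=0, lt=1)
    alpha: float = Field(gt=0, lt=1)
    variant: Literal["obuchowski_binormal"] = "obuchowski_binormal"
    one_sided: bool = True


def _placements(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Placement values of each x against the sample y: fraction of y
    strictly below x plus half the ties (midrank convention)."""
    ys = np.sort(y)
    below = np.searchsorted(ys, x, side="left")
    equal = np.searchsorted(ys, x, side="right") - below
    return (below + 0.5 * equal) / len(ys)


def auc_mann_whitney(
    cases: Sequence[float],
    controls: Sequence[float],
    direction: Literal["lower", "higher"] = "lower",
    se_method: Literal["delong", "hanley-mcneil"] = "delong",
    ci_level: float = 0.95,
) -> RocResult:
    """Mann-Whitney AUC with DeLong SE and normal-approximation CI.

    ``direction`` states which side of the scale disease occupies: with
    "lower" (the default; screener totals drop with impairment) the AUC is
    P(case < control) + P(tie)/2, so values above 0.5 mean cases score
    lower. Complete separation gives 1; identical samples give 0.5.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise DiagnosticsError("both groups must be non-empty")
    if direction == "lower":
        cases = -cases
        controls = -controls
    # AUC = P(case > control) + 0.5 P(=) after orientation
    v_cases = _placements(cases, controls)  # per-case placements
    v_controls = 1.0 - _placements(controls, cases)  # per-control placements
    auc = float(v_cases.mean())
    m, n = len(cases), len(controls)
    if se_method == "delong":
        s10 = v_cases.var(ddof=1) if m > 1 else 0.0
        s01 = v_controls.var(ddof=1) if n > 1 else 0.0
        se = math.sqrt(s10 / m + s01 / n)
    else:  # Hanley & McNeil (1982) binormal-exponential approximation
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        se = math.sqrt(
            (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2))
            / (m * n)
        )
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return RocResult(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        n_cases=m,
        n_controls=n,
    )


def regression_power(n_total: int, spec: PowerSpec) -> float:
    """Power of the level-alpha F(u, v) test at total sample size N, with
    v = N - u - 1 and noncentrality lambda = f^2 * N."""
    v = n_total - spec.u - 1
    if v < 1:
        return 0.0
    lam = spec.f2 * n_total
    fcrit = stats.f.isf(spec.alpha, spec.u, v)
    return float(stats.ncf.sf(fcrit, spec.u, v, lam))


def regression_min_n(spec: PowerSpec, max_n: int = 100_000) -> int:
    """Smallest total N = u + v + 1 whose noncentral-F power reaches the
    target, found by integer search over the denominator df."""
    for n_total in range(spec.u + 2, max_n + 1):
        if regression_power(n_total, spec) >= spec.power:
            return n_total
    raise DiagnosticsError(f"requested power not attainable below N={max_n}")


def _obuchowski_variance(auc: float, k: float) -> float:
    a = stats.norm.ppf(auc) * math.sqrt(2.0)
    return 0.0099 * math.exp(-(a**2) / 4.0) * ((5 * a**2 + 8) + (a**2 + 8) / k)


def roc_min_n(spec: RocSizeSpec) -> tuple[int, int]:
    """Minimum (n_cases, n_controls) for a single-test ROC study to detect
    AUC > 0.5 at the alternative ``auc_alt``."""
    alpha = spec.alpha if spec.one_sided else spec.alpha / 2
    z_a = stats.norm.ppf(1 - alpha)
    z_b = stats.norm.ppf(spec.power)
    v0 = _obuchowski_variance(0.5, spec.k)
    v1 = _obuchowski_variance(spec.auc_alt, spec.k)
    # a non-positive numerator means any single case suffices (degenerate
    # power request): floor at one case
    numer = max(z_a * math.sqrt(v0) + z_b * math.sqrt(v1), 0.0)
    n_cases = max(math.ceil(numer**2 / (spec.auc_alt - 0.5) ** 2), 1)
    return n_cases, math.ceil(spec.k * n_cases)
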