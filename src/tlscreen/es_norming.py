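"""Equivalent-Score norming: demographic adjustment, tolerance limits, ES bands.

The Equivalent Score (ES) method norms a cognitive test in three steps:

1. *Adjustment*: raw scores RS are regressed on candidate demographic
   transforms (one age-derived, one education-derived term at most, plus sex)
   by forward stepwise OLS; the adjusted score removes the fitted demographic
   effect, ``AS = RS + sum c_t * (t(x) - center_t)`` with ``c_t`` the negated
   regression slope and ``center_t`` the normative mean of the transform, so
   that AS equals RS exactly at the centering demographics.
2. *Tolerance limits*: a one-sided non-parametric interval estimate of the
   population 5th centile of adjusted scores. On the ascending sample, the
   outer limit (oTL) is the largest order statistic that lies below the 5th
   centile with 95% confidence, the inner limit (iTL) the smallest that lies
   above it with 95% confidence; both are found by exact binomial rank search.
3. *Banding*: AS <= oTL is ES=0 ("impaired"), AS >= sample median is ES=4
   ("high-end normal"); the region between is split into ES=1/2/3 at the
   empirical quantiles matching an equal split of the z interval
   [z_0.05, 0] = [-1.6449, 0] (cuts at z = -1.0966 and -0.5483, i.e. the
   13.64th and 29.17th centiles). Scores in (oTL, iTL] are ES=1 but flagged
   as inferentially non-classifiable.

A published norm table ships as a versioned JSON fixture and can be applied
to new records without refitting.
"""

from __future__ import annotations

import json
import math
import os
from importlib import resources
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

# --------------------------------------------------------------------------
# Demographic transforms
# --------------------------------------------------------------------------

class TransformError(ValueError):
    """A demographic transform is undefined for the given input."""


def _log_100_minus_age(age: float, edu: float, sex: float) -> float:
    if age >= 100:
        raise TransformError(f"ln(100 - age) undefined for age {age} >= 100")
    return math.log(100.0 - age)


def _inv_education(age: float, edu: float, sex: float) -> float:
    if edu == 0:
        raise TransformError("1/education undefined for education 0")
    return 1.0 / edu


TRANSFORMS: dict[str, Callable[[float, float, float], float]] = {
    "age": lambda a, e, s: a,
    "age2": lambda a, e, s: a**2,
    "age3": lambda a, e, s: a**3,
    "log_100_minus_age": _log_100_minus_age,
    "education": lambda a, e, s: e,
    "inv_education": _inv_education,
    "sqrt_education": lambda a, e, s: math.sqrt(e),
    "log10_education": lambda a, e, s: math.log10(e),
    "sex_male": lambda a, e, s: s,
}

AGE_TRANSFORMS = ("age", "age2", "age3", "log_100_minus_age")
EDU_TRANSFORMS = ("education", "inv_education", "sqrt_education", "log10_education")
SEX_TRANSFORMS = ("sex_male",)

#: z cuts splitting [z_{0.05}, 0] into three equal widths; the corresponding
#: normal centiles (~13.64% and ~29.17%) bound ES=1/2 and ES=2/3.
ES_INTERIOR_Z = (-1.0966, -0.5483)


def transform_features(
    age: float, education: float, sex: str | int, centers: dict[str, float]
) -> dict[str, float]:
    """Evaluate and center the transforms named in ``centers``.

    ``sex`` may be 'male'/'female' or a 0/1 male indicator. Returns
    ``{transform: t(x) - center}``; all zeros at the centering point.
    """
    s = float(sex == "male") if isinstance(sex, str) else float(sex)
    return {
        name: TRANSFORMS[name](float(age), float(education), s) - center
        for name, center in centers.items()
    }


# --------------------------------------------------------------------------
# Norm-table data model
# --------------------------------------------------------------------------

class AdjustmentTerm(BaseModel):
    model_config = ConfigDict(frozen=True)

    transform: str
    coefficient: float
    center: float

    @model_validator(mode="after")
    def _known_transform(self) -> "AdjustmentTerm":
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        return self


class AdjustmentEquation(BaseModel):
    """Per-measure demographic correction; an empty term list means the
    measure had no significant demographic predictors (AS = RS)."""

    model_config = ConfigDict(frozen=True)

    measure: str
    terms: tuple[AdjustmentTerm, ...] = ()

    @model_validator(mode="after")
    def _one_term_per_family(self) -> "AdjustmentEquation":
        for family in (AGE_TRANSFORMS, EDU_TRANSFORMS, SEX_TRANSFORMS):
            if sum(t.transform in family for t in self.terms) > 1:
                raise ValueError(
                    f"{self.measure}: at most one transform per demographic variable"
                )
        return self


class EsThresholds(BaseModel):
    """Tolerance limits and band boundaries on the adjusted-score scale.

    ``es1_upper``/``es2_upper``/``es3_upper`` are the upper bounds of bands
    ES=1..3 and ``es4_lower`` the lower bound of ES=4; a published row may
    omit interior bounds (partial band table). ``median`` is stored for
    fitted tables (it equals ``es4_lower``); published rows do not print it.
    """

    model_config = ConfigDict(frozen=True)

    oTL: float
    iTL: float
    es1_upper: Optional[float] = None
    es2_upper: Optional[float] = None
    es3_upper: Optional[float] = None
    es4_lower: float
    median: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "EsThresholds":
        if self.oTL > self.iTL:
            raise ValueError("oTL must not exceed iTL")
        bounds = [self.oTL, self.es1_upper, self.es2_upper, self.es3_upper,
                  self.es4_lower]
        present = [b for b in bounds if b is not None]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError("ES band bounds must be non-decreasing")
        return self

    @property
    def has_interior_bands(self) -> bool:
        return self.es1_upper is not None and self.es2_upper is not None


class EsResult(BaseModel):
    """ES level for one adjusted score. ``es`` is None when the norm row is
    partial and the score falls in the unavailable middle region;
    ``non_classifiable`` is True iff oTL < AS <= iTL (an ES=1 that cannot be
    inferentially judged against the cut-off)."""

    model_config = ConfigDict(frozen=True)

    es: Optional[int] = Field(default=None, ge=0, le=4)
    non_classifiable: bool = False

    @model_validator(mode="after")
    def _flag_implies_es1(self) -> "EsResult":
        if self.non_classifiable and self.es != 1:
            raise ValueError("non_classifiable scores must carry ES=1")
        return self


class MeasureNorm(BaseModel):
    model_config = ConfigDict(frozen=True)

    equation: AdjustmentEquation
    thresholds: EsThresholds


class NormTable(BaseModel):
    """Per-measure adjustment equations and ES thresholds."""

    model_config = ConfigDict(frozen=True)

    provenance: str = "fitted"
    version: str = ""
    description: str = ""
    measures: dict[str, MeasureNorm]

    def __getitem__(self, measure: str) -> MeasureNorm:
        return self.measures[measure]


# --------------------------------------------------------------------------
# Scoring with a norm table
# --------------------------------------------------------------------------

def adjust_score(
    rs: float, age: float, education: float, sex: str | int, eq: AdjustmentEquation
) -> float:
    """AS = RS + sum coefficient * (transform - center); identity for
    equation-less measures."""
    if not eq.terms:
        return float(rs)
    centers = {t.transform: t.center for t in eq.terms}
    feats = transform_features(age, education, sex, centers)
    return float(rs) + sum(t.coefficient * feats[t.transform] for t in eq.terms)


def assign_es(as_value: float, th: EsThresholds) -> EsResult:
    """Band an adjusted score: ES=0 iff AS <= oTL, ES=4 iff AS >= the ES4
    lower bound, interior bands by their upper bounds (half-open on the
    left). Partial rows return ``es=None`` between oTL and the ceiling."""
    if as_value <= th.oTL:
        return EsResult(es=0)
    if as_value >= th.es4_lower:
        return EsResult(es=4)
    nc = as_value <= th.iTL
    if not th.has_interior_bands:
        # Partial published row: only the impairment bound and the ceiling
        # are interpretable; the middle region has no printed bands.
        return EsResult(es=1, non_classifiable=True) if nc else EsResult(es=None)
    if as_value <= th.es1_upper:
        return EsResult(es=1, non_classifiable=nc)
    if as_value <= th.es2_upper:
        return EsResult(es=2)
    return EsResult(es=3)


def score_record(
    rs: float, age: float, education: float, sex: str | int, norm: MeasureNorm
) -> tuple[float, EsResult]:
    as_value = adjust_score(rs, age, education, sex, norm.equation)
    return as_value, assign_es(as_value, norm.thresholds)


def score_cohort(cohort: pd.DataFrame, table: NormTable) -> pd.DataFrame:
    """Apply a norm table to a cohort frame (columns id, age, education_years,
    sex, plus raw-score columns). Returns one row per participant with
    ``<measure>_as``, ``<measure>_es`` and ``<measure>_nc`` columns for every
    normed measure present in the input."""
    out: dict[str, list] = {"id": list(cohort["id"])}
    for measure, norm in table.measures.items():
        if measure == "total" and "total" not in cohort.columns:
            from .instrument import DEFAULT_SPEC

            names = [s.name for s in DEFAULT_SPEC.total_contributing]
            if not all(n in cohort.columns for n in names):
                continue
            raw = cohort[names].sum(axis=1)
        elif measure in cohort.columns:
            raw = cohort[measure]
        else:
            continue
        as_col, es_col, nc_col = [], [], []
        for rs, age, edu, sex in zip(
            raw, cohort["age"], cohort["education_years"], cohort["sex"]
        ):
            as_value, res = score_record(rs, age, edu, sex, norm)
            as_col.append(as_value)
            es_col.append(res.es)
            nc_col.append(res.non_classifiable)
        out[f"{measure}_as"] = as_col
        out[f"{measure}_es"] = es_col
        out[f"{measure}_nc"] = nc_col
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Fitting: stepwise adjustment regression
# --------------------------------------------------------------------------

class NormingError(ValueError):
    """Raised for infeasible or degenerate norming inputs."""


def _design_matrix(cohort: pd.DataFrame, transforms: Sequence[str]) -> np.ndarray:
    age = cohort["age"].to_numpy(dtype=float)
    edu = cohort["education_years"].to_numpy(dtype=float)
    sex = (cohort["sex"] == "male").to_numpy(dtype=float)
    cols = []
    for name in transforms:
        f = TRANSFORMS[name]
        cols.append(np.array([f(a, e, s) for a, e, s in zip(age, edu, sex)]))
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def fit_adjustment(
    cohort: pd.DataFrame, measure: str, alpha_entry: float = 0.05
) -> AdjustmentEquation:
    """Forward stepwise OLS of raw scores on demographic transforms.

    At each step the candidate (from the age, education and sex families not
    yet represented) with the smallest entry p-value below ``alpha_entry``
    joins the model; at most one transform per family. The returned equation
    negates the final OLS slopes and centers each transform at its cohort
    mean, so adding the equation's correction removes the fitted demographic
    effect.
    """
    y = cohort[measure].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise NormingError(f"{measure}: constant raw scores, nothing to fit")
    families: dict[str, Sequence[str]] = {
        "age": AGE_TRANSFORMS,
        "education": EDU_TRANSFORMS,
        "sex": SEX_TRANSFORMS,
    }
    selected: list[str] = []
    remaining = set(families)
    while remaining:
        best: Optional[tuple[float, str, str]] = None
        for fam in sorted(remaining):
            for cand in families[fam]:
                X = _design_matrix(cohort, selected + [cand])
                if np.ptp(X[:, -1]) == 0:
                    raise NormingError(f"{measure}: degenerate regressor {cand!r}")
                res = sm.OLS(y, sm.add_constant(X)).fit()
                p = res.pvalues[-1]
                if not np.isfinite(p):  # e.g. saturated fit with zero residuals
                    continue
                if best is None or p < best[0]:
                    best = (p, fam, cand)
        if best is None or best[0] >= alpha_entry:
            break
        selected.append(best[2])
        remaining.discard(best[1])
    if not selected:
        return AdjustmentEquation(measure=measure, terms=())
    X = _design_matrix(cohort, selected)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    terms = tuple(
        AdjustmentTerm(
            transform=name,
            coefficient=-float(res.params[i + 1]),
            center=float(X[:, i].mean()),
        )
        for i, name in enumerate(selected)
    )
    return AdjustmentEquation(measure=measure, terms=terms)


# --------------------------------------------------------------------------
# Non-parametric tolerance limits and ES thresholds
# --------------------------------------------------------------------------

def tolerance_limit_ranks(
    n: int, tail_p: float = 0.05, confidence: float = 0.95
) -> tuple[int, int]:
    """Ranks (1-based, ascending = worst first) of the outer and inner
    one-sided tolerance limits for the population ``tail_p`` centile.

    The outer rank is the largest r with P(Binomial(n, tail_p) >= r) >=
    confidence (the r-th order statistic lies below the centile with the
    stated confidence); the inner rank is the smallest s with
    P(Binomial(n, tail_p) <= s-1) >= confidence. Infeasible below n=59 at
    (0.05, 0.95).
    """
    if stats.binom.sf(0, n, tail_p) < confidence:
        raise NormingError(
            f"n={n} too small for a {confidence:.0%} outer tolerance limit at "
            f"tail {tail_p}"
        )
    r = np.arange(1, n + 1)
    sf = stats.binom.sf(r - 1, n, tail_p)  # P(X >= r)
    r_outer = int(r[sf >= confidence].max())
    cdf = stats.binom.cdf(r - 1, n, tail_p)  # P(X <= r-1)
    r_inner = int(r[cdf >= confidence].min())
    return r_outer, r_inner


def es_thresholds(
    adjusted_scores: Sequence[float],
    tail_p: float = 0.05,
    confidence: float = 0.95,
    interior_z: tuple[float, float] = ES_INTERIOR_Z,
) -> EsThresholds:
    """Derive ES thresholds from a normative sample of adjusted scores.

    oTL/iTL are the order statistics at the tolerance-limit ranks; ES=4
    starts at the sample median; the interior ES=1/2/3 cuts sit at the
    empirical quantiles matching the normal centiles of ``interior_z``.
    """
    x = np.sort(np.asarray(adjusted_scores, dtype=float))
    if np.ptp(x) == 0:
        raise NormingError("degenerate adjusted-score distribution (all equal)")
    r_outer, r_inner = tolerance_limit_ranks(len(x), tail_p, confidence)
    otl, itl = float(x[r_outer - 1]), float(x[r_inner - 1])
    q1, q2 = (float(np.quantile(x, stats.norm.cdf(z))) for z in interior_z)
    median = float(np.median(x))
    return EsThresholds(
        oTL=otl,
        iTL=itl,
        es1_upper=max(q1, itl),
        es2_upper=max(q2, itl),
        es3_upper=median,
        es4_lower=median,
        median=median,
    )


# --------------------------------------------------------------------------
# Norm-table construction and round-tripping
# --------------------------------------------------------------------------

def build_norm_table(
    cohort: pd.DataFrame,
    measures: Optional[Sequence[str]] = None,
    alpha_entry: float = 0.05,
    tail_p: float = 0.05,
    confidence: float = 0.95,
) -> NormTable:
    """Fit adjustment equations and ES thresholds for each measure column."""
    if measures is None:
        reserved = {"id", "age", "education_years", "sex"}
        measures = [c for c in cohort.columns if c not in reserved]
    out: dict[str, MeasureNorm] = {}
    for m in measures:
        eq = fit_adjustment(cohort, m, alpha_entry=alpha_entry)
        as_values = np.array(
            [
                adjust_score(rs, age, edu, sex, eq)
                for rs, age, edu, sex in zip(
                    cohort[m], cohort["age"], cohort["education_years"], cohort["sex"]
                )
            ]
        )
        th = es_thresholds(as_values, tail_p=tail_p, confidence=confidence)
        out[m] = MeasureNorm(equation=eq, thresholds=th)
    return NormTable(provenance="fitted", measures=out)


def _table_to_dict(table: NormTable) -> dict:
    return {
        "provenance": table.provenance,
        "version": table.version,
        "description": table.description,
        "measures": {
            m: {
                "terms": [t.model_dump() for t in norm.equation.terms],
                "thresholds": norm.thresholds.model_dump(),
            }
            for m, norm in table.measures.items()
        },
    }


def _table_from_dict(data: dict) -> NormTable:
    measures = {
        m: MeasureNorm(
            equation=AdjustmentEquation(
                measure=m, terms=tuple(AdjustmentTerm(**t) for t in entry["terms"])
            ),
            thresholds=EsThresholds(**entry["thresholds"]),
        )
        for m, entry in data["measures"].items()
    }
    return NormTable(
        provenance=data.get("provenance", "fitted"),
        version=data.get("version", ""),
        description=data.get("description", ""),
        measures=measures,
    )


def save_norm_table(table: NormTable, path: str) -> None:
    """JSON round-trip is bit-exact: floats serialised at full repr precision,
    written atomically (write-then-rename)."""
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(_table_to_dict(table), fh, indent=1)
    os.replace(tmp, path)


def load_norm_table(path: Optional[str] = None) -> NormTable:
    """Load a norm table from JSON; with no path, the packaged published
    fixture (version v1)."""
    if path is None:
        text = (
            resources.files("tlscreen")
            .joinpath("data/norm_table_published_v1.json")
            .read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return _table_from_dict(json.loads(text))


PUBLISHED_NORM_TABLE = load_norm_table()
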