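"""Reliability and validity statistics for the screener battery.

Covers the standardization study's reliability/validity surface: Spearman
rank correlations with Bonferroni multiplicity control (most screener scores
are heavily skewed, so rank correlation is the default association measure),
two-way random-effects absolute-agreement single-measure ICC for test-retest
and inter-rater designs, McDonald's omega from a one-factor maximum-
likelihood solution, item-rest correlations, and a correlation-matrix PCA
for the mono-component check.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.decomposition import FactorAnalysis


class PsychometricsError(ValueError):
    pass


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PsychometricsError("paired measures must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_test(x, y) -> tuple[float, float, int]:
    """Spearman rho with midrank ties and the large-sample t approximation
    p-value; missing data excluded pairwise. Returns (rho, p, n)."""
    x, y = _complete_pairs(x, y)
    if len(x) < 3:
        raise PsychometricsError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PsychometricsError("correlation undefined for a constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), int(len(x))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha / m."""
    if m < 1:
        raise PsychometricsError("number of comparisons must be >= 1")
    return alpha / m


def icc_agreement(block: np.ndarray | pd.DataFrame) -> tuple[float, float, float]:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    ``block`` is subjects x raters/occasions. Returns (icc, ci_low, ci_high)
    with the F-distribution confidence bounds. Identical columns give 1;
    zero between-subject variance is undefined and raises.
    """
    arr = np.asarray(block, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise PsychometricsError("need at least 2 subjects and 2 raters")
    n, k = arr.shape
    if np.ptp(arr.mean(axis=1)) == 0:
        raise PsychometricsError("zero between-subject variance: ICC undefined")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": arr.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
    res = res.set_index("Type")
    # label differs across pingouin versions: ICC2 == ICC(A,1)
    key = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    ci_col = "CI95" if "CI95" in res.columns else "CI95%"
    row = res.loc[key]
    icc = float(row["ICC"])
    ci_low, ci_high = (float(v) for v in row[ci_col])
    if np.isnan(icc):
        raise PsychometricsError("ICC undefined for this ratings block")
    return icc, ci_low, ci_high


def omega_from_loadings(loadings: Sequence[float], uniquenesses: Sequence[float]) -> float:
    """McDonald's omega from a one-factor solution:
    (sum lambda)^2 / ((sum lambda)^2 + sum psi)."""
    lam = np.asarray(loadings, dtype=float)
    psi = np.asarray(uniquenesses, dtype=float)
    s = lam.sum()
    return float(s**2 / (s**2 + psi.sum()))


def mcdonald_omega(scores: np.ndarray | pd.DataFrame) -> float:
    """McDonald's omega from a one-factor maximum-likelihood factor model on
    the subtest covariance structure.

    A Heywood case (near-zero uniqueness) is reported via a warning naming
    the offending subtest; omega is still returned.
    """
    frame = pd.DataFrame(scores)
    arr = frame.to_numpy(dtype=float)
    if arr.shape[1] < 3:
        raise PsychometricsError("omega needs at least 3 subtests")
    fa = FactorAnalysis(n_components=1, random_state=0)
    fa.fit(arr)
    lam = fa.components_[0].copy()
    if lam.mean() < 0:
        lam = -lam
    psi = fa.noise_variance_
    heywood = np.where(psi <= 1e-6)[0]
    if heywood.size:
        names = [str(frame.columns[i]) for i in heywood]
        warnings.warn(
            f"Heywood case: near-zero uniqueness for subtest(s) {names}",
            stacklevel=2,
        )
    return omega_from_loadings(lam, psi)


def item_rest_correlations(scores: np.ndarray | pd.DataFrame) -> pd.Series:
    """Pearson correlation of each subtest with the total of the remaining
    subtests (rest score)."""
    frame = pd.DataFrame(scores)
    arr = frame.to_numpy(dtype=float)
    total = arr.sum(axis=1)
    out = {}
    for i, col in enumerate(frame.columns):
        rest = total - arr[:, i]
        if np.ptp(arr[:, i]) == 0 or np.ptp(rest) == 0:
            raise PsychometricsError(f"constant column {col!r}")
        out[col] = float(np.corrcoef(arr[:, i], rest)[0, 1])
    return pd.Series(out, name="item_rest_r")


def pca_first_component(
    scores: np.ndarray | pd.DataFrame,
) -> tuple[float, np.ndarray]:
    """Leading component of the subtest correlation matrix.

    Returns (variance_fraction, loadings): the leading eigenvalue over the
    number of subtests, and the leading eigenvector scaled by the square
    root of its eigenvalue (sign fixed so the mean loading is positive).
    The correlation metric puts subtests with heterogeneous ranges on a
    common scale.
    """
    arr = pd.DataFrame(scores).to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise PsychometricsError("PCA needs at least 2 subtests")
    if any(np.ptp(arr[:, j]) == 0 for j in range(arr.shape[1])):
        raise PsychometricsError("constant column in PCA input")
    corr = np.corrcoef(arr, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = np.argmax(eigvals)
    lam, vec = float(eigvals[lead]), eigvecs[:, lead]
    if vec.mean() < 0:
        vec = -vec
    return lam / arr.shape[1], vec * np.sqrt(lam)
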