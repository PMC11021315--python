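"""Two-parameter logistic IRT calibration with marginal maximum likelihood.

The item response function is P(correct | theta) = logistic(a * (theta - b))
with discrimination a and difficulty b (slope-location parameterization,
matching how screening studies report item properties). Abilities are
integrated out against a fixed standard-normal prior (identification) on an
equally spaced quadrature grid, and items are updated by a Newton M-step on
the expected complete-data log-likelihood (Bock-Aitkin EM). The marginal
log-likelihood is asserted non-decreasing at every iteration.

Classification follows the conventional screening bands: difficulty <= -3
"extremely easy", within (-3, 3) "typical", >= 3 "extremely difficult";
discrimination < 0.65 "low", 0.65-1.34 "moderate", >= 1.35 "high" and
strictly above 1.7 "extremely high".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit


class IrtError(ValueError):
    pass


def p_correct(theta, a, b):
    """2-PL item response function, logistic(a * (theta - b)); vectorized."""
    return expit(np.asarray(a) * (np.asarray(theta) - np.asarray(b)))


def dichotomize(raw_item_scores: Sequence[float], percentile: float = 5.0) -> np.ndarray:
    """Binarize polytomous item scores at the empirical ``percentile``-th
    percentile (linear interpolation): 1 iff the raw score is at or above the
    cut, 0 below it. An all-constant input therefore maps to all 1s (the cut
    coincides with the common value); documented edge."""
    x = np.asarray(raw_item_scores, dtype=float)
    if x.size == 0:
        raise IrtError("empty score list")
    cut = np.percentile(x, percentile)
    return (x >= cut).astype(int)


def classify_item(a: float, b: float) -> tuple[str, str]:
    """(difficulty_class, discrimination_class) under the screening bands."""
    if b <= -3:
        dc = "extremely easy"
    elif b >= 3:
        dc = "extremely difficult"
    else:
        dc = "typical"
    if a > 1.7:
        ac = "extremely high"
    elif a >= 1.35:
        ac = "high"
    elif a >= 0.65:
        ac = "moderate"
    else:
        ac = "low"
    return dc, ac


@dataclass(frozen=True)
class ItemResponseMatrix:
    """Persons x items binary responses; NaN marks missing. All-constant
    columns are detected at fit time and reported as "n.a." rather than
    passed to the optimizer."""

    responses: np.ndarray
    item_labels: tuple[str, ...]

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "ItemResponseMatrix":
        arr = frame.to_numpy(dtype=float)
        return ItemResponseMatrix(arr, tuple(str(c) for c in frame.columns))

    def __post_init__(self):
        r = self.responses
        if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
            raise IrtError("need at least 2 persons and 2 items")
        vals = r[~np.isnan(r)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise IrtError("responses must be 0, 1 or missing")
        if len(self.item_labels) != r.shape[1]:
            raise IrtError("item_labels length mismatch")


@dataclass(frozen=True)
class IrtItemEstimate:
    label: str
    a: Optional[float]
    b: Optional[float]
    se_a: Optional[float] = None
    se_b: Optional[float] = None
    difficulty_class: Optional[str] = None
    discrimination_class: Optional[str] = None
    status: str = "ok"  # ok | unstable | na


@dataclass(frozen=True)
class Fit2plResult:
    items: tuple[IrtItemEstimate, ...]
    loglik_history: tuple[float, ...]
    converged: bool
    n_iter: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(i) for i in self.items])


def _quadrature(n_nodes: int, span: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced nodes on [-span, span] weighted by the standard-normal
    density (normalized) — the conventional fixed grid for marginal ML."""
    t = np.linspace(-span, span, n_nodes)
    w = np.exp(-0.5 * t**2)
    return t, w / w.sum()


def _item_newton(
    alpha: float, beta: float, t: np.ndarray, r: np.ndarray, n: np.ndarray,
    n_steps: int = 5,
) -> tuple[float, float]:
    """Maximize sum_q r*log p + (n-r)*log(1-p), p = expit(alpha*t + beta),
    by damped Newton; guaranteed not to decrease the objective (step halving),
    which keeps the generalized EM monotone."""

    def obj(al, be):
        eta = al * t + be
        return float(np.sum(r * log_expit(eta) + (n - r) * log_expit(-eta)))

    cur = obj(alpha, beta)
    for _ in range(n_steps):
        p = expit(alpha * t + beta)
        resid = r - n * p
        g = np.array([np.sum(resid * t), np.sum(resid)])
        wq = n * p * (1.0 - p)
        H = -np.array(
            [[np.sum(wq * t * t), np.sum(wq * t)], [np.sum(wq * t), np.sum(wq)]]
        )
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(20):
            new = obj(alpha + scale * step[0], beta + scale * step[1])
            if new >= cur:
                alpha += scale * step[0]
                beta += scale * step[1]
                cur = new
                break
            scale *= 0.5
        else:
            break
    return alpha, beta


def _item_se(alpha: float, beta: float, t, r, n) -> tuple[float, float]:
    """Delta-method SEs for (a, b) = (alpha, -beta/alpha) from the expected
    complete-data information of the M-step objective."""
    p = expit(alpha * t + beta)
    wq = n * p * (1.0 - p)
    info = np.array([[np.sum(wq * t * t), np.sum(wq * t)], [np.sum(wq * t), np.sum(wq)]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.inf, np.inf
    jac = np.array([[1.0, 0.0], [beta / alpha**2, -1.0 / alpha]])
    cov_ab = jac @ cov @ jac.T
    return float(np.sqrt(max(cov_ab[0, 0], 0.0))), float(np.sqrt(max(cov_ab[1, 1], 0.0)))


def fit_2pl(
    matrix: ItemResponseMatrix | pd.DataFrame,
    n_quadrature: int = 61,
    max_iter: int = 500,
    tol: float = 1e-4,
    instability_b: float = 8.0,
    instability_se: float = 10.0,
) -> Fit2plResult:
    """Marginal-ML 2-PL calibration by Bock-Aitkin EM.

    Missing responses are omitted from the likelihood (assumed ignorable).
    All-constant items are excluded from fitting and reported with status
    "n.a."; items converging to |b| > ``instability_b`` with SE above
    ``instability_se`` are flagged "unstable" but kept. Fewer than ~250
    persons triggers a sample-size warning (rule of thumb for stable 2-PL
    estimates), not an error. Non-convergence after ``max_iter`` returns the
    last iterate with ``converged=False``.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = ItemResponseMatrix.from_frame(matrix)
    X = matrix.responses
    n_persons, n_items = X.shape
    if n_persons < 250:
        import warnings

        warnings.warn(
            f"{n_persons} persons is below the ~250 rule of thumb for a stable "
            "2-PL calibration",
            stacklevel=2,
        )
    obs = ~np.isnan(X)
    active = np.array(
        [
            obs[:, j].any() and 0.0 < float(np.nanmean(X[:, j])) < 1.0
            for j in range(n_items)
        ]
    )

    Xa = np.nan_to_num(X[:, active])
    Ma = obs[:, active].astype(float)
    MX = Ma * Xa
    M1mX = Ma * (1.0 - Xa)
    J = int(active.sum())
    if J < 2:
        raise IrtError("fewer than 2 non-degenerate items")

    t, A = _quadrature(n_quadrature)
    logA = np.log(A)
    # classical starts: unit slopes, intercept from the observed proportion
    pj = np.clip(np.nanmean(X[:, active], axis=0), 1e-3, 1 - 1e-3)
    alpha = np.ones(J)
    beta = np.log(pj / (1 - pj))

    loglik_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = alpha[:, None] * t[None, :] + beta[:, None]  # J x Q
        logP, log1mP = log_expit(eta), log_expit(-eta)
        logL = MX @ logP + M1mX @ log1mP + logA[None, :]  # n x Q
        m = logL.max(axis=1, keepdims=True)
        w = np.exp(logL - m)
        denom = w.sum(axis=1, keepdims=True)
        ll = float(np.sum(m.squeeze(1) + np.log(denom.squeeze(1))))
        if loglik_history and ll < loglik_history[-1] - 1e-6 * abs(loglik_history[-1]):
            raise IrtError(
                f"EM marginal log-likelihood decreased at iteration {it}: "
                f"{loglik_history[-1]} -> {ll}"
            )
        loglik_history.append(ll)
        W = w / denom  # posterior weights, n x Q
        n_jq = Ma.T @ W
        r_jq = MX.T @ W
        old = np.concatenate([alpha / 1.0, -beta / alpha])
        for j in range(J):
            alpha[j], beta[j] = _item_newton(alpha[j], beta[j], t, r_jq[j], n_jq[j])
        new = np.concatenate([alpha, -beta / alpha])
        if np.max(np.abs(new - old)) < tol:
            converged = True
            break

    # expected counts at the final parameters, for the standard errors
    eta = alpha[:, None] * t[None, :] + beta[:, None]
    logL = MX @ log_expit(eta) + M1mX @ log_expit(-eta) + logA[None, :]
    m = logL.max(axis=1, keepdims=True)
    w = np.exp(logL - m)
    W = w / w.sum(axis=1, keepdims=True)
    n_jq = Ma.T @ W
    r_jq = MX.T @ W

    items: list[IrtItemEstimate] = []
    k = 0
    for j, label in enumerate(matrix.item_labels):
        if not active[j]:
            items.append(IrtItemEstimate(label=label, a=None, b=None, status="na"))
            continue
        a_j, b_j = float(alpha[k]), float(-beta[k] / alpha[k])
        se_a, se_b = _item_se(alpha[k], beta[k], t, r_jq[k], n_jq[k])
        dc, ac = classify_item(a_j, b_j)
        status = (
            "unstable"
            if (abs(b_j) > instability_b and se_b > instability_se)
            else "ok"
        )
        items.append(
            IrtItemEstimate(
                label=label, a=a_j, b=b_j, se_a=se_a, se_b=se_b,
                difficulty_class=dc, discrimination_class=ac, status=status,
            )
        )
        k += 1
    return Fit2plResult(
        items=tuple(items),
        loglik_history=tuple(loglik_history),
        converged=converged,
        n_iter=it,
    )
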