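"""Fixed-ratio 1:k optimal propensity-score matching.

Cases are matched to exactly k controls each, without replacement, by
minimizing the *total* distance over all assignments (optimal matching, as
opposed to greedy nearest-neighbour matching which fixes one case at a
time).  Distance is the absolute difference of propensity scores on the
logit scale, the standard choice.  The assignment problem is solved exactly
as a minimum-cost bipartite matching after replicating each case k times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment

from .types import PipelineError

log = logging.getLogger(__name__)

RIDGE_PENALTY = 1e-4


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]          # (case_id, control_id)
    ratio: int
    total_distance: float
    distances: list[float] = field(default_factory=list)  # per pair, |logit gap|
    balance: pd.DataFrame | None = None   # per-covariate SMD before/after
    meta: dict = field(default_factory=dict)

    def matched_controls(self) -> list[str]:
        return [c for _, c in self.pairs]


def _ridge_logit(X: np.ndarray, y: np.ndarray,
                 penalty: float = RIDGE_PENALTY) -> np.ndarray:
    """Ridge-penalized logistic fit by IRLS (intercept unpenalized)."""
    beta = np.zeros(X.shape[1])
    pen = np.full(X.shape[1], penalty)
    pen[0] = 0.0
    for _ in range(200):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p) - pen * beta
        H = (X.T * W) @ X + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.linalg.norm(grad) < 1e-8:
            break
    return beta


def estimate_propensity(covariates: pd.DataFrame,
                        case_indicator: np.ndarray | pd.Series) -> pd.Series:
    """Propensity scores from a logistic model of case status on covariates.

    Categorical columns are dummy-coded (sex as a 0/1 indicator and so on).
    Fitting is by iteratively reweighted least squares; on perfect
    separation or non-convergence a mildly ridge-penalized fit is used
    instead, with a logged warning.  Missing covariate rows must be excluded
    upstream.
    """
    if covariates.isna().any().any():
        raise PipelineError("missing covariate values; exclude rows upstream")
    X = pd.get_dummies(covariates, drop_first=True).astype(float)
    X = sm.add_constant(X, has_constant="add")
    y = np.asarray(case_indicator, dtype=float)
    Xv = X.to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.GLM(y, Xv, family=sm.families.Binomial()).fit(
                tol=1e-10, maxiter=200)
        scores = np.asarray(res.fittedvalues)
        if not np.isfinite(scores).all():
            raise ValueError("non-finite fitted values")
    except Exception:
        log.warning("logistic fit failed (separation or non-convergence); "
                    "falling back to ridge penalty %.0e", RIDGE_PENALTY)
        beta = _ridge_logit(Xv, y)
        scores = 1.0 / (1.0 + np.exp(-(Xv @ beta)))
    eps = 1e-12
    scores = np.clip(scores, eps, 1 - eps)
    return pd.Series(scores, index=covariates.index, name="propensity")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def optimal_fixed_ratio_match(scores: pd.Series,
                              case_ids: list[str],
                              control_ids: list[str],
                              k: int) -> MatchResult:
    """Optimal 1:k matching without replacement on the logit-propensity scale.

    Each case is replicated k times and the resulting bipartite assignment
    problem is solved exactly, so the returned total distance is the global
    minimum.  Ordering of cases and controls is lexicographic, which makes
    tie-breaking deterministic.
    """
    case_ids = sorted(case_ids)
    control_ids = sorted(control_ids)
    n_cases, n_controls = len(case_ids), len(control_ids)
    if n_controls < k * n_cases:
        raise PipelineError(
            f"insufficient controls: need {k * n_cases} "
            f"(k={k} x {n_cases} cases), have {n_controls} "
            f"(short by {k * n_cases - n_controls})")
    lc = _logit(scores.loc[case_ids].to_numpy())
    lk = _logit(scores.loc[control_ids].to_numpy())
    cost = np.abs(np.repeat(lc, k)[:, None] - lk[None, :])
    rows, cols = linear_sum_assignment(cost)
    matched = sorted(
        ((case_ids[r // k], control_ids[c]), float(cost[r, c]))
        for r, c in zip(rows, cols))
    pairs = [m[0] for m in matched]
    distances = [m[1] for m in matched]
    return MatchResult(pairs=pairs, ratio=k,
                       total_distance=float(cost[rows, cols].sum()),
                       distances=distances,
                       meta={"n_cases": n_cases, "n_controls": n_controls})


def greedy_fixed_ratio_match(scores: pd.Series,
                             case_ids: list[str],
                             control_ids: list[str],
                             k: int) -> MatchResult:
    """Greedy nearest-neighbour 1:k matching (baseline for comparison only)."""
    case_ids = sorted(case_ids)
    control_ids = sorted(control_ids)
    if len(control_ids) < k * len(case_ids):
        raise PipelineError("insufficient controls for greedy matching")
    lc = {c: v for c, v in zip(case_ids,
                               _logit(scores.loc[case_ids].to_numpy()))}
    avail = dict(zip(control_ids, _logit(scores.loc[control_ids].to_numpy())))
    pairs, total = [], 0.0
    for case in case_ids:
        for _ in range(k):
            ctrl = min(avail, key=lambda c: (abs(avail[c] - lc[case]), c))
            total += abs(avail[ctrl] - lc[case])
            pairs.append((case, ctrl))
            del avail[ctrl]
    return MatchResult(pairs=sorted(pairs), ratio=k, total_distance=total)


def balance_diagnostics(covariates: pd.DataFrame,
                        case_ids: list[str],
                        control_ids: list[str],
                        result: MatchResult) -> pd.DataFrame:
    """Standardized mean differences per covariate, before and after matching.

    SMD = (mean_case - mean_control) / pooled SD; a zero pooled SD yields an
    SMD of 0 with a warning (the covariate carries no information).
    """
    X = pd.get_dummies(covariates, drop_first=True).astype(float)
    matched = result.matched_controls()
    rows = {}
    for col in X.columns:
        rows[col] = {
            "smd_before": _smd(X.loc[case_ids, col],
                               X.loc[control_ids, col]),
            "smd_after": _smd(X.loc[case_ids, col], X.loc[matched, col]),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "covariate"
    return out


def _smd(a: pd.Series, b: pd.Series) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if not np.isfinite(pooled) or pooled == 0:
        warnings.warn("zero pooled SD; reporting SMD 0")
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def match_controls(covariates: pd.DataFrame,
                   case_ids: list[str],
                   control_ids: list[str],
                   match_on: list[str],
                   k: int = 5) -> MatchResult:
    """End-to-end: propensity model on ``match_on``, optimal 1:k matching,
    balance diagnostics."""
    ids = list(case_ids) + list(control_ids)
    cov = covariates.loc[ids, match_on].dropna()
    kept_cases = [i for i in case_ids if i in cov.index]
    kept_controls = [i for i in control_ids if i in cov.index]
    indicator = cov.index.isin(kept_cases).astype(float)
    scores = estimate_propensity(cov, indicator)
    result = optimal_fixed_ratio_match(scores, kept_cases, kept_controls, k)
    result.balance = balance_diagnostics(cov, kept_cases, kept_controls,
                                         result)
    return result
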