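"""Point-wise group comparisons of directional asymmetry.

For every template point a multivariable linear model relates the
per-participant asymmetry to a group indicator plus covariates (age, sex,
total intracranial volume, and dementia severity as CDR-global where both
groups are cognitively impaired).  P-values for all points of *all*
comparisons of one structure are pooled into a single Benjamini-Hochberg
family — 512 x 6 = 3072 tests for the hippocampus and 256 x 6 = 1536 for
the amygdala — before thresholding at q < 0.05.

Sign labels follow the rendering convention: ``left_larger`` for a positive
adjusted group difference in left-minus-right asymmetry (group_a minus
group_b), ``left_smaller`` for a negative one.  A one-group mode tests the
covariate-adjusted mean asymmetry against zero (used for the baseline
hemispheric asymmetry of healthy controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .asymmetry import AsymmetryTable
from .types import PipelineError

ALPHA = 0.05
BASE_COVARIATES = ("age_at_scan", "sex", "tiv")
SENSITIVITY_COVARIATES = ("field_strength", "voxel_volume")


@dataclass(frozen=True)
class ComparisonSpec:
    """One group comparison (or one-group mean test) with its covariates."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...] = ()
    covariates: tuple[str, ...] = BASE_COVARIATES
    mode: str = "two_group"

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", tuple(np.atleast_1d(self.group_a)))
        object.__setattr__(self, "group_b", tuple(np.atleast_1d(self.group_b)))
        if self.mode == "two_group":
            if not self.group_a or not self.group_b:
                raise ValueError("two_group comparison needs both groups")
            if set(self.group_a) & set(self.group_b):
                raise ValueError("comparison groups must be disjoint")
        elif self.mode == "one_group":
            if not self.group_a or self.group_b:
                raise ValueError("one_group mode takes group_a only")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


def default_comparisons(sensitivity: bool = False) -> list[ComparisonSpec]:
    """The six study comparisons.

    Epilepsy-vs-no-epilepsy contrasts adjust for age, sex, TIV and CDR-global;
    contrasts against healthy controls adjust for age, sex and TIV.  In
    sensitivity mode MRI field strength and voxel volume are appended to
    every design.
    """
    cog = BASE_COVARIATES + ("cdr_global",)
    hc = BASE_COVARIATES
    if sensitivity:
        cog = cog + SENSITIVITY_COVARIATES
        hc = hc + SENSITIVITY_COVARIATES
    return [
        ComparisonSpec("AD_Epi_vs_AD_NoEpi", ("AD_Epi",), ("AD_NoEpi",), cog),
        ComparisonSpec("nonAD_Epi_vs_nonAD_NoEpi", ("nonAD_Epi",),
                       ("nonAD_NoEpi",), cog),
        ComparisonSpec("AD_Epi_vs_HC", ("AD_Epi",), ("HC",), hc),
        ComparisonSpec("nonAD_Epi_vs_HC", ("nonAD_Epi",), ("HC",), hc),
        ComparisonSpec("AD_NoEpi_vs_HC", ("AD_NoEpi",), ("HC",), hc),
        ComparisonSpec("nonAD_NoEpi_vs_HC", ("nonAD_NoEpi",), ("HC",), hc),
    ]


def hc_baseline_comparison(sensitivity: bool = False) -> ComparisonSpec:
    """Within-HC test of mean hemispheric asymmetry against zero."""
    cov = BASE_COVARIATES + (SENSITIVITY_COVARIATES if sensitivity else ())
    return ComparisonSpec("HC_baseline", ("HC",), (), cov, mode="one_group")


# ---------------------------------------------------------------------------
# design construction and OLS
# ---------------------------------------------------------------------------

def _encode(covariates: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    X = covariates.loc[:, list(cols)].copy()
    if "sex" in X:
        X["sex"] = (X["sex"] == "male").astype(float)
    return X.astype(float)


def build_design(covariates: pd.DataFrame,
                 spec: ComparisonSpec) -> tuple[pd.Index, np.ndarray, int]:
    """Rows, design matrix, and index of the tested coefficient.

    Rows with any missing covariate are excluded.  Two-group designs are
    ``[1, group_a_indicator, covariates...]`` and test the indicator;
    one-group designs are ``[1, centred covariates...]`` and test the
    intercept (the covariate-adjusted mean).
    """
    if spec.mode == "two_group":
        in_a = covariates["group"].isin(spec.group_a)
        in_b = covariates["group"].isin(spec.group_b)
        sub = covariates[in_a | in_b]
    else:
        sub = covariates[covariates["group"].isin(spec.group_a)]
    X = _encode(sub, spec.covariates)
    keep = ~X.isna().any(axis=1)
    X, sub = X[keep], sub[keep]
    n = len(sub)
    min_n = len(spec.covariates) + 2
    if spec.mode == "two_group":
        n_a = int(sub["group"].isin(spec.group_a).sum())
        n_b = n - n_a
        if min(n_a, n_b) < min_n:
            raise PipelineError(
                f"comparison {spec.name}: too few participants "
                f"(group sizes {n_a}/{n_b}, need >= {min_n} each)")
        cols = [np.ones(n), sub["group"].isin(spec.group_a).to_numpy(float)]
        cols += [X[c].to_numpy() for c in X.columns]
        test_idx = 1
    else:
        if n < min_n:
            raise PipelineError(
                f"comparison {spec.name}: too few participants (n={n})")
        cols = [np.ones(n)]
        cols += [(X[c] - X[c].mean()).to_numpy() for c in X.columns]
        test_idx = 0
    design = np.column_stack(cols)
    # drop collinear covariate columns (never the intercept or the tested one)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        keep_cols = [0, 1] if spec.mode == "two_group" else [0]
        for j in range(design.shape[1]):
            if j in keep_cols:
                continue
            trial = keep_cols + [j]
            if np.linalg.matrix_rank(design[:, trial]) == len(trial):
                keep_cols = trial
        dropped = design.shape[1] - len(keep_cols)
        warnings.warn(f"comparison {spec.name}: dropped {dropped} collinear "
                      "design column(s)")
        design = design[:, sorted(keep_cols)]
        test_idx = sorted(keep_cols).index(test_idx)
    return sub.index, design, test_idx


def _ols_multi(X: np.ndarray, Y: np.ndarray, test_idx: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of every column of Y on X; t-test on one coefficient.

    Returns (beta, se, t, p, zero_variance_flag), each of length Y.shape[1].
    Points with (numerically) zero residual variance get p = 1 and are
    flagged rather than dropped, keeping the test family size fixed.
    """
    n, p = X.shape
    df = n - p
    if df < 1:
        raise PipelineError("not enough observations for the design")
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    scale = max(np.mean(np.abs(Y)), 1.0)
    zero_var = rss < (1e-10 * scale) ** 2 * n
    sigma2 = rss / df
    beta = coef[test_idx]
    se = np.sqrt(XtX_inv[test_idx, test_idx] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        pvals = 2.0 * sps.t.sf(np.abs(t), df)
    pvals = np.where(zero_var, 1.0, pvals)
    t = np.where(zero_var, 0.0, t)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return beta, se, t, pvals, zero_var


def fit_point_glm(y: np.ndarray, design: np.ndarray,
                  test_idx: int = 1) -> tuple[float, float, float, float]:
    """OLS fit at a single point: (beta, se, t, two-sided p) for one coefficient."""
    beta, se, t, p, _ = _ols_multi(np.asarray(design, float),
                                   np.asarray(y, float).reshape(-1, 1),
                                   test_idx)
    return float(beta[0]), float(se[0]), float(t[0]), float(p[0])


def run_comparison(asym: AsymmetryTable, covariates: pd.DataFrame,
                   spec: ComparisonSpec) -> pd.DataFrame:
    """Fit the point-wise model at every template point for one comparison."""
    rows, X, test_idx = build_design(covariates, spec)
    missing = rows.difference(asym.point_asym.index)
    if len(missing):
        raise PipelineError(
            f"{len(missing)} participants of {spec.name} lack asymmetry data")
    Y = asym.point_asym.loc[rows].to_numpy(float)
    beta, se, t, p, zero_var = _ols_multi(X, Y, test_idx)
    return pd.DataFrame({
        "comparison": spec.name,
        "point": np.arange(asym.n_points),
        "beta": beta, "se": se, "t": t, "p": p,
        "zero_variance": zero_var,
        "n": X.shape[0],
    })


# ---------------------------------------------------------------------------
# FDR and significance maps
# ---------------------------------------------------------------------------

def family_size(M: int, n_comparisons: int) -> int:
    """Size of the pooled BH family: points x comparisons (e.g. 512 x 6 = 3072)."""
    if M < 1 or n_comparisons < 1:
        raise ValueError("family dimensions must be >= 1")
    return M * n_comparisons


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q(i) = min over j >= i of m * p(j) / j after sorting ascending, clipped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def run_family(asym: AsymmetryTable, covariates: pd.DataFrame,
               specs: list[ComparisonSpec],
               alpha: float = ALPHA,
               pooled: bool = True) -> pd.DataFrame:
    """All comparisons with one pooled BH correction per structure.

    With ``pooled=False`` each comparison is corrected separately
    (non-default; provided for sensitivity checks of the pooling choice).
    """
    frames = [run_comparison(asym, covariates, s) for s in specs]
    out = pd.concat(frames, ignore_index=True)
    if pooled:
        out["q"] = fdr_bh(out["p"].to_numpy())
    else:
        out["q"] = np.nan
        for name in out["comparison"].unique():
            sel = out["comparison"] == name
            out.loc[sel, "q"] = fdr_bh(out.loc[sel, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out["sign"] = np.where(out["beta"] > 0, "left_larger", "left_smaller")
    out["family_size"] = len(out) if pooled else asym.n_points
    return out


def significance_map(results: pd.DataFrame,
                     alpha: float = ALPHA) -> pd.DataFrame:
    """Per (comparison, point) label: nonsig / left_larger / left_smaller."""
    lab = np.where(results["q"] < alpha,
                   np.where(results["beta"] > 0, "left_larger",
                            "left_smaller"),
                   "nonsig")
    out = results[["comparison", "point"]].copy()
    out["label"] = lab
    return out


# ---------------------------------------------------------------------------
# volume-asymmetry group tests
# ---------------------------------------------------------------------------

def volume_group_test(asym: AsymmetryTable, covariates: pd.DataFrame,
                      spec: ComparisonSpec) -> dict:
    """Unadjusted two-sample t-test plus covariate-adjusted linear model."""
    rows, X, test_idx = build_design(covariates, spec)
    v = asym.volume_asym.loc[rows].to_numpy(float)
    if spec.mode != "two_group":
        raise PipelineError("volume test is defined for two-group specs")
    in_a = covariates.loc[rows, "group"].isin(spec.group_a).to_numpy()
    va, vb = v[in_a], v[~in_a]
    if np.var(va) == 0 and np.var(vb) == 0 and np.mean(va) == np.mean(vb):
        warnings.warn("zero variance in both groups; volume test degenerate")
        t_p = 1.0
    else:
        t_p = float(sps.ttest_ind(va, vb).pvalue)
    beta, se, t, p, zero_var = _ols_multi(X, v.reshape(-1, 1), test_idx)
    return {"comparison": spec.name,
            "mean_a": float(va.mean()), "mean_b": float(vb.mean()),
            "t_test_p_unadjusted": t_p,
            "glm_p_adjusted": float(p[0]),
            "beta": float(beta[0]),
            "zero_variance": bool(zero_var[0])}
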