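"""Per-animal regressions, random-intercept mixed models, and summaries.

The mixed model is the random-intercept Gaussian LMM

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),
                                      e_ij ~ N(0, sigma_e^2),

fitted by maximum likelihood (not REML: every reported inference is a
fixed-effect likelihood-ratio test, and ML likelihoods are the ones that
are comparable across fixed-effect designs).  For a given variance ratio
lambda = sigma_b^2 / sigma_e^2 both beta and sigma_e^2 have closed-form
profiles, so the fit is a one-dimensional search over lambda; the lambda=0
boundary (no between-group variance) is always evaluated explicitly.

Cohort summaries follow the means-of-individual-means convention: each
animal contributes one number per cell, then animals are averaged.  This
guards against pseudo-replication when animals contribute unequal numbers
of hops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar


@dataclass
class RegressionFit:
    animal_id: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_hops: int


@dataclass
class LMMFit:
    fixed_effects: dict[str, float]   # design column name -> ML estimate
    sigma_b: float                    # between-group SD (response units)
    sigma_e: float                    # residual SD
    loglik_ml: float
    n_obs: int
    n_groups: int
    converged: bool
    design: np.ndarray = field(repr=False, default=None)
    response: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_effects)


@dataclass
class LRTResult:
    chi_sq: float
    df: int
    p_value: float


def per_animal_regression(metrics: pd.DataFrame,
                          response: str = "alpha_td",
                          predictor: str = "gamma_td",
                          min_hops: int = 3) -> list[RegressionFit]:
    """OLS of ``response`` on ``predictor`` within each animal.

    Only included hops with finite values enter; the p-value is the
    two-sided test of zero slope.
    """
    fits = []
    table = metrics[metrics["included"]] if "included" in metrics else metrics
    for animal, sub in table.groupby("animal_id", sort=True):
        sub = sub[[response, predictor]].dropna()
        if len(sub) < min_hops:
            continue
        x = sub[predictor].to_numpy(dtype=float)
        y = sub[response].to_numpy(dtype=float)
        if np.ptp(x) < 1e-12:
            raise ValueError(
                f"degenerate predictor: {predictor} constant for {animal}")
        res = sps.linregress(x, y)
        fits.append(RegressionFit(
            animal_id=str(animal), slope=float(res.slope),
            intercept=float(res.intercept), r_squared=float(res.rvalue ** 2),
            p_value=float(res.pvalue), n_hops=len(sub)))
    return fits


# ---------------------------------------------------------------------------
# Random-intercept LMM by profiled maximum likelihood.


def _group_indices(groups) -> tuple[np.ndarray, list[np.ndarray]]:
    codes, uniques = pd.factorize(np.asarray(groups), sort=True)
    return codes, [np.nonzero(codes == g)[0] for g in range(len(uniques))]


def _profiled(y: np.ndarray, x: np.ndarray, idx: list[np.ndarray],
              lam: float) -> tuple[np.ndarray, float, float]:
    """GLS profile at fixed lambda: returns (beta, sigma_e^2, loglik)."""
    n = y.size

    def vinv(u: np.ndarray) -> np.ndarray:
        # (I + lam * 1 1')^{-1} u blockwise, via Sherman-Morrison;
        # u may be (n,) or (n, p) — sums are per column
        out = u.copy()
        for gi in idx:
            ni = gi.size
            out[gi] -= (lam / (1.0 + lam * ni)) * u[gi].sum(axis=0)
        return out

    vy = vinv(y)
    vx = vinv(x)
    a = x.T @ vx
    beta = np.linalg.solve(a, x.T @ vy)
    r = y - x @ beta
    quad = float(r @ vinv(r))
    sigma2 = quad / n
    logdet = float(sum(math.log1p(lam * gi.size) for gi in idx))
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return beta, sigma2, loglik


def profile_loglik(y, x, groups, lam: float) -> float:
    """ML log-likelihood profiled over beta and sigma_e^2 at fixed
    lambda = sigma_b^2 / sigma_e^2 (lambda = 0 collapses to OLS)."""
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    _, idx = _group_indices(groups)
    return _profiled(y, x, idx, lam)[2]


def fit_random_intercept_lmm(y, x, groups,
                             column_names: list[str] | None = None,
                             lambda_fixed: float | None = None) -> LMMFit:
    """Fit the random-intercept LMM by maximum likelihood.

    Parameters
    ----------
    y : (n,) response.
    x : (n, p) fixed-effects design matrix (include an intercept column).
    groups : (n,) group labels (the random-intercept factor, e.g. animal).
    column_names : names for the design columns (default ``x0..x{p-1}``).
    lambda_fixed : if given, skip the variance-ratio search and fit at this
        fixed lambda (``0`` forces sigma_b = 0, collapsing to OLS).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.size != x.shape[0]:
        raise ValueError("response and design have different lengths")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    codes, idx = _group_indices(groups)
    n_groups = len(idx)
    if n_groups < 2:
        raise ValueError("need >= 2 groups for a random intercept")
    names = column_names or [f"x{j}" for j in range(x.shape[1])]

    converged = True
    if lambda_fixed is not None:
        lam = float(lambda_fixed)
    else:
        def neg(loglam: float) -> float:
            return -_profiled(y, x, idx, math.exp(loglam))[2]

        res = minimize_scalar(neg, bounds=(-12.0, 15.0), method="bounded",
                              options={"xatol": 1e-8})
        converged = bool(res.success)
        lam = math.exp(float(res.x))
        # the boundary lambda -> 0 (no between-group variance) is admissible
        if _profiled(y, x, idx, 0.0)[2] >= -float(res.fun):
            lam = 0.0
    beta, sigma2, loglik = _profiled(y, x, idx, lam)
    return LMMFit(
        fixed_effects=dict(zip(names, map(float, beta))),
        sigma_b=math.sqrt(lam * sigma2),
        sigma_e=math.sqrt(sigma2),
        loglik_ml=loglik,
        n_obs=y.size,
        n_groups=n_groups,
        converged=converged,
        design=x, response=y, groups=np.asarray(groups),
    )


def _is_nested(null: LMMFit, full: LMMFit) -> bool:
    if null.design is None or full.design is None:
        return False
    if null.n_obs != full.n_obs or null.n_fixed > full.n_fixed:
        return False
    if not np.array_equal(null.response, full.response):
        return False
    if not np.array_equal(null.groups, full.groups):
        return False
    # every null design column must lie in the full design's column space
    proj, *_ = np.linalg.lstsq(full.design, null.design, rcond=None)
    resid = null.design - full.design @ proj
    scale = max(1.0, float(np.abs(null.design).max()))
    return bool(np.abs(resid).max() < 1e-8 * scale)


def likelihood_ratio_test(full: LMMFit, null: LMMFit) -> LRTResult:
    """LRT between nested ML fits: chi^2 = 2 (ll_full - ll_null).

    The statistic is clamped at zero against numerical jitter; df is the
    difference in fixed-effect parameter counts.  Identical designs give
    chi^2 = 0, df = 0, p = 1.
    """
    if not _is_nested(null, full):
        raise ValueError("invalid comparison: models are not nested")
    df = full.n_fixed - null.n_fixed
    chi_sq = max(0.0, 2.0 * (full.loglik_ml - null.loglik_ml))
    p = 1.0 if df == 0 else float(sps.chi2.sf(chi_sq, df))
    return LRTResult(chi_sq=chi_sq, df=df, p_value=p)


def treatment_design(metrics: pd.DataFrame, covariate: str | None = None,
                     treatment_col: str = "treatment"
                     ) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment dummies (reference = first level sorted), or
    intercept + a numeric covariate when ``covariate`` is given."""
    n = len(metrics)
    if covariate is not None:
        x = np.column_stack([np.ones(n),
                             metrics[covariate].to_numpy(dtype=float)])
        return x, ["intercept", covariate]
    levels = sorted(metrics[treatment_col].unique())
    cols = [np.ones(n)]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((metrics[treatment_col] == lev).to_numpy(dtype=float))
        names.append(f"{treatment_col}[{lev}]")
    return np.column_stack(cols), names


def lmm_lrt(metrics: pd.DataFrame, response: str,
            covariate: str | None = None,
            treatment_col: str = "treatment",
            group_col: str = "animal_id") -> tuple[LMMFit, LMMFit, LRTResult]:
    """Full-vs-null LRT for one response on the metrics table.

    Full model: intercept + treatment dummies (or a numeric covariate);
    null model: intercept only.  Random intercept per animal in both.
    Rows with missing response are dropped.
    """
    table = metrics[metrics["included"]] if "included" in metrics else metrics
    table = table.dropna(subset=[response])
    y = table[response].to_numpy(dtype=float)
    groups = table[group_col].to_numpy()
    x_full, names = treatment_design(table, covariate, treatment_col)
    full = fit_random_intercept_lmm(y, x_full, groups, names)
    null = fit_random_intercept_lmm(y, np.ones((len(table), 1)), groups,
                                    ["intercept"])
    return full, null, likelihood_ratio_test(full, null)


# ---------------------------------------------------------------------------
# Cohort summaries.


def summarize_treatments(metrics: pd.DataFrame,
                         metric_names: list[str],
                         treatment_col: str = "treatment") -> pd.DataFrame:
    """Means of individual means +/- SD per treatment and metric.

    Each animal contributes the mean over its included hops in the cell;
    the summary row is the mean and SD across those animal means.  Cells
    with no animal are reported as missing (NaN), never zero; single-animal
    cells have NaN SD.
    """
    table = metrics[metrics["included"]] if "included" in metrics else metrics
    rows = []
    for treatment, sub in table.groupby(treatment_col, sort=True):
        for name in metric_names:
            animal_means = sub.groupby("animal_id")[name].mean().dropna()
            n = len(animal_means)
            rows.append({
                "treatment": treatment,
                "metric": name,
                "mean_of_means": animal_means.mean() if n else np.nan,
                "sd_of_means": animal_means.std(ddof=1) if n > 1 else np.nan,
                "n_animals": n,
            })
    return pd.DataFrame(rows)


def continual_alignment_fraction(metrics: pd.DataFrame) -> float:
    """Fraction of included hops with a defined T_a that stayed in the band
    from alignment through touchdown."""
    table = metrics[metrics["included"]] if "included" in metrics else metrics
    table = table.dropna(subset=["continually_aligned"])
    if len(table) == 0:
        raise ValueError("no included hops with a defined alignment time")
    return float(table["continually_aligned"].astype(bool).mean())
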