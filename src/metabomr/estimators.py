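"""Causal-effect estimators for two-sample summary-data MR.

All estimators consume an :class:`~metabomr.instruments.InstrumentSet`
of harmonized per-SNP effects and return a common :class:`MREstimate`
(log-odds causal effect theta, SE, OR with 95% CI, two-sided p). The
methods are:

* Wald ratio — single instrument, first-order delta-method SE;
* IVW — inverse-variance-weighted regression through the origin, with
  fixed or multiplicative random effects (SE inflated by
  sqrt(Q/(k-1)), floored at 1);
* maximum likelihood — bivariate normal measurement model for
  (beta_X, beta_Y), profiled over the true SNP effects;
* simple / weighted median — interpolated median of per-SNP ratio
  estimates with parametric-bootstrap SE; consistent while valid
  instruments carry a majority of the weight;
* MR-Egger — weighted regression with a free intercept; the intercept
  tests directional pleiotropy, the slope is the causal estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import EstimationError
from .instruments import InstrumentSet
from .sumstats_io import HarmonizedInstrument

METHOD_WALD = "wald_ratio"
METHOD_IVW_FIXED = "ivw_fixed"
METHOD_IVW_RANDOM = "ivw_random"
METHOD_ML = "maximum_likelihood"
METHOD_SIMPLE_MEDIAN = "simple_median"
METHOD_WEIGHTED_MEDIAN = "weighted_median"
METHOD_EGGER = "mr_egger"

#: canonical report order of method rows within one exposure-outcome block
METHOD_ORDER = (
    METHOD_WALD, METHOD_IVW_FIXED, METHOD_IVW_RANDOM, METHOD_ML,
    METHOD_SIMPLE_MEDIAN, METHOD_WEIGHTED_MEDIAN, METHOD_EGGER,
)

GATING_BY_COUNT = "by_snp_count"
GATING_STRICT_IVW = "ivw_only_below_4"


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on an exposure-outcome pair."""

    method: str
    n_snp: int
    theta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept: directional-pleiotropy test on t(k-2)."""

    intercept: float
    se: float
    pvalue: float


def _make_estimate(
    method: str, n_snp: int, theta: float, se: float, df: int | None = None
) -> MREstimate:
    """Package (theta, se) into OR/CI/p; normal reference unless df given."""
    if se <= 0 or not math.isfinite(se):
        raise EstimationError(f"{method}: invalid standard error {se}")
    z = abs(theta) / se
    if df is None:
        q = float(stats.norm.ppf(0.975))
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    else:
        q = float(stats.t.ppf(0.975, df))
        p = float(min(1.0, 2.0 * stats.t.sf(z, df)))
    return MREstimate(
        method=method, n_snp=n_snp, theta=float(theta), se=float(se),
        or_value=math.exp(theta),
        ci_low=math.exp(theta - q * se), ci_high=math.exp(theta + q * se),
        pvalue=p,
    )


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate beta_Y/beta_X with delta-method SE."""
    if inst.beta_exp == 0:
        raise EstimationError(f"{inst.snp_id}: beta_exp is zero, ratio undefined")
    theta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return _make_estimate(METHOD_WALD, 1, theta, se)


def _ivw_components(iset: InstrumentSet) -> tuple[float, float, float]:
    """(theta, se_fixed, Q) of the inverse-variance-weighted fit."""
    bx, by, sy = iset.beta_exp, iset.beta_out, iset.se_out
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fixed, q


def ivw(iset: InstrumentSet, effects_model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate (k >= 2).

    ``effects_model``: "fixed", "random" (multiplicative, inflation
    floored at 1), or "auto" (random iff Cochran's Q p < 0.05).
    """
    k = iset.n_snp
    if k < 2:
        raise EstimationError("IVW requires >= 2 instruments; use wald_ratio")
    theta, se_fixed, q = _ivw_components(iset)
    if effects_model == "auto":
        q_p = float(stats.chi2.sf(q, k - 1))
        effects_model = "random" if q_p < 0.05 else "fixed"
    if effects_model == "fixed":
        return _make_estimate(METHOD_IVW_FIXED, k, theta, se_fixed)
    if effects_model == "random":
        infl = max(1.0, math.sqrt(q / (k - 1)))
        return _make_estimate(METHOD_IVW_RANDOM, k, theta, se_fixed * infl)
    raise EstimationError(f"unknown effects_model {effects_model!r}")


def _profile_negloglik(theta: float, bx, sx2, by, sy2) -> float:
    """Joint negative log-likelihood profiled over the true SNP effects."""
    xi = (bx / sx2 + theta * by / sy2) / (1.0 / sx2 + theta**2 / sy2)
    return float(
        0.5 * np.sum((bx - xi) ** 2 / sx2) + 0.5 * np.sum((by - theta * xi) ** 2 / sy2)
    )


def maximum_likelihood(iset: InstrumentSet, tol: float = 1e-10) -> MREstimate:
    """Profile-likelihood estimate under the bivariate normal model.

    beta_X_j ~ N(xi_j, se_X_j²), beta_Y_j ~ N(theta*xi_j, se_Y_j²),
    independent across and within SNPs. The nuisance effects xi_j are
    profiled out in closed form; theta is found by one-dimensional
    optimization started at the IVW estimate, and its SE comes from the
    numerical curvature of the profile log-likelihood at the optimum.
    """
    k = iset.n_snp
    if k < 2:
        raise EstimationError("maximum likelihood requires >= 2 instruments")
    bx, by = iset.beta_exp, iset.beta_out
    sx2, sy2 = iset.se_exp**2, iset.se_out**2
    t0, _, _ = _ivw_components(iset)

    def nll(theta: float) -> float:
        return _profile_negloglik(theta, bx, sx2, by, sy2)

    res = optimize.minimize_scalar(
        nll, bracket=(t0 - 0.5, t0 + 0.5), method="brent",
        options={"xtol": tol, "maxiter": 500},
    )
    if not res.success or not np.isfinite(res.x):
        raise EstimationError(
            "profile-likelihood optimization did not converge",
            last_iterate=float(res.x) if np.isfinite(res.x) else None,
        )
    theta = float(res.x)
    h = 1e-5 * max(1.0, abs(theta))
    curv = (nll(theta - h) - 2.0 * nll(theta) + nll(theta + h)) / h**2
    if curv <= 0 or not np.isfinite(curv):
        raise EstimationError(
            "profile log-likelihood is not locally concave at the optimum",
            last_iterate=theta,
        )
    se = curv ** -0.5
    return _make_estimate(METHOD_ML, k, theta, se)


def weighted_median_statistic(thetas, weights) -> float:
    """Interpolated weighted median of per-SNP ratio estimates.

    Sort estimates ascending; the standardized cumulative weight of the
    j-th is s_j = (sum_{i<=j} w_i - w_j/2) / sum_i w_i; the statistic is
    the linear interpolation of theta at s = 0.5 (clamped to the first /
    last estimate when 0.5 falls outside [s_1, s_k]).
    """
    thetas = np.asarray(thetas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if thetas.shape != weights.shape or thetas.ndim != 1 or len(thetas) < 1:
        raise ValueError("thetas and weights must be equal-length 1-D arrays")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    order = np.argsort(thetas)
    th, w = thetas[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 < s[0]:
        return float(th[0])
    if 0.5 > s[-1]:
        return float(th[-1])
    return float(np.interp(0.5, s, th))


def _weighted_median_rows(thetas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median (vectorized bootstrap core)."""
    order = np.argsort(thetas, axis=1)
    th = np.take_along_axis(thetas, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    s = (np.cumsum(w, axis=1) - 0.5 * w) / np.sum(w, axis=1, keepdims=True)
    k = th.shape[1]
    idx = np.sum(s < 0.5, axis=1)  # first position with s >= 0.5
    out = np.empty(th.shape[0])
    lo_clip = idx == 0
    hi_clip = idx == k
    out[lo_clip] = th[lo_clip, 0]
    out[hi_clip] = th[hi_clip, -1]
    mid = ~(lo_clip | hi_clip)
    i = idx[mid]
    rows = np.nonzero(mid)[0]
    s0, s1 = s[rows, i - 1], s[rows, i]
    t0, t1 = th[rows, i - 1], th[rows, i]
    out[mid] = t0 + (0.5 - s0) / (s1 - s0) * (t1 - t0)
    return out


def median_estimators(
    iset: InstrumentSet,
    variant: str = "weighted",
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple or weighted median of ratio estimates (k >= 3).

    Weights are equal (simple) or beta_X²/se_Y² — the inverse variance
    of the first-order ratio (weighted). The SE is the standard
    deviation of the statistic over ``n_boot`` parametric-bootstrap
    replicates resampling beta_X_j ~ N(beta_X_j, se_X_j²) and
    beta_Y_j ~ N(beta_Y_j, se_Y_j²), reproducible given ``seed``.
    """
    k = iset.n_snp
    if k < 3:
        raise EstimationError("median estimators require >= 3 instruments")
    if variant not in ("simple", "weighted"):
        raise EstimationError(f"unknown median variant {variant!r}")
    bx, sx, by, sy = iset.beta_exp, iset.se_exp, iset.beta_out, iset.se_out

    def weights_for(bx_: np.ndarray) -> np.ndarray:
        if variant == "simple":
            return np.ones_like(bx_)
        return bx_**2 / sy**2

    point = weighted_median_statistic(by / bx, weights_for(bx))
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    boots = _weighted_median_rows(by_b / bx_b, weights_for(bx_b))
    se = float(np.std(boots, ddof=1))
    method = METHOD_SIMPLE_MEDIAN if variant == "simple" else METHOD_WEIGHTED_MEDIAN
    return _make_estimate(method, k, point, se)


def mr_egger(iset: InstrumentSet) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger regression: causal slope plus pleiotropy intercept (k >= 3).

    Each SNP is oriented so beta_X_j >= 0 (both betas negated where
    needed), then beta_Y is regressed on beta_X with a free intercept,
    weights 1/se_Y². Both SEs carry the multiplicative random-effects
    inflation max(1, sigma_hat) where sigma_hat² = Q_egger/(k-2);
    inference is on t(k-2).
    """
    k = iset.n_snp
    if k < 3:
        raise EstimationError("MR-Egger requires >= 3 instruments")
    sign = np.where(iset.beta_exp < 0, -1.0, 1.0)
    bx = iset.beta_exp * sign
    by = iset.beta_out * sign
    sy = iset.se_out
    if np.ptp(bx) == 0:
        raise EstimationError("all beta_exp identical after orientation; "
                              "Egger regression is collinear")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    sigma2 = float(fit.scale)  # Q_egger / (k - 2) on the weighted scale
    infl = math.sqrt(max(1.0, sigma2))
    # unit-variance SEs from (X'WX)^-1, robust to an exact-fit sigma2 of 0
    se_unit = np.sqrt(np.diag(fit.normalized_cov_params))
    se_int, se_slope = se_unit * infl
    b0, b1 = np.asarray(fit.params)
    slope = _make_estimate(METHOD_EGGER, k, float(b1), float(se_slope), df=k - 2)
    p_int = float(min(1.0, 2.0 * stats.t.sf(abs(b0) / se_int, k - 2)))
    intercept = PleiotropyResult(intercept=float(b0), se=float(se_int), pvalue=p_int)
    return slope, intercept


def run_gated_methods(
    iset: InstrumentSet,
    seed: int = 0,
    gating_mode: str = GATING_BY_COUNT,
    n_boot: int = 1000,
) -> list[MREstimate]:
    """Run the estimators appropriate to the instrument count.

    ``by_snp_count`` gating (default, matching the method rows the report
    convention actually uses): one instrument gets the Wald ratio; two
    get IVW (fixed and random) plus maximum likelihood; three or more
    additionally get simple median, weighted median and MR-Egger.
    ``ivw_only_below_4`` confines pairs with fewer than four instruments
    to the IVW family alone (Wald ratio standing in at k = 1).
    """
    if gating_mode not in (GATING_BY_COUNT, GATING_STRICT_IVW):
        raise EstimationError(f"unknown gating mode {gating_mode!r}")
    k = iset.n_snp
    if k == 1:
        return [wald_ratio(iset.instruments[0])]
    estimates = [ivw(iset, "fixed"), ivw(iset, "random")]
    if gating_mode == GATING_STRICT_IVW and k < 4:
        return estimates
    estimates.append(maximum_likelihood(iset))
    if k >= 3:
        estimates.append(median_estimators(iset, "simple", n_boot=n_boot, seed=seed))
        estimates.append(median_estimators(iset, "weighted", n_boot=n_boot, seed=seed))
        estimates.append(mr_egger(iset)[0])
    return estimates
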