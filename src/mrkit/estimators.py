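"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure effects gamma_hat_j (SE
se_x_j) and outcome effects Gamma_hat_j (SE se_y_j), each estimator returns
a pooled causal-effect estimate theta_hat on the outcome scale (log odds
ratio for a binary outcome):

* Wald ratio           — theta_j = Gamma_hat_j / gamma_hat_j, the per-variant atom;
* IVW                  — inverse-variance weighted pooling of Wald ratios,
                         algebraically a weighted regression through the origin;
* MR-Egger             — the same weighted regression with a free intercept;
                         a nonzero intercept estimates directional pleiotropy;
* simple/weighted median — (weighted) median of the Wald ratios, consistent
                         when <50% of the weight is on invalid instruments;
* MVMR                 — joint weighted regression on K exposures' effects.

Standard errors follow the first-order delta method; IVW and MVMR apply a
multiplicative overdispersion factor floored at 1 (never narrower than the
fixed-effect model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "RatioEstimate",
    "MRResult",
    "EggerResult",
    "wald_ratio",
    "ivw",
    "egger",
    "median_estimator",
    "mvmr",
]

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with its first-order standard error."""

    variant_id: str
    theta_j: float
    se_j: float


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal-effect estimate.

    For binary outcomes ``odds_ratio`` and its CI are exp() of the log-odds
    scale fields; they are None for continuous outcomes.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    @staticmethod
    def build(
        method: str,
        estimate: float,
        se: float,
        pvalue: float,
        n_snps: int,
        binary_outcome: bool,
        ci_half_width: float | None = None,
    ) -> "MRResult":
        hw = Z95 * se if ci_half_width is None else ci_half_width
        lo, hi = estimate - hw, estimate + hw
        return MRResult(
            method=method,
            estimate=estimate,
            se=se,
            ci_low=lo,
            ci_high=hi,
            pvalue=pvalue,
            n_snps=n_snps,
            odds_ratio=math.exp(estimate) if binary_outcome else None,
            or_ci_low=math.exp(lo) if binary_outcome else None,
            or_ci_high=math.exp(hi) if binary_outcome else None,
        )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the pleiotropy-intercept test."""

    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def _gauss_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(gx: tuple[float, float], gy: tuple[float, float], variant_id: str = "") -> RatioEstimate:
    """Per-variant ratio estimate theta = Gamma/gamma, se = |se_Gamma/gamma|."""
    bx, _sx = gx
    by, sy = gy
    if bx == 0:
        raise ValueError("Wald ratio undefined for a zero exposure effect")
    return RatioEstimate(variant_id=variant_id, theta_j=by / bx, se_j=abs(sy / bx))


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, model: str):
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    J = bx.size
    if model == "fixed" or J < 2:
        return theta, se_fixed
    q = float(np.sum(w * (by - theta * bx) ** 2))
    scale = max(1.0, math.sqrt(q / (J - 1)))
    return theta, se_fixed * scale


def ivw(hset: HarmonizedInstrumentSet, model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance weighted estimate (weighted regression through the origin).

    ``model="fixed"`` uses the fixed-effect SE; ``"multiplicative_random"``
    (default) inflates it by sqrt(Q/(J-1)) floored at 1, where Q is the
    weighted residual sum of squares. CI and p-value are Gaussian.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    J = hset.n_snps
    if J < 1 or (model == "multiplicative_random" and J < 2):
        # a single instrument still admits the fixed-effect (= Wald) estimate
        if J < 1:
            raise ValueError("IVW requires at least one instrument")
        model = "fixed"
    bx, _sx, by, sy = hset.arrays()
    theta, se = _ivw_core(bx, by, sy, model)
    p = _gauss_p(theta / se)
    return MRResult.build("ivw_fe" if model == "fixed" else "ivw_mre",
                          theta, se, p, J, hset.outcome_type == "binary")


def egger(hset: HarmonizedInstrumentSet) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    Instruments are first oriented so every exposure effect is non-negative
    (both betas negated where needed) — required for identifiability of the
    intercept. SEs come from the weighted-regression covariance scaled by
    max(1, residual standard error); p-values use a t distribution on J-2 df.
    """
    J = hset.n_snps
    if J < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, _sx, by, sy = hset.arrays()
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    xtx_inv = np.linalg.inv(XtW @ X)
    coef = xtx_inv @ (XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (J - 2)
    scale2 = max(1.0, sigma2)
    cov = xtx_inv * scale2
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    tdist = stats.t(df=J - 2)
    p_slope = float(2 * tdist.sf(abs(coef[1] / se_slope)))
    p_int = float(2 * tdist.sf(abs(coef[0] / se_int)))
    tq = float(tdist.ppf(0.975))
    slope = MRResult.build(
        "egger", float(coef[1]), se_slope, p_slope, J,
        hset.outcome_type == "binary", ci_half_width=tq * se_slope,
    )
    return EggerResult(slope=slope, intercept=float(coef[0]),
                       intercept_se=se_int, intercept_pvalue=p_int)


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative mid-weight interpolation of the weighted median.

    Sort ratios; with normalized cumulative weights S_j, the mid-points
    p_j = (S_j - w_j/2)/S_J define an empirical quantile grid; the estimate
    is the linear interpolation of theta at p = 0.5.
    """
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    w = weights[order]
    s = np.cumsum(w)
    p = (s - 0.5 * w) / s[-1]
    return float(np.interp(0.5, p, t))


def _weighted_median_rows(theta: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for a (B, J) bootstrap matrix."""
    order = np.argsort(theta, axis=1, kind="stable")
    t = np.take_along_axis(theta, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    s = np.cumsum(w, axis=1)
    p = (s - 0.5 * w) / s[:, -1:]
    # row-wise linear interpolation of t at p = 0.5, clamped to the ends
    B, J = theta.shape
    hi = (p < 0.5).sum(axis=1)  # first index with p >= 0.5
    out = np.empty(B)
    at_left = hi == 0
    at_right = hi == J
    out[at_left] = t[at_left, 0]
    out[at_right] = t[at_right, -1]
    mid = ~(at_left | at_right)
    if np.any(mid):
        i = hi[mid]
        rows = np.nonzero(mid)[0]
        p0, p1 = p[rows, i - 1], p[rows, i]
        t0, t1 = t[rows, i - 1], t[rows, i]
        frac = np.where(p1 > p0, (0.5 - p0) / np.where(p1 > p0, p1 - p0, 1.0), 0.0)
        out[mid] = t0 + frac * (t1 - t0)
    return out


def median_estimator(
    hset: HarmonizedInstrumentSet,
    weighting: str = "inverse_variance",
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Simple or weighted median of the per-variant Wald ratios.

    ``weighting="simple"`` gives every ratio weight 1/J; ``"inverse_variance"``
    weights by the inverse squared first-order ratio SE. The standard error
    is a parametric bootstrap: exposure and outcome effects are resampled
    from Normal(observed, se^2), the weighted median recomputed ``n_boot``
    times, and the SE taken as the bootstrap standard deviation.
    """
    if weighting not in ("simple", "inverse_variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    J = hset.n_snps
    if J < 3:
        raise ValueError("median estimators require at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    bx, sx, by, sy = hset.arrays()

    theta = by / bx
    if weighting == "simple":
        w = np.ones_like(theta)
    else:
        w = (np.abs(bx) / sy) ** 2  # 1/se_j^2 with se_j = |se_y/bx|
    est = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, J))
    by_b = rng.normal(by, sy, size=(n_boot, J))
    theta_b = by_b / bx_b
    if weighting == "simple":
        w_b = np.ones_like(theta_b)
    else:
        w_b = (np.abs(bx_b) / sy) ** 2
    boots = _weighted_median_rows(theta_b, w_b)
    se = float(np.std(boots, ddof=1))
    se = max(se, 1e-12)  # all-identical ratios leave a degenerate bootstrap
    p = _gauss_p(est / se)
    method = "simple_median" if weighting == "simple" else "weighted_median"
    return MRResult.build(method, est, se, p, J, hset.outcome_type == "binary")


def mvmr(
    beta_exposures: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    exposure_names: list[str] | None = None,
    binary_outcome: bool = True,
) -> list[tuple[str, MRResult]]:
    """Multivariable MR: joint direct effects of K exposures from shared SNPs.

    Weighted regression (weights 1/se_y^2) of the outcome effects on the
    J x K matrix of exposure effects with no intercept; per-exposure SEs from
    the weighted covariance scaled by max(1, residual factor); t-based
    p-values with J-K degrees of freedom. All SNPs must be harmonized to one
    effect-allele convention across every exposure and the outcome.
    """
    X = np.atleast_2d(np.asarray(beta_exposures, dtype=float))
    if X.ndim != 2:
        raise ValueError("beta_exposures must be a J x K matrix")
    J, K = X.shape
    y = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    if K < 1:
        raise ValueError("MVMR requires at least one exposure")
    if J <= K:
        raise ValueError(f"MVMR requires more SNPs than exposures (J={J}, K={K})")
    if np.linalg.matrix_rank(X) < K:
        raise ValueError("exposure-effect matrix is rank deficient (collinear exposures)")
    names = exposure_names or [f"exposure_{k+1}" for k in range(K)]

    w = 1.0 / sy**2
    XtW = X.T * w
    xtx_inv = np.linalg.inv(XtW @ X)
    coef = xtx_inv @ (XtW @ y)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (J - K)
    cov = xtx_inv * max(1.0, sigma2)
    ses = np.sqrt(np.diag(cov))

    tdist = stats.t(df=J - K)
    tq = float(tdist.ppf(0.975))
    results = []
    for k in range(K):
        p = float(2 * tdist.sf(abs(coef[k] / ses[k])))
        r = MRResult.build("mvmr", float(coef[k]), float(ses[k]), p, J,
                           binary_outcome, ci_half_width=tq * ses[k])
        results.append((names[k], r))
    return results
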