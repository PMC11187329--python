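"""Causal-effect estimators for two-sample Mendelian randomization.

Given harmonized per-SNP exposure/outcome effects, the per-SNP causal
estimate is the Wald ratio θ_j = β_Yj/β_Xj with first-order standard
error se_Yj/|β_Xj|.  The headline estimator is the inverse-variance
weighted (IVW) mean of the ratios; MR-Egger adds an intercept to the
weighted regression of outcome on exposure effects as a test of average
directional pleiotropy.  Reporting transforms map (β, se) to odds
ratios, 95% confidence intervals and two-sided Wald p-values — the
schema of a standard drug-target MR results table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedPair

__all__ = [
    "Z_95",
    "WaldRatio",
    "MrResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "to_or",
]

#: 97.5% normal quantile used for all 95% intervals (fixed constant so
#: that interval arithmetic is reproducible to printed precision)
Z_95 = 1.959964


@dataclass(frozen=True)
class WaldRatio:
    snp_id: str
    theta: float
    se_theta: float


@dataclass(frozen=True)
class MrResult:
    """One estimator's output: one row of an MR results table."""

    method: str  # IVW_fixed | IVW_mre | Egger_slope | Egger_intercept | Wald_single
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    or_ci_low: float
    or_ci_high: float
    pval: float


def _make_result(method: str, n_snps: int, beta: float, se: float, df: int | None = None) -> MrResult:
    """Assemble an MrResult; p and CI from the normal reference, or from
    t(df) when ``df`` is given (MR-Egger convention)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = abs(beta) / se
    if df is None:
        pval = 2 * stats.norm.sf(z)
        crit = Z_95
    else:
        pval = 2 * stats.t.sf(z, df)
        crit = float(stats.t.ppf(0.975, df))
    pval = min(max(pval, np.nextafter(0, 1)), 1.0)
    ci_low = beta - crit * se
    ci_high = beta + crit * se
    return MrResult(
        method=method,
        n_snps=n_snps,
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        or_value=math.exp(beta),
        or_ci_low=math.exp(ci_low),
        or_ci_high=math.exp(ci_high),
        pval=float(pval),
    )


def wald_ratio(pair: HarmonizedPair) -> WaldRatio:
    """Per-SNP causal estimate θ = β_Y/β_X, se = se_Y/|β_X| (first order)."""
    if pair.beta_exposure == 0:
        raise ZeroDivisionError(f"{pair.snp_id}: zero exposure effect — degenerate instrument")
    return WaldRatio(
        snp_id=pair.snp_id,
        theta=pair.beta_outcome / pair.beta_exposure,
        se_theta=pair.se_outcome / abs(pair.beta_exposure),
    )


def _ratio_arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    ratios = [wald_ratio(p) for p in pairs]
    theta = np.array([r.theta for r in ratios])
    se = np.array([r.se_theta for r in ratios])
    return theta, se


def ivw(pairs: Sequence[HarmonizedPair], mode: str = "multiplicative_random") -> MrResult:
    """Inverse-variance weighted causal estimate.

    With weights w_j = 1/se_θj², the point estimate is Σw_jθ_j/Σw_j in
    both modes.  ``fixed`` uses se = (Σw_j)^{-1/2};
    ``multiplicative_random`` (the default) inflates it by
    max(1, Q/(J−1))^{1/2}, where Q is Cochran's Q, so that
    overdispersion across ratios widens the interval but never narrows
    it.  A single instrument is reported as a Wald ratio (with a warning
    under the random-effects mode, which needs J >= 2).
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no instruments: IVW undefined on an empty set")
    theta, se = _ratio_arrays(pairs)
    if len(pairs) == 1:
        if mode == "multiplicative_random":
            warnings.warn(
                "single instrument: multiplicative random effects undefined; "
                "falling back to the Wald ratio",
                stacklevel=2,
            )
        return _make_result("Wald_single", 1, float(theta[0]), float(se[0]))
    w = 1.0 / se**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    if mode == "fixed":
        return _make_result("IVW_fixed", len(pairs), beta, se_fixed)
    q = float(np.sum(w * (theta - beta) ** 2))
    scale = math.sqrt(max(1.0, q / (len(pairs) - 1)))
    return _make_result("IVW_mre", len(pairs), beta, se_fixed * scale)


def mr_egger(pairs: Sequence[HarmonizedPair]) -> tuple[MrResult, MrResult]:
    """MR-Egger regression: (slope, intercept) results.

    Weighted least squares of β_Y on β_X with an intercept, weights
    1/se_Y².  Pairs are first oriented so every exposure effect is
    non-negative (both betas sign-flipped where needed) — the Egger
    orientation convention.  Standard errors come from the WLS
    covariance scaled by max(1, weighted residual mean square); p-values
    are two-sided from t with J−2 degrees of freedom.  The slope is the
    causal estimate; the intercept estimates average directional
    pleiotropy.
    """
    pairs = list(pairs)
    j = len(pairs)
    if j < 3:
        raise ValueError(f"MR-Egger needs at least 3 instruments, got {j}")
    bx = np.array([p.beta_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se_int, se_slope = np.sqrt(np.diag(cov))
    intercept = _make_result("Egger_intercept", j, float(coef[0]), float(se_int), df=j - 2)
    slope = _make_result("Egger_slope", j, float(coef[1]), float(se_slope), df=j - 2)
    return slope, intercept


def to_or(beta: float, se: float) -> tuple[float, float, float, float]:
    """Reporting transform: (OR, OR 95% CI low, high, two-sided Wald p).

    OR = exp(β); CI = exp(β ± 1.959964·se); p = 2(1 − Φ(|β|/se)).
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    or_value = math.exp(beta)
    or_lo = math.exp(beta - Z_95 * se)
    or_hi = math.exp(beta + Z_95 * se)
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return or_value, or_lo, or_hi, min(max(pval, np.nextafter(0, 1)), 1.0)
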