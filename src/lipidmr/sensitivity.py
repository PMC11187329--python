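"""Heterogeneity, pleiotropy, outlier and robustness diagnostics.

The battery run after every causal estimate: Cochran's Q and I² across
per-SNP Wald ratios, the MR-Egger intercept test for average directional
pleiotropy, the simulation-based MR-PRESSO global/outlier/distortion
tests, leave-one-out re-estimation, and the scatter behind a funnel
plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import HarmonizedPair
from .mr_core import MrResult, ivw, mr_egger, wald_ratio

__all__ = [
    "HeterogeneityResult",
    "PleiotropyTest",
    "PressoResult",
    "LooResult",
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "funnel_data",
    "sensitivity_report",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p and the derived I² percentage."""

    q: float
    df: int
    pval: float
    i2: float  # percent in [0, 100]


@dataclass(frozen=True)
class PleiotropyTest:
    """MR-Egger intercept with its significance flag at 0.05."""

    intercept: MrResult
    significant: bool


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results.

    ``outlier_pvals`` are raw (un-adjusted) per-SNP empirical p-values;
    the outlier call applies a Bonferroni adjustment by the number of
    instruments.  ``beta_corrected`` and ``distortion_pval`` are present
    only when outliers were found.
    """

    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: frozenset[str]
    distortion_pval: float | None
    beta_raw: float
    beta_corrected: float | None
    n_sim: int


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out IVW series.

    ``rows`` is a DataFrame with columns snp_id, beta_without,
    se_without, pval_without; ``robust`` is True when every
    leave-one-out estimate keeps the sign of the all-SNP estimate.
    """

    rows: pd.DataFrame
    all_snp_beta: float
    robust: bool


@dataclass(frozen=True)
class SensitivityReport:
    """All diagnostics for one instrument set (entries None when the
    instrument count is below a test's minimum)."""

    heterogeneity: HeterogeneityResult | None
    egger_intercept: PleiotropyTest | None
    presso: PressoResult | None
    loo: LooResult | None


def _ratio_arrays(pairs: Sequence[HarmonizedPair]):
    ratios = [wald_ratio(p) for p in pairs]
    theta = np.array([r.theta for r in ratios])
    se = np.array([r.se_theta for r in ratios])
    return theta, se


def cochran_q(pairs: Sequence[HarmonizedPair]) -> HeterogeneityResult:
    """Cochran's Q across Wald ratios, with I² = max(0, (Q−df)/Q)·100.

    Q = Σ w_j (θ_j − θ_IVW)², w_j = 1/se_θj²; the reference distribution
    is chi-square with J−1 degrees of freedom.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    theta, se = _ratio_arrays(pairs)
    w = 1.0 / se**2
    beta = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - beta) ** 2))
    df = len(pairs) - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pval=max(pval, np.nextafter(0, 1)), i2=i2)


def egger_intercept_test(pairs: Sequence[HarmonizedPair], alpha: float = 0.05) -> PleiotropyTest:
    """The MR-Egger intercept as a test of average directional pleiotropy."""
    _, intercept = mr_egger(pairs)
    return PleiotropyTest(intercept=intercept, significant=intercept.pval < alpha)


def _loo_ivw_estimates(bx, by, sy):
    """Vectorized leave-one-out IVW point estimates (first-order weights).

    With w_j = bx_j²/sy_j² and θ_j = by_j/bx_j, the IVW numerator is
    Σ bx_j by_j / sy_j², so each leave-one-out estimate is a ratio of
    leave-one-out sums.
    """
    num = bx * by / sy**2
    den = bx**2 / sy**2
    return (num.sum(axis=-1, keepdims=True) - num) / (den.sum(axis=-1, keepdims=True) - den)


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    outlier_significance: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PressoResult:
    """MR-PRESSO: parametric-simulation residual test for pleiotropy.

    Global test: each SNP's residual r_j = β_Yj − θ̂₋ⱼ β_Xj is taken
    against the leave-one-out IVW estimate θ̂₋ⱼ; the observed weighted
    residual sum of squares RSS = Σ r_j²/se_Yj² is compared with its
    distribution under the no-pleiotropy model, simulated by drawing
    β*_Xj ~ N(β_Xj, se_Xj) and β*_Yj ~ N(θ̂₋ⱼ β_Xj, se_Yj) and
    recomputing RSS* the same way.  Empirical p-values use the
    (1 + #exceedances)/(n_sim + 1) convention.

    Outlier test: per-SNP empirical p on the weighted squared residual,
    Bonferroni-adjusted by J; SNPs below ``outlier_significance`` after
    adjustment are flagged.

    Distortion test: when outliers exist, the outlier-corrected IVW
    estimate (on the non-outliers) is compared with the raw estimate;
    the observed shift is referred to the empirical distribution of
    shifts obtained by removing random outlier-sized subsets.
    """
    pairs = list(pairs)
    j = len(pairs)
    if j < 4:
        raise ValueError(f"MR-PRESSO needs at least 4 instruments, got {j}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)

    bx = np.array([p.beta_exposure for p in pairs])
    sx = np.array([p.se_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    w = 1.0 / sy**2

    theta_loo = np.asarray(_loo_ivw_estimates(bx, by, sy)).reshape(j)
    resid = by - theta_loo * bx
    wr2_obs = w * resid**2
    rss_obs = float(wr2_obs.sum())

    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    theta_loo_sim = _loo_ivw_estimates(bx_sim, by_sim, sy)
    resid_sim = by_sim - theta_loo_sim * bx_sim
    wr2_sim = w * resid_sim**2
    rss_sim = wr2_sim.sum(axis=1)

    global_pval = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)

    p_raw = (1 + (wr2_sim >= wr2_obs).sum(axis=0)) / (n_sim + 1)
    outlier_pvals = {p.snp_id: float(pr) for p, pr in zip(pairs, p_raw)}
    outliers = frozenset(
        p.snp_id for p, pr in zip(pairs, p_raw) if min(1.0, pr * j) < outlier_significance
    )

    beta_raw = ivw(pairs, mode="fixed").beta
    beta_corrected = None
    distortion_pval = None
    if outliers and len(outliers) < j:
        keep = [p for p in pairs if p.snp_id not in outliers]
        beta_corrected = ivw(keep, mode="fixed").beta if len(keep) > 1 else wald_ratio(keep[0]).theta
        d_obs = beta_raw - beta_corrected
        n_out = len(outliers)
        d_sim = np.empty(n_sim)
        idx = np.arange(j)
        num = bx * by / sy**2
        den = bx**2 / sy**2
        for k in range(n_sim):
            drop = rng.choice(idx, size=n_out, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[drop] = False
            d_sim[k] = beta_raw - num[mask].sum() / den[mask].sum()
        distortion_pval = (1 + int(np.sum(np.abs(d_sim) >= abs(d_obs)))) / (n_sim + 1)

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=float(global_pval),
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        distortion_pval=distortion_pval,
        beta_raw=float(beta_raw),
        beta_corrected=None if beta_corrected is None else float(beta_corrected),
        n_sim=n_sim,
    )


def leave_one_out(pairs: Sequence[HarmonizedPair], mode: str = "multiplicative_random") -> LooResult:
    """IVW re-estimated with each SNP removed in turn.

    The set is called robust when every leave-one-out estimate keeps the
    sign of the all-SNP estimate — no single instrument drives the
    conclusion.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("leave-one-out needs at least 2 instruments")
    full = ivw(pairs, mode=mode)
    rows = []
    for i, left_out in enumerate(pairs):
        rest = pairs[:i] + pairs[i + 1 :]
        res = ivw(rest, mode=mode if len(rest) > 1 else "fixed")
        rows.append(
            {
                "snp_id": left_out.snp_id,
                "beta_without": res.beta,
                "se_without": res.se,
                "pval_without": res.pval,
            }
        )
    frame = pd.DataFrame(rows, columns=["snp_id", "beta_without", "se_without", "pval_without"])
    sign = math.copysign(1.0, full.beta)
    robust = bool(np.all(np.sign(frame["beta_without"]) == sign))
    return LooResult(rows=frame, all_snp_beta=full.beta, robust=robust)


def funnel_data(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Per-SNP (Wald ratio, precision) scatter underlying a funnel plot."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("funnel data needs at least 1 instrument")
    ratios = [wald_ratio(p) for p in pairs]
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in ratios],
            "theta": [r.theta for r in ratios],
            "precision": [1.0 / r.se_theta for r in ratios],
        }
    )


def sensitivity_report(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int | None = None,
) -> SensitivityReport:
    """Run every diagnostic the instrument count allows.

    Minimum instrument counts: Q and leave-one-out need 2, the Egger
    intercept needs 3, MR-PRESSO needs 4; below a minimum that entry is
    None rather than an error.
    """
    pairs = list(pairs)
    j = len(pairs)
    return SensitivityReport(
        heterogeneity=cochran_q(pairs) if j >= 2 else None,
        egger_intercept=egger_intercept_test(pairs) if j >= 3 else None,
        presso=mr_presso(pairs, n_sim=n_sim, seed=seed) if j >= 4 else None,
        loo=leave_one_out(pairs) if j >= 2 else None,
    )
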