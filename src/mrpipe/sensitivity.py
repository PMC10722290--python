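"""Sensitivity diagnostics for two-sample MR: heterogeneity, pleiotropy,
outliers, causal direction, and per-SNP influence.

Heterogeneity across per-SNP ratio estimates is quantified by Cochran's Q
(chi-square under homogeneity); directional pleiotropy by the MR-Egger
intercept; outlying instruments by the simulation-based MR-PRESSO global,
per-SNP and distortion tests; causal orientation by the Steiger comparison of
explained variance; and single-SNP influence by leave-one-out re-estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import (
    EstimatorError,
    MrEstimate,
    _arrays,
    egger,
    ivw,
    wald_ratio,
)
from .summary_io import HarmonizedInstrument


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its df and upper-tail chi-square p-value."""

    method: str
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PleiotropyTest:
    """MR-Egger intercept test for average directional pleiotropy."""

    intercept: float
    se: float
    pval: float


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check: variance explained in exposure vs outcome.

    ``direction`` is True iff the instruments explain strictly more exposure
    than outcome variance (the assumed exposure -> outcome orientation);
    ``pval`` tests the difference of the two summed correlations via Fisher's
    z transform.
    """

    r2_exposure: float
    r2_outcome: float
    direction: bool
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: list[str]
    distortion_pval: float | None = None
    corrected: MrEstimate | None = None
    n_sim: int = 0
    seed: int | None = None


def snp_r2(beta: float, se: float, n: float) -> float:
    """Per-SNP squared trait correlation from the association z-score.

    r^2 = z^2 / (z^2 + n - 2) — the observed-scale approximation, applied to
    binary traits without liability-scale conversion.
    """
    if n is None or n <= 2:
        raise EstimatorError(f"sample size must exceed 2, got {n}")
    z2 = (beta / se) ** 2
    return z2 / (z2 + n - 2)


def cochran_q(pairs: Sequence[HarmonizedInstrument], method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic across per-SNP ratio estimates.

    ``ivw``: Q = sum of w_j (r_j - beta_fixed)^2 with w_j = 1/se_ratio_j^2,
    df = J - 1.  ``egger``: the weighted residual sum of squares about the
    fitted Egger line, df = J - 2.  p is the upper chi-square tail;
    p < 0.05 is conventionally read as heterogeneity.
    """
    j = len(pairs)
    if method == "ivw":
        if j < 2:
            raise EstimatorError("Cochran's Q (IVW) needs J >= 2")
        est = [wald_ratio(p) for p in pairs]
        r = np.array([e.ratio for e in est])
        w = np.array([e.weight for e in est])
        beta = float(np.sum(w * r) / np.sum(w))
        q = float(np.sum(w * (r - beta) ** 2))
        df = j - 1
    elif method == "egger":
        if j < 3:
            raise EstimatorError("Cochran's Q (Egger) needs J >= 3")
        bx, _, by, sy = _arrays(pairs)
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        slope_est, int_est = egger(pairs)
        resid = by - (int_est.beta + slope_est.beta * bx)
        q = float(np.sum(resid**2 / sy**2))
        df = j - 2
    else:
        raise EstimatorError(f"unknown heterogeneity method {method!r}")
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(method=method, q=q, df=df, pval=pval)


def egger_intercept_test(pairs: Sequence[HarmonizedInstrument]) -> PleiotropyTest:
    """Two-sided t(J-2) test of the MR-Egger intercept (average pleiotropy).

    Uses the exact WLS residual scale (no max(1, Q/df) truncation) so the
    test is exactly calibrated under the no-pleiotropy null; the truncated,
    never-deflated SE remains the convention for the reported Egger interval.
    """
    _, intercept = egger(pairs, truncate_inflation=False)
    return PleiotropyTest(intercept=intercept.beta, se=intercept.se, pval=intercept.pval)


def _loo_ivw_betas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorized over the left-out SNP."""
    w = bx**2 / sy**2
    r = by / bx
    sw, swr = np.sum(w), np.sum(w * r)
    return (swr - w * r) / (sw - w)


def mr_presso(
    pairs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier detection.

    Global test: the observed RSS — squared outcome residuals about each
    SNP's leave-one-out IVW prediction, standardized by the outcome variance
    — is compared with ``n_sim`` parametric simulations under the
    no-pleiotropy model (effects redrawn from their sampling distributions
    around the leave-one-out fit).  Per-SNP observed vs simulated residuals
    give outlier p-values, Bonferroni-declared at ``outlier_alpha / J``.
    When outliers are found, the distortion test compares the shift in the
    IVW estimate after their removal against removals of random same-size
    subsets, and ``corrected`` carries the IVW estimate on the non-outliers.

    Fully reproducible given ``seed``.
    """
    j = len(pairs)
    if j < 4:
        raise EstimatorError(f"MR-PRESSO needs J >= 4 instruments, got {j}")
    if n_sim < 100:
        raise EstimatorError(f"n_sim must be >= 100, got {n_sim}")
    if seed is None:
        raise EstimatorError("mr_presso requires an explicit seed")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(pairs)
    rsids = [p.rsid for p in pairs]

    beta_loo = _loo_ivw_betas(bx, by, sy)
    obs_res2 = (by - beta_loo * bx) ** 2 / sy**2
    rss_obs = float(np.sum(obs_res2))

    # parametric simulations under the no-horizontal-pleiotropy model
    exp_sim = rng.normal(bx[None, :], sx[None, :], size=(n_sim, j))
    out_sim = rng.normal(beta_loo[None, :] * bx[None, :], sy[None, :], size=(n_sim, j))
    exp_sim = np.where(exp_sim == 0, np.finfo(float).tiny, exp_sim)
    w_sim = exp_sim**2 / sy[None, :] ** 2
    r_sim = out_sim / exp_sim
    sw = np.sum(w_sim, axis=1, keepdims=True)
    swr = np.sum(w_sim * r_sim, axis=1, keepdims=True)
    beta_loo_sim = (swr - w_sim * r_sim) / (sw - w_sim)
    sim_res2 = (out_sim - beta_loo_sim * exp_sim) ** 2 / sy[None, :] ** 2
    rss_sim = np.sum(sim_res2, axis=1)

    # raw exceedance fractions: an observed residual beyond every simulation
    # yields p = 0, which is what lets a per-SNP p clear the Bonferroni bar
    global_pval = float(np.mean(rss_sim >= rss_obs))
    outlier_pvals = {
        rsid: float(np.mean(sim_res2[:, k] >= obs_res2[k]))
        for k, rsid in enumerate(rsids)
    }
    threshold = outlier_alpha / j
    outliers = [rsid for rsid, p in outlier_pvals.items() if p < threshold]
    if len(outliers) == j:
        raise EstimatorError("MR-PRESSO flagged every instrument as an outlier")

    distortion_pval = None
    corrected = None
    if outliers:
        keep = [p for p in pairs if p.rsid not in set(outliers)]
        corrected = ivw(keep, mode="multiplicative_random" if len(keep) > 1 else "fixed")
        beta_all = ivw(pairs, mode="fixed").beta
        d_obs = abs(beta_all - corrected.beta)
        n_out = len(outliers)
        d_null = np.empty(n_sim)
        idx = np.arange(j)
        for s in range(n_sim):
            drop = rng.choice(idx, size=n_out, replace=False)
            mask = np.ones(j, bool)
            mask[drop] = False
            w = bx[mask] ** 2 / sy[mask] ** 2
            r = by[mask] / bx[mask]
            d_null[s] = abs(beta_all - float(np.sum(w * r) / np.sum(w)))
        distortion_pval = float(np.mean(d_null >= d_obs))

    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=sorted(outliers),
        distortion_pval=distortion_pval,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )


def steiger_direction(
    pairs: Sequence[HarmonizedInstrument],
    n_exp: float | None = None,
    n_out: float | None = None,
) -> SteigerResult:
    """MR-Steiger directionality test over the instrument set.

    Sums per-SNP squared correlations (``snp_r2``) on each side; the assumed
    exposure -> outcome orientation is confirmed (True) iff the exposure side
    strictly dominates.  The p-value compares the two aggregate correlations
    with a Fisher z-test; an exact tie yields direction False with p ~ 1
    (orientation not confirmed).

    Sample sizes default to the per-instrument ``n_exp`` / ``n_out`` medians.
    """
    if not pairs:
        raise EstimatorError("steiger_direction needs at least one instrument")
    if n_exp is None:
        sizes = [p.n_exp for p in pairs if p.n_exp is not None]
        n_exp = float(np.median(sizes)) if sizes else None
    if n_out is None:
        sizes = [p.n_out for p in pairs if p.n_out is not None]
        n_out = float(np.median(sizes)) if sizes else None
    if n_exp is None or n_out is None or n_exp <= 2 or n_out <= 2:
        raise EstimatorError("steiger_direction needs sample sizes > 2 on both sides")
    r2_exp = float(sum(snp_r2(p.beta_exp, p.se_exp, n_exp) for p in pairs))
    r2_out = float(sum(snp_r2(p.beta_out, p.se_out, n_out) for p in pairs))
    r2_exp, r2_out = min(r2_exp, 1.0 - 1e-12), min(r2_out, 1.0 - 1e-12)
    z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / math.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    pval = float(2 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction=r2_exp > r2_out,
        pval=pval,
    )


@dataclass
class LeaveOneOutRow:
    omitted: str | None  # None marks the all-SNP row
    estimate: MrEstimate
    sign_change: bool = False
    significance_change: bool = False


def leave_one_out(
    pairs: Sequence[HarmonizedInstrument], alpha: float = 0.05
) -> list[LeaveOneOutRow]:
    """Re-estimate (multiplicative random-effects IVW) omitting each SNP in turn.

    Returns J + 1 rows (each omission plus the all-SNP row) and flags
    omissions that flip the sign of the estimate or move its p-value across
    ``alpha`` — single SNPs the conclusion hinges on.
    """
    j = len(pairs)
    if j < 2:
        raise EstimatorError("leave-one-out needs J >= 2")
    mode_for = lambda n: "multiplicative_random" if n > 1 else "fixed"
    full = ivw(list(pairs), mode=mode_for(j))
    rows = []
    for k, omit in enumerate(pairs):
        sub = [p for i, p in enumerate(pairs) if i != k]
        est = ivw(sub, mode=mode_for(len(sub)))
        rows.append(
            LeaveOneOutRow(
                omitted=omit.rsid,
                estimate=est,
                sign_change=(est.beta * full.beta) < 0,
                significance_change=(est.pval < alpha) != (full.pval < alpha),
            )
        )
    rows.append(LeaveOneOutRow(omitted=None, estimate=full))
    return rows
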