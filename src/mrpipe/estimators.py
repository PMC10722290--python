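"""Causal-effect estimators for two-sample MR on harmonized summary statistics.

Every estimator combines per-SNP Wald ratios (outcome effect over exposure
effect) under a different validity assumption:

* ``ivw`` — inverse-variance-weighted mean of the ratios, equivalent to a
  weighted regression of outcome on exposure effects through the origin;
  consistent when all instruments are valid.  Fixed-effect and
  multiplicative-random-effect (SE inflated by sqrt(max(1, Q/df))) variants.
* ``egger`` — the same regression with an intercept; the slope is consistent
  under InSIDE even with directional pleiotropy, and the intercept estimates
  the average direct (pleiotropic) effect.
* ``weighted_median`` — consistent when at least half the weight comes from
  valid instruments.
* ``weighted_mode`` — consistent when the largest group of instruments
  sharing a ratio value is valid (zero modal pleiotropy).
* ``mr_raps`` — maximum profile likelihood accounting for exposure-side
  measurement error, with optional additive overdispersion for balanced
  pleiotropy.

All standard errors are on the log-odds scale; odds ratios and Wald CIs are
attached to each :class:`MrEstimate`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .summary_io import HarmonizedInstrument


class EstimatorError(ValueError):
    """Raised for undefined estimates (too few SNPs, zero exposure effect, ...)."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its first-order (delta-method) SE and IV weight."""

    rsid: str
    ratio: float
    se_ratio: float
    weight: float


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate on the log-odds scale with its OR-scale CI."""

    method: str
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int
    tau2: float | None = None
    nome_warning: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.method}: beta={self.beta:+.4g} (se {self.se:.3g}), "
            f"OR {self.or_:.4f} [{self.ci_low:.4f}, {self.ci_high:.4f}], "
            f"p={self.pval:.3g}, nSNP={self.n_snp}"
        )


def _z(alpha: float) -> float:
    return stats.norm.ppf(1 - alpha / 2)


def _estimate(
    method: str,
    beta: float,
    se: float,
    pval: float,
    n_snp: int,
    alpha: float = 0.05,
    tau2: float | None = None,
    nome_warning: bool = False,
) -> MrEstimate:
    z = _z(alpha)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pval=float(min(max(pval, 0.0), 1.0)),
        or_=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        n_snp=n_snp,
        tau2=tau2,
        nome_warning=nome_warning,
    )


def _arrays(pairs: Sequence[HarmonizedInstrument]) -> tuple[np.ndarray, ...]:
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, sx, by, sy


def wald_ratio(pair: HarmonizedInstrument, alpha: float = 0.05) -> RatioEstimate:
    """Single-SNP causal estimate: beta_out / beta_exp, SE = |se_out / beta_exp|."""
    if pair.beta_exp == 0:
        raise EstimatorError(f"{pair.rsid}: Wald ratio undefined for beta_exp = 0")
    ratio = pair.beta_out / pair.beta_exp
    se = abs(pair.se_out / pair.beta_exp)
    return RatioEstimate(rsid=pair.rsid, ratio=ratio, se_ratio=se, weight=1.0 / se**2)


def ratio_estimates(pairs: Sequence[HarmonizedInstrument]) -> list[RatioEstimate]:
    return [wald_ratio(p) for p in pairs]


def ivw_q(pairs: Sequence[HarmonizedInstrument]) -> tuple[float, float]:
    """(beta_IVW_fixed, Cochran's Q about it) using weights beta_exp^2/se_out^2."""
    bx, _, by, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise EstimatorError("IVW undefined with beta_exp = 0")
    r = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta) ** 2))
    return beta, q


def ivw(
    pairs: Sequence[HarmonizedInstrument],
    mode: str = "multiplicative_random",
    alpha: float = 0.05,
) -> MrEstimate:
    """Inverse-variance-weighted estimate over the per-SNP Wald ratios.

    ``mode='fixed'`` uses SE = (sum of weights)^(-1/2); the multiplicative
    random-effects variant inflates it by sqrt(max(1, Q/(J-1))) so
    heterogeneity widens, and never narrows, the interval.  With one SNP the
    estimate equals the Wald ratio and the mode falls back to fixed.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise EstimatorError(f"unknown IVW mode {mode!r}")
    if len(pairs) == 0:
        raise EstimatorError("IVW needs at least one instrument")
    beta, q = ivw_q(pairs)
    bx, _, _, sy = _arrays(pairs)
    w = bx**2 / sy**2
    se = float(np.sum(w) ** -0.5)
    j = len(pairs)
    method = "ivw_fe"
    if mode == "multiplicative_random":
        if j == 1:
            warnings.warn("IVW multiplicative random effects needs J >= 2; using fixed")
        else:
            se *= math.sqrt(max(1.0, q / (j - 1)))
            method = "ivw_mre"
    pval = 2 * stats.norm.sf(abs(beta / se))
    return _estimate(method, beta, se, pval, j, alpha)


def egger(
    pairs: Sequence[HarmonizedInstrument],
    alpha: float = 0.05,
    i2_threshold: float = 0.90,
    truncate_inflation: bool = True,
) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger weighted regression with intercept; returns (slope, intercept).

    Pairs are re-signed so every exposure effect is non-negative (the
    orientation convention that makes the intercept identifiable), then
    outcome effects are regressed on exposure effects with weights
    1/se_out^2.  SEs carry a multiplicative variance inflation of
    max(1, Q_egger/(J-2)) so under-dispersion never shrinks the reported
    interval below its fixed-effect width; ``truncate_inflation=False``
    keeps the plain WLS scale Q/(J-2), giving the exact t(J-2) test used
    for the pleiotropy intercept hypothesis.  If the exposure-side
    I-squared falls below ``i2_threshold`` the NOME assumption is doubtful
    and both estimates carry a warning flag (regression-dilution correction
    such as SIMEX is not applied here).
    """
    import statsmodels.api as sm

    j = len(pairs)
    if j < 3:
        raise EstimatorError(f"MR-Egger needs J >= 3 instruments, got {j}")
    bx, sx, by, sy = _arrays(pairs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise EstimatorError("MR-Egger undefined: no variance in exposure effects")
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, slope = fit.params
    # statsmodels scales the covariance by Q/(J-2); re-scale to max(1, Q/(J-2)).
    resid = by - (intercept + slope * bx)
    q = float(np.sum(w * resid**2))
    scale = q / (j - 2)
    rel_resid = q / max(float(np.sum(w * by**2)), np.finfo(float).tiny)
    if rel_resid < 1e-24:  # numerically exact fit: degenerate inference
        q = 0.0
        se_int = se_slope = 0.0
    elif truncate_inflation and scale < 1:
        se_int, se_slope = fit.bse / math.sqrt(scale)
    else:
        se_int, se_slope = fit.bse

    nome = i2_gx(pairs).value < i2_threshold if j >= 2 else False

    scale_ref = float(np.max(np.abs(by))) or 1.0

    def t_pval(value: float, se: float) -> float:
        if se == 0:  # exact fit: the test is degenerate, not significant at ~0
            return 1.0 if abs(value) < 1e-10 * scale_ref else 0.0
        return 2 * stats.t.sf(abs(value / se), df=j - 2)

    p_slope = t_pval(slope, se_slope)
    p_int = t_pval(intercept, se_int)
    slope_est = _estimate("egger_slope", slope, se_slope, p_slope, j, alpha, nome_warning=nome)
    # the intercept is an average direct effect, not an OR per SD; the
    # exponentiated columns are still populated for uniform reporting
    int_est = _estimate("egger_intercept", intercept, se_int, p_int, j, alpha, nome_warning=nome)
    return slope_est, int_est


@dataclass(frozen=True)
class I2Gx:
    """Exposure-side I-squared: how far the NOME assumption is from holding."""

    value: float
    q_gx: float
    needs_correction: bool
    threshold: float = 0.90


def i2_gx(pairs: Sequence[HarmonizedInstrument], threshold: float = 0.90) -> I2Gx:
    """I-squared of the exposure effects weighted by 1/se_exp^2.

    Values near 1 mean exposure effects are measured with negligible error
    relative to their spread (NOME holds for MR-Egger); below ``threshold``
    (default 0.90) the Egger slope is attenuated and flagged.
    """
    j = len(pairs)
    if j < 2:
        raise EstimatorError("I2_GX needs J >= 2")
    bx, sx, _, _ = _arrays(pairs)
    w = 1.0 / sx**2
    bbar = float(np.sum(w * bx) / np.sum(w))
    q_gx = float(np.sum(w * (bx - bbar) ** 2))
    value = max(0.0, (q_gx - (j - 1)) / q_gx) if q_gx > 0 else 0.0
    return I2Gx(value=value, q_gx=q_gx, needs_correction=value < threshold, threshold=threshold)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` under ``weights``.

    Ratios are sorted; the cumulative weight of each, centred on its own mass
    (cumsum - w/2, normalized), places it on [0, 1]; the value at cumulative
    weight one half is linearly interpolated.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cw = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cw, r))


def _bootstrap_se(
    pairs: Sequence[HarmonizedInstrument],
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: redraw effects from their sampling distributions."""
    bx, sx, by, sy = _arrays(pairs)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        ratios = by_b / bx_b
        weights = bx_b**2 / sy**2
        draws[b] = point_fn(ratios, weights)
    return float(np.std(draws, ddof=1))


def weighted_median(
    pairs: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MrEstimate:
    """Weighted-median estimator: robust while valid instruments hold >50% weight.

    SE by parametric bootstrap (``n_boot`` redraws of both effect vectors from
    their sampling distributions, seeded).  ``n_boot=0`` skips the bootstrap
    and reports SE/p as NaN — useful in simulation studies that only need the
    point estimate.
    """
    if len(pairs) < 3:
        raise EstimatorError(f"weighted median needs J >= 3, got {len(pairs)}")
    est = [wald_ratio(p) for p in pairs]
    ratios = np.array([e.ratio for e in est])
    weights = np.array([e.weight for e in est])
    beta = weighted_median_point(ratios, weights)
    if n_boot == 0:
        return MrEstimate(
            method="weighted_median", beta=beta, se=float("nan"), pval=float("nan"),
            or_=math.exp(beta), ci_low=float("nan"), ci_high=float("nan"),
            n_snp=len(pairs),
        )
    if seed is None:
        raise EstimatorError("weighted_median bootstrap requires an explicit seed")
    se = _bootstrap_se(pairs, weighted_median_point, n_boot, seed)
    pval = 2 * stats.norm.sf(abs(beta / se))
    return _estimate("weighted_median", beta, se, pval, len(pairs), alpha)


def mode_bandwidth(ratios: np.ndarray, phi: float = 1.0) -> float:
    """Modified Silverman bandwidth: phi * 0.9 * min(sd, scaled MAD) * J^(-1/5)."""
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return phi * 0.9 * s * len(ratios) ** (-1 / 5)


def weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    """Argmax of the weight-scaled gaussian kernel density over the ratios."""
    h = mode_bandwidth(ratios, phi)
    if h == 0 or len(ratios) == 1:
        # degenerate: all ratios (nearly) identical
        return float(ratios[np.argmax(weights)])
    w = weights / np.sum(weights)

    def neg_density(x: float) -> float:
        return -float(np.sum(w * np.exp(-0.5 * ((x - ratios) / h) ** 2)))

    # candidate peaks sit at or between nearby data points; seeding from the
    # densities at the ratios themselves is robust to arbitrarily wide ranges
    # (a single wild ratio must not starve the dense cluster of resolution)
    dens_at_points = (
        w[None, :] * np.exp(-0.5 * ((ratios[:, None] - ratios[None, :]) / h) ** 2)
    ).sum(axis=1)
    x0 = float(ratios[int(np.argmax(dens_at_points))])
    res = optimize.minimize_scalar(
        neg_density, bounds=(x0 - h, x0 + h), method="bounded",
        options={"xatol": 1e-10 * max(1.0, abs(x0))},
    )
    return float(res.x) if -res.fun >= -neg_density(x0) else x0


def weighted_mode(
    pairs: Sequence[HarmonizedInstrument],
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MrEstimate:
    """Weighted-mode estimator: the dominant cluster of ratio estimates wins.

    ``phi`` scales the kernel bandwidth (default 1 x the modified Silverman
    rule over the ratios); SE by the same parametric bootstrap as
    :func:`weighted_median`.
    """
    if len(pairs) < 3:
        raise EstimatorError(f"weighted mode needs J >= 3, got {len(pairs)}")
    if not phi > 0:
        raise EstimatorError(f"phi must be > 0, got {phi}")
    est = [wald_ratio(p) for p in pairs]
    ratios = np.array([e.ratio for e in est])
    weights = np.array([e.weight for e in est])
    beta = weighted_mode_point(ratios, weights, phi)
    if n_boot == 0:
        return MrEstimate(
            method="weighted_mode", beta=beta, se=float("nan"), pval=float("nan"),
            or_=math.exp(beta), ci_low=float("nan"), ci_high=float("nan"),
            n_snp=len(pairs),
        )
    if seed is None:
        raise EstimatorError("weighted_mode bootstrap requires an explicit seed")
    se = _bootstrap_se(
        pairs, lambda r, w: weighted_mode_point(r, w, phi), n_boot, seed
    )
    pval = 2 * stats.norm.sf(abs(beta / se))
    return _estimate("weighted_mode", beta, se, pval, len(pairs), alpha)


def _raps_negll(params: np.ndarray, bx, sx, by, sy, overdispersion: bool) -> float:
    beta = params[0]
    tau2 = params[1] ** 2 if overdispersion else 0.0
    var = sy**2 + beta**2 * sx**2 + tau2
    resid = by - beta * bx
    return 0.5 * float(np.sum(np.log(var) + resid**2 / var))


def mr_raps(
    pairs: Sequence[HarmonizedInstrument],
    overdispersion: bool = True,
    alpha: float = 0.05,
    tol: float = 1e-8,
) -> MrEstimate:
    """Robust adjusted profile score estimator.

    Maximizes the profile likelihood in which each standardized residual
    ``(beta_out - beta * beta_exp) / sqrt(se_out^2 + beta^2 se_exp^2 + tau2)``
    is standard normal; ``tau2`` is an additive overdispersion absorbing
    balanced (mean-zero) pleiotropy, fixed at 0 when ``overdispersion`` is
    off.  The SE comes from the observed information at the optimum.  With
    error-free exposure effects and no overdispersion this reduces exactly to
    fixed-effect IVW.
    """
    j = len(pairs)
    if j < 3:
        raise EstimatorError(f"MR-RAPS needs J >= 3, got {j}")
    bx, sx, by, sy = _arrays(pairs)
    beta0, _ = ivw_q(pairs)

    if overdispersion:
        x0 = np.array([beta0, 1e-3])
        res = optimize.minimize(
            _raps_negll, x0, args=(bx, sx, by, sy, True), method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": 20_000},
        )
        if not res.success:
            raise EstimatorError(f"MR-RAPS did not converge: {res.message}")
        beta, tau2 = float(res.x[0]), float(res.x[1] ** 2)
    else:
        res = optimize.minimize_scalar(
            lambda b: _raps_negll(np.array([b]), bx, sx, by, sy, False),
            bounds=(beta0 - 10.0, beta0 + 10.0), method="bounded",
            options={"xatol": tol},
        )
        beta, tau2 = float(res.x), 0.0

    # observed information for beta via central finite differences of the
    # profile negative log-likelihood (tau2 held at its optimum)
    def prof(b: float) -> float:
        p = np.array([b, math.sqrt(tau2)]) if overdispersion else np.array([b])
        return _raps_negll(p, bx, sx, by, sy, overdispersion)

    h = max(1e-5, 1e-4 * abs(beta))
    d2 = (prof(beta + h) - 2 * prof(beta) + prof(beta - h)) / h**2
    if d2 <= 0:
        raise EstimatorError("MR-RAPS information non-positive at optimum")
    se = d2**-0.5
    pval = 2 * stats.norm.sf(abs(beta / se))
    return _estimate("raps", beta, se, pval, j, alpha, tau2=tau2)
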