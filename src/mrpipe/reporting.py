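"""Result assembly: odds-ratio scaling, statistical power, multiple-testing
adjustment, and tabular/graphical report generation.

The tabular contract mirrors the two summary tables an MR study reports: a
main-results table (exposure, nSNP, OR per SD with 95% CI, IVW p, power %)
and a sensitivity table (Q statistics with p-values, exposure-side
I-squared, Egger-intercept pleiotropy p, Steiger direction).  Plots
(scatter, forest, funnel, leave-one-out) are optional artifacts behind a
flag; the tables are the contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, wald_ratio
from .sensitivity import (
    HeterogeneityResult,
    LeaveOneOutRow,
    PleiotropyTest,
    PressoResult,
    SteigerResult,
)
from .summary_io import HarmonizedInstrument


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the binary-outcome MR power calculation.

    ``or_per_sd`` is the hypothesized outcome odds ratio per SD of exposure;
    ``r2_instruments`` the exposure variance the instruments explain;
    ``case_fraction`` the case prevalence in the outcome sample.
    """

    n_total: int
    case_fraction: float
    r2_instruments: float
    or_per_sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.n_total > 0:
            raise ReportError(f"n_total must be positive, got {self.n_total}")
        for name in ("case_fraction", "r2_instruments", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ReportError(f"{name} must lie in (0, 1), got {v}")
        if not self.or_per_sd > 0:
            raise ReportError(f"or_per_sd must be positive, got {self.or_per_sd}")


def or_ci(beta: float, se: float, alpha: float = 0.05) -> tuple[float, float, float]:
    """Odds ratio and Wald CI from a log-odds estimate: exp(beta -/+ z*se)."""
    if not se > 0:
        raise ReportError(f"se must be > 0, got {se}")
    z = stats.norm.ppf(1 - alpha / 2)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def binary_outcome_power(inp: PowerInput) -> float:
    """Two-sided power of the IVW Wald test for a binary outcome.

    Noncentrality delta = ln(OR per SD) * sqrt(N * R2 * K * (1 - K)) with K
    the case fraction; power = 1 - Phi(z_{1-a/2} - |delta|) +
    Phi(-z_{1-a/2} - |delta|).  At OR = 1 this returns exactly alpha.
    """
    delta = abs(math.log(inp.or_per_sd)) * math.sqrt(
        inp.n_total * inp.r2_instruments * inp.case_fraction * (1 - inp.case_fraction)
    )
    z = stats.norm.ppf(1 - inp.alpha / 2)
    return float(stats.norm.sf(z - delta) + stats.norm.cdf(-z - delta))


def adjust_pvalues(pvals: Sequence[float], method: str = "none") -> list[float]:
    """Multiple-testing adjustment: ``none``, ``bonferroni`` or ``bh``.

    Returns adjusted p-values in the input order (an order-preserving
    mapping).  Benjamini-Hochberg controls the FDR via the standard step-up.
    """
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)):
        raise ReportError("p-values must lie in (0, 1]")
    if method == "none":
        return [float(p) for p in arr]
    if method == "bonferroni":
        return [float(p) for p in multipletests(arr, method="bonferroni")[1]]
    if method == "bh":
        return [float(p) for p in multipletests(arr, method="fdr_bh")[1]]
    raise ReportError(f"unknown adjustment method {method!r}")


@dataclass
class ExposureResult:
    """Everything computed for one exposure, feeding one row of each table."""

    exposure: str
    outcome: str
    estimates: dict[str, MrEstimate]
    heterogeneity_ivw: HeterogeneityResult | None = None
    heterogeneity_egger: HeterogeneityResult | None = None
    i2_gx: float | None = None
    pleiotropy: PleiotropyTest | None = None
    presso: PressoResult | None = None
    steiger: SteigerResult | None = None
    loo: list[LeaveOneOutRow] | None = None
    power_pct: float | None = None
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    audit: list = field(default_factory=list)

    @property
    def headline(self) -> MrEstimate:
        """Headline estimate: multiplicative random-effects IVW when available."""
        for m in ("ivw_mre", "ivw_fe", "wald"):
            if m in self.estimates:
                return self.estimates[m]
        return next(iter(self.estimates.values()))


@dataclass
class MrReport:
    """Assembled per-exposure results plus run metadata."""

    results: list[ExposureResult]
    metadata: dict = field(default_factory=dict)
    main_table: pd.DataFrame | None = None
    sensitivity_table: pd.DataFrame | None = None
    estimates_table: pd.DataFrame | None = None


_MAIN_COLUMNS = [
    "exposure", "outcome", "nSNP", "OR", "ci_low", "ci_high",
    "ivw_pval", "adjusted_pval", "power_pct",
]
_SENS_COLUMNS = [
    "exposure", "outcome", "q_ivw", "q_ivw_pval", "q_egger", "q_egger_pval",
    "i2_gx", "pleiotropy_pval", "steiger_direction",
]


def build_report(
    results: Sequence[ExposureResult],
    adjust_method: str = "none",
    outdir: str | Path | None = None,
    plots: bool = False,
    metadata: Mapping | None = None,
) -> MrReport:
    """Assemble tables (and optionally plots) from per-exposure results.

    The main table carries one row per exposure with the headline IVW
    estimate; its ``adjusted_pval`` column applies ``adjust_method`` across
    exposures (the method name is stamped in metadata).  All numeric cells
    come straight from the estimate objects.  With ``outdir``, tables are
    written as TSV plus a JSON bundle; regeneration from the same results is
    byte-identical.
    """
    if not results:
        raise ReportError("build_report needs at least one exposure result")
    main_rows = []
    sens_rows = []
    est_rows = []
    for res in results:
        head = res.headline
        main_rows.append(
            {
                "exposure": res.exposure,
                "outcome": res.outcome,
                "nSNP": head.n_snp,
                "OR": head.or_,
                "ci_low": head.ci_low,
                "ci_high": head.ci_high,
                "ivw_pval": head.pval,
                "adjusted_pval": head.pval,  # overwritten below
                "power_pct": res.power_pct,
            }
        )
        sens_rows.append(
            {
                "exposure": res.exposure,
                "outcome": res.outcome,
                "q_ivw": res.heterogeneity_ivw.q if res.heterogeneity_ivw else None,
                "q_ivw_pval": res.heterogeneity_ivw.pval if res.heterogeneity_ivw else None,
                "q_egger": res.heterogeneity_egger.q if res.heterogeneity_egger else None,
                "q_egger_pval": res.heterogeneity_egger.pval if res.heterogeneity_egger else None,
                "i2_gx": res.i2_gx,
                "pleiotropy_pval": res.pleiotropy.pval if res.pleiotropy else None,
                "steiger_direction": res.steiger.direction if res.steiger else None,
            }
        )
        for est in res.estimates.values():
            est_rows.append(
                {
                    "exposure": res.exposure,
                    "outcome": res.outcome,
                    "method": est.method,
                    "nsnp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "pval": est.pval,
                    "OR": est.or_,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
    main = pd.DataFrame(main_rows, columns=_MAIN_COLUMNS)
    main["adjusted_pval"] = adjust_pvalues(main["ivw_pval"].tolist(), adjust_method)
    sens = pd.DataFrame(sens_rows, columns=_SENS_COLUMNS)
    ests = pd.DataFrame(est_rows)

    meta = dict(metadata or {})
    meta["adjust_method"] = adjust_method
    report = MrReport(
        results=list(results),
        metadata=meta,
        main_table=main,
        sensitivity_table=sens,
        estimates_table=ests,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        main.to_csv(outdir / "main_results.tsv", sep="\t", index=False, float_format="%.10g")
        sens.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False, float_format="%.10g")
        ests.to_csv(outdir / "estimates.tsv", sep="\t", index=False, float_format="%.10g")
        bundle = {
            "metadata": meta,
            "main": json.loads(main.to_json(orient="records", double_precision=12)),
            "sensitivity": json.loads(sens.to_json(orient="records", double_precision=12)),
            "estimates": json.loads(ests.to_json(orient="records", double_precision=12)),
        }
        (outdir / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
        if plots:
            for res in results:
                render_plots(res, outdir)
    return report


def forest_table(results: Sequence[ExposureResult], alpha: float = 0.05) -> pd.DataFrame:
    """Significant exposures sorted by OR — the forest-plot data table."""
    rows = [
        {
            "exposure": r.exposure,
            "OR": r.headline.or_,
            "ci_low": r.headline.ci_low,
            "ci_high": r.headline.ci_high,
            "pval": r.headline.pval,
        }
        for r in results
        if r.headline.pval < alpha
    ]
    return pd.DataFrame(rows).sort_values("OR").reset_index(drop=True) if rows else pd.DataFrame(
        columns=["exposure", "OR", "ci_low", "ci_high", "pval"]
    )


def render_plots(res: ExposureResult, outdir: str | Path) -> list[Path]:
    """Write scatter, funnel and leave-one-out plots for one exposure (SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in res.exposure)
    pairs = res.instruments
    if pairs:
        bx = np.array([p.beta_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        sx = np.array([p.se_exp for p in pairs])
        sy = np.array([p.se_out for p in pairs])

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", ms=3, lw=0.8, alpha=0.7)
        xs = np.linspace(min(0, bx.min()), bx.max(), 50)
        for name, est in res.estimates.items():
            if name in ("ivw_mre", "ivw_fe", "egger_slope", "weighted_median"):
                intercept = 0.0
                if name == "egger_slope" and "egger_intercept" in res.estimates:
                    intercept = res.estimates["egger_intercept"].beta
                ax.plot(xs, intercept + est.beta * xs, label=name, lw=1)
        ax.set_xlabel("SNP effect on exposure")
        ax.set_ylabel("SNP effect on outcome (log odds)")
        ax.legend(fontsize=7)
        ax.set_title(res.exposure, fontsize=9)
        p = outdir / f"scatter_{safe}.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

        ratios = np.array([wald_ratio(pair).ratio for pair in pairs])
        prec = np.abs(bx / sy)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(ratios, prec, s=10)
        ax.axvline(res.headline.beta, color="k", lw=1)
        ax.set_xlabel("per-SNP Wald ratio")
        ax.set_ylabel("precision |beta_exp|/se_out")
        ax.set_title(f"funnel: {res.exposure}", fontsize=9)
        p = outdir / f"funnel_{safe}.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    if res.loo:
        rows = [r for r in res.loo if r.omitted is not None]
        fig, ax = plt.subplots(figsize=(5, 0.25 * len(rows) + 1.5))
        ys = np.arange(len(rows))
        betas = [r.estimate.beta for r in rows]
        ses = [r.estimate.se for r in rows]
        ax.errorbar(betas, ys, xerr=[1.96 * s for s in ses], fmt="o", ms=3, lw=0.8)
        ax.axvline(res.headline.beta, color="k", lw=1)
        ax.set_yticks(ys)
        ax.set_yticklabels([r.omitted for r in rows], fontsize=6)
        ax.set_xlabel("IVW estimate omitting each SNP")
        fig.tight_layout()
        p = outdir / f"leave_one_out_{safe}.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    return written
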