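"""End-to-end orchestration of the two-sample MR workflow.

``run_pipeline`` executes, in a fixed order, the full filter-and-estimate
chain: instrument p-value threshold -> LD clumping -> outcome lookup with
proxy substitution -> allele harmonization (palindrome / ambiguous removal)
-> weak-instrument (F) filter -> Steiger directionality filter -> confounder
exclusion -> MR-PRESSO outlier removal -> the five estimators -> the
sensitivity suite -> power -> report.  Every removal is logged in an audit
whose counts reconcile, so the selection narrative of a study report can be
reconstructed from the log alone.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from . import estimators as est
from . import sensitivity as sens
from .instruments import (
    ConfounderAnnotation,
    InstrumentError,
    InstrumentSet,
    LdInfo,
    exclude_confounders,
    filter_pvalue,
    filter_weak_instruments,
    ld_clump,
    proxy_substitute,
    steiger_filter,
)
from .reporting import (
    ExposureResult,
    MrReport,
    PowerInput,
    binary_outcome_power,
    build_report,
)
from .summary_io import SummarySet, harmonize, read_summary
from .synthetic import SimConfig, simulate_pair

logger = logging.getLogger(__name__)


class Thresholds(BaseModel):
    """Every numeric selection threshold of the workflow, in one place."""

    p_instrument: float = Field(1e-5, gt=0, lt=1)
    clump_r2: float = Field(0.001, gt=0, lt=1)
    clump_kb: float = Field(10_000.0, gt=0)
    proxy_r2: float = Field(0.8, gt=0, lt=1)
    f_min: float = Field(10.0, ge=0)
    palindrome_window: tuple[float, float] = (0.01, 0.30)
    confounder_p: float = Field(5e-8, gt=0, lt=1)
    presso_sims: int = Field(1000, ge=100)
    presso_alpha: float = Field(0.05, gt=0, lt=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    power_r2: float = Field(0.01, gt=0, lt=1)


class PipelineConfig(BaseModel):
    """Declarative configuration for one pipeline run.

    Either file inputs (``exposure_path`` and ``outcome_path``) or a
    ``simulate`` block must be given.  ``simulate.n_exposures`` > 1 runs a
    batch of independently seeded simulated exposures against their own
    outcomes, one report row each.
    """

    exposure_path: Optional[str] = None
    outcome_path: Optional[str] = None
    simulate: Optional[SimConfig] = None
    n_exposures: int = Field(1, ge=1)
    ld_pairs_path: Optional[str] = None
    ld_positions_path: Optional[str] = None
    proxy_pairs_path: Optional[str] = None
    confounder_path: Optional[str] = None
    confounder_traits: Optional[list[str]] = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    adjust_method: str = "none"
    seed: int = 0
    outdir: Optional[str] = None
    plots: bool = False
    skip_clump: bool = False
    skip_presso: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _analyze_exposure(
    exposure: SummarySet,
    outcome: SummarySet,
    cfg: PipelineConfig,
    ld: LdInfo,
    annotation: ConfounderAnnotation | None,
    seed: int,
) -> ExposureResult:
    th = cfg.thresholds

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    initial_rsids = exposure.rsids
    sel = stage("instrument p threshold", lambda: filter_pvalue(exposure, th.p_instrument))
    removed_p = sorted(set(initial_rsids) - set(sel.rsids))
    pre_clump = sel.rsids
    if not cfg.skip_clump:
        sel = stage("LD clumping", lambda: ld_clump(sel, ld, th.clump_r2, th.clump_kb))
    removed_clump = sorted(set(pre_clump) - set(sel.rsids))

    mapping, dropped_no_proxy = stage(
        "proxy substitution",
        lambda: proxy_substitute(sel.rsids, outcome, ld, th.proxy_r2),
    )
    from dataclasses import replace as _replace

    lookup = {}
    for rsid, target in mapping.items():
        rec = outcome[target]
        if target != rsid:
            # proxy stands in for the exposure SNP under the exposure SNP's name
            rec = _replace(rec, rsid=rsid)
        lookup[rsid] = rec
    pre_avail = sel.rsids
    sel = sel.subset(mapping.keys())
    if not len(sel):
        raise PipelineError("proxy substitution", InstrumentError("no instrument has outcome data"))
    outcome_matched = SummarySet(
        trait=outcome.trait, records=[lookup[r] for r in sel.rsids], provenance=outcome.provenance
    )

    harm = stage(
        "harmonization",
        lambda: harmonize(sel, outcome_matched, palindrome_window=th.palindrome_window),
    )
    inst = InstrumentSet(instruments=list(harm))
    inst.record("instrument p threshold", initial_rsids, removed_p, threshold=th.p_instrument)
    inst.record("LD clump", pre_clump, removed_clump, r2=th.clump_r2, window_kb=th.clump_kb)
    inst.record("outcome availability / proxy", pre_avail, sorted(dropped_no_proxy))
    inst.record(
        "palindrome / ambiguous",
        sel.rsids,
        harm.dropped["palindromic"] + harm.dropped["ambiguous"],
        dispositions=harm.dispositions,
    )

    inst = stage("weak instruments", lambda: filter_weak_instruments(inst, th.f_min))
    inst = stage("Steiger filter", lambda: steiger_filter(inst))
    if annotation is not None:
        inst = stage(
            "confounder exclusion",
            lambda: exclude_confounders(inst, annotation, th.confounder_p),
        )

    presso = None
    if not cfg.skip_presso and len(inst) >= 4:
        presso = stage(
            "MR-PRESSO",
            lambda: sens.mr_presso(
                inst.instruments, n_sim=th.presso_sims, seed=seed, outlier_alpha=th.presso_alpha
            ),
        )
        if presso.outliers:
            keep = [p for p in inst.instruments if p.rsid not in set(presso.outliers)]
            nxt = InstrumentSet(instruments=keep, audit=list(inst.audit))
            nxt.record("MR-PRESSO outliers", inst.instruments, presso.outliers)
            inst = nxt
        else:
            inst.record("MR-PRESSO outliers", inst.instruments, [])

    pairs = inst.instruments
    j = len(pairs)
    if j == 0:
        raise PipelineError("estimation", InstrumentError("no instruments survive filtering"))

    estimates: dict[str, est.MrEstimate] = {}
    het_ivw = het_egger = None
    i2 = None
    pleio = None
    steiger = None
    loo = None
    if j < 3:
        logger.warning(
            "%s: only %d instrument(s) survive; downgraded analysis (Wald/IVW only)",
            exposure.trait, j,
        )
        if j == 1:
            estimates["wald"] = est.ivw(pairs, mode="fixed", alpha=th.alpha)
        else:
            estimates["ivw_mre"] = est.ivw(pairs, mode="multiplicative_random", alpha=th.alpha)
            estimates["ivw_fe"] = est.ivw(pairs, mode="fixed", alpha=th.alpha)
            het_ivw = sens.cochran_q(pairs, "ivw")
    else:
        estimates["ivw_mre"] = est.ivw(pairs, mode="multiplicative_random", alpha=th.alpha)
        estimates["ivw_fe"] = est.ivw(pairs, mode="fixed", alpha=th.alpha)
        slope, intercept = est.egger(pairs, alpha=th.alpha)
        estimates["egger_slope"] = slope
        estimates["egger_intercept"] = intercept
        estimates["weighted_median"] = est.weighted_median(pairs, seed=seed + 1, alpha=th.alpha)
        estimates["weighted_mode"] = est.weighted_mode(pairs, seed=seed + 2, alpha=th.alpha)
        estimates["raps"] = est.mr_raps(pairs, overdispersion=True, alpha=th.alpha)
        het_ivw = sens.cochran_q(pairs, "ivw")
        het_egger = sens.cochran_q(pairs, "egger")
        i2 = est.i2_gx(pairs).value
        pleio = sens.egger_intercept_test(pairs)
        loo = sens.leave_one_out(pairs, alpha=th.alpha)
    try:
        steiger = sens.steiger_direction(pairs)
    except est.EstimatorError:
        steiger = None

    n_case = next((p.n_case for p in pairs if p.n_case), None)
    n_out = next((p.n_out for p in pairs if p.n_out), None)
    power_pct = None
    if n_case and n_out:
        head = estimates.get("ivw_mre") or next(iter(estimates.values()))
        power_pct = 100.0 * binary_outcome_power(
            PowerInput(
                n_total=int(n_out),
                case_fraction=n_case / n_out,
                r2_instruments=th.power_r2,
                or_per_sd=head.or_,
                alpha=th.alpha,
            )
        )

    for entry in inst.audit:
        logger.info(
            "%s | %-28s n_before=%-5d removed=%-4d n_after=%d",
            exposure.trait, entry.filter_name, entry.n_before, entry.n_removed, entry.n_after,
        )

    res = ExposureResult(
        exposure=exposure.trait,
        outcome=outcome.trait,
        estimates=estimates,
        heterogeneity_ivw=het_ivw,
        heterogeneity_egger=het_egger,
        i2_gx=i2,
        pleiotropy=pleio,
        presso=presso,
        steiger=steiger,
        loo=loo,
        power_pct=power_pct,
        instruments=list(pairs),
        audit=inst.audit,
    )
    return res


def run_pipeline(cfg: PipelineConfig) -> MrReport:
    """Run the full select -> harmonize -> estimate -> sensitivity -> report chain.

    Returns the assembled :class:`MrReport`; with ``cfg.outdir`` the tables,
    audit and (optionally) plots are also written to disk.  Fully
    reproducible given ``cfg.seed``.
    """
    ld = LdInfo.read(cfg.ld_pairs_path, cfg.ld_positions_path)
    if cfg.proxy_pairs_path:
        proxy_ld = LdInfo.read(cfg.proxy_pairs_path, cfg.ld_positions_path)
        ld.pairs.update(proxy_ld.pairs)
    annotation = None
    if cfg.confounder_path:
        annotation = ConfounderAnnotation.read(cfg.confounder_path, cfg.confounder_traits)
    elif cfg.confounder_traits:
        annotation = ConfounderAnnotation(entries=[], confounder_traits=frozenset(cfg.confounder_traits))

    runs: list[tuple[SummarySet, SummarySet, int]] = []
    if cfg.simulate is not None:
        for k in range(cfg.n_exposures):
            sim_cfg = cfg.simulate.model_copy(
                update={"seed": (cfg.simulate.seed + 7919 * k) % 2**31}
            )
            exposure, outcome, _truth = simulate_pair(sim_cfg)
            if cfg.n_exposures > 1:
                exposure = SummarySet(
                    trait=f"exposure_{k:03d}", records=[
                        _retrait(r, f"exposure_{k:03d}") for r in exposure.records
                    ], provenance=exposure.provenance,
                )
            runs.append((exposure, outcome, (cfg.seed + 104729 * k) % 2**31))
    elif cfg.exposure_path and cfg.outcome_path:
        exposure = read_summary(cfg.exposure_path)
        outcome = read_summary(cfg.outcome_path)
        runs.append((exposure, outcome, cfg.seed))
    else:
        raise ValueError("config needs either file inputs or a simulate block")

    results = []
    for exposure, outcome, seed in runs:
        results.append(_analyze_exposure(exposure, outcome, cfg, ld, annotation, seed))

    metadata = {
        "seed": cfg.seed,
        "thresholds": cfg.thresholds.model_dump(),
        "n_exposures": len(results),
        "filter_order": [
            "instrument p threshold", "LD clump", "outcome availability / proxy",
            "palindrome / ambiguous", "weak instrument (F)", "Steiger directionality",
            "confounder association", "MR-PRESSO outliers",
        ],
    }
    report = build_report(
        results,
        adjust_method=cfg.adjust_method,
        outdir=cfg.outdir,
        plots=cfg.plots,
        metadata=metadata,
    )
    if cfg.outdir:
        audit_path = Path(cfg.outdir) / "audit.json"
        import json as _json

        audit_path.write_text(
            _json.dumps(
                {
                    r.exposure: _json.loads(
                        InstrumentSet(instruments=r.instruments, audit=r.audit).audit_json()
                    )
                    for r in results
                },
                indent=2,
            )
            + "\n"
        )
    return report


def _retrait(rec, trait: str):
    from dataclasses import replace

    return replace(rec, trait=trait)
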