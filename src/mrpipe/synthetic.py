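"""Synthetic paired GWAS summary statistics with known causal ground truth.

The generator emulates the structure of a microbiota-abundance exposure GWAS
paired with a heavily imbalanced case/control outcome GWAS: per-SNP exposure
effects with frequency-dependent sampling noise, outcome effects on the
log-odds scale built as true_beta * (true exposure effect) + pleiotropy +
noise, a configurable fraction of invalid (pleiotropic) instruments with
directional or balanced direct effects, weak instruments via the exposure
effect scale, palindromic A/T and G/C variants, and realistic allele /
frequency metadata.  Everything flows through one seeded generator.

Default sample sizes mirror the study conditions this package was built
around: an exposure meta-analysis of ~18k subjects and an outcome cohort of
740 cases / 372,016 controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .summary_io import (
    HarmonizedInstrument,
    SnpAssociation,
    SummarySet,
)

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


class SimConfig(BaseModel):
    """Generative parameters for one exposure/outcome summary-statistic pair."""

    n_snp: int = Field(100, ge=1)
    n_exp: int = Field(18_340, gt=2)
    n_case: int = Field(740, gt=1)
    n_control: int = Field(372_016, gt=1)
    true_beta: float = 0.0
    exposure_effect_sd: float = Field(0.05, gt=0)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = Field(0.0, ge=0)
    invalid_fraction: float = Field(0.0, ge=0, le=1)
    inside_violation_corr: float = Field(0.0, ge=-1, le=1)
    palindromic_fraction: float = Field(0.0, ge=0, le=1)
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    @property
    def n_out(self) -> int:
        return self.n_case + self.n_control

    @property
    def n_eff_out(self) -> float:
        """Effective outcome sample size under case/control imbalance."""
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)

    @model_validator(mode="after")
    def _check_maf(self) -> "SimConfig":
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        return self


@dataclass
class SimTruth:
    """The generative ground truth behind a synthetic dataset."""

    true_beta: float
    rsids: list[str]
    gamma: np.ndarray  # true per-SNP exposure effects
    alpha: np.ndarray  # per-SNP pleiotropy (direct outcome effects)
    valid: np.ndarray  # bool, True where alpha == 0 by construction
    planted_outlier: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.planted_outlier is None:
            self.planted_outlier = np.zeros(len(self.rsids), dtype=bool)

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_beta": self.true_beta,
                "rsids": self.rsids,
                "gamma": self.gamma.tolist(),
                "alpha": self.alpha.tolist(),
                "valid": self.valid.astype(bool).tolist(),
                "planted_outlier": self.planted_outlier.astype(bool).tolist(),
            },
            indent=2,
        )


def _se_exposure(maf: np.ndarray, n: int) -> np.ndarray:
    # per-allele SE of a continuous-trait GWAS beta, unit trait variance
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_outcome(maf: np.ndarray, n_eff: float) -> np.ndarray:
    # log-OR SE: var = 1/(2p(1-p)n_case) + 1/(2p(1-p)n_control) = 4/(2p(1-p)n_eff)
    return 2.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)


def simulate_pair(cfg: SimConfig) -> tuple[SummarySet, SummarySet, SimTruth]:
    """Generate an exposure and an outcome :class:`SummarySet` plus their truth.

    Per SNP: a minor-allele frequency and an allele pair are drawn (palindromic
    pairs for the configured fraction); the true exposure effect gamma is
    Normal(0, exposure_effect_sd^2); the observed exposure beta adds sampling
    noise at the frequency/sample-size-implied SE; the observed outcome beta is
    Normal(true_beta * gamma + alpha, se_out^2) where the direct effect alpha
    is zero for valid SNPs and Normal(pleiotropy_mean, pleiotropy_sd^2) —
    optionally correlated with gamma to violate InSIDE — for the invalid
    fraction.  Directional pleiotropy is defined per exposure-raising allele,
    so alpha enters with the sign of gamma.  p-values are two-sided normal.
    Deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snp
    rsids = [f"rs{100000 + i}" for i in range(n)]
    chroms = rng.integers(1, 23, size=n)
    positions = rng.integers(1, 250_000_000, size=n)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    palindromic = rng.random(n) < cfg.palindromic_fraction
    allele_idx = rng.integers(0, 4, size=n)
    alleles = [
        _PALINDROMIC[allele_idx[i] % len(_PALINDROMIC)]
        if palindromic[i]
        else _NONPALINDROMIC[allele_idx[i] % len(_NONPALINDROMIC)]
        for i in range(n)
    ]
    # effect allele is the minor or major allele at random; eaf reflects that
    minor_is_effect = rng.random(n) < 0.5
    eaf = np.where(minor_is_effect, maf, 1.0 - maf)

    gamma = rng.normal(0.0, cfg.exposure_effect_sd, size=n)
    se_exp = _se_exposure(maf, cfg.n_exp)
    beta_exp = rng.normal(gamma, se_exp)

    valid = np.ones(n, dtype=bool)
    n_invalid = int(round(cfg.invalid_fraction * n))
    if n_invalid:
        invalid_idx = rng.choice(n, size=n_invalid, replace=False)
        valid[invalid_idx] = False
    alpha = np.zeros(n)
    if (~valid).any() and (cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0):
        k = int((~valid).sum())
        eps = rng.normal(0.0, 1.0, size=k)
        if cfg.inside_violation_corr != 0 and cfg.pleiotropy_sd > 0:
            g = gamma[~valid]
            gstd = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
            rho = cfg.inside_violation_corr
            mix = rho * gstd + np.sqrt(1 - rho**2) * eps
        else:
            mix = eps
        alpha[~valid] = cfg.pleiotropy_mean + cfg.pleiotropy_sd * mix

    # pleiotropy is directional with respect to the exposure-raising allele
    # (the orientation MR-Egger regresses in), so its contribution follows
    # the sign of the true exposure effect
    alpha_oriented = np.where(gamma < 0, -alpha, alpha)
    se_out = _se_outcome(maf, cfg.n_eff_out)
    beta_out = rng.normal(cfg.true_beta * gamma + alpha_oriented, se_out)

    def pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
        p = 2 * stats.norm.sf(np.abs(beta / se))
        return np.clip(p, np.finfo(float).tiny, 1.0)

    p_exp = pvals(beta_exp, se_exp)
    p_out = pvals(beta_out, se_out)

    exp_records = [
        SnpAssociation(
            rsid=rsids[i], chrom=str(chroms[i]), pos=int(positions[i]),
            effect_allele=alleles[i][0], other_allele=alleles[i][1],
            eaf=float(eaf[i]), beta=float(beta_exp[i]), se=float(se_exp[i]),
            pval=float(p_exp[i]), n=float(cfg.n_exp), trait="exposure",
        )
        for i in range(n)
    ]
    out_records = [
        SnpAssociation(
            rsid=rsids[i], chrom=str(chroms[i]), pos=int(positions[i]),
            effect_allele=alleles[i][0], other_allele=alleles[i][1],
            eaf=float(eaf[i]), beta=float(beta_out[i]), se=float(se_out[i]),
            pval=float(p_out[i]), n=float(cfg.n_out),
            n_case=float(cfg.n_case), n_control=float(cfg.n_control),
            trait="outcome",
        )
        for i in range(n)
    ]
    truth = SimTruth(
        true_beta=cfg.true_beta, rsids=rsids, gamma=gamma, alpha=alpha, valid=valid
    )
    exposure = SummarySet(trait="exposure", records=exp_records, provenance=f"simulated(seed={cfg.seed})")
    outcome = SummarySet(trait="outcome", records=out_records, provenance=f"simulated(seed={cfg.seed})")
    return exposure, outcome, truth


def simulate_instruments(cfg: SimConfig) -> tuple[list[HarmonizedInstrument], SimTruth]:
    """Shortcut for estimator studies: the same draws, already on one allele frame.

    Equivalent to harmonizing the output of :func:`simulate_pair` when no
    palindromic SNPs are generated; skips the allele bookkeeping.
    """
    exposure, outcome, truth = simulate_pair(cfg)
    pairs = [
        HarmonizedInstrument(
            rsid=e.rsid,
            beta_exp=e.beta, se_exp=e.se, pval_exp=e.pval, eaf_exp=e.eaf,
            beta_out=o.beta, se_out=o.se, eaf_out=o.eaf,
            n_exp=e.n, n_out=o.n, n_case=o.n_case, n_control=o.n_control,
        )
        for e, o in zip(exposure.records, outcome.records)
    ]
    return pairs, truth


def plant_outlier(
    exposure: SummarySet,
    outcome: SummarySet,
    truth: SimTruth,
    rsid: str,
    inflation_se: float,
) -> tuple[SummarySet, SummarySet, SimTruth]:
    """Inflate one SNP's outcome effect by ``inflation_se`` outcome SEs.

    Marks the SNP's planted-outlier flag in the returned truth; inflation 0 is
    the identity.  The inputs are not mutated.
    """
    if rsid not in outcome:
        raise KeyError(f"unknown rsid {rsid!r}")
    idx = truth.rsids.index(rsid)
    new_records = []
    for rec in outcome.records:
        if rec.rsid == rsid:
            rec = replace(rec, beta=rec.beta + inflation_se * rec.se)
        new_records.append(rec)
    planted = truth.planted_outlier.copy()
    planted[idx] = planted[idx] or (inflation_se != 0)
    new_truth = SimTruth(
        true_beta=truth.true_beta,
        rsids=list(truth.rsids),
        gamma=truth.gamma.copy(),
        alpha=truth.alpha.copy(),
        valid=truth.valid.copy(),
        planted_outlier=planted,
    )
    new_outcome = SummarySet(
        trait=outcome.trait, records=new_records, provenance=outcome.provenance
    )
    return exposure, new_outcome, new_truth


def plant_outlier_pairs(
    pairs: Sequence[HarmonizedInstrument], rsid: str, inflation_se: float
) -> list[HarmonizedInstrument]:
    """Same planting applied to an already-harmonized instrument list."""
    out = []
    found = False
    for p in pairs:
        if p.rsid == rsid:
            p = replace(p, beta_out=p.beta_out + inflation_se * p.se_out)
            found = True
        out.append(p)
    if not found:
        raise KeyError(f"unknown rsid {rsid!r}")
    return out
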