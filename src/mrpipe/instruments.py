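"""Instrument selection: the filter chain that turns raw exposure GWAS hits
into a valid instrumental-variable set.

Filters (applied in pipeline order): genome-wide p-value threshold, greedy LD
clumping, proxy substitution for SNPs missing from the outcome,
instrument-strength (F-statistic) filtering, offline confounder-annotation
exclusion, and per-SNP Steiger directionality filtering.  Every removal is
recorded in an ordered audit so the final count reconciles with the input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .summary_io import HarmonizedInstrument, SummarySet, normalize_chrom


class InstrumentError(ValueError):
    """Raised when a filter empties the instrument set or inputs are unusable."""


@dataclass
class LdInfo:
    """Sparse pairwise LD (r-squared) plus genomic positions.

    ``pairs`` maps unordered rsID pairs to r2; pairs not present are treated
    as r2 = 0.  ``positions`` maps rsID to (chromosome, base-pair position).
    """

    pairs: dict[frozenset, float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    @classmethod
    def from_tables(
        cls,
        pairs: Iterable[tuple[str, str, float]] = (),
        positions: Mapping[str, tuple[object, int]] | None = None,
    ) -> "LdInfo":
        pair_map: dict[frozenset, float] = {}
        for a, b, r2 in pairs:
            if not (0 <= r2 <= 1):
                raise InstrumentError(f"r2 out of range for ({a}, {b}): {r2}")
            pair_map[frozenset((a, b))] = max(pair_map.get(frozenset((a, b)), 0.0), r2)
        pos = {
            rsid: (normalize_chrom(chrom) or "NA", int(bp))
            for rsid, (chrom, bp) in (positions or {}).items()
        }
        return cls(pairs=pair_map, positions=pos)

    @classmethod
    def read(cls, pairs_path: str | Path | None, positions_path: str | Path | None) -> "LdInfo":
        """Load from TSVs: pairs (rsid_a, rsid_b, r2) and positions (rsid, chrom, pos)."""
        pair_rows: list[tuple[str, str, float]] = []
        if pairs_path is not None:
            df = pd.read_csv(pairs_path, sep="\t")
            pair_rows = [
                (str(r.rsid_a), str(r.rsid_b), float(r.r2)) for r in df.itertuples()
            ]
        pos: dict[str, tuple[object, int]] = {}
        if positions_path is not None:
            df = pd.read_csv(positions_path, sep="\t")
            pos = {str(r.rsid): (r.chrom, int(r.pos)) for r in df.itertuples()}
        return cls.from_tables(pair_rows, pos)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(frozenset((a, b)), 0.0)


@dataclass
class ConfounderAnnotation:
    """Offline SNP–trait association table standing in for a live confounder lookup.

    ``entries`` rows are (rsid, trait label, association p-value);
    ``confounder_traits`` is the set of trait labels treated as confounders of
    the exposure–outcome relationship.
    """

    entries: list[tuple[str, str, float]] = field(default_factory=list)
    confounder_traits: frozenset = frozenset({"smoking", "alcohol consumption", "obesity"})

    def __post_init__(self) -> None:
        for rsid, trait, p in self.entries:
            if not (0 < p <= 1):
                raise InstrumentError(f"annotation p out of range for {rsid}/{trait}: {p}")
        self.confounder_traits = frozenset(t.lower() for t in self.confounder_traits)

    @classmethod
    def read(cls, path: str | Path, confounder_traits: Iterable[str] | None = None) -> "ConfounderAnnotation":
        df = pd.read_csv(path, sep="\t")
        entries = [(str(r.rsid), str(r.trait), float(r.pval)) for r in df.itertuples()]
        kwargs = {}
        if confounder_traits is not None:
            kwargs["confounder_traits"] = frozenset(confounder_traits)
        return cls(entries=entries, **kwargs)

    def hits(self, rsid: str, p_assoc: float) -> list[tuple[str, float]]:
        return [
            (trait, p)
            for r, trait, p in self.entries
            if r == rsid and trait.lower() in self.confounder_traits and p < p_assoc
        ]


@dataclass
class AuditEntry:
    filter_name: str
    n_before: int
    n_removed: int
    rsids_removed: list[str] = field(default_factory=list)
    detail: dict = field(default_factory=dict)

    @property
    def n_after(self) -> int:
        return self.n_before - self.n_removed


@dataclass
class InstrumentSet:
    """Harmonized instruments plus the ordered audit of filters applied to them."""

    instruments: list[HarmonizedInstrument]
    audit: list[AuditEntry] = field(default_factory=list)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def rsids(self) -> list[str]:
        return [i.rsid for i in self.instruments]

    def record(self, filter_name: str, before: Sequence, removed_rsids: list[str], **detail) -> None:
        self.audit.append(
            AuditEntry(
                filter_name=filter_name,
                n_before=len(before),
                n_removed=len(removed_rsids),
                rsids_removed=sorted(removed_rsids),
                detail=detail,
            )
        )

    def audit_json(self) -> str:
        return json.dumps(
            [
                {
                    "filter": e.filter_name,
                    "n_before": e.n_before,
                    "n_removed": e.n_removed,
                    "n_after": e.n_after,
                    "rsids_removed": e.rsids_removed,
                    **({"detail": e.detail} if e.detail else {}),
                }
                for e in self.audit
            ],
            indent=2,
        )


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic: beta^2 / se^2.

    Sign-invariant in beta; F < 10 conventionally marks a weak instrument.
    """
    if not se > 0:
        raise InstrumentError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def filter_pvalue(summary: SummarySet, threshold: float = 1e-5) -> SummarySet:
    """Keep records associated with the trait at p strictly below ``threshold``."""
    if not (0 < threshold < 1):
        raise InstrumentError(f"p threshold must lie in (0, 1), got {threshold}")
    kept = [r for r in summary.records if r.pval < threshold]
    if not kept:
        raise InstrumentError(
            f"no SNP reaches p < {threshold:g} for {summary.trait!r}; "
            "consider relaxing the instrument threshold"
        )
    return SummarySet(trait=summary.trait, records=kept, provenance=summary.provenance)


def ld_clump(
    summary: SummarySet,
    ld: LdInfo,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> SummarySet:
    """Greedy LD clumping: retain an approximately independent SNP subset.

    Records are visited by ascending p-value (ties by position then rsID); a
    record is accepted iff no previously accepted record on the same
    chromosome both lies within ``window_kb`` of it and has r2 at or above
    ``r2_threshold`` with it.  Pairs absent from ``ld`` count as r2 = 0, so
    with an empty LD table nothing is ever rejected.
    """
    if not (0 < r2_threshold < 1):
        raise InstrumentError(f"r2_threshold must lie in (0, 1), got {r2_threshold}")
    if not window_kb > 0:
        raise InstrumentError(f"window_kb must be > 0, got {window_kb}")

    def locate(rsid: str, rec) -> tuple[str, int]:
        if rsid in ld.positions:
            return ld.positions[rsid]
        if rec.chrom is not None and rec.pos is not None:
            return rec.chrom, rec.pos
        raise InstrumentError(f"no genomic position known for {rsid}")

    ordered = sorted(
        summary.records,
        key=lambda r: (r.pval, locate(r.rsid, r)[1], r.rsid),
    )
    accepted: list = []
    for rec in ordered:
        chrom, pos = locate(rec.rsid, rec)
        clash = any(
            a_chrom == chrom
            and abs(a_pos - pos) / 1_000.0 <= window_kb
            and ld.r2(a.rsid, rec.rsid) >= r2_threshold
            for a, a_chrom, a_pos in accepted
        )
        if not clash:
            accepted.append((rec, chrom, pos))
    keep = {a.rsid for a, _, _ in accepted}
    return summary.subset(keep)


def proxy_substitute(
    needed: Sequence[str],
    outcome: SummarySet,
    proxies: LdInfo,
    r2_min: float = 0.8,
) -> tuple[dict[str, str], list[str]]:
    """Resolve exposure SNPs missing from the outcome set via high-LD proxies.

    Returns ``(mapping, dropped)`` where ``mapping[rsid]`` is the rsID to use
    when looking the SNP up in the outcome set (itself when present; otherwise
    the available proxy with maximal r2 >= ``r2_min``, ties broken by smaller
    base-pair distance then lexicographic rsID), and ``dropped`` lists SNPs
    with no qualifying proxy — a reported outcome, not an error.
    """
    if not (0 < r2_min < 1):
        raise InstrumentError(f"r2_min must lie in (0, 1), got {r2_min}")
    mapping: dict[str, str] = {}
    dropped: list[str] = []
    for rsid in needed:
        if rsid in outcome:
            mapping[rsid] = rsid
            continue
        candidates = []
        for pair, r2 in proxies.pairs.items():
            if rsid in pair and r2 >= r2_min:
                (other,) = pair - {rsid} if len(pair) == 2 else (rsid,)
                if other in outcome:
                    dist = math.inf
                    if rsid in proxies.positions and other in proxies.positions:
                        ca, pa = proxies.positions[rsid]
                        cb, pb = proxies.positions[other]
                        dist = abs(pa - pb) if ca == cb else math.inf
                    candidates.append((-r2, dist, other))
        if candidates:
            candidates.sort()
            mapping[rsid] = candidates[0][2]
        else:
            dropped.append(rsid)
    return mapping, dropped


def filter_weak(summary: SummarySet, f_min: float = 10.0) -> SummarySet:
    """Drop weak instruments: keep records with F = beta^2/se^2 >= ``f_min``."""
    if f_min < 0:
        raise InstrumentError(f"f_min must be >= 0, got {f_min}")
    kept = [r for r in summary.records if f_statistic(r.beta, r.se) >= f_min]
    if not kept:
        raise InstrumentError(f"all SNPs are weak instruments at F >= {f_min:g}")
    return SummarySet(trait=summary.trait, records=kept, provenance=summary.provenance)


def filter_weak_instruments(inst: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """F filter applied to harmonized pairs (exposure side), with audit."""
    kept = [i for i in inst.instruments if f_statistic(i.beta_exp, i.se_exp) >= f_min]
    removed = [i.rsid for i in inst.instruments if f_statistic(i.beta_exp, i.se_exp) < f_min]
    if not kept:
        raise InstrumentError(f"all instruments weak at F >= {f_min:g}")
    out = InstrumentSet(instruments=kept, audit=list(inst.audit))
    out.record("weak instrument (F)", inst.instruments, removed, f_min=f_min)
    return out


def exclude_confounders(
    inst: InstrumentSet,
    annotation: ConfounderAnnotation,
    p_assoc: float = 5e-8,
) -> InstrumentSet:
    """Drop instruments annotated to a confounder trait at p < ``p_assoc``.

    Enforces the exchangeability (independence) assumption offline: an
    instrument associated with smoking, alcohol consumption or obesity at the
    lookup threshold cannot be assumed to affect the outcome only through the
    exposure.
    """
    if not (0 < p_assoc < 1):
        raise InstrumentError(f"p_assoc must lie in (0, 1), got {p_assoc}")
    removed_pairs: list[tuple[str, str, float]] = []
    kept: list[HarmonizedInstrument] = []
    for i in inst.instruments:
        hits = annotation.hits(i.rsid, p_assoc)
        if hits:
            removed_pairs.extend((i.rsid, t, p) for t, p in hits)
        else:
            kept.append(i)
    out = InstrumentSet(instruments=kept, audit=list(inst.audit))
    out.record(
        "confounder association",
        inst.instruments,
        sorted({r for r, _, _ in removed_pairs}),
        associations=[{"rsid": r, "trait": t, "pval": p} for r, t, p in removed_pairs],
        p_assoc=p_assoc,
    )
    return out


def steiger_filter(inst: InstrumentSet) -> InstrumentSet:
    """Drop instruments whose explained variance is larger on the outcome.

    Per SNP, the squared trait correlation is approximated from the
    association z-score as z^2/(z^2 + n - 2); an instrument that explains
    more outcome than exposure variance points the wrong way causally and is
    removed.  Requires per-SNP sample sizes for both traits.
    """
    from .sensitivity import snp_r2  # local import to avoid cycle

    kept: list[HarmonizedInstrument] = []
    removed: list[str] = []
    for i in inst.instruments:
        if i.n_exp is None or i.n_out is None:
            raise InstrumentError(f"{i.rsid}: Steiger filtering needs n_exp and n_out")
        r2_exp = snp_r2(i.beta_exp, i.se_exp, i.n_exp)
        r2_out = snp_r2(i.beta_out, i.se_out, i.n_out)
        if r2_out > r2_exp:
            removed.append(i.rsid)
        else:
            kept.append(i)
    out = InstrumentSet(instruments=kept, audit=list(inst.audit))
    out.record("Steiger directionality", inst.instruments, removed)
    return out
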