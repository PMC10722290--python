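"""GWAS summary-statistic data model, TSV readers/writers, and allele harmonization.

The central objects are :class:`SnpAssociation` (one SNP's association with one
trait), :class:`SummarySet` (a trait's worth of them, keyed by rsID), and
:class:`HarmonizedInstrument` (an exposure/outcome SNP pair expressed on a
common effect-allele frame, the unit consumed by every MR estimator).

Harmonization resolves allele-frame mismatches between two summary sets:
swapped alleles flip the sign of the outcome effect, strand-complemented
records are mapped through A<->T / C<->G, and palindromic SNPs (A/T or G/C,
where strand cannot be resolved from alleles alone) are either
frequency-aligned or dropped when the effect-allele frequency falls in a
configurable ambiguity window.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Column order used by :func:`write_summary`; also the canonical field names
#: that ``column_map`` in :func:`read_summary` maps file headers onto.
CANONICAL_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_case",
    "n_control",
)

MANDATORY_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")


class SummaryIOError(ValueError):
    """Raised for malformed summary-statistic inputs."""


def normalize_chrom(label: object) -> str | None:
    """Normalize a chromosome label so that ``chr1``, ``1`` and ``01`` compare equal."""
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return None
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.lstrip("0") or "0"
    return s.upper()


@dataclass(frozen=True)
class SnpAssociation:
    """One biallelic SNP's summary association with one trait.

    ``beta`` is per effect-allele copy: log odds for binary traits, trait
    units otherwise.  ``eaf`` is the effect-allele frequency and may be
    ``None`` when the source did not report it.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    n_case: float | None = None
    n_control: float | None = None
    trait: str | None = None

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not ea or not oa:
            raise SummaryIOError(f"{self.rsid}: empty allele")
        if ea == oa:
            raise SummaryIOError(f"{self.rsid}: identical alleles {ea}/{oa}")
        if not (ea in _NUCLEOTIDES and oa in _NUCLEOTIDES):
            raise SummaryIOError(
                f"{self.rsid}: non-SNP alleles {ea}/{oa} (indels and multi-allelic "
                "records are not supported)"
            )
        if not self.se > 0:
            raise SummaryIOError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise SummaryIOError(f"{self.rsid}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SummaryIOError(f"{self.rsid}: eaf must be in [0, 1], got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or G/C allele pairs, whose strand is not inferable."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def f_stat(self) -> float:
        """Instrument-strength F statistic, beta^2 / se^2."""
        return (self.beta / self.se) ** 2


@dataclass
class SummarySet:
    """A set of per-SNP associations for one trait, keyed by unique rsID."""

    trait: str
    records: list[SnpAssociation] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = [r.rsid for r in self.records if r.rsid in seen or seen.add(r.rsid)]
        if dupes:
            raise SummaryIOError(f"duplicate rsids in {self.trait!r}: {sorted(set(dupes))}")
        self._index = {r.rsid: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, rsid: str) -> SnpAssociation | None:
        return self._index.get(rsid)

    def __getitem__(self, rsid: str) -> SnpAssociation:
        return self._index[rsid]

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def subset(self, rsids: Iterable[str]) -> "SummarySet":
        keep = set(rsids)
        return SummarySet(
            trait=self.trait,
            records=[r for r in self.records if r.rsid in keep],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{c: getattr(r, c) for c in CANONICAL_COLUMNS} for r in self.records]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome SNP pair with both effects on the exposure's effect allele.

    ``flipped`` records that the outcome effect was sign-flipped to reach this
    frame; ``strand_complemented`` that the outcome record was reported on the
    opposite strand; ``palindromic`` that the alleles are A/T or G/C and the
    orientation was resolved from allele frequencies.
    """

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    pval_exp: float | None = None
    eaf_exp: float | None = None
    eaf_out: float | None = None
    n_exp: float | None = None
    n_out: float | None = None
    n_case: float | None = None
    n_control: float | None = None
    flipped: bool = False
    strand_complemented: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise SummaryIOError(f"{self.rsid}: harmonized SEs must be > 0")


@dataclass
class HarmonizationResult:
    """Harmonized instruments plus the disposition bookkeeping of every shared rsID."""

    instruments: list[HarmonizedInstrument]
    dispositions: dict[str, int]
    dropped: dict[str, list[str]] = field(default_factory=dict)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    def __len__(self) -> int:
        return len(self.instruments)

    def to_json(self) -> str:
        return json.dumps(
            {"dispositions": self.dispositions, "dropped": self.dropped}, indent=2
        )


def _parse_optional(value: object) -> float | None:
    if value is None:
        return None
    try:
        v = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str | None = None,
    sep: str = "\t",
) -> SummarySet:
    """Read a GWAS summary-statistics table into a validated :class:`SummarySet`.

    Parameters
    ----------
    path
        TSV file with one row per SNP.
    column_map
        Mapping from canonical field names (see :data:`CANONICAL_COLUMNS`) to
        the file's column headers, for dialects that name columns differently
        (e.g. ``{"rsid": "SNP", "pval": "P"}``).  Unmapped canonical names are
        looked up verbatim.
    trait
        Phenotype label; defaults to the file stem.

    Rows violating the record invariants (non-SNP alleles, non-positive SE,
    out-of-range p or frequency) are rejected and reported via logging;
    duplicate rsIDs are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=sep, dtype=str)
    resolved: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in df.columns:
            resolved[canon] = src
    missing = [c for c in MANDATORY_COLUMNS if c not in resolved]
    if missing:
        raise SummaryIOError(f"{path}: missing mandatory column(s) {missing}")

    trait = trait if trait is not None else path.stem
    records: list[SnpAssociation] = []
    rejected: list[tuple[str, str]] = []
    for i, row in df.iterrows():
        def cell(name: str) -> object:
            return row[resolved[name]] if name in resolved else None

        rsid = str(cell("rsid"))
        try:
            pos_raw = _parse_optional(cell("pos"))
            records.append(
                SnpAssociation(
                    rsid=rsid,
                    chrom=cell("chrom"),
                    pos=int(pos_raw) if pos_raw is not None else None,
                    effect_allele=str(cell("effect_allele")),
                    other_allele=str(cell("other_allele")),
                    eaf=_parse_optional(cell("eaf")),
                    beta=float(cell("beta")),
                    se=float(cell("se")),
                    pval=float(cell("pval")),
                    n=_parse_optional(cell("n")),
                    n_case=_parse_optional(cell("n_case")),
                    n_control=_parse_optional(cell("n_control")),
                    trait=trait,
                )
            )
        except (SummaryIOError, TypeError, ValueError) as exc:
            rejected.append((rsid, str(exc)))
    if rejected:
        for rsid, why in rejected:
            logger.warning("%s: rejected row %s: %s", path.name, rsid, why)
    return SummarySet(trait=trait, records=records, provenance=str(path))


def write_summary(summary: SummarySet, path: str | Path) -> Path:
    """Write a :class:`SummarySet` as TSV in the canonical column order.

    Lossless round-trip partner of :func:`read_summary`.
    """
    if not summary.records:
        raise SummaryIOError("refusing to write an empty SummarySet")
    path = Path(path)
    summary.to_frame().to_csv(path, sep="\t", index=False)
    return path


def _complement_alleles(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def harmonize(
    exposure: SummarySet,
    outcome: SummarySet,
    palindrome_window: tuple[float, float] = (0.01, 0.30),
    drop_all_palindromic: bool = False,
) -> HarmonizationResult:
    """Map outcome records onto the exposure effect-allele frame.

    For every rsID shared by both sets, the outcome alleles are compared with
    the exposure alleles:

    * identical -> kept unchanged;
    * swapped -> outcome beta negated, frequency reflected (1 - eaf);
    * strand complement (possibly also swapped) -> resolved through A/T, C/G
      then aligned;
    * anything else -> dropped as ambiguous.

    Palindromic SNPs (A/T or G/C) are dropped when the exposure effect-allele
    frequency lies inside ``palindrome_window``, when either frequency is
    missing, or unconditionally with ``drop_all_palindromic`` (the strict
    preset).  Surviving palindromes are oriented by frequency concordance:
    discordant minor/major sides flip the outcome effect.

    Returns a :class:`HarmonizationResult` whose ``dispositions`` counts
    satisfy kept + palindromic_dropped + ambiguous_dropped = |shared rsIDs|.
    """
    lo, hi = palindrome_window
    if not (0 <= lo <= hi <= 1):
        raise ValueError(f"invalid palindrome window [{lo}, {hi}]")
    if not exposure.records or not outcome.records:
        raise SummaryIOError("harmonize requires two nonempty summary sets")
    shared = [r.rsid for r in exposure.records if r.rsid in outcome]
    if not shared:
        raise SummaryIOError("no shared rsids between exposure and outcome sets")

    instruments: list[HarmonizedInstrument] = []
    disp = {
        "kept": 0,
        "kept_flipped": 0,
        "kept_strand_complemented": 0,
        "palindromic_dropped": 0,
        "ambiguous_dropped": 0,
    }
    dropped: dict[str, list[str]] = {"palindromic": [], "ambiguous": []}

    for rsid in shared:
        exp = exposure[rsid]
        out = outcome[rsid]
        e_ea, e_oa = exp.effect_allele, exp.other_allele
        o_ea, o_oa = out.effect_allele, out.other_allele

        if exp.is_palindromic:
            # For palindromic pairs allele identity cannot distinguish a strand
            # flip from an allele swap; frequency is the only arbiter.
            if out.is_palindromic and {o_ea, o_oa} == {e_ea, e_oa}:
                in_window = exp.eaf is not None and lo <= exp.eaf <= hi
                freq_missing = exp.eaf is None or out.eaf is None
                if drop_all_palindromic or in_window or freq_missing:
                    disp["palindromic_dropped"] += 1
                    dropped["palindromic"].append(rsid)
                    continue
                flip = (exp.eaf < 0.5) != (out.eaf < 0.5)
                instruments.append(
                    _pair(exp, out, flip=flip, complemented=False, palindromic=True)
                )
                disp["kept_flipped" if flip else "kept"] += 1
            else:
                disp["ambiguous_dropped"] += 1
                dropped["ambiguous"].append(rsid)
            continue

        if (o_ea, o_oa) == (e_ea, e_oa):
            flip, comp = False, False
        elif (o_ea, o_oa) == (e_oa, e_ea):
            flip, comp = True, False
        elif _complement_alleles(o_ea, o_oa) == (e_ea, e_oa):
            flip, comp = False, True
        elif _complement_alleles(o_ea, o_oa) == (e_oa, e_ea):
            flip, comp = True, True
        else:
            disp["ambiguous_dropped"] += 1
            dropped["ambiguous"].append(rsid)
            continue
        instruments.append(_pair(exp, out, flip=flip, complemented=comp, palindromic=False))
        if comp:
            disp["kept_strand_complemented"] += 1
        elif flip:
            disp["kept_flipped"] += 1
        else:
            disp["kept"] += 1

    if not instruments:
        raise SummaryIOError(
            f"all {len(shared)} shared SNPs dropped during harmonization: {disp}"
        )
    return HarmonizationResult(instruments=instruments, dispositions=disp, dropped=dropped)


def _pair(
    exp: SnpAssociation,
    out: SnpAssociation,
    flip: bool,
    complemented: bool,
    palindromic: bool,
) -> HarmonizedInstrument:
    beta_out = -out.beta if flip else out.beta
    eaf_out = out.eaf
    if flip and eaf_out is not None:
        eaf_out = 1.0 - eaf_out
    return HarmonizedInstrument(
        rsid=exp.rsid,
        beta_exp=exp.beta,
        se_exp=exp.se,
        pval_exp=exp.pval,
        eaf_exp=exp.eaf,
        beta_out=beta_out,
        se_out=out.se,
        eaf_out=eaf_out,
        n_exp=exp.n,
        n_out=out.n,
        n_case=out.n_case,
        n_control=out.n_control,
        flipped=flip,
        strand_complemented=complemented,
        palindromic=palindromic,
    )


def flip_exposure_frame(summary: SummarySet) -> SummarySet:
    """Swap every record's alleles and negate its beta (same information, other frame)."""
    flipped = [
        replace(
            r,
            effect_allele=r.other_allele,
            other_allele=r.effect_allele,
            beta=-r.beta,
            eaf=None if r.eaf is None else 1.0 - r.eaf,
        )
        for r in summary.records
    ]
    return SummarySet(trait=summary.trait, records=flipped, provenance=summary.provenance)
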