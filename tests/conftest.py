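import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrpipe.summary_io import HarmonizedInstrument, SnpAssociation, SummarySet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_pairs(bx, sx, by, sy, **extra) -> list[HarmonizedInstrument]:
    """Build harmonized instruments from plain effect/SE vectors."""
    return [
        HarmonizedInstrument(
            rsid=f"rs{i}",
            beta_exp=float(bx[i]), se_exp=float(sx[i]),
            beta_out=float(by[i]), se_out=float(sy[i]),
            **extra,
        )
        for i in range(len(bx))
    ]


def make_snp(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-8, **kw) -> SnpAssociation:
    return SnpAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se, pval=pval, **kw
    )


@pytest.fixture
def eight_pairs() -> list[HarmonizedInstrument]:
    """A fixed 8-instrument fixture with heterogeneous effects and weights."""
    rng = np.random.default_rng(42)
    bx = rng.uniform(0.05, 0.3, 8)
    sx = rng.uniform(0.005, 0.02, 8)
    sy = rng.uniform(0.01, 0.05, 8)
    by = 0.4 * bx + rng.normal(0, 0.01, 8)
    return make_pairs(bx, sx, by, sy)


@pytest.fixture
def exposure_outcome_sets():
    """A tiny exposure/outcome pair covering every harmonization disposition."""
    def rec(rsid, ea, oa, beta, eaf, trait, se=0.01, pval=1e-8):
        return SnpAssociation(
            rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta,
            se=se, pval=pval, eaf=eaf, trait=trait, n=10_000,
        )

    exposure = SummarySet(
        trait="exp",
        records=[
            rec("rs1", "A", "G", 0.10, 0.3, "exp"),   # identical alleles
            rec("rs2", "A", "G", 0.12, 0.3, "exp"),   # swapped in outcome
            rec("rs3", "A", "G", 0.09, 0.3, "exp"),   # strand complement
            rec("rs4", "A", "T", 0.11, 0.15, "exp"),  # palindrome, in window
            rec("rs5", "G", "C", 0.08, 0.45, "exp"),  # palindrome, outside window
            rec("rs6", "A", "G", 0.07, 0.3, "exp"),   # mismatched alleles in outcome
        ],
    )
    outcome = SummarySet(
        trait="out",
        records=[
            rec("rs1", "A", "G", 0.020, 0.3, "out"),
            rec("rs2", "G", "A", 0.050, 0.7, "out"),
            rec("rs3", "T", "C", 0.030, 0.3, "out"),
            rec("rs4", "A", "T", 0.010, 0.15, "out"),
            rec("rs5", "G", "C", 0.015, 0.45, "out"),
            rec("rs6", "A", "C", 0.012, 0.3, "out"),
        ],
    )
    return exposure, outcome
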