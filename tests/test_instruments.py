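"""Instrument-selection filter chain."""

import itertools

import numpy as np
import pytest

from mrpipe.instruments import (
    ConfounderAnnotation,
    InstrumentError,
    InstrumentSet,
    LdInfo,
    exclude_confounders,
    f_statistic,
    filter_pvalue,
    filter_weak,
    filter_weak_instruments,
    ld_clump,
    proxy_substitute,
    steiger_filter,
)
from mrpipe.summary_io import SummarySet

from conftest import make_pairs, make_snp


def summary_of(records):
    return SummarySet(trait="t", records=records)


class TestPvalueFilter:
    def test_keeps_only_below_threshold(self):
        s = summary_of([make_snp("rs1", pval=1e-6), make_snp("rs2", pval=1e-4)])
        assert filter_pvalue(s, 1e-5).rsids == ["rs1"]

    def test_near_one_threshold_is_vacuous(self):
        s = summary_of([make_snp(f"rs{i}", pval=0.5) for i in range(5)])
        assert len(filter_pvalue(s, 1 - 1e-12)) == 5

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0, 1, 1000)
        s = summary_of([make_snp(f"rs{i}", pval=float(p)) for i, p in enumerate(ps)])
        assert len(filter_pvalue(s, 0.01)) == int(np.sum(ps < 0.01))

    def test_empty_result_errors_with_advice(self):
        s = summary_of([make_snp(pval=0.5)])
        with pytest.raises(InstrumentError, match="relax"):
            filter_pvalue(s, 1e-5)


def _clump_oracle(records, positions, r2, r2_threshold, window_kb):
    """Independent characterization of greedy clumping: a subset S is THE greedy
    result iff, visiting SNPs in (p, pos, rsid) order, each SNP is in S exactly
    when it conflicts with no earlier member of S."""
    order = sorted(records, key=lambda r: (r.pval, positions[r.rsid][1], r.rsid))

    def conflict(a, b):
        ca, pa = positions[a.rsid]
        cb, pb = positions[b.rsid]
        return ca == cb and abs(pa - pb) / 1000 <= window_kb and r2[(a.rsid, b.rsid)] >= r2_threshold

    for subset in itertools.chain.from_iterable(
        itertools.combinations(order, k) for k in range(len(order) + 1)
    ):
        chosen = set(r.rsid for r in subset)
        ok = True
        accepted = []
        for rec in order:
            should = not any(conflict(rec, a) for a in accepted)
            if should:
                accepted.append(rec)
            if (rec.rsid in chosen) != should:
                ok = False
                break
        if ok and {r.rsid for r in accepted} == chosen:
            return chosen
    raise AssertionError("oracle found no greedy-consistent subset")


class TestLdClump:
    def test_single_snp_is_its_own_clump(self):
        s = summary_of([make_snp("rs1", chrom="1", pos=100)])
        ld = LdInfo.from_tables(positions={"rs1": ("1", 100)})
        assert ld_clump(s, ld).rsids == ["rs1"]

    def test_most_significant_dominates_nearby_correlated(self):
        s = summary_of([
            make_snp("rs1", pval=1e-8, chrom="1", pos=1000),
            make_snp("rs2", pval=1e-6, chrom="1", pos=6000),
        ])
        ld = LdInfo.from_tables(
            pairs=[("rs1", "rs2", 0.5)],
            positions={"rs1": ("1", 1000), "rs2": ("1", 6000)},
        )
        assert ld_clump(s, ld, r2_threshold=0.001, window_kb=10).rsids == ["rs1"]

    def test_different_chromosomes_always_independent(self):
        s = summary_of([
            make_snp("rs1", pval=1e-8, chrom="1", pos=1000),
            make_snp("rs2", pval=1e-6, chrom="2", pos=1000),
        ])
        ld = LdInfo.from_tables(
            pairs=[("rs1", "rs2", 0.99)],
            positions={"rs1": ("1", 1000), "rs2": ("2", 1000)},
        )
        assert set(ld_clump(s, ld, 0.001, 10_000).rsids) == {"rs1", "rs2"}

    def test_absent_pairs_mean_zero_r2(self):
        s = summary_of([
            make_snp("rs1", pval=1e-8, chrom="1", pos=1000),
            make_snp("rs2", pval=1e-6, chrom="1", pos=2000),
        ])
        ld = LdInfo.from_tables(positions={"rs1": ("1", 1000), "rs2": ("1", 2000)})
        assert len(ld_clump(s, ld, 0.001, 10_000)) == 2

    def test_six_snp_fixture_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        rsids = [f"rs{i}" for i in range(6)]
        positions = {r: ("1", int(p)) for r, p in zip(rsids, sorted(rng.integers(0, 50_000, 6)))}
        pairs = []
        r2_full = {}
        for a, b in itertools.combinations(rsids, 2):
            r2 = float(rng.uniform(0, 1))
            pairs.append((a, b, r2))
            r2_full[(a, b)] = r2_full[(b, a)] = r2
        for r in rsids:
            r2_full[(r, r)] = 1.0
        records = [make_snp(r, pval=float(rng.uniform(1e-10, 1e-4)), chrom="1",
                            pos=positions[r][1]) for r in rsids]
        s = summary_of(records)
        ld = LdInfo.from_tables(pairs=pairs, positions=positions)
        got = set(ld_clump(s, ld, r2_threshold=0.5, window_kb=20).rsids)
        expect = _clump_oracle(records, positions, r2_full, 0.5, 20)
        assert got == expect

    def test_retained_set_internally_independent(self):
        rng = np.random.default_rng(11)
        rsids = [f"rs{i}" for i in range(12)]
        positions = {r: ("1", int(rng.integers(0, 100_000))) for r in rsids}
        pairs = [
            (a, b, float(rng.uniform(0, 1)))
            for a, b in itertools.combinations(rsids, 2)
        ]
        records = [make_snp(r, pval=float(rng.uniform(0, 1e-4)), chrom="1",
                            pos=positions[r][1]) for r in rsids]
        ld = LdInfo.from_tables(pairs=pairs, positions=positions)
        kept = ld_clump(summary_of(records), ld, 0.3, 50).rsids
        for a, b in itertools.combinations(kept, 2):
            pa, pb = positions[a][1], positions[b][1]
            assert not (abs(pa - pb) / 1000 <= 50 and ld.r2(a, b) >= 0.3)

    def test_unknown_position_errors(self):
        s = summary_of([make_snp("rs1")])
        with pytest.raises(InstrumentError, match="position"):
            ld_clump(s, LdInfo())


class TestProxySubstitute:
    def test_present_rsid_maps_to_itself(self):
        out = summary_of([make_snp("rs1")])
        mapping, dropped = proxy_substitute(["rs1"], out, LdInfo())
        assert mapping == {"rs1": "rs1"} and dropped == []

    def test_best_r2_proxy_wins(self):
        out = summary_of([make_snp("rsA"), make_snp("rsB")])
        proxies = LdInfo.from_tables(pairs=[("rs1", "rsA", 0.9), ("rs1", "rsB", 0.85)])
        mapping, _ = proxy_substitute(["rs1"], out, proxies)
        assert mapping["rs1"] == "rsA"

    def test_below_threshold_proxy_drops_snp(self):
        out = summary_of([make_snp("rsA")])
        proxies = LdInfo.from_tables(pairs=[("rs1", "rsA", 0.7)])
        mapping, dropped = proxy_substitute(["rs1"], out, proxies, r2_min=0.8)
        assert mapping == {} and dropped == ["rs1"]

    def test_tie_broken_by_distance_then_rsid(self):
        out = summary_of([make_snp("rsA"), make_snp("rsB")])
        proxies = LdInfo.from_tables(
            pairs=[("rs1", "rsA", 0.9), ("rs1", "rsB", 0.9)],
            positions={"rs1": ("1", 1000), "rsA": ("1", 5000), "rsB": ("1", 1500)},
        )
        mapping, _ = proxy_substitute(["rs1"], out, proxies)
        assert mapping["rs1"] == "rsB"


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expect", [(0.1, 0.05, 4.0), (-0.1, 0.05, 4.0), (0.1, 0.01, 100.0)]
    )
    def test_arithmetic(self, beta, se, expect):
        assert f_statistic(beta, se) == pytest.approx(expect)

    def test_nonpositive_se_errors(self):
        with pytest.raises(InstrumentError):
            f_statistic(0.1, 0.0)

    def test_filter_weak_keeps_strong_only(self):
        s = summary_of([
            make_snp("rs1", beta=0.1, se=0.05),   # F = 4
            make_snp("rs2", beta=0.1, se=0.01),   # F = 100
        ])
        kept = filter_weak(s, f_min=10)
        assert kept.rsids == ["rs2"]
        assert min(r.f_stat for r in kept.records) > 10

    def test_f_min_zero_is_identity(self):
        s = summary_of([make_snp("rs1", beta=0.001, se=1.0)])
        assert filter_weak(s, f_min=0).rsids == ["rs1"]

    def test_monotone_in_f_min(self):
        rng = np.random.default_rng(1)
        s = summary_of([
            make_snp(f"rs{i}", beta=float(rng.normal(0, 0.1)), se=0.02)
            for i in range(50)
        ])
        prev = None
        for f_min in (100, 30, 10, 3, 0.1):
            try:
                kept = set(filter_weak(s, f_min).rsids)
            except InstrumentError:
                kept = set()
            if prev is not None:
                assert prev <= kept  # relaxing never removes a survivor
            prev = kept


class TestConfounderExclusion:
    def _inst(self, rsids):
        n = len(rsids)
        pairs = make_pairs([0.1] * n, [0.01] * n, [0.02] * n, [0.01] * n)
        pairs = [type(p)(**{**p.__dict__, "rsid": r}) for p, r in zip(pairs, rsids)]
        return InstrumentSet(instruments=pairs)

    def test_confounder_hit_removed(self):
        inst = self._inst(["rs1", "rs2"])
        ann = ConfounderAnnotation(entries=[("rs1", "smoking", 1e-9)])
        out = exclude_confounders(inst, ann, p_assoc=5e-8)
        assert out.rsids == ["rs2"]
        assert out.audit[-1].rsids_removed == ["rs1"]

    def test_empty_annotation_is_identity(self):
        inst = self._inst(["rs1"])
        out = exclude_confounders(inst, ConfounderAnnotation())
        assert out.rsids == ["rs1"]

    def test_weak_association_retained(self):
        inst = self._inst(["rs1"])
        ann = ConfounderAnnotation(entries=[("rs1", "smoking", 1e-3)])
        assert exclude_confounders(inst, ann, p_assoc=5e-8).rsids == ["rs1"]

    def test_non_confounder_trait_ignored(self):
        inst = self._inst(["rs1"])
        ann = ConfounderAnnotation(entries=[("rs1", "height", 1e-20)])
        assert exclude_confounders(inst, ann).rsids == ["rs1"]


class TestSteigerFilter:
    def test_correct_direction_retained_wrong_removed(self):
        # rs_good: strong on exposure, null on outcome; rs_bad: the reverse
        pairs = make_pairs(
            bx=[0.1, 0.001], sx=[0.01, 0.01],
            by=[0.001, 0.1], sy=[0.01, 0.01],
            n_exp=10_000.0, n_out=10_000.0,
        )
        inst = InstrumentSet(instruments=pairs)
        out = steiger_filter(inst)
        assert out.rsids == ["rs0"]
        assert out.audit[-1].rsids_removed == ["rs1"]

    def test_missing_sample_size_errors(self):
        pairs = make_pairs([0.1], [0.01], [0.01], [0.01])
        with pytest.raises(InstrumentError, match="n_exp"):
            steiger_filter(InstrumentSet(instruments=pairs))

    def test_forward_simulation_removes_almost_nothing(self):
        """Strong instruments on a true exposure->outcome effect survive."""
        from mrpipe.synthetic import SimConfig, simulate_instruments

        removed = 0
        total = 0
        for seed in range(20):
            pairs, _ = simulate_instruments(
                SimConfig(n_snp=50, true_beta=0.1, exposure_effect_sd=0.2, seed=seed)
            )
            out = steiger_filter(InstrumentSet(instruments=pairs))
            removed += out.audit[-1].n_removed
            total += 50
        assert removed / total < 0.01


class TestAuditReconciliation:
    def test_chained_filters_counts_reconcile(self):
        from mrpipe.synthetic import SimConfig, simulate_instruments

        pairs, _ = simulate_instruments(
            SimConfig(n_snp=80, true_beta=0.05, exposure_effect_sd=0.1, seed=2)
        )
        inst = InstrumentSet(instruments=pairs)
        inst = filter_weak_instruments(inst, f_min=10)
        inst = steiger_filter(inst)
        inst = exclude_confounders(
            inst, ConfounderAnnotation(entries=[(pairs[0].rsid, "smoking", 1e-10)])
        )
        assert 80 - sum(e.n_removed for e in inst.audit) == len(inst)
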