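"""Instrument selection: significance, clumping, F screen, blocklist."""

import itertools

import numpy as np
import pytest

from mrmediate import (
    ClumpSpec, SumstatRecord, clump, exclude_blocklist, f_statistics,
    select_significant,
)
from mrmediate.instruments import load_blocklist, load_ld_table
from mrmediate.sumstats import SumstatError


def _rec(snp, pval=1e-10, chrom="1", pos=1000, beta=0.3, se=0.04, eaf=0.3, n=None):
    return SumstatRecord(snp_id=snp, effect_allele="A", other_allele="G",
                         eaf=eaf, beta=beta, se=se, pval=pval,
                         chrom=chrom, pos=pos, n=n)


class TestSelectSignificant:
    def test_published_instruments_all_retained(self, icp_records):
        assert len(select_significant(icp_records, 5e-8)) == 11

    def test_zero_threshold_empty(self, icp_records):
        assert select_significant(icp_records, 0.0) == []

    def test_strict_inequality(self):
        recs = [_rec("rs1", 1e-9), _rec("rs2", 1e-7), _rec("rs3", 0.5)]
        kept = select_significant(recs, 5e-8)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_idempotent_and_provenance(self, icp_records):
        prov = {}
        once = select_significant(icp_records, 5e-8, provenance=prov)
        assert select_significant(once, 5e-8) == once
        pr = prov["select_significant"]
        assert pr["before"] - (pr["before"] - pr["after"]) == pr["after"]


def _brute_force_clump(records, spec, r2_of):
    """Independent oracle: greedy rule re-derived from its definition."""
    order = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept = []
    for cand in order:
        conflict = False
        for lead in kept:
            same_chr = lead.chrom == cand.chrom
            close = same_chr and abs(lead.pos - cand.pos) <= spec.window_bp
            if close and (r2_of is None or r2_of[frozenset((lead.snp_id, cand.snp_id))] >= spec.r2_threshold):
                conflict = True
        if not conflict:
            kept.append(cand)
    return sorted(r.snp_id for r in kept)


class TestClump:
    def test_dominated_neighbor_pruned(self):
        a = _rec("rs1", 1e-20, pos=1000)
        b = _rec("rs2", 1e-10, pos=2000)
        kept = clump([a, b], ClumpSpec(r2_threshold=0.001), ld=lambda x, y: 0.9)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_outside_window_both_kept(self):
        a = _rec("rs1", 1e-20, pos=1_000_000)
        b = _rec("rs2", 1e-10, pos=21_000_000)
        kept = clump([a, b], ClumpSpec(), ld=lambda x, y: 1.0)
        assert len(kept) == 2

    def test_distance_only_without_ld_source(self):
        a = _rec("rs1", 1e-20, pos=1000)
        b = _rec("rs2", 1e-10, pos=2000)
        assert [r.snp_id for r in clump([a, b], ClumpSpec())] == ["rs1"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        recs = [_rec(f"rs{i}", pval=float(rng.uniform(1e-20, 1e-8)),
                     chrom="2", pos=int(rng.integers(1, 5_000_000)))
                for i in range(5)]
        r2 = {frozenset((a.snp_id, b.snp_id)): float(rng.uniform(0, 1))
              for a, b in itertools.combinations(recs, 2)}
        spec = ClumpSpec(r2_threshold=0.3, window_bp=2_000_000)
        kept = clump(recs, spec, ld=lambda x, y: r2[frozenset((x, y))])
        assert sorted(r.snp_id for r in kept) == _brute_force_clump(recs, spec, r2)

    def test_kept_set_never_violates_rule(self):
        """Exhaustive pairwise post-check on random instances."""
        rng = np.random.default_rng(17)
        for trial in range(10):
            recs = [_rec(f"rs{i}", pval=float(rng.uniform(1e-20, 1e-8)),
                         chrom=str(rng.integers(1, 3)),
                         pos=int(rng.integers(1, 3_000_000)))
                    for i in range(8)]
            r2 = {frozenset((a.snp_id, b.snp_id)): float(rng.uniform(0, 1))
                  for a, b in itertools.combinations(recs, 2)}
            spec = ClumpSpec(r2_threshold=0.4, window_bp=1_000_000)
            kept = clump(recs, spec, ld=lambda x, y: r2[frozenset((x, y))])
            for a, b in itertools.combinations(kept, 2):
                assert not (
                    a.chrom == b.chrom
                    and abs(a.pos - b.pos) <= spec.window_bp
                    and r2[frozenset((a.snp_id, b.snp_id))] >= spec.r2_threshold
                )
            again = clump(kept, spec, ld=lambda x, y: r2[frozenset((x, y))])
            assert {r.snp_id for r in again} == {r.snp_id for r in kept}

    def test_missing_positions_error(self):
        bad = SumstatRecord(snp_id="rs1", effect_allele="A", other_allele="G",
                            eaf=0.3, beta=0.3, se=0.04, pval=1e-10)
        with pytest.raises(SumstatError, match="chrom and pos"):
            clump([bad], ClumpSpec())

    def test_ld_failure_names_pair(self):
        a = _rec("rs1", 1e-20, pos=1000)
        b = _rec("rs2", 1e-10, pos=2000)

        def boom(x, y):
            raise RuntimeError("backend down")

        with pytest.raises(SumstatError, match="rs1.*rs2"):
            clump([a, b], ClumpSpec(), ld=boom)


class TestFStatistics:
    def test_published_instruments_all_strong(self, icp_records):
        report, kept = f_statistics(icp_records, formula="ratio", f_min=10)
        assert report.min_f > 10
        assert len(kept) == 11 and report.removed == []

    def test_ratio_arithmetic(self):
        report, _ = f_statistics([_rec("rs1", beta=0.242, se=0.043)], formula="ratio")
        assert report.per_snp_f[0][1] == pytest.approx((0.242 / 0.043) ** 2)
        assert report.min_f == pytest.approx(31.68, abs=0.01)

    def test_null_instrument_removed(self):
        report, kept = f_statistics([_rec("rs1", beta=0.0)], formula="ratio", f_min=1.0)
        assert report.per_snp_f[0][1] == 0.0
        assert kept == []

    def test_ratio_invariant_to_sign_flip(self, icp_records):
        r1, _ = f_statistics(icp_records, formula="ratio")
        flipped = [r.allele_flipped() for r in icp_records]
        r2, _ = f_statistics(flipped, formula="ratio")
        for (_, f1), (_, f2) in zip(r1.per_snp_f, r2.per_snp_f):
            assert f1 == pytest.approx(f2, rel=1e-15)

    def test_r2_based_formula_and_eaf_symmetry(self):
        recs = [_rec("rs1", beta=0.05, se=0.01, eaf=0.3),
                _rec("rs2", beta=0.04, se=0.01, eaf=0.6)]
        rep, _ = f_statistics(recs, n=10_000, formula="r2_based", f_min=0)
        k = 2
        r2s = [2 * 0.3 * 0.7 * 0.05**2, 2 * 0.6 * 0.4 * 0.04**2]
        expect = [r2 * (10_000 - k - 1) / (k * (1 - sum(r2s))) for r2 in r2s]
        for (_, f), e in zip(rep.per_snp_f, expect):
            assert f == pytest.approx(e, rel=1e-12)
        mirrored = [_rec("rs1", beta=0.05, se=0.01, eaf=0.7),
                    _rec("rs2", beta=0.04, se=0.01, eaf=0.4)]
        rep2, _ = f_statistics(mirrored, n=10_000, formula="r2_based", f_min=0)
        for (_, f1), (_, f2) in zip(rep.per_snp_f, rep2.per_snp_f):
            assert f1 == pytest.approx(f2, rel=1e-12)

    def test_r2_based_requires_n_and_valid_total(self):
        with pytest.raises(SumstatError, match="sample size"):
            f_statistics([_rec("rs1")], formula="r2_based")
        big = [_rec("rs1", beta=3.0, eaf=0.5), _rec("rs2", beta=3.0, eaf=0.5)]
        with pytest.raises(SumstatError, match="R2"):
            f_statistics(big, n=1000, formula="r2_based")


class TestBlocklist:
    def test_empty_blocklist_noop(self, icp_records):
        assert exclude_blocklist(icp_records, []) == list(icp_records)

    def test_single_rsid_removed(self, icp_records):
        kept = exclude_blocklist(icp_records, {"rs1800961"})
        assert len(kept) == 10
        assert "rs1800961" not in {r.snp_id for r in kept}

    def test_interval_membership_matches_oracle(self):
        recs = [_rec("rs1", chrom="1", pos=500), _rec("rs2", chrom="1", pos=1500),
                _rec("rs3", chrom="2", pos=500), _rec("rs4", chrom="2", pos=5000)]
        intervals = [("1", 1000, 2000), ("2", 400, 600)]
        kept = exclude_blocklist(recs, intervals)

        def inside(r):
            return any(c == r.chrom and s <= r.pos <= e for c, s, e in intervals)

        assert [r.snp_id for r in kept] == [r.snp_id for r in recs if not inside(r)]
        # closed-interval endpoints count as inside
        assert "rs2" not in {r.snp_id for r in kept}

    def test_malformed_interval(self):
        with pytest.raises(SumstatError, match="start > end"):
            exclude_blocklist([_rec("rs1")], [("1", 10, 5)])

    def test_idempotent(self, icp_records):
        once = exclude_blocklist(icp_records, {"rs1800961"})
        assert exclude_blocklist(once, {"rs1800961"}) == once


class TestLoaders:
    def test_blocklist_file(self, tmp_path):
        p = tmp_path / "block.txt"
        p.write_text("# comment\nrs123\n1:100-200\n")
        assert load_blocklist(p) == ["rs123", ("1", 100, 200)]

    def test_ld_table_pairs(self, tmp_path):
        p = tmp_path / "ld.tsv"
        p.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.8\n")
        ld = load_ld_table(p)
        assert ld("rs2", "rs1") == 0.8
        assert ld("rs1", "rs3") == 0.0
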