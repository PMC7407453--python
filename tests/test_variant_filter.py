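"""Discovery-side filter semantics, including boundary rules and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tilarray.variant_filter import (
    FilterConfig,
    PooledVariant,
    PooledVariantSet,
    apply_filters,
    call_support_filter,
    drop_interfering,
    load_pooled_vcf,
    pool_average_maf,
    quality_filter,
)


def make_variant(chrom="chr1", pos=100, depths=(50, 50), alts=(10, 10), **kw):
    total_alt = sum(alts)
    fields = dict(
        chrom=chrom, pos=pos, ref_allele="A", alt_allele="G",
        per_pool_depth=depths, per_pool_alt_obs=alts,
        alt_fwd=total_alt // 2, alt_rev=total_alt - total_alt // 2,
        reads_left=sum(depths) // 2, reads_right=sum(depths) - sum(depths) // 2,
        paired_frac_alt=0.95, paired_frac_ref=0.95,
    )
    fields.update(kw)
    return PooledVariant(**fields)


class TestCallSupport:
    @pytest.mark.parametrize(
        "alts,depths,expected",
        [
            # three alt reads suffice even with pool AFs at/below the floor
            ((2, 1), (150, 100), True),
            # a single pool AF above 0.02 suffices with < 3 alt reads
            ((1, 0), (30, 50), True),
            # neither condition met
            ((1, 0), (100, 100), False),
        ],
    )
    def test_disjunction(self, alts, depths, expected):
        v = make_variant(depths=depths, alts=alts,
                         alt_fwd=sum(alts) and 1, alt_rev=max(sum(alts) - 1, 0))
        ok, reason = call_support_filter(v, FilterConfig())
        assert ok is expected
        assert (reason is None) == expected

    def test_af_floor_is_strict(self):
        # pool AF exactly 0.02 does not satisfy the frequency condition
        v = make_variant(depths=(50, 50), alts=(1, 1), alt_fwd=1, alt_rev=1)
        ok, _ = call_support_filter(v, FilterConfig())
        assert not ok


class TestQualityFilter:
    def test_all_clauses_met(self):
        v = make_variant(depths=(50, 50), alts=(5, 5), alt_fwd=5, alt_rev=5,
                         reads_left=50, reads_right=50)
        ok, reasons = quality_filter(v, FilterConfig())
        assert ok and reasons == []

    @pytest.mark.parametrize(
        "kw,expected_reason",
        [
            (dict(depths=(25, 24), alts=(5, 5), reads_left=25, reads_right=24), "low_coverage"),
            (dict(depths=(80, 80), alts=(5, 5), reads_left=80, reads_right=80), "high_coverage"),
            (dict(alt_fwd=20, alt_rev=0), "strand"),
            (dict(reads_left=1, reads_right=99), "placement"),
            (dict(paired_frac_alt=0.90), "paired"),  # strict: exactly 90% fails
        ],
    )
    def test_single_clause_failures(self, kw, expected_reason):
        v = make_variant(**kw)
        ok, reasons = quality_filter(v, FilterConfig())
        assert not ok and reasons == [expected_reason]

    def test_multiple_failures_all_reported(self):
        v = make_variant(depths=(20, 20), alts=(4, 4), alt_fwd=8, alt_rev=0,
                         reads_left=20, reads_right=20, paired_frac_alt=0.5)
        _, reasons = quality_filter(v, FilterConfig())
        assert set(reasons) == {"low_coverage", "strand", "paired"}


class TestInterference:
    def _vars(self, positions, chrom="chr1"):
        return [make_variant(chrom=chrom, pos=p) for p in positions]

    def test_pair_at_39bp_both_removed(self):
        kept, removed = drop_interfering(self._vars([100, 139]))
        assert kept == [] and len(removed) == 2

    def test_pair_at_40bp_both_kept(self):
        kept, removed = drop_interfering(self._vars([100, 140]))
        assert len(kept) == 2 and removed == []

    def test_lone_variant_kept(self):
        kept, removed = drop_interfering(self._vars([100]))
        assert len(kept) == 1 and removed == []

    def test_extra_positions_exert_interference(self):
        kept, removed = drop_interfering(
            self._vars([100]), extra_positions=[("chr1", 120)]
        )
        assert kept == [] and len(removed) == 1

    def test_chromosomes_do_not_interact(self):
        vs = self._vars([100]) + self._vars([110], chrom="chr2")
        kept, _ = drop_interfering(vs)
        assert len(kept) == 2

    @given(
        positions=st.lists(st.integers(1, 2000), min_size=1, max_size=120, unique=True),
        window=st.integers(1, 100),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_all_pairs_oracle(self, positions, window):
        """Neighbour-scan implementation equals the O(n^2) definition."""
        vs = self._vars(sorted(positions))
        cfg = FilterConfig(interference_bp=window)
        kept, removed = drop_interfering(vs, cfg)
        oracle_removed = {
            v.pos
            for v in vs
            for u in vs
            if u.pos != v.pos and abs(u.pos - v.pos) < window
        }
        assert {v.pos for v in removed} == oracle_removed
        assert {v.pos for v in kept} == {v.pos for v in vs} - oracle_removed


class TestPoolAverageMaf:
    @pytest.mark.parametrize(
        "alts,depths,expected",
        [
            ((10, 20), (100, 100), 0.15),
            ((90, 80), (100, 100), 0.15),  # folded to the minor allele
            ((50, 50), (100, 100), 0.50),
        ],
    )
    def test_folding_and_averaging(self, alts, depths, expected):
        v = make_variant(depths=depths, alts=alts,
                         alt_fwd=sum(alts) // 2, alt_rev=sum(alts) - sum(alts) // 2)
        assert pool_average_maf(v) == pytest.approx(expected)

    def test_zero_depth_pools_ignored(self):
        v = make_variant(depths=(100, 0), alts=(30, 0), alt_fwd=15, alt_rev=15)
        assert pool_average_maf(v) == pytest.approx(0.30)

    def test_all_pools_empty_raises(self):
        v = make_variant(depths=(0, 0), alts=(0, 0), alt_fwd=0, alt_rev=0,
                         reads_left=0, reads_right=0)
        with pytest.raises(ValueError, match="nonzero depth"):
            pool_average_maf(v)


class TestLoadVcf:
    def test_snv_and_indel_accounting(self, tmp_path):
        vcf = tmp_path / "mini.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##INFO=<ID=AO,Number=A,Type=Integer,Description="d">\n'
            '##INFO=<ID=SAF,Number=A,Type=Integer,Description="d">\n'
            '##INFO=<ID=SAR,Number=A,Type=Integer,Description="d">\n'
            '##INFO=<ID=RPL,Number=1,Type=Integer,Description="d">\n'
            '##INFO=<ID=RPR,Number=1,Type=Integer,Description="d">\n'
            '##INFO=<ID=PAIRED,Number=A,Type=Float,Description="d">\n'
            '##INFO=<ID=PAIREDR,Number=1,Type=Float,Description="d">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="d">\n'
            "##contig=<ID=chr1,length=100000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool1\tpool2\n"
            "chr1\t100\t.\tA\tG\t99\t.\t"
            "DP=100;AO=20;SAF=10;SAR=10;RPL=50;RPR=50;PAIRED=0.95;PAIREDR=0.95"
            "\tDP:AO\t50:10\t50:10\n"
            "chr1\t200\t.\tA\tAT\t99\t.\t"
            "DP=100;AO=20;SAF=10;SAR=10;RPL=50;RPR=50;PAIRED=0.95;PAIREDR=0.95"
            "\tDP:AO\t50:10\t50:10\n"
        )
        vset = load_pooled_vcf(vcf, n_pools=2)
        assert len(vset) == 1
        assert vset.n_skipped_indel == 1
        assert vset.other_positions == [("chr1", 200)]
        v = vset.variants[0]
        assert v.per_pool_depth == (50, 50) and v.per_pool_alt_obs == (10, 10)

    def test_empty_body_is_empty_set(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool1\tpool2\n"
        )
        assert len(load_pooled_vcf(vcf, n_pools=2)) == 0

    def test_missing_info_key_raises_with_key_name(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="d">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool1\tpool2\n"
            "chr1\t100\t.\tA\tG\t99\t.\tDP=100\tDP:AO\t50:10\t50:10\n"
        )
        with pytest.raises(ValueError, match="'AO' at record chr1:100"):
            load_pooled_vcf(vcf, n_pools=2)

    def test_pool_count_mismatch_raises(self, design_inputs):
        with pytest.raises(ValueError, match="pool columns"):
            load_pooled_vcf(design_inputs["vcf"], n_pools=3)

    def test_synthetic_roundtrip_matches_truth(self, design_inputs, flagged_variants):
        vset, truth = flagged_variants
        loaded = load_pooled_vcf(design_inputs["vcf"], n_pools=2)
        assert len(loaded) == len(truth)
        assert loaded.n_skipped_indel == 10


class TestApplyFilters:
    def test_clean_sites_survive_and_flagged_fail(self, flagged_variants):
        vset, truth = flagged_variants
        passed, report = apply_filters(vset, FilterConfig())
        flags = {(r.chrom, r.pos): r.flag for r in truth.itertuples()}
        passed_keys = {(v.chrom, v.pos) for v in passed}
        for key, flag in flags.items():
            assert (key in passed_keys) == (flag == "clean")

    def test_filter_order_independence_of_per_variant_rules(self, flagged_variants):
        """Support and quality predicates commute: same verdicts in any order."""
        vset, _ = flagged_variants
        cfg = FilterConfig()
        for v in list(vset)[:200]:
            s_ok, _ = call_support_filter(v, cfg)
            q_ok, _ = quality_filter(v, cfg)
            s_ok2, _ = call_support_filter(v, cfg)
            assert (s_ok and q_ok) == (q_ok and s_ok2)
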