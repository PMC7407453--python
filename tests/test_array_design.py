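"""Tiered selection logic against brute-force oracles and boundary rules."""

import numpy as np
import pandas as pd
import pytest

from tilarray.array_design import (
    AMBIGUOUS_PAIRS,
    ArrayDesign,
    CandidateSNP,
    DesignConfig,
    GenomeAnnotation,
    allele_and_maf_filter,
    assemble_array,
    classify_context,
    crossref_panels,
    eligible_sequences,
    probe_score_gate,
    sparse_fill,
    windowed_selection,
)


def cand(chrom="chr1", pos=100, maf=0.2, ref="A", alt="G", context="intron",
         panel_hits=frozenset(), probe_classes=("recommended", "neutral")):
    return CandidateSNP(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                        avg_maf=maf, context=context, panel_hits=panel_hits,
                        probe_classes=probe_classes)


def simple_annotation():
    """One gene chr1:1000-2000 with exon 1000-1200, plus chrom lengths."""
    genes = pd.DataFrame(
        [{"chrom": "chr1", "start": 1000, "end": 2000, "strand": "+", "gene_id": "g1"}]
    )
    exons = pd.DataFrame(
        [{"chrom": "chr1", "start": 1000, "end": 1200, "gene_id": "g1"}]
    )
    return GenomeAnnotation(genes=genes, exons=exons, chrom_lengths={"chr1": 100_000})


class TestClassifyContext:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1100, "exon"),            # inside the exon
            (1500, "intron"),          # in the gene, outside exons
            (3000, "near_gene_1kb"),   # exactly 1,000 bp past the gene end
            (3001, "intergenic"),      # 1,001 bp: outside the flank
            (1, "near_gene_1kb"),      # upstream flank reaches position 1
        ],
    )
    def test_precedence_and_flank_boundary(self, pos, expected):
        out = classify_context([cand(pos=pos, context="intergenic")],
                               simple_annotation())
        assert out[0].context == expected

    def test_empty_annotation_everything_intergenic(self):
        ann = GenomeAnnotation(
            genes=pd.DataFrame(columns=["chrom", "start", "end", "strand", "gene_id"]),
            exons=pd.DataFrame(columns=["chrom", "start", "end", "gene_id"]),
        )
        out = classify_context([cand(pos=p) for p in (10, 5000)], ann)
        assert all(c.context == "intergenic" for c in out)

    def test_matches_brute_force_distance_scan(self, annotation):
        """Interval-tree classification equals a direct per-variant scan."""
        rng = np.random.default_rng(12)
        cands = [
            cand(chrom=f"chr{rng.integers(1, 3)}", pos=int(rng.integers(1, 2_000_000)))
            for _ in range(400)
        ]
        out = classify_context(cands, annotation, flank_bp=1000)
        genes = annotation.genes
        exons = annotation.exons
        for c in out:
            in_exon = (
                (exons["chrom"] == c.chrom)
                & (exons["start"] <= c.pos) & (c.pos <= exons["end"])
            ).any()
            in_gene = (
                (genes["chrom"] == c.chrom)
                & (genes["start"] <= c.pos) & (c.pos <= genes["end"])
            ).any()
            near = (
                (genes["chrom"] == c.chrom)
                & (genes["start"] - 1000 <= c.pos) & (c.pos <= genes["end"] + 1000)
            ).any()
            expected = ("exon" if in_exon else "intron" if in_gene
                        else "near_gene_1kb" if near else "intergenic")
            assert c.context == expected


class TestAlleleMafFilter:
    @pytest.mark.parametrize(
        "ref,alt,maf,kept,reason",
        [
            ("A", "T", 0.30, False, "ambiguous_alleles"),
            ("G", "C", 0.30, False, "ambiguous_alleles"),
            ("A", "G", 0.46, False, "maf"),
            ("A", "G", 0.04, False, "maf"),
            ("A", "G", 0.05, True, None),   # boundary inclusive
            ("A", "G", 0.45, True, None),   # boundary inclusive
        ],
    )
    def test_rules(self, ref, alt, maf, kept, reason):
        out, report = allele_and_maf_filter([cand(ref=ref, alt=alt, maf=maf)])
        assert bool(out) is kept
        if reason:
            assert report.iloc[0]["reason"] == reason

    def test_widening_window_never_shrinks_survivors(self):
        rng = np.random.default_rng(5)
        cands = [cand(pos=i + 1, maf=float(rng.uniform(0, 0.5))) for i in range(300)]
        kept_narrow, _ = allele_and_maf_filter(cands, maf_lo=0.10, maf_hi=0.40)
        kept_wide, _ = allele_and_maf_filter(cands, maf_lo=0.05, maf_hi=0.45)
        assert {c.pos for c in kept_narrow} <= {c.pos for c in kept_wide}


class TestCrossref:
    def test_hit_counting(self):
        c = cand(pos=500)
        panels = {
            "p1": pd.DataFrame([{"chrom": "chr1", "pos": 500, "ref": "A", "alt": "G"}]),
            "p2": pd.DataFrame([{"chrom": "chr1", "pos": 500, "ref": "A", "alt": "G"}]),
            "p3": pd.DataFrame([{"chrom": "chr1", "pos": 999, "ref": "A", "alt": "G"}]),
        }
        crossref_panels([c], panels)
        assert c.panel_hits == frozenset({"p1", "p2"})

    def test_allele_matching_mode(self):
        c = cand(pos=500, ref="A", alt="G")
        panels = {"p": pd.DataFrame([{"chrom": "chr1", "pos": 500, "ref": "C", "alt": "T"}])}
        crossref_panels([c], panels, match_alleles=True)
        assert c.panel_hits == frozenset()

    def test_synthetic_overlap_fraction_recovered(self, sim_config, flagged_variants):
        from tilarray.synthdata import simulate_panels_and_scores
        from tilarray.variant_filter import pool_average_maf

        vset, _ = flagged_variants
        panels, _ = simulate_panels_and_scores(vset, 0.1, sim_config, n_decoys=0)
        cands = [
            CandidateSNP(chrom=v.chrom, pos=v.pos, ref_allele=v.ref_allele,
                         alt_allele=v.alt_allele,
                         avg_maf=min(pool_average_maf(v), 0.5))
            for v in vset if v.total_depth > 0
        ]
        crossref_panels(cands, {"one": panels["abbassa_breeding"]})
        tagged = sum(bool(c.panel_hits) for c in cands)
        n = len(cands)
        # binomial 99.9% band around 10%
        sd = np.sqrt(0.1 * 0.9 * n)
        assert abs(tagged - 0.1 * n) < 3.5 * sd


class TestProbeGate:
    @pytest.mark.parametrize(
        "classes,kept",
        [
            (("recommended", "not_possible"), True),
            (("not_recommended", "not_possible"), False),
            (("neutral", "neutral"), True),
        ],
    )
    def test_at_least_one_viable_probe(self, classes, kept):
        c = cand()
        scores = pd.DataFrame(
            [{"snp_id": c.snp_id, "probe_fwd_class": classes[0],
              "probe_rev_class": classes[1]}]
        )
        out = probe_score_gate([c], scores)
        assert bool(out) is kept

    def test_unknown_label_raises(self):
        c = cand()
        scores = pd.DataFrame(
            [{"snp_id": c.snp_id, "probe_fwd_class": "excellent",
              "probe_rev_class": "neutral"}]
        )
        with pytest.raises(ValueError, match="excellent"):
            probe_score_gate([c], scores)

    def test_missing_policy(self):
        c = cand()
        empty = pd.DataFrame(columns=["snp_id", "probe_fwd_class", "probe_rev_class"])
        assert probe_score_gate([c], empty, missing_policy="drop") == []
        assert probe_score_gate([c], empty, missing_policy="keep") == [c]


def brute_force_windowed(cands, window_bp, contexts):
    """Exhaustive per-window argmax with the documented tie rules."""
    groups = {}
    for c in cands:
        if c.context not in contexts:
            continue
        groups.setdefault((c.chrom, (c.pos - 1) // window_bp), []).append(c)
    out = []
    for key in sorted(groups):
        out.append(min(
            groups[key],
            key=lambda c: (-c.avg_maf, c.pos, tuple(sorted({c.ref_allele, c.alt_allele}))),
        ))
    return out


class TestWindowedSelection:
    def test_highest_maf_wins(self):
        cs = [cand(pos=p, maf=m) for p, m in [(100, 0.12), (5000, 0.40), (9000, 0.33)]]
        out = windowed_selection(cs, window_bp=10_000)
        assert len(out) == 1 and out[0].pos == 5000

    def test_tie_broken_by_position(self):
        cs = [cand(pos=9990, maf=0.25), cand(pos=1050, maf=0.25)]
        out = windowed_selection(cs, window_bp=10_000)
        assert [c.pos for c in out] == [1050]

    def test_window_boundary_is_inclusive(self):
        # windows [1, 10000] and [10001, 20000]
        cs = [cand(pos=10_000, maf=0.1), cand(pos=10_001, maf=0.1)]
        out = windowed_selection(cs, window_bp=10_000)
        assert len(out) == 2

    def test_ineligible_contexts_excluded(self):
        cs = [cand(pos=100, context="exon"), cand(pos=200, context="intergenic")]
        assert windowed_selection(cs, window_bp=10_000) == []

    def test_equals_exhaustive_oracle_on_random_genomes(self):
        rng = np.random.default_rng(77)
        contexts = ("intron", "near_gene_1kb")
        for rep in range(100):
            n = int(rng.integers(1, 120))
            cs = []
            for _ in range(n):
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                cs.append(cand(
                    chrom=f"chr{rng.integers(1, 4)}",
                    pos=int(rng.integers(1, 50_000)),
                    maf=float(rng.choice([0.1, 0.25, 0.25, 0.4])),  # force ties
                    ref=ref, alt=alt,
                    context=str(rng.choice(["intron", "near_gene_1kb", "exon"])),
                ))
            got = windowed_selection(cs, window_bp=10_000, eligible_contexts=contexts)
            want = brute_force_windowed(cs, 10_000, contexts)
            assert [(c.chrom, c.pos) for c in got] == [(c.chrom, c.pos) for c in want]


class TestSparseFill:
    def test_forced_single_move(self):
        sel = [cand(pos=100, maf=0.3)]
        extra = cand(chrom="chr2", pos=50, maf=0.1)
        out = sparse_fill(sel, [sel[0], extra], region_bp=1_000_000, target_size=2)
        assert extra in out

    def test_zero_budget_is_noop(self):
        sel = [cand(pos=100)]
        out = sparse_fill(sel, [cand(pos=200)], target_size=1)
        assert out == sel

    def test_unreachable_target_returns_shortfall(self):
        sel = [cand(pos=100)]
        out = sparse_fill(sel, [sel[0]], target_size=10)
        assert len(out) == 1

    def test_greedy_trace_matches_replay_and_levels_regions(self):
        rng = np.random.default_rng(31)
        cands = [
            cand(chrom=f"chr{rng.integers(1, 3)}",
                 pos=int(rng.integers(1, 5_000_000)),
                 maf=float(rng.uniform(0.05, 0.45)))
            for _ in range(400)
        ]
        # dedupe positions
        seen, uniq = set(), []
        for c in cands:
            if c.key not in seen:
                seen.add(c.key)
                uniq.append(c)
        sel = windowed_selection(uniq, window_bp=100_000)
        target = len(sel) + 50
        out = sparse_fill(sel, uniq, region_bp=1_000_000, target_size=target)
        assert len(out) == min(target, len({c.key for c in uniq}))
        # replay the greedy loop independently
        region = lambda c: (c.chrom, (c.pos - 1) // 1_000_000)
        counts = {}
        for c in sel:
            counts[region(c)] = counts.get(region(c), 0) + 1
        available = {c.key: c for c in uniq if c.key not in {s.key for s in sel}}
        replay = list(sel)
        while len(replay) < target and available:
            regions = {}
            for c in available.values():
                regions.setdefault(region(c), []).append(c)
            best_region = min(regions, key=lambda r: (counts.get(r, 0), r))
            pick = min(
                regions[best_region],
                key=lambda c: (-c.avg_maf, c.pos,
                               tuple(sorted({c.ref_allele, c.alt_allele}))),
            )
            replay.append(pick)
            counts[best_region] = counts.get(best_region, 0) + 1
            del available[pick.key]
        assert [c.key for c in out] == [c.key for c in replay]
        # the fill never leaves a region below the pre-fill minimum
        pre_counts = {}
        for c in sel:
            pre_counts[region(c)] = pre_counts.get(region(c), 0) + 1
        post_counts = {}
        for c in out:
            post_counts[region(c)] = post_counts.get(region(c), 0) + 1
        assert min(post_counts.values()) >= min(pre_counts.values())


class TestAssembleArray:
    def _pool(self, rng, n=300):
        out = []
        seen = set()
        while len(out) < n:
            pos = int(rng.integers(1, 3_000_000))
            chrom = f"chr{rng.integers(1, 3)}"
            if (chrom, pos) in seen:
                continue
            seen.add((chrom, pos))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            out.append(cand(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                maf=float(rng.uniform(0.05, 0.45)),
                context=str(rng.choice(
                    ["exon", "intron", "near_gene_1kb", "intergenic"],
                    p=[0.2, 0.4, 0.2, 0.2],
                )),
                panel_hits=frozenset({"p1"}) if rng.random() < 0.15 else frozenset(),
            ))
        return out

    def test_tier_precedence_panel_beats_exonic(self):
        c = cand(pos=100, context="exon", panel_hits=frozenset({"p1"}))
        design = assemble_array(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]), [c],
            DesignConfig(target_size=10),
        )
        assert design.tier_counts["panel_overlap"] == 1
        assert design.tier_counts["exonic"] == 0

    def test_counts_partition_and_no_duplicates(self):
        rng = np.random.default_rng(9)
        pool = self._pool(rng)
        sex = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [7], "ref": ["A"], "alt": ["G"]}
        )
        design = assemble_array(sex, pool, DesignConfig(target_size=200))
        assert sum(design.tier_counts.values()) == len(design)
        assert not design.markers.duplicated(subset=["chrom", "pos"]).any()
        assert design.tier_counts["sex_marker"] == 1

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(10)
        pool = self._pool(rng)
        cfg = DesignConfig(target_size=150)
        sex = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        design1 = assemble_array(sex, pool, cfg)
        selected_keys = set(zip(design1.markers["chrom"], design1.markers["pos"]))
        subpool = [c for c in pool if c.key in selected_keys]
        for c in subpool:
            c.tier = None
        design2 = assemble_array(sex, subpool, cfg)
        assert list(zip(design2.markers["chrom"], design2.markers["pos"])) \
            == sorted(selected_keys) or set(
                zip(design2.markers["chrom"], design2.markers["pos"])
            ) == selected_keys

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_array(pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
                           [], DesignConfig())

    def test_maf_window_enforced_for_lower_tiers_only(self):
        high = cand(pos=100, maf=0.49, context="exon",
                    panel_hits=frozenset({"p1"}))   # bypasses MAF via tier 2
        low = cand(pos=20_000, maf=0.49, context="exon")  # dropped: outside window
        design = assemble_array(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
            [high, low], DesignConfig(target_size=10),
        )
        keys = set(zip(design.markers["chrom"], design.markers["pos"]))
        assert ("chr1", 100) in keys and ("chr1", 20_000) not in keys


class TestEligibleSequences:
    def test_longest_scaffolds_selected(self):
        lengths = {"chr1": 5_000_000, "scaf1": 100, "scaf2": 300, "scaf3": 200}
        out = eligible_sequences(lengths, chromosomes=["chr1"], n_scaffolds=2)
        assert out == {"chr1", "scaf2", "scaf3"}
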