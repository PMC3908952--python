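"""Bias statistics, HWE, homopolymer scan, tier filters and recurrence."""
import random

import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

from mosaicall.caller import SampleCall
from mosaicall.filters import (
    FilterConfig,
    FilterContext,
    apply_tier,
    homopolymer_adjacent,
    hwe_p,
    pv4,
    read_bed,
    recurrent_genes,
)
from mosaicall.samio import BaseObservation, SitePileup
from mosaicall.vcfio import VariantRecord

from conftest import make_pileup


def strand_pileup(dp4, ref="G", alt="A", bq=30, mq=60, tail=49):
    obs = []
    for count, allele, strand in ((dp4[0], ref, "+"), (dp4[1], ref, "-"),
                                  (dp4[2], alt, "+"), (dp4[3], alt, "-")):
        obs += [BaseObservation(allele, bq, mq, strand, tail)] * count
    return SitePileup("sim1", 503, ref, "S1", tuple(obs))


def fisher_oracle(table):
    """Two-sided Fisher exact by hypergeometric enumeration."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    rv = hypergeom(n1 + n2, n1, k)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(x) for x in range(max(0, k - n2), min(k, n1) + 1)
               if rv.pmf(x) <= p_obs * (1 + 1e-9))


class TestPv4:
    def test_perfect_strand_separation(self):
        p = pv4(strand_pileup((10, 0, 0, 10)), "A")
        assert p[0] == pytest.approx(2 / comb(20, 10), rel=1e-6)

    def test_identical_reads_give_unit_bias_pvalues(self):
        p = pv4(strand_pileup((5, 5, 3, 3)), "A")
        assert p == (1.0, 1.0, 1.0, 1.0)

    def test_no_alt_reads_vacuous(self):
        assert pv4(strand_pileup((5, 5, 0, 0)), "A") == (1.0, 1.0, 1.0, 1.0)

    def test_single_read_groups_vacuous_t_tests(self):
        pile = strand_pileup((1, 0, 1, 0))
        assert pv4(pile, "A")[1:] == (1.0, 1.0, 1.0)

    def test_tail_bias_detected(self):
        obs = tuple(
            [BaseObservation("G", 30, 60, "+", 49)] * 10
            + [BaseObservation("A", 30, 60, "+", 2),
               BaseObservation("A", 30, 60, "-", 1),
               BaseObservation("A", 30, 60, "+", 3)]
        )
        pile = SitePileup("sim1", 503, "G", "S1", obs)
        p = pv4(pile, "A")
        assert p[3] < 0.01  # alt reads clustered at read ends

    @pytest.mark.parametrize("table", [
        [[10, 0], [0, 10]], [[5, 5], [3, 3]], [[8, 13], [4, 11]],
        [[1, 9], [7, 2]], [[15, 15], [0, 4]], [[2, 0], [0, 2]],
    ])
    def test_fisher_matches_hypergeometric_enumeration(self, table):
        pile = strand_pileup((table[0][0], table[0][1], table[1][0], table[1][1]))
        assert pv4(pile, "A")[0] == pytest.approx(fisher_oracle(table), rel=1e-6)

    def test_mann_whitney_option(self):
        pile = strand_pileup((5, 5, 3, 3))
        assert pv4(pile, "A", method="mannwhitney") == (1.0, 1.0, 1.0, 1.0)


class TestHwe:
    def test_all_het_excess(self):
        # three heterozygotes: chi-square = 3.0
        assert hwe_p((0, 3, 0)) == pytest.approx(0.0833, abs=5e-4)

    def test_monomorphic_vacuous(self):
        assert hwe_p((3, 0, 0)) == 1.0
        assert hwe_p((0, 0, 3)) == 1.0

    def test_single_sample_vacuous(self):
        assert hwe_p((1, 0, 0)) == 1.0
        assert hwe_p((0, 1, 0)) == 1.0

    def test_equilibrium_counts_pass(self):
        assert hwe_p((25, 50, 25)) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_p((-1, 2, 0))


class TestHomopolymer:
    def test_adjacent_run_detected(self):
        assert homopolymer_adjacent("TTAAAAAG", 7)

    def test_no_runs_in_alternating_context(self):
        for offset in range(9):
            assert not homopolymer_adjacent("ACGTACGTA", offset)

    def test_run_of_four_below_threshold(self):
        assert not homopolymer_adjacent("CAAAAG", 5)

    def test_site_inside_run(self):
        assert homopolymer_adjacent("CAAAAAG", 3)

    def test_distant_run_ignored(self):
        assert not homopolymer_adjacent("AAAAACGTACGTACG", 14)

    def test_offset_outside_context_rejected(self):
        with pytest.raises(ValueError):
            homopolymer_adjacent("ACGT", 4)


def record(qual=30.0, dp4=(16, 16, 2, 2), pv4_=(1.0, 1.0, 1.0, 1.0),
           gene=None, novel=None):
    return VariantRecord(chrom="chr3", pos=1000, ref="G", alt="A", qual=qual,
                         dp=sum(dp4), dp4=dp4, pv4=pv4_, gene=gene, novel=novel,
                         samples=[SampleCall("S1", "0/1", 99, (50, 0, 50))])


class TestApplyTier:
    def test_low_quality_fails_tier1(self):
        # base-call accuracy below 90% (Phred 10)
        result = apply_tier(record(qual=4.57), FilterConfig.tier1())
        assert not result.passed
        assert result.reasons == ["min_qual"]

    def test_clean_record_passes_both_tiers(self):
        rec = record()
        assert apply_tier(rec, FilterConfig.tier1()).passed
        assert apply_tier(rec, FilterConfig.tier2()).passed

    def test_two_alt_reads_one_strand_fails_tier2_only(self):
        rec = record(dp4=(17, 17, 2, 0))
        assert apply_tier(rec, FilterConfig.tier1()).passed
        result = apply_tier(rec, FilterConfig.tier2())
        assert not result.passed
        assert set(result.reasons) == {"min_alt", "alt_both_strands"}

    def test_flagged_gene_fails_tier2(self):
        rec = record(gene="HYDIN")
        result = apply_tier(rec, FilterConfig.tier2(["HYDIN", "MUC16"]))
        assert result.reasons == ["flagged_gene"]
        assert apply_tier(rec, FilterConfig.tier1()).passed

    def test_missing_pv4_raises_naming_field(self):
        rec = record()
        rec.pv4 = None
        with pytest.raises(ValueError, match="pv4"):
            apply_tier(rec, FilterConfig.tier1())

    def test_homopolymer_context_fails_tier1(self):
        ctx = FilterContext(ref_context="TTAAAAAG", site_offset=7)
        result = apply_tier(record(), FilterConfig.tier1(), ctx)
        assert result.reasons == ["homopolymer"]

    def test_hwe_context_fails_tier1(self):
        ctx = FilterContext(genotype_counts=(0, 60, 0))  # het excess
        result = apply_tier(record(), FilterConfig.tier1(), ctx)
        assert result.reasons == ["hwe"]

    def test_repeat_mask_fails_tier1(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("chr3\t990\t1010\nchr4\t0\t100\n")
        ctx = FilterContext(repeat_mask=read_bed(str(bed)))
        assert apply_tier(record(), FilterConfig.tier1(), ctx).reasons == ["repeat_mask"]
        outside = record()
        outside.pos = 2000
        assert apply_tier(outside, FilterConfig.tier1(), ctx).passed

    def test_monotone_in_every_statistic(self):
        """Improving one statistic never flips a pass to a fail."""
        rng = random.Random(7)
        for _ in range(200):
            dp4 = tuple(rng.randint(0, 6) for _ in range(4))
            rec = record(
                qual=rng.uniform(0, 40), dp4=dp4,
                pv4_=tuple(rng.choice([1e-6, 1e-3, 0.05, 0.5, 1.0])
                           for _ in range(4)))
            for config in (FilterConfig.tier1(), FilterConfig.tier2()):
                before = apply_tier(rec, config).passed
                improved = [
                    record(qual=rec.qual + 10, dp4=rec.dp4, pv4_=rec.pv4),
                    record(qual=rec.qual,
                           dp4=(dp4[0], dp4[1], dp4[2] + 1, dp4[3] + 1),
                           pv4_=rec.pv4),
                    record(qual=rec.qual, dp4=rec.dp4,
                           pv4_=(1.0, 1.0, 1.0, 1.0)),
                ]
                for better in improved:
                    after = apply_tier(better, config).passed
                    assert not (before and not after)

    def test_tier2_passes_require_three_alt_reads(self):
        rng = random.Random(11)
        for _ in range(200):
            dp4 = tuple(rng.randint(0, 5) for _ in range(4))
            rec = record(dp4=dp4)
            if apply_tier(rec, FilterConfig.tier2()).passed:
                assert rec.alt_depth >= 3


class TestRecurrentGenes:
    def test_counting_across_samples(self):
        tables = {
            "A": [("g1", True), ("g2", True)],
            "B": [("g2", True)],
            "C": [("g2", True), ("g3", True)],
        }
        assert recurrent_genes(tables, 2) == {"g2": 3}
        assert recurrent_genes(tables, 3) == {"g2": 3}

    def test_empty_tables(self):
        assert recurrent_genes({}, 2) == {}
        assert recurrent_genes({"A": []}, 1) == {}

    def test_boundary_inclusion(self):
        tables = {"A": [("g1", True)], "B": [("g1", True)], "C": [("g1", False)]}
        assert recurrent_genes(tables, 2) == {"g1": 2}
        assert recurrent_genes(tables, 3) == {}

    def test_known_variants_do_not_count(self):
        tables = {"A": [("g1", False)], "B": [("g1", False)]}
        assert recurrent_genes(tables, 1) == {}

    def test_dataframe_input_and_ordering(self):
        tables = {
            "A": pd.DataFrame({"gene": ["z1", "a1"], "novel": [True, True]}),
            "B": pd.DataFrame({"gene": ["z1", "a1"], "novel": [True, True]}),
            "C": pd.DataFrame({"gene": ["a1"], "novel": [True]}),
        }
        hits = recurrent_genes(tables, 2)
        assert list(hits.items()) == [("a1", 3), ("z1", 2)]
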