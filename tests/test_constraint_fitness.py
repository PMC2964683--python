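"""Constraint defect functions, the Tm formula, and the weighted fitness."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from ctpp_design.constraint_fitness import (
    ConstraintConfig,
    FitnessBreakdown,
    avg_tm_diff,
    count_site_occurrences,
    dimer_defect,
    fitness,
    gc_clamp_defect,
    gc_percent,
    gc_proportion_defect,
    has_dimer,
    has_hairpin,
    len_diff_defect,
    pcr_len_checks,
    pcr_len_defect,
    specificity_defect,
    tm_bm,
    tm_diff_defect,
    tm_range_defect,
)
from ctpp_design.sequence_model import ChromosomeVector, is_feasible, realize_primer_set

from conftest import make_primer_set, REF_PF1, REF_PR1, REF_PF2, REF_PR2


class TestGCPercent:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (REF_PF1, 30.0),
            (REF_PR1, 35.0),
            ("GGCC", 100.0),
            ("ATAT", 0.0),
        ],
    )
    def test_examples(self, p, expected):
        assert gc_percent(p) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_percent("")


class TestLenDiff:
    def test_all_equal_lengths_no_defect(self, default_cfg):
        v = ChromosomeVector(20, 228, 20, 20, 105, 20)
        assert len_diff_defect(v, default_cfg) == 0

    def test_all_three_gaps_exceeded(self, default_cfg):
        v = ChromosomeVector(16, 228, 28, 16, 105, 28)
        assert len_diff_defect(v, default_cfg) == 3

    def test_single_failing_pair(self, default_cfg):
        # only the Fl2/Rl2 gap (12) exceeds 3
        v = ChromosomeVector(20, 228, 20, 28, 105, 16)
        # Fl1/Rl1 gap 0, Fl2/Rl2 gap 12, Fl1/Rl2 gap 4 -> two checks fail
        assert len_diff_defect(v, default_cfg) == 2
        v = ChromosomeVector(20, 228, 20, 28, 105, 17)
        # Fl1/Rl1 gap 0, Fl2/Rl2 gap 11, Fl1/Rl2 gap 3 -> one check fails
        assert len_diff_defect(v, default_cfg) == 1


class TestGCBounds:
    def test_reference_set_within_bounds(self, default_cfg, reference_primers):
        s = make_primer_set(**{k.lower(): v for k, v in reference_primers.items()})
        assert gc_proportion_defect(s, default_cfg) == 0

    def test_poly_a_primers_all_fail(self, default_cfg):
        s = make_primer_set("A" * 20, "A" * 20, "A" * 20, "A" * 20)
        assert gc_proportion_defect(s, default_cfg) == 4

    def test_boundary_gc_is_inclusive(self, default_cfg):
        # exactly 20% GC passes
        p20 = "G" + "A" * 4  # 20%
        s = make_primer_set(p20 * 4, "A" * 20, "A" * 20, "A" * 20)
        assert gc_proportion_defect(s, default_cfg) == 3


class TestGCClamp:
    def test_reference_sequences(self, default_cfg, reference_primers):
        s = make_primer_set(**{k.lower(): v for k, v in reference_primers.items()})
        # Pf1 ends A, Pr1 ends G, Pf2 ends A, Pr2 ends A -> 3 fail
        assert gc_clamp_defect(s, default_cfg) == 3

    def test_all_clamped(self, default_cfg):
        s = make_primer_set("AAAAC", "AAAAG", "AAAAC", "AAAAC")
        assert gc_clamp_defect(s, default_cfg) == 0


class TestTmFormula:
    def test_molar_salt_log_term_vanishes(self):
        p = "GC" * 5 + "AT" * 5  # 20-mer, 50% GC
        assert tm_bm(p, 1.0) == pytest.approx(68.25)

    def test_default_salt(self):
        p = "GC" * 5 + "AT" * 5
        assert tm_bm(p, 0.05) == pytest.approx(46.65, abs=0.01)

    def test_single_substitution_shifts_by_gc_step(self):
        p = "GC" * 5 + "AT" * 5
        q = "A" + p[1:]  # one G->A substitution: GC% drops by 5 points
        assert tm_bm(p, 0.05) - tm_bm(q, 0.05) == pytest.approx(0.41 * 5)

    def test_nonpositive_salt_rejected(self):
        with pytest.raises(ValueError):
            tm_bm("ACGT" * 5, 0.0)

    def test_monotone_in_gc_length_and_salt(self):
        # increasing GC count at fixed length
        tms = [tm_bm("G" * k + "A" * (20 - k), 0.05) for k in range(21)]
        assert all(b > a for a, b in zip(tms, tms[1:]))
        # increasing length at fixed GC%
        tms = [tm_bm("GA" * k, 0.05) for k in range(8, 15)]
        assert all(b > a for a, b in zip(tms, tms[1:]))
        # increasing salt
        tms = [tm_bm("GA" * 10, na) for na in (0.01, 0.05, 0.2, 1.0)]
        assert all(b > a for a, b in zip(tms, tms[1:]))


class TestTmChecks:
    def test_identical_primers_no_defect(self, default_cfg):
        p = "GC" * 5 + "AT" * 5
        s = make_primer_set(p, p, p, p)
        assert tm_diff_defect(s, default_cfg) == 0
        assert avg_tm_diff(s, default_cfg) == 0.0
        assert tm_range_defect(s, default_cfg) == 0

    def test_one_gc_step_breaks_all_three_pairs(self, default_cfg):
        p = "GC" * 5 + "AT" * 5
        q = "A" + p[1:]  # Tm gap 2.05 > 1
        s = make_primer_set(p, q, p, q)  # all three working pairs straddle the gap
        assert tm_diff_defect(s, default_cfg) == 3
        assert avg_tm_diff(s, default_cfg) == pytest.approx(2.05)

    def test_middle_pair_only(self, default_cfg):
        p = "GC" * 5 + "AT" * 5
        q = "A" + p[1:]
        # Pf1/Pr1 equal, Pf2/Pr2 differ, Pf1/Pr2 equal
        s = make_primer_set(p, p, q, p)
        assert tm_diff_defect(s, default_cfg) == 1

    def test_out_of_range_tm_counted_per_primer(self, default_cfg):
        hot = "GC" * 14  # 28-mer 100% GC: far above 62 C
        cold = "AT" * 8  # 16-mer 0% GC: far below 45 C
        s = make_primer_set(hot, cold, hot, cold)
        assert tm_range_defect(s, default_cfg) == 4


class TestDimerScreen:
    def test_exact_reverse_complement_pair(self, default_cfg):
        p = "ATTGCAGCTAAGCTAG"
        q = "CTAGCTTAGCTGCAAT"  # reverse complement of p
        assert has_dimer(p, q, default_cfg)

    def test_poly_purine_primers_clean(self, default_cfg):
        # purine-only primers cannot form Watson-Crick pairs with each other
        s = make_primer_set("GAAAGAGAGAAGAAAGAGAG", "AGAGAAGAAAGAGAAGAAAG",
                            "GAGAAAGAAGAGAAAGAAGG", "AAGAGAAAGAAGAGAAAGAG")
        assert dimer_defect(s, default_cfg) == 0

    def test_palindromic_motif_self_dimer(self, default_cfg):
        # GGATCC is its own reverse complement: 6-base self-duplex
        assert has_dimer("AAAGGATCCAAA", "AAAGGATCCAAA", default_cfg)

    def test_three_prime_rule(self, default_cfg):
        # complementary run of 3 at p's 3' terminus
        p = "GAAAAAAAAAGCA"
        q = "GAAAAAAAATGCA"
        # p 3' end ...GCA pairs antiparallel with q 3' ...TGC
        assert has_dimer(p, q, default_cfg)
        # same run of 3 buried internally is below the 5-base stem threshold
        assert not has_dimer("GAGCAGAAAAAAG", "GATGCGAAAAAAG", default_cfg)


class TestHairpinScreen:
    def test_stem4_loop4(self, default_cfg):
        assert has_hairpin("GGGGAAAACCCC", default_cfg)

    def test_no_complementary_stem(self, default_cfg):
        assert not has_hairpin("A" * 12, default_cfg)

    def test_stem_below_threshold(self, default_cfg):
        assert not has_hairpin("GGGAAAACCC", default_cfg)

    def test_loop_below_threshold(self, default_cfg):
        # stem 4 but loop of only 2 unpaired bases
        assert not has_hairpin("GGGGAACCCC", default_cfg)


class TestSpecificity:
    def test_repeated_site_flagged(self, toy_template, default_cfg):
        s = realize_primer_set(toy_template, ChromosomeVector(20, 110, 20, 20, 110, 20))
        doubled = toy_template.sequence + s.pf1
        from ctpp_design.sequence_model import TemplateDNA

        t2 = TemplateDNA(doubled, toy_template.snp_index, "A", "C", record_id="rep")
        assert specificity_defect(s, t2) == 1

    def test_unique_sites_pass(self, toy_template, default_cfg):
        s = realize_primer_set(toy_template, ChromosomeVector(20, 110, 20, 20, 110, 20))
        assert specificity_defect(s, toy_template) == 0

    def test_ambiguity_matches_either_allele(self):
        # M expands to {A, C}: both alleles match, G does not
        assert count_site_occurrences("TTMCC", "TAC") == 1
        assert count_site_occurrences("TTMCC", "TCC") == 1
        assert count_site_occurrences("TTMCC", "TGC") == 0
        # overlapping occurrences count separately
        assert count_site_occurrences("AAAA", "AA") == 3


class TestProductLengths:
    def test_exact_ratio_products_no_defect(self, default_cfg):
        assert pcr_len_defect((160, 260, 400), default_cfg) == 0

    def test_short_products(self, default_cfg):
        # all three length floors fail; ratio checks per explicit enumeration
        checks = pcr_len_checks((50, 50, 80), default_cfg)
        assert checks[:3] == [False, False, False]
        assert pcr_len_defect((50, 50, 80), default_cfg) == 5

    def test_floor_is_strict(self, default_cfg):
        checks = pcr_len_checks((100, 260, 400), default_cfg)
        assert checks[0] is False


class TestFitnessAggregate:
    def test_planted_zero_design(self, planted_template, default_cfg):
        t, manifest = planted_template
        v = ChromosomeVector(*manifest["zero_vector"])
        s = realize_primer_set(t, v)
        bd = fitness(s, v, t, default_cfg)
        assert bd.total == 0.0
        assert bd.is_zero(default_cfg)

    def test_single_defect_weights(self, default_cfg):
        base = dict(
            len_diff_defect=0, gc_proportion_defect=0, gc_clamp_defect=0,
            tm_defect=0, tm_diff_defect=0, avg_tm_diff=0.0, dimer_defect=0,
            hairpin_defect=0, specificity_defect=0, pcr_len_defect=0,
        )
        only_spec = FitnessBreakdown(**{**base, "specificity_defect": 1}, total=0)
        assert only_spec.recombine(default_cfg) == 10.0
        only_product = FitnessBreakdown(**{**base, "pcr_len_defect": 1}, total=0)
        assert only_product.recombine(default_cfg) == 60.0

    @given(
        fl1=st.integers(16, 28), rl1=st.integers(16, 28),
        fl2=st.integers(16, 28), rl2=st.integers(16, 28),
        pl1=st.integers(100, 528), pl2=st.integers(100, 528),
    )
    @settings(derandomize=True, max_examples=120)
    def test_defect_ranges_and_recombination(self, planted_template, default_cfg,
                                             fl1, pl1, rl1, fl2, pl2, rl2):
        """Fuzzed vectors never escape the declared defect ranges and the
        stored total always equals its weighted recombination."""
        t, _ = planted_template
        v = ChromosomeVector(fl1, pl1, rl1, fl2, pl2, rl2)
        if not is_feasible(t, v):
            return
        s = realize_primer_set(t, v)
        bd = fitness(s, v, t, default_cfg)
        assert 0 <= bd.len_diff_defect <= 3
        assert 0 <= bd.gc_proportion_defect <= 4
        assert 0 <= bd.gc_clamp_defect <= 4
        assert 0 <= bd.tm_defect <= 4
        assert 0 <= bd.tm_diff_defect <= 3
        assert bd.avg_tm_diff >= 0
        assert 0 <= bd.dimer_defect <= 10
        assert 0 <= bd.hairpin_defect <= 4
        assert bd.specificity_defect in (0, 1)
        assert 0 <= bd.pcr_len_defect <= 7
        assert bd.total == pytest.approx(bd.recombine(default_cfg))

    def test_total_monotone_in_each_defect(self, default_cfg):
        """Flipping any single check from pass to fail never lowers the total."""
        base = dict(
            len_diff_defect=1, gc_proportion_defect=1, gc_clamp_defect=1,
            tm_defect=1, tm_diff_defect=1, avg_tm_diff=0.5, dimer_defect=1,
            hairpin_defect=1, specificity_defect=0, pcr_len_defect=1,
        )
        t0 = FitnessBreakdown(**base, total=0).recombine(default_cfg)
        for key in base:
            bumped = dict(base)
            bumped[key] = base[key] + (0.5 if key == "avg_tm_diff" else 1)
            assert FitnessBreakdown(**bumped, total=0).recombine(default_cfg) > t0
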