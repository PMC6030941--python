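"""Backtracking engine: unit matchers, full scans, search-order properties."""

import random

import pytest

from patscan import (
    DEFAULT_RULES,
    DNA_ALPHABET,
    Molecule,
    PatternValidationError,
    ScanOptions,
    SequenceRecord,
    StringUnit,
    UnitSpan,
    VariationBudget,
    WeightMatrix,
    match_complement_unit,
    match_repeat_unit,
    match_string_unit,
    match_with_variations,
    parse_pattern,
    scan_both_strands,
    scan_records,
    scan_sequence,
    score_weight_window,
)
from patscan.alphabet import WOBBLE_RULES
from patscan.fixtures import (
    brute_force_scan,
    plant_witness,
    random_pattern_set,
    random_sequence,
)
from patscan.match_engine import string_template
from patscan.pattern_model import ComplementUnit, RepeatUnit

from conftest import engine_key


def _spans(match):
    return [s.text for s in match.unit_spans]


class TestScanSequence:
    def test_ire_pattern_finds_whole_18mer(self, ire_18mer, basic_ire):
        (hit,) = scan_sequence(ire_18mer, basic_ire)
        assert (hit.start, hit.end) == (0, 18)
        assert _spans(hit) == ["C", "GTCAAG", "CAGTG", "CTTGAC"]

    def test_no_hit_on_unplanted_background(self, basic_ire):
        rng = random.Random(3)
        rec = SequenceRecord("bg", "", random_sequence(rng, 2000, gc=0.72))
        assert scan_sequence(rec, basic_ire) == []

    def test_single_mismatch_window(self):
        ps = parse_pattern("CAGTG[1,0,0]")
        rec = SequenceRecord("s", "", "AACAGCGAA")
        (hit,) = scan_sequence(rec, ps)
        # 1-based inclusive 3..7, one substitution
        assert (hit.start, hit.end) == (2, 7)
        assert hit.unit_spans[0].text == "CAGCG"

    def test_empty_sequence_yields_no_match(self, basic_ire):
        rec = SequenceRecord("s", "", "")
        assert scan_sequence(rec, basic_ire) == []

    def test_molecule_mismatch_raises_not_silent_empty(self, ire_18mer):
        ps = parse_pattern("MK", Molecule.PROTEIN)
        with pytest.raises(PatternValidationError):
            scan_sequence(ire_18mer, ps)

    def test_max_hits_truncates_across_sequences(self):
        ps = parse_pattern("GA")
        recs = [
            SequenceRecord("a", "", "GAGAGA"),
            SequenceRecord("b", "", "GAGA"),
        ]
        hits = scan_records(recs, ps, ScanOptions(max_hits=4))
        assert len(hits) == 4
        assert [h.seq_id for h in hits] == ["a", "a", "a", "b"]

    def test_non_overlapping_mode_advances_past_match(self):
        ps = parse_pattern("GAGA")
        rec = SequenceRecord("s", "", "GAGAGAGA")
        per_start = scan_sequence(rec, ps)
        assert [h.start for h in per_start] == [0, 2, 4]
        non_overlap = scan_sequence(
            rec, ps, ScanOptions(overlap_mode="non_overlapping")
        )
        assert [h.start for h in non_overlap] == [0, 4]


class TestUnitMatchers:
    @pytest.mark.parametrize(
        "window, pattern, ok",
        [
            ("CAGTG", "CAGTG", True),
            ("CAGTG", "CNNNN", True),
            ("CAGTG", "GAGAG", False),
            ("CAGT", "CAGTG", False),
        ],
    )
    def test_exact_string_matching(self, window, pattern, ok):
        assert match_string_unit(window, StringUnit(pattern),
                                 DNA_ALPHABET) is ok

    def test_sequence_ambiguity_is_literal(self):
        # sequence N matches pattern N, but not pattern A
        assert match_string_unit("N", StringUnit("N"), DNA_ALPHABET)
        assert not match_string_unit("N", StringUnit("A"), DNA_ALPHABET)

    @pytest.mark.parametrize(
        "template_text, window, budget, expected",
        [
            ("CTTGAC", "CTTGAT", (1, 0, 0), (1, 0, 0)),
            ("CAGTG", "CATG", (0, 0, 1), (0, 0, 1)),
            ("CAGTG", "CATG", (1, 0, 0), None),
            ("CAGTG", "CAGTG", (0, 0, 0), (0, 0, 0)),
            ("CAGTG", "CAAGTG", (0, 1, 0), (0, 1, 0)),
        ],
    )
    def test_match_with_variations(self, template_text, window, budget,
                                   expected):
        template = string_template(template_text, DNA_ALPHABET)
        assert match_with_variations(
            template, window, VariationBudget(*budget)
        ) == expected

    def test_variation_counts_prefer_fewer_indels(self):
        # identical strings: nothing should be spent even when allowed
        template = string_template("ACGT", DNA_ALPHABET)
        assert match_with_variations(
            template, "ACGT", VariationBudget(1, 1, 1)
        ) == (0, 0, 0)

    def test_complement_unit(self):
        bindings = {"p2": UnitSpan("p2", 0, 6, "GTCAAG")}
        unit = ComplementUnit(target="p2", name="p4")
        assert match_complement_unit(bindings, unit, "CTTGAC", DEFAULT_RULES)
        assert not match_complement_unit(bindings, unit, "CTTGAT",
                                         DEFAULT_RULES)
        relaxed = ComplementUnit(target="p2", name="p4",
                                 budget=VariationBudget(1, 0, 0))
        assert match_complement_unit(bindings, relaxed, "CTTGAT",
                                     DEFAULT_RULES)

    def test_complement_under_wobble_rules(self):
        bindings = {"p1": UnitSpan("p1", 0, 2, "GT")}
        unit = ComplementUnit(target="p1", name="p2")
        # reverse of GT is TG; partners(T)={A,G}, partners(G)={C,T}
        assert match_complement_unit(bindings, unit, "GC", WOBBLE_RULES)
        assert not match_complement_unit(bindings, unit, "GC", DEFAULT_RULES)

    def test_repeat_unit_matches_bound_text(self):
        bindings = {"p1": UnitSpan("p1", 0, 4, "GAGA")}
        unit = RepeatUnit(target="p1", name="p2")
        assert match_repeat_unit(bindings, unit, "GAGA")
        assert not match_repeat_unit(bindings, unit, "GAG")
        relaxed = RepeatUnit(target="p1", name="p2",
                             budget=VariationBudget(1, 0, 0))
        assert match_repeat_unit(bindings, relaxed, "GACA")

    def test_repeat_repeats_the_match_not_the_pattern(self):
        # the range matched "GAGA" specifically; only that text repeats
        ps = parse_pattern("p1=4...4 p1")
        rec = SequenceRecord("s", "", "GAGAGAGA")
        hits = scan_sequence(rec, ps)
        assert any(_spans(h) == ["GAGA", "GAGA"] for h in hits)

    @pytest.mark.parametrize(
        "window, expected",
        [("AG", 170.0), ("AN", 90.0), ("CT", 30.0)],
    )
    def test_weight_scoring(self, window, expected):
        matrix = WeightMatrix(((90.0, 10.0, 0.0, 0.0), (0.0, 0.0, 80.0, 20.0)))
        assert score_weight_window(matrix, window) == expected

    def test_consensus_scores_sum_of_column_maxima(self):
        matrix = WeightMatrix(
            ((50.0, 20.0, 20.0, 10.0), (5.0, 80.0, 10.0, 5.0),
             (0.0, 0.0, 0.0, 100.0))
        )
        consensus = "ACT"
        assert score_weight_window(matrix, consensus) == \
            sum(max(c) for c in matrix.columns)


class TestLengthConstraints:
    @pytest.mark.parametrize(
        "expr, seq, n_hits",
        [
            ("p1=3...8 p2=CAGTG length(p1) < 5", "AAAACAGTG", 2),
            ("p1=3...8 p2=CAGTG length(p1) > 3", "AAAACAGTG", 1),
        ],
    )
    def test_constraint_prunes_range_assignments(self, expr, seq, n_hits):
        rec = SequenceRecord("s", "", seq)
        assert len(scan_sequence(rec, parse_pattern(expr))) == n_hits

    def test_boundary_is_strict(self):
        # spans of 6 and 5: total 11 is < 12 but not < 11
        rec = SequenceRecord("s", "", "ACGTACGTACG")
        base = "p1=6...6 p2=5...5 length(p1+p2) < {}"
        assert len(scan_sequence(rec, parse_pattern(base.format(12)))) == 1
        assert scan_sequence(rec, parse_pattern(base.format(11))) == []

    def test_zero_length_span_fails_greater_than_zero(self):
        rec = SequenceRecord("s", "", "ACGT")
        ps = parse_pattern("p1=0...0 p2=ACGT length(p1) > 0")
        assert scan_sequence(rec, ps) == []


class TestBothStrands:
    def test_reverse_strand_hit_mapped_back(self):
        # CACTG is the reverse complement of CAGTG
        rec = SequenceRecord("s", "", "TTCACTGTT")
        ps = parse_pattern("CAGTG")
        assert scan_sequence(rec, ps) == []
        hits = scan_both_strands(rec, ps)
        (hit,) = hits
        assert hit.strand == "-"
        assert (hit.start, hit.end) == (2, 7)
        assert hit.unit_spans[0].text == "CAGTG"

    def test_palindromic_pattern_hits_both_strands_at_same_locus(self):
        rec = SequenceRecord("s", "", "TTACGTTT")
        hits = scan_both_strands(rec, parse_pattern("ACGT"))
        assert {(h.strand, h.start, h.end) for h in hits} == {
            ("+", 2, 6),
            ("-", 2, 6),
        }

    def test_protein_cannot_scan_both_strands(self):
        rec = SequenceRecord("s", "", "MKTAY", molecule=Molecule.PROTEIN)
        ps = parse_pattern("MK", Molecule.PROTEIN)
        with pytest.raises(PatternValidationError):
            scan_both_strands(rec, ps)


class TestSearchProperties:
    N_CASES = 150

    def _cases(self, seed, **kwargs):
        rng = random.Random(seed)
        for _ in range(self.N_CASES):
            ps = random_pattern_set(rng, **kwargs)
            seq = random_sequence(rng, 150)
            if rng.random() < 0.6:
                seq = plant_witness(rng, ps, seq)
            yield rng, ps, SequenceRecord("s", "", seq)

    def test_engine_equals_brute_force_oracle(self):
        for _, ps, rec in self._cases(101):
            engine = [engine_key(m) for m in scan_sequence(rec, ps)]
            oracle = [engine_key(m) for m in brute_force_scan(rec, ps)]
            assert engine == oracle

    def test_budget_relaxation_never_loses_a_start(self):
        rng = random.Random(55)
        for _, ps, rec in self._cases(102):
            before = {m.start for m in scan_sequence(rec, ps)}
            budgeted = [
                u for u in ps.units
                if hasattr(u, "budget")
            ]
            if not budgeted:
                continue
            u = rng.choice(budgeted)
            b = u.budget
            u.budget = VariationBudget(
                b.mismatches + 1, b.insertions, b.deletions
            )
            after = {m.start for m in scan_sequence(rec, ps)}
            assert before <= after

    def test_range_widening_never_loses_a_start(self):
        rng = random.Random(56)
        for _, ps, rec in self._cases(103):
            ranges = [u for u in ps.units if u.tag == "range"]
            if not ranges:
                continue
            before = {m.start for m in scan_sequence(rec, ps)}
            u = rng.choice(ranges)
            u.min_len = max(0, u.min_len - 1)
            u.max_len += 1
            after = {m.start for m in scan_sequence(rec, ps)}
            assert before <= after

    def test_alternative_union_semantics(self):
        rng = random.Random(57)
        for _ in range(60):
            branch_a = "".join(rng.choice("ACGT") for _ in range(4))
            branch_b = "".join(rng.choice("ACGT") for _ in range(4))
            seq = plant_witness(
                rng, parse_pattern(rng.choice((branch_a, branch_b))),
                random_sequence(rng, 80),
            )
            rec = SequenceRecord("s", "", seq)
            alt = parse_pattern(f"( {branch_a} | {branch_b} )")
            starts_alt = {m.start for m in scan_sequence(rec, alt)}
            starts_a = {m.start for m in scan_sequence(rec,
                                                       parse_pattern(branch_a))}
            starts_b = {m.start for m in scan_sequence(rec,
                                                       parse_pattern(branch_b))}
            assert starts_alt == starts_a | starts_b

    def test_weight_hit_count_non_increasing_in_threshold(self):
        rng = random.Random(58)
        matrix = "{(50,20,20,10),(5,80,10,5),(25,25,25,25)}"
        rec = SequenceRecord("s", "", random_sequence(rng, 300))
        counts = [
            len(scan_sequence(rec, parse_pattern(f"{matrix} > {t}")))
            for t in range(0, 160, 10)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_exact_string_reduces_to_substring_search(self):
        rng = random.Random(59)
        for _ in range(40):
            needle = "".join(rng.choice("ACGT") for _ in range(3))
            hay = random_sequence(rng, 120)
            rec = SequenceRecord("s", "", hay)
            starts = [m.start for m in scan_sequence(rec,
                                                     parse_pattern(needle))]
            expected = [
                i for i in range(len(hay) - 2) if hay[i : i + 3] == needle
            ]
            assert starts == expected

    def test_scan_is_deterministic(self, ire_18mer):
        ps1 = parse_pattern("p1=C p2=5...6 p3=( CAGTG | GAGAG ) p4=~p2[1,0,0]")
        ps2 = parse_pattern("p1=C p2=5...6 p3=( CAGTG | GAGAG ) p4=~p2[1,0,0]")
        a = scan_sequence(ire_18mer, ps1)
        b = scan_sequence(ire_18mer, ps2)
        assert [engine_key(m) for m in a] == [engine_key(m) for m in b]
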