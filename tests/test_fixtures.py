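"""Synthetic data generation, the IRE pattern ladder, and the oracle."""

import random

import pytest

from patscan import (
    FixtureError,
    OracleBoundError,
    SequenceRecord,
    brute_force_scan,
    generate_planted,
    ire_instance,
    ire_pattern,
    ire_sampler,
    parse_pattern,
    scan_sequence,
)
from patscan.fixtures import IRE_STAGES


class TestGeneratePlanted:
    def test_literal_motif_is_planted_at_recorded_offsets(self):
        motif = "CGTCAAGCAGTGCTTGAC"
        records, placements = generate_planted(1, 100, motif, 1, 0.5, seed=7)
        (rec,), (pl,) = records, placements
        assert len(rec.residues) == 100
        assert rec.residues[pl.start : pl.end] == motif

    def test_deterministic_for_fixed_seed(self):
        a = generate_planted(3, 200, "CAGTG", 2, 0.72, seed=3)
        b = generate_planted(3, 200, "CAGTG", 2, 0.72, seed=3)
        assert [r.residues for r in a[0]] == [r.residues for r in b[0]]
        assert a[1] == b[1]

    def test_placements_never_overlap(self):
        _, placements = generate_planted(5, 120, "ACGTACGTAC", 8, 0.5, seed=1)
        by_seq = {}
        for pl in placements:
            by_seq.setdefault(pl.seq_id, []).append((pl.start, pl.end))
        for spans in by_seq.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_packing_raises(self):
        with pytest.raises(FixtureError):
            generate_planted(1, 50, "A" * 20, 3, 0.5, seed=0)

    def test_gc_fraction_roughly_respected(self):
        records, _ = generate_planted(1, 5000, "C", 0, gc=0.72, seed=2)
        seq = records[0].residues
        gc = sum(seq.count(b) for b in "GC") / len(seq)
        assert 0.67 < gc < 0.77


class TestIrePatterns:
    def test_basic_stage_structure(self):
        ps = ire_pattern("basic")
        assert [u.tag for u in ps.units] == [
            "string", "range", "string", "complement",
        ]

    def test_short_stem_stage_widens_the_stem_range(self):
        stem = ire_pattern("short_stem").units[1]
        assert (stem.min_len, stem.max_len) == (5, 6)

    def test_alt_loop_stage_uses_an_alternative(self):
        loop = ire_pattern("alt_loop").units[2]
        assert loop.tag == "alternative"
        assert loop.left[0].text == "CAGTG"
        assert loop.right[0].text == "GAGAG"

    def test_wobble_stage_declares_gu_pairs(self):
        ps = ire_pattern("wobble")
        rules = ps.rule_declarations["r1"]
        assert rules.pairs["G"] == {"C", "T"}
        comp = ps.units[-1]
        assert comp.rules == "r1"

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            ire_pattern("bogus")

    @pytest.mark.parametrize("stage", IRE_STAGES)
    def test_instance_found_by_its_stage_and_all_later_stages(self, stage):
        rng = random.Random(13)
        stage_idx = IRE_STAGES.index(stage)
        for trial in range(15):
            text = ire_instance(rng, stage)
            rec = SequenceRecord("s", "", text)
            for later in IRE_STAGES[stage_idx:]:
                starts = {m.start for m in scan_sequence(rec,
                                                         ire_pattern(later))}
                assert 0 in starts, (stage, later, text)

    def test_bacterial_instances_invisible_to_basic_pattern(self):
        rng = random.Random(17)
        basic = ire_pattern("basic")
        sampler = ire_sampler()
        for _ in range(50):
            rec = SequenceRecord("s", "", sampler(rng))
            assert 0 not in {m.start for m in scan_sequence(rec, basic)}


class TestBruteForce:
    def test_exact_string_matches_all_occurrences(self):
        hits = brute_force_scan("GAGAG", parse_pattern("GAG"))
        assert [m.start for m in hits] == [0, 2]

    def test_basic_ire_on_the_18mer(self, ire_18mer, basic_ire):
        hits = brute_force_scan(ire_18mer, basic_ire)
        assert [(m.start, m.end) for m in hits] == [(0, 18)]
        assert [s.text for s in hits[0].unit_spans] == [
            "C", "GTCAAG", "CAGTG", "CTTGAC",
        ]

    def test_combinatorial_bound_enforced(self):
        ps = parse_pattern(" ".join("0...9" for _ in range(8)))
        with pytest.raises(OracleBoundError):
            brute_force_scan("A" * 200, ps)
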