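import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trscape.detect import (
    DetectorConfig,
    ScoringScheme,
    TandemRepeat,
    align_against_perfect,
    detect,
    detect_perfect,
    resolve_overlaps,
)
from trscape.errors import MotifError
from trscape.motifs import canonical_class, reverse_complement

from _oracles import brute_force_perfect_runs, linear_repeat_align, random_dna


class TestDetectPerfect:
    def test_basic_trinucleotide(self):
        (tr,) = detect_perfect("AAGAAGAAGAAG")
        assert (tr.start, tr.end, tr.unit) == (0, 12, "AAG")
        assert tr.copy_number == 4.0 and tr.score == 12 and tr.perfect

    def test_eleven_nt_below_minimum(self):
        assert detect_perfect("AAGAAGAAGAA") == []

    def test_partial_trailing_copy(self):
        (tr,) = detect_perfect("ACGTACGTACGTAC")
        assert (tr.start, tr.end, tr.unit, tr.copy_number, tr.score) == (
            0, 14, "ACGT", 3.5, 14,
        )

    def test_empty_sequence(self):
        assert detect_perfect("") == []

    def test_mononucleotide_primitivity(self):
        trs = detect_perfect("A" * 100)
        assert [(t.start, t.end, t.unit) for t in trs] == [(0, 100, "A")]

    def test_run_broken_by_n(self):
        trs = detect_perfect("AAGAAGAAGAAGNAAGAAGAAGAAG")
        assert [(t.start, t.end) for t in trs] == [(0, 12), (13, 25)]

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_small(self, seed):
        rng = np.random.default_rng(seed)
        # low-entropy alphabet tweak: embed planted repeats to exercise runs
        seq = random_dna(rng, 600)
        seq = seq[:100] + "ATAT" * 5 + seq[120:400] + "AAGC" * 4 + seq[416:]
        got = {(t.start, t.end, t.unit) for t in detect_perfect(seq, max_unit=6)}
        expected = set(brute_force_perfect_runs(seq, max_unit=6))
        assert got == expected


class TestAlignAgainstPerfect:
    def test_perfect_copies(self):
        assert align_against_perfect("AAGAAG", "AAG") == (6, 6, 0, 0)

    def test_single_substitution(self):
        # 21 nt with one substituted base: 20 matches, 1 mismatch
        assert align_against_perfect("AAGAAGAAGTAGAAGAAGAAG", "AAG") == (16, 20, 1, 0)

    def test_single_deletion(self):
        # 8 nt left of (AAG)3 after deleting one base: 8 matches vs the
        # 9-nt reference with one unit base deleted
        assert align_against_perfect("AAGAGAAG", "AAG") == (4, 8, 0, 1)

    def test_non_acgt_window_rejected(self):
        with pytest.raises(MotifError):
            align_against_perfect("AANAAG", "AAG")

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = int(rng.integers(1, 61))
        k = int(rng.integers(1, 11))
        window = random_dna(rng, m)
        unit = random_dna(rng, k)
        score, *_ = align_against_perfect(window, unit)
        oracle_score, *_ = linear_repeat_align(window, unit)
        assert score == oracle_score

    def test_free_phase_at_both_ends(self):
        # window starts mid-unit and ends mid-unit: all matches, no penalty
        assert align_against_perfect("GAAGA", "AAG") == (5, 5, 0, 0)


class TestDetect:
    def test_planted_imperfect_array(self, rng):
        bg = random_dna(rng, 1000)
        arr = list("AAG" * 10)
        arr[13] = "T"  # substitution inside copy 5
        # flanking C's break chance continuation of the array
        seq = bg[:399] + "C" + "".join(arr) + "C" + bg[431:]
        hits = [t for t in detect(seq) if t.start < 431 and t.end > 400]
        assert len(hits) == 1
        tr = hits[0]
        assert (tr.start, tr.end) == (400, 430)
        assert tr.score == 25 and not tr.perfect
        oracle_score, *_ = linear_repeat_align(seq[400:430], "AAG")
        assert tr.score == oracle_score

    def test_all_n_sequence(self):
        assert detect("N" * 100) == []

    def test_short_sequence(self):
        assert detect("ACGT") == []

    def test_homopolymer(self):
        (tr,) = detect("A" * 100)
        assert (tr.start, tr.end, tr.unit, tr.score) == (0, 100, "A", 100)

    def test_contains_perfect_calls(self, rng):
        seq = random_dna(rng, 500)
        seq = seq[:200] + "ACGT" * 5 + seq[220:]
        perfect_spans = {
            (t.start, t.end, t.canonical_unit) for t in detect_perfect(seq)
        }
        detected = {(t.start, t.end, t.canonical_unit) for t in detect(seq)}
        assert perfect_spans <= detected

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 800)
        seq = seq[:100] + "AAG" * 6 + seq[118:300] + "AT" * 8 + seq[316:]
        base = detect(seq, DetectorConfig())
        stricter = detect(seq, DetectorConfig(min_length=20, min_score=20))
        base_keys = {(t.start, t.end, t.unit) for t in base}
        assert {(t.start, t.end, t.unit) for t in stricter} <= base_keys
        for t in base:
            assert t.length >= 12 and t.score >= 12 and t.copy_number >= 2

    def test_determinism(self, rng):
        seq = random_dna(rng, 2000)
        assert detect(seq) == detect(seq)

    def test_strand_symmetry(self, rng):
        seq = random_dna(rng, 300)
        seq = seq[:100] + "AAG" * 8 + seq[124:180] + "ACGGT" * 4 + seq[200:]
        n = len(seq)
        revcomp_seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = detect(seq)
        rev = detect(revcomp_seq)
        fwd_keys = {
            (n - t.end, n - t.start, canonical_class(reverse_complement(t.unit)))
            for t in fwd
        }
        rev_keys = {(t.start, t.end, t.canonical_unit) for t in rev}
        assert fwd_keys == rev_keys


def _tr(start, end, unit, score, seq_id="s1"):
    return TandemRepeat(
        seq_id, start, end, unit, canonical_class(unit), len(unit),
        (end - start) / len(unit), score, True,
    )


class TestResolveOverlaps:
    def test_disjoint_kept(self):
        trs = [_tr(0, 12, "A", 12), _tr(50, 62, "AG", 12)]
        assert resolve_overlaps(trs) == sorted(trs, key=lambda t: t.start)

    def test_same_span_prefers_higher_score(self):
        a = _tr(0, 24, "AAG", 24)
        b = _tr(0, 24, "AAGAAG", 20)
        assert resolve_overlaps([a, b]) == [a]

    def test_score_tie_prefers_smaller_unit(self):
        a = _tr(0, 24, "AAG", 24)
        b = _tr(0, 24, "AAGAAT", 24)
        assert resolve_overlaps([a, b]) == [a]

    def test_nested_lower_scoring_dropped(self):
        outer = _tr(0, 60, "AAG", 55)
        inner = _tr(10, 30, "AG", 18)
        assert resolve_overlaps([outer, inner]) == [outer]

    def test_nested_pairs_enumerated_on_fixture(self):
        # crafted 200-nt layout: one dominant repeat, one nested, one distant
        cands = [
            _tr(20, 80, "AAG", 60),
            _tr(30, 50, "A", 20),
            _tr(75, 95, "AT", 18),  # 5 bp overlap of a 20-bp span: kept
            _tr(150, 170, "ACG", 20),
        ]
        kept = resolve_overlaps(cands)
        spans = [(t.start, t.end) for t in kept]
        assert (30, 50) not in spans
        assert {(20, 80), (75, 95), (150, 170)} == set(spans)

    @given(st.lists(
        st.tuples(st.integers(0, 150), st.integers(12, 40), st.integers(12, 60)),
        max_size=12,
    ))
    @settings(max_examples=50, deadline=None)
    def test_output_pairwise_below_threshold(self, raw):
        cands = [_tr(s, s + length, "AAG", score) for s, length, score in raw]
        kept = resolve_overlaps(cands)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                ov = min(a.end, b.end) - max(a.start, b.start)
                shorter = min(a.length, b.length)
                assert ov <= 0 or 2 * ov < shorter
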