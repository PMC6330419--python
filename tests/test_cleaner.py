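"""Similarity trace, segment detection and masking."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqshave import (
    Alignment,
    ErrorSpec,
    MatchAnnotation,
    ScoringMatrix,
    build_erroneous_msa,
    clean,
    clean_nt,
    detect_segments,
    generate_fixture_msa,
    similarity_trace,
    transfer_gaps,
)
from seqshave.cleaner import PRESETS

DEFAULT = PRESETS["default"]


def fraction_trace(symbols: str, m: ScoringMatrix) -> list[Fraction]:
    """Independent exact-rational reference accumulator."""
    costs = {
        "B": Fraction(m.c1).limit_denominator(1000),
        "P": Fraction(m.c2).limit_denominator(1000),
        "L": Fraction(m.c3).limit_denominator(1000),
        "U": Fraction(m.c4).limit_denominator(1000),
    }
    score = Fraction(1)
    out = []
    for sym in symbols:
        score = min(Fraction(1), max(Fraction(0), score + costs[sym]))
        out.append(score)
    return out


class TestScoringMatrix:
    def test_presets_match_published_values(self):
        assert (DEFAULT.c1, DEFAULT.c2, DEFAULT.c3, DEFAULT.c4) == (
            -0.15, -0.08, 0.15, 0.45,
        )
        v18 = PRESETS["v1_8"]
        assert (v18.c1, v18.c2, v18.c3, v18.c4) == (-0.30, -0.10, 0.20, 0.50)
        assert len(PRESETS) == 5

    def test_sign_validation(self):
        with pytest.raises(ValueError):
            ScoringMatrix(0.1, -0.1, 0.1, 0.1)
        with pytest.raises(ValueError):
            ScoringMatrix(-0.1, -0.1, -0.1, 0.1)

    def test_min_detectable_run(self):
        assert DEFAULT.min_detectable_run() == 7
        assert PRESETS["v1_8"].min_detectable_run() == 4  # ceil(1 / 0.30)


class TestSimilarityTrace:
    def test_all_uppercase_clamps_at_one(self):
        tr = similarity_trace(MatchAnnotation("x", "UUUUU"), DEFAULT)
        assert tr.scores.tolist() == [1, 1, 1, 1, 1]

    def test_seven_blanks_reach_zero(self):
        """-0.15 x 7 crosses zero exactly at the seventh blank."""
        tr = similarity_trace(MatchAnnotation("x", "BBBBBBB"), DEFAULT)
        assert tr.scores.tolist() == pytest.approx(
            [0.85, 0.70, 0.55, 0.40, 0.25, 0.10, 0.00]
        )
        assert tr.milli[-1] == 0

    def test_mixed_symbols_hand_accumulation(self):
        tr = similarity_trace(MatchAnnotation("x", "UUBBBPLU"), DEFAULT)
        assert tr.scores.tolist() == pytest.approx(
            [1, 1, 0.85, 0.70, 0.55, 0.47, 0.62, 1.00]
        )

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            similarity_trace(MatchAnnotation("x", ""), DEFAULT)


matrices = st.builds(
    ScoringMatrix,
    c1=st.integers(-500, -1).map(lambda k: k / 1000),
    c2=st.integers(-500, -1).map(lambda k: k / 1000),
    c3=st.integers(1, 500).map(lambda k: k / 1000),
    c4=st.integers(1, 500).map(lambda k: k / 1000),
)


@given(st.text(alphabet="BPLU", min_size=1, max_size=200), matrices)
@settings(deadline=None, max_examples=300)
def test_trace_matches_exact_rational_oracle(symbols, m):
    tr = similarity_trace(MatchAnnotation("x", symbols), m)
    expected = fraction_trace(symbols, m)
    assert all(
        Fraction(int(got), 1000) == want for got, want in zip(tr.milli, expected)
    )
    assert tr.scores.min() >= 0 and tr.scores.max() <= 1


@given(st.text(alphabet="BPLU", min_size=1, max_size=150), st.integers(1, 20))
@settings(deadline=None, max_examples=150)
def test_appending_blanks_never_removes_a_segment(symbols, k):
    before = detect_segments(similarity_trace(MatchAnnotation("x", symbols), DEFAULT))
    after = detect_segments(
        similarity_trace(MatchAnnotation("x", symbols + "B" * k), DEFAULT)
    )
    for seg in before:
        match = [s for s in after if s.start_res == seg.start_res]
        assert match and match[0].end_res >= seg.end_res


class TestDetectSegments:
    def _trace(self, symbols):
        return similarity_trace(MatchAnnotation("x", symbols), DEFAULT)

    def test_all_one_trace_has_no_segments(self):
        assert detect_segments(self._trace("UUUUUU")) == []

    def test_start_after_last_one_end_at_last_zero(self):
        # UUUBBBBBBBUUUU: below 1 from position 4, zero at position 10,
        # recovery afterwards -> segment 4..10
        segs = detect_segments(self._trace("UUUBBBBBBBUUUU"))
        assert len(segs) == 1
        assert (segs[0].start_res, segs[0].end_res) == (4, 10)

    def test_run_reaching_sequence_end(self):
        # zero at position 10, then partial recovery that never returns to 1
        segs = detect_segments(self._trace("UUUBBBBBBBL"))
        assert len(segs) == 1
        assert (segs[0].start_res, segs[0].end_res) == (4, 11)

    def test_sub_one_run_without_zero_is_not_a_segment(self):
        assert detect_segments(self._trace("UUUBBBUUUU")) == []

    def test_trace_starting_below_one_starts_at_residue_one(self):
        segs = detect_segments(self._trace("BBBBBBBUUUU"))
        assert (segs[0].start_res, segs[0].end_res) == (1, 7)

    def test_two_disjoint_segments(self):
        symbols = "BBBBBBB" + "UUU" + "BBBBBBB" + "UUU"
        segs = detect_segments(self._trace(symbols))
        assert [(s.start_res, s.end_res) for s in segs] == [(1, 7), (11, 17)]


class TestClean:
    def test_identical_msa_unchanged(self, identical_aa_msa):
        cleaned, segments = clean(identical_aa_msa)
        assert cleaned.records == identical_aa_msa.records
        assert segments == []

    def test_scrambled_block_masked_only_in_affected_sequence(self, rng):
        nt = generate_fixture_msa(rng_seed=rng)
        sid = nt.ids[int(rng.integers(25))]
        aa, truth = build_erroneous_msa(nt, [ErrorSpec("scramble", sid, 30)], rng)
        cleaned, segments = clean(aa)
        for other, (before, after) in zip(aa.ids, zip(aa.records, cleaned.records)):
            if other != sid:
                assert before == after
        t = truth[0]
        cmap = aa.coord_map(sid)
        masked = sum(
            cleaned.seq(sid)[cmap.col_of(r) - 1] == "-"
            for r in range(t.start_res, t.end_res + 1)
        )
        assert masked / t.length_codons >= 0.80

    def test_masking_conservation(self, rng):
        """Residues removed == sum of segment lengths; geometry preserved."""
        nt = generate_fixture_msa(rng_seed=rng)
        sid = nt.ids[0]
        aa, _ = build_erroneous_msa(nt, [ErrorSpec("scramble", sid, 25)], rng)
        cleaned, segments = clean(aa)
        assert cleaned.n_cols == aa.n_cols
        removed = aa.residue_count() - cleaned.residue_count()
        assert removed == sum(s.length for s in segments)

    def test_segments_carry_column_coordinates(self, rng):
        nt = generate_fixture_msa(rng_seed=rng)
        sid = nt.ids[1]
        aa, _ = build_erroneous_msa(nt, [ErrorSpec("scramble", sid, 25)], rng)
        _, segments = clean(aa)
        for s in segments:
            cmap = aa.coord_map(s.seq_id)
            assert s.start_col == cmap.col_of(s.start_res)
            assert s.end_col == cmap.col_of(s.end_res)

    def test_mask_char_option(self, rng):
        nt = generate_fixture_msa(rng_seed=rng)
        sid = nt.ids[2]
        aa, _ = build_erroneous_msa(nt, [ErrorSpec("scramble", sid, 25)], rng)
        cleaned, segments = clean(aa, mask_char="X")
        assert cleaned.residue_count() == aa.residue_count()
        seg = [s for s in segments if s.seq_id == sid][0]
        cmap = aa.coord_map(sid)
        assert cleaned.seq(sid)[cmap.col_of(seg.start_res) - 1] == "X"

    def test_second_pass_removes_nothing_new(self, rng):
        """Cleaning a once-cleaned alignment finds no further segments on
        single-error fixtures (idempotence on this fixture set)."""
        for rep in range(5):
            nt = generate_fixture_msa(rng_seed=rng)
            sid = nt.ids[int(rng.integers(25))]
            aa, _ = build_erroneous_msa(nt, [ErrorSpec("scramble", sid, 30)], rng)
            once, _ = clean(aa)
            twice, new_segments = clean(once)
            assert new_segments == []


class TestCleanNt:
    def _nt_with_error(self, rng):
        """Fixture codon alignment with one 30-codon scramble injected
        directly into the gapped nucleotide row (length-conserving)."""
        from seqshave import introduce_error

        nt = generate_fixture_msa(n_codons=120, rng_seed=rng)
        sid = nt.ids[int(rng.integers(25))]
        mutated, truth = introduce_error(nt, ErrorSpec("scramble", sid, 30), rng)
        orig = nt.seq(sid)
        it = iter(mutated)
        gapped = "".join(next(it) if ch != "-" else "-" for ch in orig)
        return nt.replace_seq(sid, gapped), truth

    def test_codon_masking_conservation(self, rng):
        nt_err, truth = self._nt_with_error(rng)
        cleaned_nt, segments = clean_nt(nt_err)
        assert segments, "the 30-codon scramble should be detected"
        aa_removed = sum(s.length for s in segments)
        nt_removed = nt_err.residue_count() - cleaned_nt.residue_count()
        assert nt_removed == 3 * aa_removed
        # masked codons overlap the true error window in the right sequence
        seg = max(segments, key=lambda s: s.length)
        assert seg.seq_id == truth.seq_id
        assert seg.start_res <= truth.end_res and seg.end_res >= truth.start_res

    def test_no_segments_leaves_nt_unchanged(self):
        nt = generate_fixture_msa(n_seqs=10, n_codons=60, divergence=0.0,
                                  indel_rate=0.0, rng_seed=4)
        cleaned, segments = clean_nt(nt)
        assert segments == []
        assert cleaned.records == nt.records

    def test_codon_coordinates_from_aa_segment(self):
        """aa residues 4..10 map to ungapped CDS positions 10..30."""
        prot = Alignment((("a", "MKVLITGAGSGI"),), "aa")
        nt = transfer_gaps(prot, {"a": "ATGAAAGTTCTTATTACTGGTGCTGGTTCTGGTATT"})
        cmap = nt.coord_map("a")
        start_nt, end_nt = 3 * (4 - 1) + 1, 3 * 10
        assert (start_nt, end_nt) == (10, 30)
        assert cmap.col_of(start_nt) == 10 and cmap.col_of(end_nt) == 30
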