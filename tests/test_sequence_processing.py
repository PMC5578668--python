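"""Reference-anchored alignment, concatenation and QC.

The aligner is checked against two independent oracles: full enumeration of
all affine-gap alignments on tiny strings, and a plain top-down memoized DP
on windows up to 30 bases.
"""

import functools
import itertools

import numpy as np
import pytest

from matriloop.align import (
    AlignmentIdentityError,
    AlignmentScoring,
    align_segment,
    align_to_window,
)
from matriloop.reference import (
    D_LOOP_LENGTH,
    GAP_REGION,
    HVR1_AMPLICON,
    HVR2_AMPLICON,
    load_reference,
)
from matriloop.seqproc import concatenate_dloop, split_dloop, validate_sequence
from matriloop.sequences import AmpliconSegment, DloopSequence
from matriloop.io import read_fasta, write_fasta

SC = AlignmentScoring()


def oracle_score_memo(query: str, ref: str, sc: AlignmentScoring = SC) -> float:
    """Independent top-down affine-gap DP (global, no free end gaps)."""

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else float("-inf")
        options = []
        if state == "M" and i > 0 and j > 0:
            s = sc.match if query[i - 1] == ref[j - 1] else sc.mismatch
            options = [best(i - 1, j - 1, p) + s for p in "MXY"]
        elif state == "X" and i > 0:  # query base unaligned (insertion)
            options = [
                best(i - 1, j, "M") + sc.gap_open,
                best(i - 1, j, "X") + sc.gap_extend,
            ]
        elif state == "Y" and j > 0:  # reference base unaligned (deletion)
            options = [
                best(i, j - 1, "M") + sc.gap_open,
                best(i, j - 1, "Y") + sc.gap_extend,
            ]
        return max(options, default=float("-inf"))

    return max(best(len(query), len(ref), s) for s in "MXY")


def oracle_score_enumerate(query: str, ref: str, sc: AlignmentScoring = SC) -> float:
    """Exhaustive enumeration of alignment paths (tiny inputs only)."""
    best = [float("-inf")]

    def walk(i, j, state, score):
        if i == len(query) and j == len(ref):
            best[0] = max(best[0], score)
            return
        if i < len(query) and j < len(ref):
            s = sc.match if query[i] == ref[j] else sc.mismatch
            walk(i + 1, j + 1, "M", score + s)
        if i < len(query) and state != "Y":
            gap = sc.gap_extend if state == "X" else sc.gap_open
            walk(i + 1, j, "X", score + gap)
        if j < len(ref) and state != "X":
            gap = sc.gap_extend if state == "Y" else sc.gap_open
            walk(i, j + 1, "Y", score + gap)

    walk(0, 0, "M", 0.0)
    return best[0]


@pytest.fixture(scope="module")
def reference():
    return load_reference()


class TestAlignmentScores:
    def test_identity_alignment_is_identity_mapping(self, reference):
        window = reference.window(*HVR2_AMPLICON)
        cols, ins, score, identity, n_mm = align_to_window(
            window, window, HVR2_AMPLICON[0]
        )
        assert cols == window
        assert ins == ()
        assert n_mm == 0
        assert identity == 1.0
        assert score == pytest.approx(len(window))

    def test_enumeration_oracle_on_tiny_strings(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 7))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            query = "".join(rng.choice(list("ACGT"), size=m))
            _, _, score, _, _ = align_to_window(
                query, ref, 15440, free_end_gaps=False
            )
            assert score == pytest.approx(oracle_score_enumerate(query, ref))

    def test_dp_oracle_on_30_base_windows(self, reference):
        rng = np.random.default_rng(23)
        window = reference.window(15500, 15529)  # 30 bases
        for _ in range(30):
            arr = list(window)
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(len(arr)))
                arr[i] = str(rng.choice(list("ACGT")))
            if rng.random() < 0.4:  # single-base indel
                i = int(rng.integers(1, len(arr)))
                if rng.random() < 0.5:
                    arr.insert(i, str(rng.choice(list("ACGT"))))
                else:
                    del arr[i]
            query = "".join(arr)
            _, _, score, _, _ = align_to_window(
                query, window, 15500, free_end_gaps=False
            )
            assert score == pytest.approx(oracle_score_memo(query, window))

    def test_recovers_planted_substitutions(self, reference):
        rng = np.random.default_rng(31)
        start, end = HVR2_AMPLICON
        window = reference.window(start, end)
        for _ in range(50):
            pos = int(rng.integers(len(window)))
            old = window[pos]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            query = window[:pos] + new + window[pos + 1 :]
            cols, ins, _, _, n_mm = align_to_window(query, window, start)
            assert ins == ()
            assert n_mm == 1
            assert cols == query
            assert cols[pos] == new


class TestInsertionDetection:
    def test_m9_like_insertion_reported_after_16371(self, reference):
        # M9 carries C at 16371 (reference T) plus one inserted C; the event
        # must normalise to after-position 16371
        start, end = 16340, 16420
        window = reference.window(start, end)
        i = 16371 - start
        query = window[:i] + "CC" + window[i + 1 :]
        cols, ins, _, _, n_mm = align_to_window(query, window, start)
        assert ins == ((16371, "C"),)
        assert cols[i] == "C"
        assert n_mm == 1

    def test_insertion_in_homopolymer_is_right_normalised(self):
        ref = "ATGGGC"
        query = "ATGGGGC"
        cols, ins, _, _, _ = align_to_window(query, ref, 16000, free_end_gaps=False)
        assert cols == ref
        assert ins == ((16004, "G"),)  # after the last reference G


class TestAlignSegment:
    def test_reference_identical_segment(self, reference):
        seg = AmpliconSegment("s1", "HVR1", reference.window(*HVR1_AMPLICON))
        aligned = align_segment(seg, reference)
        assert aligned.n_mismatch == 0
        assert aligned.insertions == ()

    def test_identity_floor_rejects_contaminant(self, reference):
        rng = np.random.default_rng(5)
        bases = "".join(rng.choice(list("ACGT"), size=266))
        seg = AmpliconSegment("numt", "HVR2", bases)
        with pytest.raises(AlignmentIdentityError):
            align_segment(seg, reference)


class TestConcatenate:
    def test_gap_block_length_is_268(self, reference):
        h1 = align_segment(
            AmpliconSegment("s", "HVR1", reference.window(*HVR1_AMPLICON)), reference
        )
        h2 = align_segment(
            AmpliconSegment("s", "HVR2", reference.window(*HVR2_AMPLICON)), reference
        )
        seq = concatenate_dloop(h1, h2)
        assert len(seq.aligned) == D_LOOP_LENGTH
        gap = seq.slice(*GAP_REGION)
        assert gap == "-" * 268
        # outside the gap the record equals the reference
        assert seq.slice(*HVR1_AMPLICON) == reference.window(*HVR1_AMPLICON)
        assert seq.slice(*HVR2_AMPLICON) == reference.window(*HVR2_AMPLICON)

    def test_mismatched_segments_rejected(self, reference):
        h1 = align_segment(
            AmpliconSegment("s", "HVR1", reference.window(*HVR1_AMPLICON)), reference
        )
        with pytest.raises(ValueError, match="HVR2"):
            concatenate_dloop(h1, h1)

    def test_fasta_round_trip_and_split(self, reference, tmp_path):
        h1 = align_segment(
            AmpliconSegment("s", "HVR1", reference.window(*HVR1_AMPLICON)), reference
        )
        h2 = align_segment(
            AmpliconSegment("s", "HVR2", reference.window(*HVR2_AMPLICON)), reference
        )
        seq = concatenate_dloop(h1, h2)
        path = tmp_path / "roundtrip.fasta"
        write_fasta([seq], path)
        again = read_fasta(path)[0]
        assert again == seq
        assert split_dloop(again) == (h1.columns, h2.columns)


class TestValidateSequence:
    def test_fixture_sequences_pass(self, fixture_data):
        report = validate_sequence(fixture_data.sequences[0])
        assert report.passed
        assert report.n_ambiguous == 0

    def test_long_n_run_fails_default_threshold(self, fixture_data):
        seq = fixture_data.sequences[0]
        cols = list(seq.aligned)
        cols[10:40] = "N" * 30
        bad = DloopSequence("noisy", "".join(cols))
        report = validate_sequence(bad)
        assert not report.passed
        assert any("ambiguous" in r for r in report.reasons)

    def test_empty_hvr2_fails_with_missing_region(self, fixture_data):
        seq = fixture_data.sequences[0]
        cols = list(seq.aligned)
        start, end = HVR2_AMPLICON
        cols[start - 15440 : end - 15440 + 1] = "-" * (end - start + 1)
        report = validate_sequence(DloopSequence("gone", "".join(cols)))
        assert not report.passed
        assert "missing region: HVR2" in report.reasons
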