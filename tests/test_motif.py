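"""Unit and property tests for the compositional window test and scanner."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paskscan.motif import (
    MotifConfig,
    ProteinSequence,
    QualifyingWindow,
    has_motif,
    merge_windows,
    min_composition_count,
    scan_sequence,
    window_qualifies,
)

from conftest import naive_scan, random_protein


class TestMinCompositionCount:
    @pytest.mark.parametrize(
        "threshold,window,expected",
        [
            (0.75, 20, 15),
            (1.0, 20, 20),
            (0.60, 20, 12),
            (0.50, 20, 10),
            ("75%", 20, 15),
            (Fraction(3, 4), 20, 15),
        ],
    )
    def test_known_values(self, threshold, window, expected):
        assert min_composition_count(threshold, window) == expected

    @pytest.mark.parametrize("window", [1, 7, 20, 33])
    def test_matches_smallest_integer_loop(self, window):
        # oracle: scan candidate integers for the smallest c >= f*W
        for num in range(1, 101):
            frac = Fraction(num, 100)
            expected = next(
                c for c in range(window + 1) if c >= frac * window
            )
            assert min_composition_count(frac, window) == expected

    @pytest.mark.parametrize("bad", [0, -0.1, 1.1, 2])
    def test_out_of_range_threshold(self, bad):
        with pytest.raises(ValueError):
            min_composition_count(bad, 20)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            min_composition_count(0.75, 0)

    def test_no_float_boundary_artifacts(self):
        # 0.6 * 20 must be treated as exactly 12, despite float representation
        assert min_composition_count(0.6, 20) == 12
        assert min_composition_count(0.7, 10) == 7


class TestWindowQualifies:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("DDDDDEEEEESSSSSKKKKK", True),   # all counted, K present
            ("DDDDDEEEEESSSSSAAAAA", False),  # 15/20 counted but no K
            ("AAAAADDDDDEEEEESSSSK", True),   # exactly 15 counted incl. one K
            ("AAAAAADDDDEEEEESSSSK", False),  # 14 counted
            ("K" * 20, True),
        ],
    )
    def test_default_config(self, window, expected, default_config):
        assert window_qualifies(window, default_config) == expected
        # cross-check against an explicit per-character tally
        counted = sum(1 for aa in window if aa in "DESK")
        tally_ok = counted >= 15 and window.count("K") >= 1
        assert tally_ok == expected

    def test_wrong_length_rejected(self, default_config):
        with pytest.raises(ValueError, match="19"):
            window_qualifies("K" * 19, default_config)

    def test_required_residue_count_above_one(self):
        cfg = MotifConfig(required_residues={"K": 3})
        assert window_qualifies("K" * 2 + "D" * 18, cfg) is False
        assert window_qualifies("K" * 3 + "D" * 17, cfg) is True

    def test_ambiguous_residues_never_counted(self, default_config):
        # X in place of a needed D/E/S/K drops the window below threshold
        assert window_qualifies("X" * 6 + "D" * 13 + "K", default_config) is False


class TestMotifConfig:
    def test_required_must_be_counted(self):
        with pytest.raises(ValueError, match="required residue"):
            MotifConfig(required_residues={"R": 1})

    def test_required_count_positive(self):
        with pytest.raises(ValueError):
            MotifConfig(required_residues={"K": 0})

    def test_threshold_normalized_to_exact_rational(self):
        assert MotifConfig(fraction_threshold=0.6).fraction_threshold == Fraction(3, 5)

    def test_with_threshold_keeps_other_fields(self):
        cfg = MotifConfig(window_length=10).with_threshold(0.5)
        assert cfg.window_length == 10
        assert cfg.fraction_threshold == Fraction(1, 2)


class TestProteinSequence:
    def test_trailing_stop_stripped(self):
        p = ProteinSequence.from_raw("p1", "mkkl*")
        assert p.residues == "MKKL"

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ProteinSequence.from_raw("p1", "MK*KL")

    def test_whitespace_and_case_normalized(self):
        p = ProteinSequence.from_raw("p1", "mk\nkl ")
        assert p.residues == "MKKL"

    def test_empty_identifier_rejected(self):
        with pytest.raises(ValueError):
            ProteinSequence(identifier="", residues="MK")


class TestScanSequence:
    def test_shorter_than_window_is_empty(self, default_config):
        p = ProteinSequence("short", "D" * 19)
        assert scan_sequence(p, default_config) == []
        assert scan_sequence(ProteinSequence("e", ""), default_config) == []

    def test_single_full_window_hit(self, default_config):
        p = ProteinSequence("k20", "K" * 20)
        wins = scan_sequence(p, default_config)
        assert [(w.start, w.end) for w in wins] == [(1, 20)]
        assert wins[0].counted_count == 20
        assert wins[0].required_counts == {"K": 20}

    def test_matches_naive_oracle_on_block_sequence(self, default_config):
        p = ProteinSequence("block", "A" * 10 + "DESK" * 5 + "A" * 10)
        got = [(w.start, w.end) for w in scan_sequence(p, default_config)]
        assert got == naive_scan(p, default_config)
        assert got  # the DESK block must produce at least one window

    def test_matches_naive_oracle_on_random_sequences(self, default_config, rng):
        for _ in range(300):
            p = random_protein(rng, rng.randrange(0, 201))
            got = [(w.start, w.end) for w in scan_sequence(p, default_config)]
            assert got == naive_scan(p, default_config)

    @given(
        seq=st.text(alphabet="ADEKSKLG", min_size=0, max_size=120),
        threshold=st.sampled_from([Fraction(1, 2), Fraction(3, 5), Fraction(3, 4)]),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_incremental_equals_naive(self, seq, threshold):
        cfg = MotifConfig(fraction_threshold=threshold)
        p = ProteinSequence("h", seq or "A")
        got = [(w.start, w.end) for w in scan_sequence(p, cfg)]
        assert got == naive_scan(p, cfg)

    @given(seq=st.text(alphabet="ADEKS", min_size=20, max_size=80))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_threshold_monotonicity(self, seq):
        p = ProteinSequence("h", seq)
        hits = {
            t: {(w.start, w.end) for w in scan_sequence(p, MotifConfig(fraction_threshold=t))}
            for t in (Fraction(1, 2), Fraction(3, 5), Fraction(3, 4))
        }
        assert hits[Fraction(3, 4)] <= hits[Fraction(3, 5)] <= hits[Fraction(1, 2)]

    def test_translation_invariance(self, default_config, rng):
        for _ in range(25):
            p = random_protein(rng, 80)
            base = [(w.start, w.end) for w in scan_sequence(p, default_config)]
            for k in (1, 7):
                shifted = ProteinSequence("s", "A" * k + p.residues)
                got = [(w.start, w.end) for w in scan_sequence(shifted, default_config)]
                assert got == [(s + k, e + k) for s, e in base]

    def test_k_to_r_eliminates_every_motif(self, default_config, rng):
        for _ in range(50):
            p = random_protein(rng, 120, alphabet="DESKAL")
            mutated = ProteinSequence("m", p.residues.replace("K", "R"))
            assert has_motif(mutated, default_config) is False


class TestMergeWindows:
    def test_empty(self):
        assert merge_windows([]) == []

    def test_overlap_merges(self):
        wins = [QualifyingWindow(1, 20, 15), QualifyingWindow(2, 21, 15)]
        regions = merge_windows(wins)
        assert [(r.start, r.end, r.window_support) for r in regions] == [(1, 21, 2)]

    def test_abutting_merges(self):
        wins = [QualifyingWindow(1, 20, 15), QualifyingWindow(21, 40, 15)]
        assert [(r.start, r.end) for r in merge_windows(wins)] == [(1, 40)]

    def test_disjoint_preserved(self):
        wins = [QualifyingWindow(1, 20, 15), QualifyingWindow(30, 49, 15)]
        regions = merge_windows(wins)
        assert [(r.start, r.end) for r in regions] == [(1, 20), (30, 49)]

    def test_unsorted_rejected(self):
        wins = [QualifyingWindow(30, 49, 15), QualifyingWindow(1, 20, 15)]
        with pytest.raises(ValueError, match="sorted"):
            merge_windows(wins)

    def test_merge_soundness_on_random_scans(self, default_config, rng):
        """Every window lies in exactly one region; support totals match."""
        for _ in range(50):
            p = random_protein(rng, 150, alphabet="DESKAL")
            wins = scan_sequence(p, default_config)
            regions = merge_windows(wins)
            assert sum(r.window_support for r in regions) == len(wins)
            for w in wins:
                containing = [
                    r for r in regions if r.start <= w.start and w.end <= r.end
                ]
                assert len(containing) == 1
            # regions disjoint and sorted
            for a, b in zip(regions, regions[1:]):
                assert a.end < b.start - 1 or a.end < b.start


class TestHasMotif:
    def test_trivial_cases(self, default_config):
        assert has_motif(ProteinSequence("k", "K" * 20), default_config)
        assert not has_motif(ProteinSequence("a", "A" * 100), default_config)

    def test_equals_scan_nonempty(self, default_config, rng):
        for _ in range(100):
            p = random_protein(rng, rng.randrange(0, 150), alphabet="DESKALG")
            assert has_motif(p, default_config) == bool(scan_sequence(p, default_config))
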