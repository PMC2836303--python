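import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tileprobe.thermo import (ThermoParams, adjust_length_to_median, median_tm,
                              shorten_for_cycles, synthesis_cycles, tm)

P = ThermoParams()


class TestSynthesisCycles:
    def test_first_flow_couples(self):
        assert synthesis_cycles("A", "ACGT", "5to3") == 1
        assert synthesis_cycles("A", "ACGT", "3to5") == 1

    def test_sequence_matching_flow_order_uses_one_flow_per_base(self):
        # 3'->5' deposition of TGCA is A,C,G,T: each couples immediately
        assert synthesis_cycles("TGCA", "ACGT", "3to5") == 4

    def test_repeated_base_waits_a_full_cycle(self):
        assert synthesis_cycles("AA", "ACGT", "5to3") == 5

    def test_empty_sequence(self):
        assert synthesis_cycles("") == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_cycles_at_least_length(self, seq):
        c = synthesis_cycles(seq)
        assert c >= len(seq)
        # equality iff each deposited base directly follows the previous one
        deposit = seq[::-1]
        follows = all(
            "ACGT"[("ACGT".index(a) + 1) % 4] == b
            for a, b in zip(deposit, deposit[1:])
        ) and deposit[0] == "A"
        assert (c == len(seq)) == follows


class TestShortenForCycles:
    def test_within_budget_unchanged(self):
        p = ThermoParams(max_cycles=200, min_len=1, max_len=50)
        seq, cycles, rejected = shorten_for_cycles("ACGTACGT", p)
        assert seq == "ACGTACGT" and not rejected

    def test_trims_to_fit(self):
        p = ThermoParams(max_cycles=1, min_len=1, max_len=50,
                         synthesis_direction="5to3")
        seq, cycles, rejected = shorten_for_cycles("AC", p)
        assert seq == "A" and cycles == 1 and not rejected

    def test_infeasible_budget_flags_rejection(self):
        p = ThermoParams(max_cycles=0, min_len=1, max_len=50)
        _, _, rejected = shorten_for_cycles("ACGT", p)
        assert rejected


class TestTm:
    def test_short_branch_spot_check(self):
        seq = "G" * 25 + "A" * 25  # N=50, 25 GC
        assert tm(seq, P) == pytest.approx(81.5 + 20.5 - 13.5)

    def test_long_branch_spot_check(self):
        seq = "G" * 27 + "A" * 27  # N=54, 27 GC
        assert tm(seq, P) == pytest.approx(81.5 + 20.5 - 675 / 54)

    def test_formamide_only_affects_long_probes(self):
        p10 = ThermoParams(formamide_pct=10.0)
        long_seq = "G" * 27 + "A" * 27
        short_seq = "G" * 25 + "A" * 25
        assert tm(long_seq, P) - tm(long_seq, p10) == pytest.approx(6.5)
        assert tm(short_seq, P) == tm(short_seq, p10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            tm("ACGTACG", P)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(8, 60), st.data())
    def test_monotone_in_gc_and_salt(self, n, data):
        gc = data.draw(st.integers(0, n - 1))
        seq_lo = "G" * gc + "A" * (n - gc)
        seq_hi = "G" * (gc + 1) + "A" * (n - gc - 1)
        assert tm(seq_hi, P) > tm(seq_lo, P)
        saltier = ThermoParams(na_molar=2.0)
        assert tm(seq_lo, saltier) > tm(seq_lo, P)


class TestMedianAndAdjustment:
    def test_median_examples(self):
        assert median_tm([80.0]) == 80.0
        assert median_tm([70.0, 80.0, 90.0]) == 80.0
        assert median_tm([70.0, 80.0]) == 75.0

    def test_probe_at_median_unchanged(self):
        seq = "G" * 25 + "A" * 25
        out, t, dev = adjust_length_to_median(seq, tm(seq, P), P)
        assert out == seq and dev == 0.0

    def test_no_truncation_when_min_equals_max(self):
        p = ThermoParams(min_len=50, max_len=50)
        seq = "G" * 25 + "A" * 25
        out, _, _ = adjust_length_to_median(seq, 10.0, p)
        assert out == seq

    def test_homopolymer_truncates_to_median_length(self):
        # scan oracle over lengths 45..50 picks the 47-mer exactly
        target = tm("G" * 47, P)
        out, t, dev = adjust_length_to_median("G" * 50, target, P)
        assert out == "G" * 47 and dev == 0.0

    def test_never_worse_than_full_length(self):
        seq = "GCGTACGTAGCATCGGATCCGATTACGGCATCGATTGCAACGGTACGATC"
        median = 85.0
        _, _, dev = adjust_length_to_median(seq, median, P)
        assert dev <= abs(tm(seq, P) - median)
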