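import pytest

from tileprobe.enumeration import ProbeCandidate
from tileprobe.genome import CIRCULAR, LINEAR, GenomeMolecule, GenomicPosition
from tileprobe.selection import (DesignPlan, SelectionState,
                                 default_min_distance, gap_fill,
                                 plan_window_size, rank_in_gap,
                                 rank_in_window, run_sequential,
                                 select_sequential)


def make_cand(seq, positions, level=1, tm_dev=0.0, mfe=0.0, is_pct=0.0, pi=0.0):
    return ProbeCandidate(
        sequence=seq,
        positions=[GenomicPosition(m, s, st) for m, s, st in positions],
        offsets=[], xhyb_level=level, tm_dev=tm_dev, mfe=mfe,
        is_pct=is_pct, pi=pi,
    )


class TestPlan:
    def test_window_size_from_published_designs(self):
        assert plan_window_size(2_340_000, 385_000).window_size == 12
        assert plan_window_size(13_000_000, 1_620_000).window_size == 16
        assert plan_window_size(1_000, 2_000).window_size == 1

    def test_oversubscribed_array_is_an_error(self):
        with pytest.raises(ValueError):
            plan_window_size(1_000, 2_001)

    @pytest.mark.parametrize("ws,md", [(12, 3), (16, 4), (5, 2), (4, 1)])
    def test_default_min_distance(self, ws, md):
        assert default_min_distance(ws) == md

    def test_user_overrides_pass_through(self):
        plan = plan_window_size(1000, 100, user_ws=30, user_min_distance=7)
        assert plan.window_size == 30 and plan.min_distance == 7


class TestComparators:
    def test_level_gating_beats_every_other_key(self):
        good = make_cand("g", [("m", 50, "+")], level=1, tm_dev=9.9)
        others = [
            make_cand(f"b{i}", [("m", 10 + i, "+")], level=4, tm_dev=0.0)
            for i in range(10)
        ]
        items = [(c, c.positions[0].start) for c in others + [good]]
        assert rank_in_window(items) is good

    def test_tm_deviation_breaks_level_ties(self):
        a = make_cand("a", [("m", 10, "+")], tm_dev=0.2)
        b = make_cand("b", [("m", 5, "+")], tm_dev=0.5)
        assert rank_in_window([(a, 10), (b, 5)]) is a

    def test_full_tie_selects_first_encountered(self):
        a = make_cand("a", [("m", 4, "+")])
        b = make_cand("b", [("m", 9, "+")])
        assert rank_in_window([(b, 9), (a, 4)]) is a

    def test_less_negative_mfe_preferred(self):
        a = make_cand("a", [("m", 5, "+")], mfe=-1.0)
        b = make_cand("b", [("m", 6, "+")], mfe=-8.0)
        assert rank_in_window([(a, 5), (b, 6)]) is a

    def test_gap_comparator_shares_window_semantics(self):
        a = make_cand("a", [("m", 5, "+")], tm_dev=0.1)
        b = make_cand("b", [("m", 6, "+")], tm_dev=0.9)
        assert rank_in_gap([(a, 5), (b, 6)]) is a

    def test_empty_window_yields_none(self):
        assert rank_in_window([]) is None


def uniform_state(L=1200, strands=("+", "-")):
    mol = GenomeMolecule("m", "A" * L, LINEAR)
    cands = [
        make_cand(f"c{st}{s}", [("m", s, st)])
        for st in strands
        for s in range(1, L + 1)
    ]
    return SelectionState(cands, [mol]), mol


class TestSequential:
    def test_uniform_genome_one_probe_per_window(self):
        state, mol = uniform_state()
        plan = DesignPlan(gs=1200, ms=240, window_size=12, min_distance=3)
        n = select_sequential(state, plan)
        assert n == 200  # 100 windows per strand
        for strand in ("+", "-"):
            occ = state.occupied[("m", strand)]
            assert len(occ) == 100
            spacings = [b - a for a, b in zip(occ, occ[1:])]
            assert all(3 <= d <= 2 * 12 - 1 for d in spacings)

    def test_repeat_occupancy_skips_windows(self):
        # one candidate occurring in three tandem windows: later windows skip
        mol = GenomeMolecule("m", "A" * 60, LINEAR)
        rep = make_cand("rep", [("m", 1, "+"), ("m", 21, "+"), ("m", 41, "+")])
        others = [make_cand(f"u{s}", [("m", s, "+")]) for s in (25, 45)]
        state = SelectionState([rep] + others, [mol])
        plan = DesignPlan(gs=60, ms=10, window_size=20, min_distance=5)
        n = select_sequential(state, plan)
        assert n == 1 and state.candidates[state.selected[0]] is rep
        assert state.occupied[("m", "+")] == [1, 21, 41]

    def test_min_distance_excludes_neighbors_globally(self):
        mol = GenomeMolecule("m", "A" * 20, LINEAR)
        first = make_cand("a", [("m", 10, "+")])
        # next window's only candidate is too close to the selected probe
        near = make_cand("b", [("m", 12, "+")])
        state = SelectionState([first, near], [mol])
        plan = DesignPlan(gs=20, ms=10, window_size=10, min_distance=5)
        assert select_sequential(state, plan) == 1

    def test_window_retry_widens_until_count_fits(self):
        state, _ = uniform_state(L=1000)
        # floor window 2*1000/300 = 6 -> 167 windows/strand = 334 > 300
        plan = run_sequential(state, 1000, 300)
        assert plan.window_size == 7
        assert len(state.selected) <= 300


class TestGapFill:
    def test_first_fill_lands_in_largest_gap(self):
        mol = GenomeMolecule("m", "A" * 120, LINEAR)
        pre = [make_cand("p001", [("m", 1, "+")]), make_cand("p101", [("m", 101, "+")])]
        # equal-length sequences so the comparator ties down to position
        fillers = [make_cand(f"f{s:03d}", [("m", s, "+")]) for s in range(2, 120)]
        state = SelectionState(pre + fillers, [mol])
        state.occupy(0)
        state.occupy(1)
        plan = DesignPlan(gs=120, ms=3, window_size=12, min_distance=3)
        assert gap_fill(state, plan, 3)
        # uniform quality: earliest admissible start in the 100-gap wins
        third = state.candidates[state.selected[-1]]
        assert third.positions[0].start == 4

    def test_noop_when_target_reached(self):
        mol = GenomeMolecule("m", "A" * 50, LINEAR)
        state = SelectionState([make_cand("a", [("m", 10, "+")])], [mol])
        state.occupy(0)
        plan = DesignPlan(gs=50, ms=1, window_size=10, min_distance=2)
        assert gap_fill(state, plan, 1)
        assert len(state.selected) == 1

    def test_exhausted_gaps_report_shortfall(self):
        mol = GenomeMolecule("m", "A" * 30, LINEAR)
        state = SelectionState([make_cand("a", [("m", 10, "+")])], [mol])
        state.occupy(0)
        plan = DesignPlan(gs=30, ms=5, window_size=10, min_distance=3)
        assert not gap_fill(state, plan, 5)

    def test_fill_respects_min_distance_and_is_additive(self):
        state, _ = uniform_state(L=400)
        plan = DesignPlan(gs=400, ms=100, window_size=8, min_distance=2)
        select_sequential(state, plan)
        before = list(state.selected)
        assert gap_fill(state, plan, len(before) + 30)
        assert state.selected[: len(before)] == before  # purely additive
        assert len(state.selected) == len(before) + 30
        for strand in ("+", "-"):
            occ = state.occupied[("m", strand)]
            assert all(b - a >= 2 for a, b in zip(occ, occ[1:]))

    def test_circular_wrap_gap_is_fillable(self):
        mol = GenomeMolecule("m", "A" * 100, CIRCULAR)
        pre = [make_cand("p1", [("m", 40, "+")]), make_cand("p2", [("m", 60, "+")])]
        fillers = [make_cand(f"f{s}", [("m", s, "+")]) for s in range(1, 40)] + [
            make_cand(f"f{s}", [("m", s, "+")]) for s in range(61, 101)
        ]
        state = SelectionState(pre + fillers, [mol])
        state.occupy(0)
        state.occupy(1)
        plan = DesignPlan(gs=100, ms=3, window_size=20, min_distance=5)
        assert gap_fill(state, plan, 3)
        third = state.candidates[state.selected[-1]]
        s = third.positions[0].start
        # the wrap gap (60 -> 140) is the largest; the fill lands inside it
        assert s >= 65 or s <= 35
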