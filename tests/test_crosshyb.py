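import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tileprobe.crosshyb import (LevelLimits, PseudoIndex, assign_level,
                                exhaustive_hits, search_hits)
from tileprobe.genome import LINEAR, GenomeMolecule, build_pseudomolecule
from tileprobe.synth import RepeatSpec, SynthSpec, generate

LIMITS = LevelLimits()


class TestAssignLevel:
    @pytest.mark.parametrize(
        "pi,is_pct,level",
        [
            (40, 10, 1),    # PI < 50
            (60, 20, 2),    # 50 <= PI < 75, IS < 30
            (80, 35, 3),    # 75 <= PI < 90, 30 <= IS < 40
            (95, 50, 4),    # PI >= 90, IS >= 40
            (80, 10, 3),    # between printed definitions: worse band wins
            (20, 35, 3),    # low PI but a long stretch is still risky
        ],
    )
    def test_printed_and_extended_combinations(self, pi, is_pct, level):
        assert assign_level(pi, is_pct, LIMITS) == level

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0, 100), st.floats(0, 100),
        st.floats(0, 5), st.floats(0, 5),
    )
    def test_monotone_in_both_arguments(self, pi, is_pct, dpi, dis):
        lo = assign_level(pi, is_pct, LIMITS)
        hi = assign_level(min(100, pi + dpi), min(100, is_pct + dis), LIMITS)
        assert hi >= lo

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            LevelLimits(pi_bounds=(75, 50, 90))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSearchHits:
    def test_unique_probe_scores_level_one(self):
        # chance word seeds in random background may fire, but the best
        # alignment stays far below every similarity threshold
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 300)
        mol = GenomeMolecule("m", seq, LINEAR)
        pseudo = build_pseudomolecule([mol], 50)
        probe = seq[:50]
        hits = search_hits(probe, [(0, "+")], pseudo)
        assert hits.pi < 50.0 and hits.is_pct < 30.0
        assert assign_level(hits.pi, hits.is_pct, LIMITS) == 1

    def test_partial_copy_yields_expected_pi_and_is(self):
        # second locus matches 45/50 bases with a longest run of 20
        rng = np.random.default_rng(1)
        probe = _random_seq(rng, 50)
        variant = list(probe)
        for i in (20, 31, 39, 44, 49):  # match runs 20,10,7,4,4 -> 45 of 50
            variant[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[variant[i]]
        seq = probe + _random_seq(rng, 100) + "".join(variant)
        mol = GenomeMolecule("m", seq, LINEAR)
        pseudo = build_pseudomolecule([mol], 50)
        hits = search_hits(probe, [(0, "+")], pseudo)
        assert hits.pi == pytest.approx(90.0)
        assert hits.is_pct == pytest.approx(40.0)

    def test_exact_repeat_copies_are_self(self):
        rng = np.random.default_rng(2)
        probe = _random_seq(rng, 50)
        seq = probe + _random_seq(rng, 80) + probe
        mol = GenomeMolecule("m", seq, LINEAR)
        pseudo = build_pseudomolecule([mol], 50)
        # both loci recorded -> both full-length exact alignments are self
        hits = search_hits(probe, [(0, "+"), (130, "+")], pseudo)
        assert hits.pi == 0.0 and hits.n_hits == 0
        # only one locus recorded -> the other counts as cross-hybridization
        hits = search_hits(probe, [(0, "+")], pseudo)
        assert hits.pi == 100.0

    def test_origin_extension_image_not_counted_as_crosshyb(self):
        # circular genome: the origin region exists twice in the pseudo-
        # molecule; a probe at position 1 must not see its own image
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 400)
        mol = GenomeMolecule("m", seq)
        pseudo = build_pseudomolecule([mol], 50)
        probe = seq[:50]
        hits = search_hits(probe, [(0, "+")], pseudo)
        assert hits.is_pct < 98.0  # the 49-base extension image is excluded

    def test_builtin_matches_exhaustive_oracle(self):
        spec = SynthSpec(
            lengths=[2000], seed=9,
            repeats=[RepeatSpec(120, 2, mutation_rate=0.05)],
        )
        mols, _ = generate(spec)
        pseudo = build_pseudomolecule(mols, 50)
        index = PseudoIndex(pseudo, 7)
        rng = np.random.default_rng(4)
        for _ in range(20):
            s = int(rng.integers(0, 1950))
            probe = pseudo.sequence[s : s + 50]
            a = index.summarize(probe, [(s, "+")])
            b = exhaustive_hits(probe, [(s, "+")], pseudo, 7)
            assert a == b
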