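"""Duplex geometry, ERA design and toehold-exchange feasibility."""

import pytest
from hypothesis import given, settings, strategies as st

from eragate import (
    Alphabet,
    CrRNASpec,
    DesignError,
    ERASpec,
    LayoutError,
    NucleicSequence,
    ToeholdDirection,
    build_duplex_layout,
    design_era,
    design_te_era,
    full_activator,
    mismatch_distance,
    reverse_complement,
)

D5, D3 = ToeholdDirection.FIVE_PRIME, ToeholdDirection.THREE_PRIME


class TestDuplexLayout:
    def test_five_prime_toehold_from_span(self, crrna22):
        era = design_era(crrna22, D5, 7)
        layout = build_duplex_layout(crrna22, era, full_activator(crrna22))
        assert layout.toehold_direction is D5
        assert (layout.toehold_length_f, layout.toehold_length_r,
                layout.bm_length) == (7, 0, 15)

    def test_three_prime_mirror(self, crrna22):
        era = design_era(crrna22, D3, 7)
        layout = build_duplex_layout(crrna22, era, full_activator(crrna22))
        assert layout.toehold_direction is D3
        assert (layout.toehold_length_f, layout.toehold_length_r,
                layout.bm_length) == (7, 0, 15)

    def test_te_layout_from_activator_deletion(self, crrna22):
        # 5-nt 5' forward toehold exchanged for a 5-nt 3' reverse toehold
        era = design_era(crrna22, D5, 5)
        act = full_activator(crrna22, deletion_3p=5)
        layout = build_duplex_layout(crrna22, era, act)
        assert (layout.toehold_length_f, layout.toehold_length_r) == (5, 5)

    def test_ambiguous_era_rejected(self, crrna22):
        # ERA pairing only the middle leaves both ends unpaired
        mid = design_era(crrna22, D5, 4)  # span [5, 22]
        shifted = ERASpec(
            NucleicSequence(mid.sequence.residues[3:], Alphabet.RNA),
            paired_span=(5, 19),
        )
        with pytest.raises(LayoutError, match="ambiguous"):
            build_duplex_layout(crrna22, shifted, full_activator(crrna22))

    def test_undeclared_mismatch_rejected(self, crrna22):
        era = design_era(crrna22, D5, 7, era_mismatches=(9,))
        undeclared = ERASpec(era.sequence, era.paired_span, ())
        with pytest.raises(LayoutError, match="inconsistency"):
            build_duplex_layout(crrna22, undeclared, full_activator(crrna22))

    def test_era_mismatch_distance_reported(self, crrna22):
        era = design_era(crrna22, D5, 7, era_mismatches=(9,))
        layout = build_duplex_layout(crrna22, era, full_activator(crrna22))
        assert layout.era_mismatch_distances == (1,)


class TestDesignEra:
    def test_is_reverse_complement_over_span(self, crrna22):
        era = design_era(crrna22, D5, 7)
        span_seq = NucleicSequence(crrna22.spacer.residues[7:], Alphabet.RNA)
        assert era.sequence.residues == reverse_complement(span_seq).residues

    def test_mismatch_substitutes_single_base(self, crrna22):
        plain = design_era(crrna22, D5, 7)
        mm = design_era(crrna22, D5, 7, era_mismatches=(9,))
        diffs = [i for i, (a, b) in enumerate(zip(plain.sequence.residues,
                                                  mm.sequence.residues))
                 if a != b]
        assert len(diffs) == 1

    def test_full_toehold_is_empty_duplex(self, crrna22):
        with pytest.raises(DesignError, match="empty duplex"):
            design_era(crrna22, D5, 22)

    def test_mismatch_in_toehold_rejected(self, crrna22):
        with pytest.raises(DesignError, match="outside duplex"):
            design_era(crrna22, D5, 7, era_mismatches=(3,))

    @settings(deadline=None, max_examples=60)
    @given(toehold=st.integers(0, 21),
           direction=st.sampled_from([D5, D3]),
           seed=st.integers(0, 10))
    def test_design_build_round_trip(self, toehold, direction, seed):
        """build_duplex_layout inverts design_era across the argument grid."""
        import numpy as np
        rng = np.random.default_rng(seed)
        residues = "".join(rng.choice(list("ACGU"), size=22))
        crrna = CrRNASpec(NucleicSequence(residues, Alphabet.RNA))
        era = design_era(crrna, direction, toehold)
        layout = build_duplex_layout(crrna, era, full_activator(crrna))
        assert layout.toehold_length_f == toehold
        assert layout.bm_length == 22 - toehold
        if toehold > 0:
            assert layout.toehold_direction is direction

    def test_designer_is_deterministic(self, crrna22):
        a = design_era(crrna22, D3, 6, era_mismatches=(5, 9))
        b = design_era(crrna22, D3, 6, era_mismatches=(5, 9))
        assert a.sequence.residues == b.sequence.residues


class TestToeholdExchangeFeasibility:
    def test_22nt_accepts_reverse_up_to_4(self, crrna22):
        era, act = design_te_era(crrna22, D3, 9, 4)
        layout = build_duplex_layout(crrna22, era, act)
        assert (layout.toehold_length_f, layout.toehold_length_r) == (9, 4)

    def test_22nt_rejects_reverse_5(self, crrna22):
        with pytest.raises(DesignError, match="infeasible"):
            design_te_era(crrna22, D3, 9, 5)

    def test_35nt_accepts_19_rejects_20(self, crrna35):
        design_te_era(crrna35, D3, 9, 19)
        with pytest.raises(DesignError, match="infeasible"):
            design_te_era(crrna35, D3, 9, 20)

    def test_smallest_rejected_reverse_is_5_for_22nt(self, crrna22):
        first_rejected = next(
            r for r in range(1, 23)
            if _rejected(crrna22, r)
        )
        assert first_rejected == 5


def _rejected(crrna, r):
    try:
        design_te_era(crrna, D3, 9, r)
        return False
    except DesignError:
        return True


class TestMismatchDistance:
    def test_adjacent_to_five_prime_toehold_is_zero(self, layout_5p):
        assert mismatch_distance(layout_5p(7), 8) == 0

    def test_three_prime_complement_convention(self, layout_3p):
        # same offset within the bm domain maps to the complementary distance
        layout = layout_3p(7)  # bm spans spacer positions 1..15
        assert mismatch_distance(layout, 1) == 14
        assert mismatch_distance(layout, 15) == 0

    def test_direction_mirror_property(self, layout_5p, layout_3p):
        f, bm = 7, 15
        for offset in range(bm):
            d5 = mismatch_distance(layout_5p(f), f + 1 + offset)
            d3 = mismatch_distance(layout_3p(f), 1 + offset)
            assert d3 == bm - 1 - d5

    def test_position_in_toehold_errors(self, layout_5p):
        with pytest.raises(LayoutError, match="toehold"):
            mismatch_distance(layout_5p(7), 4)
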