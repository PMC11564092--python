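"""Mismatch-tolerance rule engine against the mutagenesis outcomes."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cas13bdesign.tolerance import (
    ActivityLabel,
    MismatchPattern,
    ToleranceRules,
    classify_mismatch_pattern,
    classify_truncation,
    default_rules,
    max_tolerated_scattered,
    min_required_pairing,
)

T, P, L = ActivityLabel.TOLERATED, ActivityLabel.PARTIAL_LOSS, ActivityLabel.LOST


def block(start, end):
    return frozenset(range(start, end + 1))


class TestMutagenesisPanels30:
    """Every experimentally tested pattern encoded by the 30-nt table."""

    @pytest.mark.parametrize(
        "positions,expected",
        [
            # 3' end series: 3-nt block tolerated, longer blocks lost
            (block(28, 30), T),
            (block(25, 30), L),
            (block(22, 30), L),
            (block(1, 30), L),
            # 5' end series: every block lost, incl. the 3-nt (G-G-G removal)
            (block(1, 3), L),
            (block(1, 6), L),
            (block(1, 9), L),
            # 6-nt blocks compromised everywhere
            (block(7, 12), L),
            (block(13, 18), L),
            (block(19, 24), L),
            # 5-nt blocks: partial in 6-10, 11-15, 26-30; lost elsewhere
            (block(6, 10), P),
            (block(11, 15), P),
            (block(26, 30), P),
            (block(1, 5), L),
            (block(16, 20), L),
            (block(21, 25), L),
            # 4-nt blocks: partial at 9-12, 13-16, 17-20; lost at the ends
            (block(9, 12), P),
            (block(13, 16), P),
            (block(17, 20), P),
            (block(1, 4), L),
            (block(5, 8), L),
            (block(21, 24), L),
            (block(25, 28), L),
            # 3-nt blocks tolerated away from the 5' end
            (block(5, 7), T),
            (block(14, 16), T),
            (block(26, 28), T),
        ],
    )
    def test_consecutive_blocks(self, positions, expected):
        assert classify_mismatch_pattern(positions).label is expected

    @pytest.mark.parametrize(
        "positions,expected",
        [
            (frozenset(), T),
            (frozenset({4, 10}), T),  # 2 scattered
            (frozenset({4, 10, 18}), T),  # 3 scattered
            (frozenset({4, 10, 18, 26}), T),  # 4 scattered: still tolerated
            (frozenset({4, 9, 14, 19, 24}), L),  # 5 scattered: loss
            (frozenset({4, 8, 12, 16, 20, 24}), L),
            (frozenset({4, 7, 10, 13, 16, 19, 22}), L),
            (frozenset(range(4, 24, 2)), L),  # 10 scattered
            # several 2-3-nt runs spread over the spacer: complete loss
            (frozenset({5, 6, 14, 15, 24, 25}), L),
            (frozenset({6, 7, 8, 20, 21, 22}), L),
        ],
    )
    def test_nonconsecutive_patterns(self, positions, expected):
        assert classify_mismatch_pattern(positions).label is expected

    def test_single_mismatches_tolerated(self):
        for p in (1, 2, 7, 15, 30):
            assert classify_mismatch_pattern({p}).label is T


class TestDerivedQuantities:
    def test_max_tolerated_scattered_is_four(self):
        assert max_tolerated_scattered(30) == 4

    def test_beyond_max_all_scattered_patterns_lost(self, rng):
        # consistency: sampled 5-mismatch scattered patterns never tolerated
        for _ in range(200):
            picks = sorted(rng.choice(range(4, 31), size=5, replace=False))
            label = classify_mismatch_pattern(frozenset(picks)).label
            assert label is not T

    def test_min_required_pairing_is_26(self):
        assert min_required_pairing(30) == 26
        assert min_required_pairing(30) + max_tolerated_scattered(30) == 30

    def test_empty_rule_table_is_an_error(self):
        with pytest.raises(ValueError, match="empty rule table"):
            ToleranceRules(
                spacer_len=30,
                block_rules=(),
                scattered_rules=default_rules(30).scattered_rules,
            )


class TestEngineContracts:
    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_mismatch_pattern({0}, spacer_len=30)
        with pytest.raises(ValueError, match="outside"):
            classify_mismatch_pattern({31}, spacer_len=30)

    @given(st.sets(st.integers(min_value=1, max_value=30), max_size=30))
    def test_totality_over_random_subsets(self, positions):
        activity = classify_mismatch_pattern(frozenset(positions))
        assert activity.label in set(ActivityLabel)
        assert activity.rule_id

    @given(
        st.sets(st.integers(min_value=1, max_value=30), min_size=2, max_size=10),
        st.integers(min_value=1, max_value=30),
    )
    def test_scattered_anti_monotonicity(self, positions, extra):
        """Adding a mismatch to a lost scattered pattern never rescues it."""
        pattern = MismatchPattern(frozenset(positions))
        if len(pattern.runs) < 2:
            return
        if classify_mismatch_pattern(pattern).label is not L:
            return
        grown = frozenset(positions | {extra})
        assert classify_mismatch_pattern(grown).label is not T

    def test_rule_table_roundtrips_through_yaml(self, tmp_path):
        rules = default_rules(30)
        path = tmp_path / "rules.yaml"
        rules.to_yaml(path)
        assert ToleranceRules.from_yaml(path) == rules

    def test_pattern_with_mismatched_rule_table_rejected(self):
        with pytest.raises(ValueError, match="rule table"):
            classify_mismatch_pattern({5}, spacer_len=27, rules=default_rules(30))


class TestTruncatedSpacerRules:
    """The 27-nt table is strictly harsher than the 30-nt one."""

    @pytest.mark.parametrize(
        "positions,expected",
        [
            (block(1, 3), L),  # G-G-G to C-C-C
            (block(22, 24), L),
            (block(4, 6), P),
            (block(7, 9), P),
            (block(10, 12), P),
            (block(13, 15), T),
            (block(16, 18), T),
            (block(19, 21), T),
            (frozenset({7}), T),
            (frozenset({14}), T),
            (frozenset({21}), P),
            (frozenset({5, 12}), L),  # any scattered pair loses activity
            (frozenset({6, 13, 20}), L),
        ],
    )
    def test_panel_outcomes(self, positions, expected):
        got = classify_mismatch_pattern(positions, spacer_len=27)
        assert got.label is expected

    def test_scattered_tolerance_collapses_to_one(self):
        assert max_tolerated_scattered(27) == 1


class TestTruncation:
    @pytest.mark.parametrize(
        "end,n,expected",
        [
            ("3prime", 0, T),
            ("3prime", 3, T),
            ("3prime", 6, P),
            ("3prime", 15, P),
            ("5prime", 0, T),
            ("5prime", 2, T),
            ("5prime", 3, L),
            ("5prime", 9, L),
        ],
    )
    def test_end_asymmetry(self, end, n, expected):
        assert classify_truncation(end, n).label is expected

    def test_invalid_end_label_rejected(self):
        with pytest.raises(ValueError, match="end"):
            classify_truncation("middle", 3)
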