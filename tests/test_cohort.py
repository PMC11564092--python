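"""Cohort analytics: splitting, PWMs, delta probabilities, PFS, accuracy."""

import numpy as np
import pytest

from cas13bdesign.cohort import (
    EfficiencyRecord,
    delta_probabilities,
    evaluate_predictions,
    pfs_matrices,
    pwm,
    read_efficiency_table,
    split_cohorts,
    write_efficiency_table,
)
from cas13bdesign.scoring import MotifClass

from conftest import random_rna


def _rec(eff, spacer=None):
    return EfficiencyRecord(spacer=spacer or "A" * 30, efficiency=eff)


class TestSplitCohorts:
    def test_strict_thresholds(self):
        records = [_rec(e) for e in (95, 92, 70, 40)]
        potent, ineffective, excluded = split_cohorts(records)
        assert [r.efficiency for r in potent] == [95, 92]
        assert [r.efficiency for r in ineffective] == [40]
        assert [r.efficiency for r in excluded] == [70]

    def test_boundaries_are_excluded(self):
        potent, ineffective, excluded = split_cohorts([_rec(90), _rec(50)])
        assert not potent and not ineffective
        assert [r.efficiency for r in excluded] == [90, 50]

    def test_empty_table_gives_three_empty_cohorts(self):
        assert split_cohorts([]) == ([], [], [])

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        records = [_rec(float(e)) for e in rng.uniform(0, 100, size=300)]
        potent, ineffective, excluded = split_cohorts(records)
        assert len(potent) + len(ineffective) + len(excluded) == len(records)
        ids = [id(r) for part in (potent, ineffective, excluded) for r in part]
        assert len(set(ids)) == len(ids)

    def test_out_of_range_efficiency_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _rec(105)


class TestPwm:
    def test_identical_spacers_give_indicator_columns(self):
        matrix = pwm(["ACGU" * 7 + "AC"] * 5)
        assert set(np.unique(matrix.values)) == {0.0, 1.0}
        assert (matrix.values.sum(axis=0) == 1).all()

    def test_balanced_cohort_is_uniform(self):
        matrix = pwm(["A" * 30, "C" * 30, "G" * 30, "U" * 30])
        assert np.allclose(matrix.values, 0.25)

    def test_matches_hand_counted_frequencies(self, rng):
        spacers = [random_rna(rng, 30) for _ in range(40)]
        matrix = pwm(spacers)
        for i in range(30):
            for b_idx, base in enumerate("ACGU"):
                manual = sum(s[i] == base for s in spacers) / len(spacers)
                assert matrix.values[b_idx, i] == pytest.approx(manual)

    def test_columns_sum_to_one(self, rng):
        matrix = pwm([random_rna(rng, 30) for _ in range(25)])
        assert np.allclose(matrix.values.sum(axis=0), 1.0, atol=1e-9)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            pwm(["A" * 30, "A" * 29])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pwm([])


class TestDeltaProbabilities:
    def test_uniform_cohort_gives_zero_matrix(self):
        delta = delta_probabilities(
            ["A" * 30, "C" * 30, "G" * 30, "U" * 30], baseline="cohort_mean"
        )
        assert np.allclose(delta.values, 0.0)

    def test_all_g_cohort_against_uniform_baseline(self):
        delta = delta_probabilities(["G" * 30] * 3, baseline="uniform")
        assert np.allclose(delta.values[2], 0.75)  # G row
        for row in (0, 1, 3):
            assert np.allclose(delta.values[row], -0.25)

    def test_columns_sum_to_zero(self, rng):
        delta = delta_probabilities([random_rna(rng, 30) for _ in range(30)])
        assert np.allclose(delta.values.sum(axis=0), 0.0, atol=1e-9)

    def test_custom_baseline_must_be_probability_vector(self):
        with pytest.raises(ValueError, match="baseline"):
            delta_probabilities(["A" * 30], baseline=[0.5, 0.5, 0.5, 0.5])

    def test_custom_baseline_applied(self):
        delta = delta_probabilities(["A" * 30], baseline=[1.0, 0.0, 0.0, 0.0])
        assert np.allclose(delta.values, 0.0)


class TestPfsMatrices:
    def test_identical_flanks_give_indicator_matrices(self):
        records = [
            EfficiencyRecord("A" * 30, 95, flank_up="ACGU", flank_down="GGCC")
        ] * 4
        up, down = pfs_matrices(records)
        assert set(np.unique(up.values)) == {0.0, 1.0}
        assert down.values[2, 0] == 1.0  # G at first downstream position

    def test_random_flanks_approach_uniformity(self, rng):
        records = [
            EfficiencyRecord(
                "A" * 30,
                50,
                flank_up=random_rna(rng, 4),
                flank_down=random_rna(rng, 4),
            )
            for _ in range(4000)
        ]
        up, down = pfs_matrices(records)
        # no PFS bias planted, so all entries concentrate near 0.25
        assert np.abs(up.values - 0.25).max() < 0.03
        assert np.abs(down.values - 0.25).max() < 0.03

    def test_n_counts_records_with_flanks(self):
        records = [
            EfficiencyRecord("A" * 30, 95, flank_up="ACGU", flank_down="ACGU"),
            EfficiencyRecord("A" * 30, 95),
        ]
        up, _ = pfs_matrices(records)
        assert up.n == 1

    def test_all_records_missing_flanks_rejected(self):
        with pytest.raises(ValueError, match="flanks"):
            pfs_matrices([EfficiencyRecord("A" * 30, 95)])


class TestEvaluatePredictions:
    def test_perfectly_predictive_table(self):
        records = [
            EfficiencyRecord("GG" + "A" * 28, 95),
            EfficiencyRecord("GG" + "U" * 28, 97),
            EfficiencyRecord("CC" + "A" * 28, 20),
        ]
        summary = evaluate_predictions(records)
        assert summary["potent_precision"] == 1.0
        assert summary["ineffective_precision"] == 1.0

    def test_twenty_of_twentyone_validated(self):
        # arithmetic of a validation table: 21 predicted potent, 20 confirmed
        records = [EfficiencyRecord("GG" + "A" * 28, 95) for _ in range(20)]
        records.append(EfficiencyRecord("GG" + "A" * 28, 60))
        summary = evaluate_predictions(records)
        assert summary["n_predicted_potent"] == 21
        assert summary["potent_precision"] == pytest.approx(20 / 21)

    def test_order_invariance(self, rng):
        records = [
            EfficiencyRecord(random_rna(rng, 30), float(e))
            for e in rng.uniform(0, 100, size=60)
        ]
        base = evaluate_predictions(records)
        permuted = evaluate_predictions(list(reversed(records)))
        for key in ("potent_precision", "ineffective_precision"):
            assert base.get(key) == permuted.get(key)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            evaluate_predictions([])

    def test_confusion_table_totals(self):
        records = [
            EfficiencyRecord("GG" + "A" * 28, 95),
            EfficiencyRecord("CA" + "A" * 28, 30),
        ]
        summary = evaluate_predictions(records)
        assert int(summary["confusion"].to_numpy().sum()) == 2


class TestTableIO:
    def test_roundtrip(self, tmp_path, rng):
        records = [
            EfficiencyRecord(
                random_rna(rng, 30),
                float(e),
                flank_up=random_rna(rng, 4),
                flank_down=random_rna(rng, 4),
            )
            for e in rng.uniform(0, 100, size=10)
        ]
        path = tmp_path / "eff.tsv"
        write_efficiency_table(records, path)
        back = read_efficiency_table(path)
        assert [r.spacer for r in back] == [r.spacer for r in records]
        assert [r.efficiency for r in back] == pytest.approx(
            [r.efficiency for r in records]
        )

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("spacer\nAAAA\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_efficiency_table(path)
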