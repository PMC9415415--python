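"""Confusion-matrix metrics, Cohen's kappa, Altman rating, timeline scoring."""

import datetime as dt
import math

import numpy as np
import pytest

from croptime import (ConfusionMatrix, accuracy_report, altman_rating,
                      confusion, kappa, overall_accuracy, producers_accuracy,
                      timeline_evaluate, users_accuracy)


def cm(counts, classes=None):
    counts = np.asarray(counts)
    if classes is None:
        classes = tuple(f"c{i}" for i in range(len(counts)))
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def brute_force_kappa(counts):
    """Independent elementwise computation of p_o and p_e."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_o = sum(counts[i, i] for i in range(len(counts))) / n
    p_e = sum(counts[i, :].sum() * counts[:, i].sum() for i in range(len(counts))) / n ** 2
    return (p_o - p_e) / (1 - p_e)


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        truth = ["a", "b", "c", "a"]
        out = confusion(truth, truth, vocabulary=["a", "b", "c"])
        assert np.trace(out.counts) == 4 and out.counts.sum() == 4

    def test_single_offdiagonal_cell(self):
        out = confusion(["a"] * 5, ["b"] * 5, vocabulary=["a", "b"])
        assert out.counts[0, 1] == 5 and out.counts.sum() == 5

    def test_cell_sum_conserved(self, rng):
        vocab = ["a", "b", "c"]
        truth = rng.choice(vocab, 50)
        pred = rng.choice(vocab, 50)
        assert confusion(truth, pred, vocab).total == 50

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="length"):
            confusion(["a"], ["a", "b"])
        with pytest.raises(ValueError, match="vocabulary"):
            confusion(["a"], ["z"], vocabulary=["a", "b"])


class TestAccuracyMetrics:
    def test_diagonal_matrix_all_100(self):
        m = cm([[3, 0], [0, 7]])
        assert overall_accuracy(m) == 100.0
        assert all(v == 100.0 for v in producers_accuracy(m).values())
        assert all(v == 100.0 for v in users_accuracy(m).values())

    def test_hand_computed_2x2(self):
        m = cm([[45, 5], [10, 40]])
        assert overall_accuracy(m) == pytest.approx(85.0)
        pa = producers_accuracy(m)
        ua = users_accuracy(m)
        assert pa["c0"] == pytest.approx(90.0) and pa["c1"] == pytest.approx(80.0)
        assert ua["c0"] == pytest.approx(81.8, abs=0.05)
        assert ua["c1"] == pytest.approx(88.9, abs=0.05)

    def test_empty_truth_row_gives_nan_pa(self):
        m = cm([[0, 0], [1, 9]])
        assert math.isnan(producers_accuracy(m)["c0"])

    def test_oa_invariant_under_class_permutation(self, rng):
        counts = rng.integers(0, 20, size=(3, 3))
        counts[np.diag_indices(3)] += 5
        perm = rng.permutation(3)
        assert overall_accuracy(cm(counts)) == pytest.approx(
            overall_accuracy(cm(counts[np.ix_(perm, perm)])))

    def test_oa_is_pa_weighted_by_class_prevalence(self, rng):
        counts = rng.integers(1, 30, size=(4, 4))
        m = cm(counts)
        rows = counts.sum(axis=1)
        weighted = sum((pa / 100) * (rows[i] / counts.sum())
                       for i, pa in enumerate(producers_accuracy(m).values()))
        assert overall_accuracy(m) / 100 == pytest.approx(weighted)


class TestKappa:
    def test_perfect_diagonal_is_one(self):
        assert kappa(cm([[5, 0], [0, 5]])) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        assert kappa(cm([[25, 25], [25, 25]])) == pytest.approx(0.0)

    def test_hand_computed_2x2(self):
        # p_o = 0.85, p_e = 0.50
        assert kappa(cm([[45, 5], [10, 40]])) == pytest.approx(0.70)

    def test_proportional_rows_give_exact_zero(self):
        # rows proportional to column totals: expected agreement achieved
        assert kappa(cm([[10, 30], [10, 30]])) == pytest.approx(0.0, abs=1e-15)

    def test_oracle_agreement_on_random_matrices(self, rng):
        for _ in range(1000):
            counts = rng.integers(0, 50, size=(3, 3))
            if counts.sum() == 0 or (counts > 0).sum() == 1:
                continue  # degenerate single-cell mass
            assert kappa(cm(counts)) == pytest.approx(
                brute_force_kappa(counts), abs=1e-12)

    def test_degenerate_single_cell_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            kappa(cm([[7, 0], [0, 0]]))


class TestAltmanRating:
    @pytest.mark.parametrize("value,label", [
        (0.53, "moderate"), (0.74, "good"), (0.91, "particularly good"),
        (0.10, "poor"), (-0.4, "poor"), (0.20, "poor"), (0.21, "regular"),
        (0.40, "regular"), (0.60, "moderate"), (0.80, "good"), (1.0, "particularly good"),
    ])
    def test_bands(self, value, label):
        assert altman_rating(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            altman_rating(1.2)


class TestTimeline:
    def test_single_date_single_combination_reduces_to_direct_eval(
            self, survey_ds, cycle_b_ds, soil_line):
        from croptime import (PolySVMClassifier, assemble_training_table,
                              descriptor_columns, evaluate)
        cols = descriptor_columns("C4")
        train = assemble_training_table(
            survey_ds.table, survey_ds.calendar, "C4", soil_line,
            analysis_dates=survey_ds.config.analysis_dates)
        model = PolySVMClassifier().fit(train[cols], train["crop_label"])
        date = dt.date(2020, 6, 20)
        tl = timeline_evaluate({"C4": model}, cycle_b_ds.table,
                               cycle_b_ds.calendar, [date], soil_line)
        direct_table = assemble_training_table(
            cycle_b_ds.table, cycle_b_ds.calendar, "C4", soil_line,
            analysis_dates=[date])
        direct = evaluate(model, direct_table, cols)
        assert len(tl) == 1
        assert tl.loc[0, "overall_accuracy"] == pytest.approx(direct.overall_accuracy)
        assert tl.loc[0, "kappa"] == pytest.approx(direct.kappa)

    def test_early_date_offers_only_short_lag_combination(
            self, survey_ds, cycle_b_ds, soil_line):
        """On the first usable 2020 date only the 15-day pair can be formed."""
        from croptime import PolySVMClassifier, assemble_training_table, descriptor_columns
        models = {}
        for comb in ("C1", "C2", "C3", "C4"):
            train = assemble_training_table(
                survey_ds.table, survey_ds.calendar, comb, soil_line,
                analysis_dates=survey_ds.config.analysis_dates)
            models[comb] = PolySVMClassifier().fit(
                train[descriptor_columns(comb)], train["crop_label"])
        tl = timeline_evaluate(models, cycle_b_ds.table, cycle_b_ds.calendar,
                               [dt.date(2020, 5, 6)], soil_line)
        assert list(tl["combination"]) == ["C4"]

    def test_report_carries_rating_and_per_class_columns(self, survey_ds,
                                                         cycle_b_ds, soil_line):
        from croptime import PolySVMClassifier, assemble_training_table, descriptor_columns
        train = assemble_training_table(
            survey_ds.table, survey_ds.calendar, "C2", soil_line,
            analysis_dates=survey_ds.config.analysis_dates)
        model = PolySVMClassifier().fit(train[descriptor_columns("C2")],
                                        train["crop_label"])
        tl = timeline_evaluate({"C2": model}, cycle_b_ds.table,
                               cycle_b_ds.calendar, [dt.date(2020, 6, 5)], soil_line)
        assert {"altman_rating", "PA_corn", "UA_corn", "PA_alfalfa"} <= set(tl.columns)

    def test_accuracy_report_bundle(self):
        rep = accuracy_report(cm([[45, 5], [10, 40]]))
        assert rep.overall_accuracy == pytest.approx(85.0)
        assert rep.kappa == pytest.approx(0.70)
        assert rep.altman_rating == "good"
        assert rep.n == 100
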