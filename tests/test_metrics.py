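"""Confusion-panel, AUC/DeLong, and ICC statistics against naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clungrads.errors import ContractError, DegenerateInputError
from clungrads.metrics import (
    ConfusionMatrix,
    confusion_matrix,
    delong_paired_test,
    icc_absolute_agreement,
    ordinal_auc,
    panel_from_cm,
    pct,
)

from conftest import anova_icc21, brute_auc, naive_delong


class TestConfusionMatrix:
    def test_enumeration_of_all_four_outcomes(self):
        cm = confusion_matrix([True, True, False, False], [True, False, True, False])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_all_correct_positives(self):
        cm = confusion_matrix([True] * 5, [True] * 5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 0, 0, 0)

    def test_counts_match_engineered_outcome_mix(self):
        preds = [True] * 145 + [False] * 24
        labels = [True] * 131 + [False] * 14 + [True] * 7 + [False] * 17
        cm = confusion_matrix(preds, labels)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (131, 14, 7, 17)

    @pytest.mark.parametrize(
        "preds,labels", [([], []), ([True], [True, False])]
    )
    def test_contract_errors(self, preds, labels):
        with pytest.raises(ContractError):
            confusion_matrix(preds, labels)

    def test_negative_cells_rejected(self):
        with pytest.raises(ContractError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=1)


class TestMetricPanel:
    def test_study_training_cells(self):
        """(131, 14, 7, 17) at beta = 0.5: the four internally consistent
        published percentages, plus the exact MCC of 55.2 (not the printed
        60.2, which is inconsistent with its own cells)."""
        panel = panel_from_cm(ConfusionMatrix(131, 14, 7, 17), beta=0.5)
        assert pct(panel.recall) == 94.9
        assert pct(panel.precision) == 90.3
        assert pct(panel.accuracy) == 87.6
        assert pct(panel.f_weighted) == 91.2
        assert pct(panel.mcc) == 55.2

    def test_study_validation_cells(self):
        panel = panel_from_cm(ConfusionMatrix(257, 53, 26, 67), beta=0.5)
        assert pct(panel.recall) == 90.8
        assert pct(panel.f1) == 86.7
        assert pct(panel.mcc) == 50.6
        assert pct(panel.accuracy) == 80.4

    def test_perfect_classifier(self):
        panel = panel_from_cm(ConfusionMatrix(10, 0, 0, 10))
        assert panel.recall == panel.precision == panel.accuracy == 1.0
        assert panel.f1 == panel.f_weighted == 1.0
        assert panel.mcc == 1.0

    def test_degenerate_all_negative_predictions_on_mixed_labels(self):
        panel = panel_from_cm(ConfusionMatrix(0, 0, 5, 5))
        assert panel.recall == 0.0
        assert panel.precision is None  # flagged, not silently 0
        assert panel.mcc == 0.0  # zero-denominator convention
        assert any("precision" in f for f in panel.flags)

    def test_no_positive_labels_flags_recall(self):
        panel = panel_from_cm(ConfusionMatrix(0, 3, 0, 7))
        assert panel.recall is None
        assert any("recall" in f for f in panel.flags)

    @pytest.mark.parametrize("cm", [ConfusionMatrix(37, 11, 5, 23)])
    def test_f_beta_limits(self, cm):
        """F-beta tends to precision as beta -> 0 and to recall as beta -> inf."""
        lo = panel_from_cm(cm, beta=1e-6)
        hi = panel_from_cm(cm, beta=1e6)
        assert lo.f_weighted == pytest.approx(lo.precision, abs=1e-4)
        assert hi.f_weighted == pytest.approx(hi.recall, abs=1e-4)

    @given(
        tp=st.integers(1, 50), fp=st.integers(1, 50),
        fn=st.integers(1, 50), tn=st.integers(1, 50),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mcc_negated_by_prediction_flip(self, tp, fp, fn, tn):
        mcc = panel_from_cm(ConfusionMatrix(tp, fp, fn, tn)).mcc
        flipped = panel_from_cm(ConfusionMatrix(fn, tn, tp, fp)).mcc
        assert -1.0 <= mcc <= 1.0
        assert flipped == pytest.approx(-mcc, abs=1e-12)

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    @settings(max_examples=100, derandomize=True)
    def test_fractions_stay_in_unit_interval(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        panel = panel_from_cm(ConfusionMatrix(tp, fp, fn, tn))
        for v in (panel.recall, panel.precision, panel.accuracy,
                  panel.f1, panel.f_weighted):
            assert v is None or 0.0 <= v <= 1.0
        assert -1.0 <= panel.mcc <= 1.0

    def test_panel_from_raw_outcomes_equals_panel_from_summed_cells(self, rng):
        preds = rng.random(400) < 0.4
        labels = rng.random(400) < 0.6
        cm = confusion_matrix(preds, labels)
        by_hand = ConfusionMatrix(
            int(np.sum(preds & labels)), int(np.sum(preds & ~labels)),
            int(np.sum(~preds & labels)), int(np.sum(~preds & ~labels)),
        )
        assert panel_from_cm(cm) == panel_from_cm(by_hand)


class TestOrdinalAuc:
    def test_perfect_separation(self):
        assert ordinal_auc([1, 2, 3, 4], [False, False, True, True]).auc == 1.0

    def test_complete_ties(self):
        assert ordinal_auc([2, 2, 2, 2], [True, False, True, False]).auc == 0.5

    def test_small_tied_example_against_pair_count(self):
        # positives at ranks {2, 3, 1}, negatives at {1, 2}: 4 of 6 pair-credits
        res = ordinal_auc([1, 2, 2, 3, 1], [False, True, False, True, True])
        assert res.auc == pytest.approx(4 / 6)

    def test_single_class_labels_raise(self):
        with pytest.raises(DegenerateInputError):
            ordinal_auc([1, 2, 3], [True, True, True])

    def test_ci_brackets_estimate_within_unit_interval(self, rng):
        scores = rng.integers(1, 6, size=80)
        labels = rng.random(80) < 0.5
        res = ordinal_auc(scores, labels)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 200))
            scores = rng.integers(1, 6, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert ordinal_auc(scores, labels).auc == pytest.approx(
                brute_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = rng.integers(1, 6, size=100).astype(float)
            labels = rng.random(100) < 0.4
            if labels.all() or not labels.any():
                continue
            assert ordinal_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        scores = rng.integers(1, 6, size=120).astype(float)
        labels = rng.random(120) < 0.5
        base = ordinal_auc(scores, labels).auc
        for f in (lambda x: 3 * x + 7, np.exp, lambda x: x**3):
            assert ordinal_auc(f(scores), labels).auc == pytest.approx(base, abs=1e-12)

    def test_binary_score_auc_is_mean_of_sensitivity_and_specificity(self, rng):
        preds = rng.random(300) < 0.3
        labels = rng.random(300) < 0.6
        cm = confusion_matrix(preds, labels)
        sens = cm.tp / (cm.tp + cm.fn)
        spec = cm.tn / (cm.tn + cm.fp)
        auc = ordinal_auc(preds.astype(float), labels).auc
        assert auc == pytest.approx((sens + spec) / 2, abs=1e-12)


class TestDeLong:
    def test_self_comparison_has_p_one(self, rng):
        scores = rng.integers(1, 6, size=60).astype(float)
        labels = rng.random(60) < 0.5
        res = delong_paired_test(scores, scores, labels)
        assert res.difference == 0.0
        assert res.p_two_sided == 1.0

    def test_extreme_separation_difference_is_one(self):
        labels = [True, True, True, False, False, False]
        res = delong_paired_test([2, 2, 2, 1, 1, 1], [1, 1, 1, 2, 2, 2], labels)
        assert res.auc_a == 1.0 and res.auc_b == 0.0
        assert res.difference == 1.0

    def test_matches_naive_double_loop_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 100))
            labels = np.zeros(n, dtype=bool)
            labels[: max(2, n // 3)] = True
            rng.shuffle(labels)
            a = rng.integers(1, 6, size=n).astype(float)
            b = rng.integers(1, 6, size=n).astype(float)
            res = delong_paired_test(a, b, labels)
            auc_a, auc_b, var = naive_delong(a, b, labels)
            assert res.auc_a == pytest.approx(auc_a, abs=1e-10)
            assert res.auc_b == pytest.approx(auc_b, abs=1e-10)
            assert res.variance_diff == pytest.approx(var, abs=1e-10)

    def test_ten_subject_paired_example_z_and_p(self):
        labels = [True] * 5 + [False] * 5
        a = [5, 4, 5, 3, 4, 2, 1, 3, 2, 1]
        b = [5, 1, 2, 3, 4, 5, 1, 2, 3, 4]
        res = delong_paired_test(a, b, labels)
        auc_a, auc_b, var = naive_delong(a, b, labels)
        z = (auc_a - auc_b) / np.sqrt(var)
        from scipy.stats import norm

        assert res.z == pytest.approx(z, abs=1e-10)
        assert res.p_two_sided == pytest.approx(2 * norm.sf(abs(z)), abs=1e-10)

    def test_length_mismatch_and_single_class_raise(self):
        with pytest.raises(ContractError):
            delong_paired_test([1, 2], [1, 2, 3], [True, False])
        with pytest.raises(DegenerateInputError):
            delong_paired_test([1, 2], [2, 1], [True, True])


class TestICC:
    def test_perfect_agreement_is_one(self):
        ratings = np.tile(np.arange(1, 11)[:, None], (1, 3))
        assert icc_absolute_agreement(ratings) == pytest.approx(1.0)

    def test_all_identical_cells_returns_one_by_convention(self):
        assert icc_absolute_agreement(np.full((5, 3), 2.0)) == 1.0

    def test_matches_anova_oracle_on_integer_matrix(self):
        ratings = np.array([[1, 2, 1], [3, 3, 4], [5, 5, 5], [2, 1, 2]])
        assert icc_absolute_agreement(ratings) == pytest.approx(
            anova_icc21(ratings), abs=1e-10
        )

    def test_matches_pingouin_icc2(self, rng):
        import pandas as pd
        import pingouin as pg

        ratings = rng.integers(1, 6, size=(12, 3)).astype(float)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": ratings.ravel(),
            }
        )
        # single-rater absolute agreement: labelled ICC2 or ICC(A,1)
        table = pg.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
        icc2 = table.loc[key, "ICC"]
        assert icc_absolute_agreement(ratings) == pytest.approx(icc2, abs=1e-10)

    def test_systematic_rater_offsets_are_penalized(self):
        # identical subjects, raters offset by a constant: no subject signal
        ratings = np.array([[1, 2, 3]] * 6, dtype=float)
        assert icc_absolute_agreement(ratings) <= 0.0

    def test_added_noise_does_not_increase_agreement_on_average(self, rng):
        base = np.tile(rng.integers(1, 6, size=20)[:, None], (1, 3)).astype(float)
        clean = icc_absolute_agreement(base)
        noisy_vals = [
            icc_absolute_agreement(base + rng.normal(0, 1.0, size=base.shape))
            for _ in range(30)
        ]
        assert np.mean(noisy_vals) < clean

    def test_shape_contracts(self):
        with pytest.raises(ContractError):
            icc_absolute_agreement(np.ones((1, 3)))
        with pytest.raises(ContractError):
            icc_absolute_agreement(np.ones((5, 1)))
        with pytest.raises(ContractError):
            icc_absolute_agreement(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestPercentRendering:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.94927, 94.9), (0.90345, 90.3), (0.8755, 87.6), (0.0545, 5.5), (0.5, 50.0)],
    )
    def test_one_decimal_round_half_up(self, fraction, expected):
        assert pct(fraction) == expected

    def test_none_passthrough(self):
        assert pct(None) is None
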