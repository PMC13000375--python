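import numpy as np
import pytest

from vocalrisk import evaluation as ev
from vocalrisk.errors import VocalRiskError
from vocalrisk.features import PatientFeatures


class TestAUC:
    def test_perfect_separation(self):
        roc = ev.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = ev.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == 0.5

    def test_three_quarters_concordant(self):
        roc = ev.roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(VocalRiskError):
            ev.roc_auc([0.1, 0.9], [1, 1])

    def test_matches_exhaustive_oracle_on_small_cohorts(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, int)
            labels[:int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert ev.roc_auc(scores, labels).auc == pytest.approx(
                ev.auc_brute_force(scores, labels))

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        roc = ev.roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert np.all(np.diff(roc.sensitivity) >= -1e-12)

    def test_ci_shrinks_with_sample_size(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (35, 350):
            labels = rng.integers(0, 2, n)
            scores = labels + rng.normal(0, 1.2, n)
            roc = ev.roc_auc(scores, labels)
            assert roc.ci[0] <= roc.auc <= roc.ci[1]
            widths.append(roc.ci[1] - roc.ci[0])
        assert widths[1] < widths[0]


class TestClassificationMetrics:
    def test_symmetric_table(self):
        m = ev.classification_metrics(ev.ConfusionTable(1, 1, 1, 1))
        for key in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert m[key] == pytest.approx(0.5)

    def test_zero_denominator_undefined_not_zero(self):
        m = ev.classification_metrics(ev.ConfusionTable(tp=0, fn=0, fp=2, tn=3))
        assert m["sensitivity"] is None
        assert m["specificity"] == pytest.approx(0.6)

    def test_f1_from_precision_recall(self):
        assert ev.f1_score(0.58, 0.70) == pytest.approx(0.63, abs=0.005)

    def test_confusion_from_predictions(self):
        t = ev.confusion_table([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (t.tp, t.fn, t.fp, t.tn) == (2, 1, 1, 1)


class TestYoudenCutoff:
    def test_hand_arithmetic(self):
        # sens 0.579 + spec 0.812 - 1 = 0.391
        assert 0.579 + 0.812 - 1 == pytest.approx(0.391)

    def test_perfect_separation_lower_boundary(self):
        roc = ev.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert ev.youden_cutoff(roc) == pytest.approx(0.8)

    def test_all_ties_returns_minimum(self):
        roc = ev.roc_auc([0.5] * 4, [1, 0, 1, 0])
        assert ev.youden_cutoff(roc) == pytest.approx(0.5)


class TestDecisionCurve:
    def test_treat_none_is_zero(self):
        dc = ev.decision_curve([0.2, 0.8], [0, 1])
        assert np.all(dc.nb_treat_none == 0.0)

    def test_treat_all_closed_form(self):
        labels = np.array([1] * 19 + [0] * 16)
        dc = ev.decision_curve(np.linspace(0, 1, 35), labels,
                               grid=np.array([0.35]))
        expected = 19 / 35 - (16 / 35) * (0.35 / 0.65)
        assert dc.nb_treat_all[0] == pytest.approx(expected, abs=1e-6)
        assert dc.nb_treat_all[0] == pytest.approx(0.297, abs=0.002)

    def test_perfect_model_net_benefit_equals_prevalence(self):
        labels = np.array([1] * 10 + [0] * 25)
        scores = labels.astype(float) * 0.9 + 0.05
        dc = ev.decision_curve(scores, labels, grid=np.array([0.5]))
        assert dc.nb_model[0] == pytest.approx(10 / 35)

    def test_model_never_beats_prevalence(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 60)
        dc = ev.decision_curve(rng.random(60), labels)
        assert np.all(dc.nb_model <= labels.mean() + 1e-12)

    def test_unit_threshold_rejected(self):
        with pytest.raises(VocalRiskError):
            ev.decision_curve([0.5], [1], grid=np.array([1.0]))


class TestCalibration:
    def test_near_perfect_scores_near_zero_brier(self):
        labels = np.array([1, 1, 0, 0] * 50)
        scores = np.clip(labels.astype(float), 1e-6, 1 - 1e-6)
        out = ev.calibration_assess(scores, labels, n_boot=50)
        assert out["brier"] == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_half_scores(self):
        labels = np.array([1, 0] * 100)
        scores = np.full(200, 0.5)
        out = ev.calibration_assess(scores, labels, n_boot=50)
        assert out["brier"] == pytest.approx(0.25)
        assert abs(out["slope"]) < 0.2


class TestGroupStats:
    def _patients(self, xa, xb, feat="Jitter_local"):
        out = []
        for i, v in enumerate(xa):
            out.append(PatientFeatures(f"a{i}", 65, "male", "high", {feat: v}))
        for i, v in enumerate(xb):
            out.append(PatientFeatures(f"b{i}", 65, "male", "low", {feat: v}))
        return out

    def test_identical_groups_null(self):
        vals = [0.01, 0.02, 0.03, 0.04]
        df = ev.group_stats(self._patients(vals, vals))
        assert df.mean_diff[0] == pytest.approx(0.0)
        assert df.p[0] == pytest.approx(1.0)

    def test_bh_step_up_by_hand(self):
        q = ev.bh_qvalues([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_bh_monotone_and_bounded_below_by_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(20)
        q = ev.bh_qvalues(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_power_at_planted_jitter_effect(self):
        # mean shift 0.0085, sd 0.005, n = 200/group: q < 0.05 nearly always
        rng = np.random.default_rng(6)
        hits = 0
        n_sims = 40
        for _ in range(n_sims):
            xa = rng.normal(0.0185, 0.005, 200)
            xb = rng.normal(0.0100, 0.005, 200)
            df = ev.group_stats(self._patients(xa, xb))
            if df.q[0] < 0.05:
                hits += 1
        assert hits >= int(0.95 * n_sims)

    def test_degenerate_zero_variance_flagged(self):
        df = ev.group_stats(self._patients([1.0, 1.0], [1.0, 1.0]))
        assert bool(df.degenerate[0])
        assert np.isnan(df.p[0])


class TestDemographicTests:
    def test_balanced_2x2_null(self):
        assert ev.fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_2x2_hypergeometric(self):
        assert ev.fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-6)

    def test_rxc_enumeration_matches_R(self):
        # fisher.test oracle values (R 4.3): 0.5714286 and 0.5151907
        assert ev.fisher_exact([[3, 4, 5], [1, 2, 0]]) == pytest.approx(
            0.5714286, abs=1e-6)
        assert ev.fisher_exact([[2, 4, 3], [3, 0, 1], [1, 2, 2]]) == pytest.approx(
            0.5151907, abs=1e-6)

    def test_empty_margin_rejected(self):
        with pytest.raises(VocalRiskError):
            ev.fisher_exact([[0, 0], [2, 3]])

    def test_kruskal_identical_groups(self):
        assert ev.kruskal_wallis([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_kruskal_shifted_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 60)
        assert ev.kruskal_wallis(a, a + 2.0) < 1e-6


class TestAgreement:
    def test_identical_raters_kappa_one(self):
        assert ev.cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_hand_example_half(self):
        assert ev.cohen_kappa([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.5)

    def test_complete_disagreement_negative_one(self):
        assert ev.cohen_kappa([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)

    def test_symmetry_and_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        k = ev.cohen_kappa(a, b)
        assert ev.cohen_kappa(b, a) == pytest.approx(k)
        assert ev.cohen_kappa(1 - a, 1 - b) == pytest.approx(k)

    def test_constant_raters_undefined(self):
        assert np.isnan(ev.cohen_kappa([1, 1, 1], [1, 1, 1]))

    def test_panel_matrix_and_metrics(self):
        preds = {"r1": [1, 1, 0, 0], "r2": [1, 0, 0, 0]}
        out = ev.rater_agreement(preds, [1, 1, 0, 0])
        assert out["kappa"][("r1", "r2")] == pytest.approx(0.5)
        assert out["metrics"]["r1"]["accuracy"] == pytest.approx(1.0)

    def test_mismatched_panel_rejected(self):
        with pytest.raises(VocalRiskError):
            ev.rater_agreement({"r1": [1, 0], "r2": [1]}, [1, 0])


class TestPairedTests:
    def test_balanced_discordance_null(self):
        assert ev.mcnemar_exact(5, 5) == pytest.approx(1.0)

    def test_binomial_tail_by_hand(self):
        # 2 * P(X <= 2 | n = 12, 1/2) = 0.0386
        assert ev.mcnemar_exact(10, 2) == pytest.approx(0.0386, abs=5e-4)

    def test_no_discordance_convention(self):
        assert ev.mcnemar_exact(0, 0) == 1.0

    def test_identical_scores_delong_p_one(self):
        scores = np.array([0.9, 0.7, 0.3, 0.2])
        labels = np.array([1, 1, 0, 0])
        out = ev.delong_test(scores, scores, labels)
        assert out["p"] == pytest.approx(1.0)

    def test_paired_tests_report_per_rater(self):
        truth = np.array([1, 1, 1, 0, 0, 0])
        machine_pred = np.array([1, 1, 0, 0, 0, 1])
        machine_scores = np.array([0.9, 0.8, 0.4, 0.3, 0.2, 0.6])
        out = ev.paired_tests({"r1": [1, 0, 1, 0, 1, 0]},
                              machine_pred, machine_scores, truth)
        assert 0.0 <= out["r1"]["mcnemar_p"] <= 1.0
        assert "delong" in out["r1"]
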