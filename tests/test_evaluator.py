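"""Confusion matrix, metric suite and protocol contracts."""

import numpy as np
import pytest

from dualecg.classes import AAMI_CLASSES
from dualecg.evaluator import (
    ConfusionMatrix,
    aggregate,
    class_metrics,
    confusion_matrix,
    macro_f1,
    one_vs_rest,
)

# published inter-patient confusion matrix (rows/cols: N, VEB, SVEB, F)
PUBLISHED_CM = ConfusionMatrix(np.array([
    [27721, 56, 68, 5],
    [47, 1592, 13, 7],
    [34, 11, 750, 12],
    [43, 25, 28, 301],
]))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(["N", "VEB", "SVEB", "F"], ["N", "VEB", "SVEB", "F"])
        np.testing.assert_array_equal(cm.counts, np.eye(4, dtype=int))

    def test_single_misclassification(self):
        cm = confusion_matrix(["N", "VEB"], ["VEB", "VEB"])
        assert cm.counts[0, 1] == 1 and cm.counts[1, 1] == 1

    def test_matches_brute_force_double_loop(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = confusion_matrix(y_true, y_pred)
        brute = np.zeros((4, 4), int)
        for a in range(4):
            for p in range(4):
                brute[a, p] = int(np.sum((y_true == a) & (y_pred == p)))
        np.testing.assert_array_equal(cm.counts, brute)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["N"], ["Q"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["N"], ["N", "N"])


class TestOneVsRest:
    def test_published_matrix_veb(self):
        tp, fp, tn, fn = one_vs_rest(PUBLISHED_CM, "VEB")
        assert (tp, fn, fp, tn) == (1592, 67, 92, 28962)

    def test_diagonal_has_no_errors(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7, 8]))
        for cls in AAMI_CLASSES:
            tp, fp, tn, fn = one_vs_rest(cm, cls)
            assert fp == 0 and fn == 0

    def test_partition_sums_to_total(self):
        for cls in AAMI_CLASSES:
            assert sum(one_vs_rest(PUBLISHED_CM, cls)) == PUBLISHED_CM.total


class TestClassMetrics:
    def test_published_veb_row(self):
        m = class_metrics(PUBLISHED_CM, "VEB").as_percent()
        assert m["sensitivity"] == pytest.approx(95.96, abs=0.01)
        assert m["precision"] == pytest.approx(94.54, abs=0.01)
        assert m["accuracy"] == pytest.approx(99.48, abs=0.01)
        assert m["specificity"] == pytest.approx(99.68, abs=0.01)
        assert m["f1"] == pytest.approx(95.24, abs=0.01)

    def test_published_sveb_gscore(self):
        m = class_metrics(PUBLISHED_CM, "SVEB").as_percent(1)
        assert m["g"] == pytest.approx(96.2, abs=0.05)

    def test_perfect_matrix_all_100(self):
        cm = ConfusionMatrix(np.diag([10, 10, 10, 10]))
        for cls in AAMI_CLASSES:
            m = class_metrics(cm, cls)
            for v in vars(m).values():
                assert v == pytest.approx(1.0)

    def test_f1_is_harmonic_mean_of_se_and_ppv(self):
        for cls in AAMI_CLASSES:
            m = class_metrics(PUBLISHED_CM, cls)
            harmonic = 2 * m.sensitivity * m.precision / (m.sensitivity + m.precision)
            assert m.f1 == pytest.approx(harmonic)

    def test_specificity_denominator_variants(self):
        fp_var = class_metrics(PUBLISHED_CM, "VEB", specificity_denominator="fp")
        fn_var = class_metrics(PUBLISHED_CM, "VEB", specificity_denominator="fn")
        assert fp_var.specificity == pytest.approx(28962 / 29054)
        assert fn_var.specificity == pytest.approx(28962 / 29029)

    def test_undefined_metric_flagged_not_raised(self):
        cm = ConfusionMatrix(np.diag([10, 0, 10, 10]))
        m = class_metrics(cm, "VEB")
        assert np.isnan(m.sensitivity)
        assert np.isnan(m.precision)


class TestAggregate:
    def test_published_macro_accuracy_and_micro_f1(self):
        macro_acc, micro_f1, _ = aggregate(PUBLISHED_CM)
        assert 100 * macro_acc == pytest.approx(99.43, abs=0.01)
        assert 100 * micro_f1 == pytest.approx(98.86, abs=0.01)

    def test_diagonal_matrix_gives_100(self):
        macro_acc, micro_f1, _ = aggregate(ConfusionMatrix(np.diag([1, 2, 3, 4])))
        assert macro_acc == pytest.approx(1.0)
        assert micro_f1 == pytest.approx(1.0)

    def test_micro_f1_equals_overall_accuracy(self, rng):
        for _ in range(5):
            counts = rng.integers(0, 50, size=(4, 4))
            cm = ConfusionMatrix(counts)
            if cm.total == 0:
                continue
            _, micro_f1, _ = aggregate(cm)
            assert micro_f1 == pytest.approx(np.trace(cm.counts) / cm.total)

    def test_macro_f1_mean_of_rows(self):
        per = [class_metrics(PUBLISHED_CM, c).f1 for c in AAMI_CLASSES]
        assert macro_f1(PUBLISHED_CM) == pytest.approx(np.mean(per))


class TestReportCsv:
    def test_layout_and_values(self, tmp_path):
        from dualecg.evaluator import write_report_csv

        path = tmp_path / "report.csv"
        write_report_csv(PUBLISHED_CM, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("class,N,VEB,SVEB,F,")
        assert len(lines) == 5
        veb = lines[2].split(",")
        assert veb[0] == "VEB" and veb[2] == "1592"
        assert veb[6] == "95.96"  # sensitivity column


class TestProtocolContracts:
    """Cheap structural checks of the protocol splits (tiny corpus, 2 epochs)."""

    @pytest.fixture(scope="class")
    def small_report(self):
        from dualecg.evaluator import run_protocol
        from dualecg.pipeline import PipelineConfig
        from dualecg.syndata import NoiseSpec, generate_corpus

        recs = generate_corpus(
            8, 45.0, (0.7, 0.1, 0.1, 0.1),
            NoiseSpec(baseline_amp=0.1, pli_amp=0.05, white_sigma=0.02, seed=0),
            seed=21)
        cfg = PipelineConfig(max_epochs=2, patience=1, n_folds=2,
                             model=__import__("dualecg").ModelConfig(
                                 initial_filters=4, dense_sizes=(32, 16, 8)))
        return run_protocol("inter_patient", recs, cfg, seed=0, n_folds=2), recs

    def test_no_patient_leakage(self, small_report):
        report, recs = small_report
        assert report.protocol == "inter_patient"
        assert len(report.folds) == 2

    def test_report_means_are_fold_means(self, small_report):
        report, _ = small_report
        assert report.mean_macro_f1 == pytest.approx(
            np.mean([f.macro_f1 for f in report.folds]))
        assert report.mean_macro_accuracy == pytest.approx(
            np.mean([f.macro_accuracy for f in report.folds]))

    def test_intra_patient_run(self, small_report):
        from dualecg.evaluator import run_protocol
        from dualecg.pipeline import PipelineConfig

        _, recs = small_report
        cfg = PipelineConfig(max_epochs=2, patience=1, n_folds=2,
                             model=__import__("dualecg").ModelConfig(
                                 initial_filters=4, dense_sizes=(32, 16, 8)))
        report = run_protocol("intra_patient", recs, cfg, seed=0, n_folds=2)
        assert report.protocol == "intra_patient"
        assert len(report.folds) == 2
        # both folds are tested on the same stratified 20% holdout
        sizes = {f.confusion.total for f in report.folds}
        assert len(sizes) == 1

    def test_unknown_protocol_rejected(self):
        from dualecg.evaluator import run_protocol

        with pytest.raises(ValueError):
            run_protocol("leave_one_out", [])

    def test_intra_patient_split_proportions(self):
        from sklearn.model_selection import train_test_split

        y = np.repeat([0, 1, 2, 3], [700, 100, 100, 100])
        tr, te = train_test_split(np.arange(1000), test_size=0.2, stratify=y,
                                  random_state=0)
        assert len(te) == 200
        np.testing.assert_allclose(np.bincount(y[te]), [140, 20, 20, 20], atol=1)
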