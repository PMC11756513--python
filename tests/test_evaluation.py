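"""Confusion metrics, the Ct-40 MAE convention, and analyst comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tacall
from tacall import AlignmentError, ConfusionMatrix, ReactionLabel

# Published validation confusion matrices (amplification = positive class).
INTERNAL_CM = ConfusionMatrix(tp=7752, fp=72, fn=53, tn=25166)
EXTERNAL_CM = ConfusionMatrix(tp=349, fp=2, fn=3, tn=1118)


def call(rid, p, ct=None):
    return tacall.make_call(rid, p, ct)


class TestConfusion:
    def test_perfect_agreement(self):
        labels = [
            ReactionLabel("a", True, 20.0), ReactionLabel("b", True, 30.0),
            ReactionLabel("c", False, None), ReactionLabel("d", False, None),
        ]
        calls = [call("a", 0.99, 20.0), call("b", 0.99, 30.0),
                 call("c", 0.01), call("d", 0.01)]
        cm = tacall.confusion(calls, labels)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_all_negative_labels_all_positive_calls(self):
        labels = [ReactionLabel(f"r{i}", False, None) for i in range(6)]
        calls = [call(f"r{i}", 0.99, 22.0) for i in range(6)]
        cm = tacall.confusion(calls, labels)
        assert cm.fp == 6 and cm.tp == cm.fn == cm.tn == 0

    def test_id_mismatch_rejected(self):
        labels = [ReactionLabel("a", False, None)]
        calls = [call("b", 0.2)]
        with pytest.raises(AlignmentError):
            tacall.confusion(calls, labels)

    def test_internal_validation_counts_sum(self):
        assert INTERNAL_CM.total == 33_043
        assert INTERNAL_CM.n_misclassified == 125
        assert EXTERNAL_CM.total == 1472
        assert EXTERNAL_CM.n_misclassified == 5


class TestMetrics:
    def test_internal_validation_accuracy(self):
        report = tacall.metrics(INTERNAL_CM)
        assert round(report.accuracy, 3) == 0.996
        assert round(100 * INTERNAL_CM.n_misclassified / INTERNAL_CM.total, 2) == 0.38

    def test_external_validation_accuracy(self):
        report = tacall.metrics(EXTERNAL_CM)
        assert round(report.accuracy, 3) == 0.997
        assert round(100 * EXTERNAL_CM.n_misclassified / EXTERNAL_CM.total, 2) == 0.34

    def test_perfect_two_by_two_all_ones(self):
        report = tacall.metrics(ConfusionMatrix(tp=1, fp=0, fn=0, tn=1))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(report, name) == 1.0

    def test_zero_denominator_reported_absent(self):
        report = tacall.metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
        assert report.sensitivity is None
        assert report.ppv is None
        assert any("sensitivity" in n for n in report.notes)

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(min_value=0, max_value=10_000)] * 4))
    def test_accuracy_complement_identity(self, counts):
        tp, fp, fn, tn = counts
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        if cm.total == 0:
            return
        report = tacall.metrics(cm)
        assert report.accuracy == pytest.approx(1 - (fp + fn) / cm.total)


class TestCtMae:
    def test_perfect_predictions_zero_error(self):
        labels = [ReactionLabel("a", True, 24.0), ReactionLabel("b", False, None)]
        calls = [call("a", 0.99, 24.0), call("b", 0.01)]
        mae, mae_excl = tacall.ct_mae(calls, labels)
        assert mae == 0.0 and mae_excl == 0.0

    def test_false_positive_substitution_worked_example(self):
        """Two true positives off by 0.4 and 0.8, one false positive at 37:
        the false positive contributes |37 - 40| = 3."""
        labels = [
            ReactionLabel("a", True, 20.0), ReactionLabel("b", True, 30.0),
            ReactionLabel("c", False, None),
        ]
        calls = [call("a", 0.99, 20.4), call("b", 0.99, 30.8), call("c", 0.8, 37.0)]
        mae, mae_excl = tacall.ct_mae(calls, labels, no_amp_ct=40.0)
        assert mae == pytest.approx(1.4)
        assert mae_excl == pytest.approx(0.6)

    def test_no_amplified_calls_gives_absent_values(self):
        labels = [ReactionLabel("a", False, None)]
        calls = [call("a", 0.1)]
        assert tacall.ct_mae(calls, labels) == (None, None)

    def test_symmetric_mode_counts_false_negatives(self):
        labels = [ReactionLabel("a", True, 35.0)]
        calls = [call("a", 0.2)]
        mae, _ = tacall.ct_mae(calls, labels, include_false_negatives=True)
        assert mae == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_excluding_variant_smaller_when_fp_errors_dominate(self, seed):
        """Dropping false positives lowers the MAE whenever their |pred - 40|
        penalty exceeds the true positives' errors — the regime the
        substitution rule is designed for (accurate Ct on real amplifiers,
        false calls predicting well before cycle 40)."""
        rng = np.random.default_rng(seed)
        n = 30
        labels, calls = [], []
        for i in range(n):
            amplified = rng.random() < 0.5
            p = float(rng.uniform(0.51, 1.0)) if rng.random() < 0.7 else float(rng.uniform(0, 0.5))
            if amplified:
                gold_ct = float(rng.uniform(15, 35))
                labels.append(ReactionLabel(f"r{i}", True, gold_ct))
                pred_ct = gold_ct + float(rng.uniform(-2, 2))  # small TP error
            else:
                labels.append(ReactionLabel(f"r{i}", False, None))
                pred_ct = float(rng.uniform(15, 37))  # FP error >= 3
            calls.append(call(f"r{i}", p, pred_ct if p > 0.5 else None))
        mae, mae_excl = tacall.ct_mae(calls, labels)
        if mae_excl is not None and mae is not None:
            assert mae_excl <= mae


class TestEvaluate:
    def test_full_report_fields_consistent(self):
        labels = [
            ReactionLabel("a", True, 22.0), ReactionLabel("b", False, None),
            ReactionLabel("c", True, 38.0), ReactionLabel("d", False, None),
        ]
        calls = [call("a", 0.95, 22.5), call("b", 0.45), call("c", 0.2),
                 call("d", 0.99, 36.0)]
        report = tacall.evaluate(calls, labels)
        assert report.n_misclassified == 2  # the missed 'c' and false 'd'
        assert report.accuracy == pytest.approx(0.5)
        # mae over amplified calls: |22.5-22| and |36-40|
        assert report.mae == pytest.approx((0.5 + 4.0) / 2)
        assert report.mae_excluding_misclassified == pytest.approx(0.5)
        assert report.n_flagged_misclassified == 1  # 'c' at 0.2
        assert report.n_flagged_correct == 1  # 'b' at 0.45


class TestCompareAnalysts:
    def test_perfect_analyst_ranked_last(self):
        gold = [ReactionLabel(f"r{i}", i < 3, 20.0 + i if i < 3 else None)
                for i in range(10)]
        perfect = list(gold)
        sloppy = list(gold)
        sloppy[0] = ReactionLabel("r0", False, None)  # one miss
        table = tacall.compare_analysts({"perfect": perfect, "sloppy": sloppy}, gold)
        assert list(table["analyst"]) == ["sloppy", "perfect"]
        assert table.iloc[-1]["accuracy"] == 1.0
        assert table.iloc[-1]["mae"] == 0.0

    def test_missing_reactions_rejected(self):
        gold = [ReactionLabel("a", False, None), ReactionLabel("b", False, None)]
        with pytest.raises(AlignmentError, match="'partial'.*\\['b'\\]"):
            tacall.compare_analysts({"partial": [gold[0]]}, gold)

    def test_injected_error_rates_recover_ordering(self):
        """Simulated EQA: analysts corrupting gold at 0-5% recover their rank."""
        rng = np.random.default_rng(11)
        cfg = tacall.SimConfig(n_reactions=600, seed=11)
        _, gold = tacall.simulate_dataset(cfg)
        rates = {"a0": 0.0, "a1": 0.01, "a2": 0.02, "a3": 0.035, "a4": 0.05}
        analysts = {}
        for name, rate in rates.items():
            table = []
            for lab in gold:
                if rng.random() < rate:  # flip the call
                    if lab.amplified:
                        table.append(ReactionLabel(lab.reaction_id, False, None))
                    else:
                        table.append(ReactionLabel(lab.reaction_id, True, 35.0))
                else:
                    table.append(lab)
            analysts[name] = table
        result = tacall.compare_analysts(analysts, gold)
        assert list(result["analyst"]) == ["a4", "a3", "a2", "a1", "a0"]

    def test_automated_model_included_with_ties_broken_by_mae(self):
        gold = [ReactionLabel(f"r{i}", i < 2, 25.0 + i if i < 2 else None)
                for i in range(4)]
        analyst = [ReactionLabel("r0", True, 25.5), ReactionLabel("r1", True, 26.0),
                   ReactionLabel("r2", False, None), ReactionLabel("r3", False, None)]
        automated = [call("r0", 0.99, 25.0), call("r1", 0.99, 27.0),
                     call("r2", 0.01), call("r3", 0.01)]
        table = tacall.compare_analysts({"alice": analyst}, gold, automated=automated)
        # both have accuracy 1.0; the analyst's MAE 0.25 < automated 0.5
        assert list(table["analyst"]) == ["alice", "Automated Analysis"]
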