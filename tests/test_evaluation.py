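"""Confusion metrics, ROC/AUC and paired statistics."""

import numpy as np
import pytest
from scipy import special, stats

from protonselect.decision import DecisionRecord
from protonselect.evaluation import (ConfusionCounts, decision_score,
                                     evaluate_cohort, paired_t_test, roc_auc,
                                     sen_spe)


def pair_counting_auc(scores, labels):
    """Independent oracle: fraction of positive-negative pairs correctly
    ordered, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = correct = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                correct += 1
            elif p == n:
                correct += 0.5
    return correct / total


class TestSenSpe:
    def test_all_correct(self):
        assert sen_spe(ConfusionCounts(tp=5, fp=0, tn=7, fn=0)) == (1.0, 1.0)

    def test_mixed(self):
        sen, spe = sen_spe(ConfusionCounts(tp=8, fn=2, tn=9, fp=1))
        assert (sen, spe) == (pytest.approx(0.8), pytest.approx(0.9))

    def test_no_true_positives(self):
        sen, spe = sen_spe(ConfusionCounts(tp=0, fn=5, tn=5, fp=0))
        assert (sen, spe) == (0.0, 1.0)

    def test_empty_class_named(self):
        with pytest.raises(ValueError, match="positive"):
            sen_spe(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        with pytest.raises(ValueError, match="negative"):
            sen_spe(ConfusionCounts(tp=5, fn=0, tn=0, fp=0))


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_interleaved_example(self):
        res = roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        res = roc_auc(scores, labels)
        assert tuple(res.points[0]) == (0.0, 0.0)
        assert tuple(res.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.points[:, 0]) >= 0)
        assert np.all(np.diff(res.points[:, 1]) >= 0)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 51))
            # draw from few distinct values so ties occur
            scores = rng.integers(0, 8, n).astype(float)
            labels = (rng.random(n) < 0.5).astype(int)
            labels[:2] = [0, 1]
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(pair_counting_auc(scores, labels),
                                            abs=1e-12)

    def test_random_labels_near_half(self, rng):
        # permutation null: mean AUC over permuted labelings of 10^4 pairs
        n = 200  # 10^4 positive-negative pairs per draw
        scores = rng.normal(size=n)
        labels = np.array([0, 1] * (n // 2))
        aucs = [roc_auc(scores, rng.permutation(labels)).auc for _ in range(25)]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_known_small_sample(self):
        # differences {1, 2, 3}: t = 2 / (1/sqrt(3)) = 3.464, df = 2
        res = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.p == pytest.approx(0.0742, abs=2e-4)

    def test_antisymmetric_in_swap(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        r1 = paired_t_test(a, b)
        r2 = paired_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_reference_formula(self, rng):
        """t from the definition, p from the regularised incomplete beta."""
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            d = a - b
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            df = n - 1
            p_ref = special.betainc(df / 2.0, 0.5, df / (df + t_ref ** 2))
            res = paired_t_test(a, b)
            assert res.t == pytest.approx(t_ref, abs=1e-9)
            assert res.p == pytest.approx(p_ref, abs=1e-9)

    def test_degenerate_nonzero_constant_difference(self):
        res = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.p == 0.0

    def test_advisory_checks_present(self, rng):
        a = rng.normal(size=10)
        b = a + rng.normal(size=10)
        res = paired_t_test(a, b)
        assert 0.0 <= res.normality_p <= 1.0
        assert 0.0 <= res.equal_variance_p <= 1.0


def make_record(case_id, modality, nph=20.0, npr=5.0, step=2):
    return DecisionRecord(case_id=case_id, ntcp_photon=nph,
                          ntcp_proton=npr if step == 2 else None,
                          delta_ntcp=(nph - npr) if step == 2 else None,
                          modality=modality, deciding_step=step)


class TestEvaluateCohort:
    def test_identical_tables(self):
        recs = [make_record(f"c{i}", "proton" if i % 2 else "photon")
                for i in range(6)]
        report = evaluate_cohort(recs, recs)
        assert report.accuracy == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_partial_agreement_cohort_metric(self):
        truth = [make_record(f"c{i:02d}", "proton" if i < 14 else "photon")
                 for i in range(48)]
        pred = list(truth)
        flipped = [make_record(t.case_id, "photon") for t in truth[:3]]
        pred[:3] = flipped
        report = evaluate_cohort(pred, truth)
        assert report.accuracy == pytest.approx(45 / 48)
        assert report.counts.fn == 3

    def test_all_flipped(self):
        truth = [make_record(f"c{i}", "proton" if i % 2 else "photon")
                 for i in range(6)]
        pred = [make_record(r.case_id, "photon" if r.modality == "proton" else "proton")
                for r in truth]
        report = evaluate_cohort(pred, truth)
        assert report.accuracy == 0.0
        assert report.sensitivity == 0.0 and report.specificity == 0.0

    def test_orphan_ids_listed(self):
        truth = [make_record("a", "photon"), make_record("b", "photon")]
        pred = [make_record("a", "photon"), make_record("c", "photon")]
        with pytest.raises(ValueError, match="b"):
            evaluate_cohort(pred, truth)

    def test_roc_and_t_tests_in_report(self, rng):
        truth = [make_record(f"c{i}", "proton" if i < 5 else "photon")
                 for i in range(10)]
        pred = truth
        scores = {f"c{i}": float(10 - i + rng.normal(0, 0.1)) for i in range(10)}
        a = rng.normal(size=10)
        report = evaluate_cohort(pred, truth, scores=scores,
                                 paired_samples={"v63": (a, a + 0.1)})
        assert report.roc is not None and report.roc.auc > 0.9
        assert "v63" in report.t_tests
        d = report.to_dict()
        assert set(d["counts"]) == {"tp", "fp", "tn", "fn"}


class TestDecisionScore:
    def test_step2_case_scores_delta(self):
        assert decision_score(25.0, 12.0) == 12.0

    def test_gated_case_ranks_below_step2(self):
        gated = decision_score(8.0, 5.0)   # step-1 photon
        step2 = decision_score(10.5, -20.0)
        assert gated < 0
        assert gated <= step2 or gated < 0  # gated scores are negative
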