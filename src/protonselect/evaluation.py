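"""Decision-accuracy and agreement statistics.

The decision method is scored against reference ("treatment-planning
system") decisions: proton selection is the positive class, so sensitivity
is the fraction of truly proton-favoured patients the method sends to
protons and specificity the fraction of photon patients it keeps on
photons. ROC analysis needs a continuous score; by default the predicted
ΔNTCP is used, with cases stopped at step 1 ranked below all step-2 cases
via min(ΔNTCP, NTCP_photon - step-1 threshold). Paired two-tailed t-tests
(with advisory Shapiro–Wilk normality and Levene variance checks) compare
predicted against reference dosimetric quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .decision import DecisionRecord

__all__ = [
    "ConfusionCounts",
    "ROCResult",
    "TTestResult",
    "sen_spe",
    "roc_auc",
    "paired_t_test",
    "decision_score",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 decision counts; proton = positive, photon = negative."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("no samples")
        return (self.tp + self.tn) / self.total


@dataclass
class ROCResult:
    thresholds: np.ndarray
    points: np.ndarray  # (n, 2) array of (1 - SPE, SEN), monotone from (0,0) to (1,1)
    auc: float


@dataclass
class TTestResult:
    t: float
    p: float
    n: int
    normality_p: float | None      # Shapiro-Wilk on paired differences, advisory
    equal_variance_p: float | None  # Levene across the two samples, advisory
    degenerate: bool = False


def sen_spe(counts: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(FP+TN)."""
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive (proton) samples: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative (photon) samples: specificity undefined")
    return counts.tp / (counts.tp + counts.fn), counts.tn / (counts.fp + counts.tn)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and trapezoidal AUC over a sweep of score thresholds.

    Equivalent to the Mann–Whitney rank statistic U/(n1*n2) with midrank
    handling of ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    uniq = np.unique(labels)
    if uniq.size != 2 or not np.array_equal(uniq, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    fpr, tpr, thr = roc_curve(labels, scores)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, points=points, auc=auc)


def paired_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Two-tailed paired t-test with advisory normality/variance reports."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be equal-length 1-D sequences")
    n = a.size
    if n < 3:
        raise ValueError("paired t-test requires at least 3 pairs")
    d = a - b

    normality_p = None
    try:
        normality_p = float(stats.shapiro(d).pvalue)
    except ValueError:
        pass  # e.g. all differences identical
    try:
        equal_variance_p = float(stats.levene(a, b).pvalue)
    except ValueError:
        equal_variance_p = None

    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d.mean(), 0.0):
            return TTestResult(t=0.0, p=1.0, n=n, normality_p=normality_p,
                               equal_variance_p=equal_variance_p)
        return TTestResult(t=float(np.sign(d.mean()) * np.inf), p=0.0, n=n,
                           normality_p=normality_p,
                           equal_variance_p=equal_variance_p, degenerate=True)

    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), n=n,
                       normality_p=normality_p, equal_variance_p=equal_variance_p)


def decision_score(ntcp_photon: float, delta: float | None,
                   step1_threshold: float = 10.0) -> float:
    """Continuous proton-preference score used for ROC ranking.

    Step-2 cases score their ΔNTCP; cases stopped at step 1 score
    min(ΔNTCP, NTCP_photon - threshold), which is negative and therefore
    ranks them below every case that reached step 2.
    """
    gap = ntcp_photon - step1_threshold
    if ntcp_photon > step1_threshold:
        if delta is None:
            raise ValueError("step-2 case needs a delta NTCP for scoring")
        return float(delta)
    return float(min(delta, gap)) if delta is not None else float(gap)


@dataclass
class EvaluationReport:
    accuracy: float
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    binary_auc: float                     # (SEN + SPE)/2: AUC of the hard decisions
    roc: ROCResult | None
    t_tests: dict[str, TTestResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "binary_auc": self.binary_auc,
            "auc": self.roc.auc if self.roc is not None else None,
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "t_tests": {k: {"t": v.t, "p": v.p, "n": v.n,
                            "normality_p": v.normality_p,
                            "equal_variance_p": v.equal_variance_p,
                            "degenerate": v.degenerate}
                        for k, v in self.t_tests.items()},
        }
        return out


def evaluate_cohort(decisions_pred: Sequence[DecisionRecord],
                    decisions_truth: Sequence[DecisionRecord],
                    scores: Mapping[str, float] | None = None,
                    paired_samples: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
                    ) -> EvaluationReport:
    """Score predicted decisions against reference decisions.

    ``scores`` maps case_id -> continuous proton-preference score (see
    :func:`decision_score`); ``paired_samples`` maps a label (for example
    ``"v6300_photon"``) to (predicted, reference) per-case value sequences
    for paired t-testing.
    """
    pred = {r.case_id: r for r in decisions_pred}
    truth = {r.case_id: r for r in decisions_truth}
    orphans = sorted(set(pred) ^ set(truth))
    if orphans:
        raise ValueError(f"case id mismatch between decision tables: {orphans}")

    ids = sorted(pred)
    tp = sum(1 for i in ids if pred[i].modality == "proton" and truth[i].modality == "proton")
    fp = sum(1 for i in ids if pred[i].modality == "proton" and truth[i].modality == "photon")
    tn = sum(1 for i in ids if pred[i].modality == "photon" and truth[i].modality == "photon")
    fn = sum(1 for i in ids if pred[i].modality == "photon" and truth[i].modality == "proton")
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sen, spe = sen_spe(counts)

    roc = None
    if scores is not None:
        labels = [1 if truth[i].modality == "proton" else 0 for i in ids]
        if len(set(labels)) == 2:
            roc = roc_auc([scores[i] for i in ids], labels)

    t_tests = {}
    if paired_samples:
        for name, (a, b) in paired_samples.items():
            t_tests[name] = paired_t_test(a, b)

    return EvaluationReport(accuracy=counts.accuracy, counts=counts,
                            sensitivity=sen, specificity=spe,
                            binary_auc=(sen + spe) / 2.0, roc=roc,
                            t_tests=t_tests)
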