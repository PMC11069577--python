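"""Imbalance-aware benchmarking of editing-site predictors.

Editing sites are rare (about 1 per 468 cytosines in curated data), so two
evaluation sets are used:

* the *testing set*: the held-out 30% of a stratified 70-30 split, carrying
  a 1:3 editing:non-editing ratio;
* the *proportional set*: the same positives plus additional negatives
  topping the ratio up to 1:468, the realistic prevalence.

Because the positives are shared by construction, any fixed classifier has
identical recall on both sets; precision, F1 and MCC degrade with
prevalence, which is the point of the exercise.  Threshold-free comparisons
use AUROC and AUPRC; the AUPRC baseline equals the positive prevalence
(1/469 ~ 0.00213 on the proportional set).

Point metrics with zero denominators are reported as NaN, never 0, so that
e.g. a classifier that calls nothing does not get a silently perfect
precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import train_test_split

from .ml import LabeledSite

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "BenchmarkSet",
    "split_train_test",
    "make_proportional_set",
    "counts_from_calls",
    "compute_metrics",
    "roc_and_pr_curves",
    "redundancy_audit",
    "LeakageError",
]

logger = logging.getLogger(__name__)


class LeakageError(ValueError):
    """Evaluation negatives overlap the training data."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Point metrics (NaN where undefined) plus optional curve areas."""

    recall: float
    precision: float
    f1: float
    mcc: float
    auroc: float | None = None
    auprc: float | None = None
    baseline_auprc: float | None = None
    set_name: str = ""


@dataclass(frozen=True)
class BenchmarkSet:
    sites: tuple[LabeledSite, ...]
    ratio: float
    name: str = ""

    @property
    def n_pos(self) -> int:
        return sum(s.label for s in self.sites)

    @property
    def n_neg(self) -> int:
        return len(self.sites) - self.n_pos

    @property
    def prevalence(self) -> float:
        return self.n_pos / len(self.sites)


def split_train_test(sites: list[LabeledSite], fraction: float = 0.7,
                     seed: int = 0) -> tuple[list[LabeledSite], list[LabeledSite]]:
    """Stratified, seeded train/test split (default 70-30)."""
    labels = [s.label for s in sites]
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present to stratify")
    train, test = train_test_split(sites, train_size=fraction,
                                   stratify=labels, random_state=seed)
    return list(train), list(test)


def _site_key(s: LabeledSite) -> tuple[str, int]:
    return (s.window.gene, s.window.c_pos)


def make_proportional_set(test: BenchmarkSet, neg_pool: list[LabeledSite],
                          ratio: int = 468, seed: int = 0,
                          train: list[LabeledSite] | None = None) -> BenchmarkSet:
    """Top the test set up with extra negatives to the target neg:pos ratio.

    Positives are exactly the test positives; negatives are the test
    negatives plus a seeded uniform sample from ``neg_pool``.  If ``train``
    is given, any pool overlap with it raises :class:`LeakageError`.
    """
    if train is not None:
        train_keys = {_site_key(s) for s in train}
        bad = [s for s in neg_pool if _site_key(s) in train_keys]
        if bad:
            raise LeakageError(
                f"{len(bad)} pool negatives overlap the training set, "
                f"e.g. {_site_key(bad[0])}"
            )
    pos = [s for s in test.sites if s.label == 1]
    neg = [s for s in test.sites if s.label == 0]
    n_extra = ratio * len(pos) - len(neg)
    if n_extra < 0:
        raise ValueError("test set already exceeds the requested ratio")
    existing = {_site_key(s) for s in test.sites}
    pool = [s for s in neg_pool if s.label == 0 and _site_key(s) not in existing]
    if n_extra > len(pool):
        logger.warning("negative pool has %d sites, %d requested; taking all",
                       len(pool), n_extra)
        n_extra = len(pool)
    rng = np.random.default_rng(seed)
    extra = [pool[i] for i in rng.choice(len(pool), size=n_extra,
                                         replace=False)] if n_extra else []
    sites = pos + neg + extra
    order = rng.permutation(len(sites))
    return BenchmarkSet(sites=tuple(sites[i] for i in order), ratio=ratio,
                        name="proportional")


def counts_from_calls(labels, calls) -> ConfusionCounts:
    """Tally a confusion matrix from parallel label and call sequences."""
    labels = np.asarray(labels, dtype=bool)
    calls = np.asarray(calls, dtype=bool)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must align")
    return ConfusionCounts(
        tp=int(np.sum(labels & calls)),
        fp=int(np.sum(~labels & calls)),
        fn=int(np.sum(labels & ~calls)),
        tn=int(np.sum(~labels & ~calls)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting NaN", name)
        return math.nan
    return num / den


def compute_metrics(counts: ConfusionCounts, set_name: str = "") -> MetricsReport:
    """Recall, precision, F1 and MCC from a confusion matrix.

    Zero-denominator cases yield NaN with a warning.  MCC uses the closed
    form (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    recall = _ratio(tp, tp + fn, "recall")
    precision = _ratio(tp, tp + fp, "precision")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1")
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, denom, "MCC")
    return MetricsReport(recall=recall, precision=precision, f1=f1, mcc=mcc,
                         set_name=set_name)


def roc_and_pr_curves(scores, labels, set_name: str = ""):
    """AUROC/AUPRC with the underlying curves.

    ``scores`` may be integer rules totals (the no-structure sentinel must
    already be mapped to a rank below every integer) or forest
    probabilities; the sweep is over unique score values.  AUROC is the
    trapezoidal area (equal to the normalized Mann-Whitney U statistic);
    AUPRC is the step-wise average precision.  The baseline AUPRC is the
    positive prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC/PR require both classes present")
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    report = MetricsReport(
        recall=math.nan, precision=math.nan, f1=math.nan, mcc=math.nan,
        auroc=auroc, auprc=auprc,
        baseline_auprc=float(labels.mean()), set_name=set_name,
    )
    curves = {"roc": (fpr, tpr, roc_thr), "pr": (prec, rec, pr_thr)}
    return auroc, auprc, report, curves


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def redundancy_audit(windows: list[str], block: int = 512) -> dict[str, float]:
    """Pairwise 25-nt sequence-identity audit.

    ``windows`` are the 25 context nucleotides around each cytosine (the
    same representation the classifier consumes).  Identity of a pair is the
    fraction of matching positions out of 25; reported are the fractions of
    distinct pairs exceeding 75% identity (at least 19 matching positions)
    and exceeding 30% identity.
    """
    n = len(windows)
    if n < 2:
        raise ValueError("need at least two windows")
    for w in windows:
        if len(w) != 25:
            raise ValueError(f"windows must be 25 nt, got {len(w)}")
    M = np.array([[_BASE_CODE[b] for b in w] for w in windows], dtype=np.int8)
    n_over_75 = 0
    n_over_30 = 0
    total = 0
    for i0 in range(0, n, block):
        A = M[i0:i0 + block]
        for j0 in range(i0, n, block):
            B = M[j0:j0 + block]
            matches = (A[:, None, :] == B[None, :, :]).sum(-1)
            if i0 == j0:
                iu = np.triu_indices(len(A), k=1)
                vals = matches[iu]
            else:
                vals = matches.ravel()
            ident = vals / 25.0
            n_over_75 += int(np.sum(ident > 0.75))
            n_over_30 += int(np.sum(ident > 0.30))
            total += len(vals)
    return {
        "n_pairs": total,
        "frac_over_75": n_over_75 / total,
        "frac_over_30": n_over_30 / total,
    }
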