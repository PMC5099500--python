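"""5-fold cross-validation, per-class/macro precision-recall-F, paired t-tests.

Conventions:

* Folds are an unstratified uniform random partition (seeded permutation cut
  into K near-equal blocks); a stratified option exists but is off by
  default.
* precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R); when a
  denominator is zero the metric is defined as 0 and the class is flagged.
* Macro averages are unweighted arithmetic means of the per-class values.
* Classifier comparison is a paired one-tailed t-test on per-fold F-scores
  (H1: mean(a-b) > 0, df = n-1). A zero t-statistic yields p = 0.5; a
  zero-variance nonzero difference is reported as a degenerate limit
  (p = 0 or 1) and flagged rather than returned as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .corpus import Corpus, LabeledTweet

__all__ = [
    "FoldAssignment",
    "ClassMetrics",
    "FoldResult",
    "EvalReport",
    "TTestResult",
    "make_folds",
    "per_class_metrics",
    "macro_average",
    "evaluate_predictions",
    "cross_validate",
    "compare_classifiers",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Map tweet id -> fold index in 0..K-1; fold sizes differ by at most 1."""

    fold_of: dict[str, int]
    K: int
    seed: int

    def members(self, k: int) -> list[str]:
        return [tid for tid, f in self.fold_of.items() if f == k]


def make_folds(
    corpus: Corpus, K: int = 5, seed: int = 0, stratify_by: str | None = None
) -> FoldAssignment:
    """Randomly partition a corpus into K near-equal folds (seeded).

    With ``stratify_by`` ("source"/"sentiment") the split preserves label
    proportions per fold; the default is a plain random partition.
    """
    n = len(corpus)
    if K <= 0:
        raise ValueError("K must be positive")
    if K > n:
        raise ValueError(f"K={K} exceeds corpus size {n}")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    if stratify_by is None:
        order = rng.permutation(n)
        # first n % K folds get the extra item
        sizes = [n // K + (1 if k < n % K else 0) for k in range(K)]
        pos = 0
        for k, size in enumerate(sizes):
            for i in order[pos : pos + size]:
                fold_of[corpus.items[i].tweet.id] = k
            pos += size
    else:
        by_label: dict[object, list[int]] = {}
        for i, it in enumerate(corpus.items):
            by_label.setdefault(getattr(it, stratify_by), []).append(i)
        k = 0
        for label in sorted(by_label, key=str):
            idxs = by_label[label]
            for i in rng.permutation(len(idxs)):
                fold_of[corpus.items[idxs[i]].tweet.id] = k % K
                k += 1
    return FoldAssignment(fold_of=fold_of, K=K, seed=seed)


class ClassMetrics(NamedTuple):
    precision: float
    recall: float
    f: float
    flagged: bool = False  # a zero-denominator convention was applied


def per_class_metrics(
    gold: Sequence[str], predicted: Sequence[str], cls: str
) -> ClassMetrics:
    """One-vs-rest precision/recall/F for one class."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must have equal length")
    if not gold:
        raise ValueError("empty evaluation set")
    tp = sum(1 for g, p in zip(gold, predicted) if g == cls and p == cls)
    fp = sum(1 for g, p in zip(gold, predicted) if g != cls and p == cls)
    fn = sum(1 for g, p in zip(gold, predicted) if g == cls and p != cls)
    flagged = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ClassMetrics(precision, recall, f, flagged or (precision + recall == 0))


def macro_average(per_class: Mapping[str, ClassMetrics]) -> ClassMetrics:
    """Unweighted mean of per-class precision, recall and F."""
    if not per_class:
        raise ValueError("no classes to average")
    ms = list(per_class.values())
    return ClassMetrics(
        precision=sum(m.precision for m in ms) / len(ms),
        recall=sum(m.recall for m in ms) / len(ms),
        f=sum(m.f for m in ms) / len(ms),
        flagged=any(m.flagged for m in ms),
    )


@dataclass(frozen=True)
class FoldResult:
    fold: int
    n_test: int
    per_class: dict[str, ClassMetrics]
    macro: ClassMetrics


def evaluate_predictions(
    gold: Sequence[str],
    predicted: Sequence[str],
    classes: Sequence[str] | None = None,
    fold: int = 0,
) -> FoldResult:
    """Per-class and macro metrics for one evaluation set."""
    if classes is None:
        classes = sorted(set(gold) | set(predicted))
    per_class = {c: per_class_metrics(gold, predicted, c) for c in classes}
    return FoldResult(
        fold=fold, n_test=len(gold), per_class=per_class, macro=macro_average(per_class)
    )


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def compare_classifiers(
    fold_f_a: Sequence[float], fold_f_b: Sequence[float], paired: bool = True
) -> TTestResult:
    """One-tailed t-test that classifier a outperforms b on per-fold F-scores.

    Paired by shared folds by default (df = n-1); ``paired=False`` runs an
    unpaired Welch test instead.
    """
    a = np.asarray(fold_f_a, dtype=float)
    b = np.asarray(fold_f_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length score sequences of length >= 2")
    if paired:
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            mean = float(diff.mean())
            if mean == 0.0:
                return TTestResult(0.0, 0.5, degenerate=True)
            return TTestResult(
                math.copysign(math.inf, mean), 0.0 if mean > 0 else 1.0, degenerate=True
            )
        res = stats.ttest_rel(a, b, alternative="greater")
    else:
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            mean = float(a.mean() - b.mean())
            if mean == 0.0:
                return TTestResult(0.0, 0.5, degenerate=True)
            return TTestResult(
                math.copysign(math.inf, mean), 0.0 if mean > 0 else 1.0, degenerate=True
            )
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return TTestResult(float(res.statistic), float(res.pvalue))


@dataclass
class EvalReport:
    """Cross-validation results: per-fold metrics, their mean, and comparisons."""

    per_fold: list[FoldResult]
    mean_macro: ClassMetrics
    classes: tuple[str, ...]
    comparisons: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def fold_macro_f(self) -> list[float]:
        return [fr.macro.f for fr in self.per_fold]

    def mean_per_class(self) -> dict[str, ClassMetrics]:
        out = {}
        for c in self.classes:
            ms = [fr.per_class[c] for fr in self.per_fold]
            out[c] = ClassMetrics(
                sum(m.precision for m in ms) / len(ms),
                sum(m.recall for m in ms) / len(ms),
                sum(m.f for m in ms) / len(ms),
                any(m.flagged for m in ms),
            )
        return out

    def to_tsv(self) -> str:
        """Report table: one row per class plus the macro average."""
        lines = [f"# seed={self.metadata.get('seed')} config={self.metadata.get('config_hash', '')}"]
        lines.append("row\tprecision\trecall\tf_score")
        for c, m in self.mean_per_class().items():
            lines.append(f"{c}\t{m.precision:.4f}\t{m.recall:.4f}\t{m.f:.4f}")
        m = self.mean_macro
        lines.append(f"macro\t{m.precision:.4f}\t{m.recall:.4f}\t{m.f:.4f}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        m = self.mean_macro
        lines = [
            f"{len(self.per_fold)}-fold cross-validation over {sum(fr.n_test for fr in self.per_fold)} tweets",
            f"classes: {', '.join(self.classes)}",
            f"mean macro precision {m.precision:.4f}  recall {m.recall:.4f}  F {m.f:.4f}",
        ]
        for c, cm in self.mean_per_class().items():
            flag = "  (zero-denominator fold flagged)" if cm.flagged else ""
            lines.append(f"  {c:<10} P {cm.precision:.4f}  R {cm.recall:.4f}  F {cm.f:.4f}{flag}")
        for comp in self.comparisons:
            lines.append(
                f"  {comp['pair']}: t={comp['t']:.3f}, one-tailed p={comp['p']:.4f}"
                + ("  [degenerate]" if comp.get("degenerate") else "")
            )
        return "\n".join(lines)


Trainer = Callable[[Sequence[LabeledTweet]], Callable[[Sequence[LabeledTweet]], list[str]]]


def cross_validate(
    corpus: Corpus,
    trainer: Trainer,
    folds: FoldAssignment,
    axis: str,
    classes: Sequence[str] | None = None,
) -> EvalReport:
    """Run K-fold CV: ``trainer(train_items) -> predict_fn(test_items) -> labels``.

    Feature selection and training happen inside ``trainer`` on the training
    folds only; metrics are computed on each held-out fold and aggregated.
    """
    if classes is None:
        classes = sorted(
            {getattr(it, axis) for it in corpus.items if getattr(it, axis) is not None}
        )
    per_fold: list[FoldResult] = []
    for k in range(folds.K):
        train_items = [it for it in corpus.items if folds.fold_of[it.tweet.id] != k]
        test_items = [it for it in corpus.items if folds.fold_of[it.tweet.id] == k]
        train_labels = {getattr(it, axis) for it in train_items}
        if len(train_labels) < 2:
            raise ValueError(f"fold {k}: training data contains a single class")
        predict_fn = trainer(train_items)
        predicted = predict_fn(test_items)
        gold = [getattr(it, axis) for it in test_items]
        per_fold.append(evaluate_predictions(gold, predicted, classes, fold=k))
    mean_macro = ClassMetrics(
        precision=sum(fr.macro.precision for fr in per_fold) / len(per_fold),
        recall=sum(fr.macro.recall for fr in per_fold) / len(per_fold),
        f=sum(fr.macro.f for fr in per_fold) / len(per_fold),
        flagged=any(fr.macro.flagged for fr in per_fold),
    )
    return EvalReport(
        per_fold=per_fold,
        mean_macro=mean_macro,
        classes=tuple(classes),
        metadata={"K": folds.K, "seed": folds.seed, "axis": axis},
    )
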