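"""Metrics, thread-level cross-validation and resampled confidence intervals.

Scores are reported on the percent scale (F = 77.1 means 0.771).  The
cross-validation unit is the *thread*, not the post: the sequence model
reads a post's whole preceding context, so post-level folding would
leak test information into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus import Corpus

__all__ = [
    "Metrics",
    "Interval",
    "precision_recall_f",
    "all_positive_baseline",
    "thread_folds",
    "cross_validate",
    "cv_report",
    "resampled_scores",
    "resampled_ci",
]


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/F for one positive class, percent scale."""

    precision: float
    recall: float
    f: float
    positive: object

    def __iter__(self):
        return iter((self.precision, self.recall, self.f))


@dataclass(frozen=True)
class Interval:
    center: float
    halfwidth: float
    level: float = 0.95

    @property
    def low(self) -> float:
        return self.center - self.halfwidth

    @property
    def high(self) -> float:
        return self.center + self.halfwidth


def precision_recall_f(pred, gold, positive) -> Metrics:
    """Precision, recall and F for the positive class, in percent.

    Zero-division cases (no predicted positives, no gold positives, or
    P + R = 0) yield 0 with a warning.
    """
    pred, gold = list(pred), list(gold)
    if len(pred) != len(gold):
        raise ValueError("prediction and gold sequences differ in length")
    tp = fp = fn = 0
    for p, g in zip(pred, gold):
        if p == positive:
            if g == positive:
                tp += 1
            else:
                fp += 1
        elif g == positive:
            fn += 1
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision set to 0")
        precision = 0.0
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no gold positives; recall set to 0")
        recall = 0.0
    else:
        recall = 100.0 * tp / (tp + fn)
    if precision + recall == 0.0:
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return Metrics(precision, recall, f, positive)


def all_positive_baseline(posts, positive) -> list:
    """The trivial baseline that labels every post as the positive class."""
    return [positive] * len(posts)


def thread_folds(corpus: Corpus, k: int = 5, seed: int = 0) -> list[list[int]]:
    """Partition thread indices into k folds, shuffled by ``seed``."""
    n = len(corpus.threads)
    if n < k:
        raise ValueError(f"need at least {k} threads for {k}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [list(fold) for fold in np.array_split(order, k)]


def cross_validate(
    corpus: Corpus,
    labels: dict,
    model_factory,
    positive,
    k: int = 5,
    seed: int = 0,
    binary: bool = True,
) -> list[Metrics]:
    """Thread-level k-fold cross-validation of a thread classifier.

    ``model_factory()`` must return an unfitted estimator with
    ``fit(threads, labels_dict)`` and ``predict(threads) -> list of
    per-thread label lists``.  Gold labels are collapsed to the binary
    debate view when ``binary`` is true.  Returns per-fold metrics for
    the ``positive`` class.
    """
    from .models import to_binary  # local import to avoid a cycle

    threads = list(corpus.threads)
    folds = thread_folds(corpus, k=k, seed=seed)
    out = []
    for fold in folds:
        test_idx = set(fold)
        train = [t for i, t in enumerate(threads) if i not in test_idx]
        test = [threads[i] for i in fold]
        model = model_factory()
        model.fit(train, labels)
        preds = model.predict(test)
        flat_pred, flat_gold = [], []
        for thread, p in zip(test, preds):
            for post, lab in zip(thread.posts, p):
                gold = labels[post.post_id]
                if binary:
                    gold = to_binary(gold)
                flat_pred.append(lab)
                flat_gold.append(gold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(precision_recall_f(flat_pred, flat_gold, positive))
    return out


def resampled_scores(
    corpus: Corpus,
    labels: dict,
    model_factory,
    positive,
    k: int = 5,
    reruns: int = 5,
    seed: int = 0,
    binary: bool = True,
) -> list[float]:
    """F scores from re-randomized fold assignments: reruns x k values.

    Re-sampling the fold split ``reruns`` times (5 x 5 = 25 scores by
    default) gives the sample the normal-theory confidence interval of
    :func:`resampled_ci` is computed from.
    """
    scores = []
    for r in range(reruns):
        ms = cross_validate(corpus, labels, model_factory, positive,
                            k=k, seed=seed + r, binary=binary)
        scores.extend(m.f for m in ms)
    return scores


def cv_report(
    corpus: Corpus,
    labels: dict,
    model_factory,
    positive,
    csv_path,
    json_path,
    k: int = 5,
    reruns: int = 5,
    seed: int = 0,
    binary: bool = True,
) -> Interval:
    """Run the resampled cross-validation protocol and write reports.

    Writes a CSV with one row per (rerun, fold) — precision, recall, F
    for the positive class — and a summary JSON with the mean F and its
    normal-theory confidence interval over the ``reruns x k`` scores.
    """
    import csv as _csv
    import json as _json

    rows = []
    for r in range(reruns):
        ms = cross_validate(corpus, labels, model_factory, positive,
                            k=k, seed=seed + r, binary=binary)
        for fold, m in enumerate(ms):
            rows.append((r, fold, str(positive), m.precision, m.recall, m.f))
    with open(csv_path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["rerun", "fold", "class", "precision", "recall", "f"])
        for row in rows:
            w.writerow([row[0], row[1], row[2]] +
                       [f"{x:.1f}" for x in row[3:]])
    ci = resampled_ci([row[5] for row in rows])
    with open(json_path, "w") as fh:
        _json.dump({
            "class": str(positive), "k": k, "reruns": reruns,
            "f_mean": round(ci.center, 1),
            "f_halfwidth": round(ci.halfwidth, 1),
            "level": ci.level,
        }, fh, indent=2)
    return ci


def resampled_ci(scores, level: float = 0.95) -> Interval:
    """Normal-assumption confidence interval: mean +/- z * sd / sqrt(n)."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores for an interval")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    center = float(scores.mean())
    halfwidth = z * float(scores.std(ddof=1)) / np.sqrt(scores.size)
    return Interval(center, halfwidth, level)
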