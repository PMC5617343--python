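"""Reference experiment protocols run on synthetic corpora.

These functions bundle the study's evaluation protocol — thread-level
5-fold cross-validation of the sequence model against the
engineered-feature lasso baseline, overfitting sanity checks, and the
trivial all-positive baseline arithmetic — at a problem scale a single
CPU core handles in minutes.  They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np

from .corpus import DebateLabel, Post, StanceLabel, Thread
from .evaluation import cross_validate, precision_recall_f
from .features import FeatureExtractor
from .models import DebateThreadClassifier, FeatureBaselineClassifier, StanceCNNClassifier
from .synthetic import SimConfig, generate_corpus

__all__ = [
    "SMALL_NET",
    "debate_cv_comparison",
    "overfit_instances",
    "overfit_accuracies",
    "all_positive_f",
    "debate_share_percent",
]

#: reduced network/feature dimensions used for the multi-fold
#: comparisons so a full 2 x 5-fold experiment runs in minutes on one
#: core; the architecture (CBOW init -> CNN -> highway -> LSTM) is the
#: full one
SMALL_NET = dict(embedding_dim=16, filter_widths=(2, 3, 4),
                 filters_per_width=16, hidden_dim=16, epochs=6,
                 learning_rate=0.05)
SMALL_FEATURES = dict(d=16, k=10, cbow_iters=8, lda_max_iter=10)


def debate_cv_comparison(gamma: float, seed: int, n_threads: int = 200,
                         debate_rate: float = 0.25, k: int = 5) -> dict:
    """5-fold F of the sequence model vs the lasso baseline.

    Generates a corpus with context-dependence strength ``gamma``,
    trains the unsupervised lexical models once on it, then
    cross-validates both classifiers over the same thread folds on the
    binary debate task.  Returns mean F scores (percent) and the gap.
    """
    cfg = SimConfig(n_threads=n_threads, debate_rate=debate_rate,
                    gamma=gamma, seed=seed)
    corpus, debate_labels, _ = generate_corpus(cfg)
    extractor = FeatureExtractor.fit(corpus, seed=seed, **SMALL_FEATURES)
    emb = extractor.embeddings

    def sequence_factory():
        return DebateThreadClassifier(task="binary", seed=seed,
                                      embedding_init=emb, **SMALL_NET)

    def baseline_factory():
        return FeatureBaselineClassifier(extractor, task="binary",
                                         lam=1.0, seed=seed)

    m_seq = cross_validate(corpus, debate_labels, sequence_factory,
                           positive="DEBATE", k=k, seed=seed)
    m_lr = cross_validate(corpus, debate_labels, baseline_factory,
                          positive="DEBATE", k=k, seed=seed)
    f_seq = float(np.mean([m.f for m in m_seq]))
    f_lr = float(np.mean([m.f for m in m_lr]))
    return {
        "f_sequence": f_seq,
        "f_baseline": f_lr,
        "gap": f_seq - f_lr,
        "n_posts": len(corpus.posts),
        "fold_f_sequence": [m.f for m in m_seq],
        "fold_f_baseline": [m.f for m in m_lr],
    }


def overfit_instances() -> tuple[list[Thread], dict, list[Post], list[StanceLabel]]:
    """Small separable training sets for the memorization sanity check.

    20 debate-task posts in 4 threads (debate posts carry overt
    disagreement phrasing) and 20 stance posts (pro posts carry pro
    lexicon, con posts con lexicon).
    """
    t0 = datetime(2020, 1, 1, tzinfo=timezone.utc)
    threads, labels = [], {}
    i = 0
    for ti in range(4):
        posts = []
        for j in range(5):
            debate = j % 2 == 1
            text = ("i completely disagree that is wrong and dangerous !"
                    if debate else "had a lovely quiet walk this morning")
            pid = f"ov{ti}p{j}"
            posts.append(Post.create(pid, f"ov{ti}", f"u{j % 3}",
                                     t0 + timedelta(minutes=i), text))
            labels[pid] = (DebateLabel.CAM_DEBATE if debate
                           else DebateLabel.NON_DEBATE)
            i += 1
        threads.append(Thread(f"ov{ti}", tuple(posts)))

    stance_posts, stance_y = [], []
    for j in range(20):
        pro = j < 12
        text = ("the supplement really helped me and works wonders"
                if pro else "laetrile is a dangerous scam and useless hoax")
        stance_posts.append(Post.create(f"st{j}", "st", f"u{j % 4}",
                                        t0 + timedelta(minutes=j), text))
        stance_y.append(StanceLabel.PRO_CAM if pro else StanceLabel.CON_CAM)
    return threads, labels, stance_posts, stance_y


def overfit_accuracies(epochs: int = 60, seed: int = 0) -> tuple[float, float]:
    """Training accuracy of both neural models on the separable sets."""
    threads, labels, stance_posts, stance_y = overfit_instances()
    deb = DebateThreadClassifier(task="binary", embedding_dim=8,
                                 filter_widths=(2, 3), filters_per_width=8,
                                 hidden_dim=8, epochs=epochs,
                                 learning_rate=0.1, seed=seed)
    deb.fit(threads, labels)
    preds = deb.predict(threads)
    correct = [
        p == ("DEBATE" if labels[post.post_id].is_debate else "NON_DEBATE")
        for th, ps in zip(threads, preds)
        for post, p in zip(th.posts, ps)
    ]
    acc_debate = float(np.mean(correct))

    st = StanceCNNClassifier(embedding_dim=8, filter_widths=(2, 3),
                             filters_per_width=8, epochs=epochs,
                             learning_rate=0.1, seed=seed)
    st.fit(stance_posts, stance_y)
    acc_stance = float(np.mean([p == g for p, g in
                                zip(st.predict(stance_posts), stance_y)]))
    return acc_debate, acc_stance


def all_positive_f(n_positive: int, n_total: int) -> float:
    """F score (percent) of the always-positive classifier at a given
    class prevalence, computed through the metrics code."""
    gold = [1] * n_positive + [0] * (n_total - n_positive)
    pred = [1] * n_total
    m = precision_recall_f(pred, gold, positive=1)
    return m.f


def debate_share_percent(n_debate: int, n_total: int) -> float:
    """Debate share of a post collection as a percent (one decimal),
    via the all-positive baseline identity precision = prevalence."""
    gold = [1] * n_debate + [0] * (n_total - n_debate)
    m = precision_recall_f([1] * n_total, gold, positive=1)
    return round(m.precision, 1)
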