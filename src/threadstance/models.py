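"""The three classifiers: sequence debate model, stance CNN, lasso baseline.

All are scikit-learn-style estimators (``fit`` / ``predict`` /
``get_params``).  :class:`DebateThreadClassifier` consumes whole
threads, since its label distribution for a post depends on the
preceding posts; :class:`StanceCNNClassifier` classifies posts
independently; :class:`EngineeredLogisticRegression` is an ordinary
tabular classifier over the engineered feature matrix, and
:class:`FeatureBaselineClassifier` adapts it to the thread-level fit
interface so it can be cross-validated head-to-head with the sequence
model.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .corpus import DebateLabel, Post, StanceLabel, Thread
from .features import EmbeddingMatrix, FeatureExtractor, Vocabulary
from .neural_core import DebateNet, NetConfig, StanceNet, sgd_update

__all__ = [
    "DebateThreadClassifier",
    "StanceCNNClassifier",
    "EngineeredLogisticRegression",
    "FeatureBaselineClassifier",
    "save_checkpoint",
    "load_checkpoint",
    "binary_debate_classes",
    "DEBATE_4CLASS",
]

#: class orderings; the conservative class sits first so exact
#: probability ties resolve toward it under argmax
binary_debate_classes = ("NON_DEBATE", "DEBATE")
DEBATE_4CLASS = (
    DebateLabel.NON_DEBATE,
    DebateLabel.CAM_DEBATE,
    DebateLabel.BC_DEBATE,
    DebateLabel.OTHER_DEBATE,
)
STANCE_CLASSES = (StanceLabel.PRO_CAM, StanceLabel.CON_CAM)


def to_binary(label: DebateLabel) -> str:
    return "DEBATE" if label.is_debate else "NON_DEBATE"


def _thread_tokens(thread: Thread) -> list[list[str]]:
    return [p.tokens for p in thread.posts]


def _labels_for_thread(thread: Thread, y) -> list | None:
    """Resolve per-post labels for a thread from a dict or aligned list."""
    if isinstance(y, dict):
        labs = [y.get(p.post_id) for p in thread.posts]
        if all(l is None for l in labs):
            return None
        if any(l is None for l in labs):
            raise ValueError(
                f"thread {thread.thread_id} is only partially labeled; "
                "the sequence model needs the full thread context"
            )
        return labs
    raise TypeError("labels must be a dict post_id -> label")


class _TokenIndexer:
    """Map tokens to embedding-table columns; unknown words to the OOV column."""

    def __init__(self, vocab: Vocabulary):
        self.vocab = vocab
        self.oov_id = len(vocab)

    def __call__(self, tokens: list[str]) -> np.ndarray:
        w2i = self.vocab.word_to_index
        return np.array([w2i.get(t, self.oov_id) for t in tokens], dtype=np.intp)


class DebateThreadClassifier(BaseEstimator):
    """CNN+highway+LSTM sequence labeler for debate detection.

    Trained by backpropagation through time on the negative
    log-likelihood of each thread's label sequence, one thread per SGD
    update.  ``task`` selects the binary debate/non-debate formulation
    or the 4-class typed formulation (two separately trained models).

    Parameters mirror the published configuration by default: 50-dim
    word embeddings initialized from CBOW, 100 filters for each width
    2-5 (400 total), a highway layer, and an LSTM whose hidden size is
    a free choice (default 100).
    """

    def __init__(self, task: str = "binary", embedding_dim: int = 50,
                 filter_widths: tuple[int, ...] = (2, 3, 4, 5),
                 filters_per_width: int = 100, hidden_dim: int = 100,
                 use_highway: bool = True, epochs: int = 30,
                 learning_rate: float = 0.05, clip: float = 5.0,
                 seed: int = 0, embedding_init: EmbeddingMatrix | None = None):
        self.task = task
        self.embedding_dim = embedding_dim
        self.filter_widths = filter_widths
        self.filters_per_width = filters_per_width
        self.hidden_dim = hidden_dim
        self.use_highway = use_highway
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.clip = clip
        self.seed = seed
        self.embedding_init = embedding_init

    @property
    def classes(self):
        if self.task == "binary":
            return binary_debate_classes
        if self.task == "4class":
            return DEBATE_4CLASS
        raise ValueError(f"unknown task {self.task!r}")

    def _encode_labels(self, labels) -> list[int]:
        classes = self.classes
        if self.task == "binary":
            labels = [to_binary(l) if isinstance(l, DebateLabel) else l
                      for l in labels]
        return [classes.index(l) for l in labels]

    def fit(self, X: list[Thread], y) -> "DebateThreadClassifier":
        """Fit on threads ``X`` with per-post labels ``y`` (dict post_id->label)."""
        classes = self.classes
        usable: list[tuple[list[np.ndarray], list[int]]] = []
        token_lists: list[list[str]] = []
        for thread in X:
            labs = _labels_for_thread(thread, y)
            if labs is None:
                warnings.warn(f"thread {thread.thread_id} has no labels; skipped")
                continue
            usable.append((thread, labs))
            token_lists.extend(_thread_tokens(thread))
        if not usable:
            raise ValueError("no labeled threads to train on")

        if self.embedding_init is not None:
            if self.embedding_init.dim != self.embedding_dim:
                raise ValueError("embedding_init dimension mismatch")
            vocab = self.embedding_init.vocab
            emb0 = self.embedding_init.matrix
        else:
            words = sorted({t for toks in token_lists for t in toks})
            vocab = Vocabulary(words)
            emb0 = None
        self.vocab_ = vocab
        self.indexer_ = _TokenIndexer(vocab)

        cfg = NetConfig(
            embedding_dim=self.embedding_dim,
            filter_widths=tuple(self.filter_widths),
            filters_per_width=self.filters_per_width,
            hidden_dim=self.hidden_dim,
            n_classes=len(classes),
            use_highway=self.use_highway,
            seed=self.seed,
        )
        net = DebateNet(cfg, len(vocab), embedding_init=emb0)
        data = [
            ([self.indexer_(toks) for toks in _thread_tokens(th)],
             self._encode_labels(labs))
            for th, labs in usable
        ]
        rng = np.random.default_rng(self.seed)
        trace = []
        for _ in range(self.epochs):
            order = rng.permutation(len(data))
            total = 0.0
            nposts = 0
            for i in order:
                ids, labs = data[i]
                loss, grads = net.loss_and_grads(ids, labs)
                sgd_update(net.params, grads, self.learning_rate, self.clip)
                total += loss
                nposts += len(labs)
            trace.append(total / nposts)
        self.net_ = net
        self.loss_trace_ = trace
        self.classes_ = classes
        return self

    def predict_proba(self, X: list[Thread]) -> list[np.ndarray]:
        """Per-thread arrays of shape (n_posts, n_classes)."""
        out = []
        for thread in X:
            ids = [self.indexer_(toks) for toks in _thread_tokens(thread)]
            if not ids:
                out.append(np.zeros((0, len(self.classes_))))
                continue
            out.append(self.net_.predict_thread(ids))
        return out

    def predict(self, X: list[Thread]) -> list[list]:
        """Per-thread label lists; exact ties resolve to the first class
        (NON_DEBATE)."""
        preds = []
        for probs in self.predict_proba(X):
            preds.append([self.classes_[int(np.argmax(p))] for p in probs])
        return preds


class StanceCNNClassifier(BaseEstimator, ClassifierMixin):
    """CNN post classifier for pro-CAM vs con-CAM stance.

    Same convolutional encoder as the debate model, but each post is
    classified independently by a softmax over the pooled feature
    vector; no thread context is used.
    """

    def __init__(self, embedding_dim: int = 50,
                 filter_widths: tuple[int, ...] = (2, 3, 4, 5),
                 filters_per_width: int = 100, epochs: int = 30,
                 learning_rate: float = 0.05, clip: float = 5.0,
                 seed: int = 0, embedding_init: EmbeddingMatrix | None = None):
        self.embedding_dim = embedding_dim
        self.filter_widths = filter_widths
        self.filters_per_width = filters_per_width
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.clip = clip
        self.seed = seed
        self.embedding_init = embedding_init

    @staticmethod
    def _tokens(x) -> list[str]:
        return x.tokens if isinstance(x, Post) else list(x)

    def fit(self, X, y) -> "StanceCNNClassifier":
        """Fit on posts ``X`` (Post objects or token lists) with stance labels."""
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y differ in length")
        token_lists = [self._tokens(x) for x in X]
        if self.embedding_init is not None:
            vocab = self.embedding_init.vocab
            emb0 = self.embedding_init.matrix
        else:
            vocab = Vocabulary(sorted({t for toks in token_lists for t in toks}))
            emb0 = None
        self.vocab_ = vocab
        self.indexer_ = _TokenIndexer(vocab)
        cfg = NetConfig(
            embedding_dim=self.embedding_dim,
            filter_widths=tuple(self.filter_widths),
            filters_per_width=self.filters_per_width,
            n_classes=2,
            use_highway=False,
            seed=self.seed,
        )
        net = StanceNet(cfg, len(vocab), embedding_init=emb0)
        ids = [self.indexer_(toks) for toks in token_lists]
        labs = [STANCE_CLASSES.index(l) for l in y]
        rng = np.random.default_rng(self.seed)
        trace = []
        for _ in range(self.epochs):
            order = rng.permutation(len(ids))
            total = 0.0
            for i in order:
                loss, grads = net.loss_and_grads(ids[i], labs[i])
                sgd_update(net.params, grads, self.learning_rate, self.clip)
                total += loss
            trace.append(total / len(ids))
        self.net_ = net
        self.loss_trace_ = trace
        self.classes_ = STANCE_CLASSES
        return self

    def predict_proba(self, X) -> np.ndarray:
        return np.array([
            self.net_.predict_post(self.indexer_(self._tokens(x))) for x in X
        ])

    def predict(self, X) -> list[StanceLabel]:
        """Stance per post; an exact tie resolves to PRO_CAM (majority class)."""
        probs = self.predict_proba(X)
        return [self.classes_[int(np.argmax(p))] for p in probs]


class EngineeredLogisticRegression(BaseEstimator, ClassifierMixin):
    """L1-penalized (lasso) logistic regression over engineered features.

    Features are z-scored with training statistics before the penalty is
    applied.  ``lam`` is the lasso strength on the summed log-loss; when
    ``None`` it is chosen by an inner stratified cross-validated grid.
    """

    def __init__(self, lam: float | None = None, cv: int = 3,
                 grid: tuple[float, ...] = tuple(np.logspace(-3, 2, 11)),
                 tol: float = 1e-8, max_iter: int = 20000, seed: int = 0):
        self.lam = lam
        self.cv = cv
        self.grid = grid
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def _fit_one(self, X, y, lam: float) -> LogisticRegression:
        # sklearn's C multiplies the data term: loss = C * sum_logloss + |w|_1
        C = 1.0 / max(lam, 1e-12)
        clf = LogisticRegression(
            penalty="l1", C=C, solver="saga", tol=self.tol,
            max_iter=self.max_iter, random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        return clf

    def fit(self, X, y) -> "EngineeredLogisticRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels are constant; cannot fit")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        if self.lam is not None:
            lam = float(self.lam)
        else:
            skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                                  random_state=self.seed)
            best, lam = -np.inf, float(self.grid[0])
            for cand in self.grid:
                accs = []
                for tr, te in skf.split(Xs, y):
                    clf = self._fit_one(Xs[tr], y[tr], cand)
                    accs.append(clf.score(Xs[te], y[te]))
                score = float(np.mean(accs))
                if score > best:
                    best, lam = score, float(cand)
        self.lam_ = lam
        self.model_ = self._fit_one(Xs, y, lam)
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        return self

    def predict(self, X):
        return self.model_.predict(self.scaler_.transform(np.asarray(X, float)))

    def predict_proba(self, X):
        return self.model_.predict_proba(self.scaler_.transform(np.asarray(X, float)))


class FeatureBaselineClassifier(BaseEstimator):
    """Thread-level adapter putting the lasso baseline behind the same
    fit/predict-on-threads interface as the sequence model.

    The unsupervised lexical models inside ``extractor`` are trained
    once on the unlabeled corpus; only the supervised logistic
    regression is (re-)fitted per training set.
    """

    def __init__(self, extractor: FeatureExtractor, task: str = "binary",
                 lam: float | None = None, seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 5000):
        self.extractor = extractor
        self.task = task
        self.lam = lam
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter

    def _map_labels(self, labels):
        if self.task == "binary":
            return [to_binary(l) if isinstance(l, DebateLabel) else l
                    for l in labels]
        return [l.value for l in labels]

    def fit(self, X: list[Thread], y) -> "FeatureBaselineClassifier":
        rows, labs = [], []
        for thread in X:
            thread_labs = _labels_for_thread(thread, y)
            if thread_labs is None:
                continue
            rows.append(self.extractor.transform_thread(thread))
            labs.extend(self._map_labels(thread_labs))
        if not rows:
            raise ValueError("no labeled threads to train on")
        self.lr_ = EngineeredLogisticRegression(lam=self.lam, seed=self.seed,
                                                tol=self.tol,
                                                max_iter=self.max_iter)
        self.lr_.fit(np.vstack(rows), np.array(labs))
        self.classes_ = tuple(self.lr_.classes_)
        return self

    def predict(self, X: list[Thread]) -> list[list]:
        out = []
        for thread in X:
            preds = self.lr_.predict(self.extractor.transform_thread(thread))
            labels = list(preds)
            if self.task == "4class":
                labels = [DebateLabel(l) for l in labels]
            out.append(labels)
        return out

    def predict_proba(self, X: list[Thread]) -> list[np.ndarray]:
        return [self.lr_.predict_proba(self.extractor.transform_thread(t))
                for t in X]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model) -> None:
    """Serialize a fitted model: named arrays + JSON manifest."""
    if isinstance(model, FeatureBaselineClassifier):
        _save_feature_lr(path, model)
        return
    if isinstance(model, DebateThreadClassifier):
        kind = "debate"
        extra = {"task": model.task, "hidden_dim": model.hidden_dim,
                 "use_highway": model.use_highway}
    elif isinstance(model, StanceCNNClassifier):
        kind = "stance"
        extra = {}
    else:
        raise TypeError("unsupported model type for checkpointing")
    manifest = {
        "kind": kind,
        "embedding_dim": model.embedding_dim,
        "filter_widths": list(model.filter_widths),
        "filters_per_width": model.filters_per_width,
        "seed": model.seed,
        "epochs": model.epochs,
        "learning_rate": model.learning_rate,
        "vocab": model.vocab_.index_to_word,
        **extra,
    }
    with open(path, "wb") as fh:  # keep the exact filename (no .npz suffix)
        np.savez(fh, __manifest__=np.array(json.dumps(manifest)),
                 **model.net_.params)


def _save_feature_lr(path, model: FeatureBaselineClassifier) -> None:
    lr = model.lr_
    ex = model.extractor
    manifest = {
        "kind": "feature_lr",
        "task": model.task,
        "lam": lr.lam_,
        "classes": [str(c) for c in lr.classes_],
        "emb_vocab": ex.embeddings.vocab.index_to_word,
        "lda_vocab": ex.topics.vocab.index_to_word,
        "lda_hyper": [ex.topics.k, ex.topics.alpha, ex.topics.beta,
                      ex.topics.em_iters],
    }
    with open(path, "wb") as fh:
        np.savez(fh, __manifest__=np.array(json.dumps(manifest)),
                 coef=lr.coef_, intercept=lr.intercept_,
                 scaler_mean=lr.scaler_.mean_, scaler_scale=lr.scaler_.scale_,
                 topic_word=ex.topics.topic_word,
                 emb_matrix=ex.embeddings.matrix)


def _load_feature_lr(manifest, params) -> FeatureBaselineClassifier:
    from .features import TopicModel

    topics = TopicModel(
        int(manifest["lda_hyper"][0]), float(manifest["lda_hyper"][1]),
        float(manifest["lda_hyper"][2]), Vocabulary(manifest["lda_vocab"]),
        params["topic_word"], em_iters=int(manifest["lda_hyper"][3]))
    emb = EmbeddingMatrix(params["emb_matrix"], Vocabulary(manifest["emb_vocab"]))
    extractor = FeatureExtractor(topics, emb)
    model = FeatureBaselineClassifier(extractor, task=manifest["task"],
                                      lam=manifest["lam"])
    inner = EngineeredLogisticRegression(lam=manifest["lam"])
    skl = LogisticRegression(penalty="l1", solver="saga")
    skl.coef_ = params["coef"]
    skl.intercept_ = params["intercept"]
    skl.classes_ = np.array(manifest["classes"])
    scaler = StandardScaler()
    scaler.mean_ = params["scaler_mean"]
    scaler.scale_ = params["scaler_scale"]
    inner.model_ = skl
    inner.scaler_ = scaler
    inner.classes_ = skl.classes_
    inner.coef_ = skl.coef_
    inner.intercept_ = skl.intercept_
    inner.lam_ = manifest["lam"]
    model.lr_ = inner
    model.classes_ = tuple(skl.classes_)
    return model


def load_checkpoint(path):
    """Restore a model saved by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["__manifest__"]))
        params = {k: data[k] for k in data.files if k != "__manifest__"}
    if manifest["kind"] == "feature_lr":
        return _load_feature_lr(manifest, params)
    vocab = Vocabulary(manifest["vocab"])
    common = dict(
        embedding_dim=manifest["embedding_dim"],
        filter_widths=tuple(manifest["filter_widths"]),
        filters_per_width=manifest["filters_per_width"],
        seed=manifest["seed"],
        epochs=manifest["epochs"],
        learning_rate=manifest["learning_rate"],
    )
    if manifest["kind"] == "debate":
        model = DebateThreadClassifier(
            task=manifest["task"], hidden_dim=manifest["hidden_dim"],
            use_highway=manifest["use_highway"], **common)
        cfg = NetConfig(
            embedding_dim=model.embedding_dim,
            filter_widths=tuple(model.filter_widths),
            filters_per_width=model.filters_per_width,
            hidden_dim=model.hidden_dim,
            n_classes=len(model.classes),
            use_highway=model.use_highway,
            seed=model.seed,
        )
        net = DebateNet(cfg, len(vocab))
    else:
        model = StanceCNNClassifier(**common)
        cfg = NetConfig(
            embedding_dim=model.embedding_dim,
            filter_widths=tuple(model.filter_widths),
            filters_per_width=model.filters_per_width,
            n_classes=2, use_highway=False, seed=model.seed,
        )
        net = StanceNet(cfg, len(vocab))
        model.classes_ = STANCE_CLASSES
    net.params.update(params)
    # rebind layer views onto the freshly loaded arrays
    for layer in ("encoder", "highway", "lstm"):
        obj = getattr(net, layer, None)
        if obj is not None:
            obj.params = net.params
    model.net_ = net
    model.vocab_ = vocab
    model.indexer_ = _TokenIndexer(vocab)
    if manifest["kind"] == "debate":
        model.classes_ = model.classes
    return model
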