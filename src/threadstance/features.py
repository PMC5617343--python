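"""Engineered features and the lexical models behind them.

The logistic-regression baseline represents each post by three blocks:

* thread-level features (NumPost, NumUser, AvgLen),
* post-level features (author-name mentions, sentiment keyword counts,
  CAM keyword counts, overlap with the previous post, punctuation,
  time gap, signature flag, agree/disagree counts), and
* lexical features (LDA topic proportions, CBOW embedding averages and
  cosine similarities with the previous post).

Keyword inventories are shipped as plain-text data files; morphological
variants of the sentiment adjectives are expanded by a fixed suffix
table at load time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation

from .corpus import Corpus, Post, Thread

__all__ = [
    "Vocabulary",
    "EmbeddingMatrix",
    "TopicModel",
    "thread_features",
    "post_features",
    "lexical_features",
    "train_cbow",
    "train_lda",
    "FeatureExtractor",
    "load_word_list",
    "POSITIVE_WORDS",
    "NEGATIVE_WORDS",
    "CAM_KEYWORDS",
    "STOPWORDS",
]


def load_word_list(name: str) -> list[str]:
    """Load a one-term-per-line data file shipped with the package."""
    text = importlib.resources.files("threadstance.data").joinpath(name).read_text()
    return [w.strip() for w in text.splitlines() if w.strip()]


def _morph_variants(words: list[str]) -> frozenset[str]:
    # fixed suffix table: -s / -ly forms plus the -ed <-> -ing swap
    out: set[str] = set()
    for w in words:
        out.add(w)
        out.add(w + "s")
        out.add(w + "ly")
        if w.endswith("ed"):
            out.add(w[:-2] + "ing")
        if w.endswith("ing"):
            out.add(w[:-3] + "ed")
    return frozenset(out)


POSITIVE_WORDS = _morph_variants(load_word_list("positive_words.txt"))
NEGATIVE_WORDS = _morph_variants(load_word_list("negative_words.txt"))
CAM_KEYWORDS = frozenset(load_word_list("cam_keywords.txt"))
STOPWORDS = frozenset(load_word_list("stopwords.txt"))

_PUNCT = {"?", "!", ",", ";", ":"}
_NEGATORS = {"not", "don't", "dont", "never", "cannot", "can't"}
_AGREE = {"agree", "agrees", "agreed", "agreeing"}
_DISAGREE = {"disagree", "disagrees", "disagreed", "disagreeing"}

#: TimeDif is clipped here so single huge gaps do not dominate scaling.
TIMEDIF_CLIP_SECONDS = 30 * 86400


# ---------------------------------------------------------------------------
# Vocabulary and embeddings
# ---------------------------------------------------------------------------


class Vocabulary:
    """Bijective word <-> contiguous-index map."""

    def __init__(self, words: list[str]):
        self.index_to_word = list(words)
        self.word_to_index = {w: i for i, w in enumerate(words)}
        if len(self.word_to_index) != len(self.index_to_word):
            raise ValueError("duplicate words in vocabulary")

    def __len__(self) -> int:
        return len(self.index_to_word)

    def __contains__(self, word: str) -> bool:
        return word in self.word_to_index

    def __getitem__(self, word: str) -> int:
        return self.word_to_index[word]

    @staticmethod
    def from_corpus(corpus: Corpus, min_count: int = 1) -> "Vocabulary":
        counts: dict[str, int] = {}
        for post in corpus.posts:
            for tok in post.tokens:
                counts[tok] = counts.get(tok, 0) + 1
        words = sorted(w for w, c in counts.items() if c >= min_count)
        return Vocabulary(words)


@dataclass
class EmbeddingMatrix:
    """Word embeddings: one column of ``matrix`` (shape d x |V|) per word."""

    matrix: np.ndarray
    vocab: Vocabulary

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.vocab):
            raise ValueError("embedding matrix / vocabulary size mismatch")

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[0])

    def vector(self, word: str) -> np.ndarray | None:
        i = self.vocab.word_to_index.get(word)
        return None if i is None else self.matrix[:, i]

    def mean_vector(self, tokens: list[str]) -> np.ndarray:
        """Mean embedding of the known tokens; zero vector if none known."""
        cols = [self.vocab.word_to_index[t] for t in tokens if t in self.vocab]
        if not cols:
            return np.zeros(self.dim)
        return self.matrix[:, cols].mean(axis=1)

    def save(self, path) -> None:
        """Serialize in the de-facto whitespace text format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vocab)} {self.dim}\n")
            for i, w in enumerate(self.vocab.index_to_word):
                vec = " ".join(repr(float(x)) for x in self.matrix[:, i])
                fh.write(f"{w} {vec}\n")

    @staticmethod
    def load(path) -> "EmbeddingMatrix":
        with open(path) as fh:
            n, d = (int(x) for x in fh.readline().split())
            words, cols = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                cols.append([float(x) for x in parts[1:]])
        mat = np.array(cols, dtype=float).T
        if mat.shape != (d, n):
            raise ValueError("embedding file shape mismatch")
        return EmbeddingMatrix(mat, Vocabulary(words))


def train_cbow(
    corpus: Corpus,
    d: int = 50,
    iters: int = 100,
    seed: int = 0,
    window: int = 5,
    negative: int = 5,
    lr: float = 0.05,
) -> EmbeddingMatrix:
    """Train continuous-bag-of-words embeddings with negative sampling.

    For each position the mean of the context word vectors predicts the
    center word against ``negative`` noise words drawn from the unigram
    distribution raised to 3/4.  Single-threaded SGD with a linearly
    decaying learning rate; deterministic for a fixed seed.
    """
    if len(corpus.threads) == 0:
        raise ValueError("empty corpus")
    vocab = Vocabulary.from_corpus(corpus)
    if len(vocab) == 0:
        raise ValueError("corpus has no tokens")
    sentences = [
        np.array([vocab[t] for t in sent], dtype=np.intp)
        for post in corpus.posts
        for sent in post.sentences
        if sent
    ]
    counts = np.zeros(len(vocab))
    for s in sentences:
        np.add.at(counts, s, 1.0)
    noise = counts**0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    w_in = (rng.random((len(vocab), d)) - 0.5) / d
    w_out = np.zeros((len(vocab), d))

    total_steps = max(1, iters * len(sentences))
    step = 0
    for epoch in range(iters):
        for sent in sentences:
            step += 1
            alpha = lr * max(1e-4, 1.0 - step / total_steps)
            n = len(sent)
            if n < 2:
                continue
            for pos in range(n):
                lo, hi = max(0, pos - window), min(n, pos + window + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1 : hi]])
                if ctx.size == 0:
                    continue
                hvec = w_in[ctx].mean(axis=0)
                targets = np.concatenate(
                    [[sent[pos]], rng.choice(len(vocab), size=negative, p=noise)]
                )
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                scores = w_out[targets] @ hvec
                g = (labels - 1.0 / (1.0 + np.exp(-scores))) * alpha
                dh = g @ w_out[targets]
                np.add.at(w_out, targets, np.outer(g, hvec))
                w_in[ctx] += dh / ctx.size
    return EmbeddingMatrix(w_in.T.copy(), vocab)


# ---------------------------------------------------------------------------
# Topic model
# ---------------------------------------------------------------------------


@dataclass
class TopicModel:
    """LDA topic model over post-level bags of content words.

    ``topic_word`` rows are normalized per-topic word distributions.
    Defaults follow the study configuration: 15 topics, document-topic
    prior alpha=0.5, topic-word prior beta=0.05.  Inference for a new
    post runs a fixed 50-iteration EM over the frozen topic-word
    matrix, so the model is fully defined by its arrays.
    """

    k: int
    alpha: float
    beta: float
    vocab: Vocabulary
    topic_word: np.ndarray
    em_iters: int = 50

    def topic_proportions(self, tokens: list[str]) -> np.ndarray:
        """Infer topic proportions for one post (normalized k-vector)."""
        ids, counts = [], []
        seen: dict[int, int] = {}
        for t in tokens:
            i = self.vocab.word_to_index.get(t)
            if i is not None:
                seen[i] = seen.get(i, 0) + 1
        if not seen:
            return np.full(self.k, 1.0 / self.k)
        ids = np.array(list(seen.keys()), dtype=np.intp)
        counts = np.array(list(seen.values()), dtype=float)
        beta_w = self.topic_word[:, ids].T  # (n_words, k)
        theta = np.full(self.k, 1.0 / self.k)
        n = counts.sum()
        for _ in range(self.em_iters):
            phi = beta_w * theta  # responsibilities
            phi /= np.maximum(phi.sum(axis=1, keepdims=True), 1e-300)
            theta = (counts @ phi + self.alpha) / (n + self.k * self.alpha)
        return theta / theta.sum()

    def top_words(self, topic: int, n: int = 10) -> list[str]:
        order = np.argsort(-self.topic_word[topic])[:n]
        return [self.vocab.index_to_word[i] for i in order]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            np.savez(fh, topic_word=self.topic_word,
                     hyper=np.array([self.k, self.alpha, self.beta,
                                     self.em_iters]),
                     vocab=np.array(self.vocab.index_to_word))

    @staticmethod
    def load(path) -> "TopicModel":
        with np.load(path, allow_pickle=False) as data:
            k, alpha, beta, em = data["hyper"]
            return TopicModel(int(k), float(alpha), float(beta),
                              Vocabulary([str(w) for w in data["vocab"]]),
                              data["topic_word"], em_iters=int(em))


def train_lda(
    corpus: Corpus,
    k: int = 15,
    alpha: float = 0.5,
    beta: float = 0.05,
    seed: int = 0,
    max_iter: int = 20,
) -> TopicModel:
    """Fit LDA (variational Bayes) on per-post bags of non-stopword tokens."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(corpus.threads) == 0:
        raise ValueError("empty corpus")
    vocab = Vocabulary.from_corpus(corpus)
    docs = np.zeros((len(corpus.posts), len(vocab)))
    for i, post in enumerate(corpus.posts):
        for t in post.tokens:
            if t in STOPWORDS or t in _PUNCT:
                continue
            docs[i, vocab[t]] += 1
    lda = LatentDirichletAllocation(
        n_components=k,
        doc_topic_prior=alpha,
        topic_word_prior=beta,
        max_iter=max_iter,
        random_state=seed,
    )
    lda.fit(docs)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(k=k, alpha=alpha, beta=beta, vocab=vocab,
                      topic_word=topic_word)


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------


def thread_features(thread: Thread) -> tuple[int, int, float]:
    """(NumPost, NumUser, AvgLen) for a thread."""
    if len(thread) == 0:
        raise ValueError("empty thread")
    num_post = len(thread)
    num_user = len(thread.participants)
    avg_len = float(np.mean([len(p.tokens) for p in thread.posts]))
    return num_post, num_user, avg_len


def _content_tokens(post: Post) -> list[str]:
    return [t for t in post.tokens
            if t not in STOPWORDS and t not in _PUNCT]


def post_features(
    post: Post, prev_post: Post | None, thread: Thread
) -> dict[str, float]:
    """The eleven post-level features of one post within its thread."""
    tokens = post.tokens
    others = {a.lower() for a in thread.participants if a != post.author_id}

    num_name = sum(1 for t in tokens if t in others)
    num_pos = sum(1 for t in tokens if t in POSITIVE_WORDS)
    num_neg = sum(1 for t in tokens if t in NEGATIVE_WORDS)
    num_cam = sum(1 for t in tokens if t in CAM_KEYWORDS)
    num_q = tokens.count("?")
    num_x = tokens.count("!")

    n_agree = 0
    n_disagree = 0
    for i, t in enumerate(tokens):
        if t in _DISAGREE:
            n_disagree += 1
        elif t in _AGREE:
            negated = any(u in _NEGATORS for u in tokens[max(0, i - 2) : i])
            if negated:
                n_disagree += 1
            else:
                n_agree += 1

    if prev_post is None:
        num_overlap = 0
        time_dif = 0.0
    else:
        cur = _content_tokens(post)
        prev = _content_tokens(prev_post)
        prev_counts: dict[str, int] = {}
        for t in prev:
            prev_counts[t] = prev_counts.get(t, 0) + 1
        cur_counts: dict[str, int] = {}
        for t in cur:
            cur_counts[t] = cur_counts.get(t, 0) + 1
        num_overlap = sum(
            min(c, prev_counts.get(t, 0)) for t, c in cur_counts.items()
        )
        time_dif = (post.timestamp - prev_post.timestamp).total_seconds()
        time_dif = float(min(max(time_dif, 0.0), TIMEDIF_CLIP_SECONDS))

    return {
        "NumName": float(num_name),
        "NumNeg": float(num_neg),
        "NumPos": float(num_pos),
        "NumCAM": float(num_cam),
        "NumOverlap": float(num_overlap),
        "Num?": float(num_q),
        "Num!": float(num_x),
        "TimeDif": time_dif,
        "Sig": 1.0 if post.has_signature else 0.0,
        "NAgree": float(n_agree),
        "NDisagree": float(n_disagree),
    }


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def lexical_features(
    post: Post,
    prev_post: Post | None,
    topics: TopicModel,
    emb: EmbeddingMatrix,
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """(LDA, LDA-sim, W2V, W2V-sim) for one post.

    LDA is the inferred topic-proportion vector, W2V the mean token
    embedding; the similarity features are the cosine with the previous
    post's corresponding vector, 0 for the first post of a thread or
    when either vector is zero.
    """
    lda = topics.topic_proportions(post.tokens)
    w2v = emb.mean_vector(post.tokens)
    if prev_post is None:
        return lda, 0.0, w2v, 0.0
    lda_prev = topics.topic_proportions(prev_post.tokens)
    w2v_prev = emb.mean_vector(prev_post.tokens)
    return lda, _cosine(lda, lda_prev), w2v, _cosine(w2v, w2v_prev)


class FeatureExtractor:
    """Extract the full engineered feature matrix for a corpus.

    The lexical models (LDA, CBOW) are unsupervised and trained once on
    the full corpus; `transform` then produces one named feature row per
    post, in thread order.
    """

    def __init__(self, topics: TopicModel, embeddings: EmbeddingMatrix):
        self.topics = topics
        self.embeddings = embeddings
        # thread feature rows are deterministic; cache for reuse across
        # cross-validation folds
        self._cache: dict[str, np.ndarray] = {}

    @staticmethod
    def fit(corpus: Corpus, d: int = 50, k: int = 15, seed: int = 0,
            cbow_iters: int = 100, lda_max_iter: int = 20) -> "FeatureExtractor":
        emb = train_cbow(corpus, d=d, iters=cbow_iters, seed=seed)
        topics = train_lda(corpus, k=k, seed=seed, max_iter=lda_max_iter)
        return FeatureExtractor(topics, emb)

    @property
    def feature_names(self) -> list[str]:
        names = ["NumPost", "NumUser", "AvgLen",
                 "NumName", "NumNeg", "NumPos", "NumCAM", "NumOverlap",
                 "Num?", "Num!", "TimeDif", "Sig", "NAgree", "NDisagree"]
        names += [f"LDA{i}" for i in range(self.topics.k)]
        names += ["LDA-sim"]
        names += [f"W2V{i}" for i in range(self.embeddings.dim)]
        names += ["W2V-sim"]
        return names

    def transform_thread(self, thread: Thread) -> np.ndarray:
        cached = self._cache.get(thread.thread_id)
        if cached is not None:
            return cached
        tf = thread_features(thread)
        rows = []
        # infer topic/embedding vectors once per post, reuse for the
        # similarity with the following post
        lda_vecs = [self.topics.topic_proportions(p.tokens) for p in thread.posts]
        w2v_vecs = [self.embeddings.mean_vector(p.tokens) for p in thread.posts]
        for i, post in enumerate(thread.posts):
            prev = thread.posts[i - 1] if i > 0 else None
            pf = post_features(post, prev, thread)
            lda_sim = _cosine(lda_vecs[i], lda_vecs[i - 1]) if i > 0 else 0.0
            w2v_sim = _cosine(w2v_vecs[i], w2v_vecs[i - 1]) if i > 0 else 0.0
            row = np.concatenate([
                np.array(tf, dtype=float),
                np.array([pf[n] for n in
                          ["NumName", "NumNeg", "NumPos", "NumCAM",
                           "NumOverlap", "Num?", "Num!", "TimeDif", "Sig",
                           "NAgree", "NDisagree"]]),
                lda_vecs[i], [lda_sim], w2v_vecs[i], [w2v_sim],
            ])
            rows.append(row)
        out = np.array(rows)
        self._cache[thread.thread_id] = out
        return out

    def transform(self, corpus: Corpus) -> tuple[np.ndarray, list[str]]:
        """Feature matrix over all posts (thread order) + post_id list."""
        mats, pids = [], []
        for thread in corpus:
            mats.append(self.transform_thread(thread))
            pids.extend(p.post_id for p in thread.posts)
        return np.vstack(mats), pids

    def to_dataframe(self, corpus: Corpus):
        import pandas as pd

        X, pids = self.transform(corpus)
        df = pd.DataFrame(X, columns=self.feature_names)
        df.insert(0, "post_id", pids)
        return df
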