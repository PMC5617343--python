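"""Threaded forum corpora: domain types, preprocessing, I/O and sampling.

A corpus is a collection of discussion threads; a thread is a
time-ordered sequence of posts by community members.  Debate detection
operates on the post sequence of a thread, so thread membership and
ordering are part of the data contract, not an afterthought.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DebateLabel",
    "StanceLabel",
    "Post",
    "Thread",
    "Corpus",
    "preprocess_post",
    "read_corpus",
    "write_corpus",
    "read_labels",
    "write_labels",
    "sample_for_coding",
    "cohens_kappa",
]


class DebateLabel(Enum):
    """Per-post debate annotation.

    The binary task collapses the three debate types to a single DEBATE
    class; :meth:`is_debate` gives that view.
    """

    NON_DEBATE = "NON_DEBATE"
    CAM_DEBATE = "CAM_DEBATE"
    BC_DEBATE = "BC_DEBATE"
    OTHER_DEBATE = "OTHER_DEBATE"

    @property
    def is_debate(self) -> bool:
        return self is not DebateLabel.NON_DEBATE


class StanceLabel(Enum):
    """Stance toward CAM usage; defined only for CAM-debate posts."""

    PRO_CAM = "PRO_CAM"
    CON_CAM = "CON_CAM"


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

#: Emoticon inventory: fixed table mapping surface forms to code tokens.
EMOTICONS: dict[str, str] = {
    ":-)": "EMO_SMILE",
    ":)": "EMO_SMILE",
    "(:": "EMO_SMILE",
    ":-(": "EMO_FROWN",
    ":(": "EMO_FROWN",
    ";-)": "EMO_WINK",
    ";)": "EMO_WINK",
    ":-D": "EMO_GRIN",
    ":D": "EMO_GRIN",
    ":-P": "EMO_TONGUE",
    ":P": "EMO_TONGUE",
    ":'(": "EMO_CRY",
    "<3": "EMO_HEART",
}

_EMO_PATTERN = re.compile(
    "|".join(re.escape(k) for k in sorted(EMOTICONS, key=len, reverse=True))
)

#: Abbreviations that end with a period but do not end a sentence.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st", "vs", "etc", "e.g", "i.e",
    "approx", "dept", "est", "jan", "feb", "mar", "apr", "jun", "jul",
    "aug", "sep", "sept", "oct", "nov", "dec",
}

# Sentence boundary: terminal punctuation, whitespace, then an upper-case
# letter or an opening quote.  The guard against abbreviations is applied
# separately because variable-width lookbehind is not supported.
_BOUNDARY = re.compile(r"([.?!]+)\s+(?=[A-Z\"'(])")

# Word tokens keep internal apostrophes ("don't"); question/exclamation
# marks and commas survive as their own tokens because the engineered
# features count them.  Periods are dropped.
_TOKEN = re.compile(r"EMO_[A-Z]+|[a-z0-9]+(?:'[a-z0-9]+)*|[?!,;:]", re.IGNORECASE)


def _split_sentences(text: str) -> list[str]:
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        # guard: "Dr. Smith" must not split
        prefix = text[start : m.start(1)]
        last_word = re.findall(r"[A-Za-z.]+$", prefix)
        if m.group(1) == "." and last_word:
            w = last_word[0].lower().rstrip(".")
            if w in _ABBREVIATIONS or len(w) == 1:
                continue
        sentences.append(text[start : m.end(1)])
        start = m.end()
    tail = text[start:]
    if tail.strip():
        sentences.append(tail)
    return sentences


def preprocess_post(raw_text: str) -> list[list[str]]:
    """Normalize raw post text into sentences of lower-cased tokens.

    Emoticons are replaced by ``EMO_*`` code tokens, other non-ASCII
    content is stripped, sentences are split on terminal punctuation
    followed by a capitalized continuation (with an abbreviation guard),
    and each sentence is tokenized.  ``?``/``!``/``,`` survive as tokens;
    sentence-final periods are dropped.  Deterministic; empty or
    non-textual input yields ``[]``.
    """
    if not raw_text:
        return []
    text = _EMO_PATTERN.sub(lambda m: " %s " % EMOTICONS[m.group(0)], raw_text)
    text = text.encode("ascii", errors="ignore").decode("ascii")
    text = re.sub(r"\s+", " ", text).strip()
    if not text:
        return []
    sentences = []
    for sent in _split_sentences(text):
        tokens = [
            t if t.startswith("EMO_") else t.lower()
            for t in _TOKEN.findall(sent)
        ]
        if tokens:
            sentences.append(tokens)
    return sentences


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Post:
    """A single forum post with its preprocessed token content."""

    post_id: str
    thread_id: str
    author_id: str
    timestamp: datetime
    raw_text: str
    sentences: tuple[tuple[str, ...], ...] = field(default=())
    has_signature: bool = False

    @staticmethod
    def create(
        post_id: str,
        thread_id: str,
        author_id: str,
        timestamp: datetime | str,
        raw_text: str,
        has_signature: bool = False,
    ) -> "Post":
        """Build a post, applying :func:`preprocess_post` to ``raw_text``."""
        if isinstance(timestamp, str):
            timestamp = datetime.fromisoformat(timestamp)
        if timestamp.tzinfo is None:
            timestamp = timestamp.replace(tzinfo=timezone.utc)
        sentences = tuple(tuple(s) for s in preprocess_post(raw_text))
        return Post(post_id, thread_id, author_id, timestamp, raw_text,
                    sentences, has_signature)

    @property
    def tokens(self) -> list[str]:
        """All tokens of the post, sentence boundaries flattened."""
        return [t for sent in self.sentences for t in sent]


@dataclass(frozen=True)
class Thread:
    """An ordered post sequence; the unit the sequence model runs over."""

    thread_id: str
    posts: tuple[Post, ...]

    def __post_init__(self) -> None:
        for p in self.posts:
            if p.thread_id != self.thread_id:
                raise ValueError(
                    f"post {p.post_id} has thread_id {p.thread_id!r}, "
                    f"expected {self.thread_id!r}"
                )
        ordered = tuple(sorted(self.posts, key=lambda p: (p.timestamp, p.post_id)))
        object.__setattr__(self, "posts", ordered)

    def __len__(self) -> int:
        return len(self.posts)

    @property
    def participants(self) -> set[str]:
        return {p.author_id for p in self.posts}


@dataclass(frozen=True)
class Corpus:
    """A collection of threads with unique ids."""

    threads: tuple[Thread, ...]

    def __post_init__(self) -> None:
        ids = [t.thread_id for t in self.threads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate thread_id in corpus")

    def __len__(self) -> int:
        return len(self.threads)

    def __iter__(self):
        return iter(self.threads)

    @property
    def posts(self) -> list[Post]:
        return [p for t in self.threads for p in t.posts]

    def thread(self, thread_id: str) -> Thread:
        for t in self.threads:
            if t.thread_id == thread_id:
                return t
        raise KeyError(thread_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSONL corpus (one post object per line) into a :class:`Corpus`.

    Required fields per line: ``post_id``, ``thread_id``, ``author_id``,
    ``timestamp`` (ISO-8601; naive timestamps are taken as UTC), ``text``.
    Optional: ``has_signature``.  Posts are grouped by thread and sorted
    by timestamp (ties broken by post_id).  Malformed lines and duplicate
    post ids raise ``ValueError`` naming the offending line.
    """
    path = Path(path)
    by_thread: dict[str, list[Post]] = {}
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                post = Post.create(
                    post_id=str(obj["post_id"]),
                    thread_id=str(obj["thread_id"]),
                    author_id=str(obj["author_id"]),
                    timestamp=obj["timestamp"],
                    raw_text=obj["text"],
                    has_signature=bool(obj.get("has_signature", False)),
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed post line: {exc}") from exc
            if post.post_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate post_id {post.post_id!r}")
            seen.add(post.post_id)
            by_thread.setdefault(post.thread_id, []).append(post)
    threads = tuple(
        Thread(tid, tuple(posts)) for tid, posts in by_thread.items()
    )
    return Corpus(threads)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to JSONL (inverse of :func:`read_corpus`)."""
    with Path(path).open("w") as fh:
        for thread in corpus:
            for p in thread.posts:
                fh.write(json.dumps({
                    "post_id": p.post_id,
                    "thread_id": p.thread_id,
                    "author_id": p.author_id,
                    "timestamp": p.timestamp.isoformat(),
                    "text": p.raw_text,
                    "has_signature": p.has_signature,
                }) + "\n")


def read_labels(path: str | Path) -> tuple[dict[str, DebateLabel], dict[str, StanceLabel]]:
    """Read a label CSV (``post_id,debate_label[,stance_label]``)."""
    debate: dict[str, DebateLabel] = {}
    stance: dict[str, StanceLabel] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["post_id"]
            debate[pid] = DebateLabel(row["debate_label"])
            s = (row.get("stance_label") or "").strip()
            if s:
                stance[pid] = StanceLabel(s)
    return debate, stance


def write_labels(
    path: str | Path,
    debate: dict[str, DebateLabel],
    stance: dict[str, StanceLabel] | None = None,
) -> None:
    stance = stance or {}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["post_id", "debate_label", "stance_label"])
        for pid, lab in debate.items():
            s = stance.get(pid)
            writer.writerow([pid, lab.value, s.value if s else ""])


# ---------------------------------------------------------------------------
# Sampling for manual coding
# ---------------------------------------------------------------------------


def sample_for_coding(
    posts: Sequence[tuple[Post, str]] | Corpus,
    n: int,
    seed: int,
) -> list[Post]:
    """Sample posts for manual coding, covering every thread.

    Every thread represented in ``posts`` contributes at least one post;
    the ``n`` base slots are allocated to threads proportionally to their
    length with largest-remainder rounding, so the returned sample has
    between ``n`` and ``n + n_threads`` posts.  When ``n`` is smaller
    than the number of threads, one post is drawn from each of ``n``
    threads chosen with probability proportional to thread length.
    Deterministic for a fixed seed.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    if isinstance(posts, Corpus):
        pairs = [(p, t.thread_id) for t in posts for p in t.posts]
    else:
        pairs = list(posts)
    by_thread: dict[str, list[Post]] = {}
    for post, tid in pairs:
        by_thread.setdefault(tid, []).append(post)
    tids = sorted(by_thread)
    sizes = np.array([len(by_thread[t]) for t in tids], dtype=float)
    rng = np.random.default_rng(seed)

    if n < len(tids):
        # undersampling rule: one post from each of n length-weighted threads
        chosen = rng.choice(len(tids), size=n, replace=False, p=sizes / sizes.sum())
        alloc = np.zeros(len(tids), dtype=int)
        alloc[chosen] = 1
    else:
        shares = n * sizes / sizes.sum()
        alloc = np.floor(shares).astype(int)
        remainder = n - alloc.sum()
        # largest-remainder rounding; ties broken by thread id order
        order = np.argsort(-(shares - np.floor(shares)), kind="stable")
        alloc[order[:remainder]] += 1
        alloc = np.maximum(alloc, 1)

    sample: list[Post] = []
    for tid, k in zip(tids, alloc):
        pool = sorted(by_thread[tid], key=lambda p: p.post_id)
        k = min(int(k), len(pool))
        if k:
            idx = rng.choice(len(pool), size=k, replace=False)
            sample.extend(pool[i] for i in sorted(idx))
    return sample


def cohens_kappa(a: Iterable, b: Iterable) -> float:
    """Cohen's kappa between two annotators' label sequences (utility)."""
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValueError("annotation sequences differ in length")
    labels = sorted({*a, *b}, key=str)
    idx = {l: i for i, l in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        m[idx[x], idx[y]] += 1
    m /= m.sum()
    po = np.trace(m)
    pe = float(m.sum(axis=1) @ m.sum(axis=0))
    if pe == 1.0:
        return 1.0
    return float((po - pe) / (1 - pe))
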