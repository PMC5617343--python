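"""Synthetic threaded-forum generator with labeled debate episodes.

Real annotated forum data of this kind is not redistributable, so every
stage of the pipeline is exercised on generated corpora that carry the
statistical structure the method assumes: threads of topic-specific
background chatter interleaved with *debate episodes* — runs of at
least two consecutive posts by at least two alternating authors (a
debate requires interaction).  With probability ``gamma`` a debate post
carries interaction cues (a mention of another participant,
agree/disagree phrasing, question/exclamation marks) plus
topic-type keywords, and for CAM debates stance-bearing lexicon tokens;
with ``gamma = 0`` debate posts are textually indistinguishable from
background, so content-based classifiers can do no better than chance.
Background posts carry the same cue types at low label-independent
noise rates, which is what makes single-post classification imperfect
and thread context genuinely informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np

from .corpus import Corpus, DebateLabel, Post, StanceLabel, Thread

__all__ = ["SimConfig", "generate_corpus", "golden_fixture", "GOLDEN_SEED"]

_FUNCTION_WORDS = [
    "the", "and", "i", "to", "a", "of", "it", "is", "was", "my",
    "for", "that", "on", "with", "this", "but", "have", "you", "are", "be",
]

_CAM_WORDS = ["gerson", "laetrile", "supplement", "ginseng", "massage",
              "alternative", "marijuana", "cream", "tcm", "cam"]
_BC_WORDS = ["chemo", "tamoxifen", "dcis", "radiation", "oncologist",
             "biopsy", "mammogram"]
_OTHER_WORDS = ["rules", "moderator", "offense", "behavior", "trolling",
                "posting", "respect"]

_PRO_LEXICON = ["helped", "works", "worked", "miracle", "healed",
                "recovered", "improved", "effective"]
_CON_LEXICON = ["dangerous", "scam", "hoax", "useless", "harmful",
                "risky", "quack", "debunked"]

_DISAGREE_PHRASES = [
    ["i", "disagree"],
    ["i", "don't", "agree"],
    ["that", "is", "not", "true"],
    ["sorry", "but", "i", "disagree"],
]
_AGREE_PHRASES = [["i", "agree", "but"], ["i", "agree", "with", "you"]]

_DEBATE_TYPES = (DebateLabel.CAM_DEBATE, DebateLabel.BC_DEBATE,
                 DebateLabel.OTHER_DEBATE)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    ``debate_rate`` is the target fraction of posts that belong to a
    debate episode; ``gamma`` is the context-dependence strength — the
    probability that a debate post carries content cues; ``pro_share``
    is the pro:con stance mixture inside CAM debates (default 0.68,
    the observed share of supportive posts in this kind of community).
    """

    n_threads: int = 200
    posts_per_thread: tuple[int, int] = (8, 20)
    n_authors: int = 40
    vocab_size: int = 120
    n_topics: int = 4
    debate_rate: float = 0.25
    episode_len: tuple[int, int] = (2, 6)
    gamma: float = 0.8
    pro_lexicon_size: int = 8
    con_lexicon_size: int = 8
    pro_share: float = 0.68
    type_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    background_cue_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.posts_per_thread[0] > self.posts_per_thread[1]:
            raise ValueError("posts_per_thread min > max")
        if self.episode_len[0] > self.episode_len[1]:
            raise ValueError("episode_len min > max")
        if self.episode_len[0] < 2:
            raise ValueError("a debate episode needs at least 2 posts")
        for r in (self.debate_rate, self.gamma, self.pro_share,
                  self.background_cue_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")


def _topic_distributions(cfg: SimConfig, rng) -> np.ndarray:
    """Per-topic unigram distributions concentrated on word slices."""
    v = cfg.vocab_size
    dists = np.full((cfg.n_topics, v), 0.2 / v)
    span = max(1, v // cfg.n_topics)
    for t in range(cfg.n_topics):
        lo = t * span
        hi = min(v, lo + span)
        w = rng.dirichlet(np.ones(hi - lo))
        dists[t, lo:hi] += 0.8 * w
    return dists / dists.sum(axis=1, keepdims=True)


def _plan_thread(cfg: SimConfig, length: int, rng) -> list[tuple[DebateLabel, int]]:
    """Segment a thread into background posts and debate episodes.

    The per-thread debate-post budget is drawn with mean rho * length
    (stochastic rounding), packed into episodes of the configured
    length distribution, and the episodes are shuffled uniformly among
    the background posts — so the expected debate prevalence equals the
    configured rate with no thread-edge bias.
    """
    lo, hi = cfg.episode_len
    target = cfg.debate_rate * length
    budget = int(np.floor(target)) + (1 if rng.random() < target % 1.0 else 0)
    lengths: list[int] = []
    rem = budget
    while rem >= lo:
        e = min(int(rng.integers(lo, hi + 1)), rem)
        lengths.append(e)
        rem -= e
    # stochastic top-up keeps the expected debate count unbiased despite
    # the leftover < lo that cannot form an episode on its own
    if rem > 0 and rng.random() < rem / lo and sum(lengths) + lo <= length:
        lengths.append(lo)
    items: list[tuple[DebateLabel, int]] = [
        (_DEBATE_TYPES[rng.choice(3, p=np.array(cfg.type_mix))], e)
        for e in lengths
    ]
    items += [(DebateLabel.NON_DEBATE, 1)] * (length - sum(lengths))
    order = rng.permutation(len(items))
    return [items[i] for i in order]


_TYPE_WORDS = {
    DebateLabel.CAM_DEBATE: _CAM_WORDS,
    DebateLabel.BC_DEBATE: _BC_WORDS,
    DebateLabel.OTHER_DEBATE: _OTHER_WORDS,
}

#: label-independent rates at which ordinary posts emit cue-like tokens
#: (people mention each other, ask questions, agree politely and talk
#: about therapies outside of debates); these make every single cue
#: ambiguous evidence, so context is genuinely informative
_NOISE = {
    "name": 0.12,
    "question": 0.10,
    "exclaim": 0.05,
    "agree": 0.05,
    "disagree": 0.02,
    "type_word": 0.10,
    "stance_word": 0.08,
}


def _background_tokens(cfg: SimConfig, topic_dist, rng, participants,
                       author: str, words) -> list[str]:
    n = int(rng.integers(8, 25))
    toks: list[str] = []
    for _ in range(n):
        if rng.random() < 0.45:
            toks.append(_FUNCTION_WORDS[rng.integers(len(_FUNCTION_WORDS))])
        else:
            toks.append(words[rng.choice(cfg.vocab_size, p=topic_dist)])
    scale = cfg.background_cue_rate / 0.10
    if rng.random() < _NOISE["question"] * scale:
        toks.append("?")
    if rng.random() < _NOISE["exclaim"] * scale:
        toks.append("!")
    if rng.random() < _NOISE["agree"] * scale:
        toks.extend(_AGREE_PHRASES[rng.integers(len(_AGREE_PHRASES))])
    if rng.random() < _NOISE["disagree"] * scale:
        toks.extend(_DISAGREE_PHRASES[rng.integers(len(_DISAGREE_PHRASES))])
    if rng.random() < _NOISE["type_word"] * scale:
        tw = _TYPE_WORDS[_DEBATE_TYPES[rng.integers(3)]]
        toks.append(tw[rng.integers(len(tw))])
    if rng.random() < _NOISE["stance_word"] * scale:
        lex = _PRO_LEXICON if rng.random() < 0.5 else _CON_LEXICON
        toks.append(lex[rng.integers(len(lex))])
    others = [a for a in participants if a != author]
    if others and rng.random() < _NOISE["name"] * scale:
        toks.insert(int(rng.integers(len(toks) + 1)),
                    others[rng.integers(len(others))])
    return toks


def _cue_tokens(cfg: SimConfig, etype: DebateLabel,
                stance: StanceLabel | None, episode_authors, author, rng,
                first: bool) -> list[str]:
    """Content cues of one cued debate post.

    The episode opener carries the overt provocation — a mention,
    a (dis)agreement phrase, topic-type keywords and punctuation; later
    posts are replies whose own cues are sparse (a mention, sometimes a
    phrase), so their debate-ness is mostly inferable from what came
    before.
    """
    toks: list[str] = []
    others = [a for a in episode_authors if a != author]

    def phrase():
        if rng.random() < 0.7:
            toks.extend(_DISAGREE_PHRASES[rng.integers(len(_DISAGREE_PHRASES))])
        else:
            toks.extend(_AGREE_PHRASES[rng.integers(len(_AGREE_PHRASES))])

    if first:
        if others:
            toks.append(others[rng.integers(len(others))])
        phrase()
        for _ in range(int(rng.integers(1, 4))):
            tw = _TYPE_WORDS[etype]
            toks.append(tw[rng.integers(len(tw))])
        toks.append("?" if rng.random() < 0.5 else "!")
    else:
        if others and rng.random() < 0.6:
            toks.append(others[rng.integers(len(others))])
        if rng.random() < 0.4:
            phrase()
        if rng.random() < 0.3:
            toks.append("?" if rng.random() < 0.5 else "!")
    if stance is not None:
        lex = (_PRO_LEXICON[: cfg.pro_lexicon_size]
               if stance is StanceLabel.PRO_CAM
               else _CON_LEXICON[: cfg.con_lexicon_size])
        for _ in range(int(rng.integers(1, 4))):
            toks.append(lex[rng.integers(len(lex))])
    return toks


def generate_corpus(
    cfg: SimConfig,
) -> tuple[Corpus, dict[str, DebateLabel], dict[str, StanceLabel]]:
    """Generate a labeled corpus under ``cfg``; deterministic per seed.

    Returns the corpus plus per-post debate labels and, for CAM-debate
    posts, stance labels.  Debate posts always occur in runs of length
    at least 2 with at least 2 distinct alternating authors, and
    timestamps increase strictly within each thread.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    words = [f"word{i}" for i in range(cfg.vocab_size)]
    topics = _topic_distributions(cfg, rng)
    authors = [f"user{i}" for i in range(cfg.n_authors)]

    threads: list[Thread] = []
    debate_labels: dict[str, DebateLabel] = {}
    stance_labels: dict[str, StanceLabel] = {}
    t0 = datetime(2014, 1, 1, tzinfo=timezone.utc)

    for ti in range(cfg.n_threads):
        tid = f"t{ti}"
        length = int(rng.integers(cfg.posts_per_thread[0],
                                  cfg.posts_per_thread[1] + 1))
        n_part = int(rng.integers(3, min(8, cfg.n_authors) + 1))
        participants = list(rng.choice(authors, size=n_part, replace=False))
        topic = int(rng.integers(cfg.n_topics))
        plan = _plan_thread(cfg, length, rng)

        posts: list[Post] = []
        ts = t0 + timedelta(days=ti, minutes=int(rng.integers(0, 600)))
        pi = 0
        for etype, ep_len in plan:
            if etype is DebateLabel.NON_DEBATE:
                author = participants[rng.integers(n_part)]
                toks = _background_tokens(cfg, topics[topic], rng,
                                          participants, author, words)
                post_specs = [(author, etype, None, toks)]
            else:
                n_ep_auth = 2 if ep_len == 2 else int(rng.integers(2, 4))
                ep_authors = list(rng.choice(participants,
                                             size=min(n_ep_auth, n_part),
                                             replace=False))
                if len(ep_authors) < 2:
                    ep_authors = list(rng.choice(
                        authors, size=2, replace=False))
                # per-post stances for CAM episodes; force both stances
                if etype is DebateLabel.CAM_DEBATE:
                    stances = [StanceLabel.PRO_CAM
                               if rng.random() < cfg.pro_share
                               else StanceLabel.CON_CAM
                               for _ in range(ep_len)]
                    if len(set(stances)) == 1:
                        flip = int(rng.integers(ep_len))
                        stances[flip] = (StanceLabel.CON_CAM
                                         if stances[flip] is StanceLabel.PRO_CAM
                                         else StanceLabel.PRO_CAM)
                else:
                    stances = [None] * ep_len
                post_specs = []
                for j in range(ep_len):
                    author = ep_authors[j % len(ep_authors)]
                    toks = _background_tokens(cfg, topics[topic], rng,
                                              participants, author, words)
                    if rng.random() < cfg.gamma:
                        toks.extend(_cue_tokens(cfg, etype, stances[j],
                                                ep_authors, author, rng,
                                                first=(j == 0)))
                    post_specs.append((author, etype, stances[j], toks))

            for author, lab, stance, toks in post_specs:
                pid = f"{tid}p{pi:03d}"
                pi += 1
                ts = ts + timedelta(seconds=int(rng.integers(120, 86400)))
                text = " ".join(toks)
                post = Post.create(pid, tid, author, ts, text)
                posts.append(post)
                debate_labels[pid] = lab
                if stance is not None:
                    stance_labels[pid] = stance
        threads.append(Thread(tid, tuple(posts)))

    return Corpus(tuple(threads)), debate_labels, stance_labels


#: seed of the packaged golden fixture (chosen once so that all three
#: debate types occur in the small corpus)
GOLDEN_SEED = 0


def golden_fixture() -> tuple[Corpus, dict[str, DebateLabel], dict[str, StanceLabel]]:
    """Small frozen corpus (6 threads) used by golden-file tests."""
    cfg = SimConfig(
        n_threads=6,
        posts_per_thread=(5, 9),
        n_authors=8,
        vocab_size=60,
        n_topics=3,
        debate_rate=0.35,
        episode_len=(2, 4),
        gamma=0.9,
        seed=GOLDEN_SEED,
    )
    return generate_corpus(cfg)
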