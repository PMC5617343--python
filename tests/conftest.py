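from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import settings

from threadstance.corpus import Corpus, Post, Thread
from threadstance.synthetic import golden_fixture

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

T0 = datetime(2020, 1, 1, tzinfo=timezone.utc)


def make_post(pid: str, tid: str, author: str, minutes: int, text: str,
              has_signature: bool = False) -> Post:
    return Post.create(pid, tid, author, T0 + timedelta(minutes=minutes),
                       text, has_signature=has_signature)


@pytest.fixture(scope="session")
def golden():
    """The packaged deterministic small corpus with labels."""
    return golden_fixture()


@pytest.fixture()
def toy_thread() -> Thread:
    posts = (
        make_post("p1", "t1", "alice", 0, "Has anyone tried the gerson diet?"),
        make_post("p2", "t1", "bob", 10,
                  "alice I don't agree, gerson therapy is a dangerous scam!"),
        make_post("p3", "t1", "carol", 25,
                  "I agree with bob. It helped nobody I know."),
    )
    return Thread("t1", posts)


@pytest.fixture()
def toy_corpus(toy_thread) -> Corpus:
    other = Thread("t2", (
        make_post("q1", "t2", "dave", 0, "lovely weather today"),
        make_post("q2", "t2", "erin", 60, "indeed it is lovely"),
    ))
    return Corpus((toy_thread, other))
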