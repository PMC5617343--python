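"""Engineered features, CBOW embeddings and LDA topics."""

import numpy as np
import pytest

from threadstance.corpus import Corpus, Thread
from threadstance.features import (
    EmbeddingMatrix,
    FeatureExtractor,
    Vocabulary,
    lexical_features,
    post_features,
    thread_features,
    train_cbow,
    train_lda,
)

from .conftest import make_post


def _thread(texts, authors=None, tid="ft"):
    authors = authors or [f"u{i}" for i in range(len(texts))]
    posts = tuple(
        make_post(f"{tid}p{i}", tid, a, i * 10, s)
        for i, (a, s) in enumerate(zip(authors, texts))
    )
    return Thread(tid, posts)


class TestThreadFeatures:
    def test_counts_users_and_mean_length(self):
        th = _thread(["one two three four", "a b c d e f", "x y"],
                     authors=["u1", "u2", "u1"])
        assert thread_features(th) == (3, 2, 4.0)

    def test_single_post(self):
        th = _thread(["just five little words here"])
        assert thread_features(th) == (1, 1, 5)

    def test_empty_thread_rejected(self):
        with pytest.raises(ValueError):
            thread_features(Thread("e", ()))


class TestPostFeatures:
    def test_name_mentions_and_negated_agree(self):
        th = _thread(["hello all", "x , I don't agree with y"],
                     authors=["x", "z"])
        f = post_features(th.posts[1], th.posts[0], th)
        # participants are {x, z}; author is z, so only "x" counts
        assert f["NumName"] == 1
        assert f["NAgree"] == 0
        assert f["NDisagree"] == 1

    def test_mentions_of_two_other_participants(self):
        th = _thread(["hi", "ok", "x and y are both right"],
                     authors=["x", "y", "z"])
        f = post_features(th.posts[2], th.posts[1], th)
        assert f["NumName"] == 2

    def test_sentiment_and_exclamations(self):
        th = _thread(["so happy and grateful!!"], authors=["u"])
        f = post_features(th.posts[0], None, th)
        assert f["NumPos"] == 2
        assert f["Num!"] == 2
        assert f["NumNeg"] == 0

    def test_morphological_variant_counts(self):
        th = _thread(["that was frustrating and scary, very frustrating"])
        f = post_features(th.posts[0], None, th)
        assert f["NumNeg"] == 2  # frustrated -> frustrating (twice)

    def test_cam_keywords(self):
        th = _thread(["gerson and laetrile supplement"])
        f = post_features(th.posts[0], None, th)
        assert f["NumCAM"] == 3

    def test_overlap_excludes_stopwords(self):
        th = _thread(["the gerson therapy helped", "the gerson therapy scared me"])
        f = post_features(th.posts[1], th.posts[0], th)
        # "the" is a stopword; gerson + therapy overlap
        assert f["NumOverlap"] == 2

    def test_first_post_conventions(self):
        th = _thread(["anything at all here"])
        f = post_features(th.posts[0], None, th)
        assert f["NumOverlap"] == 0 and f["TimeDif"] == 0.0

    def test_time_difference_clipped_at_30_days(self):
        a = make_post("a", "t", "u1", 0, "first")
        b = make_post("b", "t", "u2", 60 * 24 * 90, "ninety days later")
        th = Thread("t", (a, b))
        f = post_features(b, a, th)
        assert f["TimeDif"] == 30 * 86400

    def test_signature_flag(self):
        p = make_post("a", "t", "u", 0, "hi", has_signature=True)
        th = Thread("t", (p,))
        assert post_features(p, None, th)["Sig"] == 1.0

    def test_count_features_order_invariant(self):
        toks = "gerson helped me so happy ! really happy ?".split()
        th1 = _thread([" ".join(toks)])
        th2 = _thread([" ".join(reversed(toks))])
        f1 = post_features(th1.posts[0], None, th1)
        f2 = post_features(th2.posts[0], None, th2)
        for key in ("NumPos", "NumNeg", "NumCAM", "Num?", "Num!"):
            assert f1[key] == f2[key]


class TestCBOW:
    def test_shape_and_determinism(self, toy_corpus):
        emb = train_cbow(toy_corpus, d=5, iters=3, seed=1)
        assert emb.matrix.shape == (5, len(emb.vocab))
        emb2 = train_cbow(toy_corpus, d=5, iters=3, seed=1)
        np.testing.assert_array_equal(emb.matrix, emb2.matrix)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_cbow(Corpus(()), d=4)

    def test_shared_contexts_mean_similar_vectors(self):
        # "gerson" and "laetrile" appear in identical context frames;
        # "weather" never does
        rng = np.random.default_rng(0)
        frames = ["i tried {} for my treatment",
                  "the {} protocol seemed risky",
                  "she swears the {} regimen works",
                  "doctors warned about {} usage"]
        texts = []
        for i in range(120):
            frame = frames[rng.integers(len(frames))]
            texts.append(frame.format("gerson" if i % 2 else "laetrile"))
            texts.append("the weather stayed lovely and calm all day")
        threads = [
            Thread(f"c{j}",
                   tuple(make_post(f"c{j}p{i}", f"c{j}", "u", i, s)
                         for i, s in enumerate(texts[j::4])))
            for j in range(4)
        ]
        emb = train_cbow(Corpus(tuple(threads)), d=12, iters=20, seed=3)

        def cos(a, b):
            va, vb = emb.vector(a), emb.vector(b)
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

        assert cos("gerson", "laetrile") > cos("gerson", "weather")

    def test_text_serialization_round_trip(self, toy_corpus, tmp_path):
        emb = train_cbow(toy_corpus, d=4, iters=2, seed=0)
        path = tmp_path / "vectors.txt"
        emb.save(path)
        back = EmbeddingMatrix.load(path)
        assert back.vocab.index_to_word == emb.vocab.index_to_word
        np.testing.assert_allclose(back.matrix, emb.matrix)


class TestLDA:
    def test_rows_normalized_and_deterministic(self, toy_corpus):
        tm = train_lda(toy_corpus, k=3, seed=5, max_iter=5)
        np.testing.assert_allclose(tm.topic_word.sum(axis=1), 1.0, atol=1e-9)
        tm2 = train_lda(toy_corpus, k=3, seed=5, max_iter=5)
        np.testing.assert_array_equal(tm.topic_word, tm2.topic_word)

    def test_invalid_k_rejected(self, toy_corpus):
        with pytest.raises(ValueError):
            train_lda(toy_corpus, k=0)

    def test_disjoint_vocabularies_separate_topics(self):
        a_words = ["gerson", "laetrile", "protocol", "regimen", "detox"]
        b_words = ["weather", "garden", "recipe", "holiday", "puppy"]
        rng = np.random.default_rng(2)
        posts = []
        for i in range(80):
            pool = a_words if i % 2 else b_words
            text = " ".join(pool[rng.integers(5)] for _ in range(12))
            posts.append(make_post(f"l{i}", "lt", "u", i, text))
        corpus = Corpus((Thread("lt", tuple(posts)),))
        tm = train_lda(corpus, k=2, seed=0, max_iter=30)
        tops = [set(tm.top_words(t, 5)) for t in range(2)]
        assert any(t <= set(a_words) for t in tops)
        assert any(t <= set(b_words) for t in tops)

    def test_inference_is_a_probability_vector(self, toy_corpus):
        tm = train_lda(toy_corpus, k=4, seed=1, max_iter=5)
        theta = tm.topic_proportions(["gerson", "helped", "unseenword"])
        assert theta.shape == (4,)
        assert theta.sum() == pytest.approx(1.0, abs=1e-9)

    def test_array_round_trip(self, toy_corpus, tmp_path):
        tm = train_lda(toy_corpus, k=3, seed=5, max_iter=5)
        path = tmp_path / "lda.npz"
        tm.save(path)
        from threadstance.features import TopicModel

        back = TopicModel.load(path)
        np.testing.assert_array_equal(back.topic_word, tm.topic_word)
        toks = ["gerson", "scam"]
        np.testing.assert_allclose(back.topic_proportions(toks),
                                   tm.topic_proportions(toks))


class TestLexicalFeatures:
    @pytest.fixture()
    def models(self, toy_corpus):
        emb = train_cbow(toy_corpus, d=6, iters=3, seed=0)
        tm = train_lda(toy_corpus, k=3, seed=0, max_iter=5)
        return tm, emb

    def test_identical_posts_have_unit_similarity(self, models, toy_thread):
        tm, emb = models
        post = toy_thread.posts[1]
        lda, lda_sim, w2v, w2v_sim = lexical_features(post, post, tm, emb)
        assert lda_sim == pytest.approx(1.0, abs=1e-6)
        assert w2v_sim == pytest.approx(1.0, abs=1e-6)

    def test_first_post_similarities_are_zero(self, models, toy_thread):
        tm, emb = models
        lda, lda_sim, w2v, w2v_sim = lexical_features(
            toy_thread.posts[0], None, tm, emb)
        assert lda_sim == 0.0 and w2v_sim == 0.0
        assert lda.sum() == pytest.approx(1.0, abs=1e-9)

    def test_cosine_matches_brute_force(self, models, toy_thread):
        tm, emb = models
        cur, prev = toy_thread.posts[1], toy_thread.posts[0]
        _, lda_sim, _, w2v_sim = lexical_features(cur, prev, tm, emb)
        a = emb.mean_vector(cur.tokens)
        b = emb.mean_vector(prev.tokens)
        expected = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert w2v_sim == pytest.approx(expected, abs=1e-12)
        ta = tm.topic_proportions(cur.tokens)
        tb = tm.topic_proportions(prev.tokens)
        expected = float(ta @ tb) / (np.linalg.norm(ta) * np.linalg.norm(tb))
        assert lda_sim == pytest.approx(expected, abs=1e-12)


class TestFeatureExtractor:
    def test_matrix_shape_and_names(self, golden):
        corpus, _, _ = golden
        ex = FeatureExtractor.fit(corpus, d=6, k=4, seed=0,
                                  cbow_iters=2, lda_max_iter=3)
        X, pids = ex.transform(corpus)
        assert X.shape == (len(corpus.posts), len(ex.feature_names))
        assert len(pids) == len(corpus.posts)
        assert not np.isnan(X).any()

    def test_extraction_does_not_mutate_corpus(self, golden):
        corpus, _, _ = golden
        before = [(p.post_id, p.tokens) for p in corpus.posts]
        ex = FeatureExtractor.fit(corpus, d=4, k=3, seed=0,
                                  cbow_iters=1, lda_max_iter=2)
        ex.transform(corpus)
        assert [(p.post_id, p.tokens) for p in corpus.posts] == before

    def test_engineered_block_matches_frozen_golden_file(self, golden):
        """The deterministic count/time features of the packaged fixture
        match the frozen CSV committed alongside the tests."""
        import pandas as pd
        from pathlib import Path

        corpus, _, _ = golden
        rows = []
        for thread in corpus:
            npost, nuser, avglen = thread_features(thread)
            for i, post in enumerate(thread.posts):
                prev = thread.posts[i - 1] if i else None
                f = post_features(post, prev, thread)
                rows.append({"post_id": post.post_id, "NumPost": npost,
                             "NumUser": nuser, "AvgLen": avglen, **f})
        got = pd.DataFrame(rows)
        path = Path(__file__).parent / "data" / "golden_features.csv"
        want = pd.read_csv(path)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)
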