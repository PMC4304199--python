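import numpy as np
import pytest

from dilitopics.corpus import BowCorpus, Vocabulary
from dilitopics.lda import (
    Hyperparams,
    conditional_distribution,
    estimate_log_likelihood,
    estimate_phi,
    estimate_theta,
    fit,
    gibbs_sweep,
    init_assignments,
    log_p_words_given_z,
    select_num_topics,
    top_words,
)
from conftest import random_bow
from oracles import sequential_log_p_words


def small_hyper(T, seed=0, **kw):
    kw.setdefault("n_iter", 20)
    kw.setdefault("burn_in", 10)
    kw.setdefault("sample_lag", 2)
    return Hyperparams(n_topics=T, seed=seed, **kw)


def test_hyperparams_validation():
    with pytest.raises(ValueError):
        Hyperparams(n_topics=0)
    with pytest.raises(ValueError):
        Hyperparams(n_topics=2, alpha=0.0)
    with pytest.raises(ValueError):
        Hyperparams(n_topics=2, burn_in=10, n_iter=10)


def test_init_single_topic_assigns_everything_to_topic_zero(tiny_corpus):
    state = init_assignments(tiny_corpus, small_hyper(1))
    assert np.all(state.z == 0)
    assert state.n_k[0] == tiny_corpus.total_tokens


def test_init_deterministic_and_consistent(tiny_corpus):
    s1 = init_assignments(tiny_corpus, small_hyper(3, seed=42))
    s2 = init_assignments(tiny_corpus, small_hyper(3, seed=42))
    assert np.array_equal(s1.z, s2.z)
    n_dk, n_kw, n_k = s1.recount()
    assert np.array_equal(n_dk, s1.n_dk)
    assert np.array_equal(n_kw, s1.n_kw)
    assert np.array_equal(n_k, s1.n_k)


def test_conditional_single_topic_is_degenerate(tiny_corpus):
    state = init_assignments(tiny_corpus, small_hyper(1))
    np.testing.assert_allclose(
        conditional_distribution(state, 0, 0, small_hyper(1)), [1.0]
    )


def test_conditional_matches_hand_formula():
    """D=2, V=3, T=2 with a pinned assignment: compare against the exclude-
    counts formula evaluated by independent explicit arithmetic."""
    corpus = BowCorpus(
        Vocabulary(["a", "b", "c"]),
        [np.array([0, 1, 2], dtype=np.int32), np.array([2, 2], dtype=np.int32)],
        ["d0", "d1"],
    )
    hyper = small_hyper(2, alpha=0.1, beta=0.01)
    state = init_assignments(corpus, hyper)
    state.z[:] = [0, 1, 1, 0, 1]
    state.n_dk[:], state.n_kw[:], state.n_k[:] = state.recount()

    # token (doc 0, pos 1): word b assigned topic 1; exclude it from counts
    n_dk_ex = {0: 1, 1: 1}      # doc 0 without this token
    n_kw_ex = {0: 0, 1: 0}      # word b count per topic without this token
    n_k_ex = {0: 2, 1: 2}       # topic totals without this token
    V = 3
    raw = [
        (n_dk_ex[k] + 0.1) * (n_kw_ex[k] + 0.01) / (n_k_ex[k] + V * 0.01)
        for k in (0, 1)
    ]
    expected = np.array(raw) / sum(raw)
    got = conditional_distribution(state, 0, 1, hyper)
    np.testing.assert_allclose(got, expected, rtol=1e-12)
    # exclude-then-restore contract: state unchanged
    n_dk, n_kw, n_k = state.recount()
    assert np.array_equal(n_dk, state.n_dk) and np.array_equal(n_k, state.n_k)


def test_conditional_symmetric_counts_give_equal_probabilities():
    corpus = BowCorpus(
        Vocabulary(["a", "b"]),
        [np.array([0], dtype=np.int32), np.array([0, 0], dtype=np.int32)],
        ["d0", "d1"],
    )
    hyper = small_hyper(2)
    state = init_assignments(corpus, hyper)
    # after excluding the single token of doc 0, the remaining counts are
    # perfectly symmetric across the two topics
    state.z[:] = [0, 0, 1]
    state.n_dk[:], state.n_kw[:], state.n_k[:] = state.recount()
    np.testing.assert_allclose(conditional_distribution(state, 0, 0, hyper), [0.5, 0.5])


def test_sweep_single_topic_is_identity(tiny_corpus):
    hyper = small_hyper(1)
    state = init_assignments(tiny_corpus, hyper)
    z0 = state.z.copy()
    gibbs_sweep(state, hyper)
    assert np.array_equal(state.z, z0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sweep_preserves_count_consistency(seed):
    """After every sweep, recounting from z reproduces the stored matrices."""
    rng = np.random.default_rng(seed)
    corpus = random_bow(rng)
    hyper = small_hyper(3, seed=seed)
    state = init_assignments(corpus, hyper)
    for _ in range(5):
        gibbs_sweep(state, hyper)
        n_dk, n_kw, n_k = state.recount()
        assert np.array_equal(n_dk, state.n_dk)
        assert np.array_equal(n_kw, state.n_kw)
        assert np.array_equal(n_k, state.n_k)
        assert np.array_equal(state.n_dk.sum(axis=1), state.n_d)


def test_sweep_trajectory_deterministic():
    rng = np.random.default_rng(5)
    corpus = random_bow(rng)
    hyper = small_hyper(4, seed=9)
    s1, s2 = init_assignments(corpus, hyper), init_assignments(corpus, hyper)
    for _ in range(10):
        gibbs_sweep(s1, hyper)
        gibbs_sweep(s2, hyper)
    assert np.array_equal(s1.z, s2.z)


def test_theta_closed_form():
    """3 tokens all in topic 0, T=2, alpha=0.1 -> [3.1/3.2, 0.1/3.2]."""
    corpus = BowCorpus(
        Vocabulary(["a"]), [np.array([0, 0, 0], dtype=np.int32)], ["d0"]
    )
    hyper = small_hyper(2)
    state = init_assignments(corpus, hyper)
    state.z[:] = 0
    state.n_dk[:], state.n_kw[:], state.n_k[:] = state.recount()
    np.testing.assert_allclose(
        estimate_theta(state, hyper), [[3.1 / 3.2, 0.1 / 3.2]], rtol=1e-12
    )


def test_theta_empty_document_is_uniform():
    corpus = BowCorpus(
        Vocabulary(["a"]),
        [np.array([0, 0], dtype=np.int32), np.array([], dtype=np.int32)],
        ["d0", "d1"],
    )
    hyper = small_hyper(4)
    state = init_assignments(corpus, hyper)
    np.testing.assert_allclose(estimate_theta(state, hyper)[1], [0.25] * 4)


def test_phi_closed_forms():
    corpus = BowCorpus(
        Vocabulary(["a", "b"]), [np.array([0], dtype=np.int32)], ["d0"]
    )
    hyper = small_hyper(2, beta=0.01)
    state = init_assignments(corpus, hyper)
    state.z[:] = 0
    state.n_dk[:], state.n_kw[:], state.n_k[:] = state.recount()
    phi = estimate_phi(state, hyper)
    np.testing.assert_allclose(phi[0], [1.01 / 1.02, 0.01 / 1.02], rtol=1e-12)
    np.testing.assert_allclose(phi[1], [0.5, 0.5])  # empty topic -> uniform


def test_theta_phi_rows_are_normalized_and_positive():
    rng = np.random.default_rng(3)
    corpus = random_bow(rng, n_docs=6, vocab_size=8)
    hyper = small_hyper(5, seed=1)
    model = fit(corpus, hyper)
    np.testing.assert_allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)
    assert (model.theta > 0).all() and (model.phi > 0).all()


def test_log_p_words_first_token_symmetry():
    """One token, V=2, T=1, any beta: p(w) = beta/(2 beta) = 1/2."""
    corpus = BowCorpus(Vocabulary(["a", "b"]), [np.array([0], dtype=np.int32)], ["d0"])
    hyper = small_hyper(1, beta=0.01)
    state = init_assignments(corpus, hyper)
    assert log_p_words_given_z(state, hyper) == pytest.approx(np.log(0.5))


@pytest.mark.parametrize("seed", [0, 7])
def test_log_p_words_matches_sequential_polya_product(seed):
    rng = np.random.default_rng(seed)
    corpus = random_bow(rng, n_docs=3, vocab_size=4, max_len=6)
    hyper = small_hyper(3, seed=seed)
    state = init_assignments(corpus, hyper)
    expected = sequential_log_p_words(state.z, state.w, 3, 4, hyper.beta)
    assert log_p_words_given_z(state, hyper) == pytest.approx(expected, abs=1e-9)


def test_log_p_words_decreases_as_tokens_are_added():
    hyper = small_hyper(2)
    vals = []
    for n in (1, 2, 3):
        corpus = BowCorpus(
            Vocabulary(["a", "b"]), [np.array([0] * n, dtype=np.int32)], ["d0"]
        )
        state = init_assignments(corpus, hyper)
        state.z[:] = 0
        state.n_dk[:], state.n_kw[:], state.n_k[:] = state.recount()
        vals.append(log_p_words_given_z(state, hyper))
    assert vals[0] > vals[1] > vals[2]
    assert all(np.isfinite(v) for v in vals)


def test_harmonic_mean_estimator_hand_cases():
    assert estimate_log_likelihood([-1.5] * 4) == pytest.approx(-1.5)
    # samples {log 1/2, log 1/4}: HM = 1/((2 + 4)/2) = 1/3
    got = estimate_log_likelihood([np.log(0.5), np.log(0.25)])
    assert got == pytest.approx(np.log(1 / 3))
    with pytest.raises(ValueError):
        estimate_log_likelihood([])


def test_select_singleton_grid():
    rng = np.random.default_rng(0)
    corpus = random_bow(rng)
    sel = select_num_topics(corpus, [7], small_hyper(2))
    assert sel.chosen_T == 7
    assert all(np.isfinite(v) for v in sel.log_likelihoods)


def test_select_empty_grid_errors(tiny_corpus):
    with pytest.raises(ValueError):
        select_num_topics(tiny_corpus, [], small_hyper(2))


def test_top_words_dominant_word_first():
    rng = np.random.default_rng(1)
    corpus = random_bow(rng, n_docs=3, vocab_size=5)
    model = fit(corpus, small_hyper(2, seed=2))
    model.phi = np.array([[0.05, 0.7, 0.1, 0.1, 0.05], [0.2] * 5])
    assert top_words(model, 1)[0] == ["word1"]
    # uniform row: tie broken by vocabulary order
    assert top_words(model, 3)[1] == ["word0", "word1", "word2"]
    assert sorted(top_words(model, 5)[0]) == sorted(corpus.vocabulary.words)
    with pytest.raises(ValueError):
        top_words(model, 6)


def test_top_words_agrees_with_bruteforce_sort():
    rng = np.random.default_rng(4)
    corpus = random_bow(rng, n_docs=3, vocab_size=7)
    model = fit(corpus, small_hyper(3, seed=4))
    for k, row in enumerate(model.phi):
        expected = [
            corpus.vocabulary[i]
            for i in sorted(range(7), key=lambda i: (-row[i], i))[:4]
        ]
        assert top_words(model, 4)[k] == expected


def test_fit_bit_deterministic():
    rng = np.random.default_rng(8)
    corpus = random_bow(rng, n_docs=5, vocab_size=6)
    hyper = small_hyper(3, seed=17, n_iter=30, burn_in=15)
    m1, m2 = fit(corpus, hyper), fit(corpus, hyper)
    assert np.array_equal(m1.theta, m2.theta)
    assert np.array_equal(m1.phi, m2.phi)
    assert m1.log_likelihood == m2.log_likelihood
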