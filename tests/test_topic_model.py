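"""Variational-EM LDA: closed forms, the exact-enumeration oracle, ELBO
monotonicity, planted-parameter recovery, perplexity and the grid search."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from cuitopics.corpus import CuiCorpus, CuiDocument, build_corpus
from cuitopics.synthetic import SyntheticSpec, generate_corpus, make_dictionary
from cuitopics.topic_model import (
    ALPHA_GRID_DEFAULT,
    K_GRID_DEFAULT,
    LdaOptions,
    fit_lda,
    grid_search,
    load_model,
    log_likelihood_bound,
    perplexity,
    save_model,
)

from conftest import block_beta, corpus_from_planted, NO_NOISE


def _cui(v: int) -> str:
    return f"C{v + 1:07d}"


def _corpus_from_matrix(X: np.ndarray) -> CuiCorpus:
    docs = [
        CuiDocument(f"d{i}", {_cui(v): int(x[v]) for v in range(len(x)) if x[v]})
        for i, x in enumerate(X)
    ]
    return CuiCorpus(documents=docs, vocabulary=[_cui(v) for v in range(X.shape[1])])


def exact_log_marginal(X: np.ndarray, alpha: float, beta: np.ndarray) -> float:
    """Exact log p(X | alpha, beta) by enumerating every topic assignment.

    For one document with tokens w_1..w_N, summing over assignments z:
    p(w) = sum_z E[prod_n theta_{z_n}] prod_n beta_{z_n, w_n}, where the
    Dirichlet moment E[prod theta_k^{c_k}] has the closed rising-factorial
    form. Tractable only for tiny N and K; the independent oracle.
    """
    K = beta.shape[0]
    total = 0.0
    for x in X:
        words = [v for v in range(len(x)) for _ in range(int(x[v]))]
        N = len(words)
        p = 0.0
        for z in itertools.product(range(K), repeat=N):
            ck = np.bincount(z, minlength=K)
            log_moment = (
                gammaln(K * alpha)
                - gammaln(K * alpha + N)
                + np.sum(gammaln(alpha + ck) - gammaln(alpha))
            )
            log_beta = sum(np.log(beta[zk, w]) for zk, w in zip(z, words))
            p += np.exp(log_moment + log_beta)
        total += np.log(p)
    return total


class TestClosedForms:
    def test_single_topic_beta_is_empirical_frequency(self):
        X = np.array([[2.0, 1.0, 0.0], [0.0, 3.0, 1.0]])
        c = _corpus_from_matrix(X)
        model, posterior = fit_lda(c, 1, 1.0, LdaOptions(eta=0.0, n_restarts=1, seed=0))
        np.testing.assert_allclose(model.beta[0], X.sum(0) / X.sum(), atol=1e-10)
        np.testing.assert_allclose(posterior.theta_hat, 1.0)

    def test_single_topic_perplexity_is_unigram_perplexity(self):
        X = np.array([[3.0, 1.0], [2.0, 2.0]])
        c = _corpus_from_matrix(X)
        model, _ = fit_lda(c, 1, 1.0, LdaOptions(eta=0.0, n_restarts=1, seed=0))
        p = X.sum(0) / X.sum()
        expected = np.exp(-(X.sum(0) @ np.log(p)) / X.sum())
        assert perplexity(model, c) == pytest.approx(expected, rel=1e-8)

    def test_single_token_deterministic_model_perplexity_one(self):
        c = _corpus_from_matrix(np.array([[1.0]]))
        model, _ = fit_lda(c, 1, 1.0, LdaOptions(eta=0.0, n_restarts=1))
        assert perplexity(model, c) == pytest.approx(1.0, abs=1e-9)


class TestEnumerationOracle:
    def test_bound_never_exceeds_exact_likelihood(self):
        """ELBO <= exact enumerated log-likelihood on 25 tiny instances."""
        rng = np.random.default_rng(7)
        for trial in range(25):
            K = int(rng.integers(1, 4))
            V = int(rng.integers(2, 5))
            D = int(rng.integers(1, 4))
            rows = []
            for _ in range(D):
                n = int(rng.integers(1, 5))
                rows.append(np.bincount(rng.integers(0, V, size=n), minlength=V))
            X = np.array(rows, dtype=float)
            c = _corpus_from_matrix(X)
            alpha = float(rng.uniform(0.1, 5.0))
            with np.errstate(all="ignore"):
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    model, _ = fit_lda(
                        c, K, alpha, LdaOptions(seed=int(rng.integers(1000)), n_restarts=2)
                    )
            bound = log_likelihood_bound(model, c)
            exact = exact_log_marginal(X, alpha, model.beta)
            assert bound <= exact + 1e-8, f"trial {trial}: {bound} > {exact}"


class TestFitInvariants:
    @pytest.fixture(scope="class")
    def planted(self):
        K, V = 3, 30
        d = make_dictionary(V, 2, seed=21)
        spec = SyntheticSpec(
            n_docs=120, n_cuis=V, K_true=K, alpha_true=0.5,
            beta_true=block_beta(K, V), seed=21, doc_len_mean=60,
            doc_len_sd=20, mention_fraction=0.3, noise_rates=dict(NO_NOISE),
        )
        posts, truth = generate_corpus(spec, d)
        return corpus_from_planted(posts, truth), truth

    def test_elbo_monotone_nondecreasing(self, planted):
        c, _ = planted
        for seed in (0, 1, 2):
            model, _ = fit_lda(c, 3, 0.5, LdaOptions(seed=seed, n_restarts=1))
            tr = np.array(model.elbo_trace)
            assert np.all(np.diff(tr) >= -1e-6 * np.abs(tr[:-1]))

    def test_rows_normalized(self, planted):
        c, _ = planted
        model, posterior = fit_lda(c, 3, 0.5, LdaOptions(seed=0))
        np.testing.assert_allclose(model.beta.sum(1), 1.0, atol=1e-8)
        assert np.all(model.beta > 0)
        np.testing.assert_allclose(posterior.theta_hat.sum(1), 1.0, atol=1e-8)

    def test_deterministic_for_fixed_seed(self, planted):
        c, _ = planted
        m1, p1 = fit_lda(c, 3, 0.5, LdaOptions(seed=11))
        m2, p2 = fit_lda(c, 3, 0.5, LdaOptions(seed=11))
        np.testing.assert_array_equal(m1.beta, m2.beta)
        np.testing.assert_array_equal(p1.gamma, p2.gamma)

    def test_planted_beta_recovery(self, planted):
        c, truth = planted
        model, _ = fit_lda(c, 3, 0.5, LdaOptions(seed=1))
        bt, bh = truth.beta_true, model.beta
        cos = (bt / np.linalg.norm(bt, axis=1, keepdims=True)) @ (
            bh / np.linalg.norm(bh, axis=1, keepdims=True)
        ).T
        r, cidx = linear_sum_assignment(-cos)
        assert cos[r, cidx].mean() >= 0.9

    def test_empty_documents_get_uniform_posterior(self):
        docs = [CuiDocument("a", {"C0000001": 3}), CuiDocument("b", {})]
        c = CuiCorpus(documents=docs, vocabulary=["C0000001"])
        _, posterior = fit_lda(c, 2, 1.0, LdaOptions(seed=0, n_restarts=1))
        np.testing.assert_allclose(posterior.theta_hat[1], 0.5)

    def test_k_exceeding_docs_warns_but_fits(self):
        c = _corpus_from_matrix(np.array([[2.0, 1.0]]))
        with pytest.warns(UserWarning, match="exceeds"):
            model, _ = fit_lda(c, 3, 1.0, LdaOptions(seed=0, n_restarts=1))
        assert model.K == 3

    def test_empty_vocabulary_refused(self):
        c = CuiCorpus(documents=[CuiDocument("a", {})], vocabulary=[])
        with pytest.raises(ValueError, match="vocabulary"):
            fit_lda(c, 2, 1.0)


class TestPerplexity:
    def test_true_model_beats_random_beta(self):
        K, V = 3, 30
        beta_true = block_beta(K, V)
        d = make_dictionary(V, 2, seed=33)
        spec = SyntheticSpec(
            n_docs=80, n_cuis=V, K_true=K, alpha_true=0.5, beta_true=beta_true,
            seed=33, doc_len_mean=50, doc_len_sd=15, mention_fraction=0.4,
            noise_rates=dict(NO_NOISE),
        )
        posts, truth = generate_corpus(spec, d)
        c = corpus_from_planted(posts, truth)
        from cuitopics.topic_model import LdaModel

        def as_model(beta):
            return LdaModel(
                K=K, alpha=0.5, beta=beta, vocabulary=list(truth.cui_order),
                eta=0.0, converged=True, elbo_trace=[0.0], seed=0,
            )

        rng = np.random.default_rng(4)
        random_beta = rng.dirichlet(np.ones(V), size=K)
        assert perplexity(as_model(beta_true), c) <= perplexity(as_model(random_beta), c)

    def test_out_of_vocabulary_cui_named_in_error(self):
        c = _corpus_from_matrix(np.array([[2.0, 1.0]]))
        model, _ = fit_lda(c, 1, 1.0, LdaOptions(n_restarts=1))
        bad = CuiCorpus(
            documents=[CuiDocument("x", {"C9999999": 1})], vocabulary=["C9999999"]
        )
        with pytest.raises(KeyError, match="C9999999"):
            perplexity(model, bad)


class TestGridSearch:
    def test_default_grids_are_canonical(self):
        assert ALPHA_GRID_DEFAULT == (0.01, 0.05, 0.1, 0.5, 1, 1.5, 2, 5, 10, 15, 20, 25)
        assert K_GRID_DEFAULT == (3, 4, 5, 10, 15, 20)

    def test_single_cell_grid(self):
        c = _corpus_from_matrix(np.array([[3.0, 1.0], [1.0, 2.0]]))
        res = grid_search(c, [1], [1.0], LdaOptions(n_restarts=1, seed=0))
        assert len(res.rows) == 1

    def test_grid_is_complete_and_sorted(self):
        c = _corpus_from_matrix(
            np.vstack([np.random.default_rng(0).integers(0, 4, size=(8, 5))]).astype(float) + 1
        )
        res = grid_search(c, [1, 2], [0.5, 1.0, 2.0], LdaOptions(n_restarts=1, seed=0))
        assert len(res.rows) == 6
        perps = [r["perplexity"] for r in res.rows]
        assert perps == sorted(perps)

    def test_empty_grid_rejected(self):
        c = _corpus_from_matrix(np.array([[1.0]]))
        with pytest.raises(ValueError):
            grid_search(c, [], [1.0])

    def test_heldout_model_selection_prefers_true_k(self):
        """Held-out perplexity at the planted K is no worse than at K=2."""
        K, V = 4, 40
        d = make_dictionary(V, 2, seed=17)
        spec = SyntheticSpec(
            n_docs=300, n_cuis=V, K_true=K, alpha_true=0.3,
            beta_true=block_beta(K, V), seed=17, doc_len_mean=60, doc_len_sd=15,
            mention_fraction=0.4, noise_rates=dict(NO_NOISE),
        )
        posts, truth = generate_corpus(spec, d)
        c = corpus_from_planted(posts, truth)
        res = grid_search(
            c, [2, 4], [0.3], LdaOptions(seed=2), heldout_fraction=0.2
        )
        by_k = {r["K"]: r["perplexity"] for r in res.rows}
        assert by_k[4] <= by_k[2]


def test_model_save_load_round_trip(tmp_path):
    c = _corpus_from_matrix(np.array([[3.0, 1.0, 2.0], [1.0, 2.0, 0.0]]))
    model, posterior = fit_lda(c, 2, 1.0, LdaOptions(seed=5, n_restarts=1))
    save_model(model, posterior, tmp_path / "m")
    back, post_back = load_model(tmp_path / "m")
    assert back.K == model.K and back.alpha == model.alpha
    np.testing.assert_allclose(back.beta, model.beta, rtol=1e-9)
    np.testing.assert_allclose(post_back.gamma, posterior.gamma, rtol=1e-9)
    assert back.vocabulary == model.vocabulary


def test_cross_check_against_sklearn_recovery():
    """Independent route: scikit-learn's variational LDA on the same counts
    recovers topics aligned with ours (both match the planted truth)."""
    sklearn_lda = pytest.importorskip("sklearn.decomposition").LatentDirichletAllocation
    K, V = 3, 30
    d = make_dictionary(V, 2, seed=8)
    spec = SyntheticSpec(
        n_docs=200, n_cuis=V, K_true=K, alpha_true=0.3,
        beta_true=block_beta(K, V), seed=8, doc_len_mean=60, doc_len_sd=15,
        mention_fraction=0.4, noise_rates=dict(NO_NOISE),
    )
    posts, truth = generate_corpus(spec, d)
    c = corpus_from_planted(posts, truth)
    X = np.zeros((len(c.documents), V))
    for i, doc in enumerate(c.documents):
        for cui, n in doc.counts.items():
            X[i, c.vocab_index(cui)] = n
    model, _ = fit_lda(c, K, 0.3, LdaOptions(seed=3))
    sk = sklearn_lda(
        n_components=K, doc_topic_prior=0.3, random_state=0, max_iter=50
    ).fit(X)
    beta_sk = sk.components_ / sk.components_.sum(1, keepdims=True)
    norm = lambda b: b / np.linalg.norm(b, axis=1, keepdims=True)
    cos = norm(model.beta) @ norm(beta_sk).T
    r, cidx = linear_sum_assignment(-cos)
    assert cos[r, cidx].mean() >= 0.9
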