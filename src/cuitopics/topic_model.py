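"""Latent Dirichlet allocation over bag-of-CUI corpora, by variational EM.

The generative model: each document draws a topic mixture
theta_d ~ Dirichlet(alpha) (symmetric, scalar alpha per component); each
token draws a topic z ~ Categorical(theta_d) and then a CUI
w ~ Categorical(beta[z]). Inference is mean-field variational EM in the
Blei-Ng-Jordan formulation: per-document coordinate ascent on the Dirichlet
posterior parameters gamma_d and token assignments phi_d (E-step), then a
point (MAP-style) update of the topic-CUI matrix beta with a symmetric
pseudo-count eta (M-step). alpha is held FIXED at the supplied value — the
pipeline selects it by grid search rather than learning it.

The E-step is vectorized over documents: with
Elogtheta_dk = psi(gamma_dk) - psi(sum_k gamma_dk), the optimal phi gives
S_dv = sum_k exp(Elogtheta_dk) * beta_kv and the gamma update
gamma = alpha + expElogtheta * ((X / S) @ beta.T), iterated to a tolerance
on the mean absolute gamma change.

The reported objective is the evidence lower bound (ELBO) on
log p(X | alpha, beta) plus the eta * sum log beta smoothing term, which
the EM iterations increase monotonically; the unpenalized per-document
bound (used for perplexity) never exceeds the exact marginal likelihood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln, psi

from .corpus import CuiCorpus

__all__ = [
    "ALPHA_GRID_DEFAULT",
    "K_GRID_DEFAULT",
    "LdaOptions",
    "LdaModel",
    "DocTopicPosterior",
    "GridResult",
    "fit_lda",
    "perplexity",
    "grid_search",
    "save_model",
    "load_model",
]

#: Default grid for the symmetric Dirichlet document-topic prior.
ALPHA_GRID_DEFAULT = (0.01, 0.05, 0.1, 0.5, 1, 1.5, 2, 5, 10, 15, 20, 25)
#: Default grid for the number of topics.
K_GRID_DEFAULT = (3, 4, 5, 10, 15, 20)

_EPS = 1e-100


@dataclass(frozen=True)
class LdaOptions:
    """Fitting controls.

    max_iter: EM iteration cap. em_tol: relative ELBO change stopping rule.
    var_tol: E-step mean absolute gamma change tolerance. eta: symmetric
    topic-CUI smoothing pseudo-count. n_restarts: independent seeded
    initializations, best final ELBO kept.
    """

    max_iter: int = 100
    em_tol: float = 1e-4
    var_tol: float = 1e-6
    eta: float = 0.01
    seed: int = 0
    n_restarts: int = 3
    max_var_iter: int = 200


@dataclass
class LdaModel:
    K: int
    alpha: float
    beta: np.ndarray  # K x V, rows sum to 1
    vocabulary: list[str]
    eta: float
    converged: bool
    elbo_trace: list[float]
    seed: int

    @property
    def elbo(self) -> float:
        return self.elbo_trace[-1]


@dataclass
class DocTopicPosterior:
    """Variational Dirichlet parameters gamma per document and the
    row-normalized point estimate theta_hat."""

    post_ids: list[str]
    gamma: np.ndarray  # n_docs x K

    @property
    def theta_hat(self) -> np.ndarray:
        return self.gamma / self.gamma.sum(axis=1, keepdims=True)


@dataclass
class GridResult:
    """One row per (K, alpha) pair, sorted ascending by perplexity. The
    final choice of (K, alpha) is the analyst's, recorded in config; the
    grid only ranks."""

    rows: list[dict] = field(default_factory=list)

    def as_table(self) -> list[tuple[int, float, float, float]]:
        return [(r["K"], r["alpha"], r["perplexity"], r["elbo"]) for r in self.rows]


def _dense_counts(corpus: CuiCorpus, vocabulary: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Dense doc-term count matrix over ``vocabulary`` for the non-empty
    documents, plus their post ids. Raises on out-of-vocabulary CUIs."""
    index = {c: i for i, c in enumerate(vocabulary)}
    docs = corpus.nonempty_documents()
    X = np.zeros((len(docs), len(vocabulary)))
    for d, doc in enumerate(docs):
        for cui, cnt in doc.counts.items():
            try:
                X[d, index[cui]] = cnt
            except KeyError:
                raise KeyError(f"CUI {cui!r} not in model vocabulary") from None
    return X, [doc.post_id for doc in docs]


def _e_step(
    X: np.ndarray, beta: np.ndarray, alpha: float, var_tol: float, max_var_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-document coordinate ascent on (gamma, phi), vectorized.

    Returns (gamma, sstats) where sstats_kv = sum_d sum_tokens phi_dvk,
    the expected topic-CUI counts for the M-step.
    """
    n_docs, _ = X.shape
    K = beta.shape[0]
    gamma = np.full((n_docs, K), alpha + X.sum(axis=1, keepdims=True) / K)
    expElog = np.exp(psi(gamma) - psi(gamma.sum(axis=1, keepdims=True)))
    for _ in range(max_var_iter):
        S = expElog @ beta + _EPS
        gamma_new = alpha + expElog * ((X / S) @ beta.T)
        change = np.abs(gamma_new - gamma).mean()
        gamma = gamma_new
        expElog = np.exp(psi(gamma) - psi(gamma.sum(axis=1, keepdims=True)))
        if change < var_tol:
            break
    S = expElog @ beta + _EPS
    sstats = beta * (expElog.T @ (X / S))
    return gamma, sstats


def _per_doc_bound(
    X: np.ndarray, gamma: np.ndarray, beta: np.ndarray, alpha: float
) -> np.ndarray:
    """Variational lower bound on log p(w_d | alpha, beta) per document."""
    K = beta.shape[0]
    Elog = psi(gamma) - psi(gamma.sum(axis=1, keepdims=True))
    S = np.exp(Elog) @ beta + _EPS
    word_term = (X * np.log(S)).sum(axis=1)
    theta_term = (
        gammaln(K * alpha)
        - K * gammaln(alpha)
        + ((alpha - gamma) * Elog).sum(axis=1)
        + gammaln(gamma).sum(axis=1)
        - gammaln(gamma.sum(axis=1))
    )
    return word_term + theta_term


def _init_beta(X: np.ndarray, K: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Seed each topic from a randomly chosen document plus uniform noise."""
    n_docs, V = X.shape
    beta = np.empty((K, V))
    seeds = rng.choice(n_docs, size=K, replace=K > n_docs)
    for k in range(K):
        row = X[seeds[k]] + 1.0 + rng.uniform(0, 0.5, size=V) + eta
        beta[k] = row / row.sum()
    return beta


def _fit_once(
    X: np.ndarray, K: int, alpha: float, opts: LdaOptions, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    beta = _init_beta(X, K, opts.eta, rng)
    trace: list[float] = []
    converged = False
    gamma = None
    def penalty(b: np.ndarray) -> float:
        # eta=0 disables smoothing; avoid 0 * log(0)
        return float(opts.eta * np.log(b + _EPS).sum()) if opts.eta > 0 else 0.0

    for _ in range(opts.max_iter):
        gamma, sstats = _e_step(X, beta, alpha, opts.var_tol, opts.max_var_iter)
        elbo = float(_per_doc_bound(X, gamma, beta, alpha).sum() + penalty(beta))
        if trace and abs(elbo - trace[-1]) / max(abs(trace[-1]), 1e-12) < opts.em_tol:
            trace.append(elbo)
            converged = True
            break
        trace.append(elbo)
        beta = sstats + opts.eta
        beta /= beta.sum(axis=1, keepdims=True)
    # final E-step so gamma matches the last beta
    gamma, _ = _e_step(X, beta, alpha, opts.var_tol, opts.max_var_iter)
    final = float(_per_doc_bound(X, gamma, beta, alpha).sum() + penalty(beta))
    trace.append(final)
    return beta, gamma, trace, converged


def fit_lda(
    corpus: CuiCorpus,
    K: int,
    alpha: float,
    opts: LdaOptions | None = None,
) -> tuple[LdaModel, DocTopicPosterior]:
    """Fit a K-topic LDA model with fixed symmetric prior ``alpha``.

    Empty documents are excluded from fitting and given a uniform
    posterior (gamma = alpha in every component). Runs ``opts.n_restarts``
    seeded initializations and keeps the best final ELBO. Deterministic
    for a fixed ``opts.seed``.
    """
    opts = opts or LdaOptions()
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not corpus.vocabulary:
        raise ValueError("refusing to fit: corpus vocabulary is empty")
    X, fit_ids = _dense_counts(corpus, corpus.vocabulary)
    if X.shape[0] == 0:
        raise ValueError("refusing to fit: all documents are empty")
    if K > X.shape[0]:
        warnings.warn(
            f"K={K} exceeds the {X.shape[0]} non-empty documents; fitting anyway",
            stacklevel=2,
        )
    best = None
    ss = np.random.SeedSequence(opts.seed)
    for child in ss.spawn(max(opts.n_restarts, 1)):
        rng = np.random.default_rng(child)
        beta, gamma, trace, converged = _fit_once(X, K, alpha, opts, rng)
        if best is None or trace[-1] > best[2][-1]:
            best = (beta, gamma, trace, converged)
    beta, gamma_fit, trace, converged = best
    model = LdaModel(
        K=K,
        alpha=float(alpha),
        beta=beta,
        vocabulary=list(corpus.vocabulary),
        eta=opts.eta,
        converged=converged,
        elbo_trace=trace,
        seed=opts.seed,
    )
    # posterior for every document, empty ones uniform
    gamma_all = np.full((len(corpus.documents), K), float(alpha))
    by_id = {pid: g for pid, g in zip(fit_ids, gamma_fit)}
    post_ids = [d.post_id for d in corpus.documents]
    for i, pid in enumerate(post_ids):
        if pid in by_id:
            gamma_all[i] = by_id[pid]
    return model, DocTopicPosterior(post_ids=post_ids, gamma=gamma_all)


def log_likelihood_bound(
    model: LdaModel, corpus: CuiCorpus, opts: LdaOptions | None = None
) -> float:
    """Variational lower bound on log p(corpus | alpha, beta), with
    per-document variational parameters freshly optimized. Never exceeds
    the exact marginal log-likelihood at the same (alpha, beta)."""
    opts = opts or LdaOptions(eta=model.eta, seed=model.seed)
    X, _ = _dense_counts(corpus, model.vocabulary)
    gamma, _ = _e_step(X, model.beta, model.alpha, opts.var_tol, opts.max_var_iter)
    return float(_per_doc_bound(X, gamma, model.beta, model.alpha).sum())


def perplexity(
    model: LdaModel, corpus: CuiCorpus, opts: LdaOptions | None = None
) -> float:
    """exp(-sum_d bound_d / sum_d N_d) with freshly optimized per-document
    variational parameters; lower is better."""
    opts = opts or LdaOptions(eta=model.eta, seed=model.seed)
    X, _ = _dense_counts(corpus, model.vocabulary)
    if X.shape[0] == 0:
        raise ValueError("perplexity undefined on an all-empty corpus")
    gamma, _ = _e_step(X, model.beta, model.alpha, opts.var_tol, opts.max_var_iter)
    bound = _per_doc_bound(X, gamma, model.beta, model.alpha).sum()
    return float(np.exp(-bound / X.sum()))


def _split_corpus(
    corpus: CuiCorpus, heldout_fraction: float, seed: int
) -> tuple[CuiCorpus, CuiCorpus]:
    rng = np.random.default_rng(seed)
    docs = list(corpus.documents)
    idx = rng.permutation(len(docs))
    n_hold = int(round(heldout_fraction * len(docs)))
    hold = {int(i) for i in idx[:n_hold]}
    train = [d for i, d in enumerate(docs) if i not in hold]
    held = [d for i, d in enumerate(docs) if i in hold]
    return (
        CuiCorpus(documents=train, vocabulary=list(corpus.vocabulary)),
        CuiCorpus(documents=held, vocabulary=list(corpus.vocabulary)),
    )


def grid_search(
    corpus: CuiCorpus,
    K_grid: Sequence[int] = K_GRID_DEFAULT,
    alpha_grid: Sequence[float] = ALPHA_GRID_DEFAULT,
    opts: LdaOptions | None = None,
    heldout_fraction: float = 0.0,
) -> GridResult:
    """Fit every (K, alpha) pair and rank by perplexity (ascending).

    By default perplexity is computed on the training corpus; with
    ``heldout_fraction`` > 0 a seeded document split is held out and scored
    instead. No winner is auto-selected.
    """
    if not K_grid or not alpha_grid:
        raise ValueError("grids must be non-empty")
    opts = opts or LdaOptions()
    if heldout_fraction > 0:
        train, held = _split_corpus(corpus, heldout_fraction, opts.seed)
        if held.n_tokens == 0:
            raise ValueError("held-out split contains no tokens")
    else:
        train, held = corpus, corpus
    rows = []
    for K in K_grid:
        for alpha in alpha_grid:
            try:
                model, _ = fit_lda(train, K, alpha, opts)
                rows.append(
                    {
                        "K": int(K),
                        "alpha": float(alpha),
                        "perplexity": perplexity(model, held, opts),
                        "elbo": model.elbo,
                        "model": model,
                    }
                )
            except Exception as exc:
                raise RuntimeError(f"grid fit failed at (K={K}, alpha={alpha}): {exc}") from exc
    rows.sort(key=lambda r: r["perplexity"])
    return GridResult(rows=rows)


def save_model(
    model: LdaModel, posterior: DocTopicPosterior, out_dir: str | Path
) -> None:
    """Vocabulary file + dense beta text matrix + JSON header + gamma TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "vocabulary.txt").write_text(
        "".join(c + "\n" for c in model.vocabulary), encoding="utf-8"
    )
    np.savetxt(out / "beta.txt", model.beta, fmt="%.10e")
    (out / "model.json").write_text(
        json.dumps(
            {
                "K": model.K,
                "alpha": model.alpha,
                "eta": model.eta,
                "seed": model.seed,
                "converged": model.converged,
                "elbo": model.elbo,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    with open(out / "gamma.tsv", "w", encoding="utf-8") as fh:
        fh.write("post_id\t" + "\t".join(f"g{k+1}" for k in range(model.K)) + "\n")
        for pid, row in zip(posterior.post_ids, posterior.gamma):
            fh.write(pid + "\t" + "\t".join(f"{v:.10e}" for v in row) + "\n")


def load_model(out_dir: str | Path) -> tuple[LdaModel, DocTopicPosterior]:
    out = Path(out_dir)
    header = json.loads((out / "model.json").read_text(encoding="utf-8"))
    vocab = [
        line.strip()
        for line in (out / "vocabulary.txt").read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    beta = np.loadtxt(out / "beta.txt", ndmin=2)
    post_ids, gammas = [], []
    with open(out / "gamma.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            post_ids.append(parts[0])
            gammas.append([float(v) for v in parts[1:]])
    model = LdaModel(
        K=int(header["K"]),
        alpha=float(header["alpha"]),
        beta=beta,
        vocabulary=vocab,
        eta=float(header["eta"]),
        converged=bool(header["converged"]),
        elbo_trace=[float(header["elbo"])],
        seed=int(header["seed"]),
    )
    return model, DocTopicPosterior(post_ids=post_ids, gamma=np.asarray(gammas))
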