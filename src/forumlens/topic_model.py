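"""Latent Dirichlet Allocation by collapsed Gibbs sampling.

Each document (post) is modelled as a mixture over K topics and each topic
as a distribution over the vocabulary.  Inference integrates out the
mixture weights θ and topic-word distributions φ and resamples each
token's topic assignment from the collapsed conditional

    p(z_i = k | z_-i, w)  ∝  (n_dk^{-i} + α) · (n_kw^{-i} + β) / (n_k^{-i} + V·β)

where ``n_dk`` counts tokens of document d assigned to topic k, ``n_kw``
counts tokens of word w assigned to k, and ``n_k`` is the per-topic total.
θ and φ are recovered from the count tables as posterior-predictive means,
optionally averaged over thinned post-burn-in samples.

All randomness flows through one seeded generator; tokens are visited in
document order then token order, so identical seed and input give
bit-identical assignments.  The per-token resampling loop is JIT-compiled
(numba); its uniform variates are drawn outside the kernel.

For tiny corpora, :func:`enumerate_posterior_theta` computes the exact
posterior mean of θ by summing over all K^N assignment vectors — an
independent brute-force reference for validating the sampler.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln

from forumlens.corpus_io import Corpus
from forumlens.errors import ValidationError

__all__ = [
    "LdaParams",
    "TopicModelState",
    "DocTopicMatrix",
    "TopicWordMatrix",
    "fit_lda",
    "fit_lda_docs",
    "estimate_theta",
    "estimate_phi",
    "top_words",
    "greedy_topic_match",
    "enumerate_posterior_theta",
    "collapsed_log_likelihood",
]


@dataclass(frozen=True)
class LdaParams:
    """Sampler configuration.

    ``alpha`` defaults to 50/K and ``beta`` to 0.01 (symmetric Dirichlet
    concentrations); 1000 sweeps with a 500-sweep burn-in, θ/φ averaged
    over every 10th retained sweep.  ``sample_every = 0`` disables
    averaging (estimates then come from the final count tables).
    """

    k: int
    alpha: float | None = None
    beta: float = 0.01
    n_iterations: int = 1000
    burn_in: int = 500
    sample_every: int = 10
    seed: int = 0
    n_chains: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"K must be >= 1, got {self.k}")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.alpha is None:
            object.__setattr__(self, "alpha", 50.0 / self.k)
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if self.beta <= 0:
            raise ValidationError(f"beta must be > 0, got {self.beta}")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValidationError(
                f"burn_in must lie in [0, n_iterations), got {self.burn_in}"
            )
        if self.sample_every < 0:
            raise ValidationError("sample_every must be >= 0")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "alpha": self.alpha,
            "beta": self.beta,
            "n_iterations": self.n_iterations,
            "burn_in": self.burn_in,
            "sample_every": self.sample_every,
            "seed": self.seed,
            "n_chains": self.n_chains,
        }


@dataclass
class DocTopicMatrix:
    """Documents × K matrix of topic proportions (rows sum to 1)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValidationError("theta must be 2-dimensional")
        if self.theta.size:
            if self.theta.min() < 0:
                raise ValidationError("theta has negative entries")
            sums = self.theta.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValidationError("theta rows must sum to 1 (±1e-9)")

    @property
    def n_documents(self) -> int:
        return self.theta.shape[0]

    @property
    def k(self) -> int:
        return self.theta.shape[1]

    @classmethod
    def from_rows(cls, rows: np.ndarray, normalize: bool = False) -> "DocTopicMatrix":
        rows = np.asarray(rows, dtype=float)
        if normalize and rows.size:
            sums = rows.sum(axis=1, keepdims=True)
            if (sums <= 0).any():
                raise ValidationError("cannot normalize a zero row")
            rows = rows / sums
        return cls(rows)


@dataclass
class TopicWordMatrix:
    """K × V matrix of topic-word probabilities (rows sum to 1)."""

    phi: np.ndarray
    vocabulary: list[str] | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValidationError("phi must be 2-dimensional")
        if self.phi.size:
            if self.phi.min() < 0:
                raise ValidationError("phi has negative entries")
            sums = self.phi.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValidationError("phi rows must sum to 1 (±1e-9)")
        if self.vocabulary is not None and len(self.vocabulary) != self.phi.shape[1]:
            raise ValidationError("vocabulary length does not match phi columns")

    @property
    def k(self) -> int:
        return self.phi.shape[0]

    @property
    def n_vocab(self) -> int:
        return self.phi.shape[1]


@dataclass
class TopicModelState:
    """Token-level assignments and sufficient statistics of a fitted model."""

    z: np.ndarray          # topic per token occurrence (flattened doc order)
    token_doc: np.ndarray  # document index per token occurrence
    token_word: np.ndarray  # word id per token occurrence
    n_dk: np.ndarray       # (D, K) document-topic counts
    n_kw: np.ndarray       # (K, V) topic-word counts
    n_k: np.ndarray        # (K,) topic totals
    params: LdaParams
    vocabulary: list[str]
    doc_lengths: np.ndarray
    theta_sum: np.ndarray | None = None
    phi_sum: np.ndarray | None = None
    n_samples: int = 0

    @property
    def n_documents(self) -> int:
        return self.n_dk.shape[0]

    @property
    def n_vocab(self) -> int:
        return self.n_kw.shape[1]

    def check_invariants(self) -> None:
        """Count-conservation checks; cheap enough to assert mid-run."""
        if (self.n_dk < 0).any() or (self.n_kw < 0).any() or (self.n_k < 0).any():
            raise ValidationError("negative counts")
        if not np.array_equal(self.n_dk.sum(axis=1), self.doc_lengths):
            raise ValidationError("n_dk rows do not sum to document lengths")
        if not np.array_equal(self.n_kw.sum(axis=1), self.n_k):
            raise ValidationError("n_kw rows do not sum to n_k")
        ndk = np.zeros_like(self.n_dk)
        nkw = np.zeros_like(self.n_kw)
        np.add.at(ndk, (self.token_doc, self.z), 1)
        np.add.at(nkw, (self.z, self.token_word), 1)
        if not (np.array_equal(ndk, self.n_dk) and np.array_equal(nkw, self.n_kw)):
            raise ValidationError("count tables inconsistent with z")

    def save(self, path: str | Path) -> Path:
        """Serialize the full state to a single .npz archive."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path,
            z=self.z,
            token_doc=self.token_doc,
            token_word=self.token_word,
            n_dk=self.n_dk,
            n_kw=self.n_kw,
            n_k=self.n_k,
            doc_lengths=self.doc_lengths,
            theta_sum=self.theta_sum if self.theta_sum is not None else np.empty(0),
            phi_sum=self.phi_sum if self.phi_sum is not None else np.empty(0),
            n_samples=np.array(self.n_samples),
            params_json=np.array(json.dumps(self.params.to_dict())),
            vocabulary=np.array(self.vocabulary, dtype=object),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TopicModelState":
        with np.load(Path(path), allow_pickle=True) as arc:
            params = LdaParams(**json.loads(str(arc["params_json"])))
            theta_sum = arc["theta_sum"]
            phi_sum = arc["phi_sum"]
            return cls(
                z=arc["z"],
                token_doc=arc["token_doc"],
                token_word=arc["token_word"],
                n_dk=arc["n_dk"],
                n_kw=arc["n_kw"],
                n_k=arc["n_k"],
                params=params,
                vocabulary=[str(w) for w in arc["vocabulary"]],
                doc_lengths=arc["doc_lengths"],
                theta_sum=theta_sum if theta_sum.size else None,
                phi_sum=phi_sum if phi_sum.size else None,
                n_samples=int(arc["n_samples"]),
            )


@njit(cache=True)
def _gibbs_init(token_word, token_doc, z, n_dk, n_kw, n_k, alpha, beta, u):
    """Incremental initialization: assign tokens one at a time from the
    collapsed conditional given the tokens assigned so far.  Starting the
    chain near a coherent mode this way makes it far less likely to settle
    into merged-topic local optima than uniform random assignment."""
    n_topics = n_dk.shape[1]
    n_vocab = n_kw.shape[1]
    cum = np.empty(n_topics)
    for i in range(token_word.shape[0]):
        w = token_word[i]
        d = token_doc[i]
        total = 0.0
        for kk in range(n_topics):
            total += (
                (n_dk[d, kk] + alpha)
                * (n_kw[kk, w] + beta)
                / (n_k[kk] + n_vocab * beta)
            )
            cum[kk] = total
        r = u[i] * total
        k = 0
        while cum[k] < r and k < n_topics - 1:
            k += 1
        z[i] = k
        n_dk[d, k] += 1
        n_kw[k, w] += 1
        n_k[k] += 1


@njit(cache=True)
def _gibbs_sweep(token_word, token_doc, z, n_dk, n_kw, n_k, alpha, beta, u):
    """One full sweep: resample every token's topic in order."""
    n_topics = n_dk.shape[1]
    n_vocab = n_kw.shape[1]
    cum = np.empty(n_topics)
    for i in range(token_word.shape[0]):
        w = token_word[i]
        d = token_doc[i]
        k = z[i]
        n_dk[d, k] -= 1
        n_kw[k, w] -= 1
        n_k[k] -= 1
        total = 0.0
        for kk in range(n_topics):
            total += (
                (n_dk[d, kk] + alpha)
                * (n_kw[kk, w] + beta)
                / (n_k[kk] + n_vocab * beta)
            )
            cum[kk] = total
        r = u[i] * total
        k = 0
        while cum[k] < r and k < n_topics - 1:
            k += 1
        z[i] = k
        n_dk[d, k] += 1
        n_kw[k, w] += 1
        n_k[k] += 1


def _theta_from_counts(n_dk: np.ndarray, alpha: float) -> np.ndarray:
    k = n_dk.shape[1]
    lengths = n_dk.sum(axis=1, keepdims=True)
    return (n_dk + alpha) / (lengths + k * alpha)


def _phi_from_counts(n_kw: np.ndarray, beta: float) -> np.ndarray:
    v = n_kw.shape[1]
    totals = n_kw.sum(axis=1, keepdims=True)
    return (n_kw + beta) / (totals + v * beta)


def collapsed_log_likelihood(
    n_dk: np.ndarray, n_kw: np.ndarray, n_k: np.ndarray,
    alpha: float, beta: float,
) -> float:
    """log p(z, w) up to assignment-independent constants.

    Chains are ranked by the mean of this quantity over their retained
    post-burn-in samples: degenerate local modes (two topics merged, a
    topic starved empty) and chains still converging during the sampling
    window both score systematically lower than a well-mixed chain.
    """
    n_vocab = n_kw.shape[1]
    return float(
        gammaln(n_dk + alpha).sum()
        + gammaln(n_kw + beta).sum()
        - gammaln(n_k + n_vocab * beta).sum()
    )


def _run_chain(token_word, token_doc, doc_lengths, n_docs, n_vocab,
               params: LdaParams, seed: int):
    rng = np.random.default_rng(seed)
    k = params.k
    n_tokens = token_word.shape[0]
    z = np.zeros(n_tokens, dtype=np.int64)
    n_dk = np.zeros((n_docs, k), dtype=np.int64)
    n_kw = np.zeros((k, n_vocab), dtype=np.int64)
    n_k = np.zeros(k, dtype=np.int64)
    alpha = float(params.alpha)  # type: ignore[arg-type]
    beta = float(params.beta)
    _gibbs_init(token_word, token_doc, z, n_dk, n_kw, n_k, alpha, beta,
                rng.random(n_tokens))
    theta_sum = np.zeros((n_docs, k))
    phi_sum = np.zeros((k, n_vocab))
    n_samples = 0
    log_lik_sum = 0.0
    for sweep in range(params.n_iterations):
        _gibbs_sweep(token_word, token_doc, z, n_dk, n_kw, n_k, alpha, beta,
                     rng.random(n_tokens))
        if (
            params.sample_every
            and sweep >= params.burn_in
            and (sweep - params.burn_in) % params.sample_every == 0
        ):
            theta_sum += _theta_from_counts(n_dk, alpha)
            phi_sum += _phi_from_counts(n_kw, beta)
            log_lik_sum += collapsed_log_likelihood(n_dk, n_kw, n_k, alpha, beta)
            n_samples += 1
    if n_samples:
        score = log_lik_sum / n_samples
    else:
        score = collapsed_log_likelihood(n_dk, n_kw, n_k, alpha, beta)
    return z, n_dk, n_kw, n_k, theta_sum, phi_sum, n_samples, score


def fit_lda_docs(
    docs: Sequence[np.ndarray],
    n_vocab: int,
    params: LdaParams,
    vocabulary: Sequence[str] | None = None,
) -> TopicModelState:
    """Fit LDA on pre-encoded documents (token-id arrays).

    Runs ``params.n_chains`` independent chains (seeds derived from
    ``params.seed``) and returns the one with the highest collapsed joint
    likelihood at its final sweep.  Empty documents are retained (they get
    a prior-only, uniform θ row); at least one document must be non-empty.
    """
    if not len(docs):
        raise ValidationError("corpus has no documents")
    doc_lengths = np.array([len(d) for d in docs], dtype=np.int64)
    n_tokens = int(doc_lengths.sum())
    if n_tokens == 0:
        raise ValidationError("all documents are empty; nothing to fit")
    for d in docs:
        if len(d) and (np.asarray(d).max() >= n_vocab or np.asarray(d).min() < 0):
            raise ValidationError("token id outside vocabulary range")

    token_word = np.concatenate(
        [np.asarray(d, dtype=np.int64) for d in docs if len(d)]
    )
    token_doc = np.repeat(np.arange(len(docs), dtype=np.int64), doc_lengths)

    seed_rng = np.random.default_rng(params.seed)
    chain_seeds = [int(s) for s in seed_rng.integers(0, 2**31 - 1,
                                                     size=params.n_chains)]
    best = None
    for chain_seed in chain_seeds:
        result = _run_chain(token_word, token_doc, doc_lengths, len(docs),
                            n_vocab, params, chain_seed)
        if best is None or result[-1] > best[-1]:
            best = result
    z, n_dk, n_kw, n_k, theta_sum, phi_sum, n_samples, _ = best  # type: ignore[misc]

    vocab = (
        list(vocabulary)
        if vocabulary is not None
        else [f"w{i}" for i in range(n_vocab)]
    )
    return TopicModelState(
        z=z,
        token_doc=token_doc,
        token_word=token_word,
        n_dk=n_dk,
        n_kw=n_kw,
        n_k=n_k,
        params=params,
        vocabulary=vocab,
        doc_lengths=doc_lengths,
        theta_sum=theta_sum if n_samples else None,
        phi_sum=phi_sum if n_samples else None,
        n_samples=n_samples,
    )


def fit_lda(corpus: Corpus, params: LdaParams) -> TopicModelState:
    """Fit LDA to a tokenized corpus (one document per post)."""
    if not corpus.is_tokenized or corpus.vocabulary is None:
        raise ValidationError("corpus must be tokenized before fitting")
    vocab_words = [None] * len(corpus.vocabulary)
    for word, idx in corpus.vocabulary.items():
        vocab_words[idx] = word
    return fit_lda_docs(
        corpus.docs_as_ids(),
        n_vocab=len(corpus.vocabulary),
        params=params,
        vocabulary=[w for w in vocab_words],  # type: ignore[misc]
    )


def estimate_theta(state: TopicModelState) -> DocTopicMatrix:
    """Posterior-mean document-topic proportions.

    ``theta[d,k] = (n_dk[d,k] + α) / (N_d + K·α)``, averaged over retained
    post-burn-in samples when sample averaging was enabled.  Empty
    documents get the uniform prior row 1/K.
    """
    if state.n_samples and state.theta_sum is not None:
        return DocTopicMatrix(state.theta_sum / state.n_samples)
    return DocTopicMatrix(
        _theta_from_counts(state.n_dk, float(state.params.alpha))  # type: ignore[arg-type]
    )


def estimate_phi(state: TopicModelState) -> TopicWordMatrix:
    """Posterior-mean topic-word distributions.

    ``phi[k,w] = (n_kw[k,w] + β) / (n_k[k] + V·β)``; topics never sampled
    get the uniform prior row 1/V.
    """
    if state.n_samples and state.phi_sum is not None:
        return TopicWordMatrix(state.phi_sum / state.n_samples, state.vocabulary)
    return TopicWordMatrix(
        _phi_from_counts(state.n_kw, state.params.beta), state.vocabulary
    )


def top_words(phi: TopicWordMatrix, m: int) -> list[list[str]]:
    """The m highest-probability terms per topic, ties broken by word id."""
    if m > phi.n_vocab:
        raise ValidationError(f"m={m} exceeds vocabulary size {phi.n_vocab}")
    vocab = phi.vocabulary or [f"w{i}" for i in range(phi.n_vocab)]
    out = []
    for row in phi.phi:
        # stable sort on -p keeps ascending word-id order within ties
        order = np.argsort(-row, kind="stable")[:m]
        out.append([vocab[i] for i in order])
    return out


def top_words_table(phi: TopicWordMatrix, m: int) -> "list[tuple[int, int, str, float]]":
    """(topic, rank, term, probability) rows for the top-words report."""
    if m > phi.n_vocab:
        raise ValidationError(f"m={m} exceeds vocabulary size {phi.n_vocab}")
    vocab = phi.vocabulary or [f"w{i}" for i in range(phi.n_vocab)]
    rows = []
    for k, row in enumerate(phi.phi):
        order = np.argsort(-row, kind="stable")[:m]
        for rank, i in enumerate(order, start=1):
            rows.append((k, rank, vocab[i], float(row[i])))
    return rows


def greedy_topic_match(
    phi_est: np.ndarray, phi_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedily pair estimated topics with ground-truth topics by L1 distance.

    Repeatedly takes the globally closest unmatched (estimated, true) pair.
    Returns ``(perm, l1)`` where ``perm[j]`` is the estimated topic matched
    to true topic ``j`` and ``l1[j]`` the L1 distance of that pair.
    Label-switching makes this step necessary before any recovery metric.
    """
    phi_est = np.asarray(phi_est, dtype=float)
    phi_true = np.asarray(phi_true, dtype=float)
    if phi_est.shape != phi_true.shape:
        raise ValidationError("phi matrices must have identical shapes")
    k = phi_est.shape[0]
    dist = np.abs(phi_est[:, None, :] - phi_true[None, :, :]).sum(axis=2)
    perm = np.full(k, -1, dtype=np.int64)
    l1 = np.zeros(k)
    work = dist.copy()
    for _ in range(k):
        i, j = np.unravel_index(np.argmin(work), work.shape)
        perm[j] = i
        l1[j] = dist[i, j]
        work[i, :] = np.inf
        work[:, j] = np.inf
    return perm, l1


def enumerate_posterior_theta(
    docs: Sequence[np.ndarray], n_vocab: int, k: int, alpha: float, beta: float,
    max_states: int = 2_000_000,
) -> np.ndarray:
    """Exact posterior mean of θ by exhaustive enumeration over assignments.

    Sums the collapsed joint p(z, w) over all K^N topic-assignment vectors
    (N = total tokens); only feasible for toy corpora, and used as the
    independent reference the sampler is validated against.
    """
    docs = [np.asarray(d, dtype=np.int64) for d in docs]
    n_tokens = int(sum(len(d) for d in docs))
    n_states = k ** n_tokens
    if n_states > max_states:
        raise ValidationError(
            f"{n_states} assignment states exceed the enumeration limit"
        )
    token_doc = np.repeat(np.arange(len(docs)), [len(d) for d in docs])
    token_word = np.concatenate([d for d in docs if len(d)]) if n_tokens else np.empty(0, np.int64)
    doc_lengths = np.array([len(d) for d in docs], dtype=float)

    theta_acc = np.zeros((len(docs), k))
    log_weights = []
    thetas = []
    for assignment in itertools.product(range(k), repeat=n_tokens):
        z = np.array(assignment, dtype=np.int64)
        n_dk = np.zeros((len(docs), k))
        n_kw = np.zeros((k, n_vocab))
        np.add.at(n_dk, (token_doc, z), 1)
        np.add.at(n_kw, (z, token_word), 1)
        n_k = n_kw.sum(axis=1)
        # log p(z, w) up to assignment-independent constants
        lw = (
            gammaln(n_dk + alpha).sum()
            + gammaln(n_kw + beta).sum()
            - gammaln(n_k + n_vocab * beta).sum()
        )
        log_weights.append(lw)
        thetas.append((n_dk + alpha) / (doc_lengths[:, None] + k * alpha))
    log_weights = np.array(log_weights)
    weights = np.exp(log_weights - log_weights.max())
    weights /= weights.sum()
    for w_i, th in zip(weights, thetas):
        theta_acc += w_i * th
    return theta_acc
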