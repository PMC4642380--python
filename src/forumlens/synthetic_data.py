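"""Synthetic forum corpora with known LDA structure and lexicon prevalence.

The crawled forum data behind the original analyses is not
redistributable, so every pipeline stage is exercised against corpora
drawn from the very generative model the topic model assumes: per-topic
word distributions φ from a symmetric Dirichlet(β_true), per-post topic
mixtures θ from Dirichlet(α_true), post lengths log-normal, tokens drawn
topic-then-word.  Ground truth (θ, φ, topic assignments, injection flags)
is returned alongside the corpus so recovery can be measured.

Lexicon terms are injected by exact count: round(p·n_posts) distinct posts
receive one term each, so the prevalence statistic must recover p exactly
rather than approximately — an equality test, not a statistical one.

Default scale echoes the smallest real forums studied (about two thousand
posts, log-normal token counts with mean 189 and SD 378); content is
deliberately abstract ("w0001", ...), only scale is emulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from forumlens.corpus_io import Corpus, ForumPost
from forumlens.errors import ValidationError
from forumlens.lexicon_prevalence import Lexicon

__all__ = ["SimConfig", "GroundTruth", "simulate_corpus", "inject_lexicon_terms"]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    ``post_length_mean`` / ``post_length_sd`` parameterize the log-normal
    token-count distribution (minimum 1 token per post).  ``injection``
    lists (category, prevalence) pairs applied after text generation; the
    named categories must exist in the lexicon collection supplied to
    :func:`simulate_corpus`.
    """

    n_posts: int = 2092
    post_length_mean: float = 189.0
    post_length_sd: float = 378.0
    k_true: int = 20
    v: int = 2000
    alpha_true: float = 0.1
    beta_true: float = 0.05
    injection: tuple[tuple[str, float], ...] = ()
    seed: int = 0
    forum_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_posts < 1:
            raise ValidationError("n_posts must be >= 1")
        if self.v < self.k_true:
            raise ValidationError(
                f"vocabulary size {self.v} must be >= K_true={self.k_true}"
            )
        if self.k_true < 1:
            raise ValidationError("K_true must be >= 1")
        if self.alpha_true <= 0 or self.beta_true <= 0:
            raise ValidationError("Dirichlet concentrations must be > 0")
        if self.post_length_mean <= 0 or self.post_length_sd < 0:
            raise ValidationError("post length mean must be > 0, SD >= 0")
        for cat, p in self.injection:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"injection prevalence for {cat!r} outside [0, 1]: {p}"
                )
        object.__setattr__(
            self, "injection", tuple((c, float(p)) for c, p in self.injection)
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            raw = (
                json.load(fh)
                if path.suffix.lower() == ".json"
                else yaml.safe_load(fh)
            ) or {}
        if "injection" in raw:
            raw["injection"] = tuple(
                (str(item[0]), float(item[1])) for item in raw["injection"]
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "n_posts": self.n_posts,
            "post_length_mean": self.post_length_mean,
            "post_length_sd": self.post_length_sd,
            "k_true": self.k_true,
            "v": self.v,
            "alpha_true": self.alpha_true,
            "beta_true": self.beta_true,
            "injection": [list(pair) for pair in self.injection],
            "seed": self.seed,
            "forum_id": self.forum_id,
        }


@dataclass
class GroundTruth:
    """What the generator knows: mixtures, topics, assignments, injections."""

    theta_true: np.ndarray               # (n_posts, K_true)
    phi_true: np.ndarray                 # (K_true, V)
    z_true: list[np.ndarray]             # per-post topic assignments
    injected_flags: dict[str, np.ndarray] = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {
            "theta_true": self.theta_true,
            "phi_true": self.phi_true,
            "z_lengths": np.array([len(z) for z in self.z_true]),
            "z_flat": (
                np.concatenate(self.z_true)
                if self.z_true
                else np.empty(0, dtype=np.int64)
            ),
        }
        for cat, flags in self.injected_flags.items():
            arrays[f"flags::{cat}"] = flags
        np.savez_compressed(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with np.load(Path(path)) as arc:
            lengths = arc["z_lengths"]
            flat = arc["z_flat"]
            z_true = []
            offset = 0
            for n in lengths:
                z_true.append(flat[offset:offset + int(n)].astype(np.int64))
                offset += int(n)
            flags = {
                key.split("::", 1)[1]: arc[key]
                for key in arc.files
                if key.startswith("flags::")
            }
            return cls(
                theta_true=arc["theta_true"],
                phi_true=arc["phi_true"],
                z_true=z_true,
                injected_flags=flags,
            )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _sample_categorical(rng: np.random.Generator, cdf: np.ndarray, size: int) -> np.ndarray:
    return np.searchsorted(cdf, rng.random(size), side="right").astype(np.int64)


def simulate_corpus(
    cfg: SimConfig,
    lexicons: Sequence[Lexicon] | None = None,
) -> tuple[Corpus, GroundTruth]:
    """Draw a forum corpus from the LDA generative process.

    Returns the corpus already tokenized, with the vocabulary in generator
    id order (so fitted φ columns align with ``GroundTruth.phi_true``
    without re-indexing), plus the ground truth.  ``lexicons`` supplies the
    term lists for any injections configured in ``cfg``; the packaged
    starter lexicons are used when omitted.
    """
    rng = np.random.default_rng(cfg.seed)
    k, v, n = cfg.k_true, cfg.v, cfg.n_posts

    phi_true = rng.dirichlet(np.full(v, cfg.beta_true), size=k)
    theta_true = rng.dirichlet(np.full(k, cfg.alpha_true), size=n)

    mu, sigma = _lognormal_params(cfg.post_length_mean, cfg.post_length_sd)
    lengths = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n))).astype(np.int64)

    width = max(4, len(str(v - 1)))
    words = [f"w{i:0{width}d}" for i in range(v)]

    theta_cdf = np.cumsum(theta_true, axis=1)
    phi_cdf = np.cumsum(phi_true, axis=1)

    posts: list[ForumPost] = []
    tokens: list[list[str]] = []
    z_true: list[np.ndarray] = []
    id_width = len(str(n))
    for d in range(n):
        length = int(lengths[d])
        zs = np.searchsorted(theta_cdf[d], rng.random(length), side="right")
        zs = np.minimum(zs, k - 1).astype(np.int64)
        ws = np.empty(length, dtype=np.int64)
        for topic in np.unique(zs):
            idx = np.nonzero(zs == topic)[0]
            ws[idx] = np.minimum(
                np.searchsorted(phi_cdf[topic], rng.random(idx.size), side="right"),
                v - 1,
            )
        toks = [words[w] for w in ws]
        posts.append(
            ForumPost(
                forum_id=cfg.forum_id,
                post_id=f"p{d:0{id_width}d}",
                text=" ".join(toks),
            )
        )
        tokens.append(toks)
        z_true.append(zs)

    corpus = Corpus(forum_id=cfg.forum_id, posts=posts)
    corpus.tokens = tokens
    corpus.vocabulary = {w: i for i, w in enumerate(words)}
    truth = GroundTruth(theta_true=theta_true, phi_true=phi_true, z_true=z_true)

    if cfg.injection:
        if lexicons is None:
            from forumlens.lexicon_prevalence import default_lexicons

            lexicons = default_lexicons()
        by_cat = {lx.category: lx for lx in lexicons}
        for cat, p in cfg.injection:
            if cat not in by_cat:
                raise ValidationError(f"injection category {cat!r} not in lexicons")
            child_seed = int(rng.integers(0, 2**31 - 1))
            corpus, flags = inject_lexicon_terms(corpus, by_cat[cat], p, child_seed)
            truth.injected_flags[cat] = flags

    return corpus, truth


def inject_lexicon_terms(
    corpus: Corpus, lexicon: Lexicon, p: float, seed: int = 0
) -> tuple[Corpus, np.ndarray]:
    """Append lexicon terms to exactly round(p·n_posts) distinct posts.

    Posts already containing a lexicon term count toward the quota; the
    remainder is filled by appending one uniformly chosen term to posts
    drawn without replacement from the non-matching ones.  Returns a new
    (untokenized) corpus and the per-post boolean flags; ``prevalence`` on
    the result equals the injected fraction exactly.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"prevalence p must lie in [0, 1], got {p}")
    if not lexicon.terms:
        raise ValidationError(f"lexicon {lexicon.category!r} has no terms")
    n = len(corpus)
    # round-half-up so p=0.25, n=2000 -> 500 and p=0.5, n=3 -> 2
    quota = int(np.floor(p * n + 0.5))
    pat = lexicon.pattern()
    natural = np.array(
        [pat.search(post.text.lower()) is not None for post in corpus.posts]
    )
    n_natural = int(natural.sum())
    if n_natural > quota:
        raise ValidationError(
            f"{n_natural} posts already match lexicon {lexicon.category!r}; "
            f"cannot reach an exact prevalence of {p}"
        )
    rng = np.random.default_rng(seed)
    candidates = np.nonzero(~natural)[0]
    chosen = rng.choice(candidates, size=quota - n_natural, replace=False)
    terms = sorted(lexicon.terms)
    flags = natural.copy()
    new_posts = list(corpus.posts)
    for d in chosen:
        term = terms[int(rng.integers(0, len(terms)))]
        post = new_posts[d]
        new_posts[d] = ForumPost(
            forum_id=post.forum_id,
            post_id=post.post_id,
            text=(post.text + " " + term) if post.text else term,
            thread_id=post.thread_id,
            author=post.author,
            timestamp=post.timestamp,
        )
        flags[d] = True
    return Corpus(forum_id=corpus.forum_id, posts=new_posts), flags
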