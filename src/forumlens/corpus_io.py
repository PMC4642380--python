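"""Forum-post corpora: reading, writing, validation and tokenization.

The unit of analysis is the individual post (one document = one post).
Corpora are stored natively as JSONL (one post object per line, which is
robust to newlines inside post text); RFC-4180 CSV is supported for small
fixtures.  A reader for the tab-separated per-document topic-composition
dialect emitted by common topic-modelling toolkits (doc index, doc name,
then alternating topic-id / proportion pairs) provides interop with
externally fitted models.

Tokenization deliberately does **not** stem: keeping the original word
forms (lowercased only) makes fitted topics easier to read.  The stop list
is expected to be augmented with forum-specific noise — contraction
fragments such as ``ill`` (I'll) and ``dont``, and member usernames.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from forumlens.errors import ParseError, ValidationError

__all__ = [
    "ForumPost",
    "Corpus",
    "StopWordList",
    "read_posts",
    "write_posts",
    "tokenize",
    "read_stop_words",
    "read_doc_topics",
    "write_doc_topics",
]

_POST_FIELDS = ("forum_id", "thread_id", "post_id", "author", "timestamp", "text")

# Apostrophes (straight and typographic) are deleted before splitting so
# contractions collapse to the forms stop lists carry: "I'll" -> "ill".
_APOSTROPHES = re.compile(r"[’']")
_NON_ALNUM = re.compile(r"[^\w]+", re.UNICODE)


@dataclass(frozen=True)
class ForumPost:
    """A single forum post; ``post_id`` is unique within its forum."""

    forum_id: str
    post_id: str
    text: str = ""
    thread_id: str = ""
    author: str = ""
    timestamp: str = ""


@dataclass
class StopWordList:
    """A set of lowercase stop words (no internal whitespace)."""

    words: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        words = frozenset(w for w in self.words)
        for w in words:
            if w != w.lower() or any(c.isspace() for c in w):
                raise ValidationError(
                    f"stop word {w!r} must be lowercase with no whitespace"
                )
        object.__setattr__(self, "words", words)

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)

    @classmethod
    def from_words(cls, words: Iterable[str]) -> "StopWordList":
        return cls(frozenset(w.strip().lower() for w in words if w.strip()))


def tokenize(text: str, stops: StopWordList | None = None) -> list[str]:
    """Tokenize post text for topic modelling.

    Rules: Unicode-aware lowercasing; apostrophes deleted (so "I'll" becomes
    "ill" and can be stop-listed); split on non-alphanumeric characters;
    pure numbers and single-character tokens dropped; stop words removed.
    No stemming.  Deterministic and idempotent on its own output.
    """
    if not text:
        return []
    stops = stops or StopWordList()
    cleaned = _APOSTROPHES.sub("", text.lower())
    out: list[str] = []
    for tok in _NON_ALNUM.split(cleaned):
        if len(tok) <= 1:
            continue
        if tok.isdigit():
            continue
        if tok in stops:
            continue
        out.append(tok)
    return out


@dataclass
class Corpus:
    """An ordered collection of posts from one forum, optionally tokenized.

    ``tokens`` is filled by :meth:`tokenize_posts`; ``vocabulary`` maps each
    retained token to a dense integer id (first-occurrence order).
    """

    forum_id: str
    posts: list[ForumPost] = field(default_factory=list)
    tokens: list[list[str]] | None = None
    vocabulary: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.posts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.forum_id == other.forum_id and self.posts == other.posts

    def validate(self) -> None:
        seen: set[str] = set()
        for i, post in enumerate(self.posts):
            if post.post_id in seen:
                raise ValidationError(
                    f"duplicate post_id {post.post_id!r} in forum "
                    f"{self.forum_id!r} (record {i})"
                )
            seen.add(post.post_id)
        if self.tokens is not None and len(self.tokens) != len(self.posts):
            raise ValidationError("tokens and posts have different lengths")

    @property
    def is_tokenized(self) -> bool:
        return self.tokens is not None

    def tokenize_posts(self, stops: StopWordList | None = None) -> "Corpus":
        """Tokenize every post in place and build the dense vocabulary."""
        stops = stops or StopWordList()
        self.tokens = [tokenize(p.text, stops) for p in self.posts]
        vocab: dict[str, int] = {}
        for seq in self.tokens:
            for tok in seq:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
        self.vocabulary = vocab
        return self

    def docs_as_ids(self) -> list[np.ndarray]:
        """Per-post token-id arrays (requires prior tokenization)."""
        if self.tokens is None or self.vocabulary is None:
            raise ValidationError("corpus is not tokenized")
        vocab = self.vocabulary
        return [
            np.array([vocab[t] for t in seq], dtype=np.int64)
            for seq in self.tokens
        ]

    def post_lengths(self) -> np.ndarray:
        if self.tokens is not None:
            return np.array([len(seq) for seq in self.tokens])
        return np.array([len(p.text.split()) for p in self.posts])


def _post_from_record(rec: dict, lineno: int, path: Path) -> ForumPost:
    for required in ("forum_id", "post_id", "text"):
        if required not in rec or rec[required] is None:
            raise ParseError(
                f"{path}:{lineno}: record missing required field {required!r}"
            )
    return ForumPost(
        forum_id=str(rec["forum_id"]),
        post_id=str(rec["post_id"]),
        text=str(rec["text"]),
        thread_id=str(rec.get("thread_id", "") or ""),
        author=str(rec.get("author", "") or ""),
        timestamp=str(rec.get("timestamp", "") or ""),
    )


def _iter_jsonl(path: Path) -> Iterator[tuple[int, dict]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from exc
            if not isinstance(rec, dict):
                raise ParseError(f"{path}:{lineno}: record is not an object")
            yield lineno, rec


def _iter_csv(path: Path) -> Iterator[tuple[int, dict]]:
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return
        for rec in reader:
            lineno = reader.line_num
            if rec.get("text") is None and "text" not in (reader.fieldnames or []):
                raise ParseError(f"{path}:{lineno}: record missing required field 'text'")
            yield lineno, {k: v for k, v in rec.items() if k is not None}


def read_posts(path: str | Path, fmt: str | None = None, forum_id: str | None = None) -> Corpus:
    """Read a post corpus from JSONL or CSV.

    ``fmt`` is inferred from the file extension when omitted.  All records
    must carry ``forum_id``, ``post_id`` and ``text``; other fields default
    to empty.  ``forum_id`` overrides the forum id recorded in the file
    (useful when one file holds a single forum under another name).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if fmt not in ("jsonl", "csv"):
        raise ValidationError(f"unknown corpus format {fmt!r}")
    iterator = _iter_csv(path) if fmt == "csv" else _iter_jsonl(path)
    posts: list[ForumPost] = []
    fid = forum_id
    for lineno, rec in iterator:
        post = _post_from_record(rec, lineno, path)
        if forum_id is not None:
            post = ForumPost(
                forum_id=forum_id,
                post_id=post.post_id,
                text=post.text,
                thread_id=post.thread_id,
                author=post.author,
                timestamp=post.timestamp,
            )
        if fid is None:
            fid = post.forum_id
        posts.append(post)
    return Corpus(forum_id=fid if fid is not None else "", posts=posts)


def write_posts(corpus: Corpus, path: str | Path, fmt: str | None = None) -> Path:
    """Write a corpus so that :func:`read_posts` round-trips it exactly."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if fmt not in ("jsonl", "csv"):
        raise ValidationError(f"unknown corpus format {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for p in corpus.posts:
                fh.write(
                    json.dumps(
                        {f: getattr(p, f) for f in _POST_FIELDS},
                        ensure_ascii=False,
                    )
                )
                fh.write("\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_POST_FIELDS))
            writer.writeheader()
            for p in corpus.posts:
                writer.writerow({f: getattr(p, f) for f in _POST_FIELDS})
    return path


def read_stop_words(*paths: str | Path) -> StopWordList:
    """Read one-word-per-line stop lists; multiple files are unioned."""
    words: set[str] = set()
    for path in paths:
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                w = line.strip().lower()
                if w and not w.startswith("#"):
                    words.add(w)
    return StopWordList(frozenset(words))


def read_doc_topics(path: str | Path, k: int | None = None) -> np.ndarray:
    """Read a per-document topic-composition table (tab-separated dialect).

    Each row is ``doc_index<TAB>doc_name<TAB>topic<TAB>proportion...`` with
    alternating topic-id / proportion pairs in any topic order.  Returns a
    dense (n_documents, K) array ordered by topic id; proportions are
    clipped to [0, 1].  A row whose proportions sum outside [0.99, 1.01]
    raises :class:`ValidationError`.
    """
    path = Path(path)
    rows: list[dict[int, float]] = []
    max_topic = -1
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4 or len(parts) % 2 != 0:
                raise ParseError(
                    f"{path}:{lineno}: expected doc index, name and "
                    f"topic/proportion pairs, got {len(parts)} fields"
                )
            try:
                pairs = {
                    int(parts[i]): float(parts[i + 1])
                    for i in range(2, len(parts), 2)
                }
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            for topic, prop in pairs.items():
                if topic < 0:
                    raise ParseError(f"{path}:{lineno}: negative topic id {topic}")
                if not (-0.01 <= prop <= 1.01):
                    raise ValidationError(
                        f"{path}:{lineno}: proportion {prop} for topic {topic} "
                        "outside [0, 1]"
                    )
            total = sum(pairs.values())
            if not (0.99 <= total <= 1.01):
                raise ValidationError(
                    f"{path}:{lineno}: proportions sum to {total:.4f}, "
                    "outside [0.99, 1.01]"
                )
            max_topic = max(max_topic, max(pairs))
            rows.append(pairs)
    n_topics = k if k is not None else max_topic + 1
    if rows and k is not None and max_topic >= k:
        raise ValidationError(f"topic id {max_topic} >= declared K={k}")
    theta = np.zeros((len(rows), max(n_topics, 0)))
    for d, pairs in enumerate(rows):
        for topic, prop in pairs.items():
            theta[d, topic] = prop
    return np.clip(theta, 0.0, 1.0)


def write_doc_topics(theta: np.ndarray | Sequence[Sequence[float]],
                     path: str | Path,
                     doc_names: Sequence[str] | None = None) -> Path:
    """Write θ in the tab-separated dialect read by :func:`read_doc_topics`.

    Topics are written in descending proportion order per document, as the
    common toolkit output does.
    """
    theta = np.asarray(theta, dtype=float)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for d, row in enumerate(theta):
            name = doc_names[d] if doc_names is not None else f"doc{d}"
            order = np.argsort(-row, kind="stable")
            fields = [str(d), name]
            for kk in order:
                fields.append(str(int(kk)))
                fields.append(repr(float(row[kk])))
            fh.write("\t".join(fields) + "\n")
    return path
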