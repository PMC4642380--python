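"""Lexicon-based prevalence of contextual factors across forums.

Each contextual-factor category (e-cigarette, symptoms, quitting, setting,
time, cost, sensory experience, ...) is operationalised as a term lexicon.
The prevalence of a category in a forum is the proportion of posts that
contain at least one lexicon term; a post counts once per category no
matter how many terms match.  Prevalences across forums and categories are
collected into a matrix and rendered as a heat map (darker hue = more of
that content), which is how forums with the richest discussion of a factor
are identified.

Matching runs on the lowercased raw post text with word-boundary-aware
regular expressions, not on the stop-word-filtered token stream: the stop
list serves topic modelling, and a lexicon term that happens to be
stop-like (e.g. "hit") must still count here.  Multiword terms match as
contiguous word sequences separated by any non-word material.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from forumlens.corpus_io import Corpus
from forumlens.errors import ValidationError

__all__ = [
    "GROUPS",
    "Lexicon",
    "PrevalenceMatrix",
    "load_lexicons",
    "default_lexicons",
    "post_matches",
    "prevalence",
    "render_heatmap",
]

#: The three category groups a contextual factor may belong to.
GROUPS = ("subject matter", "health", "context")


@dataclass(frozen=True)
class Lexicon:
    """A named contextual-factor category and its (lowercase) term list."""

    category: str
    group: str
    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.category:
            raise ValidationError("lexicon category name must be non-empty")
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for category {self.category!r}; "
                f"expected one of {GROUPS}"
            )
        terms = frozenset(t.strip().lower() for t in self.terms)
        if "" in terms:
            raise ValidationError(f"empty term in lexicon {self.category!r}")
        object.__setattr__(self, "terms", terms)

    def with_terms(self, extra: Iterable[str]) -> "Lexicon":
        return Lexicon(self.category, self.group, self.terms | frozenset(extra))

    def pattern(self) -> re.Pattern | None:
        """Compiled alternation over all terms, word-boundary anchored."""
        if not self.terms:
            return None
        parts = []
        # Longest-first so multiword terms are preferred by the alternation.
        for term in sorted(self.terms, key=lambda t: (-len(t), t)):
            words = term.split()
            body = r"\W+".join(re.escape(w) for w in words)
            parts.append(body)
        return re.compile(r"(?<!\w)(?:" + "|".join(parts) + r")(?!\w)")


def post_matches(post_text: str, lexicon: Lexicon) -> bool:
    """True iff at least one lexicon term occurs in the post.

    Matching is case-insensitive and word-boundary aware ("atty" matches in
    "my atty burnt out" but not in "attyx"); an empty lexicon matches
    nothing.
    """
    pat = lexicon.pattern()
    if pat is None:
        return False
    return pat.search(post_text.lower()) is not None


@dataclass
class PrevalenceMatrix:
    """Forums x categories matrix of prevalence fractions in [0, 1]."""

    forums: list[str]
    categories: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.forums), len(self.categories)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.forums)} forums x {len(self.categories)} categories"
            )
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValidationError("prevalence values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.forums, columns=self.categories)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index_label="forum")
        return path

    def cell(self, forum: str, category: str) -> float:
        return float(
            self.values[self.forums.index(forum), self.categories.index(category)]
        )


def load_lexicons(path: str | Path) -> list[Lexicon]:
    """Load lexicons from a CSV with columns category, group, term.

    One :class:`Lexicon` per distinct category, in first-appearance order;
    terms are lowercased and deduplicated.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"category", "group", "term"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    order: list[str] = []
    groups: dict[str, str] = {}
    terms: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        cat = row.category.strip()
        grp = row.group.strip().lower()
        term = row.term.strip().lower()
        if not cat:
            raise ValidationError(f"{path}: empty category name")
        if grp not in GROUPS:
            raise ValidationError(
                f"{path}: unknown group {grp!r} for category {cat!r}"
            )
        if not term:
            raise ValidationError(f"{path}: empty term in category {cat!r}")
        if cat not in groups:
            order.append(cat)
            groups[cat] = grp
            terms[cat] = set()
        elif groups[cat] != grp:
            raise ValidationError(
                f"{path}: category {cat!r} assigned to two groups "
                f"({groups[cat]!r}, {grp!r})"
            )
        terms[cat].add(term)
    return [Lexicon(c, groups[c], frozenset(terms[c])) for c in order]


def default_lexicons() -> list[Lexicon]:
    """The packaged starter lexicons (example terms per category).

    These carry the published example terms for each contextual factor and
    are meant to be extended by users for real analyses.
    """
    from importlib.resources import files

    return load_lexicons(files("forumlens.data").joinpath("lexicons.csv"))  # type: ignore[arg-type]


def prevalence(
    corpora: Sequence[Corpus], lexicons: Sequence[Lexicon]
) -> PrevalenceMatrix:
    """Per-forum, per-category proportion of posts containing a lexicon term.

    ``cell(f, c) = #{posts in forum f matching lexicon c} / #{posts in f}``.
    Every corpus must be non-empty (the proportion is undefined otherwise).
    """
    for corpus in corpora:
        if len(corpus) == 0:
            raise ValidationError(
                f"forum {corpus.forum_id!r} has no posts; prevalence undefined"
            )
    forums = [c.forum_id for c in corpora]
    categories = [lx.category for lx in lexicons]
    values = np.zeros((len(corpora), len(lexicons)))
    for j, lx in enumerate(lexicons):
        pat = lx.pattern()
        for i, corpus in enumerate(corpora):
            if pat is None:
                continue
            hits = sum(1 for p in corpus.posts if pat.search(p.text.lower()))
            values[i, j] = hits / len(corpus)
    return PrevalenceMatrix(forums=forums, categories=categories, values=values)


def render_heatmap(
    matrix: PrevalenceMatrix,
    out_path: str | Path | None = None,
    palette: str = "Blues",
    annotate: bool = True,
) -> plt.Figure:
    """Render the cross-forum prevalence heat map.

    Rows are categories and columns are forums; a sequential palette maps
    larger values to darker hues, scaled on [0, max cell] so cells are
    comparable across forums.  Returns the figure; saves it when
    ``out_path`` is given (an ``.svg`` twin is written next to a ``.png``).
    """
    frame = matrix.to_frame().T  # rows = categories, columns = forums
    vmax = float(matrix.values.max()) if matrix.values.size else 1.0
    if vmax <= 0.0:
        vmax = 1.0
    fig, ax = plt.subplots(
        figsize=(1.6 + 1.1 * len(matrix.forums), 1.2 + 0.45 * len(matrix.categories))
    )
    sns.heatmap(
        frame,
        ax=ax,
        cmap=palette,
        vmin=0.0,
        vmax=vmax,
        annot=annotate,
        fmt=".2f",
        linewidths=0.5,
        linecolor="white",
        cbar_kws={"label": "proportion of posts"},
    )
    ax.set_xlabel("forum")
    ax.set_ylabel("contextual factor")
    fig.tight_layout()
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=150)
        if out_path.suffix.lower() == ".png":
            fig.savefig(out_path.with_suffix(".svg"))
    return fig
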