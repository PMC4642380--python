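"""Document-topic thresholding, proportion statistics and Topic Bars.

A topic is a *major constituent* of a document when its estimated
proportion θ[d,k] reaches a minimum threshold; each such (document, topic)
pair is one "document-topic".  The threshold is calibrated per forum by
scanning a candidate grid for the value at which the number of
document-topics comes closest to the number of posts — so that, summed
over topics, roughly every post is represented once.  Per-topic counts of
document-topics divided by the total give the share of a forum occupied by
each topic; thematically similar topics are grouped into user-supplied
categories and the category shares drawn as one horizontal stacked bar per
forum ("Topic Bars"), which supports comparison within and across forums.

A document whose θ never reaches the threshold contributes no pairs: it
holds small amounts of many topics and is not representative of any one.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from forumlens.errors import ValidationError
from forumlens.topic_model import DocTopicMatrix

__all__ = [
    "DocumentTopicSet",
    "TopicCategoryMap",
    "CategoryProportions",
    "DEFAULT_THRESHOLD_GRID",
    "count_document_topics",
    "calibrate_threshold",
    "topic_proportions",
    "category_proportions",
    "render_topic_bars",
]

#: Candidate thresholds scanned during calibration: 0.05 .. 0.95 step 0.05.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(
    round(0.05 * i, 2) for i in range(1, 20)
)


def _as_theta(theta: DocTopicMatrix | np.ndarray) -> np.ndarray:
    if isinstance(theta, DocTopicMatrix):
        return theta.theta
    arr = np.asarray(theta, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("theta must be a documents x topics matrix")
    return arr


@dataclass
class DocumentTopicSet:
    """All (document, topic) pairs whose θ meets the threshold."""

    threshold: float
    pairs: list[tuple[int, int]]
    n_documents: int

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValidationError(
                f"threshold must lie in (0, 1], got {self.threshold}"
            )
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate (document, topic) pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def topic_counts(self, k: int) -> np.ndarray:
        counts = np.zeros(k, dtype=np.int64)
        for _, topic in self.pairs:
            if topic >= k:
                raise ValidationError(f"topic id {topic} >= K={k}")
            counts[topic] += 1
        return counts


def count_document_topics(
    theta: DocTopicMatrix | np.ndarray, threshold: float
) -> DocumentTopicSet:
    """Collect every (document, topic) pair with θ[d,k] ≥ threshold."""
    arr = _as_theta(theta)
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    d_idx, k_idx = np.nonzero(arr >= threshold)
    pairs = list(zip(d_idx.tolist(), k_idx.tolist()))
    return DocumentTopicSet(
        threshold=threshold, pairs=pairs, n_documents=arr.shape[0]
    )


def calibrate_threshold(
    theta: DocTopicMatrix | np.ndarray,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> float:
    """Pick the grid threshold whose document-topic count is closest to N.

    Scans the candidate grid and returns the value minimizing
    ``|#document-topics(T) − n_documents|``; ties break toward the larger
    (stricter) threshold.
    """
    arr = _as_theta(theta)
    if len(grid) == 0:
        raise ValidationError("candidate grid is empty")
    for t in grid:
        if not (0.0 < t <= 1.0):
            raise ValidationError(f"grid candidate {t} outside (0, 1]")
    n_docs = arr.shape[0]
    best_t = None
    best_diff = None
    for t in sorted(grid):
        n_pairs = int((arr >= t).sum())
        diff = abs(n_pairs - n_docs)
        if best_diff is None or diff <= best_diff:
            best_t, best_diff = t, diff
    return float(best_t)  # type: ignore[arg-type]


def topic_proportions(dts: DocumentTopicSet, k: int) -> np.ndarray:
    """Share of all document-topics belonging to each topic (sums to 1)."""
    if len(dts) == 0:
        raise ValidationError(
            "no document-topics at this threshold; proportions undefined"
        )
    counts = dts.topic_counts(k)
    return counts / counts.sum()


@dataclass
class TopicCategoryMap:
    """Mapping from topic id to a thematic category, with display colors.

    The grouping itself is a human judgment made per corpus; the package
    takes it as input.  ``colors`` maps category name to a hex color (an
    automatic palette fills the gaps at render time).
    """

    topic_to_category: dict[int, str]
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for topic, cat in self.topic_to_category.items():
            if not cat:
                raise ValidationError(f"topic {topic} mapped to empty category")

    @property
    def categories(self) -> list[str]:
        """Distinct categories in first-appearance (topic-id) order."""
        seen: list[str] = []
        for topic in sorted(self.topic_to_category):
            cat = self.topic_to_category[topic]
            if cat not in seen:
                seen.append(cat)
        return seen

    @classmethod
    def identity(cls, k: int) -> "TopicCategoryMap":
        """Each topic is its own category ("topic 0", "topic 1", ...)."""
        return cls({i: f"topic {i}" for i in range(k)})

    @classmethod
    def from_csv(cls, path: str | Path) -> "TopicCategoryMap":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"topic_id", "category"}
        if required - set(df.columns):
            raise ValidationError(
                f"{path}: expected columns topic_id, category[, color]"
            )
        mapping: dict[int, str] = {}
        colors: dict[str, str] = {}
        for row in df.itertuples(index=False):
            topic = int(row.topic_id)
            if topic in mapping:
                raise ValidationError(f"{path}: topic {topic} mapped twice")
            mapping[topic] = row.category.strip()
            color = getattr(row, "color", "").strip()
            if color:
                colors[row.category.strip()] = color
        return cls(mapping, colors)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "topic_id": t,
                "category": c,
                "color": self.colors.get(c, ""),
            }
            for t, c in sorted(self.topic_to_category.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


@dataclass
class CategoryProportions:
    """Per-category share of a forum's document-topics (sums to 1)."""

    forum_id: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for cat, frac in self.fractions.items():
            if frac < 0:
                raise ValidationError(f"negative fraction for {cat!r}")
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {total}, expected 1")

    def as_percent(self, ndigits: int = 2) -> dict[str, float]:
        return {c: round(100.0 * f, ndigits) for c, f in self.fractions.items()}


def category_proportions(
    topic_fractions: np.ndarray | Sequence[float],
    tc_map: TopicCategoryMap,
    forum_id: str = "",
) -> CategoryProportions:
    """Aggregate per-topic shares into category shares.

    Every topic with a nonzero share must be mapped; the category share is
    the sum of its member topics' shares, so the total stays 1.
    """
    fractions = np.asarray(topic_fractions, dtype=float)
    out: dict[str, float] = {}
    for topic, frac in enumerate(fractions):
        if frac == 0.0 and topic not in tc_map.topic_to_category:
            continue
        if topic not in tc_map.topic_to_category:
            raise ValidationError(
                f"topic {topic} has nonzero share {frac:.4f} but no category"
            )
        cat = tc_map.topic_to_category[topic]
        out[cat] = out.get(cat, 0.0) + float(frac)
    return CategoryProportions(forum_id=forum_id, fractions=out)


def proportions_to_tsv(
    rows: Sequence[CategoryProportions], path: str | Path
) -> Path:
    """Write category proportions (one row per forum) as TSV."""
    categories: list[str] = []
    for row in rows:
        for cat in row.fractions:
            if cat not in categories:
                categories.append(cat)
    frame = pd.DataFrame(
        [[row.fractions.get(c, 0.0) for c in categories] for row in rows],
        index=[row.forum_id for row in rows],
        columns=categories,
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index_label="forum")
    return path


def render_topic_bars(
    rows: Sequence[CategoryProportions],
    tc_map: TopicCategoryMap | Mapping[str, str] | None = None,
    out_path: str | Path | None = None,
) -> plt.Figure:
    """Draw one horizontal stacked bar per forum (the Topic Bars figure).

    Segment widths are proportional to category shares; every bar spans the
    same total width (shares sum to 1), so forums are directly comparable.
    Shared categories get identical colors across bars; a legend maps
    colors to categories.
    """
    if not rows:
        raise ValidationError("need at least one forum row")
    categories: list[str] = []
    for row in rows:
        for cat in row.fractions:
            if cat not in categories:
                categories.append(cat)
    explicit: Mapping[str, str]
    if isinstance(tc_map, TopicCategoryMap):
        explicit = tc_map.colors
    elif tc_map is None:
        explicit = {}
    else:
        explicit = tc_map
    palette = plt.get_cmap("tab20")
    colors = {}
    auto = 0
    for cat in categories:
        if cat in explicit and explicit[cat]:
            colors[cat] = explicit[cat]
        else:
            colors[cat] = palette(auto % 20)
            auto += 1

    fig, ax = plt.subplots(figsize=(9, 1.0 + 0.7 * len(rows)))
    y = np.arange(len(rows))
    left = np.zeros(len(rows))
    for cat in categories:
        widths = np.array([row.fractions.get(cat, 0.0) for row in rows])
        ax.barh(y, widths, left=left, color=colors[cat], label=cat,
                edgecolor="white", linewidth=0.4, height=0.6)
        left += widths
    ax.set_yticks(y)
    ax.set_yticklabels([row.forum_id for row in rows])
    ax.invert_yaxis()
    ax.set_xlim(0, 1)
    ax.set_xlabel("proportion of document-topics")
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), frameon=False,
              fontsize="small")
    fig.tight_layout()
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        if out_path.suffix.lower() == ".png":
            fig.savefig(out_path.with_suffix(".svg"), bbox_inches="tight")
    return fig


def run_manifest(
    forum_id: str,
    n_posts: int,
    k: int,
    threshold: float,
    n_document_topics: int,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Per-forum summary record: posts, topics, threshold, document-topics."""
    manifest: dict[str, object] = {
        "forum_id": forum_id,
        "total_posts": int(n_posts),
        "total_topics": int(k),
        "document_topic_threshold": float(threshold),
        "document_topics": int(n_document_topics),
        "threshold_grid": [float(t) for t in grid],
    }
    if extra:
        manifest.update(extra)
    return manifest
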