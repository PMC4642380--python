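"""Document-topic thresholding, calibration, proportions and the figure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forumlens.errors import ValidationError
from forumlens.topic_bars import (
    DEFAULT_THRESHOLD_GRID,
    CategoryProportions,
    DocumentTopicSet,
    TopicCategoryMap,
    calibrate_threshold,
    category_proportions,
    count_document_topics,
    proportions_to_tsv,
    render_topic_bars,
    topic_proportions,
)

# -- counting ---------------------------------------------------------------


@pytest.mark.parametrize(
    "row,threshold,expected_pairs",
    [
        ([0.6, 0.4], 0.3, 2),
        ([0.6, 0.4], 0.5, 1),
        ([0.6, 0.4], 1.0, 0),
        ([1.0, 0.0], 1.0, 1),  # closed threshold: >= counts
    ],
)
def test_count_document_topics_rule(row, threshold, expected_pairs):
    dts = count_document_topics(np.array([row]), threshold)
    assert len(dts) == expected_pairs
    assert dts.n_documents == 1


def test_count_rejects_bad_threshold():
    theta = np.array([[0.5, 0.5]])
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValidationError):
            count_document_topics(theta, bad)


@given(
    st.integers(min_value=1, max_value=12),
    st.integers(min_value=2, max_value=6),
    st.integers(min_value=0, max_value=2**31 - 1),
)
@settings(max_examples=60, deadline=None)
def test_document_topic_count_nonincreasing_in_threshold(n, k, seed):
    theta = np.random.default_rng(seed).dirichlet(np.ones(k), size=n)
    counts = [len(count_document_topics(theta, t)) for t in DEFAULT_THRESHOLD_GRID]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert counts[0] <= n * k
    assert len(count_document_topics(theta, 1.0)) <= n


# -- calibration ------------------------------------------------------------


def test_calibration_tie_breaks_toward_larger_threshold():
    theta = np.array([[0.5, 0.5], [0.5, 0.5], [1.0, 0.0]])
    # T=0.3 -> 5 pairs (|5-3|=2); T=0.6 -> 1 pair (|1-3|=2): tie -> 0.6
    assert calibrate_threshold(theta, [0.3, 0.6]) == 0.6


def test_calibration_degenerate_theta_gives_largest_candidate():
    theta = np.eye(3)  # every document is 100% one topic
    assert calibrate_threshold(theta, [0.2, 0.5, 0.9]) == 0.9


def test_calibration_rejects_bad_grid():
    theta = np.array([[0.5, 0.5]])
    with pytest.raises(ValidationError):
        calibrate_threshold(theta, [])
    with pytest.raises(ValidationError):
        calibrate_threshold(theta, [0.0, 0.5])


@given(
    st.integers(min_value=1, max_value=15),
    st.integers(min_value=2, max_value=5),
    st.integers(min_value=0, max_value=2**31 - 1),
)
@settings(max_examples=60, deadline=None)
def test_calibration_matches_exhaustive_grid_search(n, k, seed):
    theta = np.random.default_rng(seed).dirichlet(np.full(k, 0.3), size=n)
    chosen = calibrate_threshold(theta)
    diffs = {
        t: abs(len(count_document_topics(theta, t)) - n)
        for t in DEFAULT_THRESHOLD_GRID
    }
    best = min(diffs.values())
    assert diffs[chosen] == best
    # ties resolved toward the largest qualifying candidate
    assert chosen == max(t for t, d in diffs.items() if d == best)


# -- proportions ------------------------------------------------------------


def test_topic_proportions_match_published_worked_example():
    """Category-level counts 1435/362/225 of 2368 give 60.60/15.29/9.50%."""
    counts = {0: 1435, 1: 362, 2: 225, 3: 2368 - 1435 - 362 - 225}
    pairs = []
    d = 0
    for topic, c in counts.items():
        for _ in range(c):
            pairs.append((d, topic))
            d += 1
    dts = DocumentTopicSet(threshold=0.2, pairs=pairs, n_documents=d)
    fractions = topic_proportions(dts, 4)
    percents = [round(100 * f, 2) for f in fractions]
    assert percents[:3] == [60.60, 15.29, 9.50]
    assert fractions.sum() == pytest.approx(1.0)


def test_topic_proportions_equal_counts_and_empty_error():
    dts = DocumentTopicSet(0.5, [(0, 0), (1, 1), (2, 2)], 3)
    assert np.allclose(topic_proportions(dts, 3), 1 / 3)
    with pytest.raises(ValidationError):
        topic_proportions(DocumentTopicSet(0.5, [], 3), 3)


def test_category_proportions_aggregation():
    tc = TopicCategoryMap({0: "A", 1: "A", 2: "B"})
    got = category_proportions([0.2, 0.3, 0.5], tc, forum_id="f")
    assert got.fractions == pytest.approx({"A": 0.5, "B": 0.5})
    identity = TopicCategoryMap.identity(3)
    same = category_proportions([0.2, 0.3, 0.5], identity)
    assert list(same.fractions.values()) == pytest.approx([0.2, 0.3, 0.5])
    everything = TopicCategoryMap({0: "all", 1: "all", 2: "all"})
    assert category_proportions([0.2, 0.3, 0.5], everything).fractions["all"] == pytest.approx(1.0)


def test_category_proportions_unmapped_topic_named_in_error():
    tc = TopicCategoryMap({0: "A"})
    with pytest.raises(ValidationError, match="topic 1"):
        category_proportions([0.4, 0.6], tc)
    # zero-share topics may stay unmapped
    ok = category_proportions([1.0, 0.0], tc)
    assert ok.fractions == {"A": 1.0}


@given(
    st.integers(min_value=2, max_value=8),
    st.integers(min_value=0, max_value=2**31 - 1),
)
@settings(max_examples=40, deadline=None)
def test_category_grouping_preserves_total(k, seed):
    rng = np.random.default_rng(seed)
    fractions = rng.dirichlet(np.ones(k))
    labels = {i: f"cat{rng.integers(0, 3)}" for i in range(k)}
    got = category_proportions(fractions, TopicCategoryMap(labels))
    assert sum(got.fractions.values()) == pytest.approx(1.0)


# -- category map I/O -------------------------------------------------------


def test_topic_category_map_csv_round_trip(tmp_path):
    tc = TopicCategoryMap({0: "Psychology", 1: "Quitting Methods", 2: "Psychology"},
                          {"Psychology": "#1f77b4"})
    path = tc.to_csv(tmp_path / "map.csv")
    back = TopicCategoryMap.from_csv(path)
    assert back.topic_to_category == tc.topic_to_category
    assert back.colors == tc.colors


# -- figure -----------------------------------------------------------------


def test_topic_bars_segment_widths(tmp_path):
    rows = [CategoryProportions("forum1", {"A": 0.6, "B": 0.4})]
    out = tmp_path / "bars.png"
    fig = render_topic_bars(rows, None, out)
    assert out.exists() and out.with_suffix(".svg").exists()
    widths = sorted(p.get_width() for p in fig.axes[0].patches)
    assert widths == pytest.approx([0.4, 0.6])
    assert widths[1] / widths[0] == pytest.approx(1.5)  # 3:2 ratio


def test_topic_bars_equal_total_width_across_forums():
    rows = [
        CategoryProportions("f1", {"A": 0.7, "B": 0.3}),
        CategoryProportions("f2", {"A": 0.2, "B": 0.8}),
    ]
    fig = render_topic_bars(rows)
    ax = fig.axes[0]
    totals = {}
    for patch in ax.patches:
        y = round(patch.get_y(), 6)
        totals[y] = totals.get(y, 0.0) + patch.get_width()
    assert list(totals.values()) == pytest.approx([1.0, 1.0])


def test_topic_bars_single_category_full_width():
    fig = render_topic_bars([CategoryProportions("only", {"all": 1.0})])
    patches = fig.axes[0].patches
    assert len(patches) == 1 and patches[0].get_width() == pytest.approx(1.0)


def test_proportions_tsv(tmp_path):
    rows = [
        CategoryProportions("f1", {"A": 0.25, "B": 0.75}),
        CategoryProportions("f2", {"A": 1.0}),
    ]
    path = proportions_to_tsv(rows, tmp_path / "props.tsv")
    text = path.read_text().splitlines()
    assert text[0] == "forum\tA\tB"
    assert text[1].startswith("f1\t0.25\t0.75")
    assert text[2].startswith("f2\t1.0\t0.0")
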