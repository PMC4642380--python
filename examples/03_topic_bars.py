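"""Document-topic thresholding, category proportions and Topic Bars.

First reproduces a worked example with published document-topic counts
(1435, 362 and 225 of 2368), then calibrates a threshold on a random θ
matrix and renders a Topic Bars figure for two mock forums.
"""

import numpy as np

from forumlens import (
    CategoryProportions,
    DocumentTopicSet,
    calibrate_threshold,
    count_document_topics,
    render_topic_bars,
    topic_proportions,
)

# -- worked example: counts -> percentages ----------------------------------
counts = {"Psychology": 1435, "Quitting Methods": 362, "E-cigarette": 225}
total = 2368
pairs, doc = [], 0
for topic, c in enumerate(list(counts.values()) + [total - sum(counts.values())]):
    for _ in range(c):
        pairs.append((doc, topic))
        doc += 1
dts = DocumentTopicSet(threshold=0.2, pairs=pairs, n_documents=total)
fractions = topic_proportions(dts, 4)
for name, frac in zip(counts, fractions):
    print(f"{name}: {100 * frac:.2f}% of document-topics")

# -- calibration on an estimated θ ------------------------------------------
rng = np.random.default_rng(0)
theta = rng.dirichlet(np.full(5, 0.2), size=200)
threshold = calibrate_threshold(theta)
n_dts = len(count_document_topics(theta, threshold))
print(f"\ncalibrated threshold {threshold:.2f}: {n_dts} document-topics "
      f"for {theta.shape[0]} posts (closest over the 0.05..0.95 grid)")

# -- Topic Bars across two forums -------------------------------------------
rows = [
    CategoryProportions("quit-forum", {"Psychology": 0.61, "Quitting Methods": 0.15,
                                       "E-cigarette": 0.10, "Other": 0.14}),
    CategoryProportions("vape-forum", {"Psychology": 0.08, "Quitting Methods": 0.05,
                                       "E-cigarette": 0.62, "Other": 0.25}),
]
render_topic_bars(rows, None, "example_topic_bars.png")
print("\nTopic Bars written to example_topic_bars.png (+ .svg);")
print("segment widths are each category's share of the forum's document-topics.")
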