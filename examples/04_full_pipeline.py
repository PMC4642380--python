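"""The full pipeline, end to end, on a synthetic forum.

Simulates a forum with one dominant topic per post and an injected
'quitting' lexicon signal, writes it to disk, then runs the prevalence,
LDA and Topic Bars stages exactly as the command-line interface would
(`forumlens all -c run.yaml`), printing the manifest counts.
"""

import json
from pathlib import Path

from forumlens import SimConfig, simulate_corpus
from forumlens.corpus_io import write_posts
from forumlens.pipeline import ForumSpec, RunConfig, run_lda, run_prevalence, run_topicbars

workdir = Path("example_pipeline")
workdir.mkdir(exist_ok=True)

cfg = SimConfig(n_posts=200, post_length_mean=30, post_length_sd=10,
                k_true=3, v=80, alpha_true=0.05, beta_true=0.05,
                injection=(("quitting", 0.3),), seed=2, forum_id="demo")
corpus, truth = simulate_corpus(cfg)
corpus_path = write_posts(corpus, workdir / "demo.jsonl")
print(f"simulated forum: {len(corpus)} posts, quitting terms injected into "
      f"{int(truth.injected_flags['quitting'].sum())} posts (30%)")

rc = RunConfig(
    output_dir=str(workdir / "out"),
    seed=9,
    forums=[ForumSpec("demo", path=str(corpus_path), k=3)],
    lda={"alpha": 0.1, "n_iterations": 400, "burn_in": 200, "sample_every": 10},
)

run_prevalence(rc)
run_lda(rc)
outputs = run_topicbars(rc)

manifest = json.loads(outputs["manifest"].read_text())
forum = manifest["forums"][0]
print("\nTopic Bars manifest (the per-forum summary schema):")
print(f"  total posts:        {forum['total_posts']}")
print(f"  total topics:       {forum['total_topics']}")
print(f"  threshold:          {forum['document_topic_threshold']}")
print(f"  document-topics:    {forum['document_topics']}")
print(f"\nall artefacts (TSVs, figures, manifests) are under {workdir / 'out'}")
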