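"""Fit LDA by collapsed Gibbs sampling to a corpus with known topics.

Simulates a 300-post forum from a 4-topic generative process, fits a
4-topic model, and reports how well the fitted topic-word distributions
match the generator's after greedy label matching (topic labels are
arbitrary, so matching is required before any comparison).
"""

import numpy as np

from forumlens import LdaParams, SimConfig, estimate_phi, estimate_theta, simulate_corpus
from forumlens.topic_model import fit_lda, greedy_topic_match, top_words

cfg = SimConfig(n_posts=300, post_length_mean=40, post_length_sd=12,
                k_true=4, v=120, alpha_true=0.1, beta_true=0.05, seed=4)
corpus, truth = simulate_corpus(cfg)
print(f"simulated {len(corpus)} posts, "
      f"{sum(len(t) for t in corpus.tokens)} tokens, V={cfg.v}")

params = LdaParams(k=4, alpha=0.1, n_iterations=500, burn_in=250,
                   sample_every=10, seed=11)
state = fit_lda(corpus, params)
phi = estimate_phi(state)
theta = estimate_theta(state)

perm, l1 = greedy_topic_match(phi.phi, truth.phi_true)
print(f"mean per-topic L1 distance to the true topic-word distributions: "
      f"{l1.mean():.3f} (0 = perfect, 2 = disjoint)")
r = np.corrcoef(theta.theta[:, perm].ravel(), truth.theta_true.ravel())[0, 1]
print(f"Pearson r between fitted and true document-topic proportions: {r:.3f}")

print("\ntop words per fitted topic (synthetic vocabulary):")
for k, words in enumerate(top_words(phi, 5)):
    print(f"  topic {k}: {' '.join(words)}")
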