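"""Compare contextual-factor prevalence across two forums with a heat map.

Builds two tiny in-memory forums whose posts mention different contextual
factors, estimates per-forum prevalence (the fraction of posts containing
at least one lexicon term per category), and renders the cross-forum heat
map.  Higher values mean more of that category's content in that forum.
"""

from forumlens import Corpus, ForumPost, prevalence, render_heatmap
from forumlens.lexicon_prevalence import default_lexicons

health_forum = Corpus(
    forum_id="health",
    posts=[
        ForumPost("health", "p1", "My throat hurts and I keep coughing since I quit."),
        ForumPost("health", "p2", "The cravings are worst in the morning."),
        ForumPost("health", "p3", "Asked my doctor whether vaping is safe."),
        ForumPost("health", "p4", "New atty arrived, much smoother hit."),
    ],
)
general_forum = Corpus(
    forum_id="general",
    posts=[
        ForumPost("general", "p1", "Best price I found for a carto was online."),
        ForumPost("general", "p2", "Huge clouds with this vape at the lounge."),
        ForumPost("general", "p3", "Cheap shisha night with friends at the bar."),
        ForumPost("general", "p4", "What flavor should I try next?"),
    ],
)

lexicons = default_lexicons()
matrix = prevalence([health_forum, general_forum], lexicons)

print(matrix.to_frame().round(2).to_string())
print()
print("Each cell is the share of the forum's posts mentioning that factor;")
print("e.g. symptoms are prominent in 'health', cost and sensory talk in 'general'.")

render_heatmap(matrix, "example_heatmap.png")
print("heat map written to example_heatmap.png (+ .svg)")
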