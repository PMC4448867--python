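"""A walk small enough to solve by hand: two proteins, one interaction.

Restarting into vertex a with probability 0.15 per step and following the
single edge otherwise gives x_a = 0.85*x_b + 0.15 and x_b = 0.85*x_a,
hence x_a = 0.15/(1 - 0.85^2). The power iteration must land on the same
numbers.
"""

from targetrank import (
    AccessionPair,
    build_graph,
    personalized_pagerank,
    scale_min_to_one,
    seed_personalization,
)

g = build_graph([AccessionPair("P00001", "P00002")])
s = personalized_pagerank(g, seed_personalization(g, {"P00001"}))

hand_a = 0.15 / (1 - 0.85**2)
print(f"power iteration : a = {s['P00001']:.7f}   b = {s['P00002']:.7f}")
print(f"hand algebra    : a = {hand_a:.7f}   b = {1 - hand_a:.7f}")

scaled = scale_min_to_one(s)
print(f"min-scaled      : a = {scaled['P00001']:.7f}   b = {scaled['P00002']:.7f}")
print()
print("The seeded vertex holds ~54% of the stationary mass; after scaling")
print("the smallest score is exactly 1, as the candidate tables expect.")
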