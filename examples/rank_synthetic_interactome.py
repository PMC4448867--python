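"""End-to-end target prioritization on a hub-heavy synthetic interactome.

A 2000-vertex preferential-attachment graph mimics the fat-tailed degree
distribution of real interactomes. Personalizing the walk to 50 random
"disease" seeds and ranking by raw score vs by the PageRank/degree
quotient shows why the quotient matters: raw PageRank crowns the hubs,
the quotient surfaces important low-degree vertices.
"""

from targetrank import (
    generate_graph,
    personalized_pagerank,
    quotient_ranking,
    resolve_seeds,
    sample_seed_set,
    scale_min_to_one,
    seed_personalization,
    top_pagerank_table,
)

g, manifest = generate_graph("preferential_attachment", 2000, rng_seed=0, m=3)
seeds = sample_seed_set(g, 50, rng_seed=0)
effective, missing = resolve_seeds(seeds, g)

raw = personalized_pagerank(g, seed_personalization(g, set(effective.accessions)))
scaled = scale_min_to_one(raw)
print(f"graph: {g.n_vertices} vertices, {g.n_directed_edges} directed edges, "
      f"max degree {manifest.planted['max_degree']}")
print(f"converged in {raw.iterations} sweeps (L1 residual {raw.residual:.2e})\n")


def show(title, rows):
    print(title)
    print(f"{'accession':10s} {'scaledPR':>10s} {'degree':>6s} {'PR/deg':>8s} {'seed':>4s}")
    for c in rows:
        print(f"{c.accession:10s} {c.scaled_score:10.2f} {c.degree:6d} "
              f"{c.quotient:8.2f} {'yes' if c.is_seed else 'no':>4s}")
    print()


show("top 5 by personalized PageRank (hub-dominated view):",
     top_pagerank_table(scaled, g, effective, top_k=5))
show("top 5 by PageRank/degree quotient (seeds excluded):",
     quotient_ranking(scaled, g, effective, exclude_seeds=True, top_k=5))

print("The score table is headed by high-degree hubs; the quotient table")
print("promotes low-degree vertices sitting close to the seed set - the")
print("candidates worth reviewing as potential intervention points.")
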