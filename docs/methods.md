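# Methods

## Model

`targetrank` treats the interactome as an undirected graph realized as its
symmetric directed-edge closure: every cleaned interaction (a, b)
contributes both (a, b) and (b, a), once each, and a self-interaction
contributes a single loop edge (a, a). A vertex's degree is its out-degree
in the closure, so a self-loop adds exactly 1 and the walk at a looped
vertex may step to itself with probability 1/d. Vertices are induced by
the edge list; consequently every vertex has out-degree ≥ 1 and no
dangling-node patching is ever needed (this is asserted, not handled).
The graph is not required to be connected: teleportation makes the chain
ergodic whenever any teleport mass is positive, and vertices unreachable
from the restart support simply receive score 0 (min-scaling then refuses
to run, with an explanatory error, rather than divide by zero).

The walk has three per-step outcomes: follow a uniformly chosen outgoing
edge (probability `follow_mass`), teleport to a uniformly random vertex
(`uniform_mass`, the classic damping term), or teleport into the restart
distribution (`personalization_mass`). The score vector is the stationary
point of

    x = follow_mass · Wᵀx + uniform_mass · u + personalization_mass · p.

Treating the two damping parameters as *independent* teleport masses with
the follow mass as remainder is a deliberate design choice: it reproduces
classic PageRank (uniform mass only), pure random-walk-with-restart
(personalization mass only — the disease-study setting 0 / 0.15), and any
mixture, under one update rule.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `uniform_mass` (α) | 0.0 | probability of a uniform teleport per step |
| `personalization_mass` (β) | 0.15 | probability of restarting into the seed distribution |
| `tol` | 1e−12 | L1 convergence threshold of the power iteration |
| `max_iter` | 1000 | sweep cap; exceeding it raises, carrying the residual |
| taxon | `9606` | NCBI taxon both interactors must carry during cleaning |

The defaults are the executed study parameters (damping 0, restart 0.15,
hence follow mass 0.85). The tight tolerance costs little — the walk
contracts by the follow mass per sweep, so ~170 sweeps bound the default
setting and the study-scale synthetic graph converges in ~55 — and makes
two-decimal table output insensitive to the exact sweep count. The power
iteration starts from the restart distribution (uniform when β = 0);
since the fixed point is unique for follow mass < 1, this choice affects
only the sweep count. All vectorized computation uses lexicographic vertex
order, so results are bit-reproducible across runs and platforms.

## Cleaning rules and their bookkeeping

Records are rejected in a fixed rule order — taxon, identifier namespace,
accession validity — and each rejected record is attributed to the *first*
rule it fails, so `parsed = survived + Σ rejections` holds exactly. Only
the MI-TAB unique-identifier columns (1–2) are consulted; alias columns
are not, which is the conservative reading of "identified by a UniProt
accession". A taxid field such as `taxid:9606(human)` matches taxon 9606,
a multi-xref field matches if any xref does, and an empty or `-` field is
rejected (the organism cannot be confirmed). Isoform stripping removes
only a trailing `-<digits>`; feature-chain tokens (`PRO_…`) and other
non-accession strings fail the validity rule instead of being coerced.
Validity is the official UniProt accession pattern (6- or 10-character
forms). Duplicates survive cleaning untouched — deduplication belongs to
graph construction, and keeping multiplicities is what makes the filter
statistics an exact partition.

## Scaling and ranking

Raw scores sum to 1; the tables divide by the minimum score so the
smallest becomes exactly 1 (readability only — every ratio and every rank
is invariant). Candidates are ranked by scaled-score/degree; since the
scaling constant is global, ranking by raw-score/degree would be
identical. Ties are broken by accession ascending: published tables print
exact ties without a stated rule, and a deterministic total order is worth
more than guessing one. Seed vertices are excluded from the candidate
ranking by default (they score highly by construction) but are retained,
flagged, in the full report so score-ordered hub views remain
constructible.

## The degree-constancy anchor

For an undirected graph, restarting into the degree distribution
p(v) = d(v)/Σd leaves the walk stationary: (Wᵀp)(v) = Σ_{u→v} (1/d(u))·
d(u)/Σd = d(v)/Σd = p(v), so x = p for any mass split. Hence the
PageRank/degree quotient is one constant across vertices. The suite
verifies this identity on every generator model to a relative spread of
1e−9 (observed: ~1e−15, pure floating-point noise). It is the package's
main correctness anchor beyond the dense-solve oracle, because it
exercises the walk matrix, the teleport assembly and the quotient in one
closed loop.

## Synthetic data: what it emulates, what it does not

The generators produce (i) Erdős–Rényi graphs, (ii) preferential-
attachment (Barabási–Albert) graphs whose fat-tailed degree distribution
mimics real interactomes' hub structure, (iii) an explicit hub-and-spokes
star for worst-case hub domination, and (iv) MI-TAB 2.5 text with
controlled contamination — non-human rows, foreign-namespace and invalid
identifiers, isoform suffixes, duplicates — each carrying a manifest with
the exact expected survivor and per-rule rejection counts. The default
study-scale fixture is a 2000-vertex preferential-attachment graph with
attachment count 3 and a 50-seed restart set: large enough that hubs
visibly dominate raw PageRank, small enough that the full pipeline runs
in well under a second. All fixtures are deterministic functions of their
RNG seed.

What the fixtures do *not* reproduce: the real interactome's exact degree
exponent, its community structure, correlated experimental biases
(sticky proteins, bait effects), or biologically meaningful seed
placement. Passing tests therefore demonstrate that the algorithmic
pipeline is correct and deterministic, not that the biological rankings
on real data are meaningful — that judgement needs the real edge list and
seed list, which the same pipeline consumes unchanged.

## The star-graph boundary case

On a pure hub-and-spokes star with spoke seeds and masses (0, 0.15), every
non-seed spoke's score is exactly 0.85·x_hub/d_hub, while the hub's
quotient is x_hub/d_hub — the hub's quotient exceeds a non-seed spoke's by
the factor 1/0.85 *identically*. So with seeds excluded, the hub tops the
quotient ranking of a star; no parameter choice changes this. The
hub-vs-quotient demonstration therefore uses the seeds-retained quotient
view (the full-report table): there the degree-1 seed spokes lead and the
hub drops to rank 6, which is the degree-compensation behaviour the
quotient exists to show. On richer topologies (the preferential-attachment
fixture, real interactomes) the seed-excluded ranking itself promotes
low-degree vertices, as the study-scale example demonstrates.

## Numerical and degenerate-input choices

- Convergence failure raises an error carrying the residual; the CLI maps
  it to a distinct exit code (3) so pipelines can tell it from bad input (2).
- The dense oracle refuses graphs above 2000 vertices (an O(n³) solve has
  no business on bigger inputs) and follow mass 1 (singular system).
- An edge-list file whose (a, b) lacks (b, a) is rejected naming the first
  offending pair — a symmetric closure is the file format's contract.
- Empty graphs, empty seed intersections, zero minimum scores and
  malformed MI-TAB lines all fail loudly with specific messages; malformed
  lines are additionally recorded in the rejects report with line numbers.

## Known limitations

- No edge weights or interaction-confidence filtering; every cleaned
  interaction counts equally.
- No statistical calibration of ranks (permutation p-values); the output
  is an ordering, not a significance statement.
- MI-TAB 2.6/2.7 extended columns are ignored; alias columns are never
  consulted when the primary identifier is not a UniProt accession.
- Approximate PageRank schemes (push, Monte Carlo) are out of scope: at
  interactome scale the exact iterate takes seconds.
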