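"""Personalized PageRank with two independent teleport masses.

The walk on the interactome is governed by three probabilities per step:

* ``follow_mass`` — follow a uniformly chosen outgoing edge (probability
  1/d(v) each at a vertex of degree d(v); a self-loop is one such edge);
* ``uniform_mass`` — teleport to a uniformly random vertex (the classic
  damping term of web PageRank);
* ``personalization_mass`` — teleport into the seed distribution (random
  walk with restart; uniform over the seed set in the disease study).

The stationary distribution x of

    x = follow_mass * W^T x + uniform_mass * u + personalization_mass * p

is the personalized PageRank, where W is the row-stochastic walk matrix
and u the uniform distribution.  The study's setting is uniform_mass = 0,
personalization_mass = 0.15 (follow mass 0.85), i.e. pure restart into the
disease seed set.

Two useful special cases anchor correctness: with personalization only and
p proportional to the degree distribution, the stationary distribution *is*
the degree distribution, so PageRank/degree is constant — the theoretical
identity the degree-quotient ranking rests on.

Scores are computed as a probability vector (sum 1) and may be rescaled so
the smallest score equals exactly 1, which is how the study's tables print
them (raw values on an 11k-vertex graph are otherwise ~1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .graph import Interactome

__all__ = [
    "TeleportConfig",
    "PersonalizationVector",
    "ScoreVector",
    "ConvergenceError",
    "personalized_pagerank",
    "dense_pagerank_oracle",
    "scale_min_to_one",
    "uniform_personalization",
    "seed_personalization",
]

RAW = "raw"
MIN_SCALED = "min_scaled"

_DENSE_GUARD = 2000


@dataclass(frozen=True)
class TeleportConfig:
    """Teleport masses of the walk; the remainder follows edges.

    ``uniform_mass`` is the classic damping factor (0 in the study),
    ``personalization_mass`` the restart probability into the seed
    distribution (0.15 in the study).
    """

    uniform_mass: float = 0.0
    personalization_mass: float = 0.15

    def __post_init__(self) -> None:
        if self.uniform_mass < 0 or self.personalization_mass < 0:
            raise ValueError("teleport masses must be non-negative")
        if self.uniform_mass + self.personalization_mass > 1 + 1e-12:
            raise ValueError("teleport masses must sum to at most 1")

    @property
    def follow_mass(self) -> float:
        return 1.0 - self.uniform_mass - self.personalization_mass


@dataclass(frozen=True)
class PersonalizationVector:
    """Non-negative vertex weights summing to 1 (the restart distribution)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("personalization weights must be non-negative")
        total = sum(self.weights.values())
        if self.weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"personalization weights must sum to 1, got {total}")

    @property
    def support(self) -> set[str]:
        return {v for v, w in self.weights.items() if w > 0}


@dataclass(frozen=True)
class ScoreVector:
    """Per-vertex PageRank values, raw (sum 1) or scaled so min == 1."""

    scores: dict[str, float]
    scaling: str = RAW
    iterations: int = 0
    residual: float = field(default=0.0)

    def __getitem__(self, vertex: str) -> float:
        return self.scores[vertex]


class ConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float, tol: float):
        self.iterations = iterations
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"power iteration did not reach tol={tol:g} in {iterations} sweeps "
            f"(final L1 residual {residual:g})"
        )


def uniform_personalization(g: Interactome) -> PersonalizationVector:
    n = g.n_vertices
    return PersonalizationVector({v: 1.0 / n for v in g.vertices})


def seed_personalization(g: Interactome, seeds: set[str]) -> PersonalizationVector:
    """Uniform restart distribution over a seed set (1/m each)."""
    missing = seeds - g.vertices
    if missing:
        raise KeyError(f"seed vertices absent from graph: {sorted(missing)[:5]}")
    if not seeds:
        raise ValueError("seed set is empty")
    m = len(seeds)
    return PersonalizationVector({v: 1.0 / m for v in seeds})


def _vertex_order(g: Interactome) -> list[str]:
    # lexicographic order makes every vectorized result bit-reproducible
    return sorted(g.vertices)


def _walk_matrix_T(g: Interactome, order: list[str]) -> sp.csr_matrix:
    """W^T as CSR: column u holds 1/d(u) on the rows of u's out-neighbours."""
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    rows = np.empty(g.n_directed_edges, dtype=np.int64)
    cols = np.empty(g.n_directed_edges, dtype=np.int64)
    vals = np.empty(g.n_directed_edges, dtype=np.float64)
    for k, (a, b) in enumerate(sorted(g.directed_edges)):
        d = g.degree[a]
        assert d >= 1, "edge-induced vertices always have out-degree >= 1"
        rows[k] = index[b]
        cols[k] = index[a]
        vals[k] = 1.0 / d
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _teleport_vectors(
    g: Interactome, p: PersonalizationVector, cfg: TeleportConfig, order: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    n = len(order)
    u = np.full(n, 1.0 / n)
    pvec = np.zeros(n)
    if cfg.personalization_mass > 0:
        if not p.support:
            raise ValueError("personalization mass > 0 but personalization support is empty")
        extra = set(p.weights) - g.vertices
        if extra:
            raise KeyError(f"personalization vertex absent from graph: {sorted(extra)[0]!r}")
        index = {v: i for i, v in enumerate(order)}
        for v, w in p.weights.items():
            pvec[index[v]] = w
    return u, pvec


def personalized_pagerank(
    g: Interactome,
    p: PersonalizationVector,
    cfg: TeleportConfig = TeleportConfig(),
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> ScoreVector:
    """Stationary distribution of the teleporting walk, by power iteration.

    Iterates ``x <- follow*W^T x + uniform_mass*u + personalization_mass*p``
    from the restart distribution until the L1 change drops to ``tol``.
    The fixed point is unique whenever follow_mass < 1.  Returns raw
    scores (sum 1) together with the sweep count and final residual.
    """
    if not g.vertices:
        raise ValueError("graph is empty")
    order = _vertex_order(g)
    WT = _walk_matrix_T(g, order)
    u, pvec = _teleport_vectors(g, p, cfg, order)

    teleport = cfg.uniform_mass * u + cfg.personalization_mass * pvec
    f = cfg.follow_mass
    x = pvec.copy() if cfg.personalization_mass > 0 else u.copy()
    if x.sum() == 0:
        x = u.copy()

    residual = np.inf
    for it in range(1, max_iter + 1):
        x_new = f * (WT @ x) + teleport
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual <= tol:
            return ScoreVector(dict(zip(order, x.tolist())), RAW, it, residual)
    raise ConvergenceError(max_iter, residual, tol)


def dense_pagerank_oracle(
    g: Interactome, p: PersonalizationVector, cfg: TeleportConfig = TeleportConfig()
) -> ScoreVector:
    """Direct dense solve of (I - follow*W^T) x = teleport; small graphs only.

    Exists as an independent route to the same stationary distribution; it
    shares no iteration machinery with :func:`personalized_pagerank`.
    """
    if g.n_vertices > _DENSE_GUARD:
        raise ValueError(f"dense solve guarded at {_DENSE_GUARD} vertices, graph has {g.n_vertices}")
    if cfg.follow_mass >= 1.0:
        raise ValueError("follow_mass = 1 makes the linear system singular")
    order = _vertex_order(g)
    WT = _walk_matrix_T(g, order).toarray()
    u, pvec = _teleport_vectors(g, p, cfg, order)
    b = cfg.uniform_mass * u + cfg.personalization_mass * pvec
    A = np.eye(len(order)) - cfg.follow_mass * WT
    x = np.linalg.solve(A, b)
    x = x / x.sum()
    return ScoreVector(dict(zip(order, x.tolist())), RAW, 0, 0.0)


def scale_min_to_one(s: ScoreVector) -> ScoreVector:
    """Rescale raw scores so the smallest equals exactly 1.

    Raw probabilities on a large graph are uncomfortably small; dividing
    by the minimum preserves every ratio and ordering while making the
    tables readable.  Fails if some vertex has score 0 (unreachable from
    the restart distribution with no uniform teleport).
    """
    if s.scaling != RAW:
        raise ValueError("input must be a raw score vector")
    if not s.scores:
        raise ValueError("empty score vector")
    m = min(s.scores.values())
    if m <= 0:
        raise ValueError(
            "minimum raw score is 0: some vertex is unreachable from the "
            "personalization support; its personalized PageRank vanishes and "
            "min-scaling is undefined"
        )
    scaled = {v: x / m for v, x in s.scores.items()}
    return replace(s, scores=scaled, scaling=MIN_SCALED)
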