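"""Candidate tables: seed handling, PageRank/degree quotient, ranking, reports.

Seed proteins soak up restart mass and score highly by construction, and
hubs score highly because the walk funnels through them; neither makes a
good intervention point.  The quotient of (min-scaled) personalized
PageRank and degree compensates low-degree vertices, so ranking non-seed
vertices by it surfaces important proteins with few interaction partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .graph import Interactome
from .mitab import UNIPROT_ACCESSION_RE
from .pagerank import MIN_SCALED, ScoreVector

__all__ = [
    "SeedSet",
    "RankedCandidate",
    "EmptySeedIntersectionError",
    "read_seed_list",
    "read_name_map",
    "resolve_seeds",
    "quotient_ranking",
    "top_pagerank_table",
    "write_report",
]


@dataclass(frozen=True)
class SeedSet:
    """The accessions the walk restarts into, plus a provenance label."""

    accessions: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("seed set is empty")
        bad = [a for a in self.accessions if "-" in a]
        if bad:
            raise ValueError(f"seed accessions must be isoform-free: {sorted(bad)[:3]}")

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass(frozen=True)
class RankedCandidate:
    """One output row of a candidate table."""

    accession: str
    scaled_score: float
    degree: int
    quotient: float
    rank: int
    is_seed: bool
    name: str = ""


class EmptySeedIntersectionError(ValueError):
    """No seed accession occurs in the graph; personalization is undefined."""


def read_seed_list(stream: Iterable[str], provenance: str = "") -> SeedSet:
    """Read one accession per line; '#' comments and blank lines allowed."""
    accs: set[str] = set()
    for line in stream:
        token = line.split("#", 1)[0].strip()
        if not token:
            continue
        if not UNIPROT_ACCESSION_RE.match(token):
            raise ValueError(f"not a valid UniProt accession: {token!r}")
        accs.add(token)
    return SeedSet(frozenset(accs), provenance)


def read_name_map(stream: Iterable[str]) -> dict[str, str]:
    """Two-column TSV of accession -> human-readable name."""
    names: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        acc, _, name = line.partition("\t")
        names[acc.strip()] = name.strip()
    return names


def resolve_seeds(seeds: SeedSet, g: Interactome) -> tuple[SeedSet, list[str]]:
    """Intersect the seed list with the graph's vertex set.

    Seed lists and interaction graphs come from different databases, so
    some seeds may be absent from the graph; they carry no restart mass
    and are reported back.  An empty intersection is an error.
    """
    effective = seeds.accessions & g.vertices
    missing = sorted(seeds.accessions - g.vertices)
    if not effective:
        raise EmptySeedIntersectionError(
            f"none of the {len(seeds)} seed accessions occur in the graph"
        )
    return SeedSet(frozenset(effective), seeds.provenance), missing


def _require_cover(s: ScoreVector, g: Interactome) -> None:
    if s.scaling != MIN_SCALED:
        raise ValueError("candidate tables are built from min-scaled scores")
    missing = g.vertices - set(s.scores)
    if missing:
        raise ValueError(f"score vector does not cover vertex {sorted(missing)[0]!r}")


def _assign_ranks(
    rows: list[tuple[str, float, int, float, bool]], key_index: int
) -> list[RankedCandidate]:
    rows.sort(key=lambda r: (-r[key_index], r[0]))
    return [
        RankedCandidate(acc, score, deg, quot, rank, is_seed)
        for rank, (acc, score, deg, quot, is_seed) in enumerate(rows, start=1)
    ]


def quotient_ranking(
    s: ScoreVector,
    g: Interactome,
    seeds: SeedSet,
    exclude_seeds: bool = True,
    top_k: int | None = None,
) -> list[RankedCandidate]:
    """Rank vertices by scaled-PageRank/degree, seeds excluded by default.

    Ties are broken by accession ascending so the ordering is total and
    reproducible.  ``top_k`` truncates after ranking.
    """
    _require_cover(s, g)
    rows = []
    for v in g.vertices:
        if exclude_seeds and v in seeds.accessions:
            continue
        d = g.degree[v]
        assert d > 0
        score = s.scores[v]
        rows.append((v, score, d, score / d, v in seeds.accessions))
    ranked = _assign_ranks(rows, key_index=3)
    return ranked[:top_k] if top_k is not None else ranked


def top_pagerank_table(
    s: ScoreVector,
    g: Interactome,
    seeds: SeedSet,
    top_k: int | None = None,
) -> list[RankedCandidate]:
    """Rank all vertices by scaled PageRank itself (seeds included, flagged).

    This is the hub-dominated view: without the degree quotient the top of
    the table is occupied by very-high-degree vertices.
    """
    _require_cover(s, g)
    rows = []
    for v in g.vertices:
        d = g.degree[v]
        score = s.scores[v]
        rows.append((v, score, d, score / d, v in seeds.accessions))
    ranked = _assign_ranks(rows, key_index=1)
    return ranked[:top_k] if top_k is not None else ranked


REPORT_COLUMNS = (
    "accession",
    "scaled_pagerank",
    "degree",
    "quotient",
    "rank",
    "is_seed",
    "name",
    "scaled_pagerank_2dp",
    "quotient_2dp",
)


def write_report(
    candidates: Sequence[RankedCandidate],
    sink: TextIO,
    name_map: dict[str, str] | None = None,
) -> None:
    """TSV report: full-precision values plus 2-decimal display columns."""
    name_map = name_map or {}
    sink.write("\t".join(REPORT_COLUMNS) + "\n")
    for c in candidates:
        name = c.name or name_map.get(c.accession, "")
        sink.write(
            "\t".join(
                (
                    c.accession,
                    repr(c.scaled_score),
                    str(c.degree),
                    repr(c.quotient),
                    str(c.rank),
                    "1" if c.is_seed else "0",
                    name,
                    f"{c.scaled_score:.2f}",
                    f"{c.quotient:.2f}",
                )
            )
            + "\n"
        )
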