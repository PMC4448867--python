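"""Synthetic fixtures with known ground truth.

Every other module is testable offline: this module fabricates interaction
graphs (Erdős–Rényi, preferential attachment to mimic the hub-heavy degree
distribution of real interactomes, and an explicit hub-and-spokes
topology), MI-TAB 2.5 files with controlled contamination exercising each
cleaning rule, and seed sets with optionally planted absent accessions.
Each generator returns a manifest recording the parameters and the counts
its output must satisfy; all output is a deterministic function of the
RNG seed.

Synthetic accessions follow the UniProt pattern ("P" + 5 digits for graph
vertices, "Q9...." for planted-missing seeds) so validity filtering treats
them exactly like real ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .graph import Interactome, build_graph
from .mitab import AccessionPair
from .pagerank import PersonalizationVector
from .scoring import SeedSet

__all__ = [
    "FixtureManifest",
    "generate_graph",
    "generate_mitab_fixture",
    "degree_personalization",
    "sample_seed_set",
    "STUDY_SCALE",
]

#: Default study-scale fixture: hub-heavy preferential-attachment graph,
#: large enough to show hub domination of raw PageRank, small enough for
#: sub-second tests.
STUDY_SCALE = {"model": "preferential_attachment", "n": 2000, "m": 3, "n_seeds": 50}


@dataclass(frozen=True)
class FixtureManifest:
    """Ground truth for one generated fixture."""

    rng_seed: int
    params: dict[str, Any]
    expected: dict[str, Any] = field(default_factory=dict)
    planted: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rng_seed": self.rng_seed,
                "params": self.params,
                "expected": self.expected,
                "planted": self.planted,
            },
            indent=2,
        )


def _acc(i: int) -> str:
    return f"P{i:05d}"


def generate_graph(
    model: str, n: int, rng_seed: int = 0, **params: Any
) -> tuple[Interactome, FixtureManifest]:
    """Generate a synthetic interactome with a ground-truth manifest.

    Models: ``erdos_renyi`` (param ``p``), ``preferential_attachment``
    (param ``m``, attachment count), ``hub_and_spokes`` (node 0 joined to
    each of the n-1 spokes).  Vertices are labelled with synthetic UniProt
    accessions; isolated vertices of the random models are dropped (the
    interactome is edge-induced).
    """
    if n < 1:
        raise ValueError("n must be positive")
    if model == "erdos_renyi":
        p = params.get("p", 0.05)
        ug = nx.gnp_random_graph(n, p, seed=rng_seed)
    elif model == "preferential_attachment":
        m = params.get("m", 3)
        ug = nx.barabasi_albert_graph(n, m, seed=rng_seed)
    elif model == "hub_and_spokes":
        ug = nx.star_graph(n - 1)
    else:
        raise ValueError(f"unknown model {model!r}")

    pairs = [AccessionPair(_acc(a), _acc(b)) for a, b in ug.edges()]
    if not pairs:
        raise ValueError(f"{model} with these parameters produced no edges; the graph is empty")
    g = build_graph(pairs)

    degrees = g.degree
    max_deg = max(degrees.values())
    hubs = sorted(v for v, d in degrees.items() if d == max_deg)
    manifest = FixtureManifest(
        rng_seed=rng_seed,
        params={"model": model, "n": n, **params},
        expected={
            "n_vertices": g.n_vertices,
            "n_directed_edges": g.n_directed_edges,
            "n_undirected_edges": ug.number_of_edges(),
            "n_loops": sum(1 for a, b in g.directed_edges if a == b),
        },
        planted={
            "hub_vertices": hubs,
            "max_degree": max_deg,
            "min_degree_vertices": sorted(
                v for v, d in degrees.items() if d == min(degrees.values())
            )[:10],
        },
    )
    return g, manifest


_TAXON_HUMAN = "taxid:9606(human)"
_TAXON_OTHER = "taxid:10090(mouse)"
_FILLER = "-"


def _mitab_line(id_a: str, id_b: str, tax_a: str, tax_b: str) -> str:
    cols = [id_a, id_b] + [_FILLER] * 7 + [tax_a, tax_b] + [_FILLER] * 4
    return "\t".join(cols)


def generate_mitab_fixture(
    n_interactions: int = 100,
    frac_nonhuman: float = 0.2,
    frac_nonuniprot: float = 0.1,
    frac_isoform: float = 0.1,
    frac_duplicate: float = 0.1,
    rng_seed: int = 0,
) -> tuple[str, FixtureManifest]:
    """Emit MI-TAB 2.5 text with controlled contamination.

    Row categories (counts = round(frac * n), remainder clean): non-human
    taxon rows and non-UniProt identifier rows are rejected by the
    cleaner (the latter split between a foreign namespace and an invalid
    uniprotkb token so both the namespace and the accession-validity rules
    fire); isoform rows survive with the suffix stripped; duplicate rows
    repeat an earlier clean row and survive as multiplicities.  The
    manifest records the exact expected survivor and per-rule rejection
    counts.
    """
    for name, frac in (
        ("frac_nonhuman", frac_nonhuman),
        ("frac_nonuniprot", frac_nonuniprot),
        ("frac_isoform", frac_isoform),
        ("frac_duplicate", frac_duplicate),
    ):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    n_nonhuman = round(frac_nonhuman * n_interactions)
    n_nonuniprot = round(frac_nonuniprot * n_interactions)
    n_isoform = round(frac_isoform * n_interactions)
    n_duplicate = round(frac_duplicate * n_interactions)
    if n_nonhuman + n_nonuniprot + n_isoform + n_duplicate > n_interactions:
        raise ValueError("contamination fractions sum to more than 1")
    n_clean = n_interactions - n_nonhuman - n_nonuniprot - n_isoform - n_duplicate
    if n_duplicate > 0 and n_clean == 0:
        raise ValueError("duplicate rows need at least one clean row to copy")

    rng = np.random.default_rng(rng_seed)

    def fresh_pair() -> tuple[str, str]:
        a, b = rng.integers(0, 100000, size=2)
        return _acc(int(a)), _acc(int(b))

    lines: list[tuple[str, str]] = []  # (category, text)
    clean_rows: list[tuple[str, str]] = []
    isoform_rows: list[dict[str, str]] = []

    for _ in range(n_clean):
        a, b = fresh_pair()
        clean_rows.append((a, b))
        lines.append(("clean", _mitab_line(f"uniprotkb:{a}", f"uniprotkb:{b}", _TAXON_HUMAN, _TAXON_HUMAN)))
    for i in range(n_nonhuman):
        a, b = fresh_pair()
        tax_a, tax_b = (_TAXON_OTHER, _TAXON_HUMAN) if i % 2 == 0 else (_TAXON_HUMAN, _TAXON_OTHER)
        lines.append(("nonhuman", _mitab_line(f"uniprotkb:{a}", f"uniprotkb:{b}", tax_a, tax_b)))
    n_foreign_ns = (n_nonuniprot + 1) // 2
    for i in range(n_nonuniprot):
        a, b = fresh_pair()
        if i < n_foreign_ns:
            bad = f"intact:EBI-{int(rng.integers(100000, 999999))}"
            cat = "nonuniprot_namespace"
        else:
            bad = "uniprotkb:PRO_0000123"
            cat = "nonuniprot_accession"
        lines.append((cat, _mitab_line(bad, f"uniprotkb:{b}", _TAXON_HUMAN, _TAXON_HUMAN)))
    for _ in range(n_isoform):
        a, b = fresh_pair()
        iso = int(rng.integers(2, 9))
        isoform_rows.append({"written": f"{a}-{iso}", "stripped": a, "partner": b})
        lines.append(("isoform", _mitab_line(f"uniprotkb:{a}-{iso}", f"uniprotkb:{b}", _TAXON_HUMAN, _TAXON_HUMAN)))
    for _ in range(n_duplicate):
        a, b = clean_rows[int(rng.integers(0, len(clean_rows)))]
        lines.append(("duplicate", _mitab_line(f"uniprotkb:{a}", f"uniprotkb:{b}", _TAXON_HUMAN, _TAXON_HUMAN)))

    order = rng.permutation(len(lines))
    shuffled = [lines[i] for i in order]
    text = "\n".join(line for _, line in shuffled) + "\n" if shuffled else ""

    n_namespace_rej = n_foreign_ns
    n_accession_rej = n_nonuniprot - n_foreign_ns
    manifest = FixtureManifest(
        rng_seed=rng_seed,
        params={
            "n_interactions": n_interactions,
            "frac_nonhuman": frac_nonhuman,
            "frac_nonuniprot": frac_nonuniprot,
            "frac_isoform": frac_isoform,
            "frac_duplicate": frac_duplicate,
        },
        expected={
            "records": n_interactions,
            "survivors": n_clean + n_isoform + n_duplicate,
            "rejected": {
                "taxon": n_nonhuman,
                "namespace": n_namespace_rej,
                "accession": n_accession_rej,
            },
        },
        planted={
            "isoform_rows": isoform_rows,
            "categories_by_line": [cat for cat, _ in shuffled],
        },
    )
    return text, manifest


def degree_personalization(g: Interactome) -> PersonalizationVector:
    """Restart distribution proportional to degree: weight(v) = d(v)/sum d.

    Personalizing the walk to this distribution leaves it invariant, so
    score(v)/d(v) comes out constant — the identity the quotient ranking
    is calibrated against.
    """
    if not g.vertices:
        raise ValueError("graph is empty")
    total = sum(g.degree.values())
    return PersonalizationVector({v: g.degree[v] / total for v in g.vertices})


def sample_seed_set(
    g: Interactome, k: int, rng_seed: int = 0, planted_missing: int = 0
) -> SeedSet:
    """Sample k vertices uniformly, plus accessions guaranteed absent.

    The planted-missing accessions use a "Q9" prefix, disjoint from the
    "P"-prefixed vertex labels, so they are valid UniProt accessions that
    resolve_seeds must report as missing.
    """
    if k > g.n_vertices:
        raise ValueError(f"k={k} exceeds vertex count {g.n_vertices}")
    if k < 1:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(rng_seed)
    vertices = sorted(g.vertices)
    chosen = {vertices[i] for i in rng.choice(len(vertices), size=k, replace=False)}
    missing = {f"Q9{i:04d}" for i in range(planted_missing)}
    return SeedSet(frozenset(chosen | missing), provenance=f"synthetic(seed={rng_seed})")
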