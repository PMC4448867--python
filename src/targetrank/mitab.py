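"""Parsing and cleaning of PSI-MI TAB 2.5 interaction records.

MI-TAB 2.5 is the tab-separated exchange format for binary molecular
interactions: columns 1-2 carry the interactors' unique identifiers
(namespace-qualified, e.g. ``uniprotkb:P02545``), columns 10-11 their NCBI
taxa (e.g. ``taxid:9606(human)``).  Interaction resources exported in this
dialect mix species, identifier namespaces and splice-isoform accessions,
so before a protein-interaction graph can be built the records are cleaned:

1. keep only records where *both* interactors belong to the requested
   taxon (human, 9606, in the diabetes study);
2. keep only records where both unique identifiers are UniProt accessions;
3. strip splice-isoform suffixes (``P02545-2`` -> ``P02545``) so isoforms
   collapse onto their parent entry.

Duplicates are deliberately *not* removed here — deduplication is the
graph module's job, and keeping multiplicities makes the filter statistics
an exact partition of the parsed records.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "RawInteraction",
    "AccessionPair",
    "MalformedLine",
    "FilterStats",
    "UNIPROT_ACCESSION_RE",
    "parse_mitab",
    "filter_to_clean_pairs",
    "write_pairs_tsv",
    "write_rejects_tsv",
]

MIN_COLUMNS = 15

#: Official UniProt accession pattern (6- or 10-character forms), anchored.
UNIPROT_ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

_ISOFORM_SUFFIX_RE = re.compile(r"-(\d+)$")


@dataclass(frozen=True)
class RawInteraction:
    """One parsed MI-TAB 2.5 data row, before any filtering."""

    id_a: str
    id_b: str
    taxid_a: str
    taxid_b: str
    source_line_number: int


@dataclass(frozen=True)
class AccessionPair:
    """An interaction between two bare (isoform-free) UniProt accessions."""

    a: str
    b: str


@dataclass(frozen=True)
class MalformedLine:
    line_number: int
    reason: str


# Rules are applied in this order; a record failing several rules is
# attributed to the first one, so the counts partition the input.
RULE_TAXON = "taxon"
RULE_NAMESPACE = "namespace"
RULE_ACCESSION = "accession"
RULE_ORDER = (RULE_TAXON, RULE_NAMESPACE, RULE_ACCESSION)


@dataclass
class FilterStats:
    """Per-rule bookkeeping for one cleaning pass.

    ``parsed == survived + sum(rejected.values())`` always holds.
    """

    taxon: str
    parsed: int = 0
    survived: int = 0
    rejected: dict[str, int] = field(default_factory=lambda: dict.fromkeys(RULE_ORDER, 0))
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "taxon": self.taxon,
                "parsed": self.parsed,
                "survived": self.survived,
                "rejected": self.rejected,
            },
            indent=2,
        )


def parse_mitab(stream: Iterable[str]) -> tuple[list[RawInteraction], list[MalformedLine]]:
    """Parse MI-TAB 2.5 text into raw records.

    Lines starting with ``#`` (the optional header) are skipped; blank
    lines are ignored.  A data line with fewer than 15 tab-separated
    columns is malformed and reported with its line number rather than
    silently dropped.  No filtering happens here.
    """
    records: list[RawInteraction] = []
    malformed: list[MalformedLine] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < MIN_COLUMNS:
            malformed.append(
                MalformedLine(lineno, f"expected >= {MIN_COLUMNS} columns, found {len(cols)}")
            )
            continue
        if not cols[0] or not cols[1]:
            malformed.append(MalformedLine(lineno, "empty interactor identifier"))
            continue
        records.append(
            RawInteraction(
                id_a=cols[0],
                id_b=cols[1],
                taxid_a=cols[9],
                taxid_b=cols[10],
                source_line_number=lineno,
            )
        )
    return records, malformed


def _taxid_matches(fieldval: str, taxon: str) -> bool:
    # "taxid:9606(human)" matches 9606; multiple xrefs are "|"-separated
    # and match if any does.  Empty / "-" fields cannot be confirmed.
    if not fieldval or fieldval == "-":
        return False
    for xref in fieldval.split("|"):
        xref = xref.strip()
        if ":" not in xref:
            continue
        value = xref.split(":", 1)[1]
        value = value.split("(", 1)[0].strip()
        if value == taxon:
            return True
    return False


def _uniprot_token(fieldval: str) -> str | None:
    """Return the accession token of a ``uniprotkb:`` unique identifier.

    Only the primary identifier column is consulted (alias columns are
    not); the field may in principle hold several "|"-separated xrefs, in
    which case the first uniprotkb entry wins.
    """
    for xref in fieldval.split("|"):
        xref = xref.strip()
        if xref.lower().startswith("uniprotkb:"):
            return xref.split(":", 1)[1]
    return None


def _strip_isoform(token: str) -> str:
    return _ISOFORM_SUFFIX_RE.sub("", token)


def _classify(rec: RawInteraction, taxon: str) -> tuple[str | None, AccessionPair | None]:
    if not (_taxid_matches(rec.taxid_a, taxon) and _taxid_matches(rec.taxid_b, taxon)):
        return RULE_TAXON, None
    tok_a = _uniprot_token(rec.id_a)
    tok_b = _uniprot_token(rec.id_b)
    if tok_a is None or tok_b is None:
        return RULE_NAMESPACE, None
    acc_a = _strip_isoform(tok_a)
    acc_b = _strip_isoform(tok_b)
    if not (UNIPROT_ACCESSION_RE.match(acc_a) and UNIPROT_ACCESSION_RE.match(acc_b)):
        return RULE_ACCESSION, None
    return None, AccessionPair(acc_a, acc_b)


def filter_to_clean_pairs(
    records: Iterable[RawInteraction], taxon: str = "9606"
) -> tuple[list[AccessionPair], FilterStats]:
    """Apply the taxon / namespace / accession-validity rules in order.

    A record survives iff both taxid fields denote ``taxon`` and both
    unique identifiers are valid UniProt accessions (after isoform
    stripping).  Output preserves input order and multiplicities.  Every
    rejection is counted under the first rule it fails and recorded with
    its source line number.
    """
    pairs: list[AccessionPair] = []
    stats = FilterStats(taxon=taxon)
    for rec in records:
        stats.parsed += 1
        rule, pair = _classify(rec, taxon)
        if pair is not None:
            pairs.append(pair)
            stats.survived += 1
        else:
            assert rule is not None
            stats.rejected[rule] += 1
            stats.rejects.append((rec.source_line_number, rule))
    return pairs, stats


def write_pairs_tsv(pairs: Iterable[AccessionPair], sink: TextIO) -> None:
    for p in pairs:
        sink.write(f"{p.a}\t{p.b}\n")


def write_rejects_tsv(stats: FilterStats, sink: TextIO) -> None:
    sink.write("line_number\trule\n")
    for lineno, rule in stats.rejects:
        sink.write(f"{lineno}\t{rule}\n")
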