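"""PubAnnotation reader and per-term occurrence aggregation.

A PubAnnotation document binds character spans of a text (0-based,
end-exclusive offsets, counted in characters) to ontology terms; each such
binding is a *denotation*. Annotation sets are read from files — frozen
snapshots — rather than produced by calling an annotator on the fly, so
that the same article always yields the same markup: live annotators track
moving ontology versions and can return different annotations for the same
text at different times.

Aggregation collapses denotations to one record per distinct term IRI with
its occurrence count, which is what downstream consumers (markup, word
clouds of frequent terms) need. Terms given as CURIEs are expanded through
a prefix map first; two spans of the same expanded term merge even when
their surface text differs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import AnnotationParseError, SpanValidationError, TermFormatError

__all__ = [
    "TextSpan",
    "Denotation",
    "AnnotationSet",
    "TermAggregate",
    "parse_pubannotation",
    "expand_term",
    "aggregate_terms",
    "filter_by_occurrence",
    "read_label_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TextSpan:
    """Character span, 0-based begin (inclusive) to end (exclusive)."""

    begin: int
    end: int


@dataclass(frozen=True)
class Denotation:
    """One span-to-term binding."""

    denotation_id: str
    span: TextSpan
    term: str


@dataclass
class AnnotationSet:
    """All denotations of one annotated document."""

    source_db: str = ""
    source_id: str = ""
    project: str | None = None
    text: str | None = None
    denotations: list[Denotation] = field(default_factory=list)


@dataclass
class TermAggregate:
    """Occurrence summary for one distinct term within one document."""

    term_iri: str
    label: str
    occurrences: int
    first_offset: int
    ontology_hint: str | None = None


def parse_pubannotation(json_text: str | bytes) -> AnnotationSet:
    """Load a PubAnnotation JSON document into an :class:`AnnotationSet`.

    Denotations are kept in document order. When the document carries its
    text, every span is validated against it; a degenerate span
    (begin ≥ end) or an out-of-bounds span raises
    :class:`SpanValidationError` naming the offending denotation.
    """
    try:
        data = json.loads(json_text)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise AnnotationParseError(f"malformed PubAnnotation JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise AnnotationParseError("PubAnnotation document must be a JSON object")

    text = data.get("text")
    aset = AnnotationSet(
        source_db=str(data.get("sourcedb", "")),
        source_id=str(data.get("sourceid", "")),
        project=data.get("project"),
        text=text,
    )
    seen_ids: set[str] = set()
    for i, raw in enumerate(data.get("denotations", [])):
        try:
            did = str(raw.get("id") or f"T{i + 1}")
            span = raw["span"]
            begin, end = int(span["begin"]), int(span["end"])
            term = str(raw["obj"])
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationParseError(
                f"denotation #{i} is malformed: {exc!r}"
            ) from exc
        if did in seen_ids:
            raise AnnotationParseError(f"duplicate denotation id {did!r}")
        seen_ids.add(did)
        if begin < 0 or begin >= end:
            raise SpanValidationError(
                f"denotation {did!r}: invalid span [{begin}, {end})"
            )
        if text is not None and end > len(text):
            raise SpanValidationError(
                f"denotation {did!r}: span end {end} exceeds text length {len(text)}"
            )
        if not term:
            raise TermFormatError(f"denotation {did!r} has an empty term")
        aset.denotations.append(Denotation(did, TextSpan(begin, end), term))
    return aset


def expand_term(term: str, prefix_map: dict[str, str] | None = None) -> str:
    """Expand a CURIE to an absolute IRI through ``prefix_map``.

    Absolute IRIs pass through unchanged; a CURIE with an unknown prefix
    passes through verbatim with a logged warning.
    """
    if not term:
        raise TermFormatError("empty annotation term")
    if "://" in term:
        return term
    prefix, sep, local = term.partition(":")
    if sep and prefix_map and prefix in prefix_map:
        return prefix_map[prefix] + local
    if sep:
        logger.warning("unknown CURIE prefix %r; keeping term %r verbatim",
                       prefix, term)
    return term


def _local_name(iri: str) -> str:
    cut = max(iri.rfind("/"), iri.rfind("#"), iri.rfind("_"))
    return iri[cut + 1 :] if 0 <= cut < len(iri) - 1 else iri


def _namespace(iri: str) -> str | None:
    if "://" not in iri:
        return None
    cut = max(iri.rfind("/"), iri.rfind("#"), iri.rfind("_"))
    ns = iri[: cut + 1]
    return ns if "://" in ns else None


def aggregate_terms(
    aset: AnnotationSet,
    labels: dict[str, str] | None = None,
    prefix_map: dict[str, str] | None = None,
) -> list[TermAggregate]:
    """Collapse denotations to one aggregate per distinct expanded term IRI.

    Occurrences count the denotations carrying that term; the label comes
    from the label map when available, else the IRI's local name (text after
    the last ``/``, ``#`` or ``_``). Aggregates are ordered by occurrence
    count descending, ties broken by term IRI ascending, so the output is a
    pure function of the input counts.
    """
    counts: dict[str, int] = {}
    first_offsets: dict[str, int] = {}
    for d in aset.denotations:
        iri = expand_term(d.term, prefix_map)
        counts[iri] = counts.get(iri, 0) + 1
        if iri not in first_offsets or d.span.begin < first_offsets[iri]:
            first_offsets[iri] = d.span.begin
    aggregates = [
        TermAggregate(
            term_iri=iri,
            label=(labels or {}).get(iri) or _local_name(iri),
            occurrences=n,
            first_offset=first_offsets[iri],
            ontology_hint=_namespace(iri),
        )
        for iri, n in counts.items()
    ]
    aggregates.sort(key=lambda a: (-a.occurrences, a.term_iri))
    return aggregates


def filter_by_occurrence(
    aggregates: list[TermAggregate], min_occurrences: int
) -> list[TermAggregate]:
    """Keep aggregates seen at least ``min_occurrences`` times.

    Order is preserved and counts are never renormalized. ``min_occurrences
    = 2`` keeps exactly the terms with more than one occurrence — the
    threshold frequent-term displays use.
    """
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    return [a for a in aggregates if a.occurrences >= min_occurrences]


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (term IRI, preferred label) into a dict."""
    labels: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        iri, _, label = line.partition("\t")
        if iri and label.strip():
            labels[iri.strip()] = label.strip()
    return labels
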