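"""Entity-graph assembly and deterministic JSON-LD serialization.

The markup for one article is a small linked-data graph:

* a top-level ``CreativeWork`` *record* node — the structured-data
  representation itself, kept separate from the publication and linked to
  it via ``mainEntity``;
* a ``ScholarlyArticle`` node carrying the bibliographic metadata;
* a containment chain ``article → PublicationIssue → PublicationVolume →
  Periodical`` via ``isPartOf``, with absent levels omitted and the chain
  re-linked so it stays contiguous;
* one ``DefinedTerm`` node per aggregated semantic annotation, linked from
  the article via ``about`` and back via ``subjectOf`` (bidirectional
  closure). Occurrence counts ride on an extension property
  ``biotea:occurrences`` since schema.org has no native slot for them.

Serialization is byte-deterministic: fixed ``@context``, fixed node order
(record, article, chain innermost first, annotations in aggregate order),
and within each node ``@id``, ``@type``, then properties alphabetically.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .annotations import TermAggregate
from .errors import BuildError, MarkupParseError, MintingError, SerializationError
from .jats import ArticleMetadata, PeriodicalContext

__all__ = [
    "BIOTEA_NS",
    "IriPolicy",
    "EntityNode",
    "MarkupDocument",
    "mint_iri",
    "build_markup",
    "serialize_jsonld",
    "parse_jsonld",
    "embed_in_html",
]

#: Namespace for extension properties not covered by schema.org.
BIOTEA_NS = "https://biotea.github.io/ns#"

_CONTEXT = ["https://schema.org", {"biotea": BIOTEA_NS}]

_ABSOLUTE_IRI_RE = re.compile(r"^[a-zA-Z][a-zA-Z0-9+.-]*://\S+$")


@dataclass(frozen=True)
class IriPolicy:
    """How node IRIs are minted: one base IRI + per-entity fragments."""

    base_iri: str = "https://biotea.github.io/bioschemas"
    article_fragment: str = "article"
    record_fragment: str = "record"
    annotation_fragment_prefix: str = "ann-"

    def __post_init__(self) -> None:
        if not _ABSOLUTE_IRI_RE.match(self.base_iri) or "#" in self.base_iri:
            raise ValueError(
                f"base_iri must be an absolute IRI without fragment: "
                f"{self.base_iri!r}"
            )
        for frag in (self.article_fragment, self.record_fragment,
                     self.annotation_fragment_prefix):
            if "#" in frag:
                raise ValueError(f"fragment {frag!r} must not contain '#'")


@dataclass
class EntityNode:
    """One typed node of the markup graph."""

    node_id: str
    node_type: str
    properties: dict[str, object] = field(default_factory=dict)

    def ref(self) -> dict[str, str]:
        return {"@id": self.node_id}


@dataclass
class MarkupDocument:
    """The assembled entity graph for one article, ready to serialize."""

    record: EntityNode | None
    article: EntityNode | None
    periodical_chain: list[EntityNode] = field(default_factory=list)
    annotations: list[EntityNode] = field(default_factory=list)

    def typed_nodes(self) -> list[EntityNode]:
        """All profiled nodes: article, chain, annotations (never the record)."""
        nodes = []
        if self.article is not None:
            nodes.append(self.article)
        nodes.extend(self.periodical_chain)
        nodes.extend(self.annotations)
        return nodes

    def all_nodes(self) -> list[EntityNode]:
        nodes = [self.record] if self.record is not None else []
        return nodes + self.typed_nodes()

    def check_invariants(self) -> None:
        """Raise :class:`SerializationError` naming the first violated invariant."""
        ids = [n.node_id for n in self.all_nodes()]
        if len(ids) != len(set(ids)):
            raise SerializationError("node ids are not unique within the document")
        if self.record is not None and self.article is not None:
            main = self.record.properties.get("mainEntity")
            if not (isinstance(main, dict) and main.get("@id") == self.article.node_id):
                raise SerializationError(
                    "record.mainEntity does not reference the article node"
                )
        self._check_chain()
        self._check_closure()

    def _check_chain(self) -> None:
        if self.article is None:
            return
        chain = self.periodical_chain
        expected_head = chain[0].node_id if chain else None
        is_part_of = self.article.properties.get("isPartOf")
        got_head = is_part_of.get("@id") if isinstance(is_part_of, dict) else None
        if got_head != expected_head:
            raise SerializationError(
                "isPartOf chain is not contiguous: article does not link to the "
                "innermost periodical-chain node"
            )
        for i, node in enumerate(chain):
            link = node.properties.get("isPartOf")
            target = link.get("@id") if isinstance(link, dict) else None
            if i + 1 < len(chain):
                if target != chain[i + 1].node_id:
                    raise SerializationError(
                        f"isPartOf chain is not contiguous at {node.node_id}"
                    )
            elif target is not None:
                raise SerializationError(
                    "isPartOf chain has a dangling link past the Periodical"
                )
        if chain and chain[-1].node_type != "Periodical":
            raise SerializationError("isPartOf chain does not end at a Periodical")

    def _check_closure(self) -> None:
        if self.article is None:
            if self.annotations:
                raise SerializationError("annotation nodes without an article node")
            return
        about = self.article.properties.get("about") or []
        about_ids = [
            v.get("@id") for v in about if isinstance(v, dict)
        ] if isinstance(about, list) else []
        ann_ids = [a.node_id for a in self.annotations]
        if about_ids != ann_ids:
            raise SerializationError(
                "article.about does not list exactly the annotation nodes "
                "(bidirectional closure violated)"
            )
        for ann in self.annotations:
            subj = ann.properties.get("subjectOf")
            if not (isinstance(subj, dict) and subj.get("@id") == self.article.node_id):
                raise SerializationError(
                    f"annotation {ann.node_id} does not link back to the article "
                    "via subjectOf (bidirectional closure violated)"
                )


_FRAGMENTS = {"periodical": "journal", "volume": "volume", "issue": "issue"}


def mint_iri(
    entity_kind: str,
    meta: ArticleMetadata,
    policy: IriPolicy,
    annotation_index: int | None = None,
) -> str:
    """Mint the deterministic IRI for one entity of an article's graph.

    The IRI stem is ``{base}/{identifier}`` where the identifier is the
    pmcid, else the DOI with ``/`` replaced by ``_``, else the pmid; the
    entity kind selects the fragment. Annotation IRIs are indexed from 1 in
    aggregate order.
    """
    if meta.pmcid:
        ident = meta.pmcid
    elif meta.doi:
        ident = meta.doi.replace("/", "_")
    elif meta.pmid:
        ident = meta.pmid
    else:
        raise MintingError(
            "article has no identifier (pmcid, doi or pmid); cannot mint IRIs"
        )
    stem = f"{policy.base_iri}/{ident}"
    if entity_kind == "record":
        return f"{stem}#{policy.record_fragment}"
    if entity_kind == "article":
        return f"{stem}#{policy.article_fragment}"
    if entity_kind in _FRAGMENTS:
        return f"{stem}#{_FRAGMENTS[entity_kind]}"
    if entity_kind == "annotation":
        if annotation_index is None or annotation_index < 1:
            raise ValueError("annotation_index must be >= 1 for annotation IRIs")
        return f"{stem}#{policy.annotation_fragment_prefix}{annotation_index}"
    raise ValueError(f"unknown entity kind {entity_kind!r}")


def _person(author) -> dict[str, object]:
    node: dict[str, object] = {"@type": "Person", "name": author.display_name}
    if author.given_names:
        node["familyName"] = author.surname
        node["givenName"] = author.given_names
    if author.orcid:
        node["sameAs"] = author.orcid
    return node


def _citation(cit) -> dict[str, object]:
    node: dict[str, object] = {"@type": "CreativeWork"}
    if cit.title:
        node["name"] = cit.title
    else:
        node["name"] = cit.raw_text
    ids = [i for i in (cit.doi, cit.pmid) if i]
    if ids:
        node["identifier"] = ids if len(ids) > 1 else ids[0]
    return node


def _build_chain(
    periodical: PeriodicalContext, meta: ArticleMetadata, policy: IriPolicy
) -> list[EntityNode]:
    """Innermost-first chain with only the levels present in the input."""
    if not periodical.journal_name:
        return []
    journal = EntityNode(
        node_id=mint_iri("periodical", meta, policy),
        node_type="Periodical",
        properties={"name": periodical.journal_name},
    )
    issns = [i for i in (periodical.issn_print, periodical.issn_electronic) if i]
    if issns:
        journal.properties["issn"] = issns if len(issns) > 1 else issns[0]
    if periodical.publisher:
        journal.properties["publisher"] = {
            "@type": "Organization",
            "name": periodical.publisher,
        }
    chain = [journal]
    if periodical.volume:
        volume = EntityNode(
            node_id=mint_iri("volume", meta, policy),
            node_type="PublicationVolume",
            properties={"volumeNumber": periodical.volume,
                        "isPartOf": journal.ref()},
        )
        chain.insert(0, volume)
    if periodical.issue:
        issue = EntityNode(
            node_id=mint_iri("issue", meta, policy),
            node_type="PublicationIssue",
            properties={"issueNumber": periodical.issue,
                        "isPartOf": chain[0].ref()},
        )
        chain.insert(0, issue)
    return chain


def build_markup(
    meta: ArticleMetadata,
    periodical: PeriodicalContext,
    aggregates: list[TermAggregate] | None = None,
    policy: IriPolicy | None = None,
) -> MarkupDocument:
    """Assemble the markup graph for one article.

    One annotation node is created per term aggregate, in aggregate order;
    ``about`` on the article and ``subjectOf`` on each annotation are set
    together so bidirectional closure holds by construction.
    """
    aggregates = aggregates or []
    policy = policy or IriPolicy()
    if not meta.title or not meta.title.strip():
        raise BuildError("article title is empty; cannot build markup")
    iris = [a.term_iri for a in aggregates]
    if len(iris) != len(set(iris)):
        raise BuildError("duplicate term IRIs among aggregates")

    article = EntityNode(
        node_id=mint_iri("article", meta, policy),
        node_type="ScholarlyArticle",
        properties={"name": meta.title},
    )
    idents = meta.identifiers()
    if idents:
        article.properties["identifier"] = idents if len(idents) > 1 else idents[0]
    if meta.authors:
        article.properties["author"] = [_person(a) for a in meta.authors]
    if meta.date_published:
        article.properties["datePublished"] = meta.date_published
    if meta.abstract:
        article.properties["description"] = meta.abstract
    if meta.page_start:
        article.properties["pageStart"] = meta.page_start
    if meta.page_end:
        article.properties["pageEnd"] = meta.page_end
    if meta.license_url:
        article.properties["license"] = meta.license_url
    if meta.keywords:
        article.properties["keywords"] = list(meta.keywords)
    if meta.citations:
        article.properties["citation"] = [_citation(c) for c in meta.citations]

    chain = _build_chain(periodical, meta, policy)
    if chain:
        article.properties["isPartOf"] = chain[0].ref()

    annotations: list[EntityNode] = []
    for i, agg in enumerate(aggregates, start=1):
        props: dict[str, object] = {
            "name": agg.label,
            "sameAs": agg.term_iri,
            "subjectOf": article.ref(),
            "biotea:occurrences": agg.occurrences,
        }
        if agg.ontology_hint:
            props["inDefinedTermSet"] = agg.ontology_hint
        annotations.append(
            EntityNode(
                node_id=mint_iri("annotation", meta, policy, annotation_index=i),
                node_type="DefinedTerm",
                properties=props,
            )
        )
    if annotations:
        article.properties["about"] = [a.ref() for a in annotations]

    record = EntityNode(
        node_id=mint_iri("record", meta, policy),
        node_type="CreativeWork",
        properties={"mainEntity": article.ref()},
    )
    doc = MarkupDocument(
        record=record,
        article=article,
        periodical_chain=chain,
        annotations=annotations,
    )
    doc.check_invariants()
    return doc


def _normalize_value(value: object) -> object:
    """Recursively order mapping keys: @id, @type, then alphabetical."""
    if isinstance(value, dict):
        ordered: dict[str, object] = {}
        for key in ("@id", "@type"):
            if key in value:
                ordered[key] = _normalize_value(value[key])
        for key in sorted(k for k in value if k not in ("@id", "@type")):
            ordered[key] = _normalize_value(value[key])
        return ordered
    if isinstance(value, (list, tuple)):
        return [_normalize_value(v) for v in value]
    return value


def _node_to_jsonld(node: EntityNode) -> dict[str, object]:
    out: dict[str, object] = {"@id": node.node_id, "@type": node.node_type}
    for key in sorted(node.properties):
        out[key] = _normalize_value(node.properties[key])
    return out


def serialize_jsonld(doc: MarkupDocument) -> str:
    """Serialize the document as deterministic JSON-LD text.

    Output is a single object with ``@context`` and an ``@graph`` array
    (record, article, chain innermost first, annotations); UTF-8, 2-space
    indentation, LF line endings, byte-identical across runs for equal
    input. Serialization is refused if a document invariant is violated.
    """
    doc.check_invariants()
    top = {
        "@context": _CONTEXT,
        "@graph": [_node_to_jsonld(n) for n in doc.all_nodes()],
    }
    return json.dumps(top, indent=2, ensure_ascii=False) + "\n"


_TYPE_KINDS = {
    "CreativeWork": "record",
    "ScholarlyArticle": "article",
    "PublicationIssue": "chain",
    "PublicationVolume": "chain",
    "Periodical": "chain",
    "DefinedTerm": "annotation",
}


def parse_jsonld(text: str | bytes) -> MarkupDocument:
    """Parse JSON-LD in the emitted markup shape back into a document.

    Inverse of :func:`serialize_jsonld` for documents this package emits;
    node order inside ``@graph`` is preserved.
    """
    try:
        data = json.loads(text)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise MarkupParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(data, dict) or "@graph" not in data:
        raise MarkupParseError("expected a top-level object with an @graph array")
    graph = data["@graph"]
    if not isinstance(graph, list):
        raise MarkupParseError("@graph must be an array")

    doc = MarkupDocument(record=None, article=None)
    for raw in graph:
        if not isinstance(raw, dict) or "@type" not in raw:
            raise MarkupParseError("every @graph node needs @id and @type")
        node = EntityNode(
            node_id=str(raw.get("@id", "")),
            node_type=str(raw["@type"]),
            properties={
                k: v for k, v in raw.items() if k not in ("@id", "@type")
            },
        )
        kind = _TYPE_KINDS.get(node.node_type)
        if kind == "record" and doc.record is None:
            doc.record = node
        elif kind == "article" and doc.article is None:
            doc.article = node
        elif kind == "chain":
            doc.periodical_chain.append(node)
        elif kind == "annotation":
            doc.annotations.append(node)
        else:
            raise MarkupParseError(
                f"unexpected node type {node.node_type!r} in @graph"
            )
    return doc


_BODY_CLOSE_RE = re.compile(r"</body\s*>", re.IGNORECASE)


def embed_in_html(html_text: str, doc: MarkupDocument) -> str:
    """Append the markup to an HTML page as its last body element.

    The JSON-LD rides in a ``<script type="application/ld+json">`` element
    inserted immediately before the final ``</body>`` tag, so the
    machine-readable markup loads after the human-readable content. All
    pre-existing page content is preserved byte for byte; pages without a
    body element get the script appended at the document end.
    """
    script = (
        '<script type="application/ld+json">\n'
        + serialize_jsonld(doc)
        + "</script>\n"
    )
    matches = list(_BODY_CLOSE_RE.finditer(html_text))
    if matches:
        pos = matches[-1].start()
        return html_text[:pos] + script + html_text[pos:]
    return html_text + script


def extract_embedded_jsonld(html_text: str) -> str:
    """Return the contents of the last JSON-LD script element in a page."""
    pattern = re.compile(
        r'<script type="application/ld\+json">\n(.*?)</script>', re.DOTALL
    )
    matches = pattern.findall(html_text)
    if not matches:
        raise MarkupParseError("no JSON-LD script element found in the page")
    return matches[-1]
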