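"""JATS XML reader: bibliographic metadata and periodical context.

Parses a single JATS (Journal Article Tag Suite) article record — bare, or
wrapped in an OAI-PMH envelope as returned by the PMC Open-Access OAI
interface — and extracts the elements of interest for structured-data
markup: title, authors, abstract, identifiers, dates, pagination, license,
citations, and the journal/volume/issue containment context.

Elements are matched by local name regardless of namespace prefixes, since
PMC-OAI responses vary in their namespace declarations. Absent elements
yield absent fields; no placeholder text is ever fabricated, and partial
publication dates keep their real precision (``2019``, ``2019-06``,
``2019-06-19``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from lxml import etree

from .errors import IdentifierFormatError, JatsParseError, JatsStructureError

__all__ = [
    "ArticleMetadata",
    "ContributorRecord",
    "CitationRecord",
    "PeriodicalContext",
    "parse_jats",
    "normalize_identifier",
]


@dataclass
class ContributorRecord:
    """One author; group/collaboration names are stored in ``surname``."""

    surname: str
    given_names: str | None = None
    orcid: str | None = None
    affiliation_texts: list[str] = field(default_factory=list)

    @property
    def display_name(self) -> str:
        if self.given_names:
            return f"{self.given_names} {self.surname}"
        return self.surname


@dataclass
class CitationRecord:
    """One bibliographic reference; ``raw_text`` is always populated."""

    raw_text: str
    label: str | None = None
    title: str | None = None
    doi: str | None = None
    pmid: str | None = None


@dataclass
class ArticleMetadata:
    """Bibliographic record of one scholarly article extracted from JATS."""

    title: str
    pmcid: str | None = None
    doi: str | None = None
    pmid: str | None = None
    authors: list[ContributorRecord] = field(default_factory=list)
    abstract: str | None = None
    keywords: list[str] = field(default_factory=list)
    license_url: str | None = None
    date_published: str | None = None
    page_start: str | None = None
    page_end: str | None = None
    citations: list[CitationRecord] = field(default_factory=list)

    def identifiers(self) -> list[str]:
        """Present identifiers, most specific first (pmcid, doi, pmid)."""
        return [i for i in (self.pmcid, self.doi, self.pmid) if i]


@dataclass
class PeriodicalContext:
    """Journal / volume / issue containment hierarchy for one article."""

    journal_name: str | None = None
    issn_print: str | None = None
    issn_electronic: str | None = None
    publisher: str | None = None
    volume: str | None = None
    issue: str | None = None


_DOI_PREFIX_RE = re.compile(r"^(https?://(dx\.)?doi\.org/|doi\.org/|doi:)\s*", re.I)


def normalize_identifier(raw: str, id_type: str) -> str:
    """Canonicalize an article identifier.

    pmc → ``PMC`` + digits; doi → bare DOI (scheme/``doi:`` prefixes
    stripped); pmid → digits only. Idempotent for all three types.
    """
    raw = raw.strip()
    if not raw:
        raise IdentifierFormatError("identifier is empty")
    if id_type == "pmc":
        digits = raw[3:] if raw.upper().startswith("PMC") else raw
        if not digits.isdigit():
            raise IdentifierFormatError(f"not a PMC identifier: {raw!r}")
        return f"PMC{digits}"
    if id_type == "doi":
        return _DOI_PREFIX_RE.sub("", raw)
    if id_type == "pmid":
        if not raw.isdigit():
            raise IdentifierFormatError(f"PMID must be digits only: {raw!r}")
        return raw
    raise ValueError(f"unknown identifier type {id_type!r}")


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _iter_local(root: etree._Element, name: str):
    for el in root.iter():
        if isinstance(el.tag, str) and _local(el) == name:
            yield el


def _first_local(root: etree._Element, name: str) -> etree._Element | None:
    return next(_iter_local(root, name), None)


def _text(el: etree._Element | None) -> str | None:
    """Whitespace-normalized text content, inline markup flattened."""
    if el is None:
        return None
    value = " ".join("".join(el.itertext()).split())
    return value or None


def _find_article(root: etree._Element) -> etree._Element:
    articles = list(_iter_local(root, "article"))
    if isinstance(root.tag, str) and _local(root) == "article":
        articles = [root]
    if len(articles) != 1:
        raise JatsStructureError(
            f"expected exactly one JATS <article> element, found {len(articles)}"
        )
    return articles[0]


def _parse_contrib(contrib: etree._Element) -> ContributorRecord | None:
    surname = _text(_first_local(contrib, "surname"))
    given = _text(_first_local(contrib, "given-names"))
    collab = _text(_first_local(contrib, "collab"))
    if not surname and not collab:
        return None
    orcid = None
    for cid in _iter_local(contrib, "contrib-id"):
        if cid.get("contrib-id-type", "").lower() == "orcid":
            orcid = _text(cid)
    affs = [t for aff in _iter_local(contrib, "aff") if (t := _text(aff))]
    return ContributorRecord(
        surname=surname or collab,  # type: ignore[arg-type]
        given_names=given if surname else None,
        orcid=orcid,
        affiliation_texts=affs,
    )


def _parse_authors(article_meta: etree._Element) -> list[ContributorRecord]:
    authors: list[ContributorRecord] = []
    for group in _iter_local(article_meta, "contrib-group"):
        for contrib in _iter_local(group, "contrib"):
            ctype = contrib.get("contrib-type")
            if ctype is not None and ctype != "author":
                continue
            rec = _parse_contrib(contrib)
            if rec is not None:
                authors.append(rec)
    return authors


def _parse_abstract(article_meta: etree._Element) -> str | None:
    # Only the first <abstract> (trans-abstracts are ignored); paragraphs
    # joined with a blank line, inline tags flattened to their text.
    abstract_el = _first_local(article_meta, "abstract")
    if abstract_el is None:
        return None
    paras = [t for p in _iter_local(abstract_el, "p") if (t := _text(p))]
    if paras:
        return "\n\n".join(paras)
    return _text(abstract_el)


_MONTHS = {str(i): f"{i:02d}" for i in range(1, 13)}


def _format_date(date_el: etree._Element) -> str | None:
    year = _text(_first_local(date_el, "year"))
    if not year:
        return None
    month = _text(_first_local(date_el, "month"))
    day = _text(_first_local(date_el, "day"))
    parts = [year]
    if month and month.strip() in _MONTHS:
        parts.append(_MONTHS[month.strip()])
        if day and day.strip().isdigit():
            parts.append(f"{int(day):02d}")
    return "-".join(parts)


def _parse_date(article_meta: etree._Element) -> str | None:
    dates = list(_iter_local(article_meta, "pub-date"))
    if not dates:
        return None

    def kind(el: etree._Element) -> str:
        return (el.get("pub-type") or el.get("date-type") or "").lower()

    # Electronic publication date wins, then print, then document order.
    for wanted in ("epub", "ppub"):
        for el in dates:
            if kind(el) == wanted and _format_date(el):
                return _format_date(el)
    for el in dates:
        if _format_date(el):
            return _format_date(el)
    return None


def _parse_license(article_meta: etree._Element) -> str | None:
    for lic in _iter_local(article_meta, "license"):
        for key, value in lic.attrib.items():
            if key.endswith("href"):
                return value
        for link in lic.iter():
            if not isinstance(link.tag, str):
                continue
            for key, value in link.attrib.items():
                if key.endswith("href"):
                    return value
    return None


def _parse_citations(article: etree._Element) -> list[CitationRecord]:
    citations: list[CitationRecord] = []
    ref_list = _first_local(article, "ref-list")
    if ref_list is None:
        return citations
    for ref in _iter_local(ref_list, "ref"):
        raw = _text(ref)
        if not raw:
            continue
        rec = CitationRecord(raw_text=raw)
        rec.label = _text(_first_local(ref, "label"))
        rec.title = _text(_first_local(ref, "article-title"))
        for pub_id in _iter_local(ref, "pub-id"):
            ptype = pub_id.get("pub-id-type", "").lower()
            value = _text(pub_id)
            if not value:
                continue
            if ptype == "doi":
                rec.doi = normalize_identifier(value, "doi")
            elif ptype == "pmid" and value.isdigit():
                rec.pmid = value
        citations.append(rec)
    return citations


def _parse_identifiers(article_meta: etree._Element, meta: ArticleMetadata) -> None:
    for aid in _iter_local(article_meta, "article-id"):
        ptype = (aid.get("pub-id-type") or "").lower()
        value = _text(aid)
        if not value:
            continue
        try:
            if ptype in ("pmc", "pmcid"):
                meta.pmcid = normalize_identifier(value, "pmc")
            elif ptype == "doi":
                meta.doi = normalize_identifier(value, "doi")
            elif ptype == "pmid":
                meta.pmid = normalize_identifier(value, "pmid")
        except IdentifierFormatError:
            continue


def _parse_periodical(article: etree._Element) -> PeriodicalContext:
    ctx = PeriodicalContext()
    journal_meta = _first_local(article, "journal-meta")
    if journal_meta is not None:
        ctx.journal_name = _text(_first_local(journal_meta, "journal-title"))
        for issn in _iter_local(journal_meta, "issn"):
            kind = (issn.get("pub-type") or issn.get("publication-format") or "").lower()
            value = _text(issn)
            if not value:
                continue
            if kind in ("epub", "electronic", "online"):
                ctx.issn_electronic = value
            else:
                ctx.issn_print = value
        ctx.publisher = _text(_first_local(journal_meta, "publisher-name"))
    article_meta = _first_local(article, "article-meta")
    if article_meta is not None:
        ctx.volume = _text(_first_local(article_meta, "volume"))
        ctx.issue = _text(_first_local(article_meta, "issue"))
    return ctx


def parse_jats(xml_text: str | bytes) -> tuple[ArticleMetadata, PeriodicalContext]:
    """Parse one JATS article record into metadata + periodical context.

    Accepts a bare ``<article>`` document or one inside an OAI-PMH
    ``GetRecord`` envelope; both yield identical results. Malformed XML
    raises :class:`JatsParseError` with line information; zero or multiple
    article elements raise :class:`JatsStructureError`.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise JatsParseError(f"malformed XML: {exc}") from exc

    article = _find_article(root)
    article_meta = _first_local(article, "article-meta")
    if article_meta is None:
        raise JatsStructureError("JATS article lacks an <article-meta> element")

    title_group = _first_local(article_meta, "title-group")
    title = _text(
        _first_local(title_group if title_group is not None else article_meta,
                     "article-title")
    )
    if not title:
        raise JatsStructureError("JATS article has no <article-title>")

    meta = ArticleMetadata(title=title)
    _parse_identifiers(article_meta, meta)
    meta.authors = _parse_authors(article_meta)
    meta.abstract = _parse_abstract(article_meta)
    meta.keywords = [
        t for kwd in _iter_local(article_meta, "kwd") if (t := _text(kwd))
    ]
    meta.license_url = _parse_license(article_meta)
    meta.date_published = _parse_date(article_meta)
    meta.page_start = _text(_first_local(article_meta, "fpage"))
    meta.page_end = _text(_first_local(article_meta, "lpage"))
    meta.citations = _parse_citations(article)

    return meta, _parse_periodical(article)
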