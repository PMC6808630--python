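"""Deterministic synthetic JATS and PubAnnotation inputs.

Everything downstream of the readers can be exercised without any network
access: this module fabricates JATS article records and PubAnnotation
documents from explicit parameter sets, with all randomness drawn from one
seeded generator so equal parameters always produce byte-identical output.

Fixture text is lorem-style ASCII by default, which keeps span arithmetic
trivial; offsets are counted in characters (not bytes), so Unicode text can
be exercised by passing multi-byte words explicitly. The generators are not
statistically realistic corpora — they honor counts, presence flags and
term multiplicities exactly, which is what parser round-trip and
aggregation-conservation checks need.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from lxml import etree

from .errors import FixtureError

__all__ = [
    "JatsFixtureParams",
    "PubAnnotationFixtureParams",
    "make_jats_fixture",
    "make_pubannotation_fixture",
]

_WORDS = (
    "lorem ipsum dolor sit amet consectetur adipiscing elit sed do eiusmod "
    "tempor incididunt ut labore et dolore magna aliqua enim ad minim veniam "
    "quis nostrud exercitation ullamco laboris nisi aliquip ex ea commodo"
).split()


@dataclass(frozen=True)
class JatsFixtureParams:
    """Observable knobs of a synthetic JATS record."""

    seed: int = 0
    title: str = "A synthetic study of markup generation"
    n_authors: int = 3
    has_volume: bool = True
    has_issue: bool = True
    n_citations: int = 2
    pmcid_digits: str = "2628047"
    include_oai_envelope: bool = False
    journal_name: str = "Journal of Synthetic Markup"
    volume: str = "17"
    issue: str = "2"
    page_start: str = "10"
    page_end: str = "12"

    def __post_init__(self) -> None:
        if self.n_authors < 0 or self.n_citations < 0:
            raise FixtureError("author/citation counts must be >= 0")
        if not self.pmcid_digits.isdigit():
            raise FixtureError("pmcid_digits must be all digits")
        if not self.title.strip():
            raise FixtureError("title must be non-empty")


@dataclass(frozen=True)
class PubAnnotationFixtureParams:
    """Observable knobs of a synthetic PubAnnotation document.

    Each denotation occupies a fixed 6-character span followed by a
    2-character gap, so ``8 × total multiplicity`` characters of text are
    required; infeasible packings are rejected.
    """

    seed: int = 0
    text_length: int = 400
    term_multiplicities: dict[str, int] = field(default_factory=dict)
    source_id: str = "2628047"

    def __post_init__(self) -> None:
        if self.text_length < 0:
            raise FixtureError("text_length must be >= 0")
        for term, mult in self.term_multiplicities.items():
            if not term:
                raise FixtureError("empty term IRI in multiplicities")
            if mult < 1:
                raise FixtureError(f"multiplicity for {term!r} must be >= 1")


def _lorem(rng: random.Random, n_words: int) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(n_words))


def make_jats_fixture(params: JatsFixtureParams) -> str:
    """Emit a well-formed JATS article honoring every parameter.

    Same seed and parameters give byte-identical XML. All profile-mapped
    fields (identifiers, authors, abstract, dates, pages, license, keywords,
    citations, journal metadata) are populated so that a fixture article
    converts to fully conformant markup.
    """
    rng = random.Random(params.seed)
    article = etree.Element("article", {"article-type": "research-article"})

    front = etree.SubElement(article, "front")
    journal_meta = etree.SubElement(front, "journal-meta")
    jtg = etree.SubElement(journal_meta, "journal-title-group")
    etree.SubElement(jtg, "journal-title").text = params.journal_name
    etree.SubElement(journal_meta, "issn", {"pub-type": "ppub"}).text = "1234-5678"
    etree.SubElement(journal_meta, "issn", {"pub-type": "epub"}).text = "8765-4321"
    publisher = etree.SubElement(journal_meta, "publisher")
    etree.SubElement(publisher, "publisher-name").text = "Synthetic Press"

    meta = etree.SubElement(front, "article-meta")
    etree.SubElement(
        meta, "article-id", {"pub-id-type": "pmc"}
    ).text = params.pmcid_digits
    etree.SubElement(
        meta, "article-id", {"pub-id-type": "doi"}
    ).text = f"10.99999/synthetic.{params.pmcid_digits}"
    etree.SubElement(
        meta, "article-id", {"pub-id-type": "pmid"}
    ).text = str(10_000_000 + int(params.pmcid_digits) % 10_000_000)

    tg = etree.SubElement(meta, "title-group")
    etree.SubElement(tg, "article-title").text = params.title

    cg = etree.SubElement(meta, "contrib-group")
    for i in range(1, params.n_authors + 1):
        contrib = etree.SubElement(cg, "contrib", {"contrib-type": "author"})
        name = etree.SubElement(contrib, "name")
        etree.SubElement(name, "surname").text = f"Surname{i}"
        etree.SubElement(name, "given-names").text = f"Given{i}"

    pub_date = etree.SubElement(meta, "pub-date", {"pub-type": "epub"})
    etree.SubElement(pub_date, "day").text = "19"
    etree.SubElement(pub_date, "month").text = "6"
    etree.SubElement(pub_date, "year").text = "2019"

    if params.has_volume:
        etree.SubElement(meta, "volume").text = params.volume
    if params.has_issue:
        etree.SubElement(meta, "issue").text = params.issue
    etree.SubElement(meta, "fpage").text = params.page_start
    etree.SubElement(meta, "lpage").text = params.page_end

    permissions = etree.SubElement(meta, "permissions")
    etree.SubElement(
        permissions,
        "license",
        {"{http://www.w3.org/1999/xlink}href":
         "https://creativecommons.org/licenses/by/4.0/"},
    )

    abstract = etree.SubElement(meta, "abstract")
    for _ in range(2):
        etree.SubElement(abstract, "p").text = _lorem(rng, 12).capitalize() + "."

    kwd_group = etree.SubElement(meta, "kwd-group")
    for _ in range(3):
        etree.SubElement(kwd_group, "kwd").text = rng.choice(_WORDS)

    back = etree.SubElement(article, "back")
    ref_list = etree.SubElement(back, "ref-list")
    for i in range(1, params.n_citations + 1):
        ref = etree.SubElement(ref_list, "ref", {"id": f"r{i}"})
        etree.SubElement(ref, "label").text = str(i)
        cit = etree.SubElement(ref, "element-citation")
        etree.SubElement(cit, "article-title").text = (
            _lorem(rng, 5).capitalize()
        )
        etree.SubElement(cit, "pub-id", {"pub-id-type": "doi"}).text = (
            f"10.99999/ref.{params.pmcid_digits}.{i}"
        )

    root = article
    if params.include_oai_envelope:
        oai_ns = "http://www.openarchives.org/OAI/2.0/"
        root = etree.Element(f"{{{oai_ns}}}OAI-PMH", nsmap={None: oai_ns})
        get_record = etree.SubElement(root, f"{{{oai_ns}}}GetRecord")
        record = etree.SubElement(get_record, f"{{{oai_ns}}}record")
        metadata = etree.SubElement(record, f"{{{oai_ns}}}metadata")
        metadata.append(article)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


# Fixed packing geometry keeps feasibility checkable up front.
_SPAN_WIDTH = 6
_SPAN_GAP = 2


def make_pubannotation_fixture(params: PubAnnotationFixtureParams) -> str:
    """Emit a PubAnnotation JSON document with exact term multiplicities.

    Spans are non-overlapping, in-bounds and strictly increasing; the
    interleaving of terms along the text is seeded, so the same parameters
    always give byte-identical JSON.
    """
    rng = random.Random(params.seed)
    occurrences: list[str] = []
    for term, mult in params.term_multiplicities.items():
        occurrences.extend([term] * mult)
    needed = len(occurrences) * (_SPAN_WIDTH + _SPAN_GAP)
    if needed > params.text_length:
        raise FixtureError(
            f"cannot pack {len(occurrences)} spans into text of length "
            f"{params.text_length} (need {needed})"
        )
    rng.shuffle(occurrences)

    chars: list[str] = []
    while len(chars) < params.text_length:
        chars.extend(rng.choice(_WORDS))
        chars.append(" ")
    text = "".join(chars)[: params.text_length]

    denotations = []
    cursor = 0
    for i, term in enumerate(occurrences, start=1):
        denotations.append(
            {
                "id": f"T{i}",
                "span": {"begin": cursor, "end": cursor + _SPAN_WIDTH},
                "obj": term,
            }
        )
        cursor += _SPAN_WIDTH + _SPAN_GAP
    doc = {
        "text": text,
        "sourcedb": "PMC",
        "sourceid": params.source_id,
        "project": "biotea-synthetic",
        "denotations": denotations,
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
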