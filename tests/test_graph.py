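"""Graph assembly, IRI minting, JSON-LD serialization, HTML embedding."""

import copy
import json

import pytest

from biotea_bioschemas import (
    ArticleMetadata,
    IriPolicy,
    PeriodicalContext,
    TermAggregate,
    build_markup,
    embed_in_html,
    mint_iri,
    parse_jsonld,
    serialize_jsonld,
    validate_document,
)
from biotea_bioschemas.errors import BuildError, MintingError, SerializationError
from biotea_bioschemas.graph import extract_embedded_jsonld

B = "https://biotea.github.io/bioschemas"


def _meta(**kw):
    defaults = dict(title="T", pmcid="PMC2628047")
    defaults.update(kw)
    return ArticleMetadata(**defaults)


class TestMintIri:
    def test_article_iri_from_pmcid(self):
        iri = mint_iri("article", _meta(), IriPolicy(base_iri=B))
        assert iri == f"{B}/PMC2628047#article"

    def test_all_fragments(self):
        policy = IriPolicy(base_iri=B)
        meta = _meta()
        assert mint_iri("record", meta, policy).endswith("#record")
        assert mint_iri("periodical", meta, policy).endswith("#journal")
        assert mint_iri("volume", meta, policy).endswith("#volume")
        assert mint_iri("issue", meta, policy).endswith("#issue")
        assert mint_iri("annotation", meta, policy, 2).endswith("#ann-2")

    def test_identifier_fallback_order(self):
        policy = IriPolicy(base_iri=B)
        doi_meta = _meta(pmcid=None, doi="10.5808/GI.2019.17.2.e14")
        assert mint_iri("article", doi_meta, policy) == \
            f"{B}/10.5808_GI.2019.17.2.e14#article"
        pmid_meta = _meta(pmcid=None, pmid="12345")
        assert "/12345#" in mint_iri("article", pmid_meta, policy)

    def test_no_identifier_is_minting_error(self):
        with pytest.raises(MintingError):
            mint_iri("article", _meta(pmcid=None), IriPolicy(base_iri=B))

    def test_deterministic(self):
        policy = IriPolicy(base_iri=B)
        assert mint_iri("article", _meta(), policy) == \
            mint_iri("article", _meta(), policy)


class TestIriPolicy:
    @pytest.mark.parametrize("base", ["not-an-iri", "https://x.org/base#frag"])
    def test_invalid_base_rejected(self, base):
        with pytest.raises(ValueError):
            IriPolicy(base_iri=base)


@pytest.mark.parametrize(
    "volume,issue,expected_types",
    [
        ("17", "2", ["PublicationIssue", "PublicationVolume", "Periodical"]),
        ("17", None, ["PublicationVolume", "Periodical"]),
        (None, "2", ["PublicationIssue", "Periodical"]),
        (None, None, ["Periodical"]),
    ],
)
def test_chain_contiguous_for_all_presence_combinations(volume, issue,
                                                        expected_types):
    periodical = PeriodicalContext(journal_name="J", volume=volume, issue=issue)
    doc = build_markup(_meta(), periodical)
    assert [n.node_type for n in doc.periodical_chain] == expected_types
    # walk isPartOf from the article; it must reach the Periodical with no gap
    by_id = {n.node_id: n for n in doc.periodical_chain}
    node = doc.article
    hops = 0
    while "isPartOf" in node.properties:
        node = by_id[node.properties["isPartOf"]["@id"]]
        hops += 1
    assert node.node_type == "Periodical"
    assert hops == len(expected_types)


def test_no_journal_means_no_chain():
    doc = build_markup(_meta(), PeriodicalContext())
    assert doc.periodical_chain == []
    assert "isPartOf" not in doc.article.properties


def test_bidirectional_closure_two_aggregates():
    aggs = [
        TermAggregate("http://x.org/A", "A", 3, 0),
        TermAggregate("http://x.org/B", "B", 1, 5),
    ]
    doc = build_markup(_meta(), PeriodicalContext(journal_name="J"), aggs)
    about = [v["@id"] for v in doc.article.properties["about"]]
    assert about == [a.node_id for a in doc.annotations]
    assert len(about) == 2
    for ann in doc.annotations:
        assert ann.properties["subjectOf"]["@id"] == doc.article.node_id
    assert doc.annotations[0].node_id.endswith("#ann-1")
    assert doc.annotations[1].node_id.endswith("#ann-2")
    assert doc.annotations[0].properties["biotea:occurrences"] == 3


def test_no_aggregates_means_no_about():
    doc = build_markup(_meta(), PeriodicalContext(journal_name="J"))
    assert "about" not in doc.article.properties
    assert doc.annotations == []


def test_empty_title_is_build_error():
    with pytest.raises(BuildError, match="title"):
        build_markup(_meta(title="  "), PeriodicalContext())


def test_duplicate_term_iris_is_build_error():
    aggs = [TermAggregate("http://x.org/A", "A", 2, 0),
            TermAggregate("http://x.org/A", "A", 1, 8)]
    with pytest.raises(BuildError, match="duplicate"):
        build_markup(_meta(), PeriodicalContext(), aggs)


def test_record_node_links_article_via_main_entity(document):
    assert document.record.node_type == "CreativeWork"
    assert document.record.properties["mainEntity"]["@id"] == \
        document.article.node_id


class TestSerialization:
    def test_shape_and_node_order(self, document):
        data = json.loads(serialize_jsonld(document))
        assert data["@context"][0] == "https://schema.org"
        assert "biotea" in data["@context"][1]
        types = [n["@type"] for n in data["@graph"]]
        assert types[:2] == ["CreativeWork", "ScholarlyArticle"]
        assert types[2:5] == ["PublicationIssue", "PublicationVolume",
                              "Periodical"]
        assert all(t == "DefinedTerm" for t in types[5:])
        for node in data["@graph"]:
            keys = list(node)
            assert keys[:2] == ["@id", "@type"]
            assert keys[2:] == sorted(keys[2:])

    def test_byte_identical_across_runs(self, document):
        assert serialize_jsonld(document) == serialize_jsonld(copy.deepcopy(document))

    def test_round_trip_fixed_point(self, document):
        text = serialize_jsonld(document)
        assert serialize_jsonld(parse_jsonld(text)) == text

    def test_violated_invariant_refuses_serialization(self, document):
        broken = copy.deepcopy(document)
        broken.annotations[0].properties["subjectOf"] = {"@id": "http://x.org/other"}
        with pytest.raises(SerializationError, match="subjectOf"):
            serialize_jsonld(broken)
        broken2 = copy.deepcopy(document)
        broken2.periodical_chain[0].properties.pop("isPartOf")
        with pytest.raises(SerializationError, match="chain"):
            serialize_jsonld(broken2)


def test_rdflib_reads_the_markup_back(document):
    """Independent oracle: an off-the-shelf JSON-LD parser sees the same graph.

    The well-known remote @context is replaced by its inline equivalent so
    the check runs without network access.
    """
    rdflib = pytest.importorskip("rdflib")
    data = json.loads(serialize_jsonld(document))
    data["@context"][0] = {"@vocab": "https://schema.org/"}
    g = rdflib.Graph().parse(data=json.dumps(data), format="json-ld")
    SDO = rdflib.Namespace("https://schema.org/")
    article = rdflib.URIRef(document.article.node_id)
    record = rdflib.URIRef(document.record.node_id)
    assert (record, SDO.mainEntity, article) in g
    about = set(g.objects(article, SDO.about))
    assert about == {rdflib.URIRef(a.node_id) for a in document.annotations}
    for ann in document.annotations:
        assert (rdflib.URIRef(ann.node_id), SDO.subjectOf, article) in g


class TestEmbed:
    HTML = "<html><head></head><body><p>content</p></body></html>"

    def test_script_is_last_body_element(self, document):
        out = embed_in_html(self.HTML, document)
        script_pos = out.index('<script type="application/ld+json">')
        assert script_pos > out.index("<p>content</p>")
        assert out.index("</body>") > script_pos
        assert out.replace(
            '<script type="application/ld+json">\n'
            + serialize_jsonld(document) + "</script>\n", "") == self.HTML

    def test_extract_round_trip(self, document):
        out = embed_in_html(self.HTML, document)
        assert extract_embedded_jsonld(out) == serialize_jsonld(document)
        assert json.loads(extract_embedded_jsonld(out)) == \
            json.loads(serialize_jsonld(document))

    def test_existing_scripts_preserved_new_one_last(self, document):
        html = "<html><body><script>var x=1;</script></body></html>"
        out = embed_in_html(html, document)
        assert "var x=1;" in out
        assert out.index("application/ld+json") > out.index("var x=1;")

    def test_page_without_body_gets_script_appended(self, document):
        out = embed_in_html("<p>bare fragment</p>", document)
        assert out.startswith("<p>bare fragment</p>")
        assert out.rstrip().endswith("</script>")


def test_builder_output_conformant(document):
    report = validate_document(document)
    assert report.conformant
    assert not [i for i in report.issues if i.severity == "error"]
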