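import pytest

from biotea_bioschemas import aggregate_terms, build_markup, parse_jats, parse_pubannotation
from biotea_bioschemas.fixtures import (
    JatsFixtureParams,
    PubAnnotationFixtureParams,
    make_jats_fixture,
    make_pubannotation_fixture,
)

TERMS = {
    "http://purl.obolibrary.org/obo/GO_0008150": 3,
    "http://purl.obolibrary.org/obo/DOID_1234": 1,
}


@pytest.fixture
def jats_xml():
    return make_jats_fixture(JatsFixtureParams(seed=7))


@pytest.fixture
def article(jats_xml):
    return parse_jats(jats_xml)


@pytest.fixture
def aggregates():
    text = make_pubannotation_fixture(
        PubAnnotationFixtureParams(seed=7, term_multiplicities=dict(TERMS))
    )
    return aggregate_terms(parse_pubannotation(text))


@pytest.fixture
def document(article, aggregates):
    meta, periodical = article
    return build_markup(meta, periodical, aggregates)


def build_doc_from_seed(seed: int, **overrides):
    """One fully populated markup document per seed, annotations included."""
    params = JatsFixtureParams(seed=seed, **overrides)
    meta, periodical = parse_jats(make_jats_fixture(params))
    ann = make_pubannotation_fixture(
        PubAnnotationFixtureParams(seed=seed, term_multiplicities=dict(TERMS))
    )
    aggs = aggregate_terms(parse_pubannotation(ann))
    return build_markup(meta, periodical, aggs)
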