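"""Exception hierarchy for the biotea_bioschemas package."""


class BioteaError(Exception):
    """Base class for all package errors."""


class JatsParseError(BioteaError):
    """The input is not well-formed XML."""


class JatsStructureError(BioteaError):
    """The XML is well-formed but does not contain exactly one JATS article."""


class IdentifierFormatError(BioteaError, ValueError):
    """An article identifier does not match its declared type."""


class AnnotationParseError(BioteaError):
    """The input is not valid PubAnnotation JSON."""


class SpanValidationError(BioteaError):
    """A denotation span is degenerate or out of text bounds."""


class TermFormatError(BioteaError, ValueError):
    """An annotation term is empty or unusable."""


class BuildError(BioteaError):
    """Markup document construction failed a precondition."""


class MintingError(BioteaError):
    """No usable identifier is available to mint an IRI from."""


class SerializationError(BioteaError):
    """A document invariant is violated; serialization refused."""


class MarkupParseError(BioteaError):
    """Input JSON-LD is not in the emitted markup shape."""


class FixtureError(BioteaError):
    """Fixture parameters are invalid or infeasible."""


class SitemapError(BioteaError):
    """Sitemap specification is invalid (bad ids or URL)."""
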