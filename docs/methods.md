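# Methods

## The mapping

One scholarly article is represented as a small linked-data graph in
schema.org vocabulary. A top-level `CreativeWork` *record* node represents
the structured-data artifact itself and points at the publication through
`mainEntity`; this separation keeps record-level concerns out of the
article node, whose properties come from the JATS bibliographic record:
`article-title → name`, `contrib → author`, `abstract → description`,
`pub-date → datePublished`, `fpage/lpage → pageStart/pageEnd`,
`article-id → identifier`, `permissions/license → license`,
`ref-list → citation`, plus `keywords`. The periodical context maps to a
containment chain `ScholarlyArticle → PublicationIssue →
PublicationVolume → Periodical` via `isPartOf`; levels absent from the
input are omitted and the chain re-linked so it is always contiguous and
always terminates at the `Periodical`.

Semantic annotations — ontology terms recognized in the article text —
enter as PubAnnotation denotations (character spans bound to term IRIs,
0-based, end-exclusive, counted in characters). Denotations are aggregated
to one record per distinct expanded term IRI with its occurrence count;
each aggregate becomes a `DefinedTerm` node carrying the label in `name`,
the ontology class IRI in `sameAs`, the IRI namespace in
`inDefinedTermSet`, and the count in `biotea:occurrences`. schema.org has
no annotation type and no occurrence-count property, so `DefinedTerm` is
used as the closest schema-native carrier and the count rides on a
namespaced extension property declared in `@context`. Article and
annotations are linked reciprocally: `about` on the article lists every
annotation node, and every annotation's `subjectOf` points back at the
article. This bidirectional closure is established by construction in the
builder and re-checked before every serialization.

Annotations are always read from files (frozen snapshots). Running an
annotator live would tie the markup to whatever ontology versions the
service currently loads, so the same article could yield different markup
at different times; frozen sets keep conversion reproducible.

## Profiles and validation

Five draft profiles — Journal (`Periodical`), Volume
(`PublicationVolume`), Issue (`PublicationIssue`), ScholarlyArticle, and
SemanticAnnotation (`DefinedTerm`) — assign properties to minimum,
recommended and optional tiers. The tier membership is deliberately *data*,
not code: the profiles are drafts whose contents are expected to change,
so they ship as one TSV row per (profile, tier, property) in
`data/profiles.tsv`. The registry enforces that exactly five profiles
exist, that tiers are pairwise disjoint, and that every minimum tier is
non-empty.

Validation reports one issue per missing or empty minimum/recommended
property (error / warning respectively). Empty strings, lists and maps
count as missing because markup consumers treat them as absent. A missing
optional property is by definition not an issue; optional properties are
only flagged (severity info) when present but empty. The record node is
never validated against a profile — it is plumbing, not a profiled entity.
A document is conformant iff it has no error-level issue. Validation is
pure: it never mutates the document.

## Determinism

Serialization is a pure function of the document: fixed `@context`
(`https://schema.org` plus the `biotea` extension namespace), fixed node
order (record, article, chain innermost first, annotations in aggregate
order), per-node key order `@id`, `@type`, then properties alphabetically,
2-space indentation, LF line endings. Aggregate order is occurrence count
descending with ties broken by term IRI ascending; annotation fragment
IRIs (`#ann-1`, `#ann-2`, …) follow that order. Node IRIs are minted from
one base IRI plus the article's best identifier (PMCID, else DOI with `/`
replaced by `_`, else PMID) and a per-entity fragment, so equal inputs
give byte-identical output — verified by round-trip (serialize → parse →
serialize is a fixed point) and double-run byte comparison.

## Parsing choices

JATS elements are matched by local name, ignoring namespaces, because
OAI responses vary in their namespace declarations; a record parses
identically bare or inside an OAI-PMH envelope. JATS can carry several
publication dates; the electronic date (`epub`) wins, then print (`ppub`),
then document order — and partial dates keep their true precision
(`2019`, `2019-06`, `2019-06-19`) rather than fabricating a day. Only the
first abstract is used, paragraphs joined with blank lines and inline
formatting flattened to text. Only author-typed (or untyped) contributors
are kept, in document order; group names are stored in the surname slot.
Each reference yields one citation record whose raw text is always
populated; structured subfields (title, DOI, PMID) are best-effort.

Term IRIs arriving as CURIEs are expanded through a configurable prefix
map; unknown prefixes pass through verbatim with a logged warning rather
than failing, since a verbatim term still identifies the annotation. The
label fallback is the IRI's local name (text after the last `/`, `#` or
`_`) because PubAnnotation denotations carry IRIs, not labels. The source
ontology of a term is not recorded explicitly in PubAnnotation, so
`inDefinedTermSet` is derived from the IRI namespace and is best-effort.

## Synthetic inputs

The fixture generators emulate the two input dialects: a JATS 1.x article
(optionally in an OAI envelope) with every profile-mapped field populated,
and a PubAnnotation document with exact per-term multiplicities. All
randomness comes from one seeded generator passed explicitly, so equal
parameters give byte-identical output. Defaults mirror the showcase
article the tooling was built around: PMCID digits 2628047, volume 17,
issue 2. Annotation spans use a fixed geometry (6-character spans,
2-character gaps), which makes packing feasibility checkable up front and
keeps span arithmetic trivial; fixture text is lorem-style ASCII, with
Unicode exercised separately since offsets are character counts.

What the generators do *not* emulate: statistically realistic corpora,
real ontology IRIs, malformed publisher XML, or full-text body structure.
Passing tests therefore demonstrate the mapping, linking, validation and
determinism contracts — not robustness against every JATS dialect in the
wild.

## Problem sizes

The validation batches run 100 seeded fixture documents for link closure
and occurrence conservation, 50 for determinism/round-trip, 25 for
builder/validator coherence with per-property deletion checks, 100
parameter vectors for generator/parser recovery, and sitemaps of 0, 1, 10
and 1000 entries. These sizes exercise every code path and all four
volume/issue presence combinations while keeping the whole suite under a
minute.

## Known limitations

* Tier membership follows this package's documented defaults; the
  upstream profile drafts may diverge, which is why the table is editable
  data.
* Validation is tier-presence checking, not SHACL/ShEx shape validation,
  and covers only the five profiles.
* No live retrieval: PMC-OAI fetching and on-the-fly annotator calls are
  out of scope by design.
* JSON-LD is emitted in one fixed shape; framing, compaction, RDFa or
  Microdata outputs are not provided.
* Citations richer than (label, title, DOI, PMID) are flattened to their
  raw text.
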