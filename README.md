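# biotea-bioschemas

Structured-data markup for scholarly publications and their semantic
annotations.

Search engines and knowledge-graph builders understand web pages through
schema.org markup embedded as JSON-LD. Literature repositories that expose
such markup usually stop at plain bibliography — title, authors, journal —
and drop the life-science entities (genes, diseases, drugs, processes)
that text mining recognizes in the article itself. This package implements
the Biotea mapping to Bioschemas: it converts a JATS XML article record
(as served by the PubMed Central Open-Access OAI interface) plus a frozen
set of PubAnnotation text annotations into a small linked-data graph and
emits it as deterministic JSON-LD, ready to embed in an article page.

It is written for data providers who publish article pages and want them
marked up, and for text-mining groups who want their annotation sets
surfaced as FAIR structured data.

## The model

The markup for one article is an entity graph built around reciprocal
links:

```
CreativeWork (record)
   └─ mainEntity → ScholarlyArticle ── isPartOf → PublicationIssue
                       │   │                        └─ isPartOf → PublicationVolume
                       │   │                                        └─ isPartOf → Periodical
                       │   └─ about → DefinedTerm (one per distinct ontology term)
                       └──────────────── subjectOf ┘   (links back to the article)
```

* The structured-data **record** is kept separate from the publication and
  linked to it via `schema:mainEntity`, so record-level properties never
  collide with article metadata.
* The article sits in a contiguous `isPartOf` containment chain; absent
  volume or issue levels are omitted and the chain is re-linked, so walking
  `isPartOf` always ends at the `Periodical`.
* Each distinct annotated ontology term becomes a `DefinedTerm` node with
  the term IRI in `sameAs` and its occurrence count in the extension
  property `biotea:occurrences`; `schema:about` and `schema:subjectOf`
  close the article↔annotation loop in both directions.

Five draft profiles — journal, volume, issue, scholarly article, semantic
annotation — assign each schema.org property a usage tier (minimum /
recommended / optional). The validator reports a missing minimum property
as an error and a missing recommended property as a warning; the tier
table ships as an editable TSV (`src/biotea_bioschemas/data/profiles.tsv`).

## Worked example

Generate synthetic inputs, convert, and keep only terms annotated more
than once:

```bash
biotea2bioschemas fixture jats --seed 7 --out article.xml
biotea2bioschemas fixture pubannotation --seed 7 \
    --term "http://purl.obolibrary.org/obo/GO_0008150=3" \
    --term "http://purl.obolibrary.org/obo/DOID_1234=1" \
    --out annotations.json
biotea2bioschemas convert article.xml --annotations annotations.json \
    --min-occurrences 2 --out markup.jsonld
```

The conversion prints a conformance summary on standard error:

```
conformant: 5 node(s) checked, 0 error(s), 1 warning(s), 0 info
  [warning] https://biotea.github.io/bioschemas/PMC2628047#article .url: recommended property 'url' is missing or empty
```

Five nodes were validated (article, issue, volume, journal, one
annotation); no minimum-tier property is missing, so the markup is
conformant, with one warning because the article page URL is not known at
conversion time. `markup.jsonld` holds the graph; its annotation node shows
how a term that occurred 3 times is carried (the DOID term, with a single
occurrence, was filtered out by `--min-occurrences 2`):

```json
{
  "@id": "https://biotea.github.io/bioschemas/PMC2628047#ann-1",
  "@type": "DefinedTerm",
  "biotea:occurrences": 3,
  "inDefinedTermSet": "http://purl.obolibrary.org/obo/GO_",
  "name": "0008150",
  "sameAs": "http://purl.obolibrary.org/obo/GO_0008150",
  "subjectOf": { "@id": "https://biotea.github.io/bioschemas/PMC2628047#article" }
}
```

The same pipeline is available as a library (`parse_jats`,
`parse_pubannotation`, `aggregate_terms`, `build_markup`,
`serialize_jsonld`, `validate_document`, `embed_in_html`), and further
subcommands cover `validate` (tier conformance with exit codes), `embed`
(append the markup as the last `<script type="application/ld+json">` of an
HTML page) and `sitemap` (a sitemaps.org urlset with one
`{base_url}?pmc={id}` entry per article).

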