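"""Sitemap generation for collections of marked-up articles.

Every article page of a deployment is listed in one sitemaps.org ``urlset``
so search engines can discover and index the markup. Page URLs follow the
``{base_url}?pmc={id}`` pattern used by article showcase pages; deployments
with a different routing scheme can override the template.
"""

from __future__ import annotations

from dataclasses import dataclass

from lxml import etree

from .errors import SitemapError

__all__ = ["SitemapSpec", "build_sitemap"]

_SITEMAP_NS = "http://www.sitemaps.org/schemas/sitemap/0.9"


@dataclass(frozen=True)
class SitemapSpec:
    """One sitemap: a base URL plus the numeric PMC ids it serves."""

    base_url: str
    article_ids: tuple[str, ...] = ()
    lastmod: str | None = None
    url_template: str = "{base_url}?pmc={id}"

    def __post_init__(self) -> None:
        if "://" not in self.base_url:
            raise SitemapError(f"base_url must be absolute: {self.base_url!r}")
        for aid in self.article_ids:
            if not aid or not aid.isdigit():
                raise SitemapError(f"article id must be digits: {aid!r}")
        if len(set(self.article_ids)) != len(self.article_ids):
            raise SitemapError("duplicate article ids in sitemap spec")


def build_sitemap(spec: SitemapSpec) -> str:
    """Render the sitemap XML: one ``<url>`` per id, in input order."""
    urlset = etree.Element(f"{{{_SITEMAP_NS}}}urlset", nsmap={None: _SITEMAP_NS})
    for aid in spec.article_ids:
        url = etree.SubElement(urlset, f"{{{_SITEMAP_NS}}}url")
        loc = etree.SubElement(url, f"{{{_SITEMAP_NS}}}loc")
        loc.text = spec.url_template.format(base_url=spec.base_url, id=aid)
        if spec.lastmod:
            etree.SubElement(url, f"{{{_SITEMAP_NS}}}lastmod").text = spec.lastmod
    return etree.tostring(
        urlset, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")
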