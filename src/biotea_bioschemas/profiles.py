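"""Bioschemas draft profiles for scholarly publications, and tier validation.

Five profiles describe how to mark up a journal, a publication volume, a
publication issue, a scholarly article, and a semantic scholarly annotation
with schema.org vocabulary. Each profile assigns properties to one of three
usage tiers — minimum, recommended, optional — following the Bioschemas
profile convention. The tier table is shipped as a plain TSV data file
(``data/profiles.tsv``) so that membership can be revised without touching
code: the profiles are drafts and their tiers are expected to evolve.

Validation walks the typed nodes of a markup document and reports one
:class:`ConformanceIssue` per missing or empty tiered property. A missing
minimum-tier property is an error, a missing recommended-tier property a
warning; optional-tier properties are only flagged (as info) when present
but empty, since their absence is by definition acceptable. The top-level
structured-data record node (a plain ``CreativeWork``) is exempt: it is
markup plumbing that links to the publication via ``mainEntity``, not a
profiled entity itself.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .graph import EntityNode, MarkupDocument

__all__ = [
    "PROFILE_NAMES",
    "ProfileSpec",
    "ConformanceIssue",
    "ConformanceReport",
    "get_profile",
    "profile_for_entity_type",
    "validate_node",
    "validate_nodes",
    "validate_document",
]

PROFILE_NAMES = (
    "Journal",
    "Volume",
    "Issue",
    "ScholarlyArticle",
    "SemanticAnnotation",
)

#: Severity ranks used to order issues within a report.
_SEVERITY_RANK = {"error": 0, "warning": 1, "info": 2}

_TIER_SEVERITY = {"minimum": "error", "recommended": "warning", "optional": "info"}


@dataclass(frozen=True)
class ProfileSpec:
    """One Bioschemas draft profile: an entity type plus tiered properties.

    The three tiers are pairwise disjoint ordered tuples; ``minimum_props``
    is never empty.
    """

    profile_name: str
    entity_type: str
    minimum_props: tuple[str, ...]
    recommended_props: tuple[str, ...]
    optional_props: tuple[str, ...]

    def tier_of(self, prop: str) -> str | None:
        if prop in self.minimum_props:
            return "minimum"
        if prop in self.recommended_props:
            return "recommended"
        if prop in self.optional_props:
            return "optional"
        return None


@dataclass(frozen=True)
class ConformanceIssue:
    """A single tier-validation finding on one node.

    ``error`` flags a missing/empty minimum-tier property, ``warning`` a
    recommended-tier one, ``info`` an optional-tier property that is present
    but empty.
    """

    severity: str
    node_id: str
    property_name: str
    message: str


@dataclass
class ConformanceReport:
    """Aggregated validation outcome over a document's profiled nodes."""

    issues: list[ConformanceIssue] = field(default_factory=list)
    checked_nodes: int = 0

    @property
    def conformant(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def summary(self) -> str:
        n_err = sum(1 for i in self.issues if i.severity == "error")
        n_warn = sum(1 for i in self.issues if i.severity == "warning")
        n_info = sum(1 for i in self.issues if i.severity == "info")
        verdict = "conformant" if self.conformant else "NOT conformant"
        lines = [
            f"{verdict}: {self.checked_nodes} node(s) checked, "
            f"{n_err} error(s), {n_warn} warning(s), {n_info} info"
        ]
        for issue in self.issues:
            lines.append(
                f"  [{issue.severity}] {issue.node_id} .{issue.property_name}: "
                f"{issue.message}"
            )
        return "\n".join(lines)


@lru_cache(maxsize=1)
def _registry() -> dict[str, ProfileSpec]:
    """Load the five profiles from the bundled TSV tier table."""
    tiers: dict[str, dict[str, list[str]]] = {}
    entity_types: dict[str, str] = {}
    path = resources.files("biotea_bioschemas").joinpath("data/profiles.tsv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = row["profile"]
            entity_types[name] = row["entity_type"]
            tiers.setdefault(
                name, {"minimum": [], "recommended": [], "optional": []}
            )[row["tier"]].append(row["property"])
    registry = {
        name: ProfileSpec(
            profile_name=name,
            entity_type=entity_types[name],
            minimum_props=tuple(t["minimum"]),
            recommended_props=tuple(t["recommended"]),
            optional_props=tuple(t["optional"]),
        )
        for name, t in tiers.items()
    }
    if set(registry) != set(PROFILE_NAMES):
        raise RuntimeError(
            f"profile table defines {sorted(registry)}, expected {PROFILE_NAMES}"
        )
    return registry


def get_profile(profile_name: str) -> ProfileSpec:
    """Return the immutable profile spec registered under ``profile_name``."""
    try:
        return _registry()[profile_name]
    except KeyError:
        raise KeyError(
            f"unknown profile {profile_name!r}; valid names: "
            f"{', '.join(PROFILE_NAMES)}"
        ) from None


def profile_for_entity_type(entity_type: str) -> ProfileSpec | None:
    """Return the profile whose entity type is ``entity_type``, if any."""
    for spec in _registry().values():
        if spec.entity_type == entity_type:
            return spec
    return None


def _is_empty(value: object) -> bool:
    # Empty string/list/dict count as missing: markup consumers treat them
    # as absent values.
    if value is None:
        return True
    if isinstance(value, str):
        return value.strip() == ""
    if isinstance(value, (list, tuple, dict)):
        return len(value) == 0
    return False


def validate_node(node: "EntityNode", spec: ProfileSpec) -> list[ConformanceIssue]:
    """Check one typed node against a profile's property tiers.

    Returns one issue per missing or empty minimum/recommended property and
    per present-but-empty optional property, ordered by (severity, property
    name). A node whose type does not match the spec is a usage error.
    """
    if node.node_type != spec.entity_type:
        raise ValueError(
            f"node {node.node_id} has type {node.node_type!r}, "
            f"expected {spec.entity_type!r} for profile {spec.profile_name}"
        )
    issues: list[ConformanceIssue] = []
    for tier, props in (
        ("minimum", spec.minimum_props),
        ("recommended", spec.recommended_props),
    ):
        for prop in props:
            value = node.properties.get(prop)
            if prop not in node.properties or _is_empty(value):
                issues.append(
                    ConformanceIssue(
                        severity=_TIER_SEVERITY[tier],
                        node_id=node.node_id,
                        property_name=prop,
                        message=f"{tier} property {prop!r} is missing or empty",
                    )
                )
    for prop in spec.optional_props:
        if prop in node.properties and _is_empty(node.properties[prop]):
            issues.append(
                ConformanceIssue(
                    severity="info",
                    node_id=node.node_id,
                    property_name=prop,
                    message=f"optional property {prop!r} is present but empty",
                )
            )
    issues.sort(key=lambda i: (_SEVERITY_RANK[i.severity], i.property_name))
    return issues


def validate_nodes(nodes: Iterable["EntityNode"]) -> ConformanceReport:
    """Validate every node whose type has a registered profile.

    Nodes of unregistered types (e.g. the CreativeWork record node) are
    skipped and not counted.
    """
    report = ConformanceReport()
    for node in nodes:
        spec = profile_for_entity_type(node.node_type)
        if spec is None:
            continue
        report.issues.extend(validate_node(node, spec))
        report.checked_nodes += 1
    return report


def validate_document(doc: "MarkupDocument") -> ConformanceReport:
    """Validate all profiled nodes of a markup document.

    The record node is structured-data plumbing and is never validated
    against a profile; everything else (article, periodical chain,
    annotation nodes) is checked against the profile matching its type.
    """
    return validate_nodes(doc.typed_nodes())
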