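"""Parse and compose multipartite concept names.

Concept names concatenate up to five segments, separated by single spaces,
in a fixed order::

    [elementary domain] [operation domain] <core element> [property] <data-type literal>

e.g. ``unit digital measurement device URI <string>`` decomposes into
elementary domain *digital*, operation domain *measurement*, core element
``device``, property ``URI`` and the text data type.  Only the core element
and the data-type literal are mandatory: a name may omit the operation
domain (object-trait concepts such as
``unit physical (host) organism muscle tissue <category>``) and generic
record-keeping concepts carry the bare ``unit`` prefix with no elementary
domain (``unit record creation date/time <string>``).

Core elements are unbounded multiword phrases, so segmentation is driven by
closed token registries rather than delimiters:

1. strip and classify the trailing data-type literal (``<category> <string>``
   is matched greedily before ``<string>``);
2. match the leading elementary-domain token, longest first
   (``unit physical`` / ``unit digital`` / bare ``unit``);
3. match a following operation-domain token if present;
4. match the longest registered property suffix against the tail of the
   remainder (whole-token match; a property is never extracted if doing so
   would leave the core element empty);
5. the residue is the core element.

Composition inverts this exactly, so ``compose(parse(name)) == name`` for
every well-formed name.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NameParseError
from .vocab import (
    DataTypeToken,
    ElementaryDomain,
    LITERAL_MATCH_ORDER,
    OperationDomain,
)

__all__ = [
    "VocabRegistries",
    "ParsedName",
    "default_registries",
    "parse_concept_name",
    "compose_concept_name",
]


#: Rendering of the elementary-domain segment.  The bare ``unit`` prefix
#: marks generic concepts without an elementary domain.
_ELEMENTARY_TOKENS: tuple[tuple[str, ElementaryDomain | None], ...] = (
    ("unit physical", ElementaryDomain.PHYSICAL),
    ("unit digital", ElementaryDomain.DIGITAL),
    ("unit", None),
)

_ELEMENTARY_RENDER: dict[ElementaryDomain | None, str] = {
    ElementaryDomain.PHYSICAL: "unit physical",
    ElementaryDomain.DIGITAL: "unit digital",
    None: "unit",
}

#: Properties attested across the schema's concept names.  Kept deliberately
#: small: an over-eager registry would start eating the tails of multiword
#: core elements.
DEFAULT_PROPERTIES: tuple[str, ...] = (
    "presence",
    "name",
    "ID",
    "DOI",
    "notes",
    "URI",
    "date/time",
    "format",
)


@dataclass(frozen=True)
class VocabRegistries:
    """Closed token sets that drive name segmentation."""

    operation_domains: tuple[str, ...] = tuple(d.value for d in OperationDomain)
    properties: tuple[str, ...] = DEFAULT_PROPERTIES

    def property_suffix(self, tokens: list[str]) -> str | None:
        """Longest registered property matching a whole-token suffix.

        Returns None when nothing matches or when a match would consume
        every token (the core element must stay non-empty).
        """
        matches = []
        for prop in self.properties:
            ptoks = prop.split(" ")
            if len(ptoks) >= len(tokens):
                continue  # would empty the core
            if tokens[-len(ptoks):] == ptoks:
                matches.append(prop)
        if not matches:
            return None
        return max(matches, key=lambda p: (len(p.split(" ")), len(p)))


_DEFAULT_REGISTRIES = VocabRegistries()


def default_registries() -> VocabRegistries:
    """The package's default token registries."""
    return _DEFAULT_REGISTRIES


@dataclass(frozen=True)
class ParsedName:
    """Decomposition of a multipartite concept name.

    ``elementary_domain`` / ``operation_domain`` use None for segments a
    name legitimately omits; ``data_type`` is always present.
    """

    elementary_domain: ElementaryDomain | None
    operation_domain: OperationDomain | None
    core_element: str
    property: str | None
    data_type: DataTypeToken

    def __post_init__(self) -> None:
        if not self.core_element:
            raise NameParseError("core element must be non-empty")

    def as_dict(self) -> dict[str, str | None]:
        return {
            "elementary_domain": self.elementary_domain.value if self.elementary_domain else None,
            "operation_domain": self.operation_domain.value if self.operation_domain else None,
            "core_element": self.core_element,
            "property": self.property,
            "data_type": self.data_type.value,
        }


def _strip_literal(name: str) -> tuple[str, DataTypeToken]:
    for literal, token in LITERAL_MATCH_ORDER:
        if name == literal:
            break
        if name.endswith(" " + literal):
            return name[: -len(literal) - 1], token
    raise NameParseError(f"no data-type literal at end of name: {name!r}")


def parse_concept_name(
    name: str,
    registries: VocabRegistries | None = None,
    *,
    sequence: bool = False,
) -> ParsedName:
    """Segment a concept name into its multipartite parts.

    ``sequence=True`` resolves the ``<string>`` literal to the sequence
    data type instead of text; the literal itself is ambiguous and the
    choice must come from concept metadata.

    Raises :class:`NameParseError` when the name lacks a trailing data-type
    literal, does not start with a ``unit`` elementary-domain token, or
    leaves no residue for the core element.
    """
    registries = registries or _DEFAULT_REGISTRIES
    if not name or not name.strip():
        raise NameParseError("empty concept name")
    rest, data_type = _strip_literal(name)
    if data_type is DataTypeToken.TEXT and sequence:
        data_type = DataTypeToken.SEQUENCE

    elementary: ElementaryDomain | None = None
    for token, domain in _ELEMENTARY_TOKENS:
        if rest == token:
            raise NameParseError(f"empty core element in name: {name!r}")
        if rest.startswith(token + " "):
            elementary = domain
            rest = rest[len(token) + 1:]
            break
    else:
        raise NameParseError(f"name does not start with a unit domain token: {name!r}")

    operation: OperationDomain | None = None
    head, _, tail = rest.partition(" ")
    if head in registries.operation_domains and tail:
        operation = OperationDomain(head)
        rest = tail

    tokens = rest.split(" ")
    prop = registries.property_suffix(tokens)
    if prop is not None:
        core = " ".join(tokens[: -len(prop.split(" "))])
    else:
        core = rest
    if not core:
        raise NameParseError(f"empty core element in name: {name!r}")
    return ParsedName(elementary, operation, core, prop, data_type)


def compose_concept_name(parsed: ParsedName) -> str:
    """Render a :class:`ParsedName` back to its string form.

    Inverse of :func:`parse_concept_name`: segments are joined with single
    spaces in the fixed order elementary domain, operation domain, core
    element, property, data-type literal.
    """
    if parsed.data_type is None:  # defensive; dataclass forbids it
        raise NameParseError("missing data type")
    parts = [_ELEMENTARY_RENDER[parsed.elementary_domain]]
    if parsed.operation_domain is not None:
        parts.append(parsed.operation_domain.value)
    parts.append(parsed.core_element)
    if parsed.property is not None:
        parts.append(parsed.property)
    parts.append(parsed.data_type.literal)
    return " ".join(parts)
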