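"""Exception hierarchy.

All package errors derive from :class:`ModcoError` so callers can catch
broadly; the CLI maps them onto exit code 2 (usage/format problems).
Validation *failures* are never exceptions — they are report entries.
"""

from __future__ import annotations


class ModcoError(Exception):
    """Base class for all package-specific errors."""


class ManifestParseError(ModcoError):
    """A manifest document is malformed or misses required fields."""


class ManifestReferenceError(ModcoError):
    """A manifest cross-reference (collection, value, parent) dangles."""


class ManifestInvariantError(ModcoError):
    """A structurally loadable manifest breaks a schema invariant."""


class NameParseError(ModcoError):
    """A concept name does not follow the multipartite naming convention."""


class RecordFormatError(ModcoError):
    """A record table breaks the documented layout (e.g. duplicate ids)."""


class RecordReferenceError(ModcoError):
    """A record refers to a concept or value absent from the manifest."""


class GraphCycleError(ModcoError):
    """Unit links form a cycle; provenance must be a DAG."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("provenance cycle: " + " -> ".join(cycle + cycle[:1]))


class GraphReferenceError(ModcoError):
    """A preceding/subsequent/origin id does not resolve in the record set."""


class MappingError(ModcoError):
    """A mapping table is inconsistent or references unknown entities."""


class GeneratorSpecError(ModcoError):
    """A synthetic-manifest specification is internally inconsistent."""


class DialectError(ModcoError):
    """An XML document violates the package's SDD dialect."""
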