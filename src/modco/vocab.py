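"""Closed vocabularies shared across the package.

The schema distinguishes units (the things records describe) along two
orthogonal axes: the *elementary domain* — whether the unit is a physical
object (sample, extract, amplicon) or a digital one (measurement data,
sequence file, document) — and the *operation domain* — which of the three
elementary operations produced or affected it:

* ``transformation`` — an invasive change of an object (subsampling,
  extraction, chemical reaction) or of a data format;
* ``measurement`` — a non-invasive analysis yielding values or data,
  including analysis of existing data;
* ``transaction`` — movement, transfer or deposition of an object or of
  data (e.g. shipping a sample, archiving a file).

Concepts (descriptors) carry one of five data types; four of them have a
distinct rendering literal used as the final segment of a concept name.
``TEXT`` and ``SEQUENCE`` both render ``<string>`` and are told apart by
explicit metadata, never by the literal.
"""

from __future__ import annotations

import enum


class ElementaryDomain(str, enum.Enum):
    """Whether a unit is a physical object or a digital one."""

    PHYSICAL = "physical"
    DIGITAL = "digital"


class OperationDomain(str, enum.Enum):
    """The three elementary operations of a workflow segment."""

    TRANSFORMATION = "transformation"
    MEASUREMENT = "measurement"
    TRANSACTION = "transaction"


class DataTypeToken(str, enum.Enum):
    """Concept data types with their name-final rendering literals."""

    TEXT = "text"
    CATEGORICAL = "categorical"
    QUANTITATIVE = "quantitative"
    SEQUENCE = "sequence"
    CATEGORICAL_PLUS_TEXT = "categorical_text"

    @property
    def literal(self) -> str:
        return _LITERALS[self]


_LITERALS: dict[DataTypeToken, str] = {
    DataTypeToken.TEXT: "<string>",
    DataTypeToken.CATEGORICAL: "<category>",
    DataTypeToken.QUANTITATIVE: "<value>",
    DataTypeToken.SEQUENCE: "<string>",
    DataTypeToken.CATEGORICAL_PLUS_TEXT: "<category> <string>",
}

#: Longest-first literal match order; "<category> <string>" must be tried
#: before "<string>" (greedy match).
LITERAL_MATCH_ORDER: tuple[tuple[str, DataTypeToken], ...] = (
    ("<category> <string>", DataTypeToken.CATEGORICAL_PLUS_TEXT),
    ("<category>", DataTypeToken.CATEGORICAL),
    ("<value>", DataTypeToken.QUANTITATIVE),
    ("<string>", DataTypeToken.TEXT),
)

#: Label of the supplementary fallback state every categorical vocabulary
#: may carry; assignments to it pair with the original wording as free text.
OTHER_VALUE_LABEL = "other value"

class MatchType(str, enum.Enum):
    """SKOS mapping property used to type a concept correspondence."""

    EXACT = "exact"
    CLOSE = "close"
    BROAD = "broad"
    NARROW = "narrow"
    RELATED = "related"


#: IUPAC nucleotide codes (incl. ambiguity codes and gap).
IUPAC_NUCLEOTIDE = frozenset("ACGTURYSWKMBDHVN-")
#: IUPAC amino-acid one-letter codes (incl. ambiguity, rare residues, stop, gap).
IUPAC_AMINO_ACID = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")
#: Default alphabet for sequence payload validation (case-insensitive union).
SEQUENCE_ALPHABET = IUPAC_NUCLEOTIDE | IUPAC_AMINO_ACID
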