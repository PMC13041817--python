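"""Domain types for interaction reconciliation.

The reconciliation engine compares *new* interactions (typically extracted
from literature by NLP systems or LLMs and converted to a BioRECIPE-style
table) against a curated *baseline* network of directed, signed, attributed
edges.  This module holds the in-memory representation of elements and
interactions plus the normalization rules that make them comparable:

* element identity = (normalized identifier, element type); identifiers are
  lower-cased and trimmed, and may come from a database ID, a gene symbol,
  or a free-text name (in that order of precedence);
* interaction sign is mapped onto {positive, negative} from a small, editable
  vocabulary of dialect variants ("activation", "+", "increase", ...);
* connection type is direct or indirect, defaulting to indirect when the
  input leaves it blank;
* provenance metadata (paper IDs, evidence statements, reader scores) is
  carried through untouched and never takes part in any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

__all__ = [
    "Element",
    "Interaction",
    "InteractionList",
    "SIGN_VOCABULARY",
    "CONNECTION_VOCABULARY",
    "POSITIVE",
    "NEGATIVE",
    "DIRECT",
    "INDIRECT",
    "normalize_identifier",
    "normalize_sign",
    "normalize_connection",
]

POSITIVE = "positive"
NEGATIVE = "negative"
DIRECT = "direct"
INDIRECT = "indirect"

#: Editable sign vocabulary: raw (lower-cased) value -> canonical sign.
#: Unknown values are row errors at parse time, never guessed.
SIGN_VOCABULARY: dict[str, str] = {
    "positive": POSITIVE,
    "activation": POSITIVE,
    "activate": POSITIVE,
    "activates": POSITIVE,
    "increase": POSITIVE,
    "increases": POSITIVE,
    "up": POSITIVE,
    "upregulation": POSITIVE,
    "+": POSITIVE,
    "pos": POSITIVE,
    "negative": NEGATIVE,
    "inhibition": NEGATIVE,
    "inhibit": NEGATIVE,
    "inhibits": NEGATIVE,
    "decrease": NEGATIVE,
    "decreases": NEGATIVE,
    "down": NEGATIVE,
    "downregulation": NEGATIVE,
    "repression": NEGATIVE,
    "-": NEGATIVE,
    "−": NEGATIVE,  # unicode minus
    "neg": NEGATIVE,
}

#: Connection-type vocabulary: raw value -> direct/indirect.  BioRECIPE
#: converters in the wild emit either the words or booleans.
CONNECTION_VOCABULARY: dict[str, str] = {
    "direct": DIRECT,
    "true": DIRECT,
    "t": DIRECT,
    "yes": DIRECT,
    "1": DIRECT,
    "indirect": INDIRECT,
    "false": INDIRECT,
    "f": INDIRECT,
    "no": INDIRECT,
    "0": INDIRECT,
}


def normalize_identifier(value: str) -> str:
    """Lower-case and trim an identifier string (idempotent)."""
    return value.strip().lower()


def normalize_sign(value: str) -> str:
    """Map a dialect sign value onto {positive, negative}.

    Raises ``ValueError`` for values absent from :data:`SIGN_VOCABULARY`.
    """
    key = value.strip().lower()
    try:
        return SIGN_VOCABULARY[key]
    except KeyError:
        raise ValueError(f"unmappable sign value: {value!r}") from None


def normalize_connection(value: Optional[str]) -> str:
    """Map a connection-type value onto {direct, indirect}.

    Blank/None defaults to indirect (conservative: avoids the stricter
    direct-only decision branches on unannotated rows).
    """
    if value is None or not value.strip():
        return INDIRECT
    key = value.strip().lower()
    try:
        return CONNECTION_VOCABULARY[key]
    except KeyError:
        raise ValueError(f"unmappable connection value: {value!r}") from None


@dataclass(frozen=True)
class Element:
    """A biological entity with a normalized identity.

    Identity is the pair (identifier, element_type); two elements match iff
    both components are equal after normalization.  ``id_source`` records
    which input column supplied the identifier (database ID beats symbol
    beats name when several are populated).
    """

    name: str
    identifier: str
    element_type: str = "other"
    id_source: str = "name"  # database_id | symbol | name
    compartment: str = ""
    compartment_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "identifier", normalize_identifier(self.identifier))
        etype = self.element_type.strip().lower() or "other"
        object.__setattr__(self, "element_type", etype)
        if not self.identifier:
            raise ValueError("element identifier is empty after normalization")

    @property
    def key(self) -> tuple[str, str]:
        """Identity key used for node lookup and element matching."""
        return (self.identifier, self.element_type)


@dataclass
class Interaction:
    """A directed, signed relation between two elements.

    ``connection`` distinguishes single-step mechanistic regulation (direct)
    from regulation mediated through unstated intermediates (indirect).
    Contextual attributes (mechanism, cell_line, cell_type, tissue, organism,
    context_other) are *non-essential*: whether they take part in mismatch
    detection is decided by the attribute-inclusion strategy.  ``provenance``
    is carried but never compared.  ``index`` is the 0-based row position in
    the originating table (used for deterministic tie-breaking and coverage
    book-keeping).
    """

    source: Element
    target: Element
    sign: str = POSITIVE
    connection: str = INDIRECT
    mechanism: str = ""
    cell_line: str = ""
    cell_type: str = ""
    tissue: str = ""
    organism: str = ""
    context_other: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    index: int = -1

    def __post_init__(self) -> None:
        if self.sign not in (POSITIVE, NEGATIVE):
            self.sign = normalize_sign(self.sign)
        if self.connection not in (DIRECT, INDIRECT):
            self.connection = normalize_connection(self.connection)

    @property
    def endpoint_keys(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.source.key, self.target.key)

    @property
    def dedup_key(self) -> tuple:
        """Uniqueness key: endpoints, sign and connection type."""
        return (self.source.key, self.target.key, self.sign, self.connection)

    def describe(self) -> str:
        arrow = "->" if self.sign == POSITIVE else "-|"
        return f"{self.source.name} {arrow} {self.target.name} ({self.connection})"


@dataclass
class InteractionList:
    """An ordered list of interactions, as read from one input table.

    Row order is preserved and duplicates are retained; ``row_errors`` holds
    (row_number, message) pairs for rows rejected during parsing when the
    reader runs in non-strict mode.
    """

    interactions: list[Interaction] = field(default_factory=list)
    source_label: str = ""
    row_errors: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self) -> Iterator[Interaction]:
        return iter(self.interactions)

    def __getitem__(self, i: int) -> Interaction:
        return self.interactions[i]
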