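"""Formal match conditions and attribute-mismatch detection.

Two elements match iff they share the same normalized identifier and the
same element type.  The necessary interaction match additionally requires
equal sign with element-matched endpoints; a sign conflict between matched
endpoints is a contradiction, not a non-match.

Non-essential attributes (compartment, mechanism, cell line, cell type,
tissue, organism, other context) enter mismatch detection only when the
selected attribute-inclusion strategy lists them.  The canonical strategies
are nested:

    CA0 = {}                          (structure only)
    CA1 = {compartment}
    CA2 = CA1 + {mechanism}
    CA3 = CA2 + {cell_line}
    CA4 = CA3 + {cell_type, tissue, organism, context_other}

A pair of attribute values with at least one empty side never counts as a
mismatch, and provenance fields never take part at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import Element, Interaction
from .graph import Path

__all__ = [
    "AttributeStrategy",
    "MismatchSet",
    "NON_ESSENTIAL_ATTRIBUTES",
    "element_match",
    "attribute_mismatches",
    "match_against_path",
]

NON_ESSENTIAL_ATTRIBUTES = (
    "compartment",
    "mechanism",
    "cell_line",
    "cell_type",
    "tissue",
    "organism",
    "context_other",
)

_PROVENANCE_NAMES = frozenset({"provenance", "score", "paper_ids", "evidence", "source_db"})

_CA_SETS: dict[str, tuple[str, ...]] = {
    "CA0": (),
    "CA1": ("compartment",),
    "CA2": ("compartment", "mechanism"),
    "CA3": ("compartment", "mechanism", "cell_line"),
    "CA4": NON_ESSENTIAL_ATTRIBUTES,
}


@dataclass(frozen=True)
class AttributeStrategy:
    """Which non-essential attributes participate in mismatch detection."""

    name: str
    included: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.included) & _PROVENANCE_NAMES
        if bad:
            raise ValueError(f"provenance fields can never be compared: {sorted(bad)}")
        unknown = set(self.included) - set(NON_ESSENTIAL_ATTRIBUTES)
        if unknown:
            raise ValueError(f"unknown attribute name(s): {sorted(unknown)}")

    @classmethod
    def from_name(cls, name: str) -> "AttributeStrategy":
        """Parse ``CA0``..``CA4`` or ``custom:name1,name2``."""
        key = name.strip()
        upper = key.upper()
        if upper in _CA_SETS:
            return cls(name=upper, included=_CA_SETS[upper])
        if key.lower().startswith("custom:"):
            names = tuple(
                n.strip().lower() for n in key.split(":", 1)[1].split(",") if n.strip()
            )
            return cls(name="custom", included=names)
        raise ValueError(f"unknown attribute strategy: {name!r}")

    def includes(self, attr: str) -> bool:
        return attr in self.included


for _name, _attrs in _CA_SETS.items():
    setattr(AttributeStrategy, _name, AttributeStrategy(name=_name, included=_attrs))


@dataclass
class MismatchSet:
    """What disagrees between a new interaction and a baseline edge or path.

    ``attr_names`` only ever contains attributes from the active strategy's
    included set, and never an attribute where either side was empty.
    ``connection_differs`` (direct vs indirect) is tracked separately: it is
    not a conflict but feeds the indirect-corroboration subtype.
    """

    has_sign: bool = False
    has_direction: bool = False
    attr_names: frozenset[str] = frozenset()
    connection_differs: bool = False

    @property
    def is_conflict_free(self) -> bool:
        """No sign, direction or attribute conflicts (connection may differ)."""
        return not (self.has_sign or self.has_direction or self.attr_names)

    @property
    def weight(self) -> tuple[int, int, int]:
        """Ordering key for best-edge selection: sign heaviest, then attribute
        count, then connection disagreement."""
        return (int(self.has_sign), len(self.attr_names), int(self.connection_differs))

    def beyond_direction(self) -> bool:
        """True if anything besides the direction flag mismatches (connection
        type excluded: an indirect report of a direct edge is not a conflict)."""
        return self.has_sign or bool(self.attr_names)

    def describe(self) -> str:
        parts: list[str] = []
        if self.has_sign:
            parts.append("sign")
        if self.has_direction:
            parts.append("direction")
        parts.extend(sorted(self.attr_names))
        if self.connection_differs:
            parts.append("connection")
        return ";".join(parts)


def element_match(a: Element, b: Element) -> bool:
    """True iff normalized identifiers and element types are both equal."""
    return a.identifier == b.identifier and a.element_type == b.element_type


def _pair_mismatch(a: str, b: str) -> bool:
    """Both sides non-empty and unequal (the empty-exclusion rule)."""
    return bool(a) and bool(b) and a != b


def _context_mismatch(a: dict[str, str], b: dict[str, str]) -> bool:
    """Key-by-key comparison; keys present on only one side are ignored."""
    return any(_pair_mismatch(a[k], b[k]) for k in a.keys() & b.keys())


def attribute_mismatches(
    new: Interaction,
    base: Interaction,
    strategy: AttributeStrategy,
    reversed_edge: bool = False,
) -> MismatchSet:
    """Compare a new interaction against one baseline edge.

    Compartments are compared per matched endpoint: source-vs-source and
    target-vs-target, or crosswise when ``reversed_edge`` pairs the new
    interaction with a baseline edge running target -> source.  The direction
    flag for reversed pairings is likewise set here.  Provenance is never
    inspected.
    """
    attrs: set[str] = set()
    if strategy.includes("compartment"):
        if reversed_edge:
            pairs = ((new.source, base.target), (new.target, base.source))
        else:
            pairs = ((new.source, base.source), (new.target, base.target))
        if any(_pair_mismatch(a.compartment, b.compartment) for a, b in pairs):
            attrs.add("compartment")
    for attr in ("mechanism", "cell_line", "cell_type", "tissue", "organism"):
        if strategy.includes(attr) and _pair_mismatch(getattr(new, attr), getattr(base, attr)):
            attrs.add(attr)
    if strategy.includes("context_other") and _context_mismatch(
        new.context_other, base.context_other
    ):
        attrs.add("context_other")
    return MismatchSet(
        has_sign=new.sign != base.sign,
        has_direction=reversed_edge,
        attr_names=frozenset(attrs),
        connection_differs=new.connection != base.connection,
    )


def match_against_path(
    new: Interaction,
    path: Path,
    strategy: AttributeStrategy,
    sign_mode: str = "net",
    reversed_path: bool = False,
) -> MismatchSet:
    """Compare a new interaction against a baseline path of >= 2 edges.

    Sign: under the default ``net`` mode the path's multiplicative net sign
    must equal the new sign; under ``strict`` mode every edge must share it.
    Scalar contextual attributes are aggregated as the union of per-edge
    conflicts (empty sides excluded per edge).  Compartments are compared at
    the path termini only — the new source against the path's start element
    and the new target against its end element, crosswise for a reversed
    path — since intermediate nodes have no counterpart on the new
    interaction.
    """
    if path.length < 2:
        raise ValueError("path matches require at least two edges")
    if sign_mode == "net":
        has_sign = new.sign != path.net_sign
    elif sign_mode == "strict":
        has_sign = any(e.sign != new.sign for e in path.edges)
    else:
        raise ValueError(f"unknown sign_mode: {sign_mode!r}")
    attrs: set[str] = set()
    if strategy.includes("compartment"):
        start, end = path.edges[0].source, path.edges[-1].target
        if reversed_path:
            pairs = ((new.source, end), (new.target, start))
        else:
            pairs = ((new.source, start), (new.target, end))
        if any(_pair_mismatch(a.compartment, b.compartment) for a, b in pairs):
            attrs.add("compartment")
    for attr in ("mechanism", "cell_line", "cell_type", "tissue", "organism"):
        if strategy.includes(attr):
            value = getattr(new, attr)
            if any(_pair_mismatch(value, getattr(e, attr)) for e in path.edges):
                attrs.add(attr)
    if strategy.includes("context_other"):
        if any(_context_mismatch(new.context_other, e.context_other) for e in path.edges):
            attrs.add("context_other")
    return MismatchSet(
        has_sign=has_sign,
        has_direction=reversed_path,
        attr_names=frozenset(attrs),
        connection_differs=False,
    )
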