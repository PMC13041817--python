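"""The reconciliation decision tree.

Every new interaction receives exactly one category and one subcategory
relative to the baseline graph:

* **corroboration** — consistent with a baseline edge (strong /
  specification / weak_missing / indirect) or with a baseline path (path);
* **contradiction** — matched elements but a sign, direction, attribute or
  path-level conflict;
* **flagged** — an ambiguous comparison deferred to manual inspection
  (direction-only reversal, mismatched path alignment, or a direct claim
  with no supporting edge under scheme CS2);
* **extension** — absent from the baseline: full (no shared nodes), hanging
  (one shared node) or internal (both nodes known, no edge).

Three classification schemes reinterpret the ambiguous branches:

* **CS1** (default): direction-only reversals and mismatched path
  alignments are flagged; direct claims that merely align with a path are
  extensions.
* **CS2**: mismatched path alignments become contradictions, and direct
  claims with no direct baseline edge are flagged as potential reader
  errors.
* **CS3**: inverts CS1's reversed-edge handling — a pure direction reversal
  is a contradiction, while a reversal with additional mismatches is
  flagged (it may be valid in another context); otherwise follows CS1.

The decision order is deterministic: node membership, then forward edge,
then reversed edge, then forward/reversed path, then no-connection.
Self-loops use only the membership and forward-edge steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .graph import BaselineGraph, Path, find_edges, shortest_paths
from .matching import AttributeStrategy, MismatchSet, attribute_mismatches, match_against_path
from .model import DIRECT, INDIRECT, Interaction, InteractionList

__all__ = [
    "ReconcilerConfig",
    "ClassifiedInteraction",
    "classify",
    "classify_all",
    "CATEGORIES",
    "SUBCATEGORIES",
]

CATEGORIES = ("corroboration", "contradiction", "flagged", "extension")
SUBCATEGORIES = {
    "corroboration": ("strong", "specification", "weak_missing", "indirect", "path"),
    "contradiction": ("sign", "direction", "attribute", "path"),
    "extension": ("full", "hanging", "internal"),
    "flagged": ("direction", "path_mismatch", "direct_no_edge"),
}


@dataclass(frozen=True)
class ReconcilerConfig:
    """Scheme, attribute strategy and path-search limits for one run."""

    scheme: str = "CS1"
    strategy: AttributeStrategy = AttributeStrategy.CA1
    max_path_len: int = 6
    max_paths: int = 10
    sign_mode: str = "net"  # net-sign parity vs strict per-edge agreement
    # CS2 flags *any* direct claim lacking a direct baseline edge between
    # known nodes; set False to restrict the flag to path-aligned claims only.
    cs2_flag_unconnected_direct: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("CS1", "CS2", "CS3"):
            raise ValueError(f"unknown scheme: {self.scheme!r}")


@dataclass
class ClassifiedInteraction:
    """A new interaction plus its category, subcategory, the baseline edge or
    path it was compared against, and the mismatch set that drove the call."""

    interaction: Interaction
    category: str
    subcategory: str
    matched: Optional[Union[Interaction, Path]] = None
    mismatches: Optional[MismatchSet] = None

    def describe_matched(self) -> str:
        if self.matched is None:
            return ""
        if isinstance(self.matched, Path):
            return "path " + self.matched.describe()
        m = self.matched
        return f"edge[{m.index}] {m.describe()}"


def _fill_slots(new: Interaction, base: Interaction, strategy: AttributeStrategy):
    """(new_value, base_value) pairs for every compared attribute slot."""
    slots: list[tuple[str, str]] = []
    if strategy.includes("compartment"):
        slots.append((new.source.compartment, base.source.compartment))
        slots.append((new.target.compartment, base.target.compartment))
    for attr in ("mechanism", "cell_line", "cell_type", "tissue", "organism"):
        if strategy.includes(attr):
            slots.append((getattr(new, attr), getattr(base, attr)))
    if strategy.includes("context_other"):
        for key in sorted(new.context_other.keys() | base.context_other.keys()):
            slots.append((new.context_other.get(key, ""), base.context_other.get(key, "")))
    return slots


def _corroboration_subtype(new: Interaction, base: Interaction, m: MismatchSet,
                           strategy: AttributeStrategy) -> str:
    """Subtype precedence: indirect (connection differs), then strong, then
    specification, then weak_missing."""
    if m.connection_differs:
        return "indirect"
    slots = _fill_slots(new, base, strategy)
    if all(a and b for a, b in slots):
        return "strong"
    new_only = any(a and not b for a, b in slots)
    base_only = any(b and not a for a, b in slots)
    if new_only and not base_only:
        return "specification"
    return "weak_missing"


def _best_edge(new: Interaction, edges: Sequence[Interaction],
               strategy: AttributeStrategy, reversed_edge: bool = False):
    """The parallel edge with the fewest mismatches (sign heaviest, then
    attribute count); ties broken by baseline input order."""
    best = None
    best_m = None
    for edge in edges:  # edges arrive in baseline input order
        m = attribute_mismatches(new, edge, strategy, reversed_edge=reversed_edge)
        if best_m is None or m.weight < best_m.weight:
            best, best_m = edge, m
    return best, best_m


def _best_path(new: Interaction, paths: Sequence[Path], cfg: ReconcilerConfig,
               reversed_path: bool = False):
    """First fully consistent path if any; otherwise the enumerated path with
    the fewest mismatches (search order is already deterministic)."""
    best = None
    best_m = None
    for path in paths:
        m = match_against_path(new, path, cfg.strategy, sign_mode=cfg.sign_mode,
                               reversed_path=reversed_path)
        if m.is_conflict_free:
            return path, m
        if best_m is None or m.weight < best_m.weight:
            best, best_m = path, m
    return best, best_m


def classify(new: Interaction, g: BaselineGraph, cfg: ReconcilerConfig) -> ClassifiedInteraction:
    """Assign a category and subcategory to one new interaction."""
    scheme = cfg.scheme
    s_in = g.has_element(new.source)
    t_in = g.has_element(new.target)

    # (1) node membership
    if not s_in and not t_in:
        return ClassifiedInteraction(new, "extension", "full")
    if s_in != t_in:
        return ClassifiedInteraction(new, "extension", "hanging")

    self_loop = new.source.key == new.target.key

    # (2) forward edge
    forward = find_edges(g, new.source, new.target)
    if forward:
        edge, m = _best_edge(new, forward, cfg.strategy)
        if m.has_sign:
            return ClassifiedInteraction(new, "contradiction", "sign", edge, m)
        if m.attr_names:
            return ClassifiedInteraction(new, "contradiction", "attribute", edge, m)
        sub = _corroboration_subtype(new, edge, m, cfg.strategy)
        return ClassifiedInteraction(new, "corroboration", sub, edge, m)

    if self_loop:
        # no matching self-edge: an unrepresented relation between known nodes
        return ClassifiedInteraction(new, "extension", "internal")

    # (3) reversed edge
    reverse = find_edges(g, new.target, new.source)
    if reverse:
        edge, m = _best_edge(new, reverse, cfg.strategy, reversed_edge=True)
        direction_only = not m.beyond_direction()
        if scheme in ("CS1", "CS2"):
            category = "flagged" if direction_only else "contradiction"
        else:  # CS3 inverts the interpretation
            category = "contradiction" if direction_only else "flagged"
        return ClassifiedInteraction(new, category, "direction", edge, m)

    # (4) path alignment: forward first, then reversed
    paths = shortest_paths(g, new.source, new.target, cfg.max_path_len, cfg.max_paths)
    reversed_path = False
    if not paths:
        paths = shortest_paths(g, new.target, new.source, cfg.max_path_len, cfg.max_paths)
        reversed_path = bool(paths)
    if paths:
        if new.connection == INDIRECT:
            path, m = _best_path(new, paths, cfg, reversed_path=reversed_path)
            if m.is_conflict_free:
                return ClassifiedInteraction(new, "corroboration", "path", path, m)
            if scheme == "CS2":
                return ClassifiedInteraction(new, "contradiction", "path", path, m)
            return ClassifiedInteraction(new, "flagged", "path_mismatch", path, m)
        # direct claim that only aligns with a multi-edge path
        if scheme == "CS2":
            return ClassifiedInteraction(new, "flagged", "direct_no_edge", paths[0])
        return ClassifiedInteraction(new, "extension", "internal", paths[0])

    # (5) both nodes known, no edge, no path either way
    if new.connection == DIRECT and scheme == "CS2" and cfg.cs2_flag_unconnected_direct:
        return ClassifiedInteraction(new, "flagged", "direct_no_edge")
    return ClassifiedInteraction(new, "extension", "internal")


def classify_all(
    lst: InteractionList, g: BaselineGraph, cfg: ReconcilerConfig
) -> list[ClassifiedInteraction]:
    """Classify every interaction independently, preserving input order."""
    return [classify(it, g, cfg) for it in lst]
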