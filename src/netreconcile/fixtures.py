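"""Synthetic benchmark fixtures with planted ground truth, plus an
independent brute-force classifier.

The generator builds a random signed background graph (directed
Erdős–Rényi, activation-heavy by default) and then *plants* new
interactions by controlled perturbation of dedicated sub-structures, one
knob per decision-tree leaf: exact copies (strong corroborations), sign
flips, endpoint swaps, attribute edits, two-hop shortcuts, fresh node
pairs, and so on.  Because every plant owns its nodes, its expected
category and subcategory under every scheme × attribute-strategy
combination is known at generation time and recorded in a truth table —
the generator is itself an oracle for the classifier.

:func:`brute_force_classify` is a second, independent oracle: the same
classification contract implemented by exhaustive scanning of all baseline
rows and exhaustive DFS enumeration of all simple paths, sharing no code
with the production classifier.  It refuses graphs with more than 12 nodes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path as FsPath
from typing import Optional, Sequence

import pandas as pd

from .classify import ClassifiedInteraction, ReconcilerConfig
from .graph import BaselineGraph, Path
from .io import interactions_to_frame, write_interactions
from .matching import MismatchSet
from .model import DIRECT, INDIRECT, NEGATIVE, POSITIVE, Element, Interaction, InteractionList

__all__ = [
    "FixtureSpec",
    "FixtureResult",
    "GenerationError",
    "PLANT_LEAVES",
    "generate",
    "brute_force_classify",
    "score_against_truth",
]

SCHEMES = ("CS1", "CS2", "CS3")
STRATEGY_NAMES = ("CA0", "CA1", "CA2", "CA3", "CA4")

_COMPARTMENTS = ("cytoplasm", "nucleus", "membrane", "extracellular")
_MECHANISMS = ("phosphorylation", "ubiquitination", "binding", "transcription")
_CELL_LINES = ("hela", "mcf7", "a549")


class GenerationError(ValueError):
    """A planted leaf cannot be generated under the given spec."""


@dataclass
class FixtureSpec:
    """Parameters of one synthetic benchmark fixture.

    Identical seed + spec always produce byte-identical fixture files.
    ``planted`` maps leaf names (see :data:`PLANT_LEAVES`) to how many new
    interactions of that kind to plant.
    """

    seed: int = 0
    n_nodes: int = 30
    n_edges: int = 60
    positive_ratio: float = 0.8
    attribute_fill_rate: float = 0.7
    duplicate_rate: float = 0.0
    planted: dict[str, int] = dc_field(default_factory=lambda: {leaf: 1 for leaf in PLANT_LEAVES})


@dataclass
class FixtureResult:
    baseline: InteractionList
    new_list: InteractionList
    truth: pd.DataFrame
    files: dict[str, FsPath] = dc_field(default_factory=dict)


def _element(name: str, compartment: str = "", etype: str = "protein") -> Element:
    return Element(name=name, identifier=name, element_type=etype, compartment=compartment)


def _full_attrs() -> dict:
    return dict(
        mechanism="phosphorylation",
        cell_line="hela",
        cell_type="epithelial",
        tissue="liver",
        organism="human",
        context_other={"disease": "cancer"},
    )


def _copy(it: Interaction, **overrides) -> Interaction:
    base = dict(
        source=it.source, target=it.target, sign=it.sign, connection=it.connection,
        mechanism=it.mechanism, cell_line=it.cell_line, cell_type=it.cell_type,
        tissue=it.tissue, organism=it.organism,
        context_other=dict(it.context_other), provenance=dict(it.provenance),
    )
    base.update(overrides)
    return Interaction(**base)


Labels = dict[tuple[str, str], str]


def _uniform(label: str) -> Labels:
    return {(cs, ca): label for cs in SCHEMES for ca in STRATEGY_NAMES}


def _by_scheme(cs1: str, cs2: str, cs3: str) -> Labels:
    return {(cs, ca): {"CS1": cs1, "CS2": cs2, "CS3": cs3}[cs]
            for cs in SCHEMES for ca in STRATEGY_NAMES}


class _Planter:
    """Builds one plant per call; owns the fresh-node namer and accumulates
    baseline rows, new interactions and their expected labels."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.counter = 0
        self.baseline_rows: list[Interaction] = []
        self.new_rows: list[tuple[str, Interaction, Labels]] = []

    def fresh(self, compartment: str = "") -> Element:
        self.counter += 1
        return _element(f"px{self.counter:04d}", compartment)

    def base_edge(self, source: Element, target: Element, sign: str = POSITIVE,
                  connection: str = DIRECT, **attrs) -> Interaction:
        edge = Interaction(source=source, target=target, sign=sign, connection=connection, **attrs)
        self.baseline_rows.append(edge)
        return edge

    def plant(self, leaf: str, new: Interaction, labels: Labels) -> None:
        self.new_rows.append((leaf, new, labels))

    # -- one method per decision-tree leaf ----------------------------

    def strong(self) -> None:
        a, b = self.fresh("cytoplasm"), self.fresh("nucleus")
        edge = self.base_edge(a, b, **_full_attrs())
        self.plant("strong", _copy(edge), _uniform("corroboration:strong"))

    def weak_missing(self) -> None:
        a, b = self.fresh(), self.fresh()
        edge = self.base_edge(a, b)
        labels = _uniform("corroboration:weak_missing")
        labels.update({(cs, "CA0"): "corroboration:strong" for cs in SCHEMES})
        self.plant("weak_missing", _copy(edge), labels)

    def specification(self) -> None:
        a, b = self.fresh("cytoplasm"), self.fresh("nucleus")
        edge = self.base_edge(a, b, mechanism="phosphorylation")
        new = _copy(edge, cell_line="hela")
        labels = _uniform("corroboration:strong")
        labels.update({(cs, ca): "corroboration:specification"
                       for cs in SCHEMES for ca in ("CA3", "CA4")})
        self.plant("specification", new, labels)

    def indirect(self) -> None:
        a, b = self.fresh("cytoplasm"), self.fresh("nucleus")
        edge = self.base_edge(a, b, **_full_attrs())
        self.plant("indirect", _copy(edge, connection=INDIRECT),
                   _uniform("corroboration:indirect"))

    def sign(self) -> None:
        a, b = self.fresh("cytoplasm"), self.fresh("nucleus")
        edge = self.base_edge(a, b, **_full_attrs())
        self.plant("sign", _copy(edge, sign=NEGATIVE), _uniform("contradiction:sign"))

    def attribute_compartment(self) -> None:
        a, b = self.fresh("cytoplasm"), self.fresh("nucleus")
        edge = self.base_edge(a, b, **_full_attrs())
        moved = Element(name=a.name, identifier=a.identifier,
                        element_type=a.element_type, compartment="membrane")
        labels = _uniform("contradiction:attribute")
        labels.update({(cs, "CA0"): "corroboration:strong" for cs in SCHEMES})
        self.plant("attribute_compartment", _copy(edge, source=moved), labels)

    def attribute_cellline(self) -> None:
        a, b = self.fresh("cytoplasm"), self.fresh("nucleus")
        edge = self.base_edge(a, b, **_full_attrs())
        labels = _uniform("corroboration:strong")
        labels.update({(cs, ca): "contradiction:attribute"
                       for cs in SCHEMES for ca in ("CA3", "CA4")})
        self.plant("attribute_cellline", _copy(edge, cell_line="mcf7"), labels)

    def direction(self) -> None:
        a, b = self.fresh("cytoplasm"), self.fresh("nucleus")
        edge = self.base_edge(a, b, **_full_attrs())
        new = _copy(edge, source=b, target=a)  # swap: compartments pair crosswise
        self.plant("direction", new,
                   _by_scheme("flagged:direction", "flagged:direction",
                              "contradiction:direction"))

    def direction_attr(self) -> None:
        a, b = self.fresh("cytoplasm"), self.fresh("nucleus")
        edge = self.base_edge(a, b, **_full_attrs())
        moved = Element(name=b.name, identifier=b.identifier,
                        element_type=b.element_type, compartment="membrane")
        new = _copy(edge, source=moved, target=a)
        labels = _by_scheme("contradiction:direction", "contradiction:direction",
                            "flagged:direction")
        labels.update({(cs, "CA0"): {"CS1": "flagged:direction", "CS2": "flagged:direction",
                                     "CS3": "contradiction:direction"}[cs] for cs in SCHEMES})
        self.plant("direction_attr", new, labels)

    def _chain(self, signs=(POSITIVE, POSITIVE)) -> tuple[Element, Element]:
        nodes = [self.fresh() for _ in range(len(signs) + 1)]
        for (u, v), s in zip(zip(nodes, nodes[1:]), signs):
            self.base_edge(u, v, sign=s)
        return nodes[0], nodes[-1]

    def path(self) -> None:
        start, end = self._chain()
        new = Interaction(source=start, target=end, sign=POSITIVE, connection=INDIRECT)
        self.plant("path", new, _uniform("corroboration:path"))

    def path_mismatch(self) -> None:
        start, end = self._chain()
        new = Interaction(source=start, target=end, sign=NEGATIVE, connection=INDIRECT)
        self.plant("path_mismatch", new,
                   _by_scheme("flagged:path_mismatch", "contradiction:path",
                              "flagged:path_mismatch"))

    def path_reversed(self) -> None:
        start, end = self._chain()
        new = Interaction(source=end, target=start, sign=POSITIVE, connection=INDIRECT)
        self.plant("path_reversed", new,
                   _by_scheme("flagged:path_mismatch", "contradiction:path",
                              "flagged:path_mismatch"))

    def full(self) -> None:
        self.counter += 1
        a = _element(f"zz{self.counter:04d}a")
        b = _element(f"zz{self.counter:04d}b")
        new = Interaction(source=a, target=b, sign=POSITIVE, connection=DIRECT)
        self.plant("full", new, _uniform("extension:full"))

    def hanging(self) -> None:
        a, b = self.fresh(), self.fresh()
        self.base_edge(a, b)
        self.counter += 1
        outsider = _element(f"zz{self.counter:04d}h")
        new = Interaction(source=a, target=outsider, sign=POSITIVE, connection=DIRECT)
        self.plant("hanging", new, _uniform("extension:hanging"))

    def _disconnected_pair(self) -> tuple[Element, Element]:
        # u is a pure sink, v only reaches a fresh sink: no u~>v or v~>u path
        u, v = self.fresh(), self.fresh()
        self.base_edge(self.fresh(), u)
        self.base_edge(v, self.fresh())
        return u, v

    def internal_indirect(self) -> None:
        u, v = self._disconnected_pair()
        new = Interaction(source=u, target=v, sign=POSITIVE, connection=INDIRECT)
        self.plant("internal_indirect", new, _uniform("extension:internal"))

    def internal_direct(self) -> None:
        u, v = self._disconnected_pair()
        new = Interaction(source=u, target=v, sign=POSITIVE, connection=DIRECT)
        self.plant("internal_direct", new,
                   _by_scheme("extension:internal", "flagged:direct_no_edge",
                              "extension:internal"))

    def direct_over_path(self) -> None:
        start, end = self._chain()
        new = Interaction(source=start, target=end, sign=POSITIVE, connection=DIRECT)
        self.plant("direct_over_path", new,
                   _by_scheme("extension:internal", "flagged:direct_no_edge",
                              "extension:internal"))


PLANT_LEAVES = (
    "strong", "weak_missing", "specification", "indirect", "sign",
    "attribute_compartment", "attribute_cellline", "direction", "direction_attr",
    "path", "path_mismatch", "path_reversed", "full", "hanging",
    "internal_indirect", "internal_direct", "direct_over_path",
)


def _background(rng: random.Random, spec: FixtureSpec) -> list[Interaction]:
    """Random directed Erdős–Rényi background, activation-heavy by default.

    Background nodes are named ``bg*`` and never collide with plant nodes, so
    plants keep their guaranteed labels regardless of background topology.
    """
    n = spec.n_nodes
    compartments = {
        i: (rng.choice(_COMPARTMENTS) if rng.random() < spec.attribute_fill_rate else "")
        for i in range(n)
    }
    elements = {i: _element(f"bg{i:04d}", compartments[i]) for i in range(n)}
    possible = n * (n - 1)
    k = min(spec.n_edges, possible)
    pairs = set()
    edges: list[Interaction] = []
    while len(edges) < k:
        i, j = rng.randrange(n), rng.randrange(n)
        if i == j or (i, j) in pairs:
            continue
        pairs.add((i, j))
        fill = spec.attribute_fill_rate
        edges.append(Interaction(
            source=elements[i],
            target=elements[j],
            sign=POSITIVE if rng.random() < spec.positive_ratio else NEGATIVE,
            connection=DIRECT if rng.random() < 0.5 else INDIRECT,
            mechanism=rng.choice(_MECHANISMS) if rng.random() < fill else "",
            cell_line=rng.choice(_CELL_LINES) if rng.random() < fill else "",
        ))
    return edges


def generate(spec: FixtureSpec, out_dir=None) -> FixtureResult:
    """Generate a fixture: baseline list, new list, and the truth table.

    The truth table has one row per new interaction with its planted leaf
    and the expected ``category:subcategory`` label for every scheme ×
    attribute-strategy combination (columns ``cs1_ca0`` ... ``cs3_ca4``).
    """
    for leaf, count in spec.planted.items():
        if leaf not in PLANT_LEAVES:
            raise GenerationError(f"unknown planted leaf: {leaf!r}")
        if count < 0:
            raise GenerationError(f"negative plant count for leaf {leaf!r}")
    if spec.n_nodes < 2 and spec.n_edges > 0:
        raise GenerationError("background edges require at least 2 nodes")

    rng = random.Random(spec.seed)
    baseline_rows = _background(rng, spec)
    planter = _Planter(rng)
    for leaf in PLANT_LEAVES:  # fixed order for determinism
        for _ in range(spec.planted.get(leaf, 0)):
            getattr(planter, leaf)()
    baseline_rows.extend(planter.baseline_rows)

    new_rows = list(planter.new_rows)
    if spec.duplicate_rate > 0 and new_rows:
        n_dup = int(round(spec.duplicate_rate * len(new_rows)))
        for _ in range(n_dup):
            leaf, it, labels = rng.choice(new_rows)
            new_rows.append((leaf + ":dup", _copy(it), dict(labels)))

    for i, it in enumerate(baseline_rows):
        it.index = i
    for i, (_, it, _) in enumerate(new_rows):
        it.index = i

    truth = pd.DataFrame([
        {"row": i, "leaf": leaf,
         **{f"{cs.lower()}_{ca.lower()}": labels[(cs, ca)]
            for cs in SCHEMES for ca in STRATEGY_NAMES}}
        for i, (leaf, _, labels) in enumerate(new_rows)
    ])

    result = FixtureResult(
        baseline=InteractionList(baseline_rows, source_label="fixture:baseline"),
        new_list=InteractionList([it for _, it, _ in new_rows], source_label="fixture:new"),
        truth=truth,
    )
    if out_dir is not None:
        out_dir = FsPath(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "baseline": out_dir / "baseline.tsv",
            "new": out_dir / "new_interactions.tsv",
            "truth": out_dir / "truth.tsv",
        }
        write_interactions(paths["baseline"], result.baseline)
        write_interactions(paths["new"], result.new_list)
        truth.to_csv(paths["truth"], sep="\t", index=False)
        result.files = paths
    return result


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

_BF_SCALARS = {
    "CA0": (),
    "CA1": (),
    "CA2": ("mechanism",),
    "CA3": ("mechanism", "cell_line"),
    "CA4": ("mechanism", "cell_line", "cell_type", "tissue", "organism"),
}


def _bf_strategy_parts(strategy) -> tuple[bool, tuple[str, ...], bool]:
    """(compare compartment?, scalar attrs, compare context?) for a strategy."""
    name = strategy.name
    if name in _BF_SCALARS:
        return (name != "CA0", _BF_SCALARS[name], name == "CA4")
    inc = set(strategy.included)
    scalars = tuple(a for a in ("mechanism", "cell_line", "cell_type", "tissue", "organism")
                    if a in inc)
    return ("compartment" in inc, scalars, "context_other" in inc)


def _bf_conflict(a: str, b: str) -> bool:
    if a == "" or b == "":
        return False
    return a != b


def _bf_edge_mismatch(new: Interaction, base: Interaction, strategy,
                      crosswise: bool) -> tuple[bool, set[str], bool]:
    cmp_comp, scalars, cmp_ctx = _bf_strategy_parts(strategy)
    attrs: set[str] = set()
    if cmp_comp:
        if crosswise:
            bad = (_bf_conflict(new.source.compartment, base.target.compartment)
                   or _bf_conflict(new.target.compartment, base.source.compartment))
        else:
            bad = (_bf_conflict(new.source.compartment, base.source.compartment)
                   or _bf_conflict(new.target.compartment, base.target.compartment))
        if bad:
            attrs.add("compartment")
    for name in scalars:
        if _bf_conflict(getattr(new, name), getattr(base, name)):
            attrs.add(name)
    if cmp_ctx:
        for key in set(new.context_other) & set(base.context_other):
            if _bf_conflict(new.context_other[key], base.context_other[key]):
                attrs.add("context_other")
    return (new.sign != base.sign, attrs, new.connection != base.connection)


def _bf_subtype(new: Interaction, base: Interaction, strategy) -> str:
    cmp_comp, scalars, cmp_ctx = _bf_strategy_parts(strategy)
    pairs: list[tuple[str, str]] = []
    if cmp_comp:
        pairs.append((new.source.compartment, base.source.compartment))
        pairs.append((new.target.compartment, base.target.compartment))
    for name in scalars:
        pairs.append((getattr(new, name), getattr(base, name)))
    if cmp_ctx:
        for key in set(new.context_other) | set(base.context_other):
            pairs.append((new.context_other.get(key, ""), base.context_other.get(key, "")))
    if all(a != "" and b != "" for a, b in pairs):
        return "strong"
    gains = sum(1 for a, b in pairs if a != "" and b == "")
    losses = sum(1 for a, b in pairs if a == "" and b != "")
    if gains >= 1 and losses == 0:
        return "specification"
    return "weak_missing"


def _bf_all_simple_paths(rows: Sequence[Interaction], s_key, t_key, max_len: int):
    """All simple node-key paths s -> t, by exhaustive DFS."""
    adjacency: dict = {}
    for e in rows:
        adjacency.setdefault(e.source.key, set()).add(e.target.key)
    found: list[list] = []

    def walk(node, visited, trail):
        if len(trail) - 1 > max_len:
            return
        if node == t_key:
            found.append(list(trail))
            return
        for nxt in sorted(adjacency.get(node, ())):
            if nxt not in visited:
                visited.add(nxt)
                trail.append(nxt)
                walk(nxt, visited, trail)
                trail.pop()
                visited.remove(nxt)

    walk(s_key, {s_key}, [s_key])
    return found


def brute_force_classify(new: Interaction, g: BaselineGraph,
                         cfg: ReconcilerConfig) -> ClassifiedInteraction:
    """Exhaustive-enumeration reference classifier (graphs of <= 12 nodes).

    Same contract as :func:`netreconcile.classify.classify`, implemented by
    scanning every baseline row and enumerating every simple path, with no
    shared code paths.
    """
    if g.n_nodes > 12:
        raise ValueError("brute-force oracle refuses graphs with more than 12 nodes")
    rows = g.all_edges()
    node_keys = set()
    for e in rows:
        node_keys.add((e.source.identifier, e.source.element_type))
        node_keys.add((e.target.identifier, e.target.element_type))

    s_key = (new.source.identifier, new.source.element_type)
    t_key = (new.target.identifier, new.target.element_type)
    s_in, t_in = s_key in node_keys, t_key in node_keys
    if not s_in and not t_in:
        return ClassifiedInteraction(new, "extension", "full")
    if s_in != t_in:
        return ClassifiedInteraction(new, "extension", "hanging")

    strategy = cfg.strategy

    def pick_best(edges, crosswise):
        best = None
        for e in edges:
            sign_d, attrs, conn_d = _bf_edge_mismatch(new, e, strategy, crosswise)
            rank = (int(sign_d), len(attrs), int(conn_d), e.index)
            if best is None or rank < best[0]:
                best = (rank, e, sign_d, attrs, conn_d)
        return best

    forward = [e for e in rows
               if (e.source.identifier, e.source.element_type) == s_key
               and (e.target.identifier, e.target.element_type) == t_key]
    if forward:
        _, edge, sign_d, attrs, conn_d = pick_best(forward, crosswise=False)
        mset = MismatchSet(has_sign=sign_d, attr_names=frozenset(attrs),
                           connection_differs=conn_d)
        if sign_d:
            return ClassifiedInteraction(new, "contradiction", "sign", edge, mset)
        if attrs:
            return ClassifiedInteraction(new, "contradiction", "attribute", edge, mset)
        if conn_d:
            return ClassifiedInteraction(new, "corroboration", "indirect", edge, mset)
        return ClassifiedInteraction(new, "corroboration",
                                     _bf_subtype(new, edge, strategy), edge, mset)

    if s_key == t_key:
        return ClassifiedInteraction(new, "extension", "internal")

    backward = [e for e in rows
                if (e.source.identifier, e.source.element_type) == t_key
                and (e.target.identifier, e.target.element_type) == s_key]
    if backward:
        _, edge, sign_d, attrs, conn_d = pick_best(backward, crosswise=True)
        mset = MismatchSet(has_sign=sign_d, has_direction=True,
                           attr_names=frozenset(attrs), connection_differs=conn_d)
        direction_only = not sign_d and not attrs
        if cfg.scheme == "CS3":
            category = "contradiction" if direction_only else "flagged"
        else:
            category = "flagged" if direction_only else "contradiction"
        return ClassifiedInteraction(new, category, "direction", edge, mset)

    def shortest_edge_paths(a_key, b_key):
        node_paths = [p for p in _bf_all_simple_paths(rows, a_key, b_key, cfg.max_path_len)
                      if len(p) - 1 >= 2]
        if not node_paths:
            return []
        shortest = min(len(p) for p in node_paths)
        node_paths = sorted(p for p in node_paths if len(p) == shortest)
        edge_paths = []
        for np_ in node_paths:
            combos: list[list[Interaction]] = [[]]
            for u, v in zip(np_, np_[1:]):
                hop = sorted((e for e in rows
                              if (e.source.identifier, e.source.element_type) == u
                              and (e.target.identifier, e.target.element_type) == v),
                             key=lambda e: e.index)
                combos = [c + [e] for c in combos for e in hop]
            edge_paths.extend(combos)
        return edge_paths[: cfg.max_paths]

    def path_mismatch(edges, reversed_path):
        negatives = sum(1 for e in edges if e.sign == NEGATIVE)
        net = POSITIVE if negatives % 2 == 0 else NEGATIVE
        if cfg.sign_mode == "strict":
            sign_d = any(e.sign != new.sign for e in edges)
        else:
            sign_d = new.sign != net
        cmp_comp, scalars, cmp_ctx = _bf_strategy_parts(strategy)
        attrs: set[str] = set()
        if cmp_comp:
            first, last = edges[0].source, edges[-1].target
            if reversed_path:
                bad = (_bf_conflict(new.source.compartment, last.compartment)
                       or _bf_conflict(new.target.compartment, first.compartment))
            else:
                bad = (_bf_conflict(new.source.compartment, first.compartment)
                       or _bf_conflict(new.target.compartment, last.compartment))
            if bad:
                attrs.add("compartment")
        for name in scalars:
            if any(_bf_conflict(getattr(new, name), getattr(e, name)) for e in edges):
                attrs.add(name)
        if cmp_ctx:
            for e in edges:
                for key in set(new.context_other) & set(e.context_other):
                    if _bf_conflict(new.context_other[key], e.context_other[key]):
                        attrs.add("context_other")
        return sign_d, attrs

    fwd_paths = shortest_edge_paths(s_key, t_key)
    rev_paths = [] if fwd_paths else shortest_edge_paths(t_key, s_key)
    chosen = fwd_paths or rev_paths
    if chosen:
        is_rev = not fwd_paths
        if new.connection == INDIRECT:
            best = None
            for edges in chosen:
                sign_d, attrs = path_mismatch(edges, is_rev)
                if not sign_d and not attrs and not is_rev:
                    return ClassifiedInteraction(
                        new, "corroboration", "path", Path(edges=tuple(edges)),
                        MismatchSet())
                rank = (int(sign_d), len(attrs))
                if best is None or rank < best[0]:
                    best = (rank, edges, sign_d, attrs)
            _, edges, sign_d, attrs = best
            mset = MismatchSet(has_sign=sign_d, has_direction=is_rev,
                               attr_names=frozenset(attrs))
            if cfg.scheme == "CS2":
                return ClassifiedInteraction(new, "contradiction", "path",
                                             Path(edges=tuple(edges)), mset)
            return ClassifiedInteraction(new, "flagged", "path_mismatch",
                                         Path(edges=tuple(edges)), mset)
        if cfg.scheme == "CS2":
            return ClassifiedInteraction(new, "flagged", "direct_no_edge",
                                         Path(edges=tuple(chosen[0])))
        return ClassifiedInteraction(new, "extension", "internal",
                                     Path(edges=tuple(chosen[0])))

    if new.connection == DIRECT and cfg.scheme == "CS2" and cfg.cs2_flag_unconnected_direct:
        return ClassifiedInteraction(new, "flagged", "direct_no_edge")
    return ClassifiedInteraction(new, "extension", "internal")


# ---------------------------------------------------------------------------
# Scoring against planted truth
# ---------------------------------------------------------------------------

def _as_label(x) -> str:
    if isinstance(x, ClassifiedInteraction):
        return x.category
    return str(x)


def score_against_truth(predicted: Sequence, truth: Sequence) -> pd.DataFrame:
    """One-vs-rest precision/recall/F1 per label plus micro-accuracy.

    ``predicted`` and ``truth`` are aligned row-by-row; entries may be
    category strings, full ``category:subcategory`` labels, or
    :class:`ClassifiedInteraction` objects (scored by category).
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truth rows"
        )
    pred = [_as_label(p) for p in predicted]
    true = [_as_label(t) for t in truth]
    labels = sorted(set(pred) | set(true))
    rows = []
    for label in labels:
        tp = sum(1 for p, t in zip(pred, true) if p == label and t == label)
        fp = sum(1 for p, t in zip(pred, true) if p == label and t != label)
        fn = sum(1 for p, t in zip(pred, true) if p != label and t == label)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append({"label": label, "precision": precision, "recall": recall,
                     "f1": f1, "support": tp + fn})
    correct = sum(1 for p, t in zip(pred, true) if p == t)
    rows.append({
        "label": "__micro__",
        "precision": correct / len(pred) if pred else 1.0,
        "recall": correct / len(pred) if pred else 1.0,
        "f1": correct / len(pred) if pred else 1.0,
        "support": len(pred),
    })
    return pd.DataFrame(rows, columns=["label", "precision", "recall", "f1", "support"])
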