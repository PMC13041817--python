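"""Decision-tree behaviour: categories, subcategories, scheme semantics."""

import random

import pytest

from netreconcile import (
    AttributeStrategy,
    InteractionList,
    ReconcilerConfig,
    build_graph,
    classify,
    classify_all,
)
from netreconcile.demo import scheme_scenarios
from netreconcile.fixtures import FixtureSpec, generate

from conftest import chain_list, edge, el

SCHEMES = ("CS1", "CS2", "CS3")
STRATEGY_NAMES = ("CA0", "CA1", "CA2", "CA3", "CA4")


def cfg_for(scheme="CS1", strategy="CA1", **kw):
    return ReconcilerConfig(scheme=scheme,
                            strategy=AttributeStrategy.from_name(strategy), **kw)


@pytest.mark.parametrize("scheme", SCHEMES)
@pytest.mark.parametrize("strategy", STRATEGY_NAMES)
def test_exact_duplicate_is_strong_corroboration_everywhere(scheme, strategy):
    base = edge(el("A", compartment="cytoplasm"), el("B", compartment="nucleus"),
                mechanism="binding", cell_line="hela", cell_type="epithelial",
                tissue="liver", organism="human")
    g = build_graph(InteractionList([base]))
    new = edge(el("A", compartment="cytoplasm"), el("B", compartment="nucleus"),
               mechanism="binding", cell_line="hela", cell_type="epithelial",
               tissue="liver", organism="human")
    c = classify(new, g, cfg_for(scheme, strategy))
    assert (c.category, c.subcategory) == ("corroboration", "strong")
    assert c.matched is base


@pytest.mark.parametrize("scenario", scheme_scenarios(), ids=lambda s: s.name)
@pytest.mark.parametrize("scheme", SCHEMES)
def test_scheme_sensitive_scenarios(scenario, scheme):
    g = build_graph(scenario.baseline)
    c = classify(scenario.new, g, cfg_for(scheme))
    assert (c.category, c.subcategory) == scenario.expected[scheme]


class TestMembershipStep:
    def test_both_endpoints_unknown_full_extension(self, small_graph):
        c = classify(edge("X", "Y"), small_graph, cfg_for())
        assert (c.category, c.subcategory) == ("extension", "full")
        assert c.matched is None

    def test_one_endpoint_unknown_hanging_extension(self, small_graph):
        c = classify(edge("A", "Y"), small_graph, cfg_for())
        assert (c.category, c.subcategory) == ("extension", "hanging")

    def test_empty_graph_everything_full_extension(self):
        g = build_graph(InteractionList([]))
        c = classify(edge("A", "B"), g, cfg_for())
        assert (c.category, c.subcategory) == ("extension", "full")


class TestForwardEdgeStep:
    def test_sign_mismatch_dominates_attribute_mismatch(self):
        base = edge(el("A"), el("B"), cell_line="hela")
        g = build_graph(InteractionList([base]))
        new = edge(el("A"), el("B"), sign="negative", cell_line="mcf7")
        c = classify(new, g, cfg_for(strategy="CA4"))
        assert (c.category, c.subcategory) == ("contradiction", "sign")
        assert c.mismatches.has_sign and "cell_line" in c.mismatches.attr_names

    def test_attribute_contradiction(self):
        base = edge(el("A", compartment="cytoplasm"), el("B"))
        g = build_graph(InteractionList([base]))
        new = edge(el("A", compartment="nucleus"), el("B"))
        c = classify(new, g, cfg_for(strategy="CA1"))
        assert (c.category, c.subcategory) == ("contradiction", "attribute")
        # same pair under CA0: compartment not compared, all slots vacuous
        c0 = classify(new, g, cfg_for(strategy="CA0"))
        assert (c0.category, c0.subcategory) == ("corroboration", "strong")

    def test_connection_difference_is_indirect_corroboration(self):
        g = build_graph(InteractionList([edge("A", "B", connection="direct")]))
        c = classify(edge("A", "B", connection="indirect"), g, cfg_for())
        assert (c.category, c.subcategory) == ("corroboration", "indirect")

    def test_specification_when_new_fills_empty_attribute(self):
        base = edge(el("A", compartment="cytoplasm"), el("B", compartment="nucleus"))
        g = build_graph(InteractionList([base]))
        new = edge(el("A", compartment="cytoplasm"), el("B", compartment="nucleus"),
                   cell_line="hela")
        c = classify(new, g, cfg_for(strategy="CA3"))
        assert (c.category, c.subcategory) == ("corroboration", "specification")

    def test_baseline_only_values_fall_to_weak_missing(self):
        base = edge(el("A"), el("B"), cell_line="hela")
        g = build_graph(InteractionList([base]))
        c = classify(edge("A", "B"), g, cfg_for(strategy="CA3"))
        assert (c.category, c.subcategory) == ("corroboration", "weak_missing")

    def test_mixed_one_sided_empty_falls_to_weak_missing(self):
        base = edge(el("A"), el("B"), cell_line="hela")  # baseline-only cell line
        g = build_graph(InteractionList([base]))
        new = edge(el("A"), el("B"), mechanism="binding")  # new-only mechanism
        c = classify(new, g, cfg_for(strategy="CA3"))
        assert (c.category, c.subcategory) == ("corroboration", "weak_missing")

    def test_best_parallel_edge_avoids_spurious_sign_contradiction(self):
        rows = [edge("A", "B", sign="negative", index=0),
                edge("A", "B", sign="positive", index=1)]
        g = build_graph(InteractionList(rows))
        c = classify(edge("A", "B"), g, cfg_for())
        assert c.category == "corroboration"
        assert c.matched.index == 1

    def test_parallel_tie_broken_by_baseline_order(self):
        rows = [edge("A", "B", index=0), edge("A", "B", index=1)]
        g = build_graph(InteractionList(rows))
        c = classify(edge("A", "B"), g, cfg_for())
        assert c.matched.index == 0


class TestReversedEdgeStep:
    def test_forward_edge_takes_precedence_over_reversed(self):
        rows = [edge("A", "B", index=0), edge("B", "A", index=1)]
        g = build_graph(InteractionList(rows))
        c = classify(edge("A", "B"), g, cfg_for())
        assert c.category == "corroboration" and c.matched.index == 0

    def test_connection_difference_does_not_escalate_reversal(self):
        # indirect new vs direct reversed baseline edge is still direction-only
        g = build_graph(InteractionList([edge("A", "B", connection="direct")]))
        new = edge("B", "A", connection="indirect")
        for scheme, expected in (("CS1", "flagged"), ("CS2", "flagged"),
                                 ("CS3", "contradiction")):
            c = classify(new, g, cfg_for(scheme))
            assert (c.category, c.subcategory) == (expected, "direction")

    def test_reversed_with_sign_conflict(self):
        g = build_graph(InteractionList([edge("A", "B")]))
        new = edge("B", "A", sign="negative")
        assert classify(new, g, cfg_for("CS1")).category == "contradiction"
        assert classify(new, g, cfg_for("CS3")).category == "flagged"


class TestPathStep:
    def test_indirect_consistent_path_corroboration(self):
        g = build_graph(chain_list("A", "B", "C"))
        c = classify(edge("A", "C", connection="indirect"), g, cfg_for())
        assert (c.category, c.subcategory) == ("corroboration", "path")
        assert c.matched.length == 2

    def test_sign_mismatched_path_by_scheme(self):
        g = build_graph(chain_list("A", "B", "C"))
        new = edge("A", "C", sign="negative", connection="indirect")
        assert classify(new, g, cfg_for("CS1")).subcategory == "path_mismatch"
        assert (classify(new, g, cfg_for("CS2")).category,
                classify(new, g, cfg_for("CS2")).subcategory) == ("contradiction", "path")
        assert classify(new, g, cfg_for("CS3")).subcategory == "path_mismatch"

    def test_one_consistent_path_among_mismatched_suffices(self):
        rows = [edge("A", "P", index=0), edge("P", "C", index=1),
                edge("A", "Q", sign="negative", index=2), edge("Q", "C", index=3)]
        g = build_graph(InteractionList(rows))
        c = classify(edge("A", "C", connection="indirect"), g, cfg_for())
        assert (c.category, c.subcategory) == ("corroboration", "path")
        assert c.matched.net_sign == "positive"

    def test_direct_over_path_by_scheme(self):
        g = build_graph(chain_list("A", "B", "C"))
        new = edge("A", "C", connection="direct")
        assert classify(new, g, cfg_for("CS1")).subcategory == "internal"
        assert (classify(new, g, cfg_for("CS2")).category,
                classify(new, g, cfg_for("CS2")).subcategory) == ("flagged", "direct_no_edge")
        assert classify(new, g, cfg_for("CS3")).subcategory == "internal"

    def test_strict_sign_mode_config_switch(self):
        g = build_graph(chain_list("A", "B", "C", signs=["negative", "negative"]))
        new = edge("A", "C", connection="indirect")  # positive
        assert classify(new, g, cfg_for()).subcategory == "path"
        strict = cfg_for(sign_mode="strict")
        assert classify(new, g, strict).subcategory == "path_mismatch"


class TestNoConnectionStep:
    def _graph(self):
        # U and V both known, not connected in either direction
        return build_graph(InteractionList([edge("x", "U", index=0),
                                            edge("V", "y", index=1)]))

    def test_indirect_internal_extension_all_schemes(self):
        for scheme in SCHEMES:
            c = classify(edge("U", "V", connection="indirect"), self._graph(),
                         cfg_for(scheme))
            assert (c.category, c.subcategory) == ("extension", "internal")

    def test_direct_flagged_only_under_cs2(self):
        new = edge("U", "V", connection="direct")
        assert classify(new, self._graph(), cfg_for("CS1")).category == "extension"
        assert classify(new, self._graph(), cfg_for("CS2")).subcategory == "direct_no_edge"
        assert classify(new, self._graph(), cfg_for("CS3")).category == "extension"

    def test_cs2_strict_path_only_variant(self):
        lenient = cfg_for("CS2", cs2_flag_unconnected_direct=False)
        c = classify(edge("U", "V", connection="direct"), self._graph(), lenient)
        assert (c.category, c.subcategory) == ("extension", "internal")


class TestSelfLoops:
    def test_matching_self_edge_corroborates(self):
        g = build_graph(InteractionList([edge("A", "A")]))
        c = classify(edge("A", "A"), g, cfg_for())
        assert c.category == "corroboration"

    def test_unmatched_self_loop_is_internal_extension(self, small_graph):
        for scheme in SCHEMES:
            c = classify(edge("A", "A"), small_graph, cfg_for(scheme))
            assert (c.category, c.subcategory) == ("extension", "internal")

    def test_unknown_self_loop_is_full_extension(self, small_graph):
        c = classify(edge("Z", "Z"), small_graph, cfg_for())
        assert (c.category, c.subcategory) == ("extension", "full")


def _case_grid():
    """One generated case per decision-tree leaf, via the fixture generator."""
    result = generate(FixtureSpec(seed=9, n_nodes=10, n_edges=15))
    g = build_graph(result.baseline)
    return result, g


def test_totality_every_interaction_gets_one_category():
    result, g = _case_grid()
    for scheme in SCHEMES:
        classified = classify_all(result.new_list, g, cfg_for(scheme))
        assert len(classified) == len(result.new_list)
        from netreconcile import CATEGORIES, SUBCATEGORIES

        for c in classified:
            assert c.category in CATEGORIES
            assert c.subcategory in SUBCATEGORIES[c.category]


def test_scheme_agreement_structure():
    """CS1 vs CS2 may differ only on path-level and direct-no-edge leaves;
    CS1 vs CS3 only on reversed-edge leaves — checked over a case grid that
    covers every decision-tree leaf."""
    result, g = _case_grid()
    for strategy in STRATEGY_NAMES:
        out = {s: classify_all(result.new_list, g, cfg_for(s, strategy))
               for s in SCHEMES}
        for c1, c2, c3 in zip(out["CS1"], out["CS2"], out["CS3"]):
            if (c1.category, c1.subcategory) != (c2.category, c2.subcategory):
                assert c1.subcategory in ("path_mismatch", "internal") or \
                    c2.subcategory in ("path", "direct_no_edge")
            if (c1.category, c1.subcategory) != (c3.category, c3.subcategory):
                assert c1.subcategory == c3.subcategory == "direction"


def test_extension_assignment_invariant_across_strategies():
    result, g = _case_grid()
    reference = classify_all(result.new_list, g, cfg_for("CS1", "CA0"))
    for strategy in STRATEGY_NAMES[1:]:
        other = classify_all(result.new_list, g, cfg_for("CS1", strategy))
        for a, b in zip(reference, other):
            a_ext = (a.category, a.subcategory) if a.category == "extension" else None
            b_ext = (b.category, b.subcategory) if b.category == "extension" else None
            if a_ext in (("extension", "full"), ("extension", "hanging")) or \
               b_ext in (("extension", "full"), ("extension", "hanging")):
                assert a_ext == b_ext


def test_permutation_equivariance():
    result, g = _case_grid()
    cfg = cfg_for()
    straight = classify_all(result.new_list, g, cfg)
    rng = random.Random(4)
    order = list(range(len(result.new_list)))
    rng.shuffle(order)
    permuted_list = InteractionList([result.new_list[i] for i in order])
    permuted = classify_all(permuted_list, g, cfg)
    for pos, original_index in enumerate(order):
        a, b = straight[original_index], permuted[pos]
        assert (a.category, a.subcategory) == (b.category, b.subcategory)


def test_repeated_interaction_classified_identically():
    g = build_graph(chain_list("A", "B", "C"))
    lst = InteractionList([edge("A", "C", connection="indirect") for _ in range(5)])
    out = classify_all(lst, g, cfg_for())
    assert len({(c.category, c.subcategory) for c in out}) == 1


def test_empty_list_empty_output(small_graph):
    assert classify_all(InteractionList([]), small_graph, cfg_for()) == []
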