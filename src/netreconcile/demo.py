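"""Built-in demonstration scenarios where the three schemes disagree.

Five tiny baseline-graph + single-new-interaction setups, one per
scheme-sensitive branch of the decision tree, each with its expected
classification under CS1, CS2 and CS3 (evaluated with the compartment-only
strategy CA1).  They are used by the worked examples, the test suite and
the acceptance script.

1. Direction-only reversal: the baseline has LKB1 activating AMPK directly;
   the new claim is that AMPK indirectly activates LKB1 — same sign,
   opposite direction.  CS1/CS2 flag it for inspection; CS3 calls it a
   contradiction.
2. Reversal plus compartment conflict: as (1) but the two claims place both
   kinases in different compartments.  CS1/CS2 now see a contradiction;
   CS3 flags it (the reversal might hold in another context).
3. Reversal plus sign and compartment conflict: AMPK directly *inhibits*
   LKB1.  CS1/CS2: contradiction; CS3: flagged.
4. Direct claim between two known but unconnected nodes (MYC and TERT,
   no edge and no path): CS1/CS3 treat it as an internal extension; CS2
   flags it as a potential reader error.
5. Indirect claim opposing a baseline path: STAT3 indirectly activates IL6
   while the baseline only has the reversed path IL6 -> IL6R -> STAT3.
   CS1/CS3 flag the path mismatch; CS2 calls it a path contradiction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import DIRECT, INDIRECT, NEGATIVE, POSITIVE, Element, Interaction, InteractionList

__all__ = ["Scenario", "scheme_scenarios"]


@dataclass(frozen=True)
class Scenario:
    name: str
    description: str
    baseline: InteractionList
    new: Interaction
    #: scheme -> (category, subcategory), under strategy CA1
    expected: dict[str, tuple[str, str]]


def _protein(name: str, compartment: str = "") -> Element:
    return Element(name=name, identifier=name, element_type="protein",
                   compartment=compartment)


def _edge(source: Element, target: Element, sign: str = POSITIVE,
          connection: str = DIRECT, index: int = 0) -> Interaction:
    return Interaction(source=source, target=target, sign=sign,
                       connection=connection, index=index)


def scheme_scenarios() -> list[Scenario]:
    scenarios: list[Scenario] = []

    lkb1, ampk = _protein("LKB1"), _protein("AMPK")
    scenarios.append(Scenario(
        name="direction_only",
        description="AMPK indirectly activates LKB1; baseline: LKB1 directly "
                    "activates AMPK (same sign, opposite direction)",
        baseline=InteractionList([_edge(lkb1, ampk)]),
        new=Interaction(source=ampk, target=lkb1, sign=POSITIVE, connection=INDIRECT),
        expected={"CS1": ("flagged", "direction"),
                  "CS2": ("flagged", "direction"),
                  "CS3": ("contradiction", "direction")},
    ))

    lkb1_c, ampk_c = _protein("LKB1", "cytoplasm"), _protein("AMPK", "cytoplasm")
    lkb1_n, ampk_n = _protein("LKB1", "nucleus"), _protein("AMPK", "nucleus")
    scenarios.append(Scenario(
        name="direction_plus_compartment",
        description="as direction_only, but the kinases are placed in "
                    "different compartments by the two claims",
        baseline=InteractionList([_edge(lkb1_c, ampk_c)]),
        new=Interaction(source=ampk_n, target=lkb1_n, sign=POSITIVE, connection=INDIRECT),
        expected={"CS1": ("contradiction", "direction"),
                  "CS2": ("contradiction", "direction"),
                  "CS3": ("flagged", "direction")},
    ))

    scenarios.append(Scenario(
        name="direction_sign_compartment",
        description="AMPK directly inhibits LKB1: reversed, sign-flipped and "
                    "compartment-conflicting vs the baseline edge",
        baseline=InteractionList([_edge(lkb1_c, ampk_c)]),
        new=Interaction(source=ampk_n, target=lkb1_n, sign=NEGATIVE, connection=DIRECT),
        expected={"CS1": ("contradiction", "direction"),
                  "CS2": ("contradiction", "direction"),
                  "CS3": ("flagged", "direction")},
    ))

    myc, tert = _protein("MYC"), _protein("TERT")
    ccnd1, e2f1 = _protein("CCND1"), _protein("E2F1")
    scenarios.append(Scenario(
        name="direct_unconnected",
        description="MYC directly increases TERT; both are baseline nodes "
                    "but share neither an edge nor a path",
        baseline=InteractionList([_edge(myc, ccnd1, index=0),
                                  _edge(e2f1, tert, index=1)]),
        new=Interaction(source=myc, target=tert, sign=POSITIVE, connection=DIRECT),
        expected={"CS1": ("extension", "internal"),
                  "CS2": ("flagged", "direct_no_edge"),
                  "CS3": ("extension", "internal")},
    ))

    il6, il6r, stat3 = _protein("IL6"), _protein("IL6R"), _protein("STAT3")
    scenarios.append(Scenario(
        name="reversed_path",
        description="STAT3 indirectly activates IL6; the baseline only has "
                    "the reversed path IL6 -> IL6R -> STAT3",
        baseline=InteractionList([_edge(il6, il6r, index=0),
                                  _edge(il6r, stat3, index=1)]),
        new=Interaction(source=stat3, target=il6, sign=POSITIVE, connection=INDIRECT),
        expected={"CS1": ("flagged", "path_mismatch"),
                  "CS2": ("contradiction", "path"),
                  "CS3": ("flagged", "path_mismatch")},
    ))
    return scenarios
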