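"""Classify a small literature-derived interaction list against a curated
baseline network and print each verdict.

The baseline is a five-edge AMPK signalling fragment; the "new" list mixes
an exact duplicate, a sign conflict, an indirect claim that matches a
two-edge path, and an interaction whose nodes the baseline has never seen.
"""

from netreconcile import (
    AttributeStrategy,
    Element,
    Interaction,
    InteractionList,
    ReconcilerConfig,
    build_graph,
    classify_all,
)


def protein(name, compartment=""):
    return Element(name=name, identifier=name, element_type="protein",
                   compartment=compartment)


LKB1, AMPK, TSC2, MTOR, S6K = (protein(n) for n in
                               ("LKB1", "AMPK", "TSC2", "MTOR", "S6K"))

baseline = InteractionList([
    Interaction(source=LKB1, target=AMPK, sign="positive", connection="direct", index=0),
    Interaction(source=AMPK, target=TSC2, sign="positive", connection="direct", index=1),
    Interaction(source=TSC2, target=MTOR, sign="negative", connection="direct", index=2),
    Interaction(source=MTOR, target=S6K, sign="positive", connection="direct", index=3),
    Interaction(source=AMPK, target=MTOR, sign="negative", connection="indirect", index=4),
])

new_list = InteractionList([
    # exact duplicate of a baseline edge -> strong corroboration
    Interaction(source=LKB1, target=AMPK, sign="positive", connection="direct"),
    # opposite sign on a known edge -> sign contradiction
    Interaction(source=AMPK, target=TSC2, sign="negative", connection="direct"),
    # indirect claim matching the net-negative path AMPK -> TSC2 -| MTOR
    Interaction(source=AMPK, target=MTOR, sign="negative", connection="indirect"),
    # both nodes unknown -> full extension
    Interaction(source=protein("FOXO3"), target=protein("SOD2"),
                sign="positive", connection="direct"),
])

g = build_graph(baseline)
cfg = ReconcilerConfig(scheme="CS1", strategy=AttributeStrategy.CA1)

print(f"baseline graph: {g.n_nodes} nodes, {g.n_edges} edges")
for c in classify_all(new_list, g, cfg):
    matched = f"  [{c.describe_matched()}]" if c.matched is not None else ""
    print(f"{c.interaction.describe():34} -> {c.category}:{c.subcategory}{matched}")

print("\nEach verdict says how the claim relates to the curated network: "
      "corroborations confirm it, contradictions conflict with it, and "
      "extensions are candidate new structure.")
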