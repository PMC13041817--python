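"""Generate a synthetic benchmark with planted ground truth, classify it,
and score the classifier against the truth table.

The generator plants one controlled perturbation per decision-tree leaf
(exact copies, sign flips, endpoint swaps, attribute edits, two-hop
shortcuts, fresh node pairs, ...) on top of a random signed background
graph, so every expected label is known by construction.
"""

from netreconcile import (
    AttributeStrategy,
    FixtureSpec,
    PLANT_LEAVES,
    ReconcilerConfig,
    build_graph,
    classify_all,
    score_against_truth,
    summarize,
)
from netreconcile.fixtures import generate

spec = FixtureSpec(seed=42, planted={leaf: 5 for leaf in PLANT_LEAVES},
                   duplicate_rate=0.1)
result = generate(spec)
g = build_graph(result.baseline)
print(f"baseline: {g.n_nodes} nodes, {g.n_edges} edges; "
      f"new list: {len(result.new_list)} interactions")

cfg = ReconcilerConfig(scheme="CS1", strategy=AttributeStrategy.CA1)
classified = classify_all(result.new_list, g, cfg)

predicted = [f"{c.category}:{c.subcategory}" for c in classified]
scores = score_against_truth(predicted, list(result.truth["cs1_ca1"]))
print("\nper-label precision/recall/F1 against the planted truth:")
print(scores.to_string(index=False,
                       formatters={c: "{:.3f}".format
                                   for c in ("precision", "recall", "f1")}))

print("\nsummary under CS1/CA1:")
print(summarize(classified, g).format_text())
print("\nA micro-F1 of 1.000 means every planted case received exactly the "
      "label the generator encoded for it.")
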