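"""How the three classification schemes reinterpret the same evidence.

Runs the five built-in scenarios where CS1, CS2 and CS3 disagree —
direction-only reversals, reversals with extra conflicts, direct claims
with no supporting edge, and claims opposing a baseline path — and prints
the verdict under each scheme.
"""

from netreconcile import AttributeStrategy, ReconcilerConfig, build_graph, classify
from netreconcile.demo import scheme_scenarios

for scenario in scheme_scenarios():
    g = build_graph(scenario.baseline)
    print(f"\n{scenario.name}: {scenario.description}")
    print(f"  new claim: {scenario.new.describe()}")
    for scheme in ("CS1", "CS2", "CS3"):
        cfg = ReconcilerConfig(scheme=scheme, strategy=AttributeStrategy.CA1)
        c = classify(scenario.new, g, cfg)
        print(f"  {scheme}: {c.category}:{c.subcategory}")

print("\nCS1 defers ambiguous reversals and path mismatches to manual review;"
      "\nCS2 treats them as conflicts and distrusts unsupported direct claims;"
      "\nCS3 calls a pure reversal a contradiction but forgives it when other"
      "\nattributes also disagree (it may hold in a different context).")
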