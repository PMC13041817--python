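import pytest
from hypothesis import settings

from netreconcile import Element, Interaction, InteractionList

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


def el(name, etype="protein", compartment="", identifier=None):
    return Element(name=name, identifier=identifier or name,
                   element_type=etype, compartment=compartment)


def edge(src, tgt, sign="positive", connection="direct", index=0, **attrs):
    if isinstance(src, str):
        src = el(src)
    if isinstance(tgt, str):
        tgt = el(tgt)
    return Interaction(source=src, target=tgt, sign=sign, connection=connection,
                       index=index, **attrs)


def chain_list(*names, signs=None, connection="direct"):
    """Baseline list forming a chain A->B->C->... with optional signs."""
    nodes = [el(n) for n in names]
    signs = signs or ["positive"] * (len(nodes) - 1)
    rows = [edge(a, b, sign=s, connection=connection, index=i)
            for i, ((a, b), s) in enumerate(zip(zip(nodes, nodes[1:]), signs))]
    return InteractionList(rows)


@pytest.fixture
def small_graph():
    """A -> B -> C plus a negative A -> D edge."""
    from netreconcile import build_graph

    lst = InteractionList([
        edge("A", "B", index=0),
        edge("B", "C", index=1),
        edge("A", "D", sign="negative", index=2),
    ])
    return build_graph(lst)
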