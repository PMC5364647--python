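import pytest

from srnanet.model import (
    Interaction,
    Region,
    RegulatoryNetwork,
    RnaNode,
    validate_network,
)


def make_network(edges, srna_len=90, mrna_len=210, scores=None, gene_names=None):
    """Build a small network from (srna, mrna, sregion, mregion) tuples."""
    net = RegulatoryNetwork()
    scores = scores or {}
    for i, (s, m, sr, mr) in enumerate(edges):
        if s not in net.nodes:
            net.add_node(RnaNode(id=s, role="sRNA", length=srna_len,
                                 gene_name=(gene_names or {}).get(s, s)))
        if m not in net.nodes:
            net.add_node(RnaNode(id=m, role="mRNA", length=mrna_len,
                                 gene_name=(gene_names or {}).get(m, m)))
        net.interactions.append(
            Interaction(s, m, Region(*sr), Region(*mr), scores.get(i, -7.0), "manual")
        )
    validate_network(net)
    return net


@pytest.fixture
def toy_net():
    """One sRNA with three targets at distinct sRNA regions and scores."""
    return make_network(
        [
            ("ryhB", "m1", (10, 20), (1, 15)),
            ("ryhB", "m2", (30, 40), (5, 20)),
            ("ryhB", "m3", (60, 70), (2, 12)),
        ],
        scores={0: -7.2, 1: -3.0, 2: -5.0},
    )


@pytest.fixture
def two_srna_net():
    return make_network(
        [
            ("s1", "m1", (1, 10), (1, 10)),
            ("s1", "m2", (1, 10), (1, 10)),
            ("s2", "m1", (20, 30), (1, 10)),
            ("s2", "m2", (20, 30), (1, 10)),
        ]
    )
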