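import networkx as nx
import pytest

from mtcr.datasets import load_uruguay_panel
from mtcr.haplotypes import (
    SUBSTITUTION,
    HaploPanel,
    Haplotype,
    Variant,
    transition,
)
from mtcr.network import MPTree, NetNode


def synth_ref(pos: int) -> str:
    return "ACGT"[pos % 4]


def hap_from_bits(hap_id: str, bits: str, sites=None, **kwargs) -> Haplotype:
    """Haplotype from a 0/1 string: 1 = transition of the synthetic reference
    at that site."""
    if sites is None:
        sites = [101 + i for i in range(len(bits))]
    variants = [
        Variant(p, SUBSTITUTION, synth_ref(p), transition(synth_ref(p)))
        for p, b in zip(sites, bits)
        if b == "1"
    ]
    return Haplotype(hap_id, frozenset(variants), **kwargs)


def panel_from_bits(bit_strings: dict[str, str], sites=None) -> HaploPanel:
    return HaploPanel(
        [hap_from_bits(hid, bits, sites) for hid, bits in bit_strings.items()]
    )


def make_tree(edge_lengths: dict[tuple[str, str], int], tips: dict[str, int],
              root: str = "root") -> MPTree:
    """Build an MPTree skeleton directly: edges carry synthetic site keys (one
    distinct substitution key per mutation), nodes in ``tips`` are sampled
    with the given multiplicity, all others are median vectors."""
    g = nx.Graph()
    placeholder = Haplotype("x", frozenset())
    next_site = [1]
    nodes = {root} | {n for e in edge_lengths for n in e}
    for n in sorted(nodes):
        mult = tips.get(n, 0)
        g.add_node(
            n,
            node=NetNode(n, placeholder, sampled=mult > 0, multiplicity=mult),
        )
    total = 0
    for (u, v), length in edge_lengths.items():
        keys = tuple(("sub", next_site[0] + i) for i in range(length))
        next_site[0] += length
        g.add_edge(u, v, weight=length, keys=keys)
        total += length
    return MPTree(g, float(total), root=root)


@pytest.fixture(scope="session")
def uruguay_panel():
    return load_uruguay_panel()
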