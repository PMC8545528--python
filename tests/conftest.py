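import networkx as nx
import pytest

from netdissect import network, synth
from netdissect.graph import TypedGraph


def typed_from_nx(g: nx.Graph) -> TypedGraph:
    out = TypedGraph()
    for n in sorted(g.nodes):
        out.add_node(str(n))
    for u, v in g.edges:
        out.add_edge(str(u), str(v), "ppi")
    return out


@pytest.fixture
def small_cfg() -> synth.SynthConfig:
    """Fast, fully-featured synthetic study configuration."""
    return synth.SynthConfig(
        seed=11, n_ppi_nodes=400, attach_m=2, n_diabetes=60, n_dr=25,
        n_common=15, n_lncrna=40, cerna_density=2.0, n_snps=40,
        n_planted_cliques=2, clique_size_range=(5, 6),
    )


@pytest.fixture
def small_clmn(small_cfg):
    """Integrated network built from the small synthetic study."""
    g, truth = synth.gen_ppi_network(small_cfg)
    labels = synth.gen_disease_sets(
        g, small_cfg,
        prefer=sorted({n for c in truth.planted_cliques for n in c}),
    )
    cerna = synth.gen_cerna_edges(g, small_cfg)
    diabetes = {k for k, v in labels.items() if v in ("diabetes", "common")}
    dr = {k for k, v in labels.items() if v in ("DR", "common")}
    clmn, _ = network.build_clmn(g, diabetes, dr, cerna)
    return clmn
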