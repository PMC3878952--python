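import logging

import pytest

from icfp import illustrative_fixture, split_reversible
from icfp.network import CarbonArcTable, Metabolite, MetabolicNetwork, Reaction

logging.getLogger("icfp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_fixture():
    """The 10-metabolite / 12-reaction illustrative network."""
    return illustrative_fixture()


@pytest.fixture(scope="session")
def toy_net(toy_fixture):
    return toy_fixture[0]


def make_chain(states=("M", "M"), medium_source=True):
    """A linear chain A -> B -> C with one reaction per arc.

    ``states`` gives the H/M/L class of each chain reaction.
    """
    n = len(states)
    mets = ["A"] + [f"X{i}" for i in range(1, n)] + ["Z"]
    metabolites = [Metabolite(mets[0], is_internal=False, in_medium=medium_source)]
    metabolites += [Metabolite(m) for m in mets[1:-1]]
    metabolites.append(Metabolite(mets[-1], is_internal=False))
    reactions = []
    arcs = CarbonArcTable()
    for i, (a, b) in enumerate(zip(mets, mets[1:])):
        rid = f"step{i}"
        reactions.append(Reaction(rid, {a: -1.0, b: 1.0}))
        arcs.add(a, b, rid)
    net = MetabolicNetwork(metabolites=metabolites, reactions=reactions,
                           carbon_arcs=arcs)
    classification = {f"step{i}": s for i, s in enumerate(states)}
    return net, classification, mets[0], mets[-1]


def make_two_path_network():
    """Source -> target via a direct arc or a two-step detour.

    Both routes balance trivially; used for exhaustion/elimination
    checks (exactly two simple carbon paths exist).
    """
    metabolites = [
        Metabolite("S", is_internal=False, in_medium=True),
        Metabolite("I"),
        Metabolite("T", is_internal=False),
    ]
    reactions = [
        Reaction("direct", {"S": -1.0, "T": 1.0}),
        Reaction("leg1", {"S": -1.0, "I": 1.0}),
        Reaction("leg2", {"I": -1.0, "T": 1.0}),
    ]
    arcs = CarbonArcTable()
    arcs.add("S", "T", "direct")
    arcs.add("S", "I", "leg1")
    arcs.add("I", "T", "leg2")
    net = MetabolicNetwork(metabolites=metabolites, reactions=reactions,
                           carbon_arcs=arcs)
    return net, {"direct": "M", "leg1": "M", "leg2": "M"}


@pytest.fixture()
def two_path_network():
    return make_two_path_network()


@pytest.fixture(scope="session")
def toy_split(toy_fixture):
    net, classification, query = toy_fixture
    return split_reversible(net), classification, query
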