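import pytest

from icfp.network import (
    CarbonArc,
    CarbonArcTable,
    Metabolite,
    MetabolicNetwork,
    NetworkFormatError,
    NetworkValidationError,
    Reaction,
    apply_medium,
    load_carbon_arcs,
    load_network,
    split_reversible,
    write_network,
)
from icfp.gpr import parse_gpr


def small_net(reversible=False):
    mets = [
        Metabolite("A", is_internal=False, in_medium=True),
        Metabolite("B"),
        Metabolite("C", is_internal=False),
    ]
    rxns = [
        Reaction("r1", {"A": -1.0, "B": 1.0}, reversible=reversible,
                 gpr=parse_gpr("(g1 and g2) or g3")),
        Reaction("r2", {"B": -1.0, "C": 1.0}),
        Reaction("r3", {"B": -2.0, "C": 1.0}),
    ]
    arcs = CarbonArcTable()
    arcs.add("A", "B", "r1")
    arcs.add("B", "C", "r2")
    return MetabolicNetwork(metabolites=mets, reactions=rxns, carbon_arcs=arcs)


class TestValidation:
    def test_toy_network_dimensions(self, toy_net):
        assert len(toy_net.metabolites) == 10
        assert len(toy_net.reactions) == 12

    def test_empty_reaction_list_rejected(self):
        with pytest.raises(NetworkValidationError):
            MetabolicNetwork(metabolites=[Metabolite("A")], reactions=[])

    def test_dangling_metabolite_reference_rejected(self):
        with pytest.raises(NetworkValidationError, match="ghost"):
            MetabolicNetwork(
                metabolites=[Metabolite("A")],
                reactions=[Reaction("r", {"A": -1.0, "ghost": 1.0})],
            )

    def test_medium_metabolite_must_be_external(self):
        with pytest.raises(NetworkValidationError):
            Metabolite("X", is_internal=True, in_medium=True)

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(NetworkValidationError):
            Reaction("r", {})

    def test_arc_with_wrong_sign_rejected(self):
        net = small_net()
        bad = CarbonArcTable()
        bad.add("B", "A", "r1")  # r1 produces B and consumes A
        with pytest.raises(NetworkValidationError, match="not consumed"):
            MetabolicNetwork(
                metabolites=list(net.metabolites),
                reactions=list(net.reactions),
                carbon_arcs=bad,
            )


class TestTabularDialect:
    def test_round_trip(self, tmp_path):
        net = small_net(reversible=True)
        write_network(net, tmp_path)
        loaded = load_network(tmp_path)
        write_network(loaded, tmp_path / "again")
        reloaded = load_network(tmp_path / "again")
        assert [m.id for m in loaded.metabolites] == [m.id for m in net.metabolites]
        assert {r.id: r.stoich for r in reloaded.reactions} == {
            r.id: r.stoich for r in loaded.reactions
        }
        assert reloaded.carbon_arcs.entries == loaded.carbon_arcs.entries
        assert str(reloaded.reaction("r1").gpr) == str(loaded.reaction("r1").gpr)

    def test_gpr_column_parsed_into_tree(self, tmp_path):
        write_network(small_net(), tmp_path)
        loaded = load_network(tmp_path)
        tree = loaded.reaction("r1").gpr
        assert tree.op == "or" and len(tree.children) == 2

    def test_bad_header_raises_format_error(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text("wrong\theader\n")
        with pytest.raises(NetworkFormatError, match="header"):
            load_network(tmp_path)

    def test_carbon_arcs_side_file(self, tmp_path, toy_net):
        path = tmp_path / "carbon_arcs.tsv"
        lines = ["reaction\tsubstrate\tproduct"]
        lines += ["R2\tA\tB", "R2\tA\tB", "R8\tC\tE"]  # duplicate collapses
        path.write_text("\n".join(lines) + "\n")
        table = load_carbon_arcs(path, toy_net)
        assert len(table) == 2

    def test_carbon_arc_substrate_that_is_a_product_rejected(
        self, tmp_path, toy_net
    ):
        path = tmp_path / "carbon_arcs.tsv"
        path.write_text("reaction\tsubstrate\tproduct\nR8\tE\tC\n")
        with pytest.raises(NetworkValidationError):
            load_carbon_arcs(path, toy_net)


class TestSplitReversible:
    def test_counts_and_partner_links(self):
        net = split_reversible(small_net(reversible=True))
        assert len(net.reactions) == 4
        fwd = net.reaction("r1")
        bwd = net.reaction(fwd.reverse_partner)
        assert bwd.reverse_partner == "r1"
        assert bwd.stoich == {"A": 1.0, "B": -1.0}
        assert net.reverse_pairs == [("r1", "r1__rev")]

    def test_arcs_mirrored_on_backward_copy(self):
        net = split_reversible(small_net(reversible=True))
        rev_id = net.reaction("r1").reverse_partner
        assert CarbonArc("B", "A", rev_id) in net.carbon_arcs.entries
        assert CarbonArc("A", "B", "r1") in net.carbon_arcs.entries

    def test_idempotent(self):
        once = split_reversible(small_net(reversible=True))
        twice = split_reversible(once)
        assert twice is once

    def test_partner_map_is_an_involution(self):
        net = split_reversible(small_net(reversible=True))
        for r in net.reactions:
            if r.reverse_partner is not None:
                assert net.reaction(r.reverse_partner).reverse_partner == r.id


class TestApplyMedium:
    def test_sets_flags_only_on_named(self):
        net = apply_medium(small_net(), {"A"})
        assert net.metabolite("A").in_medium
        assert not net.metabolite("C").in_medium

    def test_empty_medium_clears_flags(self):
        net = apply_medium(small_net(), set())
        assert net.medium_ids == set()

    def test_internal_metabolite_rejected(self):
        with pytest.raises(NetworkValidationError, match="internal"):
            apply_medium(small_net(), {"B"})

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(NetworkValidationError, match="unknown"):
            apply_medium(small_net(), {"nope"})


class TestSbmlImport:
    def test_cobra_round_trip(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        from cobra import Metabolite as CMet, Model, Reaction as CRxn

        model = Model("toy")
        a = CMet("a_e", compartment="e")
        b = CMet("b_c", compartment="c")
        rxn = CRxn("uptake")
        rxn.add_metabolites({a: -1.0, b: 1.0})
        rxn.lower_bound = -1000.0  # reversible
        rxn.gene_reaction_rule = "g1 or g2"
        model.add_reactions([rxn])
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(model, str(path))

        net = load_network(path, format="sbml")
        assert not net.metabolite("a_e").is_internal
        assert net.metabolite("b_c").is_internal
        r = net.reaction("uptake")
        assert r.reversible and r.stoich == {"a_e": -1.0, "b_c": 1.0}
        assert r.gpr.op == "or"
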