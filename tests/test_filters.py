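"""The three GI filters, the PPI lookup, polarity and composition."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from gifilters import (AliasRecord, ConfigurationError, GIEdge, HomologMap,
                       HomologRecord, FilterSpec, ValidationError,
                       apply_filters, basic_gi_filter, build_network,
                       combine_decisions, generic_network_filter,
                       gi_homologene_filter, gi_node_filter)
from gifilters.filters import FilterDecision

from conftest import make_motif, random_network


class TestBasicFilter:
    def test_direct_edge_passes_with_witness(self, toy_net):
        d = basic_gi_filter(make_motif("m1", "a", "b"), toy_net)
        assert d.passed and d.witness == (("a", "b"),)

    def test_no_edge_fails(self, toy_net):
        d = basic_gi_filter(make_motif("m1", "a", "c"), toy_net)
        assert not d.passed and d.witness == ()

    def test_alias_expansion(self):
        # S alias "P53" resolves to tp53; edge tp53-mdm2 retains the motif
        net = build_network([GIEdge("tp53", "mdm2")],
                            [AliasRecord("tp53", "P53")])
        d = basic_gi_filter(make_motif("m1", "P53", "mdm2"), net)
        assert d.passed and d.witness == (("mdm2", "tp53"),)

    def test_unresolved_endpoints_fail_with_note(self, toy_net):
        d = basic_gi_filter(make_motif("m1", "nosuch", "b"), toy_net)
        assert not d.passed and "source unresolved" in d.note
        d = basic_gi_filter(make_motif("m1", "a", "nosuch"), toy_net)
        assert "target unresolved" in d.note

    def test_self_pair_needs_self_loop(self):
        net = build_network([GIEdge("a", "b"), GIEdge("s", "s")])
        assert not basic_gi_filter(make_motif("m", "a", "a"), net).passed
        assert basic_gi_filter(make_motif("m", "s", "s"), net).passed


class TestGiNodeFilter:
    def test_direct_edge_at_n1(self, toy_net):
        d = gi_node_filter(make_motif("m", "a", "b"), toy_net, node_count=1)
        assert d.passed

    def test_path_case_witness_is_joining_edge(self):
        # s-x-y-t: ball(s,1)={s,x}, ball(t,1)={t,y}; edge x-y joins them
        net = build_network([GIEdge("s", "x"), GIEdge("x", "y"),
                             GIEdge("y", "t")])
        d = gi_node_filter(make_motif("m", "s", "t"), net, node_count=1)
        assert d.passed and d.witness == (("x", "y"),)

    def test_invalid_node_count(self, toy_net):
        with pytest.raises(ValidationError):
            gi_node_filter(make_motif("m", "a", "b"), toy_net, node_count=0)

    def test_high_node_count_warns(self, toy_net, caplog):
        with caplog.at_level("WARNING"):
            gi_node_filter(make_motif("m", "a", "d"), toy_net, node_count=5)
        assert "selectivity" in caplog.text

    @pytest.mark.parametrize("node_count", [1, 2])
    def test_equals_shortest_path_oracle(self, rng, node_count):
        """Decision equals BFS shortest-path(S,T) <= 2N+1 on random graphs."""
        for trial in range(8):
            edges, genes = random_network(rng, 50, 80, prefix=f"t{trial}_")
            net = build_network(edges)
            for i, j in rng.integers(0, 50, size=(40, 2)):
                s, t = genes[int(i)], genes[int(j)]
                if s == t:
                    continue
                motif = make_motif("m", s, t)
                got = gi_node_filter(motif, net, node_count=node_count).passed
                try:
                    sp = nx.shortest_path_length(net.graph, s, t)
                except (nx.NetworkXNoPath, nx.NodeNotFound):
                    sp = None
                expected = sp is not None and 1 <= sp <= 2 * node_count + 1
                assert got == expected, (s, t, sp, node_count)

    def test_nesting_chain(self, rng):
        """pass(basic) <= pass(node N=1) <= pass(node N=2) on any network."""
        edges, genes = random_network(rng, 40, 50)
        net = build_network(edges)
        for i, j in rng.integers(0, 40, size=(60, 2)):
            motif = make_motif("m", genes[int(i)], genes[int(j)])
            basic = basic_gi_filter(motif, net).passed
            n1 = gi_node_filter(motif, net, node_count=1).passed
            n2 = gi_node_filter(motif, net, node_count=2).passed
            assert (not basic or n1) and (not n1 or n2)


class TestHomologeneFilter:
    def test_extrapolation_rescues_basic_failure(self, fly_homology):
        net = build_network([GIEdge("s_fly", "t_fly")])
        motif = make_motif("m", "s", "t")
        assert not basic_gi_filter(motif, net).passed
        d = gi_homologene_filter(motif, net, fly_homology)
        assert d.passed and d.witness == (("s_fly", "t_fly"),)

    def test_superset_of_basic_on_taxon_complete_data(self, rng):
        edges, genes = random_network(rng, 30, 45)
        hmap = HomologMap.from_records(
            [HomologRecord(f"c{g}", "sp0", g) for g in genes])
        net = build_network(edges)
        for i, j in rng.integers(0, 30, size=(50, 2)):
            motif = make_motif("m", genes[int(i)], genes[int(j)])
            basic = basic_gi_filter(motif, net).passed
            homo = gi_homologene_filter(motif, net, hmap).passed
            assert not basic or homo


class TestGenericNetworkFilter:
    def test_ppi_edge_passes(self):
        ppi = build_network([GIEdge("s", "t", interaction_kind="physical")])
        d = generic_network_filter(make_motif("m", "s", "t"), ppi)
        assert d.passed and d.filter_name == "ppi"

    def test_empty_network_fails_everything(self):
        ppi = build_network([])
        assert not generic_network_filter(make_motif("m", "s", "t"), ppi).passed

    def test_disjoint_networks_give_disjoint_pass_sets(self, rng):
        gi = build_network([GIEdge("a", "b"), GIEdge("c", "d")])
        ppi = build_network([GIEdge("e", "f")])
        motifs = [make_motif(f"m{i}", s, t) for i, (s, t) in
                  enumerate([("a", "b"), ("c", "d"), ("e", "f"), ("a", "f")])]
        gi_pass = {m.motif_id for m in motifs
                   if basic_gi_filter(m, gi).passed}
        ppi_pass = {m.motif_id for m in motifs
                    if generic_network_filter(m, ppi).passed}
        assert gi_pass == {"m0", "m1"} and ppi_pass == {"m2"}
        assert gi_pass.isdisjoint(ppi_pass)


class TestCombineDecisions:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=5))
    def test_truth_table_equivalence(self, verdicts):
        decisions = [
            FilterDecision("m", f"f{i}", v, (("a", f"b{i}"),) if v else ())
            for i, v in enumerate(verdicts)]
        union = combine_decisions(decisions, "union")
        inter = combine_decisions(decisions, "intersection")
        assert union.passed == any(verdicts)
        assert inter.passed == all(verdicts)
        if union.passed:
            assert set(union.witness) == {w for d in decisions if d.passed
                                          for w in d.witness}

    def test_names_joined(self):
        decisions = [FilterDecision("m", "gi", True, (("a", "b"),)),
                     FilterDecision("m", "ppi", False)]
        assert combine_decisions(decisions, "union").filter_name == "gi|ppi"
        assert combine_decisions(decisions, "intersection").filter_name == "gi&ppi"

    def test_empty_and_mixed_motifs_rejected(self):
        with pytest.raises(ValidationError):
            combine_decisions([], "union")
        with pytest.raises(ValidationError):
            combine_decisions([FilterDecision("m1", "gi", True, (("a", "b"),)),
                               FilterDecision("m2", "gi", False)], "union")


class TestApplyFilters:
    def test_exclude_polarity_is_complement(self, toy_net):
        motifs = [make_motif("m1", "a", "b"), make_motif("m2", "a", "c")]
        include = apply_filters(motifs, [FilterSpec("gi", "gi")],
                                gi_network=toy_net)
        exclude = apply_filters(
            motifs, [FilterSpec("gi", "gi", polarity="exclude")],
            gi_network=toy_net)
        for inc, exc in zip(include, exclude):
            assert inc.passed != exc.passed
            assert exc.witness == ()

    def test_external_flags(self, toy_net):
        motif = make_motif("m1", "a", "b",
                           external_flags={"frequency": True})
        specs = [FilterSpec("frequency", "external_flag"),
                 FilterSpec("cell_function", "external_flag")]
        dec = apply_filters([motif], specs, gi_network=toy_net)
        assert dec[0].passed
        assert not dec[1].passed and "absent" in dec[1].note

    def test_missing_resource_errors_before_filtering(self, toy_net):
        motif = make_motif("m1", "a", "b")
        with pytest.raises(ConfigurationError):
            apply_filters([motif], [FilterSpec("gi", "gi")])
        with pytest.raises(ConfigurationError):
            apply_filters([motif], [FilterSpec("h", "gi_homologene")],
                          gi_network=toy_net)
        with pytest.raises(ConfigurationError):
            apply_filters([motif], [FilterSpec("ppi", "network_generic")],
                          gi_network=toy_net)

    def test_pass_counts_match_per_motif_recomputation(self, small_world):
        from gifilters import build_network as bn
        net = bn(small_world.gi_edges, small_world.alias_records)
        hmap = HomologMap.from_records(small_world.homolog_records)
        motifs = small_world.positive_motifs[:200]
        specs = [FilterSpec("gi", "gi"),
                 FilterSpec("gi_node", "gi_node", node_count=2),
                 FilterSpec("gi_homologene", "gi_homologene")]
        decisions = apply_filters(motifs, specs, gi_network=net, hmap=hmap)
        by_name = {}
        for d in decisions:
            by_name.setdefault(d.filter_name, []).append(d.passed)
        assert by_name["gi"] == [basic_gi_filter(m, net).passed
                                 for m in motifs]
        assert by_name["gi_node"] == [
            gi_node_filter(m, net, node_count=2).passed for m in motifs]
        assert by_name["gi_homologene"] == [
            gi_homologene_filter(m, net, hmap).passed for m in motifs]
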