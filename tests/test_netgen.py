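"""Construction of the five evolving networks and their snapshots."""

import pytest

from domarchnet.chronology import AgeMap
from domarchnet.netgen import (
    build_network,
    degrees_at,
    first_events,
    snapshot,
    undirected_snapshot,
)
from domarchnet.synthetic_data import SynthConfig, gen_entity_set


def _edges(net):
    return sorted((a.source, a.target, a.weight) for a in net.arcs)


def _pairs(net):
    return {frozenset((a.source, a.target)) for a in net.arcs}


class TestToyConstruction:
    def test_cx_arcs(self, toy_set, toy_ages):
        net = build_network("CX", toy_set, toy_ages)
        assert _edges(net) == sorted([
            ("1", "1|2", 1), ("2", "1|2", 1),
            ("3", "3|2", 1), ("2", "3|2", 1),
            ("1", "1|2|3", 1), ("2", "1|2|3", 1), ("3", "1|2|3", 1),
            ("1|2", "1|2|3", 1),
            ("2", "4|3|2", 1), ("3", "4|3|2", 1), ("3|2", "4|3|2", 1),
        ])

    def test_px_pairs_respect_disjointness(self, toy_set, toy_ages):
        net = build_network("PX", toy_set, toy_ages)
        assert _edges(net) == sorted([
            ("1", "2", 1), ("1", "3", 1), ("2", "3", 2), ("3", "1|2", 1),
        ])

    def test_pax_requires_abutting_occurrences(self, toy_set, toy_ages):
        net = build_network("PAX", toy_set, toy_ages)
        assert _edges(net) == sorted([
            ("1", "2", 1), ("2", "3", 2), ("3", "1|2", 1),
        ])

    def test_spx_token_pairs(self, toy_set, toy_ages):
        net = build_network("SPX", toy_set, toy_ages)
        assert set(net.nodes) == {"1", "2", "3", "4"}
        assert _edges(net) == sorted([
            ("1", "2", 1), ("1", "3", 1), ("2", "3", 2),
            ("3", "4", 1), ("2", "4", 1),
        ])

    def test_spax_adjacent_tokens(self, toy_set, toy_ages):
        net = build_network("SPAX", toy_set, toy_ages)
        assert _edges(net) == sorted([
            ("1", "2", 1), ("2", "3", 2), ("3", "4", 1),
        ])

    def test_missing_age_names_entity(self, toy_set):
        with pytest.raises(KeyError, match="4\\|3\\|2"):
            build_network("CX", toy_set, AgeMap({l: 0.0 for l in
                          ["1", "2", "3", "1|2", "3|2", "1|2|3"]}))


@pytest.fixture(scope="module")
def synth():
    return gen_entity_set(SynthConfig(
        n_domains=60, n_multidomains=300, n_events=60, seed=3))


class TestArcInvariants:
    @pytest.mark.parametrize("crit", ["CX", "PX", "PAX", "SPX", "SPAX"])
    def test_arcs_never_point_backward_in_time(self, synth, crit):
        es, ages = synth
        net = build_network(crit, es, ages)
        for a in net.arcs:
            if a.contemporary:
                assert net.nodes[a.source] == net.nodes[a.target]
            else:
                assert net.nodes[a.source] < net.nodes[a.target]
            assert a.age == max(net.nodes[a.source], net.nodes[a.target])
            assert a.weight >= 1

    @pytest.mark.parametrize("sup,sub", [("SPX", "SPAX"), ("PX", "PAX")])
    def test_adjacency_restriction_is_a_subset(self, synth, sup, sub):
        es, ages = synth
        big = build_network(sup, es, ages)
        small = build_network(sub, es, ages)
        assert _pairs(small) <= _pairs(big)
        wt_big = {frozenset((a.source, a.target)): a.weight for a in big.arcs}
        for a in small.arcs:
            assert a.weight <= wt_big[frozenset((a.source, a.target))]

    def test_cx_in_weights_conserve_occurrence_counts(self, synth):
        from domarchnet.ccs_entities import component_occurrences

        es, ages = synth
        net = build_network("CX", es, ages)
        in_w = {}
        for a in net.arcs:
            container = a.target if net.nodes[a.target] >= net.nodes[a.source] \
                else a.source
            in_w[container] = in_w.get(container, 0) + a.weight
        for ent in es:
            if len(ent.blocks) < 2:
                continue
            occ = component_occurrences(ent, es)
            if occ:
                assert in_w.get(ent.label, 0) >= len(occ)  # containers can
                # also act as components of still larger architectures
        # exact conservation: total arc weight equals total occurrences
        total_occ = sum(
            len(component_occurrences(e, es)) for e in es if len(e.blocks) > 1
        )
        assert sum(a.weight for a in net.arcs) == total_occ


class TestSnapshots:
    def test_first_event_has_no_directed_arcs(self, toy_set, toy_ages):
        for crit in ("CX", "PX", "SPX"):
            net = build_network(crit, toy_set, toy_ages)
            g = snapshot(net, 1)
            assert all(d["contemporary"] for _, _, d in g.edges(data=True))

    def test_last_event_is_full_network(self, toy_set, toy_ages):
        net = build_network("CX", toy_set, toy_ages)
        g = snapshot(net, net.n_events)
        assert g.number_of_nodes() == len(net.nodes)
        assert g.number_of_edges() == len(net.arcs)

    def test_cx_snapshot_before_first_container_has_no_arcs(
            self, toy_set, toy_ages):
        net = build_network("CX", toy_set, toy_ages)
        ev = net.timeline.index[0.2]  # all three domains, no containers yet
        assert snapshot(net, ev).number_of_edges() == 0

    def test_snapshots_are_monotone(self, toy_set, toy_ages):
        net = build_network("PX", toy_set, toy_ages)
        prev_edges, prev_nodes = set(), set()
        for ev in range(1, net.n_events + 1):
            g = snapshot(net, ev)
            assert prev_edges <= set(g.edges)
            assert prev_nodes <= set(g.nodes)
            prev_edges, prev_nodes = set(g.edges), set(g.nodes)

    def test_out_of_range_event(self, toy_set, toy_ages):
        net = build_network("CX", toy_set, toy_ages)
        with pytest.raises(ValueError):
            snapshot(net, 0)
        with pytest.raises(ValueError):
            snapshot(net, net.n_events + 1)

    def test_undirected_snapshot_merges_weights(self, toy_set, toy_ages):
        net = build_network("PX", toy_set, toy_ages)
        g = undirected_snapshot(net, net.n_events)
        assert g["2"]["3"]["weight"] == 2
        unweighted = undirected_snapshot(net, net.n_events, weighted=False)
        assert unweighted["2"]["3"]["weight"] == 1


class TestDegrees:
    def test_star_degrees(self, toy_set, toy_ages):
        net = build_network("CX", toy_set, toy_ages)
        df = degrees_at(net, net.n_events).set_index("label")
        # domain 2 feeds all four containers
        assert df.loc["2", "w_outdegree"] == 4
        assert df.loc["1|2|3", "w_indegree"] == 4  # 1,2,3,1|2

    def test_spx_toy_total_degree(self, toy_set, toy_ages):
        net = build_network("SPX", toy_set, toy_ages)
        df = degrees_at(net, net.n_events).set_index("label")
        assert (df.loc["3", "w_indegree"] + df.loc["3", "w_outdegree"]) == 4

    def test_weighted_at_least_unweighted(self, toy_set, toy_ages):
        net = build_network("PX", toy_set, toy_ages)
        df = degrees_at(net, net.n_events)
        assert (df["w_outdegree"] >= df["outdegree"]).all()
        assert (df["w_indegree"] >= df["indegree"]).all()


class TestFirstEvents:
    def test_toy_first_cx_arc(self, toy_set, toy_ages):
        net = build_network("CX", toy_set, toy_ages)
        arc, nd = first_events(net)
        assert (arc.source, arc.target) == ("1", "1|2")
        assert nd == 0.3

    def test_no_arcs_is_an_error(self, toy_set):
        contemporary = AgeMap({l: 0.5 for l in
                               ["1", "2", "3", "1|2", "3|2", "1|2|3", "4|3|2"]})
        net = build_network("CX", toy_set, contemporary)
        with pytest.raises(ValueError):
            first_events(net)
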