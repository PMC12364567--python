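import itertools

import networkx as nx
import pandas as pd
import pytest

from lipidtraffic.dataio import CompartmentNetwork
from lipidtraffic.presence import call_presence
from lipidtraffic.switch import (
    LABELS,
    classify_pattern,
    compare_phenotypes,
    count_table,
    spanned_edges,
    switch_analysis,
)
from lipidtraffic.synthetic_data import TrafficSimSpec, generate_traffic_dataset


def oracle_classify(pattern, network):
    """Category-membership oracle: decide by looking the pattern up in the
    explicitly enumerated category sets rather than by case analysis."""
    nodes = frozenset(network.nodes)
    pattern = frozenset(pattern)
    singletons = {frozenset([n]) for n in nodes}
    edge_pairs = {frozenset(e) for e in network.edges}
    all_pairs = {frozenset(p) for p in itertools.combinations(sorted(nodes), 2)}
    if pattern == frozenset():
        return "ABSENT"
    if pattern == nodes:
        return "A"
    if pattern in singletons:
        return "U"
    if pattern in edge_pairs:
        return "B"
    if pattern in all_pairs:
        return "N2"
    return "PARTIAL"


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "pattern, label",
        [
            ({"A", "B", "C", "D"}, "A"),
            ({"B"}, "U"),
            ({"B", "C"}, "B"),
            ({"A", "C"}, "N2"),
            ({"A", "B", "D"}, "PARTIAL"),
            (set(), "ABSENT"),
        ],
    )
    def test_path_graph_examples(self, path_network, pattern, label):
        assert classify_pattern(pattern, path_network) == label

    def test_partial_spanned_edges(self, path_network):
        assert spanned_edges({"A", "B", "D"}, path_network) == [("A", "B")]

    def test_unknown_compartment_rejected(self, path_network):
        with pytest.raises(ValueError, match="unknown"):
            classify_pattern({"A", "X"}, path_network)

    def test_matches_enumeration_oracle_on_small_graphs(self):
        """Exhaustive agreement over all patterns of some 4/5-node graphs."""
        graphs = [nx.path_graph(4), nx.cycle_graph(5), nx.star_graph(4),
                  nx.complete_graph(4)]
        for g in graphs:
            g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
            net = CompartmentNetwork.from_lists(list(g.nodes), list(g.edges))
            nodes = sorted(net.nodes)
            for r in range(len(nodes) + 1):
                for combo in itertools.combinations(nodes, r):
                    pat = frozenset(combo)
                    assert classify_pattern(pat, net) == oracle_classify(pat, net)


class TestSwitchAnalysis:
    def test_everywhere_variable_counts_as_a(self, toy_study):
        table, design, network = toy_study
        pres = call_presence(table, design)
        res = switch_analysis(pres, network)
        for phen in ("F", "M"):
            assert res[phen].labels["PC(34:2)"] == "A"
            assert "PC(34:2)" in res[phen].a_set

    def test_single_compartment_variable_is_u_for_one_phenotype_only(self, toy_study):
        table, design, network = toy_study
        res = switch_analysis(call_presence(table, design), network)
        assert res["F"].labels["TG(48:1)"] == "U"
        assert "TG(48:1)" in res["F"].u_sets["liver"]
        assert res["M"].labels["TG(48:1)"] == "ABSENT"

    def test_conservation_of_labelled_counts(self):
        spec = TrafficSimSpec(seed=4, counts={"A": 5, "U": 7, "B": 6, "N2": 4,
                                              "PARTIAL": 3})
        table, design, truth = generate_traffic_dataset(spec)
        res = switch_analysis(call_presence(table, design), spec.network)
        for r in res.values():
            counts = r.label_counts()
            nonempty = sum(1 for p in r.patterns.values() if p)
            assert sum(counts[l] for l in LABELS if l != "ABSENT") == nonempty

    def test_planted_labels_recovered_without_dropout(self):
        spec = TrafficSimSpec(seed=9, dropout=0.0)
        table, design, truth = generate_traffic_dataset(spec)
        res = switch_analysis(call_presence(table, design), spec.network)
        for _, row in truth.iterrows():
            assert res[row["phenotype"]].labels[row["variable"]] == row["label"]

    def test_partial_enrolls_in_spanned_edge_sets(self, path_network):
        spec = TrafficSimSpec(
            network=path_network, counts={"PARTIAL": 5}, seed=2,
            relocate_fraction=0.0,
        )
        table, design, _ = generate_traffic_dataset(spec)
        res = switch_analysis(call_presence(table, design), path_network)
        r = next(iter(res.values()))
        for var, edges in r.partial_edges.items():
            for e in edges:
                assert var in r.b_sets[e]
            for e in path_network.edges:
                if e not in edges:
                    assert var not in r.b_sets[e]

    def test_a_type_edge_enrollment_toggle(self, toy_study):
        table, design, network = toy_study
        pres = call_presence(table, design)
        excl = switch_analysis(pres, network)["F"]
        incl = switch_analysis(pres, network, include_a_in_edges=True)["F"]
        edge = ("liver", "serum")
        assert "PC(34:2)" not in excl.b_sets[edge]
        assert "PC(34:2)" in incl.b_sets[edge]

    def test_count_table_groups_dg_with_tg(self):
        spec = TrafficSimSpec(seed=13)
        table, design, _ = generate_traffic_dataset(spec)
        res = switch_analysis(call_presence(table, design), spec.network)
        r = next(iter(res.values()))
        # rename one variable to a DG to exercise the grouping
        var = next(iter(r.labels))
        r.labels["DG(36:3)"] = r.labels.pop(var)
        r.patterns["DG(36:3)"] = r.patterns.pop(var)
        grouped = count_table(r, group_dg_with_tg=True)
        plain = count_table(r, group_dg_with_tg=False)
        assert "DG" in plain.index and "DG" not in grouped.index
        assert grouped.loc["TG"].sum() == plain.loc["TG"].sum() + plain.loc["DG"].sum()


class TestComparePhenotypes:
    def _results(self, seed=21, relocate=0.4):
        spec = TrafficSimSpec(seed=seed, relocate_fraction=relocate)
        table, design, _ = generate_traffic_dataset(spec)
        res = switch_analysis(call_presence(table, design), spec.network)
        return res, spec

    def test_identical_results_have_unit_jaccard(self):
        res, spec = self._results(relocate=0.0)
        comp = compare_phenotypes(res["female"], res["male"], seed=0)
        for s in comp.scopes.values():
            assert s.only_1 == [] and s.only_2 == []
            assert s.jaccard == 1.0

    def test_membership_partition(self):
        res, _ = self._results()
        comp = compare_phenotypes(res["female"], res["male"], seed=0)
        for s in comp.scopes.values():
            union = set(s.shared) | set(s.only_1) | set(s.only_2)
            assert len(union) == len(s.shared) + len(s.only_1) + len(s.only_2)

    def test_symmetry(self):
        res, _ = self._results()
        fwd = compare_phenotypes(res["female"], res["male"], seed=0)
        rev = compare_phenotypes(res["male"], res["female"], seed=0)
        assert set(fwd.scopes) == set(rev.scopes)
        for key, s in fwd.scopes.items():
            m = rev.scopes[key]
            assert s.shared == m.shared
            assert s.only_1 == m.only_2 and s.only_2 == m.only_1
            assert s.jaccard == pytest.approx(m.jaccard)
            assert s.pvalue == pytest.approx(m.pvalue)

    def test_disjoint_u_sets_give_zero_jaccard(self, path_network):
        from lipidtraffic.switch import TrafficResult

        def mk(phen, node):
            r = TrafficResult(
                phen,
                {"PC(34:2)": frozenset([node])},
                {"PC(34:2)": "U"},
                set(),
                {n: set() for n in path_network.nodes},
                {e: set() for e in path_network.edges},
                {p: set() for p in path_network.nonadjacent_pairs()},
                {},
                path_network,
            )
            r.u_sets[node].add("PC(34:2)")
            return r
        comp = compare_phenotypes(mk("F", "A"), mk("M", "B"), seed=0)
        assert comp.scopes["node:A"].jaccard == 0.0
        assert comp.scopes["node:A"].shared == []

    def test_superset_edge_has_no_unique_to_smaller(self):
        res, _ = self._results(seed=33)
        t1, t2 = res["female"], res["male"]
        edge = t1.network.edges[0]
        t2.b_sets[edge] = set(t1.b_sets[edge]) | {"PC(34:2)"}
        t2.labels.setdefault("PC(34:2)", "B")
        t1.labels.setdefault("PC(34:2)", "ABSENT")
        t1.patterns.setdefault("PC(34:2)", frozenset())
        t2.patterns.setdefault("PC(34:2)", frozenset(edge))
        comp = compare_phenotypes(t1, t2, seed=0)
        key = f"edge:{edge[0]}--{edge[1]}"
        assert comp.scopes[key].only_1 == []

    def test_mismatched_networks_rejected(self, path_network):
        res, _ = self._results()
        other = switch_analysis(
            call_presence(*generate_traffic_dataset(
                TrafficSimSpec(network=path_network, seed=1,
                               counts={"U": 3, "B": 3})
            )[:2]),
            path_network,
        )
        with pytest.raises(ValueError, match="network|universe"):
            compare_phenotypes(res["female"], other["male"], seed=0)
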