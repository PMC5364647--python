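"""Filters, motif extraction, graph measures, coloration, layout."""

import itertools

import numpy as np
import pytest

from srnanet.enrichment import AnnotationCatalog
from srnanet.model import Region, validate_network
from srnanet.netalgos import (
    apply_layout,
    betweenness,
    colorize,
    coverage_curve,
    degree,
    filter_by_annotation,
    filter_by_names,
    filter_by_region,
    filter_by_score,
    filter_dor_motifs,
    filter_sim_motifs,
    layout_bipartite,
)
from srnanet.synthgen import SynthSpec, generate
from conftest import make_network


class TestScoreFilter:
    def test_le_threshold_keeps_stable_duplexes(self, toy_net):
        out = filter_by_score(toy_net, "le", -5.0)
        assert sorted(it.score for it in out.interactions) == [-7.2, -5.0]

    def test_ge_very_low_is_identity_on_edges(self, toy_net):
        out = filter_by_score(toy_net, "ge", -1e9)
        assert sorted(out.interaction_keys()) == sorted(toy_net.interaction_keys())

    def test_empty_net(self):
        net = make_network([])
        assert len(filter_by_score(net, "le", 0.0).interactions) == 0


class TestRegionFilter:
    def test_overlap_window(self, toy_net):
        out = filter_by_region(toy_net, "sRNA", Region(35, 65))
        spans = sorted((it.srna_region.start, it.srna_region.end) for it in out.interactions)
        assert spans == [(30, 40), (60, 70)]

    def test_full_window_is_identity(self, toy_net):
        out = filter_by_region(toy_net, "sRNA", Region(1, 90))
        assert sorted(out.interaction_keys()) == sorted(toy_net.interaction_keys())

    def test_contained_mode_stricter(self, toy_net):
        out = filter_by_region(toy_net, "sRNA", Region(35, 65), mode="contained")
        assert out.interactions == []


class TestNameFilter:
    def test_srna_side_match(self, two_srna_net):
        out = filter_by_names(two_srna_net, {"s1"}, side="sRNA")
        assert {it.srna_id for it in out.interactions} == {"s1"}

    def test_empty_set_empties_network(self, two_srna_net):
        assert filter_by_names(two_srna_net, set()).interactions == []

    def test_absent_name_warns(self, two_srna_net, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = filter_by_names(two_srna_net, {"ghost"})
        assert out.interactions == []
        assert any("ghost" in r.message for r in caplog.records)


class TestSimFilter:
    def test_star_kept_whole(self):
        net = make_network([("s1", f"m{i}", (1, 10), (1, 10)) for i in range(5)])
        out = filter_sim_motifs(net, 3)
        assert len(out.interactions) == 5

    def test_small_star_removed(self):
        net = make_network([("s1", f"m{i}", (1, 10), (1, 10)) for i in range(2)])
        assert filter_sim_motifs(net, 3).interactions == []

    def test_planted_sim_recovered_exactly(self):
        net, _cat, truth = generate(SynthSpec(n_srna=30, n_mrna=300, sim=(0, 20),
                                              noise_edges=40, seed=5))
        out = filter_sim_motifs(net, 20)
        assert set(out.interaction_keys()) == truth.sim_edges


class TestDorFilter:
    def test_two_by_two_block(self, two_srna_net):
        out = filter_dor_motifs(two_srna_net)
        assert len(out.interactions) == 4
        assert set(out.nodes) == {"s1", "s2", "m1", "m2"}

    def test_star_with_unique_targets_empty(self):
        net = make_network([("s1", f"m{i}", (1, 10), (1, 10)) for i in range(5)])
        assert filter_dor_motifs(net).interactions == []

    def test_planted_dor_recovered(self):
        net, _cat, truth = generate(SynthSpec(n_srna=30, n_mrna=300, dor=(3, 4),
                                              noise_edges=40, seed=6))
        out = filter_dor_motifs(net, min_srnas=3, min_mrnas=4)
        assert set(out.interaction_keys()) == truth.dor_edges
        assert set(out.nodes) == truth.dor_srnas | truth.dor_mrnas


class TestAnnotationFilter:
    @pytest.fixture
    def catalog(self):
        return AnnotationCatalog(
            term_defs={"T1": "iron ion transport", "T2": "oxygen response"},
            gene_terms={"m1": {"T1"}, "m2": {"T2"}, "m3": {"T1", "T2"}},
        )

    def test_keyword_match(self, toy_net, catalog):
        out = filter_by_annotation(toy_net, {"iron"}, catalog)
        assert {it.mrna_id for it in out.interactions} == {"m1", "m3"}

    def test_term_id_match(self, toy_net, catalog):
        out = filter_by_annotation(toy_net, {"T2"}, catalog, match="term_id")
        assert {it.mrna_id for it in out.interactions} == {"m2", "m3"}

    def test_empty_terms_empty_network(self, toy_net, catalog):
        assert filter_by_annotation(toy_net, set(), catalog).interactions == []

    def test_all_annotated_identity_on_edges(self, toy_net, catalog):
        out = filter_by_annotation(toy_net, {"T1", "T2"}, catalog, match="term_id")
        assert sorted(out.interaction_keys()) == sorted(toy_net.interaction_keys())


class TestFilterAlgebra:
    """Filters are idempotent restrictions that commute when independent."""

    def _filters(self):
        return [
            lambda n: filter_by_score(n, "le", -5.0),
            lambda n: filter_by_region(n, "sRNA", Region(25, 65)),
        ]

    def test_restriction_and_idempotence(self, toy_net):
        for f in self._filters():
            once = f(toy_net)
            assert set(once.interaction_keys()) <= set(toy_net.interaction_keys())
            assert f(once) == once
            validate_network(once)

    def test_independent_filters_commute(self, toy_net):
        f, g = self._filters()
        assert f(g(toy_net)) == g(f(toy_net))


class TestDegree:
    def test_star_degrees(self):
        net = make_network([("s1", f"m{i}", (1, 10), (1, 10)) for i in range(5)])
        deg = degree(net)
        assert deg["s1"] == 5 and all(deg[f"m{i}"] == 1 for i in range(5))

    def test_parallel_edges_each_count(self):
        net = make_network([("s1", "m1", (1, 10), (1, 10)), ("s1", "m1", (20, 30), (1, 10))])
        assert degree(net)["s1"] == 2 and degree(net)["m1"] == 2

    def test_handshake(self, toy_net):
        assert sum(degree(toy_net).values()) == 2 * len(toy_net.interactions)


def oracle_betweenness(nodes, edges):
    """All-pairs shortest-path enumeration by brute force (DFS over all
    simple paths), endpoints excluded, each unordered pair once."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in sorted(adj[v]):
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sp)
    return bc


class TestBetweenness:
    def test_path_graph(self):
        net = make_network(
            [("a", "b", (1, 5), (1, 5)), ("c", "b", (1, 5), (1, 5)), ("c", "d", (1, 5), (1, 5))]
        )
        bc = betweenness(net)
        assert bc["b"] == 2.0 and bc["c"] == 2.0 and bc["a"] == 0.0 and bc["d"] == 0.0

    def test_star_center(self):
        net = make_network([("s1", f"m{i}", (1, 10), (1, 10)) for i in range(3)])
        assert betweenness(net)["s1"] == 3.0

    def test_matches_bruteforce_on_random_bipartite_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n_s = int(rng.integers(1, 5))
            n_m = int(rng.integers(1, 9 - n_s))
            edges = []
            for i in range(n_s):
                for j in range(n_m):
                    if rng.random() < 0.5:
                        edges.append((f"s{i}", f"m{j}", (1, 10), (1, 10)))
            if not edges:
                continue
            net = make_network(edges)
            expected = oracle_betweenness(
                set(net.nodes), [(it.srna_id, it.mrna_id) for it in net.interactions]
            )
            got = betweenness(net)
            for n in expected:
                assert got[n] == pytest.approx(expected[n], abs=1e-9)


class TestCoverageCurve:
    def test_two_overlapping_regions(self):
        net = make_network(
            [("s1", "m1", (1, 3), (1, 10)), ("s1", "m2", (2, 5), (1, 10))], srna_len=10
        )
        assert coverage_curve(net, "s1") == [1, 2, 2, 1, 1, 0, 0, 0, 0, 0]

    def test_no_interactions_zero_vector(self):
        net = make_network([("s1", "m1", (1, 3), (1, 10))], srna_len=10)
        assert coverage_curve(net, "m1")[:3] == [1, 1, 1]
        sub = filter_by_score(net, "le", -100.0)
        from srnanet.model import RnaNode

        sub.add_node(RnaNode(id="s1", role="sRNA", length=10))
        assert coverage_curve(sub, "s1") == [0] * 10

    def test_mass_conservation(self, toy_net):
        curve = coverage_curve(toy_net, "ryhB")
        assert sum(curve) == sum(len(it.srna_region) for it in toy_net.interactions)


class TestColorize:
    def test_role_default_two_colors(self, toy_net):
        out = colorize(toy_net)
        cols = {out.nodes[n].attrs["color"] for n in out.nodes}
        assert len(cols) == 2

    def test_constant_measure_single_color(self, toy_net):
        out = colorize(toy_net, {n: 1.0 for n in toy_net.nodes})
        assert len({out.nodes[n].attrs["color"] for n in out.nodes}) == 1

    def test_degree_measure_separates_star_center(self):
        net = make_network([("s1", f"m{i}", (1, 10), (1, 10)) for i in range(3)])
        out = colorize(net, {k: float(v) for k, v in degree(net).items()})
        assert out.nodes["s1"].attrs["color"] != out.nodes["m0"].attrs["color"]


class TestLayout:
    def test_two_columns(self):
        net = make_network([("s1", f"m{i}", (1, 10), (1, 10)) for i in range(3)])
        pos = layout_bipartite(net)
        assert len({p for p in pos.values()}) == 4
        assert {x for x, _ in pos.values()} == {0.0, 1.0}

    def test_empty_net(self):
        assert layout_bipartite(make_network([])) == {}

    def test_disjoint_stars_not_interleaved(self):
        edges = [("s1", f"a{i}", (1, 10), (1, 10)) for i in range(3)]
        edges += [("s2", f"b{i}", (1, 10), (1, 10)) for i in range(3)]
        net = make_network(edges)
        pos = layout_bipartite(net)
        comp1 = [pos[n][1] for n in ["s1", "a0", "a1", "a2"]]
        comp2 = [pos[n][1] for n in ["s2", "b0", "b1", "b2"]]
        assert max(comp1) < min(comp2) or max(comp2) < min(comp1)

    def test_layout_step_writes_attrs(self, toy_net):
        out = apply_layout(toy_net)
        assert all("x" in out.nodes[n].attrs and "y" in out.nodes[n].attrs for n in out.nodes)
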