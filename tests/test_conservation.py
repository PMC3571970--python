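"""Neighbourhood graphs, CCC extraction, TU fates, resampling test."""

import numpy as np
import pytest

from endoreg import conservation_graphs as cg
from endoreg import synthetic_data as sd
from endoreg.genome_model import OrthologyMap, TURecord
from conftest import make_genome
import _oracles


def linear_gene_genome(n, circular=True, prefix="g"):
    genes = [(f"{prefix}{i}", i * 10, i * 10 + 8, "+", "coding") for i in range(n)]
    return make_genome("A" * (10 * n), genes=genes, circular=circular)


class TestNeighbourhoodGraphs:
    def test_three_consecutive_genes_complete(self):
        g = cg.genome_neighbourhood_graph(linear_gene_genome(3), max_gap=5).graph
        assert g.number_of_edges() == 3

    def test_gap_beyond_threshold_no_edge(self):
        genome = linear_gene_genome(20, circular=False)
        g = cg.genome_neighbourhood_graph(genome, max_gap=5).graph
        assert not g.has_edge("g0", "g7")   # 6 genes between
        assert g.has_edge("g0", "g6")       # 5 genes between

    def test_circular_wrap_edge(self):
        genome = linear_gene_genome(30)
        g = cg.genome_neighbourhood_graph(genome, max_gap=5).graph
        assert g.has_edge("g29", "g0")
        assert g.has_edge("g27", "g2")

    def test_network_path_expansion(self):
        g = cg.network_neighbourhood_graph([("a", "b"), ("b", "c")], 1).graph
        assert set(map(frozenset, g.edges)) == {
            frozenset(e) for e in [("a", "b"), ("b", "c"), ("a", "c")]
        }

    def test_two_intermediates_not_neighbours(self):
        g = cg.network_neighbourhood_graph(
            [("a", "b"), ("b", "c"), ("c", "d")], 1).graph
        assert not g.has_edge("a", "d")

    def test_empty_network(self):
        assert cg.network_neighbourhood_graph([], 1).graph.number_of_edges() == 0


class TestCommonConnectedComponents:
    def test_identical_graphs_give_ordinary_components(self):
        import networkx as nx

        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        g.add_node("lone")
        comps = cg.common_connected_components(g, g.copy())
        assert {c.gene_set for c in comps} == {
            frozenset({"a", "b", "c"}), frozenset({"x", "y"})
        }

    def test_refinement_splits_on_second_graph(self):
        import networkx as nx

        g1 = nx.Graph([("a", "b"), ("b", "c")])
        g2 = nx.Graph([("a", "b")])
        g2.add_node("c")
        comps = cg.common_connected_components(g1, g2)
        assert {c.gene_set for c in comps} == {frozenset({"a", "b"})}

    def test_matches_brute_force_on_random_graph_pairs(self, rng):
        import networkx as nx

        for _ in range(30):
            nodes = list(range(20))
            e1 = [(int(u), int(v)) for u, v in
                  rng.integers(0, 20, size=(30, 2)) if u != v]
            e2 = [(int(u), int(v)) for u, v in
                  rng.integers(0, 20, size=(30, 2)) if u != v]
            g1, g2 = nx.Graph(e1), nx.Graph(e2)
            g1.add_nodes_from(nodes)
            g2.add_nodes_from(nodes)
            got = {c.gene_set for c in cg.common_connected_components(g1, g2)}
            want = _oracles.brute_force_ccc(nodes, e1, e2)
            assert got == want

    def test_components_connected_in_both_graphs(self, rng):
        import networkx as nx

        e1 = [(int(u), int(v)) for u, v in rng.integers(0, 15, size=(25, 2)) if u != v]
        e2 = [(int(u), int(v)) for u, v in rng.integers(0, 15, size=(25, 2)) if u != v]
        g1, g2 = nx.Graph(e1), nx.Graph(e2)
        comps = cg.common_connected_components(g1, g2)
        seen = set()
        for c in comps:
            assert len(c.gene_set) >= 2
            assert not (c.gene_set & seen)  # disjoint
            seen |= c.gene_set
            assert nx.is_connected(g1.subgraph(c.gene_set))
            assert nx.is_connected(g2.subgraph(c.gene_set))


class TestComponentConservation:
    def test_consecutive_orthologs_conserved(self):
        anc = linear_gene_genome(10)
        desc = linear_gene_genome(10, prefix="d")
        orth = OrthologyMap.from_pairs((f"g{i}", f"d{i}") for i in range(10))
        res = cg.component_conservation([frozenset({"g1", "g2", "g3"})], desc, orth)
        assert res[0]["testable"] and res[0]["conserved_as_component"]

    def test_single_surviving_ortholog_not_testable(self):
        anc = linear_gene_genome(10)
        desc = linear_gene_genome(10, prefix="d")
        orth = OrthologyMap.from_pairs([("g1", "d1")])
        res = cg.component_conservation([frozenset({"g1", "g2"})], desc, orth)
        assert not res[0]["testable"]

    def test_distant_orthologs_not_conserved(self):
        desc = linear_gene_genome(30, prefix="d", circular=False)
        orth = OrthologyMap.from_pairs([("g0", "d0"), ("g1", "d20")])
        res = cg.component_conservation([frozenset({"g0", "g1"})], desc, orth)
        assert res[0]["testable"] and not res[0]["conserved_as_component"]

    def test_accounting_identity(self, rng):
        """#testable >= #conserved on random component sets."""
        desc = linear_gene_genome(40, prefix="d")
        orth = OrthologyMap.from_pairs((f"g{i}", f"d{i}") for i in range(40))
        comps = [frozenset(f"g{int(i)}" for i in
                           rng.choice(40, size=rng.integers(2, 6), replace=False))
                 for _ in range(20)]
        res = cg.component_conservation(comps, desc, orth)
        assert sum(r["testable"] for r in res) >= sum(
            r["conserved_as_component"] for r in res)


class TestTUFates:
    def _setup(self):
        anc_tus = [TURecord("A1", ("a", "b", "c"), "+"),
                   TURecord("A2", ("x", "y"), "+")]
        orth = OrthologyMap.from_pairs(
            [("a", "da"), ("b", "db"), ("c", "dc"), ("x", "dx"), ("y", "dy")]
        )
        return anc_tus, orth

    def test_identical(self):
        anc_tus, orth = self._setup()
        tu = TURecord("D1", ("da", "db", "dc"), "+")
        assert cg.classify_tu_fate(tu, anc_tus, orth).fate == "identical"

    def test_similar_after_gene_loss(self):
        anc_tus, orth = self._setup()
        orth = OrthologyMap.from_pairs([("a", "da"), ("b", "db"), ("x", "dx")])
        tu = TURecord("D1", ("da", "db"), "+")
        assert cg.classify_tu_fate(tu, anc_tus, orth).fate == "similar"

    def test_merged_from_two_ancestral_tus(self):
        anc_tus, orth = self._setup()
        tu = TURecord("D1", ("da", "dx"), "+")
        assert cg.classify_tu_fate(tu, anc_tus, orth).fate == "merged_reorganized"

    def test_split_across_descendant_tus(self):
        anc_tus, orth = self._setup()
        tus_desc = [TURecord("D1", ("da", "db"), "+"),
                    TURecord("D2", ("dc", "dx"), "+")]
        fates = {f.tu_id: f.fate for f in
                 cg.classify_tu_fates(tus_desc, anc_tus, orth)}
        assert fates["D1"] == "split"
        assert fates["D2"] == "merged_reorganized"

    def test_monocistronic_and_unclassifiable(self):
        anc_tus, orth = self._setup()
        assert cg.classify_tu_fate(
            TURecord("D1", ("da",), "+"), anc_tus, orth).fate == "monocistronic"
        assert cg.classify_tu_fate(
            TURecord("D2", ("q1", "q2"), "+"), anc_tus, orth
        ).fate == "unclassifiable"


@pytest.fixture(scope="module")
def planted_setup():
    spec = sd.buchnera_like(seed=17, n_genes_ancestor=400,
                            n_transcriptons_planted=20)
    anc, nets, tr = sd.generate_ancestor(spec)
    desc, orth = sd.derive_descendant(anc, spec, planted=tr)
    gg = cg.genome_neighbourhood_graph(anc, 5)
    ng = cg.network_neighbourhood_graph(nets["transcription"], 1)
    comps = cg.common_connected_components(gg, ng)
    cons = cg.component_conservation(comps, desc, orth, 5)
    observed = sum(c["conserved_as_component"] for c in cons)
    sizes = [len(t) for t in tr]
    return anc, desc, orth, sizes, observed


class TestResamplingTest:
    def test_perfect_conservation_gives_p_one(self):
        anc = linear_gene_genome(60)
        orth = OrthologyMap.from_pairs((f"g{i}", f"g{i}") for i in range(60))
        res = cg.r_transcripton_test(
            anc, [2, 3], orth, anc, observed_statistic=0,
            n_sims=20, cap=10, seed=3,
        )
        # every retained r-transcripton is conserved when nothing moved
        assert res.p_value == 1.0
        assert all(s > 0 for s in res.null_statistics)

    def test_deterministic_and_relabel_invariant(self, planted_setup):
        anc, desc, orth, sizes, observed = planted_setup
        r1 = cg.r_transcripton_test(anc, sizes, orth, desc, observed, n_sims=50,
                                    seed=9)
        r2 = cg.r_transcripton_test(anc, sizes, orth, desc, observed, n_sims=50,
                                    seed=9)
        assert r1.null_statistics == r2.null_statistics
        assert r1.p_value == r2.p_value

    def test_planted_conservation_is_significant(self, planted_setup):
        anc, desc, orth, sizes, observed = planted_setup
        assert observed >= 18  # planted neighbourhoods survived
        res = cg.r_transcripton_test(anc, sizes, orth, desc, observed,
                                     n_sims=100, seed=23)
        assert res.p_value <= 0.01
        assert res.p_value == np.mean(
            np.asarray(res.null_statistics) >= observed)

    def test_invalid_arguments(self, planted_setup):
        anc, desc, orth, sizes, observed = planted_setup
        with pytest.raises(ValueError):
            cg.r_transcripton_test(anc, sizes, orth, desc, observed, n_sims=0)
        with pytest.raises(ValueError):
            cg.r_transcripton_test(anc, sizes, orth, desc, observed, cap=0)
        with pytest.raises(ValueError):
            cg.r_transcripton_test(anc, [], orth, desc, observed)
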