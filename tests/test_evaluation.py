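import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from topas.core import Module
from topas.evaluation import (
    bh_fdr,
    connector_recall,
    degree_aware_sample,
    evaluate_module,
    gene_annotations,
    jaccard,
    lcc_significance,
    overlap_coefficient,
    pathway_relevance,
    read_gmt,
    read_partition,
    records_to_tsv,
    seed_connector_ratio,
    seed_recovery_rate,
)

from .oracles import bh_stepup_reference


def _module(seed_edges, seeds, connectors):
    g = nx.Graph(seed_edges)
    g.add_nodes_from(seeds | connectors)
    return Module(seeds=set(seeds), connectors=set(connectors), graph=g)


class TestScoringMetrics:
    def test_full_recovery(self):
        seeds = {f"s{i}" for i in range(10)}
        module = _module([(f"s{i}", f"s{i+1}") for i in range(9)], seeds, set())
        assert seed_recovery_rate(module, seeds) == 1.0

    def test_partial_recovery(self):
        in_module = {f"s{i}" for i in range(7)}
        module = _module([(f"s{i}", f"s{i+1}") for i in range(6)], in_module, set())
        connectable = {f"s{i}" for i in range(10)}
        assert seed_recovery_rate(module, connectable) == pytest.approx(0.7)

    def test_disjoint_is_zero(self):
        module = _module([("a", "b")], {"a", "b"}, set())
        assert seed_recovery_rate(module, {"z1", "z2"}) == 0.0

    def test_empty_connectable_errors(self):
        module = _module([("a", "b")], {"a", "b"}, set())
        with pytest.raises(ValueError):
            seed_recovery_rate(module, set())

    def test_srr_scores_largest_component_only(self):
        # 2 seeds connected, 1 seed stranded: largest component holds 2 of 3
        module = _module([("s1", "s2")], {"s1", "s2", "s3"}, set())
        assert seed_recovery_rate(module, {"s1", "s2", "s3"}) == pytest.approx(2 / 3)

    @staticmethod
    def _connected_module(n_seeds, n_conns):
        seeds = {f"s{i:02d}" for i in range(n_seeds)}
        conns = {f"c{i:02d}" for i in range(n_conns)}
        edges = [(f"s{i:02d}", f"c{i % n_conns:02d}") for i in range(n_seeds)]
        edges += [(f"c{i:02d}", f"c{i + 1:02d}") for i in range(n_conns - 1)]
        return _module(edges, seeds, conns)

    def test_scr_counts(self):
        assert seed_connector_ratio(self._connected_module(10, 8)) == pytest.approx(1.25)

    def test_scr_larger_module(self):
        assert seed_connector_ratio(self._connected_module(22, 15)) == pytest.approx(22 / 15)

    def test_scr_undefined_without_connectors(self):
        module = _module([("s1", "s2")], {"s1", "s2"}, set())
        assert seed_connector_ratio(module) is None

    def test_connector_recall(self):
        module = _module([("s", "c1"), ("s", "c2")], {"s"}, {"c1", "c2"})
        assert connector_recall(module, {"c1", "c3"}) == pytest.approx(0.5)

    def test_evaluate_module_record_and_tsv(self, tmp_path):
        module = _module([("s1", "c1"), ("c1", "s2")], {"s1", "s2"}, {"c1"})
        rec = evaluate_module(module, {"s1", "s2"}, method="toy")
        assert rec.srr == 1.0 and rec.scr == pytest.approx(2.0)
        bare = evaluate_module(_module([("s1", "s2")], {"s1", "s2"}, set()), {"s1", "s2"})
        out = tmp_path / "records.tsv"
        records_to_tsv([rec, bare], out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("method\tgene_set\tnetwork\tsrr\tscr")
        assert "\tNA\t" in lines[2]


class TestOverlapCoefficients:
    def test_jaccard_examples(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert jaccard(set(), set()) == 0.0

    def test_overlap_examples(self):
        assert overlap_coefficient({"a"}, {"a", "b", "c"}) == 1.0
        assert overlap_coefficient({"a"}, {"b"}) == 0.0
        assert overlap_coefficient({"a", "b"}, {"b", "c"}) == 0.5

    def test_overlap_empty_operand_errors(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})

    @settings(derandomize=True, max_examples=200)
    @given(st.sets(st.integers(0, 20), min_size=1), st.sets(st.integers(0, 20), min_size=1))
    def test_jaccard_never_exceeds_overlap(self, a, b):
        assert jaccard(a, b) <= overlap_coefficient(a, b) + 1e-12


class TestDegreeAwareSampling:
    def test_sample_size_and_distinctness(self):
        net = nx.barabasi_albert_graph(200, 2, seed=1)
        net = nx.relabel_nodes(net, {i: str(i) for i in net.nodes})
        template = set(list(net.nodes)[:17])
        sample = degree_aware_sample(net, template, np.random.default_rng(0), bin_size=30)
        assert len(sample) == 17

    def test_regular_graph_is_a_single_bin(self):
        net = nx.cycle_graph([str(i) for i in range(30)])
        sample = degree_aware_sample(net, {"0", "1", "2"}, np.random.default_rng(4), bin_size=100)
        assert len(sample) == 3
        assert sample <= set(net.nodes)

    def test_reproducible_given_seed(self):
        net = nx.barabasi_albert_graph(100, 2, seed=2)
        net = nx.relabel_nodes(net, {i: str(i) for i in net.nodes})
        template = set(list(net.nodes)[:10])
        s1 = degree_aware_sample(net, template, np.random.default_rng(9))
        s2 = degree_aware_sample(net, template, np.random.default_rng(9))
        assert s1 == s2

    def test_template_outside_network_errors(self):
        with pytest.raises(KeyError):
            degree_aware_sample(nx.path_graph(["a", "b"]), {"z"}, np.random.default_rng(0))


class TestLccSignificance:
    def test_planted_clique_is_significant(self):
        net = nx.barabasi_albert_graph(500, 2, seed=0)
        net = nx.relabel_nodes(net, {i: f"g{i:03d}" for i in net.nodes})
        clique = [f"g{i:03d}" for i in range(40, 48)]
        net.add_edges_from((a, b) for i, a in enumerate(clique) for b in clique[i + 1:])
        null = lcc_significance(net, clique, n_samples=500, seed=0)
        assert null.observed == 8.0
        assert null.p_value <= 0.01

    def test_single_gene_errors(self):
        net = nx.path_graph(["a", "b", "c"])
        with pytest.raises(ValueError):
            lcc_significance(net, {"a"}, n_samples=10, seed=0)

    def test_deterministic_given_seed(self):
        net = nx.barabasi_albert_graph(150, 2, seed=3)
        net = nx.relabel_nodes(net, {i: str(i) for i in net.nodes})
        genes = set(list(net.nodes)[:12])
        a = lcc_significance(net, genes, n_samples=100, seed=5)
        b = lcc_significance(net, genes, n_samples=100, seed=5)
        assert a.p_value == b.p_value
        assert np.array_equal(a.samples, b.samples)

    def test_pvalue_in_unit_interval_and_never_zero(self):
        net = nx.barabasi_albert_graph(150, 2, seed=3)
        net = nx.relabel_nodes(net, {i: str(i) for i in net.nodes})
        genes = set(list(net.nodes)[:10])
        null = lcc_significance(net, genes, n_samples=50, seed=1)
        assert 0.0 < null.p_value <= 1.0


class TestBhFdr:
    def test_textbook_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_equal_stay_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_stepup_reference(self, seed):
        rng = np.random.default_rng(seed)
        ps = rng.uniform(size=rng.integers(1, 30)).tolist()
        assert bh_fdr(ps) == pytest.approx(bh_stepup_reference(ps))


class TestPathwayRelevance:
    @staticmethod
    def _setup():
        net = nx.barabasi_albert_graph(120, 2, seed=6)
        net = nx.relabel_nodes(net, {i: f"g{i:03d}" for i in net.nodes})
        nodes = sorted(net.nodes)[:8]
        seeds, conns = set(nodes[:4]), set(nodes[4:])
        g = net.subgraph(nodes).copy()
        g.add_edges_from(zip(nodes, nodes[1:]))
        module = Module(seeds=seeds, connectors=conns, graph=g)
        net.add_edges_from(g.edges)
        return net, module, nodes

    def test_identical_terms_give_ji_one_and_significance(self):
        net, module, nodes = self._setup()
        partition = {n: "c1" for n in nodes}
        annotations = {n: {"T1", "T2"} for n in nodes}
        results = pathway_relevance(module, partition, annotations, net, n_samples=200, seed=0)
        (rec,) = results
        assert rec.testable and rec.jaccard == 1.0
        assert rec.p_adjusted is not None

    def test_eight_of_nine_term_overlap(self):
        net, module, nodes = self._setup()
        partition = {n: "c1" for n in nodes}
        seed_terms = {f"T{i}" for i in range(8)}
        conn_terms = seed_terms | {"T8"}
        annotations = {n: set(seed_terms) for n in nodes[:4]}
        annotations.update({n: set(conn_terms) for n in nodes[4:]})
        results = pathway_relevance(module, partition, annotations, net, n_samples=50, seed=0)
        assert results[0].jaccard == pytest.approx(8 / 9)

    def test_unannotated_connectors_are_untestable(self):
        net, module, nodes = self._setup()
        partition = {n: ("c1" if n in module.seeds else "c2") for n in nodes}
        annotations = {n: {"T1"} for n in module.seeds}
        results = pathway_relevance(module, partition, annotations, net, n_samples=20, seed=0)
        assert all(not r.testable for r in results)
        assert all(r.p_value is None for r in results)

    def test_partition_must_cover_module(self):
        net, module, nodes = self._setup()
        with pytest.raises(ValueError, match="cover"):
            pathway_relevance(module, {nodes[0]: "c1"}, {nodes[0]: {"T"}}, net, n_samples=5, seed=0)

    def test_empty_annotations_error(self):
        net, module, nodes = self._setup()
        with pytest.raises(ValueError):
            pathway_relevance(module, {n: "c1" for n in nodes}, {}, net, n_samples=5, seed=0)


class TestAnnotationIO:
    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "terms.gmt"
        p.write_text("T1\tdesc one\tg1\tg2\nT2\tdesc two\tg2\tg3\n")
        terms = read_gmt(p)
        assert terms == {"T1": {"g1", "g2"}, "T2": {"g2", "g3"}}
        annot = gene_annotations(terms)
        assert annot["g2"] == {"T1", "T2"}

    def test_gmt_short_row_errors(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("T1\tonly-description\n")
        with pytest.raises(ValueError):
            read_gmt(p)

    def test_partition_reader(self, tmp_path):
        p = tmp_path / "clusters.tsv"
        p.write_text("g1\tc1\ng2\tc1\ng3\tc2\n")
        assert read_partition(p) == {"g1": "c1", "g2": "c1", "g3": "c2"}
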