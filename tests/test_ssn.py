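from itertools import combinations

import numpy as np
import pytest

from baiminer import orf_search as osr
from baiminer import ssn
from baiminer import synthetic_data as sd
from baiminer.io_formats import SequenceRecord


def make_result(e_value: float) -> osr.AlignmentResult:
    return osr.AlignmentResult("q", "s", 100, 50.0, e_value, 90.0, 95.0, 100)


class TestAlignmentScore:
    def test_definition(self):
        assert ssn.alignment_score(make_result(1e-70)) == pytest.approx(70.0)
        assert ssn.alignment_score(make_result(1.0)) == pytest.approx(0.0)

    def test_underflow_clamped(self):
        assert ssn.alignment_score(make_result(1e-320)) == 300.0

    def test_monotone_in_e_value(self):
        rng = np.random.default_rng(0)
        evals = 10.0 ** rng.uniform(-200, 2, size=100)
        scores = [ssn.alignment_score(make_result(e)) for e in evals]
        order = np.argsort(evals)
        sorted_scores = np.array(scores)[order]
        assert all(np.diff(sorted_scores) <= 1e-12)


class TestBuildSSN:
    def test_identical_pair_edge(self):
        p = sd.random_protein(177, np.random.default_rng(1), "p1")
        q = SequenceRecord("p2", p.seq, "protein")
        graph = ssn.build_ssn([p, q], threshold=70.0)
        assert set(graph.edges) == {("p1", "p2")}

    def test_two_families_separate_at_70(self):
        rng = np.random.default_rng(2)
        anc_a = sd.random_protein(177, rng, "fa")
        fam_a = sd.mutate_family(sd.FamilySpec(anc_a, 4, 0.95, seed=1))
        anc_b = sd.mutate_family(sd.FamilySpec(anc_a, 1, 0.40, seed=2))[0]
        anc_b = SequenceRecord("fb", anc_b.seq, "protein")
        fam_b = sd.mutate_family(sd.FamilySpec(anc_b, 4, 0.95, seed=3))
        graph = ssn.build_ssn(fam_a + fam_b, threshold=70.0)
        ids_a = {m.id for m in fam_a}
        for a, b in graph.edges:
            assert (a in ids_a) == (b in ids_a), "between-family edge found"

    def test_threshold_zero_complete_on_family(self):
        anc = sd.random_protein(150, np.random.default_rng(4), "anc")
        fam = sd.mutate_family(sd.FamilySpec(anc, 5, 0.9, seed=5))
        graph = ssn.build_ssn(fam, threshold=0.0)
        assert len(graph.edges) == 5 * 4 // 2

    def test_edges_require_build_threshold(self):
        with pytest.raises(ValueError):
            ssn.SSNGraph(frozenset({"a", "b"}), {("a", "b"): 10.0}, threshold=70.0)


class TestComponents:
    def test_edgeless_graph_gives_singletons(self):
        graph = ssn.SSNGraph(frozenset(f"n{i}" for i in range(5)), {}, threshold=70.0)
        clusters = ssn.components(graph)
        assert len(clusters) == 5
        assert all(len(c.members) == 1 for c in clusters)
        assert all(c.min_within_identity == 100.0 for c in clusters)

    def test_planted_partition_recovered(self, three_families):
        members, planted = three_families
        graph = ssn.build_ssn(members, threshold=70.0)
        clusters = ssn.components(graph)
        got = {}
        for c in clusters:
            for m in c.members:
                got[m] = c.cluster_id
        for a, b in combinations(sorted(planted), 2):
            assert (planted[a] == planted[b]) == (got[a] == got[b])

    def test_partition_property(self, three_families):
        members, _ = three_families
        graph = ssn.build_ssn(members, threshold=70.0)
        clusters = ssn.components(graph)
        seen = [m for c in clusters for m in c.members]
        assert sorted(seen) == sorted(graph.nodes)
        assert len(seen) == len(set(seen))

    def test_raising_threshold_refines(self, three_families):
        members, _ = three_families
        alns = ssn.all_vs_all(members)
        low = ssn.components(ssn.build_ssn(members, threshold=50.0, alignments=alns))
        high = ssn.components(ssn.build_ssn(members, threshold=150.0, alignments=alns))
        low_of = {m: c.cluster_id for c in low for m in c.members}
        for c in high:
            assert len({low_of[m] for m in c.members}) == 1

    def test_contains_query_flag(self, three_families):
        members, planted = three_families
        graph = ssn.build_ssn(members, threshold=70.0)
        query = members[0].id
        clusters = ssn.components(graph, query_ids=frozenset({query}))
        for c in clusters:
            assert c.contains_query == (query in c.members)


class TestClusterReport:
    def test_all_identical_family(self):
        p = sd.random_protein(177, np.random.default_rng(6), "p")
        fam = [SequenceRecord(f"c{i}", p.seq, "protein") for i in range(3)]
        graph = ssn.build_ssn(fam, threshold=70.0)
        clusters = ssn.components(graph)
        report = ssn.cluster_report(clusters, graph.alignments)
        assert report.loc[0, "min_within_identity"] == 100.0

    def test_min_identity_matches_brute_force(self, three_families):
        members, _ = three_families
        by_id = {m.id: m for m in members}
        graph = ssn.build_ssn(members, threshold=70.0)
        clusters = ssn.components(graph)
        report = ssn.cluster_report(clusters, graph.alignments)
        for c in clusters:
            if len(c.members) < 2:
                continue
            brute = min(
                osr.local_align(by_id[a], by_id[b]).pct_identity
                for a, b in combinations(sorted(c.members), 2)
            )
            row = report[report["cluster_id"] == c.cluster_id].iloc[0]
            assert row["min_within_identity"] == pytest.approx(brute, abs=3.0)

    def test_sorted_by_size_descending(self, three_families):
        members, _ = three_families
        extra = sd.random_protein(177, np.random.default_rng(7), "lone")
        graph = ssn.build_ssn(members + [extra], threshold=70.0)
        report = ssn.cluster_report(ssn.components(graph))
        sizes = report["size"].tolist()
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 1  # the singleton is retained


class TestExports:
    def test_edgelist_and_graphml(self, tmp_path, three_families):
        members, _ = three_families
        graph = ssn.build_ssn(members[:8], threshold=70.0)
        ssn.write_edgelist(graph, tmp_path / "edges.tsv")
        ssn.write_graphml(graph, tmp_path / "graph.graphml")
        import networkx as nx

        back = nx.read_graphml(tmp_path / "graph.graphml")
        assert back.number_of_edges() == len(graph.edges)
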