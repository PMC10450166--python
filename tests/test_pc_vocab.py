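import math

import networkx as nx
import numpy as np
import pytest

from plasmeld.align import AlignmentHit, ProteinAligner
from plasmeld.pc_vocab import (
    MASK_TOKEN,
    UNKNOWN_TOKEN,
    PCAssignThresholds,
    PCVocabulary,
    all_vs_all_hits,
    assign_pc,
    build_protein_graph,
    filter_clusters,
    mcl_cluster,
)
from plasmeld.seqio import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein(pid, seq):
    contig, idx = pid.rsplit("_", 1)
    return ProteinRecord(contig, int(idx), 1, 3 * len(seq), "+", seq)


def random_protein(rng, n):
    return "M" + "".join(rng.choice(list(AA), size=n - 1))


def hit(q, s, evalue, bitscore=50.0):
    return AlignmentHit(q, s, 90.0, 100, evalue, bitscore, 1, 100, 1, 100, 90.0)


# ---------------------------------------------------------------- MCL oracle


def mcl_oracle(graph: nx.Graph, inflation: float = 2.0) -> set[frozenset]:
    """Independent dense-matrix MCL run to convergence: explicit loops,
    no shared code with the implementation under test."""
    names = sorted(graph.nodes)
    n = len(names)
    if n == 0:
        return set()
    lookup = {v: i for i, v in enumerate(names)}
    M = [[0.0] * n for _ in range(n)]
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        M[lookup[a]][lookup[b]] = w
        M[lookup[b]][lookup[a]] = w
    for i in range(n):
        M[i][i] = 1.0
    for j in range(n):
        colsum = sum(M[i][j] for i in range(n))
        for i in range(n):
            M[i][j] /= colsum
    for _ in range(10_000):
        prev = [row[:] for row in M]
        # expansion: M @ M
        newM = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)] for i in range(n)]
        # inflation + column renormalization
        newM = [[x**inflation for x in row] for row in newM]
        for j in range(n):
            colsum = sum(newM[i][j] for i in range(n)) or 1.0
            for i in range(n):
                newM[i][j] /= colsum
        M = newM
        if max(abs(M[i][j] - prev[i][j]) for i in range(n) for j in range(n)) < 1e-6:
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if M[i][j] > 1e-6:
                support.add_edge(i, j)
    return {
        frozenset(names[i] for i in comp) for comp in nx.connected_components(support)
    }


def as_partition_set(partition):
    return {frozenset(c) for c in partition}


class TestMCL:
    def test_two_disconnected_cliques(self):
        g = nx.Graph()
        for offset, names in enumerate((list("abc"), list("def"))):
            for i, u in enumerate(names):
                for v in names[i + 1 :]:
                    g.add_edge(u, v, weight=1.0)
        clusters = as_partition_set(mcl_cluster(g))
        assert clusters == {frozenset("abc"), frozenset("def")}

    def test_bridged_cliques_split_at_bridge(self):
        g = nx.Graph()
        left, right = list("abcd"), list("efgh")
        for names in (left, right):
            for i, u in enumerate(names):
                for v in names[i + 1 :]:
                    g.add_edge(u, v, weight=1.0)
        g.add_edge("d", "e", weight=1.0)
        ours = as_partition_set(mcl_cluster(g))
        assert ours == mcl_oracle(g)
        assert ours == {frozenset(left), frozenset(right)}

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("solo")
        assert as_partition_set(mcl_cluster(g)) == {frozenset(["solo"])}

    def test_is_partition_and_respects_components(self, rng):
        g = nx.gnp_random_graph(15, 0.2, seed=4)
        clusters = mcl_cluster(g)
        all_nodes = [n for c in clusters for n in c]
        assert sorted(all_nodes) == sorted(g.nodes)
        assert len(all_nodes) == len(set(all_nodes))
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        for cluster in clusters:
            assert len({comp_of[n] for n in cluster}) == 1

    def test_oracle_equivalence_100_random_graphs(self):
        mismatches = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.7)), seed=seed)
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.integers(1, 6))
            if as_partition_set(mcl_cluster(g)) != mcl_oracle(g):
                mismatches.append(seed)
        assert mismatches == []

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.Graph(), inflation=1.0)

    def test_nonconvergence_warns(self):
        g = nx.path_graph(6)
        with pytest.warns(UserWarning, match="did not converge"):
            mcl_cluster(g, max_iter=1)


class TestBuildProteinGraph:
    def test_min_evalue_rule(self):
        g = build_protein_graph([hit("A", "B", 1e-10), hit("B", "A", 1e-8)])
        assert list(g.edges) == [("A", "B")]
        assert g["A"]["B"]["weight"] == pytest.approx(10.0)

    def test_threshold_is_1e_minus_5(self):
        g = build_protein_graph([hit("A", "B", 1e-4)])
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B"}
        g2 = build_protein_graph([hit("A", "B", 1e-5)])
        assert g2.number_of_edges() == 1

    def test_empty_hits_isolated_nodes(self):
        g = build_protein_graph([], nodes=["x", "y"])
        assert set(g.nodes) == {"x", "y"} and g.number_of_edges() == 0

    def test_no_self_loops(self):
        g = build_protein_graph([hit("A", "A", 1e-50), hit("A", "B", 1e-50)])
        assert list(g.edges) == [("A", "B")]

    def test_weight_capped_at_zero_evalue(self):
        g = build_protein_graph([hit("A", "B", 0.0)])
        assert g["A"]["B"]["weight"] == pytest.approx(200.0)


class TestAllVsAll:
    def test_identical_pair_reciprocal_full_identity(self, rng):
        seq = random_protein(rng, 100)
        hits = all_vs_all_hits([protein("a_0", seq), protein("b_0", seq)])
        assert {(h.query_id, h.subject_id) for h in hits} == {("a_0", "b_0"), ("b_0", "a_0")}
        assert all(h.pct_identity == pytest.approx(100.0) for h in hits)

    def test_unrelated_proteins_rarely_hit(self, rng):
        proteins = [protein(f"p{i}_0", random_protein(rng, 90)) for i in range(6)]
        hits = all_vs_all_hits(proteins)
        assert all(h.evalue > 1e-5 for h in hits)

    def test_requires_two_proteins(self, rng):
        with pytest.raises(ValueError):
            all_vs_all_hits([protein("a_0", random_protein(rng, 50))])


class TestFilterClusters:
    def test_singletons_dropped(self):
        vocab = filter_clusters([{"a", "b", "c"}, {"d"}])
        assert set(vocab.clusters) == {2}
        assert vocab.clusters[2] == ["a", "b", "c"]

    def test_all_singletons_empty_vocabulary(self):
        vocab = filter_clusters([{"a"}, {"b"}])
        assert len(vocab) == 0 and vocab.n_tokens == 2

    def test_token_ids_by_decreasing_size(self):
        vocab = filter_clusters([{"x", "y"}, {"a", "b", "c"}])
        assert vocab.clusters[2] == ["a", "b", "c"]
        assert vocab.clusters[3] == ["x", "y"]

    def test_tie_break_lexicographic_smallest_member(self):
        vocab = filter_clusters([{"m", "n"}, {"a", "z"}])
        assert vocab.clusters[2] == ["a", "z"]
        assert vocab.clusters[3] == ["m", "n"]

    def test_representative_longest_then_smallest_id(self):
        seqs = {"a": "MAAAA", "b": "MAA", "c": "MAAAA"}
        vocab = filter_clusters([{"a", "b", "c"}], seqs)
        assert vocab.representatives[2] == "a"  # longest, ties to smaller id

    def test_deterministic_under_input_order(self, rng):
        clusters = [{"a", "b"}, {"c", "d", "e"}, {"f", "g"}]
        seqs = {k: "M" + "A" * (i + 3) for i, k in enumerate("abcdefg")}
        v1 = filter_clusters(clusters, seqs)
        v2 = filter_clusters(list(reversed(clusters)), seqs)
        assert v1.clusters == v2.clusters
        assert v1.representatives == v2.representatives

    def test_save_load_roundtrip(self, tmp_path, rng):
        seqs = {"a_0": random_protein(rng, 50), "b_0": random_protein(rng, 60)}
        vocab = filter_clusters([{"a_0", "b_0"}], seqs)
        vocab.save(tmp_path / "v.tsv", tmp_path / "v.fasta")
        back = PCVocabulary.load(tmp_path / "v.tsv", tmp_path / "v.fasta")
        assert back.clusters == vocab.clusters
        assert back.representatives == vocab.representatives
        assert back.representative_seq(2) == vocab.representative_seq(2)


class _StubAligner:
    """Returns pre-scripted hits keyed by subject id."""

    def __init__(self, hits_by_subject):
        self.hits_by_subject = hits_by_subject

    def align_pair(self, qid, qseq, sid, sseq, search_space=None):
        return self.hits_by_subject.get(sid)


def _stub_vocab(n_clusters):
    clusters = {2 + i: [f"rep{i}", f"mem{i}"] for i in range(n_clusters)}
    reps = {2 + i: f"rep{i}" for i in range(n_clusters)}
    seqs = {f"rep{i}": "M" + "A" * 40 for i in range(n_clusters)}
    return PCVocabulary(clusters, reps, seqs)


def _good_hit(sid, bitscore, evalue=1e-20):
    return AlignmentHit("q", sid, 95.0, 40, evalue, bitscore, 1, 40, 1, 40, 95.0)


class TestAssignPC:
    def test_identical_to_representative(self, rng):
        seq = random_protein(rng, 120)
        vocab = PCVocabulary({7: ["r7", "m7"]}, {7: "r7"}, {"r7": seq})
        assert assign_pc(protein("q_0", seq), vocab) == 7

    def test_random_protein_unknown(self, rng):
        vocab = PCVocabulary(
            {2: ["r", "m"]}, {2: "r"}, {"r": random_protein(rng, 100)}
        )
        assert assign_pc(protein("q_0", random_protein(rng, 100)), vocab) == UNKNOWN_TOKEN

    def test_best_bitscore_wins(self):
        vocab = _stub_vocab(10)
        stub = _StubAligner({"rep3": _good_hit("rep3", 210.0), "rep7": _good_hit("rep7", 180.0)})
        assert assign_pc(protein("q_0", "M" + "A" * 40), vocab, stub) == 5  # rep3 -> token 5

    def test_bitscore_tie_broken_by_evalue_then_token(self):
        vocab = _stub_vocab(4)
        stub = _StubAligner(
            {
                "rep1": _good_hit("rep1", 100.0, evalue=1e-10),
                "rep2": _good_hit("rep2", 100.0, evalue=1e-12),
            }
        )
        assert assign_pc(protein("q_0", "M" + "A" * 40), vocab, stub) == 4  # lower evalue
        stub2 = _StubAligner(
            {
                "rep1": _good_hit("rep1", 100.0),
                "rep2": _good_hit("rep2", 100.0),
            }
        )
        assert assign_pc(protein("q_0", "M" + "A" * 40), vocab, stub2) == 3  # smaller token

    def test_threshold_rejection(self):
        vocab = _stub_vocab(2)
        weak = AlignmentHit("q", "rep0", 20.0, 40, 1e-20, 90.0, 1, 40, 1, 40, 95.0)
        assert assign_pc(protein("q_0", "M" + "A" * 40), vocab, _StubAligner({"rep0": weak})) == UNKNOWN_TOKEN

    def test_empty_vocab_errors(self):
        with pytest.raises(ValueError):
            assign_pc(protein("q_0", "MAA"), PCVocabulary({}, {}))

    def test_member_self_consistency(self, benchmark, fitted):
        # members whose alignment to their own representative passes the
        # thresholds must map back to their own cluster
        vocab = fitted.vocab
        aligner = ProteinAligner()
        thresholds = PCAssignThresholds()
        checked = 0
        for tid in sorted(vocab.clusters)[:10]:
            for member in vocab.clusters[tid][:2]:
                seq = vocab.sequences[member]
                own = aligner.align_pair("m_0", seq, vocab.representatives[tid], vocab.representative_seq(tid))
                if own is None or (
                    own.evalue > thresholds.evalue_max
                    or own.pct_identity < thresholds.identity_min
                    or own.query_cov < thresholds.coverage_min
                ):
                    continue  # invariant only applies when thresholds are met
                rec = ProteinRecord("m", 0, 1, 3 * len(seq), "+", seq)
                assert assign_pc(rec, vocab, aligner) == tid
                checked += 1
        assert checked >= 10
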