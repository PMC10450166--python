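"""Protein-cluster vocabulary: all-vs-all alignment graph -> Markov
clustering -> size filter, plus token assignment for query proteins.

Token id 0 is the mask/padding token and id 1 the unknown token; real
clusters take contiguous ids from 2, ordered by decreasing size (ties by
the lexicographically smallest member id). The representative of a
cluster is its longest member protein.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from plasmeld.align import AlignmentHit, ProteinAligner
from plasmeld.seqio import ProteinRecord, write_fasta, read_fasta

__all__ = [
    "MASK_TOKEN",
    "UNKNOWN_TOKEN",
    "PCAssignThresholds",
    "PCVocabulary",
    "all_vs_all_hits",
    "build_protein_graph",
    "mcl_cluster",
    "filter_clusters",
    "assign_pc",
]

MASK_TOKEN = 0
UNKNOWN_TOKEN = 1

EDGE_WEIGHT_CAP = 200.0


@dataclass(frozen=True)
class PCAssignThresholds:
    """Thresholds a best hit must satisfy for a PC token assignment.

    Stand-ins for stringent production thresholds; tighten via config.
    """

    evalue_max: float = 1e-5
    identity_min: float = 30.0
    coverage_min: float = 50.0


@dataclass
class PCVocabulary:
    """clusters: token id (>= 2) -> sorted member protein ids."""

    clusters: dict[int, list[str]]
    representatives: dict[int, str]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid in self.clusters:
            if tid < 2:
                raise ValueError("cluster token ids start at 2")
            if len(self.clusters[tid]) < 1:
                raise ValueError(f"empty cluster {tid}")

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_tokens(self) -> int:
        """Total token-id space including the two reserved ids."""
        return 2 + len(self.clusters)

    def representative_seq(self, token_id: int) -> str:
        return self.sequences[self.representatives[token_id]]

    def save(self, tsv_path: str | Path, fasta_path: str | Path | None = None) -> None:
        with open(tsv_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["token_id", "representative_id", "member_ids"])
            for tid in sorted(self.clusters):
                w.writerow([tid, self.representatives[tid], ",".join(self.clusters[tid])])
        if fasta_path is not None:
            write_fasta(
                [
                    (self.representatives[tid], self.representative_seq(tid))
                    for tid in sorted(self.clusters)
                ],
                fasta_path,
            )

    @classmethod
    def load(cls, tsv_path: str | Path, fasta_path: str | Path) -> "PCVocabulary":
        seqs = {c.id: c.seq for c in read_fasta(fasta_path)}
        clusters: dict[int, list[str]] = {}
        reps: dict[int, str] = {}
        with open(tsv_path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader)
            for row in reader:
                tid = int(row[0])
                reps[tid] = row[1]
                clusters[tid] = row[2].split(",")
        return cls(clusters, reps, seqs)


def all_vs_all_hits(
    proteins: list[ProteinRecord],
    engine: ProteinAligner | None = None,
    evalue_max: float = 1e-3,
) -> list[AlignmentHit]:
    """All-against-all protein alignment (self-hits excluded).

    The internal engine is symmetric, so each unordered pair is aligned
    once and mirrored; an external engine's tabular output can be used
    instead via :func:`plasmeld.align.read_tabular_hits`.
    """
    if len(proteins) < 2:
        raise ValueError("need >= 2 proteins for all-vs-all alignment")
    engine = engine or ProteinAligner()
    hits: list[AlignmentHit] = []
    for i, p in enumerate(proteins):
        for q in proteins[i + 1 :]:
            hit = engine.align_pair(p.id, p.aa_seq, q.id, q.aa_seq)
            if hit is None or hit.evalue > evalue_max:
                continue
            hits.append(hit)
            hits.append(
                AlignmentHit(
                    query_id=hit.subject_id,
                    subject_id=hit.query_id,
                    pct_identity=hit.pct_identity,
                    length=hit.length,
                    evalue=hit.evalue,
                    bitscore=hit.bitscore,
                    q_start=hit.s_start,
                    q_end=hit.s_end,
                    s_start=hit.q_start,
                    s_end=hit.q_end,
                    query_cov=100.0 * hit.length / max(len(q.aa_seq), 1),
                )
            )
    return hits


def build_protein_graph(
    hits: list[AlignmentHit],
    edge_evalue_max: float = 1e-5,
    nodes: list[str] | None = None,
) -> nx.Graph:
    """Undirected weighted graph: one edge per unordered pair whose best
    (minimum) e-value is <= ``edge_evalue_max``; weight -log10(evalue),
    capped. Self-hits are ignored. ``nodes`` adds isolated vertices."""
    graph = nx.Graph()
    if nodes:
        graph.add_nodes_from(nodes)
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
        graph.add_node(h.query_id)
        graph.add_node(h.subject_id)
    for (a, b), ev in best.items():
        if ev <= edge_evalue_max:
            weight = EDGE_WEIGHT_CAP if ev <= 0 else min(-math.log10(ev), EDGE_WEIGHT_CAP)
            graph.add_edge(a, b, weight=weight)
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    self_loop_weight: float = 1.0,
) -> list[set[str]]:
    """Native Markov clustering.

    Column-normalizes the weighted adjacency with unit self-loops, then
    alternates expansion (matrix squaring) and inflation (elementwise
    power + column renormalization) until the maximum column change
    drops below ``tol``. Clusters are the connected components of the
    converged matrix's support. Warns on non-convergence.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    names = sorted(graph.nodes)
    if not names:
        return []
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    np.fill_diagonal(M, self_loop_weight)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = M**inflation
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; using current matrix")
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > tol)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [
        {names[i] for i in comp} for comp in nx.connected_components(support)
    ]


def filter_clusters(
    partition: list[set[str]],
    proteins: dict[str, str] | None = None,
    min_size: int = 2,
) -> PCVocabulary:
    """Drop clusters below ``min_size``; assign token ids 2, 3, ... by
    decreasing size (ties by smallest member id); representative is the
    longest member (ties by smallest id). ``proteins`` maps protein id
    to amino-acid sequence; without it representatives fall back to the
    smallest member id."""
    kept = [sorted(c) for c in partition if len(c) >= min_size]
    kept.sort(key=lambda members: (-len(members), members[0]))
    clusters: dict[int, list[str]] = {}
    reps: dict[int, str] = {}
    for offset, members in enumerate(kept):
        tid = 2 + offset
        clusters[tid] = members
        if proteins:
            longest = max(len(proteins[m]) for m in members)
            reps[tid] = min(m for m in members if len(proteins[m]) == longest)
        else:
            reps[tid] = members[0]
    return PCVocabulary(clusters, reps, dict(proteins) if proteins else {})


def assign_pc(
    protein: ProteinRecord,
    vocab: PCVocabulary,
    engine: ProteinAligner | None = None,
    thresholds: PCAssignThresholds = PCAssignThresholds(),
) -> int:
    """Token id for a query protein: best representative hit by bitscore
    (ties by lower e-value, then smaller token id) if it satisfies the
    assignment thresholds; otherwise the unknown token (1)."""
    if not vocab.clusters:
        raise ValueError("empty vocabulary")
    engine = engine or ProteinAligner()
    best: tuple[float, float, int] | None = None  # (-bitscore, evalue, token_id)
    for tid in sorted(vocab.clusters):
        hit = engine.align_pair(
            protein.id, protein.aa_seq, vocab.representatives[tid], vocab.representative_seq(tid)
        )
        if hit is None:
            continue
        if (
            hit.evalue > thresholds.evalue_max
            or hit.pct_identity < thresholds.identity_min
            or hit.query_cov < thresholds.coverage_min
        ):
            continue
        key = (-hit.bitscore, hit.evalue, tid)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else UNKNOWN_TOKEN
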