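"""The two-stage decision procedure.

Contigs pass a length filter, then an alignment shortcut (near-identical
matches to the reference plasmid DB are called plasmid directly), then
order assignment by best-hit e-value; contigs with no qualifying order
hit are rejected as non-plasmid, and the remainder are scored by the
order's attention classifier (PC scheme by default, probability
threshold tau; segment/protein schemes aggregate by majority vote).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from plasmeld.align import AlignmentHit, NucleotideDB, ProteinAligner
from plasmeld.model import TransformerClassifier
from plasmeld.pc_vocab import PCAssignThresholds, PCVocabulary, assign_pc
from plasmeld.seqio import (
    Contig,
    GeneCaller,
    LengthFilterBounds,
    OrfScannerEngine,
    predict_genes,
    segment_sequence,
)
from plasmeld.tokenizers import BPEModel, encode_aa, encode_bpe, encode_pc, CAPACITY

__all__ = [
    "PipelineThresholds",
    "Prediction",
    "overall_cov_identity",
    "alignment_stage",
    "assign_order",
    "majority_vote",
    "PlasmeldPredictor",
    "predict_contig",
    "mark_shared_regions",
    "write_predictions",
]


@dataclass(frozen=True)
class PipelineThresholds:
    tau_cov: float = 0.90
    tau_ident: float = 0.90
    tau: float = 0.5
    vote_nt_bpe: float = 0.55
    vote_aa: float = 0.41
    vote_aa_bpe: float = 0.17
    order_evalue_max: float = 10.0

    def vote_threshold(self, scheme: str) -> float:
        return {
            "nt-bpe": self.vote_nt_bpe,
            "aa": self.vote_aa,
            "aa-bpe": self.vote_aa_bpe,
        }[scheme]


@dataclass(frozen=True)
class Prediction:
    contig_id: str
    label: str  # plasmid | non-plasmid
    probability: float | None
    route: str  # alignment | transformer | rejected-no-order | rejected-length
    order: str | None = None
    regions: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.route == "alignment" and self.probability is not None:
            raise ValueError("alignment-route predictions carry no probability")
        if self.route == "transformer" and self.probability is None:
            raise ValueError("transformer-route predictions require a probability")


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def overall_cov_identity(hits: list[AlignmentHit], query_len: int) -> tuple[float, float]:
    """Overall coverage and identity of one query/subject pair.

    Coverage is the merged-interval fraction of the query covered by the
    HSPs; identity is the alignment-length-weighted mean of the HSP
    identities (both as fractions in [0, 1])."""
    if not hits:
        raise ValueError("need at least one hit")
    covered = sum(b - a + 1 for a, b in merge_intervals([(h.q_start, h.q_end) for h in hits]))
    total_len = sum(h.length for h in hits)
    identity = sum(h.pct_identity * h.length for h in hits) / total_len / 100.0
    return covered / query_len, identity


def alignment_stage(
    contig: Contig,
    hits: list[AlignmentHit],
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> Prediction | None:
    """Plasmid call when some reference reaches coverage >= tau_cov and
    identity >= tau_ident; otherwise None (pass-through)."""
    by_subject: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append(h)
    best: tuple[float, float] | None = None
    for subject_hits in by_subject.values():
        cov, ident = overall_cov_identity(subject_hits, contig.length)
        if cov >= thresholds.tau_cov and ident >= thresholds.tau_ident:
            if best is None or (cov, ident) > best:
                best = (cov, ident)
    if best is None:
        return None
    return Prediction(contig.id, "plasmid", None, "alignment")


def assign_order(
    hits: list[AlignmentHit],
    order_labels: dict[str, str],
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> str | None:
    """Order of the best qualifying hit (evalue < order_evalue_max);
    ties by lower e-value, then higher bitscore, then lexicographic
    order name. None when no hit qualifies."""
    best: tuple[float, float, str] | None = None
    for h in hits:
        if h.subject_id not in order_labels:
            raise KeyError(f"hit references unknown sequence {h.subject_id!r}")
        if h.evalue >= thresholds.order_evalue_max:
            continue
        key = (h.evalue, -h.bitscore, order_labels[h.subject_id])
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def majority_vote(unit_probs: list[float], tau: float, vote_threshold: float) -> str:
    """Plasmid iff the proportion of units with probability > tau
    exceeds the vote threshold (strict)."""
    if not unit_probs:
        raise ValueError("majority_vote needs at least one unit probability")
    proportion = sum(p > tau for p in unit_probs) / len(unit_probs)
    return "plasmid" if proportion > vote_threshold else "non-plasmid"


def mark_shared_regions(
    contig: Contig,
    chromosome_db: NucleotideDB,
    min_identity: float = 90.0,
    min_len: int = 500,
) -> list[tuple[int, int, str]]:
    """Merged query intervals aligned to chromosomes with identity >=
    ``min_identity`` percent over HSPs of >= ``min_len`` bp."""
    hits = chromosome_db.search(contig.id, contig.seq)
    intervals = [
        (h.q_start, h.q_end)
        for h in hits
        if h.pct_identity >= min_identity and h.length >= min_len
    ]
    return [(a, b, "chromosome-like") for a, b in merge_intervals(intervals)]


@dataclass
class PlasmeldPredictor:
    """Bundles databases, tokenizer resources and order models.

    ``models`` maps order name to a trained classifier; an order without
    a model falls back to the ``"pooled"`` entry."""

    plasmid_db: NucleotideDB
    order_labels: dict[str, str]
    models: dict[str, TransformerClassifier]
    vocab: PCVocabulary | None = None
    scheme: str = "pc"
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    bounds: LengthFilterBounds = field(default_factory=LengthFilterBounds)
    chromosome_db: NucleotideDB | None = None
    gene_engine: GeneCaller | None = None
    protein_aligner: ProteinAligner | None = None
    assign_thresholds: PCAssignThresholds = field(default_factory=PCAssignThresholds)
    bpe_model: BPEModel | None = None
    nt_segment_window: int = 2000

    def __post_init__(self) -> None:
        if self.scheme not in ("pc", "nt-bpe", "aa", "aa-bpe"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "pc" and self.vocab is None:
            raise ValueError("PC scheme requires a vocabulary")
        if self.scheme in ("nt-bpe", "aa-bpe") and self.bpe_model is None:
            raise ValueError(f"{self.scheme} requires a trained BPE model")
        if not self.models:
            raise ValueError("at least one order model (or 'pooled') is required")
        self.gene_engine = self.gene_engine or OrfScannerEngine()
        self.protein_aligner = self.protein_aligner or ProteinAligner()

    def _model_for(self, order: str) -> TransformerClassifier:
        if order in self.models:
            return self.models[order]
        if "pooled" in self.models:
            return self.models["pooled"]
        raise KeyError(f"no model for order {order!r} and no pooled fallback")

    def predict(self, contig: Contig) -> Prediction:
        regions: tuple[tuple[int, int, str], ...] = ()
        if self.chromosome_db is not None:
            regions = tuple(mark_shared_regions(contig, self.chromosome_db))
        if not (self.bounds.min_bp <= contig.length <= self.bounds.max_bp):
            return Prediction(contig.id, "non-plasmid", None, "rejected-length", None, regions)
        hits = self.plasmid_db.search(contig.id, contig.seq)
        shortcut = alignment_stage(contig, hits, self.thresholds)
        if shortcut is not None:
            return Prediction(contig.id, "plasmid", None, "alignment", None, regions)
        order = assign_order(hits, self.order_labels, self.thresholds)
        if order is None:
            return Prediction(contig.id, "non-plasmid", None, "rejected-no-order", None, regions)
        model = self._model_for(order)
        if self.scheme == "pc":
            label, prob = self._predict_pc(contig, model)
        elif self.scheme == "nt-bpe":
            label, prob = self._predict_vote_nt(contig, model)
        else:
            label, prob = self._predict_vote_protein(contig, model)
        return Prediction(contig.id, label, prob, "transformer", order, regions)

    def predict_many(self, contigs: list[Contig]) -> list[Prediction]:
        return [self.predict(c) for c in contigs]

    def _predict_pc(self, contig: Contig, model: TransformerClassifier) -> tuple[str, float]:
        proteins = predict_genes(contig, self.gene_engine)
        if not proteins:
            return "non-plasmid", 0.0
        capacity = model.config.sentence_len
        sentence = encode_pc(
            proteins,
            self.vocab,
            lambda p: assign_pc(p, self.vocab, self.protein_aligner, self.assign_thresholds),
            capacity=capacity,
        )
        prob = float(model.predict_proba(sentence.ids[None, :])[0])
        return ("plasmid" if prob > self.thresholds.tau else "non-plasmid"), prob

    def _predict_vote_nt(self, contig: Contig, model: TransformerClassifier) -> tuple[str, float]:
        segments = segment_sequence(contig.seq, self.nt_segment_window)
        capacity = model.config.sentence_len
        ids = np.stack(
            [encode_bpe(seg, self.bpe_model, capacity).ids for seg in segments]
        )
        probs = model.predict_proba(ids).tolist()
        label = majority_vote(probs, self.thresholds.tau, self.thresholds.vote_nt_bpe)
        proportion = sum(p > self.thresholds.tau for p in probs) / len(probs)
        return label, proportion

    def _predict_vote_protein(
        self, contig: Contig, model: TransformerClassifier
    ) -> tuple[str, float]:
        proteins = predict_genes(contig, self.gene_engine)
        if not proteins:
            return "non-plasmid", 0.0
        capacity = model.config.sentence_len
        if self.scheme == "aa":
            ids = np.stack([encode_aa(p, capacity).ids for p in proteins])
        else:
            ids = np.stack(
                [encode_bpe(p.aa_seq, self.bpe_model, capacity).ids for p in proteins]
            )
        probs = model.predict_proba(ids).tolist()
        label = majority_vote(
            probs, self.thresholds.tau, self.thresholds.vote_threshold(self.scheme)
        )
        proportion = sum(p > self.thresholds.tau for p in probs) / len(probs)
        return label, proportion


def predict_contig(contig: Contig, predictor: PlasmeldPredictor) -> Prediction:
    """Run the full two-stage decision procedure on one contig."""
    return predictor.predict(contig)


def write_predictions(predictions: list[Prediction], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["contig_id", "label", "probability", "route", "order", "regions"])
        for p in predictions:
            writer.writerow(
                [
                    p.contig_id,
                    p.label,
                    "" if p.probability is None else f"{p.probability:.4f}",
                    p.route,
                    p.order or "",
                    ";".join(f"{a}-{b}" for a, b, _ in p.regions),
                ]
            )
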