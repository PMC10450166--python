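"""Glue for the desk-scale end-to-end workflow: build a PC vocabulary
from reference contigs, tokenize labeled contigs, train a pooled model
and assemble a predictor. Used by the CLI, the test-suite fixtures and
the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plasmeld.align import NucleotideDB, ProteinAligner
from plasmeld.model import (
    TransformerClassifier,
    TransformerConfig,
    augment_training_set,
    train,
)
from plasmeld.pc_vocab import (
    PCVocabulary,
    all_vs_all_hits,
    assign_pc,
    build_protein_graph,
    filter_clusters,
    mcl_cluster,
)
from plasmeld.pipeline import PlasmeldPredictor
from plasmeld.seqio import Contig, GeneCaller, OrfScannerEngine, predict_genes
from plasmeld.synthetic import Benchmark
from plasmeld.tokenizers import encode_pc

__all__ = ["build_vocabulary_from_contigs", "tokenize_contigs", "FittedPipeline", "fit_pooled_pipeline"]

# the internal ORF scanner at 60 nt reports many tiny spurious ORFs on
# random spacers; 180 nt (59 aa) keeps every synthetic gene (>= 80 aa)
DEFAULT_GENE_ENGINE = OrfScannerEngine(min_len_nt=180)


def build_vocabulary_from_contigs(
    contigs: list[Contig],
    gene_engine: GeneCaller | None = None,
    edge_evalue_max: float = 1e-5,
    inflation: float = 2.0,
    min_cluster_size: int = 2,
) -> PCVocabulary:
    engine = gene_engine or DEFAULT_GENE_ENGINE
    proteins = []
    for contig in contigs:
        proteins.extend(predict_genes(contig, engine))
    hits = all_vs_all_hits(proteins)
    graph = build_protein_graph(hits, edge_evalue_max, nodes=[p.id for p in proteins])
    partition = mcl_cluster(graph, inflation=inflation)
    return filter_clusters(partition, {p.id: p.aa_seq for p in proteins}, min_cluster_size)


def tokenize_contigs(
    items: list[tuple[str, int]],
    vocab: PCVocabulary,
    sentence_len: int,
    gene_engine: GeneCaller | None = None,
    aligner: ProteinAligner | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PC-tokenize (sequence, label) pairs, dropping sequences with no
    callable protein; returns (sentences, labels)."""
    engine = gene_engine or DEFAULT_GENE_ENGINE
    aligner = aligner or ProteinAligner()
    X, y = [], []
    for i, (seq, label) in enumerate(items):
        proteins = predict_genes(Contig(f"unit{i}", seq), engine)
        if not proteins:
            continue
        sentence = encode_pc(
            proteins, vocab, lambda p: assign_pc(p, vocab, aligner), capacity=sentence_len
        )
        X.append(sentence.ids)
        y.append(label)
    if not X:
        raise ValueError("no tokenizable sequences")
    return np.stack(X), np.array(y)


@dataclass
class FittedPipeline:
    predictor: PlasmeldPredictor
    vocab: PCVocabulary
    model: TransformerClassifier
    loss_trace: list[tuple[int, int, float]]


def fit_pooled_pipeline(
    benchmark: Benchmark,
    sentence_len: int = 64,
    d_model: int = 64,
    heads: int = 8,
    batch_size: int = 32,
    seed: int = 0,
    augment_windows: tuple[int, ...] = (1000, 2000, 4000),
    gene_engine: GeneCaller | None = None,
) -> FittedPipeline:
    """Train a pooled PC-scheme pipeline on a synthetic benchmark.

    Dimensions default to a desk-scale reduction (sentence length 64,
    d_model 64) of the full-scale configuration (400, 512); everything
    else — 8 heads, 2 epochs, Adam at 0.001, dropout 0.1, class
    weighting, window augmentation — matches the production recipe.
    """
    engine = gene_engine or DEFAULT_GENE_ENGINE
    vocab = build_vocabulary_from_contigs(benchmark.reference_plasmids, engine)
    augmented = augment_training_set(
        [(c.seq, label) for c, label, _ in benchmark.train], windows=augment_windows
    )
    X, y = tokenize_contigs(augmented, vocab, sentence_len, engine)
    config = TransformerConfig(
        sentence_len=sentence_len,
        vocab_size=vocab.n_tokens,
        d_model=d_model,
        heads=heads,
        batch_size=batch_size,
        seed=seed,
    )
    model = TransformerClassifier(config)
    trace = train(model, X, y)
    predictor = PlasmeldPredictor(
        plasmid_db=NucleotideDB([(c.id, c.seq) for c in benchmark.reference_plasmids]),
        order_labels=dict(benchmark.reference_orders),
        models={"pooled": model},
        vocab=vocab,
        gene_engine=engine,
    )
    return FittedPipeline(predictor, vocab, model, trace)
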