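# plasmeld

Two-stage plasmid identification for assembled contigs. Contigs that are
near-identical to a reference plasmid are called directly by alignment
(query coverage and identity ≥ 90%); the remainder are routed by best-hit
e-value to a host order and scored by an order-specific attention
classifier over a protein-cluster (PC) token vocabulary; contigs with no
qualifying order hit are rejected as non-plasmid.

The package implements the full method at desk scale:

| module | contents |
|---|---|
| `plasmeld.seqio` | FASTA I/O, 1 kb–350 kb length filter, pluggable gene calling (internal six-frame ORF scanner or a Prodigal-compatible binary), sliding-window segmentation |
| `plasmeld.align` | tabular-hit interchange type, internal protein Smith–Waterman (BLOSUM62) and seeded ungapped nucleotide aligner with Karlin–Altschul e-value surrogates; BLAST/DIAMOND tabular files are accepted interchangeably |
| `plasmeld.pc_vocab` | PC vocabulary: all-vs-all protein graph (edges at e ≤ 1e−5) → native Markov clustering (inflation 2.0) → clusters of ≥ 2 members; token ids 0 = mask, 1 = unknown, clusters from 2; PC assignment by best representative hit |
| `plasmeld.tokenizers` | the four token schemes: nt-BPE (vocab 5002, sentence 350), AA (22-symbol alphabet, sentence 1000), aa-BPE (sentence 400), PC (sentence 400); deterministic incremental BPE training |
| `plasmeld.model` | single-layer attention classifier in NumPy with analytic gradients: word+position embedding (d_model 512), 8-head attention scaled by d_k, flatten (400 × 512 = 204,800), FC (64, 1), sigmoid; weighted BCE (max(N_p, N_c)/N_i), Adam lr 0.001, dropout 0.1, batch 256, 2 epochs; sliding-window training augmentation (200–4000 bp) |
| `plasmeld.pipeline` | length filter → alignment shortcut → order assignment (e-value < 10) → model probability (τ = 0.5) or majority vote (0.55 / 0.41 / 0.17 for nt-BPE / AA / aa-BPE); chromosome-like region marking |
| `plasmeld.interpret` | token importance as mean received attention per occurrence; top-k report joined with cluster representatives |
| `plasmeld.synthetic` | reproducible order-structured plasmid/chromosome fixtures with controllable shared-gene fraction and per-site mutation rate |
| `plasmeld.metrics` | precision/recall/F1 and PR curve with trapezoidal area |
| `plasmeld.workflow` | end-to-end glue: vocabulary building, tokenization, pooled-model training |

The classifier is implemented directly in NumPy (no deep-learning
framework required): exact analytic gradients, seeded Adam, and
bit-reproducible training on any machine.

## CLI

```bash
plasmeld synthesize --out fixtures/ --seed 0
plasmeld build-vocab --contigs fixtures/reference_plasmids.fasta \
    --out-tsv vocab.tsv --out-fasta vocab.fasta
plasmeld train --contigs fixtures/train_contigs.fasta \
    --labels fixtures/ground_truth.tsv \
    --vocab-tsv vocab.tsv --vocab-fasta vocab.fasta \
    --out models/pooled --sentence-len 64 --d-model 64
plasmeld predict --input fixtures/test_contigs.fasta \
    --db fixtures/reference_plasmids.fasta \
    --orders fixtures/reference_orders.tsv \
    --vocab-tsv vocab.tsv --vocab-fasta vocab.fasta \
    --model models/pooled --out predictions.tsv
```

`predict` accepts `--tau/--tau-cov/--tau-ident` overrides, an optional
`--chrom-db` for chromosome-like region marking, and a YAML `--config`
mirroring all thresholds. Output is a TSV with contig id, label,
probability, decision route, assigned order and marked regions.

## Desk-scale notes

End-to-end tests train on synthetic fixtures with reduced dimensions
(sentence length 64, d_model 64 instead of 400/512); heads, epochs,
optimizer, dropout, class weighting and augmentation follow the
full-scale recipe. The full-scale dimensions are exercised directly in
the architecture tests and the acceptance script.
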