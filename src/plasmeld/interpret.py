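"""Attention-based token-importance scoring.

Importance of a sentence position is the total attention it *receives*
(mean over heads of the column sums of the row-stochastic attention
matrix); a token's score aggregates the mean over all of its non-pad
occurrences, so frequent tokens are not favoured by frequency alone.
Occurrence counts are reported separately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from plasmeld.model import TransformerClassifier
from plasmeld.pc_vocab import MASK_TOKEN, PCVocabulary
from plasmeld.tokenizers import TokenSentence

__all__ = ["TokenImportance", "token_importance", "top_k_report", "write_report"]


@dataclass(frozen=True)
class TokenImportance:
    token_id: int
    mean_attention: float
    occurrences: int
    rank: int


def token_importance(
    model: TransformerClassifier,
    sentences: list[TokenSentence] | np.ndarray,
    batch_size: int = 64,
) -> list[TokenImportance]:
    """Score token ids by mean received attention over all occurrences.

    Pad positions (id 0) are excluded. Ranks are 1-based, ordered by
    descending score with ties broken by the smaller token id.
    """
    ids = _as_matrix(sentences)
    totals: dict[int, float] = {}
    counts: dict[int, int] = {}
    for lo in range(0, len(ids), batch_size):
        batch = ids[lo : lo + batch_size]
        _, alpha = model.forward(batch, return_attention=True)
        # received attention: mean over heads of column sums of alpha
        received = alpha.sum(axis=2).mean(axis=1)  # (B, L)
        for row, rec in zip(batch, received):
            for tid, score in zip(row, rec):
                tid = int(tid)
                if tid == MASK_TOKEN:
                    continue
                totals[tid] = totals.get(tid, 0.0) + float(score)
                counts[tid] = counts.get(tid, 0) + 1
    scored = sorted(
        ((totals[t] / counts[t], t) for t in totals),
        key=lambda st: (-st[0], st[1]),
    )
    return [
        TokenImportance(tid, score, counts[tid], rank)
        for rank, (score, tid) in enumerate(scored, start=1)
    ]


def top_k_report(
    importances: list[TokenImportance],
    vocab: PCVocabulary | None = None,
    k: int = 50,
) -> list[dict]:
    """Top-k rows joined with vocabulary representatives; returns all
    rows when fewer than k tokens were scored."""
    rows = []
    for imp in sorted(importances, key=lambda i: i.rank)[:k]:
        rep = None
        if vocab is not None and imp.token_id in vocab.representatives:
            rep = vocab.representatives[imp.token_id]
        rows.append(
            {
                "token_id": imp.token_id,
                "score": imp.mean_attention,
                "occurrences": imp.occurrences,
                "representative_protein_id": rep,
            }
        )
    return rows


def write_report(rows: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["token_id", "score", "occurrences", "representative_protein_id"],
            delimiter="\t",
        )
        writer.writeheader()
        writer.writerows(rows)


def dump_attention(
    model: TransformerClassifier, sentence: TokenSentence, path: str | Path
) -> None:
    """Write the head-averaged position-by-position attention matrix as TSV."""
    _, alpha = model.forward(sentence.ids[None, :], return_attention=True)
    np.savetxt(path, alpha[0].mean(axis=0), delimiter="\t", fmt="%.6g")


def _as_matrix(sentences) -> np.ndarray:
    if isinstance(sentences, np.ndarray):
        return np.atleast_2d(sentences)
    return np.stack([s.ids for s in sentences])
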