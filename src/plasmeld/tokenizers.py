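"""The four token schemes: nt-BPE, AA, aa-BPE and PC.

Every scheme emits a fixed-length integer sentence; id 0 is padding and
id 1 the unknown token. Sentence capacities follow the scheme: 350 for
nt-BPE, 1000 for AA, 400 for aa-BPE and PC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from plasmeld.pc_vocab import MASK_TOKEN, UNKNOWN_TOKEN, PCVocabulary
from plasmeld.seqio import ProteinRecord

__all__ = [
    "CAPACITY",
    "NT_BPE_VOCAB_SIZE",
    "TokenSentence",
    "BPEModel",
    "train_bpe",
    "encode_bpe",
    "decode_bpe",
    "encode_aa",
    "encode_pc",
    "AA_ALPHABET",
]

CAPACITY = {"nt-bpe": 350, "aa": 1000, "aa-bpe": 400, "pc": 400}
NT_BPE_VOCAB_SIZE = 5002

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # ids 2..21; X -> 22; anything else -> 23
_AA_IDS = {a: i + 2 for i, a in enumerate(AA_ALPHABET)}
_AA_X_ID = 22
_AA_OTHER_ID = 23
AA_VOCAB_SIZE = 24


@dataclass(frozen=True)
class TokenSentence:
    """Fixed-length integer token vector for one classification unit."""

    scheme: str
    ids: np.ndarray
    capacity: int

    def __post_init__(self) -> None:
        if len(self.ids) != self.capacity:
            raise ValueError(f"sentence length {len(self.ids)} != capacity {self.capacity}")
        nz = np.nonzero(self.ids)[0]
        if nz.size and np.any(self.ids[: nz[-1] + 1] == 0):
            raise ValueError("padding id 0 must only appear as a suffix")

    @property
    def n_tokens(self) -> int:
        nz = np.nonzero(self.ids)[0]
        return int(nz[-1]) + 1 if nz.size else 0


def _make_sentence(scheme: str, ids: Sequence[int], capacity: int) -> TokenSentence:
    arr = np.zeros(capacity, dtype=np.int64)
    n = min(len(ids), capacity)
    arr[:n] = np.asarray(ids[:n], dtype=np.int64)
    return TokenSentence(scheme, arr, capacity)


@dataclass
class BPEModel:
    """Byte-pair-encoding model: base alphabet + ordered merge list.

    Ids: 0 pad, 1 unknown, then alphabet symbols in sorted order, then
    merged tokens in merge order.
    """

    alphabet: list[str]
    merges: list[tuple[str, str]]
    vocab: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vocab:
            self.vocab = {sym: i + 2 for i, sym in enumerate(sorted(self.alphabet))}
            for a, b in self.merges:
                self.vocab[a + b] = len(self.vocab) + 2

    @property
    def vocab_size(self) -> int:
        return len(self.vocab) + 2

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"alphabet": self.alphabet, "merges": [list(m) for m in self.merges]},
                fh,
            )

    @classmethod
    def load(cls, path: str | Path) -> "BPEModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(data["alphabet"], [tuple(m) for m in data["merges"]])


def _merge_once(syms: list[str], pair: tuple[str, str]) -> list[str]:
    # greedy left-to-right, non-overlapping
    out: list[str] = []
    i = 0
    a, b = pair
    while i < len(syms):
        if i + 1 < len(syms) and syms[i] == a and syms[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(syms[i])
            i += 1
    return out


def train_bpe(corpus: list[str], target_vocab_size: int) -> BPEModel:
    """Train a BPE model by iterated most-frequent-pair merging.

    Pair frequencies count every adjacent symbol pair; ties break to the
    lexicographically smallest pair, making training deterministic and
    independent of corpus order. Stops at ``target_vocab_size`` total
    ids (including the 2 reserved) or when no pair occurs twice.
    """
    if not corpus:
        raise ValueError("empty corpus")
    alphabet = sorted({c for s in corpus for c in s})
    if target_vocab_size < len(alphabet) + 2:
        raise ValueError("target vocab smaller than alphabet + reserved ids")
    n_merges = target_vocab_size - len(alphabet) - 2
    merges = _train_merges(corpus, n_merges)
    return BPEModel(alphabet, merges)


def _train_merges(corpus: list[str], n_merges: int) -> list[tuple[str, str]]:
    """Incremental merge training: symbols in a doubly linked list, pair
    adjacency counts kept in an index, best pair via a lazily
    invalidated heap. Equivalent to recounting every adjacent pair and
    merging greedily left-to-right, but near-linear in corpus size."""
    import heapq

    toks: list[str | None] = []
    for s in corpus:
        if s:
            toks.extend(s)
            toks.append(None)  # string boundary: never pairs
    n = len(toks)
    nxt = list(range(1, n + 1))
    prv = list(range(-1, n - 1))
    index: dict[tuple[str, str], set[int]] = {}
    for i in range(n - 1):
        if toks[i] is not None and toks[i + 1] is not None:
            index.setdefault((toks[i], toks[i + 1]), set()).add(i)
    counts = {pair: len(pos) for pair, pos in index.items()}
    heap = [(-c, pair) for pair, c in counts.items()]
    heapq.heapify(heap)

    def _drop(pair: tuple[str, str], pos: int) -> None:
        if pair in index and pos in index[pair]:
            index[pair].discard(pos)
            counts[pair] -= 1
            heapq.heappush(heap, (-counts[pair], pair))

    def _add(pair: tuple[str, str], pos: int) -> None:
        index.setdefault(pair, set()).add(pos)
        counts[pair] = counts.get(pair, 0) + 1
        heapq.heappush(heap, (-counts[pair], pair))

    merges: list[tuple[str, str]] = []
    while len(merges) < n_merges and heap:
        neg, pair = heapq.heappop(heap)
        if counts.get(pair, 0) != -neg:
            continue  # stale entry
        if -neg < 2:
            break
        a, b = pair
        merged = a + b
        positions = sorted(index.pop(pair))
        counts[pair] = 0
        for p in positions:
            q = nxt[p]
            # stale when an earlier merge in this pass consumed p or q
            if toks[p] != a or q >= n or toks[q] != b:
                continue
            left, right = prv[p], nxt[q]
            if left >= 0 and toks[left] is not None and (toks[left], a) != pair:
                _drop((toks[left], a), left)
            if right < n and toks[right] is not None and (b, toks[right]) != pair:
                _drop((b, toks[right]), q)
            toks[p] = merged
            toks[q] = None
            nxt[p] = right
            if right < n:
                prv[right] = p
            if left >= 0 and toks[left] is not None:
                _add((toks[left], merged), left)
            if right < n and toks[right] is not None:
                _add((merged, toks[right]), p)
        merges.append(pair)
    return merges


def tokenize_bpe(seq: str, model: BPEModel) -> list[str]:
    syms = list(seq)
    for pair in model.merges:
        syms = _merge_once(syms, pair)
    return syms


def encode_bpe(seq: str, model: BPEModel, capacity: int) -> TokenSentence:
    """Encode by applying merges in training order; symbols outside the
    model vocabulary map to the unknown id; truncate/pad to capacity."""
    ids = [model.vocab.get(sym, UNKNOWN_TOKEN) for sym in tokenize_bpe(seq, model)]
    return _make_sentence("bpe", ids, capacity)


def decode_bpe(sentence: TokenSentence, model: BPEModel) -> str:
    rev = {i: sym for sym, i in model.vocab.items()}
    return "".join(rev.get(int(t), "?") for t in sentence.ids if t != MASK_TOKEN)


def encode_aa(protein: ProteinRecord | str, capacity: int = CAPACITY["aa"]) -> TokenSentence:
    """Per-residue encoding over 20 standard amino acids + X + other."""
    seq = protein if isinstance(protein, str) else protein.aa_seq
    ids = [
        _AA_IDS.get(c, _AA_X_ID if c == "X" else _AA_OTHER_ID) for c in seq.upper()
    ]
    return _make_sentence("aa", ids, capacity)


def encode_pc(
    proteins: list[ProteinRecord],
    vocab: PCVocabulary,
    assigner: Callable[[ProteinRecord], int],
    capacity: int = CAPACITY["pc"],
) -> TokenSentence:
    """PC sentence for one contig: token of each protein in genomic
    (start-coordinate) order, truncated to capacity, padded with 0.

    A contig with no proteins yields the all-zero (untokenizable)
    sentence; callers treat it as nothing-to-classify.
    """
    ordered = sorted(proteins, key=lambda p: (p.start, p.end))
    ids = [assigner(p) for p in ordered[:capacity]]
    return _make_sentence("pc", ids, capacity)
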