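"""Alignment engines and the tabular-hit interchange type.

Two pluggable engines share the :class:`AlignmentHit` contract so that
pre-computed BLAST/DIAMOND tabular output and the internal aligners are
interchangeable:

* :class:`ProteinAligner` — Smith–Waterman (BLOSUM62, affine gaps) via
  Biopython's :class:`~Bio.Align.PairwiseAligner`, with a k-mer prefilter
  and a Karlin–Altschul e-value surrogate.
* :class:`NucleotideSeedAligner` — seeded ungapped x-drop extension on
  both strands, reporting one HSP per diagonal.

E-values are surrogates calibrated with published Karlin–Altschul
parameters; they are commensurate with the coarse thresholds used by the
pipeline (1e-5 graph edges, e-value < 10 order routing), not with any
specific aligner's statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from plasmeld.seqio import reverse_complement

__all__ = [
    "AlignmentHit",
    "read_tabular_hits",
    "write_tabular_hits",
    "ProteinAligner",
    "NucleotideSeedAligner",
    "NucleotideDB",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One HSP in BLAST outfmt-6 style coordinates (1-based inclusive)."""

    query_id: str
    subject_id: str
    pct_identity: float
    length: int
    evalue: float
    bitscore: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    query_cov: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("negative evalue")
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end")


_TAB_FIELDS = (
    "qseqid sseqid pident length evalue bitscore qstart qend sstart send qcovhsp"
).split()


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Read tabular hits (qseqid sseqid pident length evalue bitscore
    qstart qend sstart send [qcovhsp])."""
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: expected >= 10 columns, got {len(f)}")
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    subject_id=f[1],
                    pct_identity=float(f[2]),
                    length=int(f[3]),
                    evalue=float(f[4]),
                    bitscore=float(f[5]),
                    q_start=int(f[6]),
                    q_end=int(f[7]),
                    s_start=int(f[8]),
                    s_end=int(f[9]),
                    query_cov=float(f[10]) if len(f) > 10 else 0.0,
                )
            )
    return hits


def write_tabular_hits(hits: list[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.length,
                        f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.q_start, h.q_end,
                        h.s_start, h.s_end, f"{h.query_cov:.2f}",
                    )
                )
                + "\n"
            )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class ProteinAligner:
    """Local protein alignment with BLOSUM62 and affine gaps (-11/-1).

    ``search_space`` (effective m*n) defaults to the actual pair product;
    a database-level value can be supplied so e-values reflect the whole
    search.
    """

    # gapped BLOSUM62 Karlin-Altschul parameters
    LAMBDA = 0.267
    K = 0.041

    def __init__(self, prefilter_k: int = 4, min_bitscore: float = 18.0):
        self.prefilter_k = prefilter_k
        self.min_bitscore = min_bitscore
        self._aligner = Align.PairwiseAligner(
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-11.0,
            extend_gap_score=-1.0,
            mode="local",
        )

    def align_pair(
        self,
        query_id: str,
        query: str,
        subject_id: str,
        subject: str,
        search_space: float | None = None,
    ) -> AlignmentHit | None:
        query = _sanitize_aa(query)
        subject = _sanitize_aa(subject)
        if self.prefilter_k and not (
            _kmer_set(query, self.prefilter_k) & _kmer_set(subject, self.prefilter_k)
        ):
            return None
        alns = self._aligner.align(query, subject)
        if len(alns) == 0:
            return None
        aln = alns[0]
        score = aln.score
        bitscore = (self.LAMBDA * score - math.log(self.K)) / math.log(2)
        if bitscore < self.min_bitscore:
            return None
        space = search_space if search_space is not None else len(query) * len(subject)
        evalue = self.K * space * math.exp(-self.LAMBDA * score)
        qblocks = aln.aligned[0]
        sblocks = aln.aligned[1]
        ident = 0
        length = 0
        for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
            qseg, sseg = query[qa:qb], subject[sa:sb]
            ident += sum(a == b for a, b in zip(qseg, sseg))
            length += qb - qa
        # count gap columns into alignment length
        span_q = qblocks[-1][1] - qblocks[0][0]
        span_s = sblocks[-1][1] - sblocks[0][0]
        length = max(span_q, span_s)
        q_start, q_end = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
        s_start, s_end = int(sblocks[0][0]) + 1, int(sblocks[-1][1])
        return AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            pct_identity=100.0 * ident / length if length else 0.0,
            length=length,
            evalue=evalue,
            bitscore=bitscore,
            q_start=q_start,
            q_end=q_end,
            s_start=s_start,
            s_end=s_end,
            query_cov=100.0 * (q_end - q_start + 1) / len(query),
        )


def _sanitize_aa(seq: str) -> str:
    allowed = set("ACDEFGHIKLMNPQRSTVWYBXZ")
    return "".join(c if c in allowed else "X" for c in seq.upper())


_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i


def _encode_nt(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class NucleotideSeedAligner:
    """Seeded ungapped aligner: exact k-mer seeds grouped by diagonal,
    then a maximal-scoring ungapped segment per diagonal (match +1,
    mismatch -2). Handles both strands of the query."""

    LAMBDA = 1.28
    K = 0.46
    MATCH = 1.0
    MISMATCH = -2.0

    def __init__(self, k: int = 13, min_score: float = 20.0, max_evalue: float = 10.0):
        self.k = k
        self.min_score = min_score
        self.max_evalue = max_evalue

    def search(
        self,
        query_id: str,
        query: str,
        subject_id: str,
        subject: str,
        index: dict[str, list[int]] | None = None,
        search_space: float | None = None,
    ) -> list[AlignmentHit]:
        index = index if index is not None else build_kmer_index(subject, self.k)
        space = search_space if search_space is not None else len(query) * len(subject)
        hits = []
        for strand, qseq in (("+", query), ("-", reverse_complement(query))):
            diags: set[int] = set()
            for qpos in range(0, len(qseq) - self.k + 1):
                kmer = qseq[qpos : qpos + self.k]
                for spos in index.get(kmer, ()):
                    diags.add(qpos - spos)
            qa = _encode_nt(qseq)
            sa = _encode_nt(subject)
            for diag in diags:
                hsp = self._best_segment(qa, sa, diag)
                if hsp is None:
                    continue
                q0, q1, score, ident, length = hsp
                if score < self.min_score:
                    continue
                evalue = self.K * space * math.exp(-self.LAMBDA * score)
                if evalue > self.max_evalue:
                    continue
                bitscore = (self.LAMBDA * score - math.log(self.K)) / math.log(2)
                s0, s1 = q0 - diag, q1 - diag
                if strand == "+":
                    q_start, q_end = q0 + 1, q1
                else:
                    q_start, q_end = len(query) - q1 + 1, len(query) - q0
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        subject_id=subject_id,
                        pct_identity=100.0 * ident / length,
                        length=length,
                        evalue=evalue,
                        bitscore=bitscore,
                        q_start=q_start,
                        q_end=q_end,
                        s_start=s0 + 1 if strand == "+" else s1,
                        s_end=s1 if strand == "+" else s0 + 1,
                        query_cov=100.0 * length / len(query),
                    )
                )
        hits.sort(key=lambda h: (h.evalue, -h.bitscore))
        return hits

    def _best_segment(
        self, qa: np.ndarray, sa: np.ndarray, diag: int
    ) -> tuple[int, int, float, int, int] | None:
        # overlap of query/subject along this diagonal (q = s + diag)
        q_lo = max(0, diag)
        q_hi = min(len(qa), len(sa) + diag)
        if q_hi - q_lo < self.k:
            return None
        qs = qa[q_lo:q_hi]
        ss = sa[q_lo - diag : q_hi - diag]
        match = (qs == ss) & (qs < 4)
        scores = np.where(match, self.MATCH, self.MISMATCH)
        cum = np.concatenate(([0.0], np.cumsum(scores)))
        run_min = np.minimum.accumulate(cum[:-1])
        gains = cum[1:] - run_min
        end = int(np.argmax(gains))
        best = gains[end]
        if best <= 0:
            return None
        # start index: position of the running minimum before `end`
        start = int(np.argmin(cum[: end + 1]))
        length = end + 1 - start
        ident = int(match[start : end + 1].sum())
        return q_lo + start, q_lo + end + 1, float(best), ident, length


def build_kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


class NucleotideDB:
    """A searchable set of reference nucleotide sequences."""

    def __init__(
        self, references: list[tuple[str, str]], aligner: NucleotideSeedAligner | None = None
    ):
        self.aligner = aligner or NucleotideSeedAligner()
        self.references = references
        self.total_len = sum(len(s) for _, s in references)
        self._indexes = {
            name: build_kmer_index(seq, self.aligner.k) for name, seq in references
        }

    def search(self, query_id: str, query: str) -> list[AlignmentHit]:
        hits: list[AlignmentHit] = []
        for name, seq in self.references:
            hits.extend(
                self.aligner.search(
                    query_id,
                    query,
                    name,
                    seq,
                    index=self._indexes[name],
                    search_space=len(query) * self.total_len,
                )
            )
        hits.sort(key=lambda h: (h.evalue, -h.bitscore))
        return hits
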