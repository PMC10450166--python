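"""Sequence I/O, length filtering, gene calling and segmentation.

Coordinates on :class:`ProteinRecord` are 1-based inclusive (GFF
convention); all internal array indexing is 0-based.
"""

from __future__ import annotations

import gzip
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Protocol

from Bio.Seq import Seq

__all__ = [
    "Contig",
    "ProteinRecord",
    "LengthFilterBounds",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "predict_genes",
    "OrfScannerEngine",
    "ProdigalEngine",
    "segment_sequence",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FastaError(ValueError):
    """Raised for malformed FASTA input; message names the offending record."""


@dataclass(frozen=True)
class Contig:
    """A nucleotide sequence with a unique id."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A translated gene anchored to its parent contig.

    ``start``/``end`` are 1-based inclusive on the forward strand of the
    contig, ``start <= end`` regardless of ``strand``.
    """

    contig_id: str
    index_on_contig: int
    start: int
    end: int
    strand: str
    aa_seq: str
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.contig_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.contig_id}: bad strand {self.strand!r}")
        if not self.aa_seq:
            raise ValueError(f"{self.contig_id}: empty protein")

    @property
    def id(self) -> str:
        return f"{self.contig_id}_{self.index_on_contig}"


@dataclass(frozen=True)
class LengthFilterBounds:
    """Inclusive contig length bounds in bp."""

    min_bp: int = 1000
    max_bp: int = 350_000

    def __post_init__(self) -> None:
        if self.min_bp > self.max_bp:
            raise ValueError("min_bp > max_bp")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fasta(handle) -> Iterator[tuple[str, str]]:
    header: str | None = None
    chunks: list[str] = []
    for lineno, raw in enumerate(handle, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0]
            if not header:
                raise FastaError(f"record with empty id at line {lineno}")
            chunks = []
        else:
            if header is None:
                raise FastaError(
                    f"sequence data before any header at line {lineno}: {line[:30]!r}"
                )
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a (possibly gzipped) FASTA file into contigs.

    Sequences are uppercased and U is mapped to T. Raises
    :class:`FastaError` on malformed input or duplicate ids, naming the
    offending record.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for name, seq in _iter_fasta(fh):
            if name in seen:
                raise FastaError(f"duplicate record id {name!r}")
            seen.add(name)
            if not seq:
                raise FastaError(f"record {name!r} has no sequence")
            contigs.append(Contig(name, seq.upper().replace("U", "T")))
    return contigs


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def filter_by_length(
    contigs: list[Contig], bounds: LengthFilterBounds = LengthFilterBounds()
) -> list[Contig]:
    """Keep contigs with ``min_bp <= length <= max_bp``, preserving order."""
    return [c for c in contigs if bounds.min_bp <= c.length <= bounds.max_bp]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneCaller(Protocol):
    def __call__(self, contig: Contig) -> list[ProteinRecord]: ...


@dataclass
class OrfScannerEngine:
    """Internal six-frame ORF scanner (standard genetic code).

    Reports the longest ORF per stop-to-stop stretch in each frame on
    both strands: from the first ATG following the previous stop codon
    through the next stop codon. ORFs truncated by a contig edge are
    reported with ``partial=True`` when ``allow_partial`` (mirroring how
    production gene callers handle contig boundaries). ORFs containing N
    are discarded. ``min_len_nt`` counts the stop codon.
    """

    min_len_nt: int = 60
    allow_partial: bool = True

    def __call__(self, contig: Contig) -> list[ProteinRecord]:
        found: list[tuple[int, int, str, str, bool]] = []
        n = contig.length
        for strand, seq in (("+", contig.seq), ("-", reverse_complement(contig.seq))):
            for frame in range(3):
                found.extend(self._scan_frame(seq, frame, strand, n))
        found.sort(key=lambda t: (t[0], t[1], t[2]))
        return [
            ProteinRecord(contig.id, i, start, end, strand, aa, partial)
            for i, (start, end, strand, aa, partial) in enumerate(found)
        ]

    def _scan_frame(
        self, seq: str, frame: int, strand: str, contig_len: int
    ) -> list[tuple[int, int, str, str, bool]]:
        out = []
        codons = [(i, seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)]
        region_start: int | None = frame if self.allow_partial else None
        left_partial = self.allow_partial
        for pos, codon in codons:
            if codon in STOP_CODONS:
                orf = self._emit(seq, region_start, pos + 3, left_partial, False)
                if orf:
                    out.append(self._with_coords(orf, strand, len(seq), contig_len))
                region_start = None
                left_partial = False
            elif region_start is None and codon == "ATG":
                region_start = pos
        if region_start is not None and self.allow_partial:
            end = codons[-1][0] + 3 if codons else region_start
            orf = self._emit(seq, region_start, end, left_partial, True)
            if orf:
                out.append(self._with_coords(orf, strand, len(seq), contig_len))
        return out

    def _emit(
        self, seq: str, start: int | None, stop_end: int, left_partial: bool, right_partial: bool
    ) -> tuple[int, int, str, bool] | None:
        if start is None:
            return None
        if not left_partial:
            # require an ATG start for internal ORFs
            atg = seq.find("ATG", start, stop_end - 2)
            while atg != -1 and (atg - start) % 3 != 0:
                atg = seq.find("ATG", atg + 1, stop_end - 2)
            if atg == -1:
                return None
            start = atg
        if stop_end - start < self.min_len_nt:
            return None
        sub = seq[start:stop_end]
        if "N" in sub:
            return None
        aa_len = (stop_end - start) // 3 - (0 if right_partial else 1)
        aa = str(Seq(sub[: 3 * aa_len]).translate())
        if not aa or "*" in aa:
            return None
        return start, stop_end, aa, left_partial or right_partial

    @staticmethod
    def _with_coords(
        orf: tuple[int, int, str, bool], strand: str, frame_len: int, contig_len: int
    ) -> tuple[int, int, str, str, bool]:
        start0, end0, aa, partial = orf
        if strand == "+":
            return start0 + 1, end0, strand, aa, partial
        # coordinates were on the reverse complement; map back
        return contig_len - end0 + 1, contig_len - start0, strand, aa, partial


@dataclass
class ProdigalEngine:
    """Production gene caller shelling out to a Prodigal-compatible binary."""

    binary: str = "prodigal"
    mode: str = "meta"

    def __call__(self, contig: Contig) -> list[ProteinRecord]:
        if shutil.which(self.binary) is None:
            raise RuntimeError(f"gene caller {self.binary!r} not found on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            fa = Path(tmp) / "in.fa"
            faa = Path(tmp) / "out.faa"
            write_fasta([(contig.id, contig.seq)], fa)
            try:
                subprocess.run(
                    [self.binary, "-i", str(fa), "-a", str(faa), "-p", self.mode, "-q"],
                    check=True,
                    capture_output=True,
                )
            except subprocess.CalledProcessError as exc:
                raise RuntimeError(
                    f"gene caller failed on contig {contig.id}: {exc.stderr.decode()[:500]}"
                ) from exc
            return _parse_prodigal_faa(faa, contig.id)


def _parse_prodigal_faa(path: Path, contig_id: str) -> list[ProteinRecord]:
    # headers carry coordinates after '#'; keep full header lines
    records = []
    with open(path) as fh:
        header = None
        chunks: list[str] = []
        entries: list[tuple[str, str]] = []
        for raw in fh:
            line = raw.rstrip()
            if line.startswith(">"):
                if header is not None:
                    entries.append((header, "".join(chunks)))
                header, chunks = line[1:], []
            elif header is not None:
                chunks.append(line)
        if header is not None:
            entries.append((header, "".join(chunks)))
    for i, (header, aa) in enumerate(entries):
        parts = [p.strip() for p in header.split("#")]
        start, end, sval = int(parts[1]), int(parts[2]), int(parts[3])
        aa = aa.rstrip("*")
        records.append(
            ProteinRecord(contig_id, i, start, end, "+" if sval > 0 else "-", aa)
        )
    records.sort(key=lambda r: (r.start, r.end))
    return [
        ProteinRecord(contig_id, i, r.start, r.end, r.strand, r.aa_seq, r.partial)
        for i, r in enumerate(records)
    ]


def predict_genes(contig: Contig, engine: GeneCaller | None = None) -> list[ProteinRecord]:
    """Call genes on a contig with a pluggable engine (default: ORF scanner)."""
    engine = engine or OrfScannerEngine()
    try:
        return engine(contig)
    except Exception as exc:
        raise RuntimeError(f"gene calling failed on contig {contig.id}: {exc}") from exc


def segment_sequence(seq: str, window: int, step: int | None = None) -> list[str]:
    """Cut a sequence into windows starting at 0, step, 2*step, ...

    A trailing piece shorter than the window is kept as its own segment
    when longer than half the window; otherwise it is merged into the
    previous segment so no segment is degenerately short. A window
    larger than the sequence yields the sequence itself.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    if window >= len(seq):
        return [seq]
    starts = list(range(0, len(seq) - window + 1, step))
    segments = [seq[s : s + window] for s in starts]
    tail_start = starts[-1] + window
    tail = len(seq) - tail_start
    if tail > 0:
        if tail * 2 > window:
            segments.append(seq[tail_start:])
        else:
            segments[-1] = seq[starts[-1] :]
    return segments
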