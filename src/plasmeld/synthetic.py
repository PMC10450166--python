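"""Synthetic order-structured plasmid/chromosome fixtures.

Generates a universe of protein families (plasmid-only, chromosome-only
or shared), realizes genomes as codon-encoded genes separated by random
intergenic spacers, and assembles reproducible train/test benchmarks
with reference databases and ground-truth gene maps — so the whole
pipeline is testable without downloading anything.

Mutation model: amino-acid point substitutions at ``mutation_rate`` per
site (the initial methionine is kept so genes stay callable). Each
family has one fixed ancestral codon realization (uniform synonymous
choice); mutated copies keep ancestral codons at unchanged sites, which
preserves nucleotide-level homology between genome instances of the
same family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from plasmeld.seqio import Contig, reverse_complement, write_fasta

__all__ = [
    "SyntheticSpec",
    "ProteinFamily",
    "PCUniverse",
    "GeneAnnotation",
    "Benchmark",
    "generate_pc_universe",
    "generate_genome",
    "generate_benchmark",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_TABLE = unambiguous_dna_by_id[11]
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()
_STOPS = sorted(_TABLE.stop_codons)


@dataclass(frozen=True)
class SyntheticSpec:
    n_orders: int = 2
    plasmids_per_order: int = 10
    chromosomes_per_order: int = 5
    n_plasmid_pcs: int = 20
    n_chromosome_pcs: int = 20
    shared_fraction: float = 0.0
    mutation_rate: float = 0.05
    members_per_family: int = 3
    genes_per_genome: tuple[int, int] = (6, 12)
    protein_len: tuple[int, int] = (80, 200)
    spacer_len: tuple[int, int] = (50, 200)
    order_bias: float = 0.7
    include_marker: bool = True
    fragment_lengths: tuple[int, ...] = (1000, 2000, 3000)
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")


@dataclass
class ProteinFamily:
    family_id: str
    kind: str  # plasmid | chromosome | shared
    home_order: str
    ancestral_aa: str
    ancestral_cds: str
    members: list[tuple[str, str]] = field(default_factory=list)  # (member_id, aa)


@dataclass
class PCUniverse:
    families: list[ProteinFamily]
    marker_family_id: str | None = None

    def usable_by(self, kind: str) -> list[ProteinFamily]:
        wanted = {"plasmid", "shared"} if kind == "plasmid" else {"chromosome", "shared"}
        return [f for f in self.families if f.kind in wanted]

    def by_id(self, family_id: str) -> ProteinFamily:
        return next(f for f in self.families if f.family_id == family_id)


@dataclass(frozen=True)
class GeneAnnotation:
    family_id: str
    start: int  # 1-based inclusive, forward strand, includes stop codon
    end: int
    strand: str
    aa_seq: str


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(AA_ALPHABET), size=length - 1)
    return "M" + "".join(body)


def _realize_cds(rng: np.random.Generator, aa: str) -> str:
    codons = [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in aa]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _mutate(
    rng: np.random.Generator, family: ProteinFamily, rate: float
) -> tuple[str, str]:
    """A mutated copy of the ancestral protein and its CDS (ancestral
    codons kept at unchanged sites; position 0 is never mutated)."""
    aa = list(family.ancestral_aa)
    cds = [family.ancestral_cds[3 * i : 3 * i + 3] for i in range(len(aa) + 1)]
    for i in range(1, len(aa)):
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != aa[i]]
            aa[i] = choices[rng.integers(len(choices))]
            cds[i] = _CODONS[aa[i]][rng.integers(len(_CODONS[aa[i]]))]
    return "".join(aa), "".join(cds)


def generate_pc_universe(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> PCUniverse:
    """Build the protein-family universe.

    ``shared_fraction`` of the plasmid families is additionally usable
    by chromosomes (kind "shared"); with 0 the class family sets are
    disjoint. Each family carries ``members_per_family`` mutated copies.
    """
    if spec.n_plasmid_pcs <= 0 or spec.n_chromosome_pcs <= 0:
        raise ValueError("family counts must be positive")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    orders = [f"order{i}" for i in range(spec.n_orders)]
    families: list[ProteinFamily] = []
    n_shared = int(round(spec.shared_fraction * spec.n_plasmid_pcs))
    if spec.include_marker:
        # the marker family must stay plasmid-only even at shared_fraction 1
        n_shared = min(n_shared, spec.n_plasmid_pcs - 1)
    kinds = ["plasmid"] * (spec.n_plasmid_pcs - n_shared) + ["shared"] * n_shared
    kinds += ["chromosome"] * spec.n_chromosome_pcs
    for i, kind in enumerate(kinds):
        length = int(rng.integers(spec.protein_len[0], spec.protein_len[1] + 1))
        aa = _random_protein(rng, length)
        fam = ProteinFamily(
            family_id=f"fam{i}",
            kind=kind,
            home_order=orders[int(rng.integers(spec.n_orders))],
            ancestral_aa=aa,
            ancestral_cds=_realize_cds(rng, aa),
        )
        for m in range(spec.members_per_family):
            maa, _ = _mutate(rng, fam, spec.mutation_rate)
            fam.members.append((f"{fam.family_id}_m{m}", maa))
        families.append(fam)
    marker = None
    if spec.include_marker:
        marker = next(f.family_id for f in families if f.kind == "plasmid")
    return PCUniverse(families, marker)


def _random_spacer(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    n = int(rng.integers(spec.spacer_len[0], spec.spacer_len[1] + 1))
    return "".join(rng.choice(list("ACGT"), size=n))


def generate_genome(
    kind: str,
    order: str,
    universe: PCUniverse,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    contig_id: str,
) -> tuple[Contig, list[GeneAnnotation]]:
    """Realize one genome: spacer-separated mutated genes sampled from
    the class-appropriate families with order-biased composition. The
    plasmid marker family (when configured) is always included."""
    pool = universe.usable_by(kind)
    home = [f for f in pool if f.home_order == order] or pool
    n_genes = int(rng.integers(spec.genes_per_genome[0], spec.genes_per_genome[1] + 1))
    chosen: list[ProteinFamily] = []
    if kind == "plasmid" and universe.marker_family_id is not None:
        chosen.append(universe.by_id(universe.marker_family_id))
    while len(chosen) < n_genes:
        src = home if rng.random() < spec.order_bias else pool
        chosen.append(src[int(rng.integers(len(src)))])
    parts: list[str] = [_random_spacer(rng, spec)]
    annotations: list[GeneAnnotation] = []
    pos = len(parts[0])
    for fam in chosen:
        aa, cds = _mutate(rng, fam, spec.mutation_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        realized = cds if strand == "+" else reverse_complement(cds)
        annotations.append(
            GeneAnnotation(fam.family_id, pos + 1, pos + len(realized), strand, aa)
        )
        parts.append(realized)
        pos += len(realized)
        spacer = _random_spacer(rng, spec)
        parts.append(spacer)
        pos += len(spacer)
    return Contig(contig_id, "".join(parts)), annotations


@dataclass
class Benchmark:
    spec: SyntheticSpec
    universe: PCUniverse
    train: list[tuple[Contig, int, str]]  # (contig, label 1=plasmid, order)
    test: list[tuple[Contig, int, str]]
    reference_plasmids: list[Contig]
    reference_orders: dict[str, str]
    reference_chromosomes: list[Contig]
    gene_maps: dict[str, list[GeneAnnotation]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([(c.id, c.seq) for c in self.reference_plasmids], outdir / "reference_plasmids.fasta")
        write_fasta([(c.id, c.seq) for c in self.reference_chromosomes], outdir / "reference_chromosomes.fasta")
        write_fasta([(c.id, c.seq) for c, _, _ in self.train], outdir / "train_contigs.fasta")
        write_fasta([(c.id, c.seq) for c, _, _ in self.test], outdir / "test_contigs.fasta")
        with open(outdir / "reference_orders.tsv", "w") as fh:
            fh.write("reference_id\torder\n")
            for rid, order in sorted(self.reference_orders.items()):
                fh.write(f"{rid}\t{order}\n")
        with open(outdir / "ground_truth.tsv", "w") as fh:
            fh.write("contig_id\tsplit\tlabel\torder\tgene_map\n")
            for split, rows in (("train", self.train), ("test", self.test)):
                for contig, label, order in rows:
                    genes = ";".join(
                        f"{g.family_id}:{g.start}-{g.end}:{g.strand}"
                        for g in self.gene_maps.get(contig.id, [])
                    )
                    name = "plasmid" if label else "chromosome"
                    fh.write(f"{contig.id}\t{split}\t{name}\t{order}\t{genes}\n")
        with open(outdir / "spec.json", "w") as fh:
            json.dump(asdict(self.spec), fh, indent=1)


def generate_benchmark(spec: SyntheticSpec) -> Benchmark:
    """Disjoint train/test genomes per order and class (train fraction
    ~4:1 by default); test genomes are additionally fragmented at each
    configured length; the reference plasmid DB is the training
    plasmids. Fixed seed gives byte-identical output."""
    rng = np.random.default_rng(spec.seed)
    universe = generate_pc_universe(spec, rng)
    orders = [f"order{i}" for i in range(spec.n_orders)]
    train: list[tuple[Contig, int, str]] = []
    test: list[tuple[Contig, int, str]] = []
    gene_maps: dict[str, list[GeneAnnotation]] = {}
    reference_orders: dict[str, str] = {}
    for order in orders:
        for kind, label, count in (
            ("plasmid", 1, spec.plasmids_per_order),
            ("chromosome", 0, spec.chromosomes_per_order),
        ):
            n_train = max(1, int(round(count * spec.train_fraction)))
            if n_train >= count:
                n_train = count - 1 if count > 1 else count
            for i in range(count):
                cid = f"{'P' if label else 'C'}_{order}_{i}"
                contig, genes = generate_genome(kind, order, universe, spec, rng, cid)
                gene_maps[cid] = genes
                if i < n_train:
                    train.append((contig, label, order))
                    if label:
                        reference_orders[cid] = order
                else:
                    test.append((contig, label, order))
    fragments: list[tuple[Contig, int, str]] = []
    for contig, label, order in test:
        for flen in spec.fragment_lengths:
            if flen >= contig.length:
                continue
            start = int(rng.integers(0, contig.length - flen + 1))
            frag = Contig(f"{contig.id}_frag{flen}", contig.seq[start : start + flen])
            fragments.append((frag, label, order))
    test = test + fragments
    reference_plasmids = [c for c, label, _ in train if label == 1]
    reference_chromosomes = [c for c, label, _ in train if label == 0]
    return Benchmark(
        spec=spec,
        universe=universe,
        train=train,
        test=test,
        reference_plasmids=reference_plasmids,
        reference_orders=reference_orders,
        reference_chromosomes=reference_chromosomes,
        gene_maps=gene_maps,
    )
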