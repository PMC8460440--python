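"""Assembly summary statistics and the mitochondrial-fragment scaffold screen.

N50 is the length of the scaffold at which the cumulative length, taken in
descending length order, first reaches half the assembly total; L50 is that
scaffold's 1-based rank. The tie rule is cumulative >= total/2 (the de facto
standard). GC is computed over unambiguous A/C/G/T only, so N-padding does
not dilute it, while total size still counts every base.

The mitochondrial screen is an exact k-mer containment test: a scaffold is
flagged as a fragmented copy of the mitochondrial genome when at least a
threshold fraction of its k-mer positions carry a k-mer present in the
(circularized) mitochondrial sequence on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import GeneModel, ReadInterval, Scaffold, gene_span0

__all__ = [
    "AssemblyStats",
    "GenomeFractions",
    "MitoScreenResult",
    "compute_assembly_stats",
    "compute_genome_fractions",
    "screen_mito_fragments",
]

_COMP = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    largest_bp: int
    smallest_bp: int
    n50_bp: int
    l50: int
    gc_percent: float


@dataclass(frozen=True)
class GenomeFractions:
    genes_pct: float
    coding_genes_pct: float
    exons_pct: float
    introns_pct: float
    repeats_pct: float
    gene_density_per_mbp: float
    mean_gene_length_bp: float


@dataclass(frozen=True)
class MitoScreenResult:
    scaffold_id: str
    containment: float
    flagged: bool


def compute_assembly_stats(
    assembly: Mapping[str, Scaffold] | Iterable[Scaffold],
    min_len_bp: int = 1000,
    exclude_ids: frozenset[str] | set[str] = frozenset(),
) -> AssemblyStats:
    """Summarise an assembly after dropping excluded ids and scaffolds
    shorter than ``min_len_bp``."""
    scaffolds = list(assembly.values() if isinstance(assembly, Mapping) else assembly)
    kept = [s for s in scaffolds if s.id not in exclude_ids and s.length >= min_len_bp]
    if not kept:
        raise ValueError("no scaffolds remain after filtering")

    lengths = sorted((s.length for s in kept), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = l50 = 0
    for rank, ln in enumerate(lengths, 1):
        cum += ln
        if cum >= half:
            n50, l50 = ln, rank
            break

    gc = at = 0
    for s in kept:
        seq = s.sequence.upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    gc_pct = 100.0 * gc / (gc + at) if gc + at else 0.0

    return AssemblyStats(
        n_scaffolds=len(kept),
        total_bp=total,
        largest_bp=lengths[0],
        smallest_bp=lengths[-1],
        n50_bp=n50,
        l50=l50,
        gc_percent=gc_pct,
    )


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of 0-based half-open intervals."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + (ce - cs)


def compute_genome_fractions(
    assembly: Mapping[str, Scaffold],
    genes: Sequence[GeneModel],
    repeat_intervals: Sequence[ReadInterval] = (),
) -> GenomeFractions:
    """Genome fractions covered by genes, exons, introns and repeats.

    Overlapping spans are counted once (interval union per scaffold);
    introns are the gene-span union minus the exon union, which assumes
    single-transcript (pre-collapsed) gene models.
    """
    total_bp = sum(s.length for s in assembly.values())
    if total_bp == 0:
        raise ValueError("empty assembly")
    for g in genes:
        if g.scaffold_id not in assembly:
            raise ValueError(f"gene {g.gene_id} on unknown scaffold {g.scaffold_id}")

    by_scaf: dict[str, list[tuple[int, int]]] = {}
    coding: dict[str, list[tuple[int, int]]] = {}
    exonic: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        span = gene_span0(g)
        by_scaf.setdefault(g.scaffold_id, []).append(span)
        if g.biotype == "protein_coding":
            coding.setdefault(g.scaffold_id, []).append(span)
        for s, e in g.exons or [(g.start, g.end)]:
            exonic.setdefault(g.scaffold_id, []).append((s - 1, e))

    genes_bp = sum(_union_bp(v) for v in by_scaf.values())
    coding_bp = sum(_union_bp(v) for v in coding.values())
    exon_bp = sum(_union_bp(v) for v in exonic.values())
    repeat_bp = _union_bp_by_scaffold(repeat_intervals)

    n_genes = len(genes)
    return GenomeFractions(
        genes_pct=100.0 * genes_bp / total_bp,
        coding_genes_pct=100.0 * coding_bp / total_bp,
        exons_pct=100.0 * exon_bp / total_bp,
        introns_pct=100.0 * (genes_bp - exon_bp) / total_bp,
        repeats_pct=100.0 * repeat_bp / total_bp,
        gene_density_per_mbp=n_genes / (total_bp / 1e6),
        mean_gene_length_bp=(sum(g.length for g in genes) / n_genes) if n_genes else 0.0,
    )


def _union_bp_by_scaffold(intervals: Sequence[ReadInterval]) -> int:
    by_scaf: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_scaf.setdefault(iv.scaffold_id, []).append((iv.start, iv.end))
    return sum(_union_bp(v) for v in by_scaf.values())


def _canonical_kmers(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    rc = revcomp(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        yield min(fwd, rc[n - k - i : n - i])


def screen_mito_fragments(
    assembly: Mapping[str, Scaffold] | Iterable[Scaffold],
    mito_sequence: str,
    k: int = 31,
    threshold: float = 0.5,
) -> list[MitoScreenResult]:
    """Flag scaffolds that are largely composed of mitochondrial sequence.

    The mitochondrial genome is treated as circular: wrap-around k-mers are
    included. Containment for a scaffold is the fraction of its k-mer start
    positions whose canonical k-mer occurs in the mitochondrial k-mer set;
    k-mers containing ambiguity codes never match. Scaffolds shorter than k
    are skipped.
    """
    if k > len(mito_sequence):
        raise ValueError(f"k={k} exceeds mitochondrial sequence length")
    scaffolds = list(assembly.values() if isinstance(assembly, Mapping) else assembly)
    circular = mito_sequence + mito_sequence[: k - 1]
    mito_kmers = set(_canonical_kmers(circular, k))

    results = []
    for sc in sorted(scaffolds, key=lambda s: s.id):
        n_pos = sc.length - k + 1
        if n_pos < 1:
            continue
        matches = sum(1 for km in _canonical_kmers(sc.sequence, k) if km in mito_kmers)
        containment = matches / n_pos
        results.append(
            MitoScreenResult(sc.id, containment, flagged=containment >= threshold)
        )
    return results
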