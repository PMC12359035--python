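"""Intron interval arithmetic and intronic read assignment.

Introns are defined per gene as the gene span minus the union of all exons of
all that gene's transcripts.  They are exported in SAF (Simplified Annotation
File: GeneID/Chr/Start/End/Strand, 1-based inclusive), reads enter as BED
intervals (0-based half-open), and genes with at least one intronic read are
flagged -- a proxy for pre-mRNA presence in an immunoprecipitate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from smsite.annotation_io import GeneModel

__all__ = [
    "IntronSet",
    "ReadInterval",
    "build_introns",
    "write_saf",
    "read_saf",
    "read_bed",
    "count_intronic",
    "flag_intronic_genes",
]


@dataclass
class IntronSet:
    """Per-gene intron intervals (0-based half-open, sorted, disjoint)."""

    introns: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    chrom: dict[str, str] = field(default_factory=dict)
    strand: dict[str, str] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.introns)


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def build_introns(genes: Sequence[GeneModel]) -> IntronSet:
    """Subtract the exon union of each gene from its span."""
    out = IntronSet()
    for g in genes:
        exons = _merge((a, b) for t in g.transcripts for a, b in t.exons)
        lo, hi = g.span()
        introns = []
        cursor = lo
        for a, b in exons:
            if a > cursor:
                introns.append((cursor, a))
            cursor = max(cursor, b)
        if cursor < hi:
            introns.append((cursor, hi))
        out.introns[g.gene_id] = introns
        out.chrom[g.gene_id] = g.chrom
        out.strand[g.gene_id] = g.strand
    return out


def write_saf(introns: IntronSet, path) -> None:
    """Write intron intervals as SAF (1-based inclusive), sorted by (Chr, Start)."""
    rows = []
    for gid in introns.genes():
        for a, b in introns.introns[gid]:
            rows.append((introns.chrom[gid], a + 1, b, gid, introns.strand[gid]))
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        fh.write("GeneID\tChr\tStart\tEnd\tStrand\n")
        for chrom, start, end, gid, strand in rows:
            fh.write(f"{gid}\t{chrom}\t{start}\t{end}\t{strand}\n")


def read_saf(path) -> IntronSet:
    out = IntronSet()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["GeneID", "Chr", "Start", "End", "Strand"]:
            raise ValueError(f"not a SAF file: {path}")
        for line in fh:
            gid, chrom, start, end, strand = line.rstrip("\n").split("\t")[:5]
            out.introns.setdefault(gid, []).append((int(start) - 1, int(end)))
            out.chrom[gid] = chrom
            out.strand[gid] = strand
    for gid in out.introns:
        out.introns[gid].sort()
    return out


@dataclass(frozen=True)
class ReadInterval:
    """An aligned read reduced to a genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty read interval [{self.start},{self.end})")


def read_bed(path) -> list[ReadInterval]:
    """Read BED3/BED6 read intervals."""
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            reads.append(
                ReadInterval(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else "",
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return reads


def count_intronic(
    reads: Sequence[ReadInterval],
    introns: IntronSet,
    min_overlap: int = 1,
    fraction: bool = False,
    stranded: bool = False,
) -> dict[str, float]:
    """Assign reads to genes by intron overlap of at least ``min_overlap`` bases.

    A read overlapping introns of several genes counts once for each
    (``fraction=True`` splits 1/k across the k genes instead).  Counts are
    integers unless ``fraction`` is set.  Strand is ignored unless
    ``stranded``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for gid in introns.genes():
        chrom = introns.chrom[gid]
        tree = trees.setdefault(chrom, IntervalTree())
        for a, b in introns.introns[gid]:
            tree.addi(a, b, gid)
    counts: dict[str, float] = {gid: 0 for gid in introns.genes()}
    for r in reads:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        genes_hit = set()
        for iv in tree.overlap(r.start, r.end):
            if min(r.end, iv.end) - max(r.start, iv.begin) >= min_overlap:
                gid = iv.data
                if stranded and r.strand in "+-" and introns.strand[gid] != r.strand:
                    continue
                genes_hit.add(gid)
        w = 1.0 / len(genes_hit) if (fraction and genes_hit) else 1.0
        for gid in genes_hit:
            counts[gid] += w
    if not fraction:
        counts = {g: int(round(c)) for g, c in counts.items()}
    return counts


def flag_intronic_genes(counts: Mapping[str, float]) -> set[str]:
    """Genes with at least one intron-assigned read."""
    return {g for g, c in counts.items() if c >= 1}
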