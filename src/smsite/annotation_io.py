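"""Reading genomes and annotations, and building transcript models.

Coordinate conventions: everything in memory is 0-based half-open.  GFF3 and
GTF are read and written 1-based inclusive, BED is 0-based half-open and SAF
is 1-based inclusive.  T and U are treated as the same letter; sequences are
uppercased on input (soft-masking is ignored) and transcript sequences are
reported in the RNA alphabet.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequences",
    "Region",
    "TranscriptModel",
    "GeneModel",
    "read_fasta",
    "read_annotation",
    "write_gff3",
    "extract_transcript_sequence",
    "map_region",
    "select_representative",
    "gene_table",
]

#: mapping chromosome name -> uppercased nucleotide string
GenomeSequences = dict


class Region(enum.Enum):
    """Transcript region of a position: 5'UTR, CDS, 3'UTR, noncoding, or N/A."""

    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"
    NONCODING = "noncoding"
    NA = "NA"

    def __str__(self) -> str:  # stable labels for TSV output
        return self.value


@dataclass
class TranscriptModel:
    """One spliced transcript: exon chain, strand, CDS bounds and tags.

    ``exons`` are genomic intervals (0-based half-open) sorted by genomic
    start; ``cds_start``/``cds_end`` are offsets in transcript coordinates
    (0-based half-open along the 5'->3' spliced sequence) or ``None`` for
    noncoding transcripts.
    """

    transcript_id: str
    gene_id: str
    gene_name: str = ""
    biotype: str = ""
    strand: str = "+"
    chrom: str = ""
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a0, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a0},{b0}) and [{a1},...)"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"transcript {self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not 0 <= self.cds_start < self.cds_end <= self.transcript_length:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS "
                    f"[{self.cds_start},{self.cds_end}) outside transcript "
                    f"of length {self.transcript_length}"
                )

    @property
    def transcript_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def utr5_length(self) -> int:
        return self.cds_start if self.is_coding else 0

    @property
    def cds_length(self) -> int:
        return (self.cds_end - self.cds_start) if self.is_coding else 0

    @property
    def utr3_length(self) -> int:
        return (self.transcript_length - self.cds_end) if self.is_coding else 0

    def genomic_to_transcript(self, gpos: int) -> int:
        """Project a genomic position inside an exon to a transcript offset."""
        off = 0
        if self.strand == "+":
            for a, b in self.exons:
                if a <= gpos < b:
                    return off + (gpos - a)
                off += b - a
        else:
            for a, b in reversed(self.exons):
                if a <= gpos < b:
                    return off + (b - 1 - gpos)
                off += b - a
        raise ValueError(
            f"genomic position {gpos} not exonic in transcript {self.transcript_id}"
        )

    def transcript_to_genomic_intervals(
        self, tstart: int, tend: int
    ) -> list[tuple[int, int]]:
        """Genomic intervals covered by transcript range [tstart, tend)."""
        out = []
        off = 0
        exons = self.exons if self.strand == "+" else list(reversed(self.exons))
        for a, b in exons:
            elen = b - a
            lo, hi = max(tstart, off), min(tend, off + elen)
            if lo < hi:
                if self.strand == "+":
                    out.append((a + (lo - off), a + (hi - off)))
                else:
                    out.append((b - (hi - off), b - (lo - off)))
            off += elen
        return sorted(out)


@dataclass
class GeneModel:
    """A gene and its transcripts, with an optional representative."""

    gene_id: str
    gene_name: str = ""
    transcripts: list[TranscriptModel] = field(default_factory=list)
    representative: str | None = None

    def __post_init__(self) -> None:
        if self.representative is not None:
            ids = {t.transcript_id for t in self.transcripts}
            if self.representative not in ids:
                raise ValueError(
                    f"gene {self.gene_id}: representative {self.representative} "
                    "is not a member transcript"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    def span(self) -> tuple[int, int]:
        starts = [a for t in self.transcripts for a, _ in t.exons]
        ends = [b for t in self.transcripts for _, b in t.exons]
        return min(starts), max(ends)


def read_fasta(path) -> GenomeSequences:
    """Read a (multi-)FASTA into a name -> uppercase sequence mapping.

    Headers are tokenized on the first whitespace.  Lowercase (soft-masked)
    letters are uppercased.  Duplicate names are an error.
    """
    seqs: GenomeSequences = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seqs:
            raise ValueError(f"duplicate FASTA header: {name}")
        s = str(rec.seq).upper()
        if not s:
            raise ValueError(f"empty sequence for FASTA record {name}")
        seqs[name] = s
    if not seqs:
        raise ValueError(f"no FASTA records parsed from {path}")
    return seqs


# Attribute keys marking representative transcripts.  GFF3 uses e.g.
# `tag=MANE_Select`; GTF uses repeated `tag "MANE_Select";` attributes.
# The keys are configurable because annotation dialects vary.
DEFAULT_TAG_VALUES = {
    "MANE_Select": "MANE",
    "MANE": "MANE",
    "Ensembl_canonical": "canonical",
    "canonical": "canonical",
}


def _attr(feature, *names) -> str | None:
    for n in names:
        if n in feature.attributes:
            v = feature.attributes[n]
            return v[0] if isinstance(v, list) else v
    return None


def read_annotation(
    path,
    dialect: str = "gff3",
    tag_values: dict[str, str] | None = None,
) -> list[GeneModel]:
    """Read a GFF3 or GTF annotation into GeneModels.

    File coordinates (1-based inclusive) are converted to 0-based half-open.
    CDS rows are projected through the exon chain into transcript coordinates.
    ``tag_values`` maps annotation tag strings to internal tags
    (``MANE``/``canonical``).
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation dialect: {dialect}")
    tag_values = DEFAULT_TAG_VALUES if tag_values is None else tag_values
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    tx_kinds = ("mRNA", "transcript")
    for g in db.features_of_type("gene"):
        gene_id = _attr(g, "gene_id", "ID") or g.id
        gene_name = _attr(g, "gene_name", "Name") or gene_id
        model = GeneModel(gene_id=gene_id, gene_name=gene_name)
        for t in db.children(g, featuretype=tx_kinds, order_by="start"):
            tid = _attr(t, "transcript_id", "ID") or t.id
            exons = []
            for e in db.children(t, featuretype="exon", order_by="start"):
                exons.append((e.start - 1, e.end))
            if not exons:
                continue
            tspan = (min(a for a, _ in exons), max(b for _, b in exons))
            if not (g.start - 1 <= tspan[0] and tspan[1] <= g.end):
                raise ValueError(
                    f"transcript {tid}: exons outside the span of gene {gene_id}"
                )
            cds = [(c.start - 1, c.end) for c in db.children(t, featuretype="CDS")]
            tags = set()
            for v in t.attributes.get("tag", []):
                if v in tag_values:
                    tags.add(tag_values[v])
            tm = TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                gene_name=gene_name,
                biotype=_attr(t, "biotype", "transcript_biotype", "gene_biotype")
                or ("protein_coding" if cds else ""),
                strand=t.strand,
                chrom=t.seqid,
                exons=exons,
                tags=frozenset(tags),
            )
            if cds:
                g0 = min(a for a, _ in cds)
                g1 = max(b for _, b in cds)
                for a, b in cds:
                    if not any(ea <= a and b <= eb for ea, eb in tm.exons):
                        raise ValueError(
                            f"transcript {tid}: CDS [{a},{b}) not contained "
                            "in any exon"
                        )
                if tm.strand == "+":
                    cs = tm.genomic_to_transcript(g0)
                    ce = tm.genomic_to_transcript(g1 - 1) + 1
                else:
                    cs = tm.genomic_to_transcript(g1 - 1)
                    ce = tm.genomic_to_transcript(g0) + 1
                tm.cds_start, tm.cds_end = cs, ce
                tm.__post_init__()
            model.transcripts.append(tm)
        if model.transcripts:
            genes[gene_id] = model
    return list(genes.values())


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Write GeneModels as GFF3 (1-based inclusive) so they round-trip."""
    inv_tags = {"MANE": "MANE_Select", "canonical": "Ensembl_canonical"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.span(), x.gene_id)):
            lo, hi = g.span()
            fh.write(
                f"{g.chrom}\tsmsite\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id};gene_name={g.gene_name}\n"
            )
            for t in g.transcripts:
                ta, tb = t.exons[0][0], t.exons[-1][1]
                attrs = (
                    f"ID={t.transcript_id};Parent={g.gene_id};"
                    f"transcript_id={t.transcript_id};biotype={t.biotype}"
                )
                for tag in sorted(t.tags):
                    attrs += f";tag={inv_tags[tag]}"
                fh.write(
                    f"{t.chrom}\tsmsite\tmRNA\t{ta + 1}\t{tb}\t.\t{t.strand}\t.\t"
                    f"{attrs}\n"
                )
                for i, (a, b) in enumerate(t.exons, 1):
                    fh.write(
                        f"{t.chrom}\tsmsite\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                if t.is_coding:
                    for a, b in t.transcript_to_genomic_intervals(
                        t.cds_start, t.cds_end
                    ):
                        fh.write(
                            f"{t.chrom}\tsmsite\tCDS\t{a + 1}\t{b}\t.\t{t.strand}\t0\t"
                            f"ID={t.transcript_id}.cds;Parent={t.transcript_id}\n"
                        )


def extract_transcript_sequence(genome: GenomeSequences, t: TranscriptModel) -> str:
    """Spliced transcript sequence, 5'->3', RNA alphabet.

    Exons are concatenated in transcript orientation; minus-strand transcripts
    are reverse-complemented; DNA letters are transcribed (T -> U).
    """
    chrom = genome.get(t.chrom)
    if chrom is None:
        raise ValueError(f"chromosome {t.chrom!r} not in genome")
    parts = []
    for a, b in t.exons:
        if not (0 <= a < b <= len(chrom)):
            raise ValueError(
                f"transcript {t.transcript_id}: exon [{a},{b}) outside "
                f"chromosome {t.chrom} of length {len(chrom)}"
            )
        parts.append(chrom[a:b])
    seq = "".join(parts)
    if t.strand == "-":
        seq = str(Seq(seq.replace("U", "T")).reverse_complement())
    return seq.replace("T", "U")


def map_region(t: TranscriptModel, pos: int) -> Region:
    """Region of a transcript coordinate (half-open CDS bounds)."""
    if pos < 0:
        raise ValueError(f"negative transcript coordinate: {pos}")
    if pos >= t.transcript_length:
        return Region.NA
    if not t.is_coding:
        return Region.NONCODING
    if pos < t.cds_start:
        return Region.FIVE_UTR
    if pos < t.cds_end:
        return Region.CDS
    return Region.THREE_UTR


def select_representative(g: GeneModel) -> str:
    """One transcript per gene: MANE > canonical > longest > smallest ID."""
    if not g.transcripts:
        raise ValueError(f"gene {g.gene_id} has no transcripts")
    best = min(
        g.transcripts,
        key=lambda t: (
            "MANE" not in t.tags,
            "canonical" not in t.tags,
            -t.transcript_length,
            t.transcript_id,
        ),
    )
    return best.transcript_id


def gene_table(genes: Iterable[GeneModel]):
    """Per-gene table of the representative transcript and region lengths."""
    import pandas as pd

    rows = []
    for g in sorted(genes, key=lambda x: x.gene_id):
        rep = select_representative(g)
        t = next(t for t in g.transcripts if t.transcript_id == rep)
        rows.append(
            {
                "gene_id": g.gene_id,
                "transcript_id": t.transcript_id,
                "gene_name": g.gene_name,
                "biotype": t.biotype,
                "transcript_length": t.transcript_length,
                "utr5_length": t.utr5_length,
                "cds_length": t.cds_length,
                "utr3_length": t.utr3_length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "transcript_id",
            "gene_name",
            "biotype",
            "transcript_length",
            "utr5_length",
            "cds_length",
            "utr3_length",
        ],
    )
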