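"""Synthetic transcriptomes, read intervals and count matrices with ground truth.

The generator emulates the statistical structure the analysis assumes, not
real genomes: a motif-free background (rejection-sampled so that no unplanted
window matches any Sm-site pattern, the degenerate noncanonical pattern
included), planted Sm-sites of known motif class, region and structure
status, and RIP-style negative-binomial count matrices in which canonical
Sm-site genes carry a planted positive log2 fold-change in an "ATP+"
condition versus "ATP-".

Structure status is guaranteed by construction.  A structured site's captured
flanking windows are fully designed: a 6-bp GC stem with a CACA loop sits
inside the 20-nt-5'/10-nt-3' decision windows, and the rest of the window is
filled with C/A letters.  With AU/GC/GU pairing rules a C/A-only stretch can
form no pair, so inside a designed window every possible pair involves a stem
base -- any maximum-weight folding pairs the stem and the filter retains the
site.  An unstructured site's windows are C/A-only throughout and can form no
pair at all, so the filter always rejects it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from smsite.annotation_io import GeneModel, Region, TranscriptModel
from smsite.enrichment_stats import CountMatrix
from smsite.intron_counts import ReadInterval
from smsite.smsite_scan import (
    DOWNSTREAM_MAX,
    MOTIF_BY_NAME,
    UPSTREAM_WINDOW,
    scan_sm_sites,
)

__all__ = [
    "PlantSpec",
    "SimConfig",
    "TruthSite",
    "TruthTable",
    "make_class_labels",
    "make_transcriptome",
    "make_counts",
    "make_reads",
    "write_simulation",
]

CANONICAL_LABEL = "Canonical"
NONCANONICAL_LABEL = "Noncanonical"
ABSENT_LABEL = "Absent"

# a noncanonical-pattern instance (AUNUKUN) that matches no canonical motif
NC_ONLY_SITE = "AUAUGUA"

STEM5 = "GGCGGC"
STEM3 = "GCCGCC"  # reverse complement of STEM5
LOOP = "CACA"
HAIRPIN = STEM5 + LOOP + STEM3
# designed downstream block: pairs begin 2 nt after the site, inside the
# 10-nt 3' decision window; 18 nt total satisfies the >= 16 nt capture rule
DOWN_BLOCK = "CC" + HAIRPIN
# designed upstream block: pairs end 2 nt before the site, inside the 20-nt
# 5' decision window
UP_BLOCK = HAIRPIN + "CC"


@dataclass(frozen=True)
class PlantSpec:
    """Plant one site of this kind in each of ``count`` genes."""

    motif_name: str
    region: Region
    structured: bool
    count: int


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults give 1000 genes of which 15% carry one structured canonical
    Sm-site, 20% one structured noncanonical site and 10% one unstructured
    canonical site (scanned but rejected by the structure filter); canonical
    genes carry a planted +1.0 log2 fold-change in the ATP+ condition, with
    negative-binomial counts at dispersion 0.1 over 3 vs 3 samples.
    """

    seed: int = 0
    n_genes: int = 1000
    frac_canonical: float = 0.15
    frac_noncanonical: float = 0.20
    frac_unstructured: float = 0.10
    site_region: Region = Region.THREE_UTR
    planted_sites: list[PlantSpec] | None = None
    # lognormal region lengths: (median nt, sigma of log), with a hard floor
    utr5_length: tuple[float, float] = (150.0, 0.4)
    cds_length: tuple[float, float] = (900.0, 0.4)
    utr3_length: tuple[float, float] = (900.0, 0.6)
    min_region_length: int = 300
    intron_length: tuple[int, int] = (80, 200)
    # count model
    basemean: tuple[float, float] = (200.0, 1.0)  # lognormal (median, sigma)
    dispersion: float = 0.1
    planted_lfc: dict = field(
        default_factory=lambda: {CANONICAL_LABEL: 1.0}
    )
    samples_per_condition: int = 3
    conditions: tuple[str, str] = ("ATP+", "ATP-")
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    # reads
    reads_per_gene: int = 20
    intronic_fraction: float = 0.5
    read_length: int = 50

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        fracs = (self.frac_canonical, self.frac_noncanonical, self.frac_unstructured)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass(frozen=True)
class TruthSite:
    motif_name: str
    start: int
    region: Region
    structured: bool


@dataclass
class TruthTable:
    """Ground truth: planted sites, class labels, true fold-changes."""

    labels: dict[str, str] = field(default_factory=dict)
    lfc: dict[str, float] = field(default_factory=dict)
    sites: dict[str, list[TruthSite]] = field(default_factory=dict)
    intronic_reads: dict[str, int] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.labels)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes():
            site_str = ";".join(
                f"{s.motif_name}@{s.start}:{s.region}:"
                f"{'hairpin' if s.structured else 'none'}"
                for s in self.sites.get(g, [])
            )
            rows.append(
                {
                    "gene_id": g,
                    "label": self.labels[g],
                    "true_lfc": self.lfc[g],
                    "planted_sites": site_str,
                    "intronic_reads": self.intronic_reads.get(g, 0),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "label", "true_lfc", "planted_sites", "intronic_reads"],
        )


def _gene_id(i: int) -> str:
    return f"g{i + 1:04d}"


def _plans(cfg: SimConfig, rng: np.random.Generator) -> list[list[PlantSpec]]:
    """Per-gene planting plans, in gene order."""
    n = cfg.n_genes
    if cfg.planted_sites is not None:
        total = sum(p.count for p in cfg.planted_sites)
        if total > n:
            raise ValueError(
                f"planted-site spec covers {total} genes but n_genes = {n}"
            )
        plans: list[list[PlantSpec]] = []
        for spec in cfg.planted_sites:
            plans.extend([[spec]] * spec.count)
        plans.extend([[]] * (n - total))
        return plans
    n_canon = round(cfg.frac_canonical * n)
    n_nc = round(cfg.frac_noncanonical * n)
    n_unstr = round(cfg.frac_unstructured * n)
    plans = []
    canonical_motifs = ("U1", "U2", "U5")
    for i in range(n_canon):
        m = canonical_motifs[int(rng.integers(3))]
        plans.append([PlantSpec(m, cfg.site_region, True, 1)])
    for _ in range(n_nc):
        plans.append([PlantSpec("NC", cfg.site_region, True, 1)])
    for i in range(n_unstr):
        m = canonical_motifs[int(rng.integers(3))]
        plans.append([PlantSpec(m, cfg.site_region, False, 1)])
    plans.extend([[]] * (n - len(plans)))
    return plans


def _label_for(plan: list[PlantSpec]) -> str:
    structured = [p for p in plan if p.structured]
    if any(p.motif_name in ("U1", "U2", "U5") for p in structured):
        return CANONICAL_LABEL
    if any(p.motif_name == "NC" for p in structured):
        return NONCANONICAL_LABEL
    return ABSENT_LABEL


def make_class_labels(cfg: SimConfig) -> TruthTable:
    """Gene class labels and true fold-changes, without building sequences.

    Uses the same random stream as :func:`make_transcriptome`, so labels are
    identical whether or not sequences are generated.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    truth = TruthTable()
    for i, plan in enumerate(_plans(cfg, rng)):
        gid = _gene_id(i)
        label = _label_for(plan)
        truth.labels[gid] = label
        truth.lfc[gid] = float(cfg.planted_lfc.get(label, 0.0))
    return truth


_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _ca_filler(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(["C", "A"])[rng.integers(0, 2, size=n)])


def _motif_free_background(rng: np.random.Generator, n: int, block: int = 80) -> str:
    """Rejection-sample background so no window matches any Sm-site motif.

    Blocks are resampled until the block, together with the junction overlap
    to the already-accepted sequence, is motif-free.  The probe is extended
    with a C guard so a block can never end in a motif prefix whose remaining
    positions are unconstrained (an ``AUNUKU`` tail, say, would otherwise be
    completed by *any* next letter); C completes an N position but no
    U-requiring position, and an all-C tail can start no motif itself.
    """
    overlap = max(len(m.pattern) for m in MOTIF_BY_NAME.values()) - 1
    guard = "C" * overlap
    out = ""
    while len(out) < n:
        take = min(block, n - len(out))
        for _ in range(1000):
            cand = _random_rna(rng, take)
            probe = out[-overlap:] + cand + guard
            if not any(
                _scan_starts(probe, name) for name in MOTIF_BY_NAME
            ):
                out += cand
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not sample a motif-free background block")
    return out


def _scan_starts(seq: str, motif_name: str) -> list[int]:
    from smsite.smsite_scan import _COMPILED

    return list(_COMPILED[motif_name].finditer(seq))


def _region_bounds(utr5: int, cds: int, utr3: int, region: Region) -> tuple[int, int]:
    if region == Region.FIVE_UTR:
        return 0, utr5
    if region == Region.CDS:
        return utr5, utr5 + cds
    if region == Region.THREE_UTR:
        return utr5 + cds, utr5 + cds + utr3
    raise ValueError(f"cannot plant a site in region {region}")


def _site_sequence(spec: PlantSpec, rng: np.random.Generator) -> str:
    if spec.motif_name == "NC":
        return NC_ONLY_SITE
    return MOTIF_BY_NAME[spec.motif_name].pattern


def _build_transcript(
    cfg: SimConfig,
    plan: list[PlantSpec],
    rng: np.random.Generator,
) -> tuple[str, int, int, list[TruthSite]]:
    """One transcript sequence with its CDS bounds and planted-site truth."""
    med5, sig5 = cfg.utr5_length
    medc, sigc = cfg.cds_length
    med3, sig3 = cfg.utr3_length
    utr5 = max(cfg.min_region_length // 3, int(rng.lognormal(np.log(med5), sig5)))
    cds = max(cfg.min_region_length, int(rng.lognormal(np.log(medc), sigc)))
    utr3 = max(cfg.min_region_length, int(rng.lognormal(np.log(med3), sig3)))
    length = utr5 + cds + utr3

    seq = list(_motif_free_background(rng, length))
    sites: list[TruthSite] = []
    for spec in plan:
        site = _site_sequence(spec, rng)
        r0, r1 = _region_bounds(utr5, cds, utr3, spec.region)
        start = r0 + (r1 - r0) // 2
        start = min(start, r1 - 1, length - len(site) - len(DOWN_BLOCK))
        if start < r0:
            raise ValueError(
                f"region {spec.region} too short to plant a "
                f"{spec.motif_name} site"
            )
        up_len = min(UPSTREAM_WINDOW, start)
        down_len = min(DOWNSTREAM_MAX, length - start - len(site))
        if up_len < len(UP_BLOCK) or down_len < len(DOWN_BLOCK):
            raise ValueError(
                f"not enough flanking sequence to plant a {spec.motif_name} "
                f"site in region {spec.region}"
            )
        if spec.structured:
            up = _ca_filler(rng, up_len - len(UP_BLOCK)) + UP_BLOCK
            down = DOWN_BLOCK + _ca_filler(rng, down_len - len(DOWN_BLOCK))
        else:
            up = _ca_filler(rng, up_len)
            down = _ca_filler(rng, down_len)
        cassette = up + site + down
        a = start - up_len
        seq[a : a + len(cassette)] = cassette
        sites.append(TruthSite(spec.motif_name, start, spec.region, spec.structured))
    return "".join(seq), utr5, utr5 + cds, sites


def _expected_hits(sites: list[TruthSite]) -> set[tuple[str, int]]:
    # every canonical or U7 site start is also a noncanonical-pattern start
    expected = set()
    for s in sites:
        expected.add((s.motif_name, s.start))
        expected.add(("NC", s.start))
    return expected


def make_transcriptome(
    cfg: SimConfig,
) -> tuple[dict, list[GeneModel], TruthTable]:
    """Generate a genome, gene models and ground truth.

    Every transcript is verified after assembly: the scanner must report
    exactly the planted sites (plus the noncanonical-pattern matches they
    imply) and nothing else; a gene whose cassette junctions create a
    spurious match is resampled.  Deterministic for a fixed seed.
    """
    rng_labels = np.random.default_rng([cfg.seed, 0])
    rng = np.random.default_rng([cfg.seed, 1])
    plans = _plans(cfg, rng_labels)
    truth = TruthTable()
    genes: list[GeneModel] = []
    chrom_parts: list[str] = []
    offset = 0
    chrom = "chrSim"
    for i, plan in enumerate(plans):
        gid = _gene_id(i)
        tid = f"t{i + 1:04d}"
        for attempt in range(100):
            seq, cds_start, cds_end, sites = _build_transcript(cfg, plan, rng)
            found = {
                (h.motif_name, h.start)
                for h in scan_sm_sites(tid, seq)
            }
            if found == _expected_hits(sites):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not build a clean transcript for {gid}")
        # two exons with an intron in between
        length = len(seq)
        split = int(rng.integers(length // 4, 3 * length // 4))
        intron_len = int(rng.integers(*cfg.intron_length))
        intron = _random_rna(rng, intron_len).replace("U", "T")
        dna = seq.replace("U", "T")
        exon1 = (offset, offset + split)
        exon2 = (exon1[1] + intron_len, exon1[1] + intron_len + (length - split))
        chrom_parts.append(dna[:split])
        chrom_parts.append(intron)
        chrom_parts.append(dna[split:])
        spacer = _random_rna(rng, 100).replace("U", "T")
        chrom_parts.append(spacer)
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            gene_name=gid.upper(),
            biotype="protein_coding",
            strand="+",
            chrom=chrom,
            exons=[exon1, exon2],
            cds_start=cds_start,
            cds_end=cds_end,
            tags=frozenset({"canonical"}),
        )
        genes.append(GeneModel(gene_id=gid, gene_name=gid.upper(), transcripts=[t]))
        offset = exon2[1] + 100
        label = _label_for(plan)
        truth.labels[gid] = label
        truth.lfc[gid] = float(cfg.planted_lfc.get(label, 0.0))
        truth.sites[gid] = sites
    genome = {chrom: "".join(chrom_parts)}
    return genome, genes, truth


def make_counts(truth: TruthTable, cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """RIP-style count matrix: NB(mean = basemean * 2^(lfc * [ATP+]) * sf_s).

    Sample-wise size factors are drawn log-uniform over
    ``cfg.size_factor_range``; counts are Gamma-Poisson draws at
    ``cfg.dispersion`` (Poisson in the zero-dispersion limit).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    gene_ids = truth.genes()
    n = len(gene_ids)
    cond_plus, cond_minus = cfg.conditions
    samples = [
        (f"{'atp_plus' if c == cond_plus else 'atp_minus'}_{r + 1}", c)
        for c in (cond_plus, cond_minus)
        for r in range(cfg.samples_per_condition)
    ]
    med, sig = cfg.basemean
    basemean = rng.lognormal(np.log(med), sig, size=n)
    lo, hi = cfg.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
    lfc = np.array([truth.lfc[g] for g in gene_ids])
    data = np.empty((n, len(samples)), dtype=np.int64)
    for j, (sample, cond) in enumerate(samples):
        mu = basemean * (2.0 ** (lfc * (cond == cond_plus))) * sf[j]
        if cfg.dispersion == 0:
            data[:, j] = rng.poisson(mu)
        else:
            lam = rng.gamma(1.0 / cfg.dispersion, mu * cfg.dispersion)
            data[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(data, index=gene_ids, columns=[s for s, _ in samples])
    design = pd.DataFrame(samples, columns=["sample", "condition"])
    return CountMatrix(counts, dict(samples)), design


def make_reads(
    genes: list[GeneModel], cfg: SimConfig, truth: TruthTable | None = None
) -> list[ReadInterval]:
    """Place read intervals inside introns or exons of each gene.

    Each read falls entirely inside a single intron (with probability
    ``cfg.intronic_fraction``, when the gene has an intron) or a single exon,
    so the per-gene intronic tally recorded in the truth table is exact.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    reads: list[ReadInterval] = []
    for g in genes:
        t = g.transcripts[0]
        exons = t.exons
        introns = [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(exons, exons[1:])
            if b_start > a_end
        ]
        n_intronic = 0
        for k in range(cfg.reads_per_gene):
            intronic = bool(introns) and rng.random() < cfg.intronic_fraction
            pool = introns if intronic else list(exons)
            a, b = pool[int(rng.integers(len(pool)))]
            rl = min(cfg.read_length, b - a)
            start = int(rng.integers(a, b - rl + 1))
            reads.append(
                ReadInterval(
                    chrom=t.chrom,
                    start=start,
                    end=start + rl,
                    name=f"{g.gene_id}_read{k + 1}_{'intron' if intronic else 'exon'}",
                    strand=t.strand,
                )
            )
            n_intronic += intronic
        if truth is not None:
            truth.intronic_reads[g.gene_id] = n_intronic
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.name))
    return reads


def write_fasta(genome: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            s = genome[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_simulation(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Run the generator and write genome.fa, annotation.gff3, reads.bed,
    counts.tsv, design.tsv and truth.tsv into ``outdir``."""
    from smsite.annotation_io import write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = make_transcriptome(cfg)
    reads = make_reads(genes, cfg, truth)
    counts, design = make_counts(truth, cfg)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "reads": outdir / "reads.bed",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(genes, paths["annotation"])
    with open(paths["reads"], "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")
    counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    design.to_csv(paths["design"], sep="\t", index=False)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
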