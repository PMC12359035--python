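"""End-to-end site discovery over a genome + annotation.

Glues the stages together the way the command-line interface and the tests
use them: pick one representative transcript per gene, extract its spliced
sequence, scan for Sm-sites, resolve the flanking-structure decision on every
hit, and summarize per gene.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from smsite.annotation_io import (
    GeneModel,
    extract_transcript_sequence,
    select_representative,
)
from smsite.smsite_scan import (
    MOTIFS,
    GeneSiteSummary,
    SmSiteHit,
    scan_sm_sites,
    summarize_gene,
)
from smsite.structure_filter import Folder, apply_structure_filter

__all__ = [
    "scan_genes",
    "hits_frame",
    "master_frame",
    "label_from_summary",
]


def scan_genes(
    genome: dict,
    genes: Sequence[GeneModel],
    motifs=MOTIFS,
    folder: Folder | None = None,
) -> tuple[list[SmSiteHit], list[GeneSiteSummary]]:
    """Scan the representative transcript of every gene.

    Returns all hits (with resolved structure decisions; rejected hits are
    kept and flagged) and the per-gene summaries of retained hits.
    """
    all_hits: list[SmSiteHit] = []
    summaries: list[GeneSiteSummary] = []
    for g in sorted(genes, key=lambda x: x.gene_id):
        rep = select_representative(g)
        t = next(t for t in g.transcripts if t.transcript_id == rep)
        seq = extract_transcript_sequence(genome, t)
        hits = scan_sm_sites(t.transcript_id, seq, motifs, transcript=t)
        hits = apply_structure_filter(hits, folder=folder)
        all_hits.extend(hits)
        summaries.append(summarize_gene(hits, t))
    return all_hits, summaries


def hits_frame(hits: Sequence[SmSiteHit], genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-hit table mirroring the per-site output files."""
    by_tid = {
        t.transcript_id: (g.gene_id, g.gene_name)
        for g in genes
        for t in g.transcripts
    }
    rows = []
    for h in hits:
        gid, gname = by_tid.get(h.transcript_id, ("", ""))
        rows.append(
            {
                "transcript_id": h.transcript_id,
                "gene_id": gid,
                "gene_name": gname,
                "motif_name": h.motif_name,
                "start": h.start,
                "region": str(h.region),
                "site_seq": h.site_seq,
                "downstream_seq": h.downstream_seq,
                "upstream_ok": h.upstream_ok,
                "downstream_ok": h.downstream_ok,
                "retained": h.retained,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "gene_name",
            "motif_name",
            "start",
            "region",
            "site_seq",
            "downstream_seq",
            "upstream_ok",
            "downstream_ok",
            "retained",
        ],
    )
    return df.sort_values(["transcript_id", "start", "motif_name"]).reset_index(
        drop=True
    )


_REGION_COLS = {
    ("canonical", "5UTR"): "canonical_5utr",
    ("canonical", "CDS"): "canonical_cds",
    ("canonical", "3UTR"): "canonical_3utr",
    ("canonical", "noncoding"): "canonical_noncoding",
    ("noncanonical", "5UTR"): "noncanonical_5utr",
    ("noncanonical", "CDS"): "noncanonical_cds",
    ("noncanonical", "3UTR"): "noncanonical_3utr",
    ("noncanonical", "noncoding"): "noncanonical_noncoding",
    ("u7", "5UTR"): "u7_5utr",
    ("u7", "CDS"): "u7_cds",
    ("u7", "3UTR"): "u7_3utr",
    ("u7", "noncoding"): "u7_noncoding",
}


def master_frame(summaries: Sequence[GeneSiteSummary]) -> pd.DataFrame:
    """Per-gene master table: motif-class counts, region counts and lengths."""
    rows = []
    for s in sorted(summaries, key=lambda x: x.gene_id):
        row = {
            "gene_id": s.gene_id,
            "transcript_id": s.transcript_id,
            "n_U1": s.n_U1,
            "n_U2": s.n_U2,
            "n_U5": s.n_U5,
            "n_U7": s.n_U7,
            "n_NC_raw": s.n_NC_raw,
            "canonical_total": s.canonical_total,
            "nc_true": s.nc_true,
            "transcript_length": s.transcript_length,
            "utr5_length": s.utr5_length,
            "cds_length": s.cds_length,
            "utr3_length": s.utr3_length,
        }
        for key, col in _REGION_COLS.items():
            row[col] = s.region_counts.get(
                (key[0], _region_from_label(key[1])), 0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _region_from_label(label: str):
    from smsite.annotation_io import Region

    return {
        "5UTR": Region.FIVE_UTR,
        "CDS": Region.CDS,
        "3UTR": Region.THREE_UTR,
        "noncoding": Region.NONCODING,
    }[label]


def label_from_summary(s: GeneSiteSummary) -> str:
    """Sm-site stratum of a gene from its retained sites.

    Canonical when at least one U1/U2/U5 site is retained; otherwise
    Noncanonical when a true noncanonical site remains; otherwise Absent
    (U7-only genes are conventionally excluded from the strata and fall into
    Absent here).
    """
    if s.canonical_total >= 1:
        return "Canonical"
    if s.nc_true >= 1:
        return "Noncanonical"
    return "Absent"
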