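import textwrap

import numpy as np
import pytest

from smsite.annotation_io import GeneModel, TranscriptModel

TOY_GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\ttoy\tgene\t101\t400\t.\t+\t.\tID=G1;gene_name=GENE1
    chr1\ttoy\tmRNA\t101\t400\t.\t+\t.\tID=T1;Parent=G1;biotype=protein_coding
    chr1\ttoy\texon\t101\t200\t.\t+\t.\tID=T1.e1;Parent=T1
    chr1\ttoy\texon\t301\t400\t.\t+\t.\tID=T1.e2;Parent=T1
    chr1\ttoy\tCDS\t151\t200\t.\t+\t0\tID=T1.c1;Parent=T1
    chr1\ttoy\tCDS\t301\t350\t.\t+\t0\tID=T1.c2;Parent=T1
    """
)

TOY_GTF = textwrap.dedent(
    """\
    chr1\ttoy\tgene\t101\t400\t.\t+\t.\tgene_id "G1"; gene_name "GENE1";
    chr1\ttoy\ttranscript\t101\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; biotype "protein_coding";
    chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\ttoy\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\ttoy\tCDS\t151\t200\t.\t+\t0\tgene_id "G1"; transcript_id "T1";
    chr1\ttoy\tCDS\t301\t350\t.\t+\t0\tgene_id "G1"; transcript_id "T1";
    """
)


@pytest.fixture
def toy_gff3(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF3)
    return p


@pytest.fixture
def toy_gtf(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(TOY_GTF)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_toy_gene(rng, gene_id="g1", chrom="c", max_span=10_000):
    """A random gene with <= 5 transcripts of <= 8 non-overlapping exons."""
    n_tx = int(rng.integers(1, 6))
    transcripts = []
    for k in range(n_tx):
        n_exons = int(rng.integers(1, 9))
        cuts = np.sort(rng.choice(np.arange(1, max_span), 2 * n_exons, replace=False))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons)]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{k}",
                gene_id=gene_id,
                chrom=chrom,
                exons=exons,
            )
        )
    return GeneModel(gene_id=gene_id, transcripts=transcripts)
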