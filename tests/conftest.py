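"""Shared fixtures: tiny in-repo SAM/FASTA/GTF fixtures are written to
tmp_path at test time so the repository stays text-only and small."""

import textwrap

import pytest

from chimloci.io_formats import TranscriptModel


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:tx1\tLN:500\n@SQ\tSN:tx2\tLN:300\n"


@pytest.fixture
def sam_file(tmp_path):
    """Two reads: r1 has a primary hit plus a 2-entry XA tag; r2 is a
    chimera with two soft-clipped local hits, one of them antisense."""
    body = "\n".join([
        "r1\t0\ttx1\t101\t60\t5S20M\t*\t0\t0\t" + "A" * 25 + "\t*\tAS:i:20\t"
        "XA:Z:tx2,+51,5S20M,1;tx2,+151,10S15M,2;",
        "r2\t0\ttx1\t201\t60\t20M20S\t*\t0\t0\t" + "C" * 40 + "\t*\tAS:i:20",
        "r2\t2048\ttx2\t61\t60\t20S20M\t*\t0\t0\t" + "C" * 40 + "\t*\tAS:i:20",
        "r3\t16\ttx2\t11\t60\t15M\t*\t0\t0\t" + "G" * 15 + "\t*\tAS:i:15",
        "r4\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*",
    ])
    path = tmp_path / "fixture.sam"
    path.write_text(SAM_HEADER + body + "\n")
    return path


@pytest.fixture
def gtf_file(tmp_path):
    """One + strand 2-exon coding transcript, one - strand single-exon
    noncoding transcript, and a gene-only line."""
    def attrs(gid, tid, name, biotype):
        return (f'gene_id "{gid}"; transcript_id "{tid}"; '
                f'gene_name "{name}"; gene_biotype "{biotype}";')

    lines = [
        "\t".join(["chr1", "test", "exon", "1001", "1100", ".", "+", ".",
                   attrs("g1", "t1", "GENE1", "protein_coding")]),
        "\t".join(["chr1", "test", "exon", "1201", "1300", ".", "+", ".",
                   attrs("g1", "t1", "GENE1", "protein_coding")]),
        "\t".join(["chr1", "test", "CDS", "1051", "1100", ".", "+", ".",
                   attrs("g1", "t1", "GENE1", "protein_coding")]),
        "\t".join(["chr1", "test", "CDS", "1201", "1250", ".", "+", ".",
                   attrs("g1", "t1", "GENE1", "protein_coding")]),
        "\t".join(["chr2", "test", "exon", "2001", "2100", ".", "-", ".",
                   attrs("g2", "t2", "MIR2", "miRNA")]),
        "\t".join(["chr3", "test", "gene", "1", "500", ".", "+", ".",
                   'gene_id "g3";']),
    ]
    path = tmp_path / "fixture.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def plus_model():
    """Spliced + strand transcript: exons (1000,1100) and (1200,1300)."""
    return TranscriptModel(transcript_id="t1", gene_id="g1", gene_symbol="GENE1",
                           biotype="protein_coding", chrom="chr1", strand="+",
                           exons=[(1000, 1100), (1200, 1300)],
                           cds=(1050, 1250))


@pytest.fixture
def minus_model():
    """Single-exon - strand transcript on (1000,1100)."""
    return TranscriptModel(transcript_id="t2", gene_id="g2", gene_symbol="MIR2",
                           biotype="miRNA", chrom="chr2", strand="-",
                           exons=[(1000, 1100)])
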