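import numpy as np
import pytest

from episplice.transcript_model import Gene, GenomeInterval, Transcript


def make_transcript(exons, tid="t1", gene_id="g1", strand="+", chrom="chr1", coding=True):
    return Transcript(
        transcript_id=tid,
        gene_id=gene_id,
        strand=strand,
        exons=[GenomeInterval(chrom, s, e, strand) for s, e in exons],
        coding_flag=coding,
    )


def make_gene(transcript_exons, strand="+", gene_id="g1", chrom="chr1"):
    ts = [
        make_transcript(exons, tid=f"t{i + 1}", gene_id=gene_id, strand=strand, chrom=chrom)
        for i, exons in enumerate(transcript_exons)
    ]
    return Gene(gene_id, chrom, strand, ts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
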