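import numpy as np
import pytest

from ttquant.genome_model import CoverageTrack, GeneModel, GenomicInterval, TranscriptModel
from ttquant.synthetic_data import SyntheticConfig, make_gene_set


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def gene_set(small_config):
    """Stratified synthetic gene set with sequences and planted motifs."""
    genes, chrom_seqs, truth = make_gene_set(small_config)
    return genes, chrom_seqs, truth


def make_toy_gene(gene_id="G1", chrom="chrT", start=1000, width=30_000, strand="+",
                  exon_bounds=None, support_level=1, transcript_id=None):
    """One gene with explicit exon structure (tx coords from the TSS)."""
    end = start + width
    iv = GenomicInterval(chrom, start, end, strand)
    exon_bounds = exon_bounds or [(0, width)]
    exons = []
    for a, b in exon_bounds:
        if strand == "+":
            exons.append(GenomicInterval(chrom, start + a, start + b, strand))
        else:
            exons.append(GenomicInterval(chrom, end - b, end - a, strand))
    tx = TranscriptModel(
        transcript_id=transcript_id or f"{gene_id}.t1", gene_id=gene_id,
        interval=iv, exons=exons, support_level=support_level,
    )
    return GeneModel(gene_id=gene_id, interval=iv, transcripts=[tx])


def uniform_track(chrom="chrT", length=60_000, depth=1.0, strand="+", bin_size=1,
                  both_strands=False):
    nbins = -(-length // bin_size)
    data = {(chrom, "+"): np.zeros(nbins), (chrom, "-"): np.zeros(nbins)}
    data[(chrom, strand)][:] = depth
    if both_strands:
        data[(chrom, "+")][:] = depth
        data[(chrom, "-")][:] = depth
    return CoverageTrack(data, bin_size=bin_size)
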