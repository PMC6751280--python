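import numpy as np
import pytest

from splicedyn.models import GeneModel, GenomeSequence, TranscriptModel


def make_tx(tid, exons, gene="G1", chrom="chr1", strand="+"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=tuple(exons),
    )


def make_gene(transcripts, gene="G1", chrom="chr1", strand="+"):
    return GeneModel(gene_id=gene, chrom=chrom, strand=strand,
                     transcripts=list(transcripts))


def random_gene(rng, gene_id="G1", max_isoforms=4, max_exons=6, strand=None):
    """A random multi-isoform gene on a shared coordinate grid.

    Exon boundaries are drawn from multiples of 10 so isoforms frequently
    share splice sites, which is what makes AS-event enumeration
    interesting.
    """
    strand = strand or rng.choice(["+", "-"])
    n_iso = int(rng.integers(2, max_isoforms + 1))
    txs = []
    for i in range(n_iso):
        n_ex = int(rng.integers(1, max_exons + 1))
        cuts = np.sort(rng.choice(np.arange(1, 80), size=2 * n_ex, replace=False)) * 10
        exons = [(int(cuts[2 * j]), int(cuts[2 * j + 1])) for j in range(n_ex)]
        txs.append(make_tx(f"{gene_id}.t{i}", exons, gene=gene_id, strand=strand))
    return make_gene(txs, gene=gene_id, strand=strand)


@pytest.fixture
def toy_genome():
    # chr1: 1000 bp with fixed content for coordinate checks
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    return GenomeSequence({"chr1": seq})


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One modest synthetic dataset shared by read-only tests."""
    from splicedyn import synthetic as syn

    genome = syn.generate_genome(2, 400_000, seed=101)
    genes, truth = syn.generate_gene_models(genome, 40, 5, seed=102)
    expr, truth = syn.generate_expression(genes, noise_sd=0.2, seed=103, truth=truth)
    records, truth = syn.generate_polya_sites(genes, genome, seed=104, truth=truth)
    return genome, genes, expr, records, truth
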