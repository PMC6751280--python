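"""Readers and writers for the standard formats the pipeline exchanges.

GTF in/out (exon features with gene_id/transcript_id attributes), FASTA
genomes, TSV expression tables, and the primitive genomic derivations
(introns, spliced transcript sequence) every downstream stage builds on.
"""
from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .models import (
    ExpressionMatrix,
    GeneModel,
    GenomeSequence,
    IntronRecord,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)


class GTFParseError(ValueError):
    """A malformed GTF line, reported with its 1-based line number."""


def read_genome_fasta(path: str | os.PathLike) -> GenomeSequence:
    return GenomeSequence(
        {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_genome_fasta(genome: GenomeSequence, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcript_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Parse exon features into GeneModels, grouped by gene_id.

    Non-exon features are ignored. Malformed lines raise :class:`GTFParseError`
    naming the line number; overlapping exons within one transcript raise
    :class:`ValidationError`.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    tx_info: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise GTFParseError(f"line {lineno}: cannot parse GTF line ({exc})") from exc
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except (KeyError, IndexError):
                raise GTFParseError(
                    f"line {lineno}: exon feature missing gene_id/transcript_id attribute"
                ) from None
            if feat.strand not in ("+", "-"):
                raise GTFParseError(
                    f"line {lineno}: transcript {transcript_id!r} has strand "
                    f"{feat.strand!r}; splice analysis requires '+' or '-'"
                )
            info = (gene_id, feat.seqid, feat.strand)
            prev = tx_info.setdefault(transcript_id, info)
            if prev != info:
                raise GTFParseError(
                    f"line {lineno}: transcript {transcript_id!r} has inconsistent "
                    "gene/chrom/strand across its exon lines"
                )
            if transcript_id not in exons:
                order.append(transcript_id)
            exons.setdefault(transcript_id, []).append((int(feat.start), int(feat.end)))

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tid in order:
        gene_id, chrom, strand = tx_info[tid]
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(sorted(exons[tid])),
        )
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand)
            gene_order.append(gene_id)
        genes[gene_id].transcripts.append(t)
    # validates chrom/strand agreement within each gene
    return [
        GeneModel(
            gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, transcripts=g.transcripts
        )
        for g in (genes[gid] for gid in gene_order)
    ]


def write_transcript_gtf(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write exon features sorted by (chrom, start), GTF attribute dialect."""
    rows = []
    for gene in models:
        for t in gene.transcripts:
            for s, e in t.exons:
                rows.append((t.chrom, s, e, t.strand, gene.gene_id, t.transcript_id))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[5]))
    with open(path, "w") as fh:
        for chrom, s, e, strand, gid, tid in rows:
            fh.write(
                f"{chrom}\tsplicedyn\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{tid}";\n'
            )


def extract_introns(t: TranscriptModel, genome: GenomeSequence) -> list[IntronRecord]:
    """One IntronRecord per exon gap, with strand-oriented boundary dinucleotides.

    On the minus strand the donor is read from the genomic 3' end of the
    intron, reverse-complemented, so that a canonical intron always reads
    GT...AG along the transcript.
    """
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} absent from genome")
    if t.end > genome.length(t.chrom):
        raise ValidationError(
            f"transcript {t.transcript_id!r} extends beyond chromosome {t.chrom!r}"
        )
    records = []
    for start, end in t.introns():
        left = genome.fetch(t.chrom, start, start + 1)
        right = genome.fetch(t.chrom, end - 1, end)
        if t.strand == "+":
            donor, acceptor = left, right
        else:
            donor, acceptor = reverse_complement(right), reverse_complement(left)
        records.append(
            IntronRecord(
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                chrom=t.chrom,
                strand=t.strand,
                start=start,
                end=end,
                donor_dinuc=donor,
                acceptor_dinuc=acceptor,
            )
        )
    if t.strand == "-":
        records.reverse()
    return records


def transcript_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced transcript sequence, reverse-complemented on the minus strand."""
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} absent from genome")
    if t.end > genome.length(t.chrom):
        raise ValidationError(
            f"transcript {t.transcript_id!r} extends beyond chromosome {t.chrom!r}"
        )
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


def read_expression_table(path: str | os.PathLike) -> ExpressionMatrix:
    """TSV with columns transcript_id, gene_id, then <stage>_<replicate> samples."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["transcript_id", "gene_id"]:
        raise ValidationError(
            "expression table must start with columns 'transcript_id', 'gene_id'"
        )
    values = df.set_index("transcript_id").drop(columns=["gene_id"])
    tx2gene = dict(zip(df["transcript_id"], df["gene_id"]))
    return ExpressionMatrix(values=values, tx2gene=tx2gene)


def write_expression_table(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = expr.values.copy()
    out.insert(0, "gene_id", expr.tx2gene)
    out.index.name = "transcript_id"
    out.reset_index().to_csv(path, sep="\t", index=False)


def all_transcripts(models: Iterable[GeneModel]) -> list[TranscriptModel]:
    return [t for g in models for t in g.transcripts]
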