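"""Isoform-catalog operations: redundancy collapse, annotation-based
classification into known / novel-isoform / novel-locus groups, and
per-gene complexity summaries.

The collapse ignores 5' differences: multi-exon transcripts with identical
intron chains are one isoform, and a transcript whose chain is a
5'-truncated suffix of another's (with matching 3' terminus) is absorbed
into the longer one. Collapse operates on genome-anchored exon chains, not
on alignments.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .models import GeneModel, TranscriptModel

CLASSES = ("known", "novel_isoform_known_gene", "novel_locus")


@dataclass
class CatalogClassification:
    assignments: dict[str, str]  # transcript_id -> class

    @property
    def counts(self) -> dict[str, int]:
        out = dict.fromkeys(CLASSES, 0)
        for c in self.assignments.values():
            out[c] += 1
        return out


def _suffix_chain(t: TranscriptModel, longer: TranscriptModel) -> bool:
    """True if t is a 5'-truncated form of ``longer``: its intron chain is a
    suffix of the longer chain (strand-aware), the 3' terminal exon ends
    match, and t's 5'-terminal exon stays inside the longer transcript's
    matching exon (otherwise t bridges an intron of the longer form — an
    intron-retaining isoform, not a truncation)."""
    ct, cl = t.intron_chain(), longer.intron_chain()
    if len(ct) > len(cl):
        return False
    if t.strand == "+":
        # 3' side is genomic right: chain must match the tail, 3' exon end equal
        k = len(cl) - len(ct)
        return (
            ct == cl[k:]
            and t.exons[-1][1] == longer.exons[-1][1]
            and t.exons[0][0] >= longer.exons[k][0]
        )
    # minus strand: 3' side is genomic left
    m = len(ct)
    return (
        ct == cl[:m]
        and t.exons[0][0] == longer.exons[0][0]
        and t.exons[-1][1] <= longer.exons[m][1]
    )


def collapse_isoforms(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Collapse redundant isoforms; 5' differences are not considered.

    Multi-exon: identical intron chains merge (representative exons span the
    union of member ends); a chain that is a 5'-truncated suffix of a longer
    chain with the same 3' terminus is absorbed into the longer transcript.
    Mono-exon: overlapping same-strand intervals merge to their union span.
    The representative keeps the lexicographically smallest member id.
    Idempotent.
    """
    multi = [t for t in transcripts if t.n_exons > 1]
    mono = [t for t in transcripts if t.n_exons == 1]

    # stage 1: identical intron chains
    by_chain: dict[tuple, list[TranscriptModel]] = defaultdict(list)
    for t in multi:
        by_chain[(t.chrom, t.strand, t.gene_id, t.intron_chain())].append(t)
    reps: list[TranscriptModel] = []
    for (chrom, strand, gene_id, chain), members in by_chain.items():
        first_start = min(m.exons[0][0] for m in members)
        last_end = max(m.exons[-1][1] for m in members)
        exons = list(members[0].exons)
        exons[0] = (first_start, exons[0][1])
        exons[-1] = (exons[-1][0], last_end)
        reps.append(
            TranscriptModel(
                transcript_id=min(m.transcript_id for m in members),
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )

    # stage 2: absorb 5'-truncated suffix chains into longer chains
    reps.sort(key=lambda t: (-len(t.intron_chain()), t.transcript_id))
    kept: list[TranscriptModel] = []
    for t in reps:
        absorbed = None
        for host in kept:
            if (
                host.chrom == t.chrom
                and host.strand == t.strand
                and host.gene_id == t.gene_id
                and len(host.intron_chain()) > len(t.intron_chain())
                and _suffix_chain(t, host)
            ):
                absorbed = host
                break
        if absorbed is None:
            kept.append(t)
        elif t.transcript_id < absorbed.transcript_id:
            kept[kept.index(absorbed)] = TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=absorbed.gene_id,
                chrom=absorbed.chrom,
                strand=absorbed.strand,
                exons=absorbed.exons,
            )

    # mono-exon: merge overlapping intervals per (chrom, strand, gene)
    by_locus: dict[tuple, list[TranscriptModel]] = defaultdict(list)
    for t in mono:
        by_locus[(t.chrom, t.strand, t.gene_id)].append(t)
    for (chrom, strand, gene_id), members in by_locus.items():
        members.sort(key=lambda t: t.exons[0])
        group = [members[0]]
        for t in members[1:]:
            cur_end = max(m.exons[0][1] for m in group)
            if t.exons[0][0] <= cur_end:
                group.append(t)
            else:
                kept.append(_merge_mono(group))
                group = [t]
        kept.append(_merge_mono(group))

    kept.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return kept


def _merge_mono(group: list[TranscriptModel]) -> TranscriptModel:
    start = min(t.exons[0][0] for t in group)
    end = max(t.exons[0][1] for t in group)
    rep = min(group, key=lambda t: t.transcript_id)
    return TranscriptModel(
        transcript_id=rep.transcript_id,
        gene_id=rep.gene_id,
        chrom=rep.chrom,
        strand=rep.strand,
        exons=((start, end),),
    )


def classify_against_annotation(
    catalog: list[TranscriptModel], reference: list[GeneModel]
) -> CatalogClassification:
    """Three-way classification of catalog transcripts against an annotation.

    known: multi-exon with an intron chain identical to a reference
    transcript (mono-exon: interval inside a reference exon, same strand);
    novel_isoform_known_gene: same-strand exonic overlap with a reference
    gene but no chain match; novel_locus: no same-strand exonic overlap.
    """
    ref_chains = set()
    ref_exons: list[tuple[str, str, int, int]] = []
    for g in reference:
        for t in g.transcripts:
            if t.n_exons > 1:
                ref_chains.add((t.chrom, t.strand, t.intron_chain()))
            for s, e in t.exons:
                ref_exons.append((t.chrom, t.strand, s, e))

    assignments: dict[str, str] = {}
    for t in catalog:
        if t.n_exons > 1 and (t.chrom, t.strand, t.intron_chain()) in ref_chains:
            assignments[t.transcript_id] = "known"
            continue
        if t.n_exons == 1 and any(
            c == t.chrom and st == t.strand and s <= t.start and t.end <= e
            for c, st, s, e in ref_exons
        ):
            assignments[t.transcript_id] = "known"
            continue
        overlap = any(
            c == t.chrom
            and st == t.strand
            and any(xs <= e and s <= xe for xs, xe in t.exons)
            for c, st, s, e in ref_exons
        )
        assignments[t.transcript_id] = (
            "novel_isoform_known_gene" if overlap else "novel_locus"
        )
    return CatalogClassification(assignments=assignments)


def catalog_summary(genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene transcript counts, mean exon counts, and gene span lengths."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_transcripts": len(g.transcripts),
                "mean_exons": sum(t.n_exons for t in g.transcripts) / len(g.transcripts),
                "max_exons": max(t.n_exons for t in g.transcripts),
                "gene_length": g.length,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def fraction_single_transcript(summary: pd.DataFrame) -> float:
    """Fraction of genes represented by a single transcript."""
    return float((summary["n_transcripts"] == 1).mean())
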