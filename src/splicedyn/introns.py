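"""Retained-intron characterization and PTC calling.

Covers positional/length/GC features of retained introns, splice-site
strength as PWM log-odds trained on non-retained introns, a Mann-Whitney
rank-sum test for retained-vs-spliced contrasts, longest-ORF search on
spliced transcript sequences, and the 50-nt rule for premature termination
codons: a stop codon more than 50 nt upstream of the last exon-exon
junction marks the transcript as a likely nonsense-mediated-decay target.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .models import (
    GeneModel,
    GenomeSequence,
    IntronRecord,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

# splice-site window geometry, in transcript orientation
DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3


@dataclass
class RetainedIntronFeatures:
    intron: IntronRecord
    position_ratio: float
    length: int
    gc: float
    canonical: bool
    donor_score: float | None = None
    acceptor_score: float | None = None


@dataclass
class SpliceSitePWM:
    """Position probability matrices for donor and acceptor windows.

    Donor window: last 3 exonic + first 6 intronic nt (9 positions);
    acceptor window: last 20 intronic + first 3 exonic nt (23 positions),
    both read 5'->3' along the transcript. Scores are log2 odds against the
    pooled background base frequencies, in bits.
    """

    donor: np.ndarray  # (9, 4)
    acceptor: np.ndarray  # (23, 4)
    background: np.ndarray  # (4,)


def _donor_window(intron: IntronRecord, genome: GenomeSequence) -> str:
    if intron.strand == "+":
        return genome.fetch(
            intron.chrom, intron.start - DONOR_EXONIC, intron.start + DONOR_INTRONIC - 1
        )
    return reverse_complement(
        genome.fetch(
            intron.chrom, intron.end - DONOR_INTRONIC + 1, intron.end + DONOR_EXONIC
        )
    )


def _acceptor_window(intron: IntronRecord, genome: GenomeSequence) -> str:
    if intron.strand == "+":
        return genome.fetch(
            intron.chrom, intron.end - ACCEPTOR_INTRONIC + 1, intron.end + ACCEPTOR_EXONIC
        )
    return reverse_complement(
        genome.fetch(
            intron.chrom,
            intron.start - ACCEPTOR_EXONIC,
            intron.start + ACCEPTOR_INTRONIC - 1,
        )
    )


def retained_intron_features(
    ir_events,
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    genome: GenomeSequence,
    pwm: "SpliceSitePWM | None" = None,
) -> list[RetainedIntronFeatures]:
    """One feature record per unique retained intron across IR events.

    ``position_ratio`` is measured in transcript orientation (0 at the gene's
    5' end): on the plus strand (intron start - gene start) / gene length, on
    the minus strand (gene end - intron end) / gene length.
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    out = []
    seen = set()
    for ev in ir_events:
        if ev.event_type != "IR":
            raise ValidationError(f"expected IR events, got {ev.event_type}")
        key = (ev.gene_id, ev.signature)
        if key in seen:
            continue
        seen.add(key)
        gene = genes[ev.gene_id]
        gstart, gend = gene.span
        s, e = ev.signature
        if s < gstart or e > gend:
            raise ValidationError(
                f"retained intron ({s},{e}) outside gene {ev.gene_id} span"
            )
        glen = gene.length
        ratio = (s - gstart) / glen if gene.strand == "+" else (gend - e) / glen
        seq = genome.fetch(gene.chrom, s, e)
        if gene.strand == "+":
            donor, acceptor = seq[:2], seq[-2:]
        else:
            donor, acceptor = reverse_complement(seq[-2:]), reverse_complement(seq[:2])
        intron = IntronRecord(
            gene_id=ev.gene_id,
            transcript_id=";".join(sorted(ev.form_a)),
            chrom=gene.chrom,
            strand=gene.strand,
            start=s,
            end=e,
            donor_dinuc=donor,
            acceptor_dinuc=acceptor,
        )
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        feat = RetainedIntronFeatures(
            intron=intron,
            position_ratio=ratio,
            length=e - s + 1,
            gc=gc,
            canonical=intron.canonical and "N" not in donor + acceptor,
        )
        if pwm is not None:
            feat.donor_score, feat.acceptor_score = score_splice_sites(
                intron, pwm, genome
            )
        out.append(feat)
    return out


def _tally(windows: Sequence[str], width: int, pseudocount: float) -> np.ndarray:
    counts = np.full((width, 4), pseudocount, dtype=float)
    for w in windows:
        for i, base in enumerate(w):
            j = BASES.find(base)
            if j >= 0:
                counts[i, j] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def train_splice_pwm(
    introns: Sequence[IntronRecord],
    genome: GenomeSequence,
    pseudocount: float = 0.5,
) -> SpliceSitePWM:
    """Train donor/acceptor position probability matrices from introns.

    Windows containing N still contribute their unambiguous positions.
    Background frequencies are pooled over both window sets.
    """
    if not introns:
        raise ValidationError("cannot train a splice-site PWM on zero introns")
    donors = [_donor_window(i, genome) for i in introns]
    acceptors = [_acceptor_window(i, genome) for i in introns]
    donor = _tally(donors, DONOR_EXONIC + DONOR_INTRONIC, pseudocount)
    acceptor = _tally(acceptors, ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC, pseudocount)
    pooled = "".join(donors) + "".join(acceptors)
    bg = np.array([pooled.count(b) for b in BASES], dtype=float)
    bg += pseudocount
    bg /= bg.sum()
    return SpliceSitePWM(donor=donor, acceptor=acceptor, background=bg)


def _score(window: str, matrix: np.ndarray, bg: np.ndarray) -> float:
    score = 0.0
    for i, base in enumerate(window):
        j = BASES.find(base)
        if j >= 0:
            score += math.log2(matrix[i, j] / bg[j])
    return score


def score_splice_sites(
    intron: IntronRecord, pwm: SpliceSitePWM, genome: GenomeSequence
) -> tuple[float, float]:
    """Log2-odds scores (bits) of the intron's donor and acceptor windows."""
    return (
        _score(_donor_window(intron, genome), pwm.donor, pwm.background),
        _score(_acceptor_window(intron, genome), pwm.acceptor, pwm.background),
    )


def rank_sum_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact enumeration over all group assignments when n_a + n_b <= 10
    (midranks, so ties are handled); otherwise the normal approximation with
    tie correction. Constant pooled data gives p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2
    if np.ptp(pooled) == 0:
        return float(u_a), 1.0
    n = a.size + b.size
    if n <= 10:
        # exact null: U over every way of labeling n_a of the pooled values
        stats_null = [
            sum(ranks[list(idx)]) - a.size * (a.size + 1) / 2
            for idx in itertools.combinations(range(n), a.size)
        ]
        stats_null = np.asarray(stats_null)
        mu = a.size * b.size / 2
        p = float(np.mean(np.abs(stats_null - mu) >= abs(u_a - mu) - 1e-12))
        return float(u_a), min(p, 1.0)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ORFResult:
    has_orf: bool
    start: int | None = None  # 0-based coordinate of the A of ATG
    stop: int | None = None  # 0-based coordinate of the last stop-codon base
    ptc: bool | None = None
    stop_to_last_junction: int | None = None


def longest_orf(seq: str) -> ORFResult:
    """Longest ATG-initiated ORF ending at the first in-frame stop codon.

    All three sense frames are searched; ties go to the 5'-most start.
    Codons containing N are neither starts nor stops.
    """
    seq = seq.upper()
    best: tuple[int, int] | None = None  # (length, -start) maximized
    best_coords: tuple[int, int] | None = None
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG":
                open_starts.append(pos)
            elif codon in STOP_CODONS and open_starts:
                start = open_starts[0]  # 5'-most open start in this frame
                length = pos + 3 - start
                cand = (length, -start)
                if best is None or cand > best:
                    best = cand
                    best_coords = (start, pos + 2)
                open_starts.clear()
    if best_coords is None:
        return ORFResult(has_orf=False)
    return ORFResult(has_orf=True, start=best_coords[0], stop=best_coords[1])


def last_junction_position(t: TranscriptModel) -> int:
    """0-based transcript coordinate of the last base before the final
    exon-exon junction (i.e. the last base of the penultimate exon in
    transcript orientation)."""
    if t.n_exons < 2:
        raise ValidationError(
            f"transcript {t.transcript_id!r} is single-exon: no junction"
        )
    last_exon_len = (
        t.exons[-1][1] - t.exons[-1][0] + 1
        if t.strand == "+"
        else t.exons[0][1] - t.exons[0][0] + 1
    )
    return t.length - last_exon_len - 1


def classify_ptc(t: TranscriptModel, orf: ORFResult) -> bool:
    """50-nt rule: the stop is premature iff it lies strictly more than 50 nt
    upstream of the last exon-exon junction (measured from the stop codon's
    last base, in spliced-transcript coordinates)."""
    if t.n_exons < 2:
        raise ValidationError(
            f"transcript {t.transcript_id!r} is single-exon: PTC not evaluable"
        )
    if not orf.has_orf:
        raise ValidationError("PTC classification requires an ORF")
    distance = last_junction_position(t) - orf.stop
    orf.stop_to_last_junction = distance
    orf.ptc = distance > 50
    return orf.ptc


@dataclass
class RepresentativeCDS:
    """The annotated coding span (genomic, 1-based inclusive) of a gene's
    representative transcript — by convention its longest annotated isoform."""

    gene_id: str
    cds_start: int
    cds_end: int


def filter_ir_transcripts_for_ptc(
    ir_transcripts: Sequence[tuple[TranscriptModel, tuple[int, int]]],
    representatives: Mapping[str, RepresentativeCDS],
) -> tuple[list[tuple[TranscriptModel, tuple[int, int]]], list[tuple[str, str]]]:
    """Keep IR transcripts whose retained intron lies strictly inside the
    representative transcript's coding span.

    ``ir_transcripts`` pairs each transcript with its retained intron's
    genomic interval. Returns (kept, excluded) where excluded entries are
    (transcript_id, reason).
    """
    kept, excluded = [], []
    for t, (istart, iend) in ir_transcripts:
        rep = representatives.get(t.gene_id)
        if rep is None:
            excluded.append((t.transcript_id, "no_representative"))
            continue
        if istart > rep.cds_start and iend < rep.cds_end:
            kept.append((t, (istart, iend)))
        elif iend < rep.cds_start or istart > rep.cds_end:
            excluded.append((t.transcript_id, "outside_cds"))
        else:
            excluded.append((t.transcript_id, "overlapping_cds_boundary"))
    return kept, excluded
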