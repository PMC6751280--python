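"""Detection and counting of the five alternative-splicing modes.

Events are found by pairwise comparison of a gene's isoforms and
deduplicated by (type, coordinate signature), so one biological event
supported by many isoform pairs is counted once.

Definitions (all coordinates genomic, 1-based inclusive):

IR    an intron (s, e) of a spliced isoform such that another isoform has a
      single exon containing [s-1, e+1] — both splice sites of the retained
      intron are used as exonic positions by the retaining form.
ES    an internal exon of one isoform whose two flanking introns are fused
      into a single intron of another isoform (same outer boundaries).
A5SS/ two introns from different isoforms sharing exactly one boundary,
A3SS  where the exons flanking the differing boundary overlap between the
      isoforms (this keeps skipped-exon and mutually-exclusive-exon
      configurations from double-counting as junction shifts); the differing
      boundary is the donor (5') or acceptor (3') in transcript orientation,
      so the label is strand-aware.
MEE   two non-overlapping internal exons, one per isoform, whose flanking
      introns share both outer boundaries, with no isoform of the gene
      containing both exons.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .models import ExpressionMatrix, GeneModel, TranscriptModel

EVENT_TYPES = ("IR", "ES", "A5SS", "A3SS", "MEE")


@dataclass
class ASEvent:
    """A typed, deduplicated splicing event with its supporting isoforms.

    ``signature`` identifies the event inside its gene; ``form_a`` /
    ``form_b`` are the transcript-id sets supporting each alternative
    (IR: spliced / retaining; ES: including / skipping; A5SS-A3SS: the two
    junction choices ordered by coordinate; MEE: first / second exon).
    """

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    signature: tuple
    form_a: set[str] = field(default_factory=set)
    form_b: set[str] = field(default_factory=set)

    @property
    def supporting_isoforms(self) -> tuple[set[str], set[str]]:
        return (self.form_a, self.form_b)


def _ir_pairs(a: TranscriptModel, b: TranscriptModel):
    """Introns of `a` fully contained (with both boundaries) in one exon of `b`."""
    for s, e in a.introns():
        for xs, xe in b.exons:
            if xs <= s - 1 and e + 1 <= xe:
                yield (s, e)
                break


def _es_pairs(a: TranscriptModel, b: TranscriptModel):
    introns_a = a.introns()
    introns_b = set(b.introns())
    for i in range(len(introns_a) - 1):
        d0, exon_minus = introns_a[i]
        exon_plus, a1 = introns_a[i + 1]
        exon = (exon_minus + 1, exon_plus - 1)  # the internal exon between them
        if (d0, a1) in introns_b:
            yield (exon[0], exon[1], d0, a1)


def _exon_after(t: TranscriptModel, intron_end: int) -> tuple[int, int]:
    for ex in t.exons:
        if ex[0] == intron_end + 1:
            return ex
    raise AssertionError("intron without downstream exon")


def _exon_before(t: TranscriptModel, intron_start: int) -> tuple[int, int]:
    for ex in t.exons:
        if ex[1] == intron_start - 1:
            return ex
    raise AssertionError("intron without upstream exon")


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] <= y[1] and y[0] <= x[1]


def _alt_ss_pairs(a: TranscriptModel, b: TranscriptModel, strand: str):
    """Yield (event_type, signature, a_has_smaller_coordinate) per shared boundary.

    Only fires when the exons flanking the differing boundary overlap — a
    genuine junction shift, not a different exon (ES/MEE territory).
    """
    for s1, e1 in a.introns():
        for s2, e2 in b.introns():
            if s1 == s2 and e1 != e2:
                # shared genomic-left boundary: the intron ends differ
                if not _overlap(_exon_after(a, e1), _exon_after(b, e2)):
                    continue
                etype = "A3SS" if strand == "+" else "A5SS"
                yield etype, (min(e1, e2), max(e1, e2), s1), e1 < e2
            elif e1 == e2 and s1 != s2:
                if not _overlap(_exon_before(a, s1), _exon_before(b, s2)):
                    continue
                etype = "A5SS" if strand == "+" else "A3SS"
                yield etype, (min(s1, s2), max(s1, s2), e1), s1 < s2


def _internal_exons_with_flanks(t: TranscriptModel):
    introns = t.introns()
    for i in range(1, t.n_exons - 1):
        yield t.exons[i], introns[i - 1], introns[i]


def _mee_pairs(a: TranscriptModel, b: TranscriptModel, gene_exons: dict[str, set]):
    exons_a = set(a.exons)
    exons_b = set(b.exons)
    for e1, (pa_s, _), (_, na_e) in _internal_exons_with_flanks(a):
        if e1 in exons_b:
            continue
        for e2, (pb_s, _), (_, nb_e) in _internal_exons_with_flanks(b):
            if e2 in exons_a:
                continue
            if e1[1] >= e2[0] and e2[1] >= e1[0]:  # overlap
                continue
            if pa_s != pb_s or na_e != nb_e:
                continue
            # no isoform of the gene may contain both exons
            if any(e1 in ex and e2 in ex for ex in gene_exons.values()):
                continue
            first, second = sorted((e1, e2))
            yield (first[0], first[1], second[0], second[1], pa_s, na_e), e1 is first


def detect_events(gene: GeneModel) -> list[ASEvent]:
    """All deduplicated AS events of one gene, by exhaustive pairwise comparison.

    A single-isoform gene yields an empty list. The result is invariant to
    isoform input order.
    """
    txs = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    if len(txs) < 2:
        return []
    gene_exons = {t.transcript_id: set(t.exons) for t in txs}
    events: dict[tuple, ASEvent] = {}

    def get(etype: str, sig: tuple) -> ASEvent:
        key = (etype, sig)
        if key not in events:
            events[key] = ASEvent(
                event_type=etype,
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                signature=sig,
            )
        return events[key]

    for a in txs:
        for b in txs:
            if a is b:
                continue
            for sig in _ir_pairs(a, b):
                ev = get("IR", sig)
                ev.form_a.add(a.transcript_id)  # spliced form
                ev.form_b.add(b.transcript_id)  # retaining form
            for sig in _es_pairs(a, b):
                ev = get("ES", sig)
                ev.form_a.add(a.transcript_id)  # exon-including form
                ev.form_b.add(b.transcript_id)  # skipping form
            if a.transcript_id < b.transcript_id:
                for etype, sig, a_is_lo in _alt_ss_pairs(a, b, gene.strand):
                    ev = get(etype, sig)
                    # form_a uses the smaller differing coordinate
                    ev.form_a.add(a.transcript_id if a_is_lo else b.transcript_id)
                    ev.form_b.add(b.transcript_id if a_is_lo else a.transcript_id)
                for sig, a_is_first in _mee_pairs(a, b, gene_exons):
                    ev = get("MEE", sig)
                    ev.form_a.add(a.transcript_id if a_is_first else b.transcript_id)
                    ev.form_b.add(b.transcript_id if a_is_first else a.transcript_id)
    return sorted(events.values(), key=lambda e: (e.event_type, e.signature))


def detect_all_events(genes) -> list[ASEvent]:
    return [ev for g in genes for ev in detect_events(g)]


def count_events_by_type(events) -> dict[str, int]:
    tally = Counter(ev.event_type for ev in events)
    return {t: tally.get(t, 0) for t in EVENT_TYPES}


def stage_event_presence(
    events, expr: ExpressionMatrix, min_fpkm: float = 0.1
) -> pd.DataFrame:
    """Per-stage, per-type counts of events whose both forms are expressed.

    An event is present at a stage iff each of its two forms has at least one
    supporting isoform with replicate-mean FPKM >= ``min_fpkm`` there.
    """
    stage_means = expr.stage_means()
    known = set(stage_means.index)
    counts = {s: dict.fromkeys(EVENT_TYPES, 0) for s in stage_means.columns}
    for ev in events:
        for tid in ev.form_a | ev.form_b:
            if tid not in known:
                raise KeyError(
                    f"supporting isoform {tid!r} of event {ev.signature} absent "
                    "from expression matrix"
                )
        for stage in stage_means.columns:
            col = stage_means[stage]
            if all(
                any(col[tid] >= min_fpkm for tid in form)
                for form in (ev.form_a, ev.form_b)
            ):
                counts[stage][ev.event_type] += 1
    return pd.DataFrame(counts).T[list(EVENT_TYPES)]
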