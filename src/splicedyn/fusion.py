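"""Rule-based filtering of fusion-transcript candidates.

A candidate is a single transcript whose alignment splits into segments on
the genome. Segments on one chromosome that overlap or fall within a small
merge window are first grouped into loci; the six criteria are then:

a. the transcript maps to two or more loci;
b. every locus lies on a placed chromosome (no contigs/scaffolds);
c. every locus covers at least 5% of the transcript;
d. the loci together cover at least 95% of the transcript;
e. every locus pair is on different chromosomes or at least 10 kb apart
   (gap between nearest segment ends);
f. the fusion junction is supported by at least one short-read observation.

The locus merge window (default 1 kb) is deliberately smaller than the
10 kb distance threshold so that criteria (a) and (e) stay independent:
nearby segments collapse into one locus, while same-chromosome loci
separated by 1-10 kb survive as two loci and fail the distance criterion.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .models import ValidationError

CRITERIA = ("a", "b", "c", "d", "e", "f")

# accessions like NW_/NT_/KQ... and names containing scaffold/contig are unplaced
_UNPLACED_RE = re.compile(r"(^NW_|^NT_|^KQ|scaffold|contig|random|^chrUn)", re.IGNORECASE)


@dataclass(frozen=True)
class AlignmentSegment:
    chrom: str
    start: int
    end: int
    fraction: float  # aligned fraction of the transcript length
    placed: bool | None = None  # None: infer from chromosome name

    def is_placed(self) -> bool:
        if self.placed is not None:
            return self.placed
        return not _UNPLACED_RE.search(self.chrom)


@dataclass
class FusionCandidate:
    transcript_id: str
    transcript_length: int
    segments: tuple[AlignmentSegment, ...]
    junction_support: int = 0

    def __post_init__(self):
        if not self.segments:
            raise ValidationError(
                f"candidate {self.transcript_id!r} has no alignment segments"
            )
        for seg in self.segments:
            if not 0.0 <= seg.fraction <= 1.0:
                raise ValidationError(
                    f"candidate {self.transcript_id!r}: fraction {seg.fraction} not in [0,1]"
                )
        total = sum(s.fraction for s in self.segments)
        if total > 1.0 + 1e-6:
            raise ValidationError(
                f"candidate {self.transcript_id!r}: aligned fractions sum to {total:.3f} > 1"
            )


@dataclass
class FusionVerdict:
    transcript_id: str
    criteria: dict[str, bool]

    @property
    def passes(self) -> bool:
        return all(self.criteria.values())

    def first_failure(self) -> str | None:
        for c in CRITERIA:
            if not self.criteria[c]:
                return c
        return None


@dataclass
class _Locus:
    chrom: str
    start: int
    end: int
    fraction: float
    placed: bool


def _merge_loci(segments: Sequence[AlignmentSegment], merge_window: int) -> list[_Locus]:
    by_chrom: dict[str, list[AlignmentSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    loci: list[_Locus] = []
    for chrom, segs in sorted(by_chrom.items()):
        segs.sort(key=lambda s: (s.start, s.end))
        cur = _Locus(chrom, segs[0].start, segs[0].end, segs[0].fraction, segs[0].is_placed())
        for s in segs[1:]:
            if s.start - cur.end <= merge_window:
                cur.end = max(cur.end, s.end)
                cur.fraction += s.fraction
                cur.placed = cur.placed and s.is_placed()
            else:
                loci.append(cur)
                cur = _Locus(chrom, s.start, s.end, s.fraction, s.is_placed())
        loci.append(cur)
    return loci


def evaluate_candidate(
    c: FusionCandidate,
    min_locus_cov: float = 0.05,
    min_total_cov: float = 0.95,
    min_distance: int = 10_000,
    min_junction_reads: int = 1,
    merge_window: int = 1_000,
) -> FusionVerdict:
    """Apply the six fusion criteria to one candidate."""
    loci = _merge_loci(c.segments, merge_window)
    pairs = [(x, y) for i, x in enumerate(loci) for y in loci[i + 1 :]]
    criteria = {
        "a": len(loci) >= 2,
        "b": all(l.placed for l in loci),
        "c": all(l.fraction >= min_locus_cov for l in loci),
        "d": sum(l.fraction for l in loci) >= min_total_cov,
        "e": all(
            x.chrom != y.chrom
            or max(x.start, y.start) - min(x.end, y.end) >= min_distance
            for x, y in pairs
        ),
        "f": c.junction_support >= min_junction_reads,
    }
    return FusionVerdict(transcript_id=c.transcript_id, criteria=criteria)


def filter_candidates(
    candidates: Iterable[FusionCandidate], **thresholds
) -> tuple[list[FusionCandidate], dict[str, int], list[FusionVerdict]]:
    """Evaluate every candidate; tally failures by first failing criterion.

    Returns (passing candidates in input order, failure tally a..f, all
    verdicts in input order).
    """
    passing: list[FusionCandidate] = []
    tally = dict.fromkeys(CRITERIA, 0)
    verdicts: list[FusionVerdict] = []
    for c in candidates:
        v = evaluate_candidate(c, **thresholds)
        verdicts.append(v)
        if v.passes:
            passing.append(c)
        else:
            tally[v.first_failure()] += 1
    return passing, tally, verdicts


def read_fusion_tsv(path) -> list[FusionCandidate]:
    """Segments TSV: transcript_id, transcript_length, chrom, start, end,
    fraction, placed (0/1), support — one row per segment."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for tid, grp in df.groupby("transcript_id", sort=False):
        segs = tuple(
            AlignmentSegment(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                fraction=float(row.fraction),
                placed=bool(row.placed),
            )
            for row in grp.itertuples()
        )
        out.append(
            FusionCandidate(
                transcript_id=str(tid),
                transcript_length=int(grp["transcript_length"].iloc[0]),
                segments=segs,
                junction_support=int(grp["support"].iloc[0]),
            )
        )
    return out


def write_fusion_tsv(candidates: Sequence[FusionCandidate], path) -> None:
    rows = []
    for c in candidates:
        for s in c.segments:
            rows.append(
                {
                    "transcript_id": c.transcript_id,
                    "transcript_length": c.transcript_length,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "fraction": s.fraction,
                    "placed": int(s.is_placed()),
                    "support": c.junction_support,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def verdicts_to_frame(verdicts: Sequence[FusionVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        row = {"transcript_id": v.transcript_id, **v.criteria, "pass": v.passes}
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")
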