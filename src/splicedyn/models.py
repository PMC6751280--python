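"""Core domain types shared by every pipeline stage.

Coordinates are 1-based inclusive genomic intervals (GTF convention)
throughout; BED exports convert to half-open 0-based at the boundary.
Transcripts must carry an explicit strand because splice-site orientation
drives all downstream analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGTN")
STAGES = tuple(f"E{i}" for i in range(1, 9))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class GenomeSequence:
    """A genome as a mapping of chromosome name to an uppercase A/C/G/T/N string."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValidationError(f"chromosome {name!r} contains invalid bases {bad}")
            if name in self.sequences:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            self.sequences[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates [start, end]."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 1 or end > len(self.sequences[chrom]) or start > end:
            raise ValidationError(
                f"window {chrom}:{start}-{end} out of bounds (length {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start - 1 : end]


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-chain transcript model anchored on the genome.

    ``exons`` is an ordered tuple of 1-based inclusive ``(start, end)``
    intervals sorted by genomic start, non-overlapping and non-adjacent
    (every gap is an intron of length >= 1).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id!r} has no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if s > e:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exon ({s},{e}) has start > end"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1 + 1:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exons ({s1},{e1}) and ({s2},{e2}) "
                    "overlap or are adjacent"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced length (sum of exon lengths)."""
        return sum(e - s + 1 for s, e in self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals (first/last intronic base), genomic order."""
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return self.introns()


@dataclass
class GeneModel:
    """A gene as the set of its transcript models (shared chrom and strand)."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self):
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"gene {self.gene_id!r}: transcript {t.transcript_id!r} disagrees on "
                    "chrom/strand"
                )
            if t.gene_id != self.gene_id:
                raise ValidationError(
                    f"gene {self.gene_id!r}: transcript {t.transcript_id!r} carries "
                    f"gene_id {t.gene_id!r}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s + 1


@dataclass(frozen=True)
class IntronRecord:
    """One intron of one transcript, with strand-oriented boundary dinucleotides.

    ``donor_dinuc`` is the first two intronic bases read 5'->3' along the
    transcript (canonically GT); ``acceptor_dinuc`` the last two (canonically AG).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    donor_dinuc: str
    acceptor_dinuc: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def canonical(self) -> bool:
        return self.donor_dinuc == "GT" and self.acceptor_dinuc == "AG"


class ExpressionMatrix:
    """Transcript x sample FPKM matrix with stage/replicate metadata.

    Samples are named ``<stage>_<replicate>`` (e.g. ``E3_2``). ``tx2gene``
    maps every transcript to exactly one gene.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        tx2gene: Mapping[str, str],
    ):
        if (values.values < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate transcript rows: {dups[:5]}")
        missing = set(values.index) - set(tx2gene)
        if missing:
            raise ValidationError(f"transcripts without gene mapping: {sorted(missing)[:5]}")
        meta = {}
        for col in values.columns:
            stage, _, rep = str(col).rpartition("_")
            if stage not in STAGES or not rep.isdigit():
                raise ValidationError(
                    f"sample name {col!r} is not of the form '<stage>_<replicate>' "
                    f"with stage in {STAGES}"
                )
            meta[col] = (stage, int(rep))
        self.values = values.astype(float)
        self.tx2gene = pd.Series({t: tx2gene[t] for t in values.index}, name="gene_id")
        self.sample_meta = pd.DataFrame.from_dict(
            meta, orient="index", columns=["stage", "replicate"]
        )

    @property
    def stages(self) -> list[str]:
        seen = dict.fromkeys(self.sample_meta["stage"])
        return [s for s in STAGES if s in seen]

    def stage_samples(self, stage: str) -> list[str]:
        return self.sample_meta.index[self.sample_meta["stage"] == stage].tolist()

    def stage_means(self) -> pd.DataFrame:
        """Transcript x stage matrix of replicate-mean FPKM."""
        cols = {s: self.values[self.stage_samples(s)].mean(axis=1) for s in self.stages}
        return pd.DataFrame(cols)

    def gene_values(self) -> pd.DataFrame:
        """Gene x sample matrix: per-gene sum of transcript FPKM."""
        return self.values.groupby(self.tx2gene).sum()

    def transcripts_of(self, gene_id: str) -> list[str]:
        return self.tx2gene.index[self.tx2gene == gene_id].tolist()
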