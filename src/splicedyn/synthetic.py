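"""Synthetic study-condition generator.

Builds genomes, isoform catalogs with planted alternative-splicing events,
staged expression matrices following designed IRT and expression
trajectories, poly(A)-site records with microheterogeneity and an upstream
AATAAA signal, and fusion-candidate panels with known verdicts — so every
pipeline stage can be exercised against exact ground truth.

All generators are deterministic for a fixed seed. Planted splice sites are
written into the genome as GT...AG (except an optional fraction of retained
introns given degenerate boundaries), and planted constructions use
boundary-matched flanking exons so each event's coordinate signature is
unambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fusion import AlignmentSegment, FusionCandidate
from .models import (
    ExpressionMatrix,
    GeneModel,
    GenomeSequence,
    STAGES,
    TranscriptModel,
    ValidationError,
)
from .polya import PolyARecord

EVENT_TYPES = ("IR", "ES", "A5SS", "A3SS", "MEE")

# gene template geometry (nt)
EXON = 120
INTRON = 150
GENE_FOOTPRINT = 4 * EXON + 3 * INTRON  # widest construction (MEE)
GENE_SPACING = 2000


class CapacityError(ValueError):
    """The genome cannot hold the requested number of genes."""


@dataclass
class TruthLabels:
    """Ground truth emitted alongside every synthetic dataset."""

    as_events: list[tuple[str, str, tuple]] = field(default_factory=list)
    control_genes: list[str] = field(default_factory=list)
    ir_transcripts: dict[str, str] = field(default_factory=dict)  # gene -> IR tx id
    degenerate_ir_genes: list[str] = field(default_factory=list)
    irt_archetype: dict[str, int] = field(default_factory=dict)
    expr_cluster: dict[str, int] = field(default_factory=dict)
    polya_truth: dict[str, list[int]] = field(default_factory=dict)
    fusion_truth: dict[str, tuple[bool, str | None]] = field(default_factory=dict)


# nine designed IRT trajectories over the eight stages
DEFAULT_IRT_ARCHETYPES = np.array(
    [
        [0.10, 0.21, 0.33, 0.44, 0.56, 0.67, 0.79, 0.90],  # rising
        [0.90, 0.79, 0.67, 0.56, 0.44, 0.33, 0.21, 0.10],  # falling
        [0.80, 0.80, 0.80, 0.80, 0.80, 0.80, 0.80, 0.80],  # stable high
        [0.15, 0.15, 0.15, 0.15, 0.15, 0.15, 0.15, 0.15],  # stable low
        [0.10, 0.30, 0.60, 0.85, 0.85, 0.60, 0.30, 0.10],  # mid peak
        [0.90, 0.70, 0.40, 0.15, 0.15, 0.40, 0.70, 0.90],  # mid dip
        [0.15, 0.15, 0.80, 0.80, 0.80, 0.80, 0.80, 0.80],  # step up at E3
        [0.80, 0.80, 0.80, 0.80, 0.80, 0.15, 0.15, 0.15],  # step down at E6
        [0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45],  # stable mid
    ]
)

# ten designed expression trajectories: a bump per stage plus two monotone ramps
_BUMP = 0.15


def _bump(stage: int) -> list[float]:
    v = [_BUMP] * 8
    v[stage] = 1.0
    if stage > 0:
        v[stage - 1] = 0.5
    if stage < 7:
        v[stage + 1] = 0.5
    return v


DEFAULT_EXPR_ARCHETYPES = np.array(
    [_bump(i) for i in range(8)]
    + [
        [0.15, 0.25, 0.36, 0.47, 0.58, 0.69, 0.80, 0.90],  # rising ramp
        [0.90, 0.80, 0.69, 0.58, 0.47, 0.36, 0.25, 0.15],  # falling ramp
    ]
)


def generate_genome(
    n_chrom: int, chrom_length: int, gc: float = 0.42, seed: int = 0
) -> GenomeSequence:
    """Random genome with independent bases at the requested GC fraction."""
    if n_chrom < 0:
        raise ValidationError("n_chrom must be >= 0")
    if n_chrom > 0 and chrom_length <= 0:
        raise ValidationError("chrom_length must be positive")
    if not 0 < gc < 1:
        raise ValidationError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for i in range(n_chrom):
        draw = rng.choice(bases, size=chrom_length, p=p)
        seqs[f"chr{i + 1}"] = draw.tobytes().decode()
    return GenomeSequence(seqs)


def _write(seq: list[str], start: int, text: str) -> None:
    """Write `text` at 1-based position `start` into a mutable chromosome."""
    seq[start - 1 : start - 1 + len(text)] = list(text)


def _plant_splice_site(seq: list[str], start: int, end: int, strand: str,
                       donor: str = "GT", acceptor: str = "AG") -> None:
    """Write strand-oriented donor/acceptor dinucleotides for intron [start, end]."""
    comp = str.maketrans("ACGT", "TGCA")
    if strand == "+":
        _write(seq, start, donor)
        _write(seq, end - 1, acceptor)
    else:
        _write(seq, end - 1, donor.translate(comp)[::-1])
        _write(seq, start, acceptor.translate(comp)[::-1])


def generate_gene_models(
    genome: GenomeSequence,
    n_genes: int,
    events_per_type: int | Mapping[str, int] = 5,
    seed: int = 0,
    degenerate_ir_fraction: float = 0.0,
) -> tuple[list[GeneModel], TruthLabels]:
    """Plant exactly ``events_per_type`` unambiguous events of each AS type.

    Genes are laid out sequentially across chromosomes, alternating strand.
    Genes beyond the planted ones are single-isoform three-exon controls.
    Splice sites are written into the genome (in place) as GT...AG, except a
    ``degenerate_ir_fraction`` of retained introns whose boundaries are made
    non-canonical (CA...GG) to emulate weak splice sites.
    """
    if isinstance(events_per_type, int):
        per_type = {t: events_per_type for t in EVENT_TYPES}
    else:
        per_type = {t: int(events_per_type.get(t, 0)) for t in EVENT_TYPES}
    n_planted = sum(per_type.values())
    if n_genes < n_planted:
        raise ValidationError(
            f"n_genes={n_genes} cannot hold {n_planted} planted event genes"
        )
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    capacity = sum(
        max((genome.length(c) - GENE_SPACING) // (GENE_FOOTPRINT + GENE_SPACING), 0)
        for c in chroms
    )
    if capacity < n_genes:
        raise CapacityError(
            f"genome holds at most {capacity} genes at this spacing; {n_genes} requested"
        )

    mutable = {c: list(genome.sequences[c]) for c in chroms}
    plan = [t for t in EVENT_TYPES for _ in range(per_type[t])]
    plan += ["control"] * (n_genes - n_planted)

    truth = TruthLabels()
    genes: list[GeneModel] = []
    chrom_i, offset = 0, GENE_SPACING
    n_ir_degenerate = int(round(per_type["IR"] * degenerate_ir_fraction))
    ir_seen = 0
    for g_i, kind in enumerate(plan):
        if offset + GENE_FOOTPRINT + GENE_SPACING > genome.length(chroms[chrom_i]):
            chrom_i += 1
            offset = GENE_SPACING
        chrom = chroms[chrom_i]
        strand = "+" if g_i % 2 == 0 else "-"
        gid = f"G{g_i + 1:05d}"
        p = offset
        seq = mutable[chrom]

        e1 = (p, p + EXON - 1)
        i1 = (p + EXON, p + EXON + INTRON - 1)
        e2 = (i1[1] + 1, i1[1] + EXON)
        i2 = (e2[1] + 1, e2[1] + INTRON)
        e3 = (i2[1] + 1, i2[1] + EXON)
        i3 = (e3[1] + 1, e3[1] + INTRON)
        e4 = (i3[1] + 1, i3[1] + EXON)

        def tx(suffix: str, exons) -> TranscriptModel:
            return TranscriptModel(
                transcript_id=f"{gid}.{suffix}",
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )

        if kind == "IR":
            a = tx("a", [e1, e2, e3])
            # retain the transcript-3' intron (emulating the 3' positional
            # bias of retained introns): genomic i2 on '+', i1 on '-'
            if strand == "+":
                retained_intron, other_intron = i2, i1
                b = tx("b", [e1, (e2[0], e3[1])])
            else:
                retained_intron, other_intron = i1, i2
                b = tx("b", [(e1[0], e2[1]), e3])
            _plant_splice_site(seq, *other_intron, strand)
            ir_seen += 1
            if ir_seen <= n_ir_degenerate:
                _plant_splice_site(seq, *retained_intron, strand,
                                   donor="CA", acceptor="GG")
                truth.degenerate_ir_genes.append(gid)
            else:
                _plant_splice_site(seq, *retained_intron, strand)
            truth.as_events.append(("IR", gid, retained_intron))
            truth.ir_transcripts[gid] = b.transcript_id
            gene = GeneModel(gid, chrom, strand, [a, b])
        elif kind == "ES":
            a = tx("a", [e1, e2, e3])
            b = tx("b", [e1, e3])
            _plant_splice_site(seq, *i1, strand)
            _plant_splice_site(seq, *i2, strand)
            truth.as_events.append(("ES", gid, (e2[0], e2[1], i1[0], i2[1])))
            gene = GeneModel(gid, chrom, strand, [a, b])
        elif kind in ("A5SS", "A3SS"):
            shift = 30
            # A5SS shifts the donor boundary, A3SS the acceptor, in transcript
            # orientation: on '+' the donor is the intron's genomic start.
            shift_start = (kind == "A5SS") == (strand == "+")
            if shift_start:
                alt_intron = (i1[0] + shift, i1[1])
                b = tx("b", [(e1[0], e1[1] + shift), e2])
                sig = (i1[0], alt_intron[0], i1[1])
            else:
                alt_intron = (i1[0], i1[1] - shift)
                b = tx("b", [e1, (e2[0] - shift, e2[1])])
                sig = (i1[1] - shift, i1[1], i1[0])
            a = tx("a", [e1, e2])
            _plant_splice_site(seq, *i1, strand)
            _plant_splice_site(seq, *alt_intron, strand)
            truth.as_events.append((kind, gid, sig))
            gene = GeneModel(gid, chrom, strand, [a, b])
        elif kind == "MEE":
            a = tx("a", [e1, e2, e4])
            b = tx("b", [e1, e3, e4])
            for intron in [
                (i1[0], e2[0] - 1),
                (e2[1] + 1, e4[0] - 1),
                (i1[0], e3[0] - 1),
                (e3[1] + 1, e4[0] - 1),
            ]:
                _plant_splice_site(seq, *intron, strand)
            truth.as_events.append(
                ("MEE", gid, (e2[0], e2[1], e3[0], e3[1], i1[0], e4[0] - 1))
            )
            gene = GeneModel(gid, chrom, strand, [a, b])
        else:  # control: single isoform, three exons
            a = tx("a", [e1, e2, e3])
            _plant_splice_site(seq, *i1, strand)
            _plant_splice_site(seq, *i2, strand)
            truth.control_genes.append(gid)
            gene = GeneModel(gid, chrom, strand, [a])
        genes.append(gene)
        offset += GENE_FOOTPRINT + GENE_SPACING

    for c in chroms:
        genome.sequences[c] = "".join(mutable[c])
    return genes, truth


def generate_expression(
    models: Sequence[GeneModel],
    irt_archetypes: np.ndarray | None = None,
    expr_archetypes: np.ndarray | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
    base_fpkm: float = 50.0,
    n_replicates: int = 3,
    truth: TruthLabels | None = None,
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Staged FPKM matrix following designed trajectories.

    Each gene gets one expression archetype (its stage total = ``base_fpkm``
    x archetype) and, if it owns an IR-containing transcript, one IRT
    archetype (the IR transcript's share of the gene total before noise).
    Replicate noise is multiplicative log-normal with log-scale s.d.
    ``noise_sd``; with ``noise_sd=0`` the realized IRT profile equals the
    archetype exactly. Archetype assignment is round-robin in gene order, so
    counts per archetype are balanced.
    """
    irt_arch = DEFAULT_IRT_ARCHETYPES if irt_archetypes is None else np.asarray(irt_archetypes, float)
    expr_arch = DEFAULT_EXPR_ARCHETYPES if expr_archetypes is None else np.asarray(expr_archetypes, float)
    if irt_arch.ndim != 2 or irt_arch.shape[1] != len(STAGES):
        raise ValidationError("IRT archetypes must be (n, 8)")
    if (irt_arch < 0).any() or (irt_arch > 1).any():
        raise ValidationError("IRT archetype values must lie in [0, 1]")
    if expr_arch.ndim != 2 or expr_arch.shape[1] != len(STAGES):
        raise ValidationError("expression archetypes must be (n, 8)")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else TruthLabels()
    ir_of = dict(truth.ir_transcripts)

    samples = [f"{s}_{r}" for s in STAGES for r in range(1, n_replicates + 1)]
    rows: dict[str, np.ndarray] = {}
    tx2gene: dict[str, str] = {}
    ir_gene_i = 0
    for g_i, gene in enumerate(models):
        e_idx = g_i % len(expr_arch)
        truth.expr_cluster[gene.gene_id] = e_idx + 1
        total = base_fpkm * expr_arch[e_idx]
        ir_tid = ir_of.get(gene.gene_id)
        if ir_tid is not None:
            i_idx = ir_gene_i % len(irt_arch)
            ir_gene_i += 1
            truth.irt_archetype[gene.gene_id] = i_idx + 1
            shares = {}
            others = [t.transcript_id for t in gene.transcripts if t.transcript_id != ir_tid]
            for t in gene.transcripts:
                if t.transcript_id == ir_tid:
                    shares[t.transcript_id] = irt_arch[i_idx]
                else:
                    shares[t.transcript_id] = (1.0 - irt_arch[i_idx]) / len(others)
        else:
            shares = {
                t.transcript_id: np.full(len(STAGES), 1.0 / len(gene.transcripts))
                for t in gene.transcripts
            }
        for t in gene.transcripts:
            stage_vals = total * shares[t.transcript_id]
            reps = np.repeat(stage_vals, n_replicates)
            if noise_sd > 0:
                reps = reps * rng.lognormal(0.0, noise_sd, size=reps.size)
            rows[t.transcript_id] = reps
            tx2gene[t.transcript_id] = gene.gene_id
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return ExpressionMatrix(values=values, tx2gene=tx2gene), truth


def generate_polya_sites(
    models: Sequence[GeneModel],
    genome: GenomeSequence,
    sites_per_gene: int = 2,
    heterogeneity_sd: float = 3.0,
    signal_rate: float = 0.8,
    reads_per_site: int = 5,
    site_spacing: int = 60,
    seed: int = 0,
    truth: TruthLabels | None = None,
) -> tuple[list[PolyARecord], TruthLabels]:
    """Planted cleavage sites downstream of each gene's 3' end.

    Each planted site is emitted ``reads_per_site`` times with integer
    offsets drawn from N(0, heterogeneity_sd) truncated at +/-9 nt, so jitter
    never bridges the 20-nt clustering window between planted sites, which
    must themselves be >= 40 nt apart. An AATAAA signal is written into the
    genome 15-30 nt upstream (transcript orientation) of a ``signal_rate``
    fraction of sites.
    """
    if site_spacing < 40:
        raise ValidationError("planted sites must be >= 40 nt apart")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else TruthLabels()
    mutable = {c: list(genome.sequences[c]) for c in genome.sequences}
    records: list[PolyARecord] = []
    comp = str.maketrans("ACGT", "TGCA")
    for gene in models:
        s, e = gene.span
        positions = []
        for k in range(sites_per_gene):
            if gene.strand == "+":
                pos = e + 10 + k * site_spacing
            else:
                pos = s - 10 - k * site_spacing
            if not 60 <= pos <= genome.length(gene.chrom) - 60:
                raise ValidationError(
                    f"planted site {pos} for gene {gene.gene_id} out of usable range"
                )
            positions.append(pos)
        if any(
            abs(p1 - p2) < 40 for i, p1 in enumerate(positions) for p2 in positions[:i]
        ):
            raise ValidationError("planted sites closer than 40 nt")
        truth.polya_truth[gene.gene_id] = sorted(positions)
        for pos in positions:
            if rng.random() < signal_rate:
                off = int(rng.integers(15, 31))  # hexamer's last base `off` nt upstream
                if gene.strand == "+":
                    _write(mutable[gene.chrom], pos - off - 5, "AATAAA")
                else:
                    _write(mutable[gene.chrom], pos + off, "AATAAA".translate(comp)[::-1])
            for _ in range(reads_per_site):
                jit = 0
                if heterogeneity_sd > 0:
                    jit = int(np.clip(round(rng.normal(0, heterogeneity_sd)), -9, 9))
                records.append(
                    PolyARecord(
                        chrom=gene.chrom,
                        position=pos + jit,
                        strand=gene.strand,
                        count=1,
                    )
                )
    for c in mutable:
        genome.sequences[c] = "".join(mutable[c])
    return records, truth


def generate_de_expression(
    n_null: int = 2000,
    n_de: int = 50,
    fold: float = 8.0,
    noise_sd: float = 0.1,
    base_fpkm: float = 20.0,
    n_replicates: int = 3,
    stage_up: str = "E2",
    seed: int = 0,
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Two-stage expression matrix for differential-expression calibration.

    ``n_null`` genes keep their baseline at both stages; ``n_de`` genes are
    raised ``fold``-fold at ``stage_up`` relative to E1. Baselines vary
    log-normally across genes; replicate noise is log-normal with log-scale
    s.d. ``noise_sd``. Each gene is represented by a single transcript.
    Truth records the up-regulated genes under ``expr_cluster`` = 2 (nulls 1).
    """
    rng = np.random.default_rng(seed)
    truth = TruthLabels()
    n = n_null + n_de
    baseline = base_fpkm * rng.lognormal(0.0, 0.5, size=n)
    stage_a_samples = [f"E1_{r}" for r in range(1, n_replicates + 1)]
    stage_b_samples = [f"{stage_up}_{r}" for r in range(1, n_replicates + 1)]
    means_b = baseline.copy()
    means_b[n_null:] *= fold
    noise = rng.lognormal(0.0, noise_sd, size=(n, 2 * n_replicates))
    values = np.column_stack(
        [baseline] * n_replicates + [means_b] * n_replicates
    ) * noise
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    tx_ids = [f"{g}.a" for g in gene_ids]
    df = pd.DataFrame(values, index=tx_ids, columns=stage_a_samples + stage_b_samples)
    for i, g in enumerate(gene_ids):
        truth.expr_cluster[g] = 2 if i >= n_null else 1
    return ExpressionMatrix(values=df, tx2gene=dict(zip(tx_ids, gene_ids))), truth


def generate_fusion_candidates(
    n_pass: int, n_fail_per_criterion: int = 1, seed: int = 0
) -> tuple[list[FusionCandidate], TruthLabels]:
    """A labeled candidate panel: ``n_pass`` all-criteria passes plus
    ``n_fail_per_criterion`` candidates violating exactly one criterion each."""
    rng = np.random.default_rng(seed)
    truth = TruthLabels()
    cands: list[FusionCandidate] = []

    def pos() -> int:
        return int(rng.integers(100_000, 5_000_000))

    def seg(chrom: str, frac: float, start: int | None = None) -> AlignmentSegment:
        s = pos() if start is None else start
        return AlignmentSegment(chrom=chrom, start=s, end=s + 1000, fraction=frac)

    idx = 0

    def add(segments, support: int, expected: tuple[bool, str | None]):
        nonlocal idx
        idx += 1
        tid = f"F{idx:04d}"
        cands.append(
            FusionCandidate(
                transcript_id=tid,
                transcript_length=int(rng.integers(1500, 4000)),
                segments=tuple(segments),
                junction_support=support,
            )
        )
        truth.fusion_truth[tid] = expected

    for _ in range(n_pass):
        add([seg("chr1", 0.50), seg("chr2", 0.48)], 3, (True, None))
    for _ in range(n_fail_per_criterion):
        add([seg("chr1", 0.97)], 3, (False, "a"))  # one locus
    for _ in range(n_fail_per_criterion):
        add([seg("chr1", 0.50), seg("NW_003763.1", 0.47)], 3, (False, "b"))
    for _ in range(n_fail_per_criterion):
        add([seg("chr1", 0.93), seg("chr2", 0.04)], 3, (False, "c"))
    for _ in range(n_fail_per_criterion):
        add([seg("chr1", 0.50), seg("chr2", 0.40)], 3, (False, "d"))
    for _ in range(n_fail_per_criterion):
        s = pos()
        add([seg("chr1", 0.50, s), seg("chr1", 0.48, s + 6000)], 3, (False, "e"))
    for _ in range(n_fail_per_criterion):
        add([seg("chr1", 0.50), seg("chr2", 0.48)], 0, (False, "f"))
    return cands, truth


def write_truth_tsv(truth: TruthLabels, path) -> None:
    """Flat TSV of every truth label (category, key, value) for inspection."""
    rows = []
    for etype, gid, sig in truth.as_events:
        rows.append(("as_event", gid, f"{etype}:{','.join(map(str, sig))}"))
    for gid in truth.control_genes:
        rows.append(("control_gene", gid, ""))
    for gid, tid in truth.ir_transcripts.items():
        rows.append(("ir_transcript", gid, tid))
    for gid, a in truth.irt_archetype.items():
        rows.append(("irt_archetype", gid, str(a)))
    for gid, c in truth.expr_cluster.items():
        rows.append(("expr_cluster", gid, str(c)))
    for gid, sites in truth.polya_truth.items():
        rows.append(("polya_sites", gid, ",".join(map(str, sites))))
    for tid, (ok, crit) in truth.fusion_truth.items():
        rows.append(("fusion_verdict", tid, "pass" if ok else f"fail:{crit}"))
    pd.DataFrame(rows, columns=["category", "key", "value"]).to_csv(
        path, sep="\t", index=False
    )
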