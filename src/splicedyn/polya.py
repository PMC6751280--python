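"""Poly(A)-site clustering and characterization.

Cleavage-site records (3' read ends) are collapsed by single-linkage
chaining with a 20-nt window to absorb microheterogeneity; clusters are
assigned to genes, compared across stages, and their sequence context is
summarized as a positional base-composition matrix and an exhaustive
hexamer enrichment scan (binomial test against an order-0 background) that
recovers the canonical AATAAA poly(A) signal.
"""
from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, GenomeSequence, ValidationError

BASES = "ACGT"
HEXAMERS = ["".join(p) for p in itertools.product(BASES, repeat=6)]


@dataclass(frozen=True)
class PolyARecord:
    """A 3'-end (cleavage) observation: 1-based genomic position of the last
    transcribed base, with a read-support count."""

    chrom: str
    position: int
    strand: str
    count: int = 1


@dataclass
class PolyACluster:
    chrom: str
    strand: str
    representative_position: int
    support: int
    member_positions: tuple[int, ...]


@dataclass
class MotifEnrichment:
    motif: str
    observed: int
    expected: float
    p: float
    rank: int


def cluster_polya_sites(
    records: Iterable[PolyARecord], window: int = 20
) -> list[PolyACluster]:
    """Single-linkage chaining of sorted positions with gap <= ``window``.

    The representative is the member position with the highest summed read
    support; ties go to the 3'-most position in transcript orientation.
    """
    by_group: dict[tuple[str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for r in records:
        by_group[(r.chrom, r.strand)][r.position] += r.count
    clusters: list[PolyACluster] = []
    for (chrom, strand), pos_counts in sorted(by_group.items()):
        positions = sorted(pos_counts)
        chain: list[int] = []
        for pos in positions:
            if chain and pos - chain[-1] > window:
                clusters.append(_make_cluster(chrom, strand, chain, pos_counts))
                chain = []
            chain.append(pos)
        if chain:
            clusters.append(_make_cluster(chrom, strand, chain, pos_counts))
    return clusters


def _make_cluster(
    chrom: str, strand: str, members: list[int], counts: Mapping[int, int]
) -> PolyACluster:
    best_support = max(counts[p] for p in members)
    candidates = [p for p in members if counts[p] == best_support]
    rep = max(candidates) if strand == "+" else min(candidates)
    return PolyACluster(
        chrom=chrom,
        strand=strand,
        representative_position=rep,
        support=sum(counts[p] for p in members),
        member_positions=tuple(members),
    )


def sites_per_gene(
    clusters: Sequence[PolyACluster],
    genes: Iterable[GeneModel],
    downstream: int = 1000,
    min_support: int = 2,
) -> tuple[pd.Series, float, float, list[PolyACluster]]:
    """Assign clusters to genes and summarize APA multiplicity.

    A cluster belongs to the same-strand gene whose span, extended
    ``downstream`` nt past its 3' end, contains the representative position.
    Clusters below ``min_support`` are dropped (low-confidence sites).
    Returns (per-gene counts, mean sites per gene with >= 1 site, fraction of
    such genes with > 1 site, unassigned clusters).
    """
    gene_list = list(genes)
    counts: dict[str, int] = {}
    unassigned: list[PolyACluster] = []
    for cl in clusters:
        if cl.support < min_support:
            continue
        hit = None
        for g in gene_list:
            if g.chrom != cl.chrom or g.strand != cl.strand:
                continue
            s, e = g.span
            if g.strand == "+":
                lo, hi = s, e + downstream
            else:
                lo, hi = s - downstream, e
            if lo <= cl.representative_position <= hi:
                hit = g.gene_id
                break
        if hit is None:
            unassigned.append(cl)
        else:
            counts[hit] = counts.get(hit, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    mean = float(series.mean()) if len(series) else float("nan")
    frac_multi = float((series > 1).mean()) if len(series) else float("nan")
    return series, mean, frac_multi, unassigned


def stage_site_sharing(
    stage_clusters: Mapping[str, Sequence[PolyACluster]],
    genes: Iterable[GeneModel],
    window: int = 20,
    downstream: int = 1000,
    min_support: int = 1,
) -> pd.Series:
    """Per-gene boolean: does the gene use the same poly(A) sites at every stage?

    Two representative positions count as the same site when they differ by at
    most ``window`` nt. Only genes with at least one assigned site at every
    stage are reported.
    """
    if len(stage_clusters) < 2:
        raise ValidationError("site sharing needs at least two stages")
    gene_list = list(genes)
    per_stage: dict[str, dict[str, list[int]]] = {}
    for stage, clusters in stage_clusters.items():
        assignment: dict[str, list[int]] = defaultdict(list)
        for cl in clusters:
            if cl.support < min_support:
                continue
            for g in gene_list:
                if g.chrom != cl.chrom or g.strand != cl.strand:
                    continue
                s, e = g.span
                lo, hi = (s, e + downstream) if g.strand == "+" else (s - downstream, e)
                if lo <= cl.representative_position <= hi:
                    assignment[g.gene_id].append(cl.representative_position)
                    break
        per_stage[stage] = assignment
    common = set.intersection(*(set(a) for a in per_stage.values()))
    result = {}
    stages = list(per_stage)
    for gid in sorted(common):
        ref = sorted(per_stage[stages[0]][gid])
        result[gid] = all(
            _sites_match(ref, sorted(per_stage[s][gid]), window) for s in stages[1:]
        )
    return pd.Series(result, dtype=bool)


def _sites_match(a: list[int], b: list[int], window: int) -> bool:
    return len(a) == len(b) and all(abs(x - y) <= window for x, y in zip(a, b))


def nucleotide_composition(
    clusters: Sequence[PolyACluster], genome: GenomeSequence, flank: int = 50
) -> pd.DataFrame:
    """Base frequencies at positions -flank..+flank around cleavage sites.

    Position 0 is the cleavage (last transcribed) base; negative positions
    are upstream in transcript orientation. Flanks running off a chromosome
    end are clipped, reducing that position's denominator.
    """
    offsets = np.arange(-flank, flank + 1)
    counts = np.zeros((len(offsets), 4), dtype=float)
    denom = np.zeros(len(offsets), dtype=float)
    for cl in clusters:
        L = genome.length(cl.chrom)
        pos = cl.representative_position
        for i, off in enumerate(offsets):
            g = pos + off if cl.strand == "+" else pos - off
            if 1 <= g <= L:
                base = genome.fetch(cl.chrom, g, g)
                if cl.strand == "-":
                    base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, base)
                j = BASES.find(base)
                if j >= 0:
                    counts[i, j] += 1
                    denom[i] += 1
    with np.errstate(invalid="ignore"):
        freqs = counts / denom[:, None]
    return pd.DataFrame(freqs, index=offsets, columns=list(BASES))


def hexamer_enrichment(
    clusters: Sequence[PolyACluster],
    genome: GenomeSequence,
    upstream: int = 50,
) -> list[MotifEnrichment]:
    """Exhaustive 6-mer enrichment in the upstream windows of cleavage sites.

    For each of the 4096 hexamers, ``observed`` counts windows containing at
    least one occurrence; the expected presence probability per window comes
    from that window's own base composition (order-0 model); the p-value is
    the upper binomial tail at the mean per-window probability. Ranked by p,
    then observed count.
    """
    if not clusters:
        raise ValidationError("hexamer enrichment needs at least one cluster")
    windows = []
    for cl in clusters:
        L = genome.length(cl.chrom)
        if cl.strand == "+":
            lo, hi = cl.representative_position - upstream, cl.representative_position - 1
            if lo < 1:
                continue
            windows.append(genome.fetch(cl.chrom, lo, hi))
        else:
            lo, hi = cl.representative_position + 1, cl.representative_position + upstream
            if hi > L:
                continue
            seq = genome.fetch(cl.chrom, lo, hi)
            windows.append(seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1])
    if not windows:
        raise ValidationError("no in-bounds upstream windows")

    n = len(windows)
    hex_index = {h: i for i, h in enumerate(HEXAMERS)}
    observed = np.zeros(4096, dtype=int)
    log_freqs = np.zeros((n, 4))
    for w_i, w in enumerate(windows):
        present = set()
        for i in range(len(w) - 5):
            h = w[i : i + 6]
            if h in hex_index:
                present.add(hex_index[h])
        for idx in present:
            observed[idx] += 1
        comp = np.array([w.count(b) for b in BASES], dtype=float) + 0.25
        log_freqs[w_i] = np.log(comp / comp.sum())

    # per-hexamer base counts: (4096, 4)
    hex_counts = np.zeros((4096, 4))
    for i, h in enumerate(HEXAMERS):
        for b_i, b in enumerate(BASES):
            hex_counts[i, b_i] = h.count(b)
    # log P(hexamer at a fixed offset) per window: (4096, n)
    logp = hex_counts @ log_freqs.T
    n_offsets = max(len(windows[0]) - 5, 1)
    with np.errstate(over="ignore"):
        p_present = 1.0 - np.exp(np.log1p(-np.exp(logp)) * n_offsets)
    expected = p_present.sum(axis=1)
    p_mean = np.clip(expected / n, 1e-300, 1.0)
    pvals = stats.binom.sf(observed - 1, n, p_mean)
    order = np.lexsort((-observed, pvals))
    out = []
    for rank, idx in enumerate(order, start=1):
        out.append(
            MotifEnrichment(
                motif=HEXAMERS[idx],
                observed=int(observed[idx]),
                expected=float(expected[idx]),
                p=float(pvals[idx]),
                rank=rank,
            )
        )
    return out


def clusters_to_bed(clusters: Sequence[PolyACluster]) -> pd.DataFrame:
    """BED6 export: half-open 0-based single-base intervals at representatives,
    score = support."""
    rows = [
        {
            "chrom": cl.chrom,
            "start": cl.representative_position - 1,
            "end": cl.representative_position,
            "name": f"polyA_{i}",
            "score": cl.support,
            "strand": cl.strand,
        }
        for i, cl in enumerate(clusters, start=1)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
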