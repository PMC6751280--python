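"""End-to-end orchestration from a single YAML config.

The config supplies either paths to real inputs (GTF + FASTA + expression
TSV + poly(A) records + fusion TSV, plus an optional reference annotation)
or a synthetic-generation block; exactly one of the two. Every stage writes
its outputs under the configured directory and contributes counts to a run
report. A single seed governs all stochastic stages.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import catalog_summary, classify_against_annotation, collapse_isoforms
from .dynamics import cluster_expression, differential_genes, sample_correlation
from .events import count_events_by_type, detect_all_events, stage_event_presence
from .fusion import filter_candidates, read_fusion_tsv, verdicts_to_frame, write_fusion_tsv
from .introns import classify_ptc, longest_orf, retained_intron_features, train_splice_pwm
from .io import (
    all_transcripts,
    extract_introns,
    read_expression_table,
    read_genome_fasta,
    read_transcript_gtf,
    transcript_sequence,
    write_expression_table,
    write_genome_fasta,
    write_transcript_gtf,
)
from .irt import IRTProfile, cluster_irt_profiles, irt_profiles
from .models import ValidationError
from .polya import (
    PolyARecord,
    cluster_polya_sites,
    clusters_to_bed,
    hexamer_enrichment,
    nucleotide_composition,
    sites_per_gene,
)
from .synthetic import (
    generate_expression,
    generate_fusion_candidates,
    generate_gene_models,
    generate_genome,
    generate_polya_sites,
    write_truth_tsv,
)

log = logging.getLogger("splicedyn")


@dataclass
class RunConfig:
    output_dir: str
    inputs: dict | None = None  # gtf, fasta, expression, polya, fusion, reference
    synthetic: dict | None = None  # generator parameters incl. seed
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.inputs is None) == (self.synthetic is None):
            raise ValidationError(
                "config must contain exactly one of 'inputs' or 'synthetic'"
            )
        for key, val in self.thresholds.items():
            if isinstance(val, (int, float)) and val <= 0:
                raise ValidationError(f"threshold {key!r} must be positive, got {val}")
        if self.inputs is not None:
            for key in ("gtf", "fasta", "expression"):
                if key not in self.inputs:
                    raise ValidationError(f"inputs block missing required field {key!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def get(self, key: str, default):
        return self.thresholds.get(key, default)


def _read_polya_tsv(path) -> list[PolyARecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PolyARecord(chrom=r.chrom, position=int(r.position), strand=r.strand,
                    count=int(r.count))
        for r in df.itertuples()
    ]


def _write_polya_tsv(records, path) -> None:
    pd.DataFrame(
        [
            {"chrom": r.chrom, "position": r.position, "strand": r.strand, "count": r.count}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; return the report (also written as TSV + summary)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, object] = {"version": __version__}
    seed = 0

    # ---- stage 0: inputs --------------------------------------------------
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        seed = int(syn.get("seed", 0))
        log.info("generating synthetic inputs (seed=%d)", seed)
        genome = generate_genome(
            n_chrom=syn.get("n_chrom", 2),
            chrom_length=syn.get("chrom_length", 400_000),
            gc=syn.get("gc", 0.42),
            seed=seed,
        )
        genes, truth = generate_gene_models(
            genome,
            n_genes=syn.get("n_genes", 60),
            events_per_type=syn.get("events_per_type", 8),
            seed=seed + 1,
            degenerate_ir_fraction=syn.get("degenerate_ir_fraction", 0.5),
        )
        expr, truth = generate_expression(
            genes,
            noise_sd=syn.get("noise_sd", 0.2),
            seed=seed + 2,
            truth=truth,
        )
        polya_records, truth = generate_polya_sites(
            genes,
            genome,
            sites_per_gene=syn.get("sites_per_gene", 2),
            heterogeneity_sd=syn.get("heterogeneity_sd", 3.0),
            signal_rate=syn.get("signal_rate", 0.8),
            seed=seed + 3,
            truth=truth,
        )
        fusion_cands, ftruth = generate_fusion_candidates(
            n_pass=syn.get("n_fusion_pass", 5),
            n_fail_per_criterion=syn.get("n_fusion_fail_per_criterion", 1),
            seed=seed + 4,
        )
        truth.fusion_truth = ftruth.fusion_truth
        reference = genes
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        write_genome_fasta(genome, inputs_dir / "genome.fa")
        write_transcript_gtf(genes, inputs_dir / "models.gtf")
        write_expression_table(expr, inputs_dir / "expression.tsv")
        _write_polya_tsv(polya_records, inputs_dir / "polya.tsv")
        write_fusion_tsv(fusion_cands, inputs_dir / "fusion.tsv")
        write_truth_tsv(truth, inputs_dir / "truth.tsv")
    else:
        paths = cfg.inputs
        for key in ("gtf", "fasta", "expression"):
            if not Path(paths[key]).exists():
                raise ValidationError(f"input file for {key!r} not found: {paths[key]}")
        log.info("loading inputs from %s", {k: str(v) for k, v in paths.items()})
        genome = read_genome_fasta(paths["fasta"])
        genes = read_transcript_gtf(paths["gtf"])
        expr = read_expression_table(paths["expression"])
        polya_records = _read_polya_tsv(paths["polya"]) if "polya" in paths else []
        fusion_cands = read_fusion_tsv(paths["fusion"]) if "fusion" in paths else []
        reference = (
            read_transcript_gtf(paths["reference"]) if "reference" in paths else genes
        )
    report["seed"] = seed
    report["n_genes"] = len(genes)
    report["n_transcripts"] = sum(len(g.transcripts) for g in genes)

    # ---- catalog ----------------------------------------------------------
    log.info("stage catalog: collapse + classify + summarize")
    collapsed = collapse_isoforms(all_transcripts(genes))
    classification = classify_against_annotation(collapsed, reference)
    summary = catalog_summary(genes)
    pd.Series(classification.assignments, name="class").rename_axis(
        "transcript_id"
    ).to_frame().to_csv(out / "classification.tsv", sep="\t")
    summary.to_csv(out / "catalog_summary.tsv", sep="\t")
    report["n_collapsed_transcripts"] = len(collapsed)
    report.update({f"class_{k}": v for k, v in classification.counts.items()})

    # ---- AS events --------------------------------------------------------
    log.info("stage as-events: detect + count + stage presence")
    events = detect_all_events(genes)
    counts = count_events_by_type(events)
    rows = [
        {
            "event_type": ev.event_type,
            "gene_id": ev.gene_id,
            "signature": ",".join(map(str, ev.signature)),
            "form_a": ";".join(sorted(ev.form_a)),
            "form_b": ";".join(sorted(ev.form_b)),
        }
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(out / "as_events.tsv", sep="\t", index=False)
    presence = stage_event_presence(events, expr, min_fpkm=cfg.get("min_fpkm", 0.1))
    presence.to_csv(out / "as_events_by_stage.tsv", sep="\t")
    report.update({f"events_{k}": v for k, v in counts.items()})

    # ---- IR features + PTC ------------------------------------------------
    log.info("stage ir: retained-intron features + PTC calls")
    ir_events = [ev for ev in events if ev.event_type == "IR"]
    gene_map = {g.gene_id: g for g in genes}
    retained = {(ev.gene_id, ev.signature) for ev in ir_events}
    non_retained = [
        rec
        for g in genes
        for t in g.transcripts
        for rec in extract_introns(t, genome)
        if t.n_exons > 1 and (g.gene_id, (rec.start, rec.end)) not in retained
    ]
    pwm = train_splice_pwm(non_retained, genome) if non_retained else None
    feats = retained_intron_features(ir_events, gene_map, genome, pwm=pwm)
    pd.DataFrame(
        [
            {
                "gene_id": f.intron.gene_id,
                "start": f.intron.start,
                "end": f.intron.end,
                "position_ratio": f.position_ratio,
                "length": f.length,
                "gc": f.gc,
                "canonical": f.canonical,
                "donor_score_pwm_logodds": f.donor_score,
                "acceptor_score_pwm_logodds": f.acceptor_score,
            }
            for f in feats
        ]
    ).to_csv(out / "ir_features.tsv", sep="\t", index=False)
    ptc_rows = []
    for ev in ir_events:
        for tid in ev.form_b:  # retaining isoforms
            t = next(
                x for x in gene_map[ev.gene_id].transcripts if x.transcript_id == tid
            )
            orf = longest_orf(transcript_sequence(t, genome))
            row = {"transcript_id": tid, "gene_id": ev.gene_id, "has_orf": orf.has_orf}
            if orf.has_orf and t.n_exons >= 2:
                row["ptc"] = classify_ptc(t, orf)
                row["stop_to_last_junction"] = orf.stop_to_last_junction
            ptc_rows.append(row)
    pd.DataFrame(ptc_rows).to_csv(out / "ir_ptc.tsv", sep="\t", index=False)
    report["n_retained_introns"] = len(feats)

    # ---- IRT dynamics -----------------------------------------------------
    log.info("stage irt: profiles + k-means")
    ir_ids = {tid for ev in ir_events for tid in ev.form_b}
    profiles = irt_profiles(expr, ir_ids)
    ir_genes = {ev.gene_id for ev in ir_events}
    eligible = profiles.eligible & profiles.values.index.isin(ir_genes)
    k_irt = cfg.get("k_irt", 9)
    prof_out = profiles.values.copy()
    prof_out["eligible"] = profiles.eligible
    prof_out.to_csv(out / "irt_profiles.tsv", sep="\t")
    if eligible.sum() >= k_irt:
        irt_clusters = cluster_irt_profiles(
            IRTProfile(values=profiles.values[eligible], eligible=eligible[eligible]),
            k=k_irt,
            seed=seed,
        )
        irt_clusters.labels.rename_axis("gene_id").to_frame().to_csv(
            out / "irt_clusters.tsv", sep="\t"
        )
        report["n_irt_clustered"] = int(eligible.sum())

    # ---- APA --------------------------------------------------------------
    log.info("stage apa: cluster + per-gene + composition + motifs")
    if polya_records:
        clusters = cluster_polya_sites(polya_records, window=cfg.get("apa_window", 20))
        per_gene, mean_sites, frac_multi, unassigned = sites_per_gene(
            clusters, genes, min_support=cfg.get("apa_min_support", 2)
        )
        clusters_to_bed(clusters).to_csv(
            out / "polya_clusters.bed", sep="\t", index=False, header=False
        )
        per_gene.rename("n_sites").rename_axis("gene_id").to_frame().to_csv(
            out / "polya_sites_per_gene.tsv", sep="\t"
        )
        nucleotide_composition(clusters, genome).rename_axis("offset").to_csv(
            out / "polya_composition.tsv", sep="\t"
        )
        motifs = hexamer_enrichment(clusters, genome)
        pd.DataFrame(
            [
                {"motif": m.motif, "observed": m.observed, "expected": m.expected,
                 "p": m.p, "rank": m.rank}
                for m in motifs[:50]
            ]
        ).to_csv(out / "polya_motifs.tsv", sep="\t", index=False)
        report["n_polya_clusters"] = len(clusters)
        report["mean_sites_per_gene"] = round(mean_sites, 3)
        report["top_motif"] = motifs[0].motif

    # ---- fusion -----------------------------------------------------------
    log.info("stage fusion: six-criterion filter")
    if fusion_cands:
        passing, tally, verdicts = filter_candidates(
            fusion_cands,
            min_locus_cov=cfg.get("fusion_min_locus_cov", 0.05),
            min_total_cov=cfg.get("fusion_min_total_cov", 0.95),
            min_distance=cfg.get("fusion_min_distance", 10_000),
            min_junction_reads=cfg.get("fusion_min_junction_reads", 1),
        )
        verdicts_to_frame(verdicts).to_csv(out / "fusion_verdicts.tsv", sep="\t")
        report["n_fusion_pass"] = len(passing)
        report.update({f"fusion_fail_{k}": v for k, v in tally.items()})

    # ---- expression dynamics ---------------------------------------------
    log.info("stage dynamics: correlation + DE + clustering")
    corr = sample_correlation(expr)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t")
    stages = expr.stages
    de_counts = []
    for a, b in zip(stages, stages[1:]):
        cmp_res = differential_genes(
            expr, a, b,
            lfc_threshold=cfg.get("lfc", 1.0),
            fdr_threshold=cfg.get("fdr", 0.01),
        )
        cmp_res.table.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
        de_counts.append({"pair": f"{a}-{b}", "n_up": cmp_res.n_up, "n_down": cmp_res.n_down})
    pd.DataFrame(de_counts).to_csv(out / "de_counts.tsv", sep="\t", index=False)
    expr_clusters = cluster_expression(expr, k=cfg.get("k_expr", 10), seed=seed)
    expr_clusters.labels.rename_axis("gene_id").to_frame().to_csv(
        out / "expression_clusters.tsv", sep="\t"
    )
    report["n_expr_clustered"] = len(expr_clusters.labels)

    # ---- report -----------------------------------------------------------
    rep = pd.Series(report, name="value").rename_axis("field")
    rep.to_frame().to_csv(out / "report.tsv", sep="\t")
    with open(out / "report.txt", "w") as fh:
        fh.write("splicedyn run report\n")
        for k, v in report.items():
            fh.write(f"{k}: {v}\n")
    log.info("pipeline complete: %d report fields", len(report))
    return report
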