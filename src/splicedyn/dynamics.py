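"""Stage-level expression structure.

Sample-sample Pearson correlation on log2(FPKM + 1), two-sample-t
differential expression between stages with Benjamini-Hochberg FDR control, and temporal
k-means clustering of z-scored stage-mean expression profiles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .irt import ClusterAssignment, kmeans_cluster
from .models import ExpressionMatrix, ValidationError

VARIANCE_FLOOR = 1e-3


@dataclass
class StageComparison:
    stage_a: str
    stage_b: str
    table: pd.DataFrame  # gene x (log2fc, p, fdr, de, direction)
    n_up: int
    n_down: int


def sample_correlation(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between samples on log2(FPKM + 1).

    Zero-variance samples yield NaN rows/columns (their correlation is
    undefined); the diagonal is 1 for well-defined samples.
    """
    if expr.values.shape[1] < 2:
        raise ValidationError("correlation needs at least two samples")
    logged = np.log2(expr.values + 1.0)
    corr = logged.corr(method="pearson")
    valid = logged.std() > 0
    for s in corr.index[valid]:
        corr.loc[s, s] = 1.0
    return corr


def _pooled_t(a: np.ndarray, b: np.ndarray, var_floor: float = VARIANCE_FLOOR):
    """Vectorized two-sample t-test per row, pooled variance, with a floor.

    Replicates within each stage share one noise model, so the pooled
    estimator (df = na + nb - 2) is used rather than Welch's: with three
    replicates per stage Welch's degrees of freedom collapse toward 2
    whenever one stage's variance estimate dominates by chance, destroying
    power at stringent FDR thresholds. The floor keeps genes with zero
    within-stage variance testable instead of producing infinite statistics.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    pooled = np.maximum(((na - 1) * va + (nb - 1) * vb) / df, var_floor)
    t = (mb - ma) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def differential_genes(
    expr: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
) -> StageComparison:
    """Differential genes between two stages (b vs a).

    Gene expression is the per-sample sum of its transcripts' FPKM. The test
    is a pooled-variance two-sample t on log2(FPKM + 1) across replicates; p-values are
    Benjamini-Hochberg adjusted across genes; a gene is differential iff
    |log2 fold change| (of stage-mean FPKM + 1) exceeds ``lfc_threshold`` and
    FDR < ``fdr_threshold``.
    """
    genes = expr.gene_values()
    cols_a = expr.stage_samples(stage_a)
    cols_b = expr.stage_samples(stage_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("differential testing needs >= 2 replicates per stage")
    logged = np.log2(genes + 1.0)
    _, p = _pooled_t(logged[cols_a].to_numpy(), logged[cols_b].to_numpy())
    lfc = np.log2(genes[cols_b].mean(axis=1) + 1.0) - np.log2(
        genes[cols_a].mean(axis=1) + 1.0
    )
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    de = (np.abs(lfc) > lfc_threshold) & (fdr < fdr_threshold)
    direction = np.where(lfc > 0, "up", "down")
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "de": de,
            "direction": direction,
        },
        index=genes.index,
    )
    n_up = int((de & (lfc > 0)).sum())
    n_down = int((de & (lfc < 0)).sum())
    return StageComparison(
        stage_a=stage_a, stage_b=stage_b, table=table, n_up=n_up, n_down=n_down
    )


def cluster_expression(
    expr: ExpressionMatrix,
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
    min_fpkm: float = 0.1,
) -> ClusterAssignment:
    """K-means over expressed genes' temporal profiles.

    Genes with max stage-mean FPKM >= ``min_fpkm`` are "expressed"; their
    stage-mean log2(FPKM + 1) profiles are z-scored per gene before
    clustering so the partition reflects trajectory shape, not level.
    Constant-profile genes (zero variance) are excluded.
    """
    gene_stage = expr.gene_values().T.groupby(expr.sample_meta["stage"]).mean().T
    gene_stage = gene_stage[[s for s in expr.stages]]
    expressed = gene_stage.max(axis=1) >= min_fpkm
    logged = np.log2(gene_stage.loc[expressed] + 1.0)
    sd = logged.std(axis=1, ddof=0)
    variable = sd > 0
    z = logged.loc[variable].sub(logged.loc[variable].mean(axis=1), axis=0).div(
        sd[variable], axis=0
    )
    return kmeans_cluster(z, k=k, seed=seed, n_restarts=n_restarts)
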