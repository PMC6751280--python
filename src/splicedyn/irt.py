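"""Per-gene IR-containing-transcript (IRT) values and temporal clustering.

The IRT value of a gene at a stage is the ratio of the summed replicate-mean
FPKM of its IR-containing transcripts to the summed replicate-mean FPKM of
all its transcripts — a [0, 1] measure of how much of the gene's output is
intron-retaining. Temporal profiles over the eight stages are clustered with
k-means (k = 9 for IRT profiles, k = 10 for expression profiles).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .models import ExpressionMatrix, ValidationError


@dataclass
class IRTProfile:
    """Gene x stage IRT matrix plus per-gene eligibility.

    A gene is ineligible when any stage has zero total FPKM (the ratio is
    undefined there); ineligible genes carry NaN at the undefined stages.
    """

    values: pd.DataFrame  # genes x stages, NaN where undefined
    eligible: pd.Series  # gene -> bool


@dataclass
class ClusterAssignment:
    labels: pd.Series  # item -> cluster label in 1..k
    centroids: np.ndarray  # (k, n_features)
    k: int
    seed: int
    inertia: float


def irt_value(
    gene_id: str,
    stage: str,
    expr: ExpressionMatrix,
    ir_ids: set[str],
) -> float:
    """IRT value of one gene at one stage; NaN when the gene is silent there."""
    tids = expr.transcripts_of(gene_id)
    if not tids:
        raise KeyError(f"gene {gene_id!r} absent from expression matrix")
    foreign = {
        t for t in ir_ids if t in expr.tx2gene.index and expr.tx2gene[t] != gene_id
    }
    if foreign:
        raise ValidationError(
            f"IR transcripts {sorted(foreign)[:3]} do not belong to gene {gene_id!r}"
        )
    samples = expr.stage_samples(stage)
    means = expr.values.loc[tids, samples].mean(axis=1)
    denom = means.sum()
    if denom == 0:
        return float("nan")
    num = means[[t for t in tids if t in ir_ids]].sum()
    return float(num / denom)


def irt_profiles(expr: ExpressionMatrix, ir_ids: set[str]) -> IRTProfile:
    """IRT profiles for every gene with at least one transcript in ``expr``.

    Only genes owning at least one IR-containing transcript are eligible for
    clustering by default; genes silent at any stage are ineligible.
    """
    foreign = ir_ids - set(expr.tx2gene.index)
    if foreign:
        raise ValidationError(
            f"IR transcript ids absent from expression matrix: {sorted(foreign)[:5]}"
        )
    stage_means = expr.stage_means()
    is_ir = stage_means.index.isin(ir_ids)
    gene = expr.tx2gene
    denom = stage_means.groupby(gene).sum()
    num = stage_means[is_ir].groupby(gene[is_ir]).sum().reindex(denom.index).fillna(0.0)
    values = num / denom.where(denom > 0)
    eligible = values.notna().all(axis=1)
    return IRTProfile(values=values, eligible=eligible)


def kmeans_cluster(
    profiles: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ seeding, best inertia over restarts.

    Deterministic for a fixed seed. Labels are reported 1..k.
    """
    if isinstance(profiles, pd.DataFrame):
        index = profiles.index
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        index = pd.RangeIndex(len(X))
    if len(X) < k:
        raise ValidationError(f"cannot form {k} clusters from {len(X)} items")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    return ClusterAssignment(
        labels=pd.Series(km.labels_ + 1, index=index, name="cluster"),
        centroids=km.cluster_centers_,
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def cluster_irt_profiles(
    profile: IRTProfile, k: int = 9, seed: int = 0, n_restarts: int = 10
) -> ClusterAssignment:
    """Cluster eligible genes' IRT trajectories (defaults to nine clusters)."""
    eligible = profile.values.loc[profile.eligible]
    return kmeans_cluster(eligible, k=k, seed=seed, n_restarts=n_restarts)
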