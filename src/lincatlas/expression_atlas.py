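"""Stage-specificity classification, profile clustering and neighbor-gene
analyses on the nine-stage RPKM atlas.

A gene counts as "expressed" in a stage when its RPKM exceeds a small floor
(default 0.1).  A gene expressed in exactly one stage is stage-exclusive; one
expressed in every stage whose highest/lowest ratio stays within tenfold is
ubiquitous; anything else expressed somewhere is broad/variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import ExpressionMatrix, GeneModel, ValidationError
from .feature_stats import pearson_r

__all__ = [
    "SpecificityCall",
    "ProfileClustering",
    "NeighborRecord",
    "log_transform",
    "classify_specificity",
    "specificity_counts",
    "calibrate_expressed_threshold",
    "profile_normalize",
    "cluster_profiles",
    "find_neighbors",
    "neighbor_correlations",
    "clamp_log2fc",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_EXPRESSED_THRESHOLD",
    "DEFAULT_FOLD_LIMIT",
    "DEFAULT_NEIGHBOR_WINDOW",
]

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_EXPRESSED_THRESHOLD = 0.1
DEFAULT_FOLD_LIMIT = 10.0
DEFAULT_NEIGHBOR_WINDOW = 100_000


@dataclass(frozen=True)
class SpecificityCall:
    gene_id: str
    category: str  # "exclusive" | "ubiquitous" | "broad_variable" | "not_expressed"
    stage: str | None  # the single stage for exclusive calls
    n_stages_expressed: int
    max_min_ratio: float | None  # defined only when expressed in all stages


@dataclass
class ProfileClustering:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray  # (k, n_stages - 1)
    reference_stage: str
    stage_order: list[str]  # non-reference stages, centroid column order
    inertia: float


@dataclass
class NeighborRecord:
    linc_id: str
    neighbor_id: str
    signed_distance: int  # bp between spans; negative = lower coordinates
    rank: int  # ..., -2, -1, +1, +2, ...
    pearson_r: float | None = None
    r_defined: bool = True
    log2_fc: float | None = None


def log_transform(
    matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """log2(RPKM + pseudocount), the expression scale used throughout."""
    return np.log2(matrix.values + pseudocount)


def classify_specificity(
    matrix: ExpressionMatrix,
    expressed_threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
    fold_limit: float = DEFAULT_FOLD_LIMIT,
) -> list[SpecificityCall]:
    """Assign each gene to exclusive / ubiquitous / broad_variable / not_expressed.

    Expression calls use raw RPKM > expressed_threshold; the max/min ratio for
    the ubiquitous test is computed on raw RPKM and only defined for genes
    expressed in every stage.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("specificity classification needs >= 2 stages")
    calls = []
    stages = matrix.stage_labels
    vals = matrix.values.to_numpy()
    for gid, row in zip(matrix.gene_ids, vals):
        expressed = row > expressed_threshold
        n_exp = int(expressed.sum())
        ratio = None
        if n_exp == 0:
            cat, stage = "not_expressed", None
        elif n_exp == 1:
            cat, stage = "exclusive", stages[int(np.argmax(expressed))]
        elif n_exp == len(stages):
            ratio = float(row.max() / row.min())
            cat = "ubiquitous" if ratio <= fold_limit else "broad_variable"
            stage = None
        else:
            cat, stage = "broad_variable", None
        calls.append(SpecificityCall(gid, cat, stage, n_exp, ratio))
    return calls


def specificity_counts(calls: Sequence[SpecificityCall]) -> dict[str, int]:
    counts = {"exclusive": 0, "ubiquitous": 0, "broad_variable": 0, "not_expressed": 0}
    for c in calls:
        counts[c.category] += 1
    return counts


def calibrate_expressed_threshold(
    matrix: ExpressionMatrix,
    target_ubiquitous: int,
    target_exclusive: int,
    fold_limit: float = DEFAULT_FOLD_LIMIT,
    grid: Sequence[float] | None = None,
) -> float:
    """Smallest threshold in [0, 1] whose classification reproduces the
    target ubiquitous and stage-exclusive counts.

    Raises ValidationError when no grid point matches.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.01), 4)
    for t in grid:
        counts = specificity_counts(classify_specificity(matrix, float(t), fold_limit))
        if counts["ubiquitous"] == target_ubiquitous and counts["exclusive"] == target_exclusive:
            return float(t)
    raise ValidationError(
        f"no threshold in [0, 1] yields {target_ubiquitous} ubiquitous and "
        f"{target_exclusive} exclusive genes"
    )


def profile_normalize(
    matrix: ExpressionMatrix,
    reference_stage: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2 ratio of each non-reference stage to the reference stage.

    Constant-expression genes map to the zero vector; the transform is
    invariant under rescaling a gene's whole profile.
    """
    if reference_stage not in matrix.stage_labels:
        raise KeyError(f"reference stage {reference_stage!r} not in matrix")
    logged = log_transform(matrix, pseudocount)
    ref = logged[reference_stage]
    others = [s for s in matrix.stage_labels if s != reference_stage]
    return logged[others].sub(ref, axis=0)


def cluster_profiles(
    matrix: ExpressionMatrix,
    k: int = 10,
    min_rpkm: float = 1.0,
    seed: int = 0,
    reference_stage: str = "embryo",
    max_iter: int = 300,
) -> ProfileClustering:
    """K-means clustering of reference-normalized expression profiles.

    Genes whose maximum stage RPKM does not exceed ``min_rpkm`` are dropped
    before normalization.  A single k-means++ run with a fixed seed makes the
    result deterministic.
    """
    keep = matrix.values.max(axis=1) > min_rpkm
    kept = ExpressionMatrix(matrix.values.loc[keep])
    if kept.shape[0] < k:
        raise ValidationError(
            f"only {kept.shape[0]} genes pass the RPKM > {min_rpkm} filter; need >= k={k}"
        )
    vectors = profile_normalize(kept, reference_stage)
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=seed)
    labels = km.fit_predict(vectors.to_numpy())
    return ProfileClustering(
        k=k,
        assignments=dict(zip(vectors.index, (int(l) for l in labels))),
        centroids=km.cluster_centers_,
        reference_stage=reference_stage,
        stage_order=list(vectors.columns),
        inertia=float(km.inertia_),
    )


def find_neighbors(
    linc: GeneModel,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> list[NeighborRecord]:
    """Genes whose span overlaps the lincRNA's span extended by ``window`` bp.

    Signed distance is the gap between spans (0 when they overlap), negative
    for neighbors at lower chromosome coordinates.  Ranks run outward from the
    lincRNA on each side (-1 is the nearest lower-coordinate neighbor, +1 the
    nearest higher-coordinate one); overlapping genes take the side of their
    midpoint.
    """
    lo, hi = linc.span.start - window, linc.span.end + window
    upstream, downstream = [], []
    for g in genes:
        if g.gene_id == linc.gene_id or g.span.chrom != linc.span.chrom:
            continue
        if g.span.end <= lo or g.span.start >= hi:
            continue
        if g.span.end <= linc.span.start:
            dist = -(linc.span.start - g.span.end)
            upstream.append((g, dist))
        elif g.span.start >= linc.span.end:
            dist = g.span.start - linc.span.end
            downstream.append((g, dist))
        else:  # overlap
            g_mid = (g.span.start + g.span.end) / 2
            l_mid = (linc.span.start + linc.span.end) / 2
            (upstream if g_mid < l_mid else downstream).append((g, 0))
    upstream.sort(key=lambda t: (-t[1], t[0].gene_id))  # nearest first
    downstream.sort(key=lambda t: (t[1], t[0].gene_id))
    records = []
    for i, (g, dist) in enumerate(upstream, start=1):
        records.append(NeighborRecord(linc.gene_id, g.gene_id, dist, -i))
    for i, (g, dist) in enumerate(downstream, start=1):
        records.append(NeighborRecord(linc.gene_id, g.gene_id, dist, +i))
    records.sort(key=lambda r: r.rank)
    return records


def neighbor_correlations(
    records: Sequence[NeighborRecord],
    matrix: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[NeighborRecord]:
    """Fill Pearson r (on log2(RPKM + pseudocount) across stages) into records.

    Pairs with a constant vector are flagged undefined rather than dropped.
    """
    logged = log_transform(matrix, pseudocount)
    out = []
    for rec in records:
        for gid in (rec.linc_id, rec.neighbor_id):
            if gid not in logged.index:
                raise KeyError(f"gene {gid!r} missing from expression matrix")
        r = pearson_r(logged.loc[rec.linc_id], logged.loc[rec.neighbor_id])
        defined = not math.isnan(r)
        out.append(
            NeighborRecord(rec.linc_id, rec.neighbor_id, rec.signed_distance,
                           rec.rank, r if defined else None, defined, rec.log2_fc)
        )
    return out


def clamp_log2fc(
    ratios: Sequence[float] | pd.Series, low: float = -5.0, high: float = 5.0
) -> np.ndarray:
    """log2 of mutant/wild-type ratios, clamped into [low, high]."""
    arr = np.asarray(ratios, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("fold-change ratios must be positive")
    return np.clip(np.log2(arr), low, high)
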