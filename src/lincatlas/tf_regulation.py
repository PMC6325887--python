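"""Assignment of TF ChIP-seq peaks to lincRNA promoter windows and the
downstream regulator-count and shared-target analyses.

The promoter window spans 1 kb upstream to 200 bp downstream of the TSS in
transcription orientation; a TF regulates a gene in a stage when any of its
peaks overlaps that window by at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import GeneModel, Interval, Peak, ValidationError
from .feature_stats import TestResult, rank_sum_test

__all__ = [
    "PromoterWindow",
    "RegulationMap",
    "promoter_window",
    "assign_peaks",
    "regulators_per_gene",
    "compare_groups",
    "shared_targets",
    "relative_enrichment",
    "DEFAULT_UPSTREAM",
    "DEFAULT_DOWNSTREAM",
]

DEFAULT_UPSTREAM = 1000
DEFAULT_DOWNSTREAM = 200


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    region: Interval


@dataclass
class RegulationMap:
    """Per-stage TF -> regulated-gene sets with best peak scores."""

    stage: str
    targets: dict[str, set[str]] = field(default_factory=dict)  # TF -> gene ids
    best_score: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, tf: str, gene_id: str, score: float) -> None:
        self.targets.setdefault(tf, set()).add(gene_id)
        key = (tf, gene_id)
        if score > self.best_score.get(key, float("-inf")):
            self.best_score[key] = score

    @property
    def tf_names(self) -> list[str]:
        return sorted(self.targets)

    def regulated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return out


def promoter_window(
    model: GeneModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    chrom_length: int | None = None,
) -> PromoterWindow:
    """[TSS - upstream, TSS + downstream) in transcription orientation.

    On the minus strand "upstream" extends toward larger coordinates.  The
    window is truncated at chromosome boundaries and always contains the TSS.
    """
    t = model.tss
    if model.span.strand == "-":
        start, end = t - (downstream - 1), t + upstream + 1
    else:
        start, end = t - upstream, t + downstream
    start = max(0, start)
    if chrom_length is not None:
        if chrom_length < model.span.end:
            raise ValidationError(
                f"{model.gene_id}: chromosome length {chrom_length} shorter than gene span"
            )
        end = min(chrom_length, end)
    return PromoterWindow(model.gene_id, Interval(model.span.chrom, start, end, model.span.strand))


def assign_peaks(
    peaks: Sequence[Peak],
    windows: Sequence[PromoterWindow],
    overlap_rule: str = "any",
) -> dict[str, RegulationMap]:
    """Stage-keyed regulation maps from peak/promoter-window overlap.

    ``overlap_rule`` is "any" (>= 1 bp of overlap, default) or "summit"
    (the peak midpoint must fall inside the window).
    """
    if overlap_rule not in {"any", "summit"}:
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    maps: dict[str, RegulationMap] = {}
    for p in peaks:
        rmap = maps.setdefault(p.stage, RegulationMap(p.stage))
        for w in windows:
            if overlap_rule == "any":
                hit = p.region.overlaps(w.region)
            else:
                summit = (p.region.start + p.region.end) // 2
                hit = (
                    p.region.chrom == w.region.chrom
                    and w.region.start <= summit < w.region.end
                )
            if hit:
                rmap.add(p.tf_name, w.gene_id, p.score)
    return maps


def regulators_per_gene(
    rmap: RegulationMap, gene_ids: Sequence[str] | None = None
) -> dict[str, int]:
    """Distinct-TF counts per gene; genes with no regulator get 0.

    ``gene_ids`` fixes the universe of genes reported (defaults to the genes
    present in the map).
    """
    counts: dict[str, int] = {g: 0 for g in (gene_ids or sorted(rmap.regulated_genes()))}
    for tf, genes in rmap.targets.items():
        for g in genes:
            if gene_ids is None or g in counts:
                counts[g] = counts.get(g, 0) + 1
    return counts


def compare_groups(
    counts: Mapping[str, int],
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
) -> TestResult:
    """Rank-sum comparison of regulator counts between two gene groups."""
    a = [counts.get(g, 0) for g in group_a_ids]
    b = [counts.get(g, 0) for g in group_b_ids]
    return rank_sum_test(a, b)


def shared_targets(
    targets_a: set[str], targets_b: set[str]
) -> dict[str, set[str] | int]:
    """Set algebra on two TFs' target sets, with sizes."""
    inter = targets_a & targets_b
    a_only = targets_a - targets_b
    b_only = targets_b - targets_a
    return {
        "shared": inter,
        "a_only": a_only,
        "b_only": b_only,
        "n_shared": len(inter),
        "n_a_only": len(a_only),
        "n_b_only": len(b_only),
    }


def relative_enrichment(rmap: RegulationMap) -> dict[tuple[str, str], float]:
    """Per-(TF, gene) best peak score normalized to that TF's maximum, in (0, 1]."""
    by_tf_max: dict[str, float] = {}
    for (tf, _gene), score in rmap.best_score.items():
        if score <= 0:
            raise ValidationError("relative enrichment requires positive peak scores")
        by_tf_max[tf] = max(by_tf_max.get(tf, 0.0), score)
    return {
        (tf, gene): score / by_tf_max[tf]
        for (tf, gene), score in rmap.best_score.items()
    }
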