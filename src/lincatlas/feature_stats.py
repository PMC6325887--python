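"""Genomic-feature summaries (length, exon number, conservation) and the
statistical tests applied to them.

Lengths are spliced (exonic) by default; conservation is averaged over the
annotated bases of the spliced transcript, with "base coverage" the fraction
of transcript bases that carry a score at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import GeneModel, ScoreTrack, ValidationError

__all__ = [
    "ConservationSummary",
    "TestResult",
    "conservation_summary",
    "rank_sum_test",
    "pearson_r",
    "chi_square_test",
    "sample_random_genes",
    "compare_feature",
    "extract_feature",
    "EXACT_RANKSUM_MAX_N",
]

#: combined sample size at or below which the tie-free rank-sum p is exact
EXACT_RANKSUM_MAX_N = 16


@dataclass(frozen=True)
class ConservationSummary:
    gene_id: str
    mean_score: float | None  # None when no base is annotated
    base_coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_coverage <= 1.0):
            raise ValidationError("base_coverage outside [0, 1]")
        if self.mean_score is not None and not (0.0 <= self.mean_score <= 1.0):
            raise ValidationError("mean_score outside [0, 1]")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    two_sided_p: float
    method: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.two_sided_p <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


def conservation_summary(track: ScoreTrack, model: GeneModel) -> ConservationSummary:
    """Mean conservation over the scored bases of the spliced transcript.

    Unannotated bases enter the coverage denominator but not the mean.
    """
    scores = []
    total = 0
    for ex in model.exons:
        for pos in range(ex.start, ex.end):
            total += 1
            s = track.get(ex.chrom, pos)
            if s is not None:
                scores.append(s)
    coverage = len(scores) / total if total else 0.0
    mean = float(np.mean(scores)) if scores else None
    return ConservationSummary(model.gene_id, mean, coverage)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of the U null distribution when the combined
    sample size is <= 16 and there are no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank_sum_test requires two non-empty groups")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= EXACT_RANKSUM_MAX_N:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal-approx"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method, a.size, b.size)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("pearson_r requires equal-length vectors")
    if x.size < 3:
        raise ValidationError("pearson_r requires length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def chi_square_test(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValidationError("chi_square_test expects a 2-D table")
    expected = stats.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise ValidationError("chi-square test undefined with zero expected counts")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(p), f"chi-square(df={dof})",
                      int(table.shape[0]), int(table.shape[1]))


def sample_random_genes(
    models: Sequence[GeneModel], n: int, seed: int
) -> list[GeneModel]:
    """Uniform sample of ``n`` models without replacement, reproducible by seed."""
    if n > len(models):
        raise ValidationError(f"cannot sample {n} from {len(models)} genes")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(models), size=n, replace=False)
    return [models[i] for i in idx]


_FEATURES = ("length", "exon_count", "mean_conservation", "base_coverage")


def extract_feature(
    models: Sequence[GeneModel],
    feature: str,
    track: ScoreTrack | None = None,
    length_mode: str = "spliced",
) -> list[float]:
    """Per-gene feature vector.

    length_mode is "spliced" (sum of exon lengths, default) or "genomic"
    (span length).  Conservation features need ``track``; genes with zero
    base coverage contribute no mean-conservation value.
    """
    if feature not in _FEATURES:
        raise ValueError(f"unknown feature {feature!r}; choose from {_FEATURES}")
    if feature == "length":
        if length_mode == "spliced":
            return [float(m.spliced_length) for m in models]
        if length_mode == "genomic":
            return [float(len(m.span)) for m in models]
        raise ValueError(f"unknown length_mode {length_mode!r}")
    if feature == "exon_count":
        return [float(m.exon_count) for m in models]
    if track is None:
        raise ValidationError(f"feature {feature!r} requires a conservation track")
    out = []
    for m in models:
        s = conservation_summary(track, m)
        if feature == "base_coverage":
            out.append(s.base_coverage)
        elif s.mean_score is not None:
            out.append(s.mean_score)
    return out


def compare_feature(
    models_a: Sequence[GeneModel],
    models_b: Sequence[GeneModel],
    feature: str,
    track: ScoreTrack | None = None,
    length_mode: str = "spliced",
) -> tuple[TestResult, dict[str, float], dict[str, float]]:
    """Rank-sum comparison of one feature between two gene groups.

    Returns the test result plus per-group median/mean summaries.
    """
    va = extract_feature(models_a, feature, track, length_mode)
    vb = extract_feature(models_b, feature, track, length_mode)
    result = rank_sum_test(va, vb)

    def _summ(v: list[float]) -> dict[str, float]:
        return {
            "n": float(len(v)),
            "median": float(np.median(v)) if v else math.nan,
            "mean": float(np.mean(v)) if v else math.nan,
        }

    return result, _summ(va), _summ(vb)
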