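"""lincRNA-miRNA ceRNA network inference.

A lincRNA is linked to a miRNA when its spliced sense transcript carries at
least two exact matches to the miRNA's seed site (the reverse complement of
miRNA nucleotides 2-8) and the two expression profiles are anti-correlated
(Pearson r < -0.1) across the nine developmental stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ValidationError, reverse_complement
from .expression_atlas import DEFAULT_EXPRESSED_THRESHOLD, DEFAULT_PSEUDOCOUNT, log_transform
from .feature_stats import pearson_r

__all__ = [
    "SeedSite",
    "CeRNAEdge",
    "seed_site",
    "count_matches",
    "build_network",
    "network_summary",
    "DEFAULT_MIN_MATCHES",
    "DEFAULT_R_MAX",
]

DEFAULT_MIN_MATCHES = 2
DEFAULT_R_MAX = -0.1


@dataclass(frozen=True)
class SeedSite:
    """The 7-nt DNA target site complementary to a miRNA seed (nt 2-8)."""

    mirna_id: str
    site_sequence: str

    def __post_init__(self) -> None:
        if not self.site_sequence:
            raise ValidationError("empty seed site")
        if set(self.site_sequence) - set("ACGT"):
            raise ValidationError("seed site must be DNA (ACGT)")


@dataclass(frozen=True)
class CeRNAEdge:
    linc_id: str
    mirna_id: str
    match_count: int
    pearson_r: float
    match_positions: tuple[int, ...]


def seed_site(
    mirna_sequence: str,
    mirna_id: str = "",
    seed_start: int = 2,
    seed_len: int = 7,
) -> SeedSite:
    """Target site for a miRNA: reverse complement of its seed region.

    ``seed_start`` is 1-based along the mature miRNA (default nucleotides
    2 .. 2+7-1 = 2-8, the canonical seed).
    """
    seq = mirna_sequence.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValidationError(f"{mirna_id or 'miRNA'}: non-ACGU/T character in sequence")
    if len(seq) < seed_start - 1 + seed_len:
        raise ValidationError(
            f"{mirna_id or 'miRNA'}: sequence length {len(seq)} too short for a "
            f"{seed_len}-mer seed starting at position {seed_start}"
        )
    seed = seq[seed_start - 1: seed_start - 1 + seed_len]
    return SeedSite(mirna_id, reverse_complement(seed))


def count_matches(transcript: str, site: SeedSite) -> tuple[int, tuple[int, ...]]:
    """All (possibly overlapping) occurrences of the site in the sense transcript."""
    seq = transcript.upper().replace("U", "T")
    if set(seq) - set("ACGTN"):
        raise ValidationError("transcript alphabet must be ACGTN")
    positions = []
    start = 0
    while True:
        pos = seq.find(site.site_sequence, start)
        if pos == -1:
            break
        positions.append(pos)
        start = pos + 1
    return len(positions), tuple(positions)


def _expressed_anywhere(row: np.ndarray, threshold: float) -> bool:
    return bool((row > threshold).any())


def build_network(
    lincs: Mapping[str, str],
    mirnas: Mapping[str, str],
    expr_linc: ExpressionMatrix,
    expr_mir: ExpressionMatrix,
    min_matches: int = DEFAULT_MIN_MATCHES,
    r_max: float = DEFAULT_R_MAX,
    seed_start: int = 2,
    seed_len: int = 7,
    expressed_threshold: float | None = DEFAULT_EXPRESSED_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[CeRNAEdge]:
    """Infer ceRNA edges between lincRNA transcripts and miRNAs.

    ``lincs`` maps lincRNA id -> spliced sense transcript (DNA); ``mirnas``
    maps miRNA id -> mature sequence (RNA or DNA).  An edge requires
    ``match_count >= min_matches`` seed sites and Pearson r < ``r_max`` on
    log2(RPKM + pseudocount) stage vectors.  Pairs where either partner never
    exceeds ``expressed_threshold`` (set it to None to disable), or whose
    correlation is undefined, emit no edge.
    """
    if expr_linc.stage_labels != expr_mir.stage_labels:
        raise ValidationError("lincRNA and miRNA matrices must share identical stage labels")
    sites = {mid: seed_site(seq, mid, seed_start, seed_len) for mid, seq in mirnas.items()}
    log_linc = log_transform(expr_linc, pseudocount)
    log_mir = log_transform(expr_mir, pseudocount)
    edges = []
    for lid in sorted(lincs):
        if lid not in expr_linc.values.index:
            continue
        raw_l = expr_linc.values.loc[lid].to_numpy()
        if expressed_threshold is not None and not _expressed_anywhere(raw_l, expressed_threshold):
            continue
        transcript = lincs[lid]
        for mid in sorted(sites):
            if mid not in expr_mir.values.index:
                continue
            count, positions = count_matches(transcript, sites[mid])
            if count < min_matches:
                continue
            raw_m = expr_mir.values.loc[mid].to_numpy()
            if expressed_threshold is not None and not _expressed_anywhere(raw_m, expressed_threshold):
                continue
            r = pearson_r(log_linc.loc[lid], log_mir.loc[mid])
            if math.isnan(r):
                continue
            if r < r_max:
                edges.append(CeRNAEdge(lid, mid, count, r, positions))
    return edges


def network_summary(edges: list[CeRNAEdge]) -> tuple[pd.DataFrame, list[str]]:
    """Per-node degree table plus the maximum-degree lincRNA(s).

    The degree table has columns (node, kind, degree), sorted by decreasing
    degree then node id; ties for the top lincRNA are all reported.
    """
    degrees: dict[tuple[str, str], int] = {}
    for e in edges:
        degrees[(e.linc_id, "lincRNA")] = degrees.get((e.linc_id, "lincRNA"), 0) + 1
        degrees[(e.mirna_id, "miRNA")] = degrees.get((e.mirna_id, "miRNA"), 0) + 1
    table = pd.DataFrame(
        [(node, kind, deg) for (node, kind), deg in degrees.items()],
        columns=["node", "kind", "degree"],
    ).sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    linc_rows = table[table["kind"] == "lincRNA"]
    if linc_rows.empty:
        return table, []
    top = int(linc_rows["degree"].max())
    hubs = sorted(linc_rows.loc[linc_rows["degree"] == top, "node"])
    return table, hubs
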