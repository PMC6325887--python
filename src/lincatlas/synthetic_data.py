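"""Synthetic genomes, annotations, expression atlases, miRNAs and ChIP-seq
peaks with planted, manifest-recorded structure.

Every generator is a pure function of (seed, parameters).  The planted
structures mirror the shapes the pipeline is meant to detect: stage-exclusive
and ubiquitous-within-tenfold expression, separated temporal profiles,
lincRNA-miRNA pairs with a prescribed number of seed sites and a target
anti-correlation, and TF peaks inside or clear of promoter windows.  The
``paper_shape`` preset is a synthetic stand-in for the study's deposited
expression table: 170 lincRNAs across nine stages with 12 ubiquitous and 8
named stage-exclusive genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    ExpressionMatrix,
    GeneModel,
    Interval,
    Peak,
    extract_spliced_sequence,
)
from .cerna_net import seed_site
from .expression_atlas import DEFAULT_PSEUDOCOUNT
from .tf_regulation import PromoterWindow

import pandas as pd

__all__ = [
    "GroundTruthManifest",
    "NINE_STAGES",
    "PAPER_EXCLUSIVE",
    "PAPER_UBIQUITOUS_COUNT",
    "make_genome",
    "make_gene_models",
    "make_expression",
    "make_profile_matrix",
    "plant_cerna_pairs",
    "make_peaks",
    "paper_shape_expression",
    "simulate_paper_shape",
]

#: the nine profiled stages and populations, in atlas column order
NINE_STAGES = ["embryo", "L1", "L2", "L3", "L4", "YA", "dauer", "starvation", "male"]

#: the eight stage-exclusive lincRNAs and their stages (synthetic stand-in
#: plants exactly these)
PAPER_EXCLUSIVE: dict[str, str] = {
    "linc-28": "embryo",
    "linc-131": "embryo",
    "linc-155": "embryo",
    "linc-148": "L2",
    "linc-52": "YA",
    "linc-141": "dauer",
    "linc-168": "dauer",
    "linc-23": "male",
}

PAPER_UBIQUITOUS_COUNT = 12


class CapacityError(RuntimeError):
    """Non-overlapping gene placement failed; use longer chromosomes."""


@dataclass
class GroundTruthManifest:
    """Record of every planted structure, for closed-loop recovery tests."""

    seed: int
    params: dict = field(default_factory=dict)
    specificity: dict = field(default_factory=dict)  # gene -> {category, stage}
    profiles: dict = field(default_factory=dict)  # gene -> planted shape id
    neighbor_pairs: list = field(default_factory=list)
    cerna_pairs: list = field(default_factory=list)  # {linc, mirna, positions, target_r, achieved_r}
    tf_regulations: dict = field(default_factory=dict)  # stage -> [[tf, gene], ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


# --------------------------------------------------------------------------
# Genome and gene models
# --------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHROM_NAMES = ["chrI", "chrII", "chrIII", "chrIV", "chrV", "chrX"]


def make_genome(seed: int, n_chrom: int = 2, chrom_length: int = 3_000_000) -> dict[str, str]:
    """Uniform-ACGT chromosomes, deterministic per seed."""
    rng = np.random.default_rng(seed)
    genome = {}
    for i in range(n_chrom):
        name = _CHROM_NAMES[i] if i < len(_CHROM_NAMES) else f"chr{i + 1}"
        idx = rng.integers(0, 4, size=chrom_length)
        genome[name] = _BASES[idx].tobytes().decode("ascii")
    return genome


def _split_lengths(rng: np.random.Generator, total: int, n: int, minimum: int = 30) -> list[int]:
    """Partition ``total`` into ``n`` parts, each >= minimum."""
    if total < n * minimum:
        raise ValueError("total too small to split")
    extra = total - n * minimum
    cuts = np.sort(rng.integers(0, extra + 1, size=n - 1)) if n > 1 else np.array([], dtype=int)
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [minimum + int(p) for p in parts]


def make_gene_models(
    seed: int,
    genome: Mapping[str, str],
    n_linc: int = 170,
    n_mrna: int = 1000,
    linc_len_median: float = 600.0,
    linc_len_sigma: float = 0.5,
    linc_exons: tuple[int, int] = (1, 3),
    mrna_len_median: float = 2000.0,
    mrna_len_sigma: float = 0.4,
    mrna_exons: tuple[int, int] = (4, 10),
    intron_range: tuple[int, int] = (50, 200),
    max_tries: int = 2000,
) -> list[GeneModel]:
    """Non-overlapping lincRNA and mRNA models on the given genome.

    Spliced lengths are lognormal (lincRNAs shorter with fewer exons than
    mRNAs, as in real annotations); introns are short and uniform; placement
    is by rejection sampling against already-placed spans.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(span_len: int) -> tuple[str, int]:
        for _ in range(max_tries):
            c = chroms[rng.integers(0, len(chroms))]
            if lengths[c] <= span_len:
                continue
            start = int(rng.integers(0, lengths[c] - span_len))
            end = start + span_len
            if all(e <= start or s >= end for s, e in placed[c]):
                placed[c].append((start, end))
                return c, start
        raise CapacityError(
            f"could not place a {span_len} bp gene after {max_tries} tries; "
            "use longer chromosomes or fewer genes"
        )

    specs = [("linc", i + 1) for i in range(n_linc)] + [("mrna", i + 1) for i in range(n_mrna)]
    models = []
    for kind, idx in specs:
        if kind == "linc":
            biotype, gid = "lincRNA", f"linc-{idx}"
            spliced = int(np.clip(rng.lognormal(np.log(linc_len_median), linc_len_sigma), 210, 4000))
            n_ex = int(rng.integers(linc_exons[0], linc_exons[1] + 1))
        else:
            biotype, gid = "mRNA", f"mrna-{idx}"
            spliced = int(np.clip(rng.lognormal(np.log(mrna_len_median), mrna_len_sigma), 500, 8000))
            n_ex = int(rng.integers(mrna_exons[0], mrna_exons[1] + 1))
        exon_lens = _split_lengths(rng, spliced, n_ex)
        intron_lens = [int(rng.integers(*intron_range)) for _ in range(n_ex - 1)]
        span_len = spliced + sum(intron_lens)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = place(span_len)
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append(Interval(chrom, pos, pos + el, strand))
            pos += el + (intron_lens[i] if i < len(intron_lens) else 0)
        span = Interval(chrom, start, start + span_len, strand)
        models.append(GeneModel(gid, biotype, span, tuple(exons)))
    models.sort(key=lambda m: (m.span.chrom, m.span.start, m.gene_id))
    return models


# --------------------------------------------------------------------------
# Expression with planted specificity classes
# --------------------------------------------------------------------------

def make_expression(
    seed: int,
    gene_ids: Sequence[str],
    stages: Sequence[str] = tuple(NINE_STAGES),
    exclusive: Mapping[str, str] | None = None,
    ubiquitous: Sequence[str] | None = None,
    expressed_threshold: float = 0.1,
    fold_limit: float = 10.0,
    manifest: GroundTruthManifest | None = None,
) -> tuple[ExpressionMatrix, GroundTruthManifest]:
    """RPKM matrix with planted specificity classes.

    ``exclusive`` maps gene id -> the single stage it is expressed in;
    ``ubiquitous`` lists genes expressed at every stage with a max/min ratio
    drawn safely inside ``fold_limit``.  All remaining genes are
    broad/variable: expressed in 2..n-1 stages, or in all stages with a ratio
    well above the limit.  Classification at the default thresholds recovers
    the planting exactly, by construction.
    """
    rng = np.random.default_rng(seed)
    exclusive = dict(exclusive or {})
    ubiquitous = list(ubiquitous or [])
    stages = list(stages)
    n = len(stages)
    if manifest is None:
        manifest = GroundTruthManifest(seed=seed)
    rows = np.zeros((len(gene_ids), n))
    for gi, gid in enumerate(gene_ids):
        if gid in exclusive:
            st = exclusive[gid]
            rows[gi, stages.index(st)] = max(1.0, rng.lognormal(np.log(5.0), 0.8))
            manifest.specificity[gid] = {"category": "exclusive", "stage": st}
        elif gid in ubiquitous:
            base = rng.lognormal(np.log(10.0), 0.5) + 1.0
            rho = rng.uniform(2.0, 0.8 * fold_limit)
            u = rng.uniform(0.0, 1.0, size=n)
            rows[gi] = base * rho ** u  # max/min <= rho < fold_limit
            manifest.specificity[gid] = {"category": "ubiquitous", "stage": None}
        else:
            if rng.random() < 0.25:
                # expressed everywhere but far outside the tenfold band
                base = rng.uniform(0.5, 2.0)
                vals = base * rng.lognormal(0.0, 0.4, size=n)
                hot = rng.integers(0, n)
                floor = np.delete(vals, hot).min()  # keep the ratio anchored
                vals[hot] = floor * rng.uniform(1.5 * fold_limit, 5 * fold_limit)
                rows[gi] = vals
            else:
                k = int(rng.integers(2, n))  # 2 .. n-1 stages
                idx = rng.choice(n, size=k, replace=False)
                rows[gi, idx] = np.maximum(0.5, rng.lognormal(np.log(5.0), 1.0, size=k))
            manifest.specificity[gid] = {"category": "broad_variable", "stage": None}
    matrix = ExpressionMatrix(pd.DataFrame(rows, index=list(gene_ids), columns=stages))
    manifest.params.setdefault("expression", {}).update(
        {"expressed_threshold": expressed_threshold, "fold_limit": fold_limit,
         "stages": stages, "n_genes": len(gene_ids)}
    )
    return matrix, manifest


def paper_shape_expression(seed: int) -> tuple[ExpressionMatrix, GroundTruthManifest]:
    """Synthetic stand-in for the study's lincRNA expression table.

    170 lincRNAs x nine stages with the documented structure planted: the 8
    named stage-exclusive genes at their stages, 12 ubiquitous genes
    (including linc-4), the rest broad/variable.  This is generated data, not
    the deposited table; it reproduces the table's class structure, not its
    numeric values.
    """
    gene_ids = [f"linc-{i}" for i in range(1, 171)]
    ubiquitous = ["linc-4"]
    for gid in gene_ids:  # deterministic fill to 12, skipping exclusives
        if len(ubiquitous) == PAPER_UBIQUITOUS_COUNT:
            break
        if gid not in PAPER_EXCLUSIVE and gid not in ubiquitous:
            ubiquitous.append(gid)
    return make_expression(
        seed, gene_ids, NINE_STAGES, exclusive=PAPER_EXCLUSIVE, ubiquitous=ubiquitous
    )


# --------------------------------------------------------------------------
# Planted temporal profiles
# --------------------------------------------------------------------------

#: well-separated log2-fold-change shapes over the five post-embryo stages
DEFAULT_PROFILE_SHAPES: dict[str, list[float]] = {
    "rising": [1.0, 2.0, 3.0, 4.0, 5.0],
    "falling": [-1.0, -2.0, -3.0, -4.0, -5.0],
    "peaked": [2.0, 4.0, 2.0, -2.0, -4.0],
}


def make_profile_matrix(
    seed: int,
    n_per_shape: int = 50,
    shapes: Mapping[str, Sequence[float]] | None = None,
    stages: Sequence[str] | None = None,
    noise_sd: float = 0.3,
    manifest: GroundTruthManifest | None = None,
) -> tuple[ExpressionMatrix, GroundTruthManifest]:
    """Expression matrix whose embryo-normalized profiles fall into planted,
    well-separated shape classes (for clustering recovery tests).
    """
    shapes = dict(shapes or DEFAULT_PROFILE_SHAPES)
    some_shape = next(iter(shapes.values()))
    if stages is None:
        stages = ["embryo"] + [f"t{i + 1}" for i in range(len(some_shape))]
    rng = np.random.default_rng(seed)
    if manifest is None:
        manifest = GroundTruthManifest(seed=seed)
    rows, ids = [], []
    for shape_name, shape in shapes.items():
        for j in range(n_per_shape):
            gid = f"{shape_name}-{j + 1}"
            base = rng.lognormal(np.log(10.0), 0.3) + 2.0
            fc = np.asarray(shape, dtype=float) + rng.normal(0.0, noise_sd, size=len(shape))
            rows.append(np.concatenate([[base], base * 2.0 ** fc]))
            ids.append(gid)
            manifest.profiles[gid] = shape_name
    matrix = ExpressionMatrix(pd.DataFrame(rows, index=ids, columns=list(stages)))
    manifest.params.setdefault("profiles", {}).update(
        {"n_per_shape": n_per_shape, "noise_sd": noise_sd, "shapes": {k: list(v) for k, v in shapes.items()}}
    )
    return matrix, manifest


# --------------------------------------------------------------------------
# ceRNA planting
# --------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _count_overlapping(seq: str, site: str) -> list[int]:
    out, start = [], 0
    while True:
        p = seq.find(site, start)
        if p == -1:
            return out
        out.append(p)
        start = p + 1


def _scrub_accidental_sites(
    rng: np.random.Generator, seq: str, site: str, keep: set[int], max_rounds: int = 50
) -> str:
    """Replace occurrences of ``site`` outside ``keep`` with fresh bases."""
    for _ in range(max_rounds):
        extra = [p for p in _count_overlapping(seq, site) if p not in keep]
        if not extra:
            return seq
        p = extra[0]
        seq = seq[:p] + _random_seq(rng, len(site)) + seq[p + len(site):]
        # re-stamp planted sites in case the rewrite clipped one
        for q in keep:
            seq = seq[:q] + site + seq[q + len(site):]
    raise RuntimeError("could not scrub accidental seed sites")


def _anticorrelated_log_vector(
    rng: np.random.Generator,
    linc_log: np.ndarray,
    target_r: float,
    tol: float = 0.15,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_tries: int = 500,
) -> tuple[np.ndarray, float]:
    """miRNA RPKM stage vector whose log2(RPKM + pc) correlation with the
    lincRNA's log vector lands within ``tol`` of ``target_r`` (Gaussian
    copula draw, re-rolled until the achieved r is in band).
    """
    z = (linc_log - linc_log.mean()) / linc_log.std()
    for _ in range(max_tries):
        eps = rng.normal(0.0, 1.0, size=linc_log.size)
        y = target_r * z + np.sqrt(max(0.0, 1 - target_r ** 2)) * eps
        y_log = np.log2(20.0) + 1.5 * y
        rpkm = np.maximum(2.0 ** y_log - pseudocount, 0.0)
        achieved = float(np.corrcoef(linc_log, np.log2(rpkm + pseudocount))[0, 1])
        if abs(achieved - target_r) <= tol:
            return rpkm, achieved
    raise RuntimeError("failed to draw an expression vector in the target correlation band")


def plant_cerna_pairs(
    seed: int,
    lincs: Mapping[str, str],
    expr_linc: ExpressionMatrix,
    n_mirna: int = 50,
    n_pairs: int = 10,
    sites_per_pair: int = 2,
    target_r: float = -0.8,
    mirna_length: int = 22,
    seed_start: int = 2,
    seed_len: int = 7,
    manifest: GroundTruthManifest | None = None,
) -> tuple[dict[str, str], dict[str, str], ExpressionMatrix, GroundTruthManifest]:
    """Plant seed sites and anti-correlated miRNA expression.

    Returns (edited transcripts, miRNA sequences, miRNA expression matrix,
    manifest).  The first ``n_pairs`` miRNAs are each paired with one
    lincRNA: ``sites_per_pair`` copies of the miRNA's seed site are written
    into the transcript at recorded positions (accidental extra occurrences
    are scrubbed), and the miRNA's stage vector is drawn to achieve a Pearson
    correlation near ``target_r`` with the lincRNA's log expression.
    Remaining miRNAs get independent lognormal expression.
    """
    rng = np.random.default_rng(seed)
    if manifest is None:
        manifest = GroundTruthManifest(seed=seed)
    stages = expr_linc.stage_labels
    logged = np.log2(expr_linc.values + DEFAULT_PSEUDOCOUNT)

    # distinct miRNAs with distinct seed sites
    mirnas: dict[str, str] = {}
    sites_seen: set[str] = set()
    i = 0
    while len(mirnas) < n_mirna:
        i += 1
        seq = _random_seq(rng, mirna_length)
        site = seed_site(seq, f"mir-{len(mirnas) + 1}", seed_start, seed_len).site_sequence
        if site in sites_seen:
            continue
        sites_seen.add(site)
        mirnas[f"mir-{len(mirnas) + 1}"] = seq

    # eligible lincs: long enough and with a non-constant expression vector
    eligible = sorted(
        lid for lid, t in lincs.items()
        if len(t) >= sites_per_pair * (seed_len + 10) + 20
        and lid in expr_linc.values.index
        and np.ptp(logged.loc[lid].to_numpy()) > 0
    )
    if len(eligible) < n_pairs:
        raise ValueError(f"only {len(eligible)} eligible lincRNAs for {n_pairs} planted pairs")
    chosen = [eligible[int(k)] for k in rng.choice(len(eligible), size=n_pairs, replace=False)]

    edited = dict(lincs)
    mir_rows = np.zeros((n_mirna, len(stages)))
    mir_ids = list(mirnas)
    for pair_idx, lid in enumerate(chosen):
        mid = mir_ids[pair_idx]
        site = seed_site(mirnas[mid], mid, seed_start, seed_len).site_sequence
        seq = edited[lid]
        # non-overlapping insertion positions, separated by > seed_len
        span = len(seq) - seed_len
        positions: list[int] = []
        while len(positions) < sites_per_pair:
            p = int(rng.integers(0, span + 1))
            if all(abs(p - q) > seed_len for q in positions):
                positions.append(p)
        positions.sort()
        for p in positions:
            seq = seq[:p] + site + seq[p + seed_len:]
        seq = _scrub_accidental_sites(rng, seq, site, set(positions))
        edited[lid] = seq

        linc_log = logged.loc[lid].to_numpy()
        rpkm, achieved = _anticorrelated_log_vector(rng, linc_log, target_r)
        mir_rows[pair_idx] = rpkm
        manifest.cerna_pairs.append(
            {"linc": lid, "mirna": mid, "positions": positions,
             "sites": sites_per_pair, "target_r": target_r, "achieved_r": achieved}
        )
    for j in range(n_pairs, n_mirna):
        mir_rows[j] = rng.lognormal(np.log(10.0), 1.0, size=len(stages))
    expr_mir = ExpressionMatrix(pd.DataFrame(mir_rows, index=mir_ids, columns=stages))
    manifest.params.setdefault("cerna", {}).update(
        {"n_mirna": n_mirna, "n_pairs": n_pairs, "sites_per_pair": sites_per_pair,
         "target_r": target_r, "seed_start": seed_start, "seed_len": seed_len}
    )
    return edited, mirnas, expr_mir, manifest


# --------------------------------------------------------------------------
# TF peaks
# --------------------------------------------------------------------------

def make_peaks(
    seed: int,
    windows: Sequence[PromoterWindow],
    n_tfs: int = 20,
    stages: Sequence[str] = ("embryo", "L1", "L2", "L3", "L4", "YA"),
    frac_targets: float = 0.2,
    n_decoys: int = 10,
    peak_width: tuple[int, int] = (200, 600),
    chrom_lengths: Mapping[str, int] | None = None,
    manifest: GroundTruthManifest | None = None,
) -> tuple[list[Peak], GroundTruthManifest]:
    """Target peaks overlapping promoter windows plus decoys clear of all.

    For every (TF, stage), each window is a target with probability
    ``frac_targets``; one peak is placed overlapping it by >= 1 bp.  Decoy
    peaks land at least 1 bp clear of every window.  Scores are lognormal.
    """
    rng = np.random.default_rng(seed)
    if manifest is None:
        manifest = GroundTruthManifest(seed=seed)
    windows = list(windows)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        by_chrom.setdefault(w.region.chrom, []).append((w.region.start, w.region.end))
    chroms = sorted(by_chrom)
    if chrom_lengths is None:
        chrom_lengths = {c: max(e for _s, e in by_chrom[c]) + 100_000 for c in chroms}

    peaks: list[Peak] = []
    for stage in stages:
        regs: list[list[str]] = []
        for t in range(1, n_tfs + 1):
            tf = f"tf-{t}"
            for w in windows:
                if rng.random() >= frac_targets:
                    continue
                width = int(rng.integers(*peak_width))
                lo = max(0, w.region.start - width + 1)
                hi = w.region.end - 1  # start here still overlaps by 1 bp
                start = int(rng.integers(lo, hi + 1))
                region = Interval(w.region.chrom, start, start + width)
                peaks.append(Peak(tf, stage, region, float(rng.lognormal(np.log(10.0), 0.8))))
                # record every window this peak touches (nearby lincRNA
                # windows can fall inside the same peak)
                for w2 in windows:
                    if region.overlaps(w2.region):
                        regs.append([tf, w2.gene_id])
            placed = 0
            while placed < n_decoys:
                c = chroms[int(rng.integers(0, len(chroms)))]
                width = int(rng.integers(*peak_width))
                start = int(rng.integers(0, max(1, chrom_lengths[c] - width)))
                end = start + width
                if all(end <= s or start >= e for s, e in by_chrom[c]):
                    peaks.append(Peak(tf, stage, Interval(c, start, end),
                                      float(rng.lognormal(np.log(10.0), 0.8))))
                    placed += 1
        manifest.tf_regulations[stage] = [list(t) for t in sorted({tuple(r) for r in regs})]
    manifest.params.setdefault("peaks", {}).update(
        {"n_tfs": n_tfs, "stages": list(stages), "frac_targets": frac_targets,
         "n_decoys": n_decoys}
    )
    return peaks, manifest


# --------------------------------------------------------------------------
# Full desk-scale bundle
# --------------------------------------------------------------------------

def simulate_paper_shape(
    seed: int,
    n_linc: int = 170,
    n_mrna: int = 1000,
    n_mirna: int = 50,
    n_cerna_pairs: int = 10,
    n_tfs: int = 20,
    n_chrom: int = 2,
    chrom_length: int = 3_000_000,
) -> dict:
    """Generate the full desk-scale dataset every pipeline stage consumes.

    Returns a dict with genome, models, lincRNA/mRNA expression, transcripts
    (with planted seed sites), miRNA sequences and expression, TF peaks,
    promoter windows and the ground-truth manifest.  Sub-generators get
    distinct seeds derived from the master seed so stages stay independently
    reproducible.
    """
    from .tf_regulation import promoter_window

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]

    genome = make_genome(seeds[0], n_chrom=n_chrom, chrom_length=chrom_length)
    models = make_gene_models(seeds[1], genome, n_linc=n_linc, n_mrna=n_mrna)
    lincs = [m for m in models if m.biotype == "lincRNA"]
    mrnas = [m for m in models if m.biotype == "mRNA"]

    expr_linc, manifest = paper_shape_expression(seeds[2])
    manifest.seed = seed
    # mRNA expression: broad/variable planting on the same stages
    expr_mrna, manifest = make_expression(
        seeds[3], [m.gene_id for m in mrnas], NINE_STAGES, manifest=manifest
    )

    transcripts = {m.gene_id: extract_spliced_sequence(genome, m) for m in lincs}
    transcripts, mirnas, expr_mir, manifest = plant_cerna_pairs(
        seeds[4], transcripts, expr_linc, n_mirna=n_mirna, n_pairs=n_cerna_pairs,
        manifest=manifest,
    )

    chrom_lengths = {c: len(s) for c, s in genome.items()}
    windows = [
        promoter_window(m, chrom_length=chrom_lengths[m.span.chrom]) for m in lincs
    ]
    peaks, manifest = make_peaks(
        seeds[5], windows, n_tfs=n_tfs, chrom_lengths=chrom_lengths, manifest=manifest
    )
    manifest.params["scale"] = {
        "n_linc": n_linc, "n_mrna": n_mrna, "n_mirna": n_mirna,
        "n_chrom": n_chrom, "chrom_length": chrom_length,
    }
    return {
        "genome": genome,
        "models": models,
        "lincs": lincs,
        "mrnas": mrnas,
        "expr_linc": expr_linc,
        "expr_mrna": expr_mrna,
        "transcripts": transcripts,
        "mirnas": mirnas,
        "expr_mir": expr_mir,
        "windows": windows,
        "peaks": peaks,
        "manifest": manifest,
    }
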