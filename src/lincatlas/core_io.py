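"""Genomic data model and readers/writers for the formats the pipeline touches.

All coordinates are 0-based, half-open internally.  GTF/GFF3 (1-based,
inclusive) and BED (0-based, half-open) conventions are converted at the I/O
boundary and nowhere else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "Interval",
    "GeneModel",
    "ExpressionMatrix",
    "Peak",
    "ScoreTrack",
    "ParseError",
    "ValidationError",
    "read_gene_models",
    "write_gene_models",
    "extract_spliced_sequence",
    "read_fasta",
    "write_fasta",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_peaks",
    "write_peaks",
    "read_score_track",
    "write_network",
    "reverse_complement",
    "DEFAULT_BIOTYPE_RULES",
]


class ParseError(ValueError):
    """A malformed input line; the message names the line number."""


class ValidationError(ValueError):
    """Input violated a documented invariant."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: one genomic span plus ordered, disjoint exons.

    The TSS is the 5' end of the span in transcription orientation:
    ``span.start`` on the plus strand, ``span.end - 1`` on the minus strand.
    """

    gene_id: str
    biotype: str  # lincRNA | mRNA | miRNA | other
    span: Interval
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene model needs at least one exon")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise ValidationError(f"{self.gene_id}: exon chrom/strand differs from span")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValidationError(f"{self.gene_id}: exon {ex} outside span {self.span}")
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = ex.end
        if self.biotype not in {"lincRNA", "mRNA", "miRNA", "other"}:
            raise ValidationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        return self.span.start if self.span.strand == "+" else self.span.end - 1

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class ExpressionMatrix:
    """Genes x stages abundance matrix on the RPKM scale.

    Backed by a pandas DataFrame (index = gene ids, columns = stage labels);
    absence of expression is encoded as 0, never as a missing cell.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate stage labels in expression matrix")
        if df.isna().any().any():
            raise ValidationError("missing cells in expression matrix (encode absence as 0)")
        if (df.to_numpy() < 0).any():
            raise ValidationError("negative expression value")
        df.index.name = "gene_id"
        df.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str):
        try:
            return self.values.loc[gene_id]
        except KeyError as exc:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from exc


@dataclass(frozen=True)
class Peak:
    """A TF-and-stage-labelled ChIP-seq interval with an enrichment score."""

    tf_name: str
    stage: str
    region: Interval
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.region) <= 0:
            raise ValidationError("peak region must be non-empty")
        if self.score < 0:
            raise ValidationError("peak score must be non-negative")


class ScoreTrack:
    """Sparse per-base conservation scores in [0, 1].

    Bases absent from the track are unannotated; conservation summaries
    average over annotated bases only.
    """

    def __init__(self) -> None:
        self._scores: dict[str, dict[int, float]] = {}

    def set_score(self, chrom: str, pos: int, score: float) -> None:
        if not (0.0 <= score <= 1.0):
            raise ValidationError(f"conservation score {score} outside [0, 1]")
        self._scores.setdefault(chrom, {})[pos] = score

    def get(self, chrom: str, pos: int) -> float | None:
        return self._scores.get(chrom, {}).get(pos)

    def add_interval(self, chrom: str, start: int, end: int, score: float) -> None:
        for pos in range(start, end):
            self.set_score(chrom, pos, score)

    def n_scored(self) -> int:
        return sum(len(v) for v in self._scores.values())


# --------------------------------------------------------------------------
# Sequence utilities
# --------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_sequence(seq: str, name: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"{name}: unsupported sequence characters {sorted(bad)}")
    return seq


def extract_spliced_sequence(
    genome: Mapping[str, str], model: GeneModel, rna: bool = False
) -> str:
    """Concatenate exon sequences in genomic order; reverse-complement the
    whole thing for minus-strand models so the result is the sense transcript.
    """
    try:
        chrom_seq = genome[model.span.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {model.span.chrom!r} not in genome") from exc
    parts = []
    for ex in model.exons:
        if ex.end > len(chrom_seq):
            raise IndexError(
                f"{model.gene_id}: exon [{ex.start}, {ex.end}) beyond chromosome "
                f"end {len(chrom_seq)}"
            )
        parts.append(chrom_seq[ex.start:ex.end])
    seq = _clean_sequence("".join(parts), model.gene_id)
    if model.span.strand == "-":
        seq = reverse_complement(seq)
    if rna:
        seq = seq.replace("T", "U")
    return seq


# --------------------------------------------------------------------------
# GTF / GFF3
# --------------------------------------------------------------------------

#: attribute key -> {value -> biotype}; first matching key wins.
DEFAULT_BIOTYPE_RULES: dict[str, dict[str, str]] = {
    "gene_biotype": {
        "lincRNA": "lincRNA",
        "lncRNA": "lincRNA",
        "protein_coding": "mRNA",
        "mRNA": "mRNA",
        "miRNA": "miRNA",
        "other": "other",
    },
    "biotype": {
        "lincRNA": "lincRNA",
        "protein_coding": "mRNA",
        "mRNA": "mRNA",
        "miRNA": "miRNA",
        "other": "other",
    },
}


def _assign_biotype(attributes, rules: Mapping[str, Mapping[str, str]]) -> str:
    for key, mapping in rules.items():
        if key in attributes:
            for value in attributes[key]:
                if value in mapping:
                    return mapping[value]
    return "other"


def read_gene_models(
    annotation_stream: TextIO | str,
    biotype_rules: Mapping[str, Mapping[str, str]] | None = None,
) -> list[GeneModel]:
    """Parse transcripts from GTF or GFF3 text into GeneModels.

    One model per transcript; GTF/GFF3 1-based inclusive coordinates become
    0-based half-open.  Book-ended duplicate exons are merged.  Output is
    ordered by (chrom, start, gene_id).
    """
    if isinstance(annotation_stream, str):
        annotation_stream = io.StringIO(annotation_stream)
    rules = DEFAULT_BIOTYPE_RULES if biotype_rules is None else biotype_rules

    spans: dict[str, Interval] = {}
    exons: dict[str, list[Interval]] = {}
    biotypes: dict[str, str] = {}
    order: list[str] = []

    for lineno, raw in enumerate(annotation_stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        try:
            feat = feature_from_line(line)
            start1, end1 = int(fields[3]), int(fields[4])
        except Exception as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        if start1 < 1 or end1 < start1:
            raise ParseError(f"line {lineno}: invalid coordinates {start1}..{end1}")

        attrs = feat.attributes
        tid = None
        for key in ("transcript_id", "ID", "Parent"):
            if key in attrs and attrs[key]:
                tid = attrs[key][0]
                break
        if tid is None:
            raise ParseError(f"line {lineno}: no transcript identifier attribute")
        iv = Interval(fields[0], start1 - 1, end1, feat.strand if feat.strand in "+-" else ".")

        if feat.featuretype in {"transcript", "gene", "mRNA", "lincRNA", "ncRNA"}:
            if feat.featuretype in {"transcript", "mRNA", "lincRNA", "ncRNA"}:
                if tid in spans:
                    raise ValidationError(f"line {lineno}: duplicate transcript id {tid!r}")
                spans[tid] = iv
                biotypes[tid] = _assign_biotype(attrs, rules)
                order.append(tid)
        elif feat.featuretype == "exon":
            # GFF3 exons point at their transcript via Parent
            if "Parent" in attrs and attrs["Parent"]:
                tid = attrs["Parent"][0]
            elif "transcript_id" in attrs and attrs["transcript_id"]:
                tid = attrs["transcript_id"][0]
            exons.setdefault(tid, []).append(iv)
            if tid not in biotypes:
                biotypes[tid] = _assign_biotype(attrs, rules)
                order.append(tid)

    models = []
    for tid in order:
        ex_list = sorted(exons.get(tid, []), key=lambda e: e.start)
        if not ex_list:
            continue
        merged: list[Interval] = []
        for ex in ex_list:  # merge book-ended duplicates
            if merged and ex.start <= merged[-1].end:
                if ex.start < merged[-1].end and ex.end > merged[-1].end:
                    raise ValidationError(f"{tid}: overlapping exons in annotation")
                if ex.end > merged[-1].end:
                    prev = merged.pop()
                    merged.append(Interval(prev.chrom, prev.start, ex.end, prev.strand))
            else:
                merged.append(ex)
        span = spans.get(
            tid,
            Interval(merged[0].chrom, merged[0].start, merged[-1].end, merged[0].strand),
        )
        if any(ex.start < span.start or ex.end > span.end for ex in merged):
            raise ValidationError(f"{tid}: exon outside declared transcript span")
        models.append(GeneModel(tid, biotypes.get(tid, "other"), span, tuple(merged)))

    models.sort(key=lambda m: (m.span.chrom, m.span.start, m.gene_id))
    return models


def write_gene_models(models: Sequence[GeneModel]) -> str:
    """Serialize models as GTF (transcript + exon rows, 1-based inclusive)."""
    out = []
    for m in models:
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}"; gene_biotype "{m.biotype}";'
        s = m.span
        out.append(
            f"{s.chrom}\tlincatlas\ttranscript\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t{attrs}"
        )
        for ex in m.exons:
            out.append(
                f"{ex.chrom}\tlincatlas\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}"
            )
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(stream: TextIO | str) -> dict[str, str]:
    """Read FASTA into a name -> uppercase-sequence map (Bio.SeqIO backed)."""
    from Bio import SeqIO

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return {
        rec.id: _clean_sequence(str(rec.seq), rec.id)
        for rec in SeqIO.parse(stream, "fasta")
    }


def write_fasta(sequences: Mapping[str, str], width: int = 70) -> str:
    out = []
    for name, seq in sequences.items():
        out.append(f">{name}")
        for i in range(0, len(seq), width):
            out.append(seq[i:i + width])
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# Expression matrices (TSV)
# --------------------------------------------------------------------------

def read_expression_matrix(stream: TextIO | str) -> ExpressionMatrix:
    """TSV with gene ids in the first column and stage labels as header."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix) -> str:
    buf = io.StringIO()
    matrix.values.to_csv(buf, sep="\t", index_label="gene_id")
    return buf.getvalue()


# --------------------------------------------------------------------------
# Peaks (BED / GFF3)
# --------------------------------------------------------------------------

def read_peaks(
    stream: TextIO | str,
    fmt: str = "bed",
    tf_name: str | None = None,
    stage: str | None = None,
) -> list[Peak]:
    """Read ChIP-seq peaks from BED (0-based half-open) or GFF3 (1-based).

    BED name column may carry "TF:stage"; otherwise supply ``tf_name`` and
    ``stage`` explicitly (explicit labels win).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    peaks: list[Peak] = []
    if fmt == "bed":
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer BED coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 and fields[4] not in {".", ""} else 0.0
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            tf, stg = tf_name, stage
            if ":" in name:
                parsed_tf, parsed_stage = name.split(":", 1)
                tf = tf or parsed_tf
                stg = stg or parsed_stage
            peaks.append(
                Peak(tf or name or "NA", stg or "NA", Interval(fields[0], start, end, strand), score)
            )
    elif fmt == "gff3":
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 GFF3 fields")
            feat = feature_from_line(line)
            attrs = feat.attributes
            tf = tf_name or (attrs["tf"][0] if "tf" in attrs else feat.source)
            stg = stage or (attrs["stage"][0] if "stage" in attrs else "NA")
            score = 0.0 if fields[5] in {".", ""} else float(fields[5])
            strand = feat.strand if feat.strand in "+-" else "."
            peaks.append(
                Peak(tf, stg, Interval(fields[0], int(fields[3]) - 1, int(fields[4]), strand), score)
            )
    else:
        raise ValueError(f"unknown peak format {fmt!r} (use 'bed' or 'gff3')")
    return peaks


def write_peaks(peaks: Iterable[Peak]) -> str:
    """BED6 with name = "TF:stage"."""
    out = []
    for p in peaks:
        r = p.region
        out.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{p.tf_name}:{p.stage}\t{p.score:g}\t{r.strand}"
        )
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# Conservation tracks (bedGraph-like text)
# --------------------------------------------------------------------------

def read_score_track(stream: TextIO | str) -> ScoreTrack:
    """bedGraph: chrom<TAB>start<TAB>end<TAB>score, 0-based half-open."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    track = ScoreTrack()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: bedGraph needs 4 columns")
        try:
            start, end, score = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        track.add_interval(fields[0], start, end, score)
    return track


# --------------------------------------------------------------------------
# Network export
# --------------------------------------------------------------------------

def write_network(edges, fmt: str = "sif") -> str:
    """Export lincRNA-miRNA edges as SIF or GraphML.

    ``edges`` is an iterable of objects with ``linc_id`` and ``mirna_id``
    attributes (or (linc, mirna) pairs).
    """
    pairs = []
    for e in edges:
        if hasattr(e, "linc_id"):
            pairs.append((e.linc_id, e.mirna_id))
        else:
            pairs.append((e[0], e[1]))
    if fmt == "sif":
        return "".join(f"{a}\tinteracts\t{b}\n" for a, b in pairs)
    if fmt == "graphml":
        import networkx as nx

        g = nx.Graph()
        for a, b in pairs:
            g.add_node(a, kind="lincRNA")
            g.add_node(b, kind="miRNA")
            g.add_edge(a, b)
        return "\n".join(nx.generate_graphml(g)) + "\n"
    raise ValueError(f"unknown network format {fmt!r} (use 'sif' or 'graphml')")
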