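"""Genomic coordinate types, transcript models, and flat-file readers/writers.

All internal coordinates are 0-based, half-open. Transcript models keep their
exons in transcript orientation (5'->3'), so minus-strand transcripts list
exons by decreasing genomic position. Transcript-space coordinates always run
5'->3' along the mature (spliced) RNA, which is the frame in which motif and
seed matching operate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

STRANDS = ("+", "-")

REGION_5UTR = "5'UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3'UTR"
REGIONS = (REGION_5UTR, REGION_CDS, REGION_3UTR)


class AnnotationError(ValueError):
    """Raised for malformed or invariant-violating annotation records."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """A spliced transcript: ordered exons plus a CDS segmentation.

    ``cds_start``/``cds_end`` are transcript-space offsets; bases in
    ``[0, cds_start)`` form the 5'UTR, ``[cds_start, cds_end)`` the CDS and
    ``[cds_end, sequence_length)`` the 3'UTR.
    """

    gene_id: str
    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        self.exons = tuple(self.exons)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"{self.transcript_id}: exons span multiple chroms/strands"
            )
        # transcript orientation: ascending genomic start on +, descending on -
        starts = [e.start for e in self.exons]
        if self.strand == "+":
            ordered = all(a < b for a, b in zip(starts, starts[1:]))
        else:
            ordered = all(a > b for a, b in zip(starts, starts[1:]))
        if not ordered:
            raise AnnotationError(
                f"{self.transcript_id}: exons not sorted 5'->3' in transcript "
                "orientation"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if not (0 <= self.cds_start < self.cds_end <= self.sequence_length):
            raise AnnotationError(
                f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                f"outside [0,{self.sequence_length})"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def sequence_length(self) -> int:
        return sum(e.length for e in self.exons)

    def to_transcript_coords(self, g: GenomicInterval) -> tuple[int, int] | None:
        """Project a genomic interval onto concatenated exon space.

        Returns the half-open transcript-space interval spanned by the exonic
        bases of ``g``, or ``None`` when ``g`` is wholly intronic or outside
        the transcript. Intronic bases inside ``g`` simply drop out of the
        projection.
        """
        if g.chrom != self.chrom:
            raise AnnotationError(
                f"chrom mismatch: {g.chrom} vs {self.chrom} "
                f"({self.transcript_id})"
            )
        if g.strand != self.strand:
            raise AnnotationError(
                f"strand mismatch: {g.strand} vs {self.strand} "
                f"({self.transcript_id})"
            )
        lo = math.inf
        hi = -math.inf
        offset = 0
        for exon in self.exons:
            ov_start = max(g.start, exon.start)
            ov_end = min(g.end, exon.end)
            if ov_start < ov_end:
                if self.strand == "+":
                    t0 = offset + (ov_start - exon.start)
                    t1 = offset + (ov_end - exon.start)
                else:
                    t0 = offset + (exon.end - ov_end)
                    t1 = offset + (exon.end - ov_start)
                lo = min(lo, t0)
                hi = max(hi, t1)
            offset += exon.length
        if hi < 0:
            return None
        return int(lo), int(hi)

    def region_of(self, t_start: int, t_end: int) -> str:
        """Classify a transcript-space interval by majority overlap.

        Ties between adjacent regions go to the more 5' region, so an interval
        split evenly across the stop codon is assigned to the CDS.
        """
        if not (0 <= t_start < t_end <= self.sequence_length):
            raise AnnotationError(
                f"interval [{t_start},{t_end}) outside transcript "
                f"{self.transcript_id}"
            )
        bounds = [
            (REGION_5UTR, 0, self.cds_start),
            (REGION_CDS, self.cds_start, self.cds_end),
            (REGION_3UTR, self.cds_end, self.sequence_length),
        ]
        best, best_ov = REGION_5UTR, -1
        for name, lo, hi in bounds:
            ov = max(0, min(t_end, hi) - max(t_start, lo))
            if ov > best_ov:
                best, best_ov = name, ov
        return best


@dataclass
class CountTable:
    """Per-gene (or per-window) integer read counts plus library sizes.

    ``counts`` is indexed by gene_id with one column per sample;
    ``library_sizes`` holds total mapped exonic reads per sample and must be
    at least the corresponding column sum.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise AnnotationError("negative counts")
        colsum = self.counts.sum(axis=0)
        for sample in self.counts.columns:
            if sample not in self.library_sizes.index:
                raise AnnotationError(f"missing library size for {sample}")
            if self.library_sizes[sample] < colsum[sample]:
                raise AnnotationError(
                    f"library size for {sample} below exonic column sum"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class MethylationEvent:
    """A called m6A methylation event (one joined run of significant windows)."""

    interval: GenomicInterval
    sample_id: str
    gene_id: str
    transcript_id: str
    n_windows: int
    min_window_p: float
    threshold_used: float


# ---------------------------------------------------------------------------
# Annotation I/O: GTF (ensembl dialect) plus a flat TSV fallback
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "gene_id",
    "transcript_id",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_start",
    "cds_end",
]


def read_annotation(path, fmt: str = "auto", strict: bool = True) -> list[TranscriptModel]:
    """Read transcript models from a GTF or the documented TSV fallback.

    With ``strict`` (default) any transcript failing the model invariants
    raises; otherwise failing transcripts are skipped with a warning naming
    them.
    """
    path = str(path)
    if fmt == "auto":
        fmt = "gtf" if path.endswith((".gtf", ".gff")) else "tsv"
    if fmt == "gtf":
        return _read_gtf(path, strict=strict)
    if fmt == "tsv":
        return _read_annotation_tsv(path, strict=strict)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gtf(path: str, strict: bool = True) -> list[TranscriptModel]:
    from gffutils.feature import feature_from_line

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:  # malformed record
                raise AnnotationError(f"{path}:{lineno}: cannot parse GTF line ({exc})")
            if f.featuretype not in ("exon", "CDS"):
                continue
            try:
                tid = f.attributes["transcript_id"][0]
                gid = f.attributes["gene_id"][0]
            except KeyError:
                raise AnnotationError(
                    f"{path}:{lineno}: missing gene_id/transcript_id attribute"
                )
            gene_of[tid] = gid
            # GTF is 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
            (exons if f.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, ex in exons.items():
        try:
            models.append(_assemble_model(gene_of[tid], tid, ex, cds.get(tid, [])))
        except AnnotationError:
            if strict:
                raise
            warnings.warn(f"skipping invalid transcript {tid}")
    models.sort(key=lambda m: m.transcript_id)
    return models


def _assemble_model(gene_id, transcript_id, exons, cds_intervals) -> TranscriptModel:
    strand = exons[0].strand
    exons = sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))
    model = TranscriptModel(gene_id, transcript_id, tuple(exons), 0, 1)
    length = model.sequence_length
    if cds_intervals:
        lo, hi = length, 0
        for iv in cds_intervals:
            proj = model.to_transcript_coords(iv)
            if proj is None:
                raise AnnotationError(f"{transcript_id}: CDS outside exons")
            lo = min(lo, proj[0])
            hi = max(hi, proj[1])
        model = replace(model, cds_start=lo, cds_end=hi)
    else:
        model = replace(model, cds_start=0, cds_end=length)
    return model


def write_gtf(models: list[TranscriptModel], path) -> None:
    """Write models as ensembl-dialect GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for exon in sorted(m.exons, key=lambda e: e.start):
                fh.write(
                    f"{exon.chrom}\tm6ate\texon\t{exon.start + 1}\t{exon.end}\t."
                    f"\t{exon.strand}\t.\t{attrs}\n"
                )
            for iv in _cds_genomic_intervals(m):
                fh.write(
                    f"{iv.chrom}\tm6ate\tCDS\t{iv.start + 1}\t{iv.end}\t."
                    f"\t{iv.strand}\t.\t{attrs}\n"
                )


def _cds_genomic_intervals(m: TranscriptModel) -> list[GenomicInterval]:
    """Genomic pieces of the transcript-space CDS, in genomic order."""
    pieces = []
    offset = 0
    for exon in m.exons:
        lo = max(m.cds_start, offset)
        hi = min(m.cds_end, offset + exon.length)
        if lo < hi:
            if m.strand == "+":
                g0 = exon.start + (lo - offset)
                g1 = exon.start + (hi - offset)
            else:
                g0 = exon.end - (hi - offset)
                g1 = exon.end - (lo - offset)
            pieces.append(GenomicInterval(exon.chrom, g0, g1, exon.strand))
        offset += exon.length
    return sorted(pieces, key=lambda iv: iv.start)


def _read_annotation_tsv(path: str, strict: bool = True) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    models = []
    for _, row in df.iterrows():
        try:
            starts = [int(x) for x in str(row.exon_starts).split(",")]
            ends = [int(x) for x in str(row.exon_ends).split(",")]
            if len(starts) != len(ends):
                raise AnnotationError(
                    f"{row.transcript_id}: exon_starts/exon_ends length mismatch"
                )
            exons = tuple(
                GenomicInterval(row.chrom, s, e, row.strand)
                for s, e in zip(starts, ends)
            )
            models.append(
                TranscriptModel(
                    row.gene_id,
                    row.transcript_id,
                    exons,
                    int(row.cds_start),
                    int(row.cds_end),
                )
            )
        except (ValueError, AnnotationError) as exc:
            if strict:
                if isinstance(exc, AnnotationError):
                    raise
                raise AnnotationError(f"{path}: malformed record for "
                                      f"{row.get('transcript_id', '?')}: {exc}")
            warnings.warn(f"skipping invalid transcript {row.get('transcript_id')}")
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_annotation_tsv(models: list[TranscriptModel], path) -> None:
    rows = []
    for m in models:
        rows.append(
            {
                "gene_id": m.gene_id,
                "transcript_id": m.transcript_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "exon_starts": ",".join(str(e.start) for e in m.exons),
                "exon_ends": ",".join(str(e.end) for e in m.exons),
                "cds_start": m.cds_start,
                "cds_end": m.cds_end,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED6 event I/O
# ---------------------------------------------------------------------------


def write_events_bed(events: list[MethylationEvent], path) -> None:
    """Write events as BED6; score = -log10 of the event's minimum window p."""
    with open(path, "w") as fh:
        for ev in events:
            p = max(ev.min_window_p, 1e-300)
            name = f"{ev.gene_id}|{ev.transcript_id}|{ev.sample_id}|{ev.n_windows}"
            fh.write(
                f"{ev.interval.chrom}\t{ev.interval.start}\t{ev.interval.end}"
                f"\t{name}\t{-math.log10(p):.6g}\t{ev.interval.strand}\n"
            )


def read_events_bed(path, threshold_used: float = float("nan")) -> list[MethylationEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise AnnotationError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, score, strand = parts
            gene_id, transcript_id, sample_id, n_windows = name.split("|")
            events.append(
                MethylationEvent(
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    sample_id=sample_id,
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    n_windows=int(n_windows),
                    min_window_p=10.0 ** (-float(score)),
                    threshold_used=threshold_used,
                )
            )
    return events


# ---------------------------------------------------------------------------
# Sequence I/O: canonical RNA alphabet {A, C, G, U}
# ---------------------------------------------------------------------------

RNA_ALPHABET = frozenset("ACGU")


def canonical_rna(seq: str) -> str:
    """Uppercase and convert T->U; reject anything outside {A,C,G,U,T}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AnnotationError(f"invalid sequence characters {sorted(bad)}")
    return s


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: canonical_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")
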