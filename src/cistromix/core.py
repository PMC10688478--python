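"""Genomic interval algebra, gene models and flat-file readers/writers.

All coordinates are 0-based half-open throughout the package.  BED input is
taken as-is; GTF input (1-based inclusive) is converted on read.  This single
convention keeps every downstream distance and overlap computation free of
off-by-one drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "CistromixError",
    "ParameterError",
    "ParseError",
    "DomainError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "FeatureAnnotation",
    "FEATURE_CATEGORIES",
    "merge_within",
    "signed_distance_to_tss",
    "read_bed",
    "write_bed",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_gtf",
    "DictGenome",
    "FastaGenome",
]


class CistromixError(Exception):
    """Base class for package errors."""


class ParameterError(CistromixError, ValueError):
    """An argument violates an operation's preconditions."""


class ParseError(CistromixError, ValueError):
    """A malformed input line; the message names the file line number."""


class DomainError(CistromixError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ParameterError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ParameterError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Peak:
    """A called or consensus ChIP interval with its summit and statistics.

    ``score`` is a read count, ``fold_enrichment`` the ChIP/input ratio at
    the best constituent window, ``fdr`` a Benjamini-Hochberg q-value and
    ``replicate_support`` the number of biological replicates in which the
    site was observed (0 for a raw single-sample call).
    """

    interval: GenomicInterval
    summit: int = -1
    score: float = 0.0
    fold_enrichment: float = 0.0
    fdr: float = 1.0
    replicate_support: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.summit < 0:
            self.summit = self.interval.center
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ParameterError(
                f"summit {self.summit} outside peak interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if not (0.0 <= self.fdr <= 1.0):
            raise ParameterError(f"fdr must be in [0, 1], got {self.fdr}")
        if self.score < 0 or self.fold_enrichment < 0:
            raise ParameterError("score and fold_enrichment must be >= 0")
        if self.replicate_support < 0:
            raise ParameterError("replicate_support must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class GeneModel:
    """A gene reduced to one canonical transcript.

    ``exons`` are non-overlapping and sorted in genomic order; introns are
    the gaps between consecutive exons, numbered 1..n in the direction of
    transcription (so intron 1 abuts the TSS-proximal exon).
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list[GenomicInterval]
    cds_start: int | None = None  # genomic-leftmost CDS bp, if annotated
    cds_end: int | None = None  # genomic-rightmost CDS bp (exclusive)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParameterError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )
        if not self.exons:
            raise ParameterError(f"gene {self.gene_id}: needs >= 1 exon")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ParameterError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
        left = self.exons[0].start
        right = self.exons[-1].end
        expected_tss = left if self.strand == "+" else right
        expected_tts = right if self.strand == "+" else left
        if self.tss != expected_tss or self.tts != expected_tts:
            raise ParameterError(
                f"gene {self.gene_id}: tss/tts inconsistent with exon extent"
            )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(
                    GenomicInterval(self.chrom, prev.end, nxt.start, self.strand)
                )
        return out

    def intron_index(self, point: int) -> int | None:
        """1-based intron number of ``point`` in transcription direction."""
        introns = self.introns()
        for i, intron in enumerate(introns):
            if intron.start <= point < intron.end:
                return i + 1 if self.strand == "+" else len(introns) - i
        return None


FEATURE_CATEGORIES = (
    "promoter",
    "5'UTR",
    "exon",
    "3'UTR",
    "TTS",
    "intron",
    "intergenic",
    "upstream_gene",
    "downstream_gene",
)


@dataclass
class FeatureAnnotation:
    """Single-label genomic classification of a peak summit."""

    category: str
    nearest_gene: str | None
    signed_tss_distance: int | None
    intron_index: int | None = None
    host_gene: str | None = None  # gene whose body contains the summit, if any

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise ParameterError(f"unknown category {self.category!r}")
        if (self.intron_index is not None) != (self.category == "intron"):
            raise ParameterError("intron_index set iff category == 'intron'")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def merge_within(
    intervals: Sequence[GenomicInterval], gap: int
) -> list[GenomicInterval]:
    """Single-linkage merge of intervals whose edge gap is <= ``gap``.

    Per chromosome, sorted intervals are unioned whenever
    ``next.start - prev.end <= gap``; with ``gap=0`` this is the classical
    union of overlapping/adjacent intervals.  Output is sorted and pairwise
    separated by more than ``gap``.  Strand is not considered (merged
    intervals carry strand '.').
    """
    if gap < 0:
        raise ParameterError(f"gap must be >= 0, got {gap}")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def signed_distance_to_tss(point: int, gene: GeneModel, chrom: str | None = None) -> int:
    """Distance from ``point`` to the gene TSS in transcription direction.

    Negative values are upstream of the TSS.  ``chrom``, when given, is
    checked against the gene's chromosome.
    """
    if chrom is not None and chrom != gene.chrom:
        raise DomainError(
            f"point on {chrom} but gene {gene.gene_id} on {gene.chrom}"
        )
    return point - gene.tss if gene.strand == "+" else gene.tss - point


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (coordinates taken as-is)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ParameterError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


_PEAK_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tsummit\tfold_enrichment\tfdr\treplicate_support"


def write_peaks_bed(path, peaks: Iterable[Peak]) -> None:
    """BED6+4 peak table (summit, fold_enrichment, fdr, replicate_support)."""
    with open(path, "w") as fh:
        fh.write(_PEAK_HEADER + "\n")
        for i, p in enumerate(peaks):
            name = p.source or f"peak_{i + 1}"
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{name}\t"
                f"{p.score:g}\t.\t{p.summit}\t{p.fold_enrichment:g}\t"
                f"{p.fdr:.6g}\t{p.replicate_support}\n"
            )


def read_peaks_bed(path) -> list[Peak]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                out.append(
                    Peak(
                        interval=iv,
                        summit=int(f[6]) if len(f) > 6 else -1,
                        score=float(f[4]) if len(f) > 4 else 0.0,
                        fold_enrichment=float(f[7]) if len(f) > 7 else 0.0,
                        fdr=float(f[8]) if len(f) > 8 else 1.0,
                        replicate_support=int(f[9]) if len(f) > 9 else 0,
                        source=f[3] if len(f) > 3 else "",
                    )
                )
            except (ValueError, ParameterError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Read GTF2.2 exon/CDS records into one canonical GeneModel per gene.

    The canonical transcript is the one with the greatest genomic exonic
    extent (ties broken by lexicographically smallest transcript id).
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    cds: dict[tuple[str, str], list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (symbol, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(f)}")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_s = f
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: gene feature lacks strand")
            attrs = _gtf_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            tx_id = attrs.get("transcript_id")
            if not gene_id or not tx_id:
                raise ParseError(f"{path}:{lineno}: missing gene_id/transcript_id")
            meta.setdefault(gene_id, (attrs.get("gene_name", gene_id), chrom, strand))
            key = (gene_id, tx_id)
            if feature == "exon":
                try:
                    exons.setdefault(key, []).append(
                        GenomicInterval(chrom, start1 - 1, end1, strand)
                    )
                except ParameterError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
            else:
                cds.setdefault(key, []).append((start1 - 1, end1))

    genes: list[GeneModel] = []
    by_gene: dict[str, list[str]] = {}
    for gene_id, tx_id in exons:
        by_gene.setdefault(gene_id, []).append(tx_id)
    for gene_id in sorted(by_gene):
        symbol, chrom, strand = meta[gene_id]

        def extent(tx: str) -> int:
            ivs = exons[(gene_id, tx)]
            return max(e.end for e in ivs) - min(e.start for e in ivs)

        canonical = sorted(by_gene[gene_id], key=lambda tx: (-extent(tx), tx))[0]
        ex = sorted(exons[(gene_id, canonical)], key=lambda e: e.start)
        tss = ex[0].start if strand == "+" else ex[-1].end
        tts = ex[-1].end if strand == "+" else ex[0].start
        cds_iv = cds.get((gene_id, canonical))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                chrom=chrom,
                strand=strand,
                tss=tss,
                tts=tts,
                exons=ex,
                cds_start=min(s for s, _ in cds_iv) if cds_iv else None,
                cds_end=max(e for _, e in cds_iv) if cds_iv else None,
            )
        )
    return genes


def write_gtf(path, genes: Iterable[GeneModel], source: str = "cistromix") -> None:
    """Write canonical gene models back out as GTF2.2 exon lines."""
    with open(path, "w") as fh:
        for g in genes:
            for i, e in enumerate(g.exons, 1):
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1"; '
                    f'gene_name "{g.symbol}"; exon_number "{i}";'
                )
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Genome sequence access
# ---------------------------------------------------------------------------


class DictGenome:
    """In-memory genome: a mapping of chromosome name to sequence string."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    def chroms(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise DomainError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq):
            raise DomainError(
                f"{chrom}:{start}-{end} outside chromosome bounds (0-{len(seq)})"
            )
        return seq[start:end]

    def fetch_clipped(self, chrom: str, start: int, end: int) -> tuple[str, int]:
        """Fetch with out-of-bounds clipping; returns (seq, clipped_start)."""
        if chrom not in self._seqs:
            raise DomainError(f"unknown chromosome {chrom!r}")
        n = len(self._seqs[chrom])
        s, e = max(0, start), min(n, end)
        return self._seqs[chrom][s:e], s


class FastaGenome:
    """Genome backed by an indexed FASTA file (via pyfaidx)."""

    def __init__(self, path):
        from pyfaidx import Fasta

        self._fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def chroms(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fa.records.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise DomainError(f"unknown chromosome {chrom!r}")
        n = len(self._fa.records[chrom])
        if start < 0 or end > n:
            raise DomainError(
                f"{chrom}:{start}-{end} outside chromosome bounds (0-{n})"
            )
        return str(self._fa[chrom][start:end])

    def fetch_clipped(self, chrom: str, start: int, end: int) -> tuple[str, int]:
        if chrom not in self._fa:
            raise DomainError(f"unknown chromosome {chrom!r}")
        n = len(self._fa.records[chrom])
        s, e = max(0, start), min(n, end)
        return str(self._fa[chrom][s:e]), s


def write_fasta(path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
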