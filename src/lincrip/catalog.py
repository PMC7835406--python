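"""Transcript catalogs on a genome: interval model, GTF/BED I/O, geometry.

All internal coordinates are 0-based half-open. GTF I/O converts from/to the
1-based inclusive convention of that format; BED12 is native 0-based
half-open. Conversion happens in exactly two places (:func:`read_gtf` /
:func:`write_gtf`) so off-by-one handling is auditable.

Geometric predicates (neighbor distance, location class) operate on genomic
*spans* — the interval from the first exon start to the last exon end — and
are strand-agnostic: an intergenic call means "no annotated transcript of any
biotype on either strand overlaps this span".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from gffutils.feature import feature_from_line

__all__ = [
    "GenomicInterval",
    "TranscriptRecord",
    "TranscriptCatalog",
    "LocationClass",
    "GtfParseError",
    "CatalogValidationError",
    "NO_NEIGHBOR",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "transcript_length",
    "neighbor_distance",
    "classify_location",
]

VALID_STRANDS = frozenset({"+", "-", "."})

#: Sentinel returned by :func:`neighbor_distance` when the transcript's
#: chromosome carries no annotated transcript at all. Callers treat it as an
#: infinite gap (the transcript trivially satisfies any minimum-gap rule).
NO_NEIGHBOR = -1


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class CatalogValidationError(ValueError):
    """A catalog or transcript violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CatalogValidationError("interval chrom must be non-empty")
        if self.strand not in VALID_STRANDS:
            raise CatalogValidationError(
                f"strand must be one of +, -, . (got {self.strand!r})"
            )
        if self.start > self.end:
            raise CatalogValidationError(
                f"interval start {self.start} > end {self.end}"
            )
        if self.start < 0:
            raise CatalogValidationError(f"negative coordinate {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptRecord:
    """An exon chain on one chromosome and strand.

    Exons are normalized on construction: sorted by start and required to be
    non-overlapping, all on the same chromosome and strand. The genomic span
    runs from the first exon start to the last exon end.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    source: str = "novel"

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise CatalogValidationError("transcript_id must be non-empty")
        if not self.exons:
            raise CatalogValidationError(
                f"{self.transcript_id}: transcript needs at least one exon"
            )
        if self.source not in ("reference", "novel"):
            raise CatalogValidationError(
                f"{self.transcript_id}: source must be 'reference' or 'novel'"
            )
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise CatalogValidationError(
                f"{self.transcript_id}: exons mix chromosomes or strands "
                f"({sorted(chroms)}, {sorted(strands)})"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise CatalogValidationError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class TranscriptCatalog:
    """A set of transcripts with unique ids, e.g. one assembly run or one
    reference annotation."""

    genome_tag: str = ""
    _records: dict[str, TranscriptRecord] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[TranscriptRecord], genome_tag: str = ""
    ) -> "TranscriptCatalog":
        cat = cls(genome_tag=genome_tag)
        for rec in records:
            cat.add(rec)
        return cat

    def add(self, rec: TranscriptRecord) -> None:
        if rec.transcript_id in self._records:
            raise CatalogValidationError(
                f"duplicate transcript_id {rec.transcript_id!r}"
            )
        self._records[rec.transcript_id] = rec
        self._span_index = None

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self._records.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._records

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        return self._records[transcript_id]

    @property
    def transcript_ids(self) -> set[str]:
        return set(self._records)

    # -- span index -------------------------------------------------------
    # Per-chromosome sorted span arrays, rebuilt lazily after mutation; used
    # by neighbor_distance / classify_location so a whole-catalog screen is
    # O(n log m) rather than O(n m).
    _span_index: Mapping[str, dict] | None = field(
        default=None, repr=False, compare=False
    )

    def span_index(self) -> Mapping[str, dict]:
        if self._span_index is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for rec in self:
                s = rec.span
                by_chrom.setdefault(rec.chrom, []).append((s.start, s.end))
            index = {}
            for chrom, spans in by_chrom.items():
                spans.sort()
                starts = np.array([s for s, _ in spans], dtype=np.int64)
                ends = np.array([e for _, e in spans], dtype=np.int64)
                index[chrom] = {
                    "starts": starts,
                    "ends_by_start": ends,
                    # running max of ends in start order: overlap queries
                    "max_end_prefix": np.maximum.accumulate(ends),
                    "ends_sorted": np.sort(ends),
                }
            self._span_index = index
        return self._span_index


class LocationClass(enum.Enum):
    """Where a transcript lies relative to an annotation: overlapping any
    annotated transcript span (strand-agnostic, 1 bp suffices) or strictly
    between annotated features."""

    INTERGENIC = "intergenic"
    GENIC_OVERLAP = "genic_overlap"


# ---------------------------------------------------------------------------
# geometry


def transcript_length(t: TranscriptRecord) -> int:
    """Spliced length in bp: the sum of exon lengths, not the genomic span."""
    return t.spliced_length


def _span_overlaps_annotation(span: GenomicInterval, index: Mapping) -> bool:
    chrom_idx = index.get(span.chrom)
    if chrom_idx is None:
        return False
    i = int(np.searchsorted(chrom_idx["starts"], span.end, side="left"))
    # any span starting before our end whose end reaches past our start
    return i > 0 and int(chrom_idx["max_end_prefix"][i - 1]) > span.start


def neighbor_distance(t: TranscriptRecord, annotation: TranscriptCatalog) -> int:
    """Bases strictly between the span of ``t`` and its nearest annotated span.

    The minimum is over all annotated transcript spans on the same chromosome
    regardless of strand or biotype. Overlap or abutment gives 0; a
    chromosome with no annotated transcript gives :data:`NO_NEIGHBOR`
    (treated as an infinite gap by the candidate filter).
    """
    span = t.span
    index = annotation.span_index()
    chrom_idx = index.get(span.chrom)
    if chrom_idx is None:
        return NO_NEIGHBOR
    if _span_overlaps_annotation(span, index):
        return 0
    gaps = []
    starts = chrom_idx["starts"]
    i = int(np.searchsorted(starts, span.end, side="left"))
    if i < len(starts):  # nearest annotated span to the right
        gaps.append(int(starts[i]) - span.end)
    ends = chrom_idx["ends_sorted"]
    j = int(np.searchsorted(ends, span.start, side="right"))
    if j > 0:  # nearest annotated span ending at/left of our start
        gaps.append(span.start - int(ends[j - 1]))
    if not gaps:
        return NO_NEIGHBOR
    return max(0, min(gaps))


def classify_location(
    t: TranscriptRecord, annotation: TranscriptCatalog
) -> LocationClass:
    """GENIC_OVERLAP if the transcript span overlaps any annotated span
    (strand-agnostic), else INTERGENIC."""
    if _span_overlaps_annotation(t.span, annotation.span_index()):
        return LocationClass.GENIC_OVERLAP
    return LocationClass.INTERGENIC


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path, source: str = "novel") -> TranscriptCatalog:
    """Read exon features from a GTF 2.2 file into a catalog.

    One :class:`TranscriptRecord` per distinct ``transcript_id``; non-exon
    feature lines contribute no geometry. Attribute values may be quoted or
    bare (Cufflinks dialects vary). Coordinates convert from 1-based
    inclusive to the internal 0-based half-open convention.
    """
    path = Path(path)
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    gene_by_tx: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                feat = feature_from_line(line)
                start1, end1 = int(fields[3]), int(fields[4])
            except Exception as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            if "transcript_id" not in feat.attributes:
                raise GtfParseError(
                    f"{path}:{lineno}: exon feature lacks a transcript_id "
                    "attribute"
                )
            tid = feat.attributes["transcript_id"][0]
            gid = (
                feat.attributes["gene_id"][0]
                if "gene_id" in feat.attributes
                else tid
            )
            strand = feat.strand if feat.strand in VALID_STRANDS else "."
            try:
                exon = GenomicInterval(feat.seqid, start1 - 1, end1, strand)
            except CatalogValidationError as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            if tid not in exons_by_tx:
                order.append(tid)
            exons_by_tx.setdefault(tid, []).append(exon)
            gene_by_tx.setdefault(tid, gid)
    catalog = TranscriptCatalog(genome_tag=path.name)
    for tid in order:
        try:
            catalog.add(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_id=gene_by_tx[tid],
                    exons=tuple(exons_by_tx[tid]),
                    source=source,
                )
            )
        except CatalogValidationError as exc:
            raise CatalogValidationError(f"{path}: {exc}") from exc
    return catalog


def write_gtf(catalog: TranscriptCatalog, path: str | Path) -> None:
    """Write one GTF exon line per exon, 1-based inclusive coordinates."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in catalog:
            for exon in rec.exons:
                attrs = (
                    f'gene_id "{rec.gene_id}"; '
                    f'transcript_id "{rec.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "lincrip",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED12


def write_bed(catalog: TranscriptCatalog, path: str | Path) -> None:
    """Write BED12, one record per transcript, exon chain as blocks."""
    path = Path(path)
    try:
        fh = open(path, "w")
    except OSError as exc:
        raise OSError(f"cannot write BED to {path}: {exc}") from exc
    with fh:
        for rec in catalog:
            span = rec.span
            sizes = ",".join(str(len(e)) for e in rec.exons)
            offsets = ",".join(str(e.start - span.start) for e in rec.exons)
            fh.write(
                "\t".join(
                    [
                        span.chrom,
                        str(span.start),
                        str(span.end),
                        rec.transcript_id,
                        "0",
                        span.strand if span.strand != "." else ".",
                        str(span.start),
                        str(span.start),
                        "0",
                        str(len(rec.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path, source: str = "novel") -> TranscriptCatalog:
    """Read BED12 records written by :func:`write_bed` back into a catalog."""
    path = Path(path)
    catalog = TranscriptCatalog(genome_tag=path.name)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GtfParseError(
                    f"{path}:{lineno}: BED12 needs 12 fields, got {len(fields)}"
                )
            chrom, start, _end, name, _score, strand = fields[:6]
            start = int(start)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise GtfParseError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            exons = tuple(
                GenomicInterval(
                    chrom, start + off, start + off + size,
                    strand if strand in VALID_STRANDS else ".",
                )
                for off, size in zip(offsets, sizes)
            )
            catalog.add(
                TranscriptRecord(
                    transcript_id=name, gene_id=name, exons=exons, source=source
                )
            )
    return catalog
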