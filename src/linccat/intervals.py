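"""Genomic coordinate primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention). Strand is one of
``"+"``, ``"-"`` or ``"."`` (ambiguous). Ambiguous strand is a first-class
value: strand-aware filters treat it as matching both strands, and
strand-blind filters ignore it entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

PLUS = "+"
MINUS = "-"
AMBIGUOUS = "."

_STRANDS = frozenset((PLUS, MINUS, AMBIGUOUS))


class BedParseError(ValueError):
    """Raised for malformed BED records; carries the offending line number."""


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) half-open intervals: sorted, disjoint, non-abutting."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    base: Sequence[tuple[int, int]], minus: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference base \\ minus for sorted disjoint interval lists."""
    out: list[tuple[int, int]] = []
    minus = sorted(minus)
    j = 0
    for s, e in sorted(base):
        cur = s
        while j < len(minus) and minus[j][1] <= cur:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < e:
            ms, me = minus[k]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if me >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two sorted disjoint interval lists."""
    out = []
    i = j = 0
    a = sorted(a)
    b = sorted(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass(frozen=True)
class GenomicInterval:
    """A located, optionally stranded interval (BED convention carrier)."""

    chrom: str
    start: int
    end: int
    strand: str = AMBIGUOUS
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def exon_overlap_bp(a: GenomicInterval | tuple, b: GenomicInterval | tuple) -> int:
    """Overlap in bp between two intervals; 0 on different chromosomes.

    Accepts GenomicInterval or bare (start, end) tuples (same-chromosome
    assumed for the latter).
    """
    if isinstance(a, GenomicInterval) and isinstance(b, GenomicInterval):
        if a.chrom != b.chrom:
            return 0
        return max(0, min(a.end, b.end) - max(a.start, b.start))
    s1, e1 = (a.start, a.end) if isinstance(a, GenomicInterval) else a
    s2, e2 = (b.start, b.end) if isinstance(b, GenomicInterval) else b
    return max(0, min(e1, e2) - max(s1, s2))


@dataclass
class TranscriptModel:
    """A blocked genomic transcript: the unit flowing through every filter.

    ``exons`` are normalized on construction to a sorted union (assemblers
    emit abutting/overlapping blocks; downstream math assumes disjoint exons).
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        self.exons = merge_intervals(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def exonic_length(self) -> int:
        return total_length(self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def span_overlap_bp(self, other: "TranscriptModel") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class ReadAlignment:
    """A blocked read placement; split reads (junction spanning) have >=2 blocks."""

    chrom: str
    blocks: list[tuple[int, int]]
    strand: str = AMBIGUOUS
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read with no blocks")
        self.blocks = merge_intervals(self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def is_split(self) -> bool:
        return len(self.blocks) >= 2


@dataclass
class GenomeSpec:
    """Chromosome sizes plus the uniquely-mappable mask.

    The mask lists, per chromosome, the sorted disjoint regions to which
    short reads can map uniquely; all genome-coverage fractions are computed
    within it.
    """

    chromosomes: list[tuple[str, int]]
    mappability_mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        for chrom, ivs in self.mappability_mask.items():
            if chrom not in sizes:
                raise ValueError(f"mask on unknown chromosome {chrom}")
            merged = merge_intervals(ivs)
            if merged and (merged[0][0] < 0 or merged[-1][1] > sizes[chrom]):
                raise ValueError(f"mask outside chromosome {chrom}")
            self.mappability_mask[chrom] = merged

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genome_size(self) -> int:
        return sum(n for _, n in self.chromosomes)

    @property
    def mappable_size(self) -> int:
        return sum(total_length(v) for v in self.mappability_mask.values())


def gap_distance(a: TranscriptModel, b: TranscriptModel) -> float:
    """Span gap in bp; 0 if spans overlap; infinite across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end)


def interval_gap_distance(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> float:
    """gap_distance for bare (chrom, start, end) triples."""
    if a[0] != b[0]:
        return math.inf
    if a[1] < b[2] and b[1] < a[2]:
        return 0
    return max(a[1] - b[2], b[1] - a[2])


# ---------------------------------------------------------------------------
# BED readers / writers
# ---------------------------------------------------------------------------

def parse_bed12(line: str, line_number: int = 0) -> TranscriptModel:
    """Parse one BED12 line into a TranscriptModel.

    Strand ``.`` maps to ambiguous. Raises :class:`BedParseError` naming the
    line number for malformed records.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 12:
        raise BedParseError(
            f"line {line_number}: expected 12 tab-separated fields, got {len(fields)}"
        )
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        chrom_end = int(fields[2])
        name = fields[3]
        strand = fields[5]
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise BedParseError(f"line {line_number}: {exc}") from exc
    if strand not in _STRANDS:
        raise BedParseError(f"line {line_number}: invalid strand {strand!r}")
    if len(sizes) != block_count or len(starts) != block_count:
        raise BedParseError(
            f"line {line_number}: blockCount {block_count} but "
            f"{len(sizes)} sizes / {len(starts)} starts"
        )
    if any(s <= 0 for s in sizes):
        raise BedParseError(f"line {line_number}: non-positive block size")
    exons = []
    for off, size in zip(starts, sizes):
        s = chrom_start + off
        e = s + size
        if e > chrom_end or s < chrom_start:
            raise BedParseError(f"line {line_number}: block outside chromStart/End")
        exons.append((s, e))
    return TranscriptModel(id=name, chrom=chrom, strand=strand, exons=exons)


def write_bed12(t: TranscriptModel, score: int = 0) -> str:
    """One canonical BED12 line (tab-separated, no trailing newline)."""
    sizes = ",".join(str(e - s) for s, e in t.exons)
    starts = ",".join(str(s - t.start) for s, e in t.exons)
    return "\t".join(
        [
            t.chrom,
            str(t.start),
            str(t.end),
            t.id,
            str(score),
            t.strand,
            str(t.start),
            str(t.end),
            "0",
            str(len(t.exons)),
            sizes,
            starts,
        ]
    )


def read_bed12_file(path) -> list[TranscriptModel]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip() and not line.startswith(("#", "track")):
                out.append(parse_bed12(line, line_number=i))
    return out


def write_bed12_file(path, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(write_bed12(t) + "\n")


def parse_bed_interval(line: str, line_number: int = 0) -> GenomicInterval:
    """Parse a BED3/BED6 line into a GenomicInterval."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {line_number}: expected >=3 fields")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {line_number}: {exc}") from exc
    name = fields[3] if len(fields) > 3 else ""
    strand = fields[5] if len(fields) > 5 else AMBIGUOUS
    return GenomicInterval(fields[0], start, end, strand=strand, name=name)


def read_bed_file(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip() and not line.startswith(("#", "track")):
                out.append(parse_bed_interval(line, line_number=i))
    return out


def write_bed_file(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )
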