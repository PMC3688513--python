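"""Full-assignment read counting and FPKM computation.

Candidate transcript sets contain many redundant, partially-overlapping
models of the same underlying transcript. Reads mapping to shared exonic
sequence are therefore counted as a *full* read for every overlapping
transcript, never split fractionally — otherwise redundant annotations would
dilute each other's expression estimates below the FPKM threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import ReadAlignment, TranscriptModel


@dataclass
class DatasetInfo:
    """Per-dataset metadata used for FPKM normalization.

    ``total_mapped_reads`` mirrors a flagstat total for the whole dataset;
    it may exceed the number of reads actually supplied when counting is run
    on a regional subset.
    """

    dataset_id: str
    library_type: str
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads < 1:
            raise ValueError("total_mapped_reads must be >= 1")


class ExonIndex:
    """Per-chromosome interval index over transcript exons."""

    def __init__(self, transcripts: Iterable[TranscriptModel], strict_strand: bool = False):
        self._trees: dict[str, IntervalTree] = {}
        self._strands: dict[str, str] = {}
        self.strict_strand = strict_strand
        for t in transcripts:
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            self._strands[t.id] = t.strand
            for s, e in t.exons:
                tree.addi(s, e, t.id)

    def overlapping(self, read: ReadAlignment) -> set[str]:
        """Ids of transcripts whose exons overlap any aligned block by >=1 bp."""
        tree = self._trees.get(read.chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for s, e in read.blocks:
            for iv in tree.overlap(s, e):
                hits.add(iv.data)
        if self.strict_strand and read.strand != ".":
            hits = {
                h for h in hits
                if self._strands[h] == "." or self._strands[h] == read.strand
            }
        return hits


def count_reads_full_assignment(
    reads: Iterable[ReadAlignment],
    transcripts: Sequence[TranscriptModel],
    strict_strand: bool = False,
) -> dict[str, int]:
    """Count reads per transcript with full assignment of shared reads.

    A read increments the count of every transcript whose exons its aligned
    blocks overlap by at least one base. A read whose blocks fall entirely
    within introns of a transcript does not count for it. Reads overlapping
    no transcript are ignored.
    """
    index = ExonIndex(transcripts, strict_strand=strict_strand)
    counts = {t.id: 0 for t in transcripts}
    for read in reads:
        for tid in index.overlapping(read):
            counts[tid] += 1
    return counts


def fpkm(count: int, exonic_length: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if exonic_length < 1 or total_mapped < 1:
        raise ValueError("exonic_length and total_mapped must be >= 1")
    return count * 1e9 / (exonic_length * total_mapped)


@dataclass
class ExpressionMatrix:
    """Transcripts x datasets counts and FPKMs with per-dataset totals."""

    counts: pd.DataFrame  # rows: transcript ids, columns: dataset ids
    fpkm: pd.DataFrame
    datasets: list[DatasetInfo]

    def max_fpkm(self) -> pd.Series:
        return self.fpkm.max(axis=1)

    def to_tsv(self, counts_path, fpkm_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="transcript_id")
        self.fpkm.to_csv(fpkm_path, sep="\t", index_label="transcript_id", float_format="%.6g")


def build_expression_matrix(
    reads_by_dataset: Mapping[str, Sequence[ReadAlignment]],
    transcripts: Sequence[TranscriptModel],
    datasets: Sequence[DatasetInfo],
) -> ExpressionMatrix:
    """Count every dataset against the transcript set and convert to FPKM."""
    lengths = {t.id: t.exonic_length for t in transcripts}
    ids = [t.id for t in transcripts]
    count_cols = {}
    fpkm_cols = {}
    for ds in datasets:
        counts = count_reads_full_assignment(
            reads_by_dataset.get(ds.dataset_id, ()), transcripts
        )
        count_cols[ds.dataset_id] = [counts[i] for i in ids]
        fpkm_cols[ds.dataset_id] = [
            fpkm(counts[i], lengths[i], ds.total_mapped_reads) for i in ids
        ]
    return ExpressionMatrix(
        counts=pd.DataFrame(count_cols, index=ids),
        fpkm=pd.DataFrame(fpkm_cols, index=ids),
        datasets=list(datasets),
    )


TIER_THRESHOLDS = (1.0, 10.0, 30.0)
TIER_NAMES = ("fpkm1", "fpkm10", "fpkm30")


def expression_tiers(matrix: ExpressionMatrix) -> dict[str, str]:
    """Assign each transcript its expression tier from its max-dataset FPKM.

    Tiers use strict comparisons (FPKM exactly 1.0 fails) and are nested:
    every fpkm30 transcript is also a member of the fpkm10 and fpkm1 sets.
    The returned label is the highest tier attained, or ``"fail"``.
    """
    tiers = {}
    for tid, mx in matrix.max_fpkm().items():
        label = "fail"
        for thr, name in zip(TIER_THRESHOLDS, TIER_NAMES):
            if mx > thr:
                label = name
        tiers[tid] = label
    return tiers


def tier_members(tiers: Mapping[str, str], tier: str) -> set[str]:
    """Inclusive membership: tier_members(..., 'fpkm1') contains fpkm30 transcripts."""
    order = {name: i for i, name in enumerate(TIER_NAMES)}
    if tier not in order:
        raise ValueError(f"unknown tier {tier!r}")
    want = order[tier]
    return {
        tid for tid, label in tiers.items()
        if label != "fail" and order[label] >= want
    }
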