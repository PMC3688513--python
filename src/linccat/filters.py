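"""The six-stage filter cascade reducing candidate transcripts to putative
long intergenic noncoding RNAs (lincRNAs).

Stage order (fixed):

1. length            — exonic (mature) length < 200 nt removed
2. proximity         — within 1 kb of a protein-coding gene on the same
                       strand (ambiguous strand matches both); opposite
                       strand removed only on >=1 bp span overlap
3. annotation        — >=1 bp span overlap with any non-lincRNA annotation
                       (other genes, pseudogenes, small ncRNAs, UTR
                       extensions), strand-blind
4. large_orf         — transcripts with a putative large ORF, then (second
                       pass) transcripts overlapping a large-ORF transcript
5. extended_gene     — >=1 bp span overlap with extended protein-coding
                       gene boundaries, strand-blind
6. expression        — max FPKM <= 1 across all datasets removed

Every removal is recorded with its stage and reason, mirroring per-stage
filtering statistics bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .expression import ExpressionMatrix, expression_tiers, tier_members
from .intervals import GenomicInterval, TranscriptModel, gap_distance
from .orf import OrfCall, find_large_orfs

STAGES = (
    "length",
    "proximity",
    "annotation",
    "large_orf",
    "extended_gene",
    "expression",
)

MIN_LENGTH_NT = 200
PROXIMITY_BP = 1000


@dataclass
class AnnotationCatalog:
    """Named annotation sets consumed by the cascade.

    ``protein_coding`` are transcript models (strand matters for the
    proximity rule); the other sets are plain intervals used strand-blind.
    """

    protein_coding: list[TranscriptModel] = field(default_factory=list)
    non_lincRNA_other: list[GenomicInterval] = field(default_factory=list)
    utr_extensions: list[GenomicInterval] = field(default_factory=list)
    extended_gene_boundaries: list[GenomicInterval] = field(default_factory=list)


@dataclass
class FilterReport:
    """Per-transcript fate and per-stage removal counts."""

    removed: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (stage, reason)
    retained: list[str] = field(default_factory=list)
    n_input: int = 0

    def stage_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STAGES}
        for stage, _ in self.removed.values():
            counts[stage] += 1
        return counts

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tfate\tstage\treason\n")
            for tid in self.retained:
                fh.write(f"{tid}\tretained\t.\t.\n")
            for tid, (stage, reason) in sorted(self.removed.items()):
                fh.write(f"{tid}\tremoved\t{stage}\t{reason}\n")


def filter_length(t: TranscriptModel, min_length: int = MIN_LENGTH_NT) -> bool:
    """Keep iff exonic length >= 200 nt (RNA length, not genomic span)."""
    return t.exonic_length >= min_length


def filter_protein_gene_proximity(
    t: TranscriptModel,
    protein_coding: Sequence[TranscriptModel],
    proximity_bp: int = PROXIMITY_BP,
) -> bool:
    """Keep unless too close to (or overlapping) a protein-coding gene.

    Same-strand or strand-ambiguous transcripts are removed when within
    ``proximity_bp`` (inclusive; overlap counts as distance 0). Transcripts
    on the definite opposite strand are removed only if they overlap the
    gene span by at least one base.
    """
    for gene in protein_coding:
        d = gap_distance(t, gene)
        same_side = (
            t.strand == "."
            or gene.strand == "."
            or t.strand == gene.strand
        )
        if same_side:
            if d <= proximity_bp:
                return False
        else:
            if d == 0:  # opposite strand: overlap by >=1 base
                return False
    return True


def _span_tree(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    return trees


def _span_overlaps(t: TranscriptModel, trees: Mapping[str, IntervalTree]) -> bool:
    tree = trees.get(t.chrom)
    return bool(tree is not None and tree.overlap(t.start, t.end))


def filter_annotation_overlap(
    t: TranscriptModel,
    non_lincRNA_other: Sequence[GenomicInterval],
    utr_extensions: Sequence[GenomicInterval],
) -> bool:
    """Keep unless the transcript span overlaps any listed annotation by
    >=1 bp, regardless of strandedness."""
    return not (
        _span_overlaps(t, _span_tree(non_lincRNA_other))
        or _span_overlaps(t, _span_tree(utr_extensions))
    )


def filter_extended_genes(
    t: TranscriptModel, extended_gene_boundaries: Sequence[GenomicInterval]
) -> bool:
    """Keep unless the span overlaps an extended gene boundary (strand-blind)."""
    return not _span_overlaps(t, _span_tree(extended_gene_boundaries))


def filter_large_orf_and_neighbors(
    transcripts: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
) -> tuple[list[TranscriptModel], dict[str, str], list[TranscriptModel]]:
    """Two-pass coding-potential filter.

    Pass 1 removes transcripts carrying a putative large ORF in any of six
    reading frames. Pass 2 removes remaining transcripts whose genomic span
    overlaps (>=1 bp, strand-blind) a pass-1 transcript — these are likely
    UTR fragments of the same coding unit. Removal is non-transitive: a
    transcript overlapping only a pass-2 victim survives.

    Returns (kept, removed_reasons, large_orf_transcripts); the last is
    exported as a resource of potential novel coding genes.
    """
    orf_positive: list[TranscriptModel] = []
    survivors: list[TranscriptModel] = []
    removed: dict[str, str] = {}
    for t in transcripts:
        if t.id not in sequences:
            raise KeyError(f"no sequence for transcript {t.id}")
        if find_large_orfs(sequences[t.id]):
            orf_positive.append(t)
            removed[t.id] = "large_orf"
        else:
            survivors.append(t)
    orf_trees: dict[str, IntervalTree] = {}
    for t in orf_positive:
        orf_trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.id)
    kept = []
    for t in survivors:
        tree = orf_trees.get(t.chrom)
        if tree is not None and tree.overlap(t.start, t.end):
            removed[t.id] = "orf_neighbor"
        else:
            kept.append(t)
    return kept, removed, orf_positive


def filter_expression(
    transcripts: Sequence[TranscriptModel], matrix: ExpressionMatrix
) -> tuple[dict[str, set[str]], set[str]]:
    """Split transcripts into nested expression-tier sets and a removed set.

    Removed transcripts are those never exceeding FPKM 1 in any dataset
    (strict >). Returns ({tier -> member ids}, removed ids); tier sets are
    inclusive: fpkm1 contains fpkm10 contains fpkm30.
    """
    missing = [t.id for t in transcripts if t.id not in matrix.fpkm.index]
    if missing:
        raise KeyError(f"transcripts missing from expression matrix: {missing[:5]}")
    ids = {t.id for t in transcripts}
    tiers = {
        tid: lab for tid, lab in expression_tiers(matrix).items() if tid in ids
    }
    kept = {
        tier: tier_members(tiers, tier) for tier in ("fpkm1", "fpkm10", "fpkm30")
    }
    removed = {tid for tid, lab in tiers.items() if lab == "fail"}
    return kept, removed


def run_cascade(
    transcripts: Sequence[TranscriptModel],
    catalog: AnnotationCatalog,
    sequences: Mapping[str, str],
    matrix: ExpressionMatrix,
    min_length: int = MIN_LENGTH_NT,
    proximity_bp: int = PROXIMITY_BP,
) -> tuple[dict[str, list[TranscriptModel]], FilterReport, list[TranscriptModel]]:
    """Run all six stages in order and report per-stage provenance.

    Returns ({tier -> surviving transcripts}, report, large_orf_transcripts).
    The report's retained list corresponds to the fpkm1 tier.
    """
    report = FilterReport(n_input=len(transcripts))
    current = []
    for t in transcripts:
        if filter_length(t, min_length=min_length):
            current.append(t)
        else:
            report.removed[t.id] = ("length", f"exonic_length={t.exonic_length}<{min_length}")

    nxt = []
    for t in current:
        if filter_protein_gene_proximity(
            t, catalog.protein_coding, proximity_bp=proximity_bp
        ):
            nxt.append(t)
        else:
            report.removed[t.id] = ("proximity", "within 1 kb of protein-coding gene")
    current = nxt

    other_trees = _span_tree(catalog.non_lincRNA_other)
    utr_trees = _span_tree(catalog.utr_extensions)
    nxt = []
    for t in current:
        if _span_overlaps(t, other_trees):
            report.removed[t.id] = ("annotation", "overlaps non-lincRNA annotation")
        elif _span_overlaps(t, utr_trees):
            report.removed[t.id] = ("annotation", "overlaps UTR extension")
        else:
            nxt.append(t)
    current = nxt

    current, orf_removed, large_orf_set = filter_large_orf_and_neighbors(
        current, sequences
    )
    for tid, reason in orf_removed.items():
        report.removed[tid] = ("large_orf", reason)

    ext_trees = _span_tree(catalog.extended_gene_boundaries)
    nxt = []
    for t in current:
        if _span_overlaps(t, ext_trees):
            report.removed[t.id] = ("extended_gene", "overlaps extended gene boundary")
        else:
            nxt.append(t)
    current = nxt

    kept_ids, removed_ids = filter_expression(current, matrix)
    for tid in removed_ids:
        report.removed[tid] = ("expression", "max FPKM <= 1 in all datasets")
    by_id = {t.id: t for t in current}
    tiered = {
        tier: [by_id[tid] for tid in sorted(ids_, key=lambda i: (by_id[i].chrom, by_id[i].start))]
        for tier, ids_ in kept_ids.items()
    }
    report.retained = [t.id for t in tiered["fpkm1"]]
    return tiered, report, large_orf_set
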