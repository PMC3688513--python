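"""Empirical test of whether a lincRNA is expressed above random intergenic
background.

The background space is the uniquely-mappable genome minus every annotation
carrying evidence of transcription. Size-matched annotations (the query's
exact block structure) are shuffled uniformly across that space, their
FPKMs computed with the same full-assignment counting, and the observed
FPKM is ranked against this dataset-specific null. P-values use the
add-one permutation estimator and are Bonferroni-corrected across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import DatasetInfo, count_reads_full_assignment, fpkm
from .intervals import (
    GenomeSpec,
    GenomicInterval,
    ReadAlignment,
    TranscriptModel,
    merge_intervals,
    subtract_intervals,
)

MIN_BACKGROUND_BP = 200  # background loci must be longer than 200 bp
DEFAULT_ALPHA = 0.1


@dataclass
class BackgroundSpace:
    """Eligible intergenic intervals per chromosome (sorted, disjoint)."""

    intervals: dict[str, list[tuple[int, int]]]

    @property
    def total_bp(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def flat(self) -> list[tuple[str, int, int]]:
        return [
            (c, s, e)
            for c in sorted(self.intervals)
            for s, e in self.intervals[c]
        ]


def build_background_space(
    genome: GenomeSpec,
    exclusions: Mapping[str, Sequence[tuple[int, int]]],
    min_bp: int = MIN_BACKGROUND_BP,
) -> BackgroundSpace:
    """Mappable mask minus the exclusion union; intervals <= min_bp dropped."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, mask in genome.mappability_mask.items():
        excl = merge_intervals(exclusions.get(chrom, [])) if exclusions.get(chrom) else []
        remaining = subtract_intervals(mask, excl)
        keep = [(s, e) for s, e in remaining if e - s > min_bp]
        if keep:
            out[chrom] = keep
    if not out:
        raise ValueError("exclusions cover the entire mappable genome")
    return BackgroundSpace(intervals=out)


def shuffle_annotation(
    t: TranscriptModel, space: BackgroundSpace, rng: np.random.Generator
) -> TranscriptModel:
    """Place t's full block structure at a uniformly chosen eligible start.

    Uniform over all valid start positions across all chromosomes' eligible
    intervals (no per-chromosome constraint); exon lengths and gaps are
    preserved exactly.
    """
    span = t.end - t.start
    slots = [
        (chrom, s, e - s - span + 1)
        for chrom, s, e in space.flat()
        if e - s >= span
    ]
    total = sum(n for _, _, n in slots)
    if total == 0:
        raise ValueError(
            f"no eligible background interval can contain a {span}-bp annotation"
        )
    pick = int(rng.integers(total))
    for chrom, s, n in slots:
        if pick < n:
            new_start = s + pick
            break
        pick -= n
    shift = new_start - t.start
    return TranscriptModel(
        id=f"{t.id}__shuffle",
        chrom=chrom,
        strand=t.strand,
        exons=[(s + shift, e + shift) for s, e in t.exons],
        source_tag="shuffled",
    )


@dataclass
class NullDistribution:
    """Sorted null FPKMs for one RNA-seq dataset."""

    dataset_id: str
    values: np.ndarray

    @property
    def n_shuffles(self) -> int:
        return self.values.size


def build_null_distribution(
    templates: Sequence[TranscriptModel],
    space: BackgroundSpace,
    reads: Sequence[ReadAlignment],
    dataset: DatasetInfo,
    n_shuffles: int,
    rng: np.random.Generator,
) -> NullDistribution:
    """Shuffle size-matched annotations (sampled from the query templates)
    across the background space and record their FPKMs."""
    placed = []
    for i in range(n_shuffles):
        template = templates[int(rng.integers(len(templates)))]
        s = shuffle_annotation(template, space, rng)
        s.id = f"null_{i}"
        placed.append(s)
    counts = count_reads_full_assignment(reads, placed)
    values = np.sort(
        np.array(
            [
                fpkm(counts[p.id], p.exonic_length, dataset.total_mapped_reads)
                for p in placed
            ]
        )
    )
    return NullDistribution(dataset_id=dataset.dataset_id, values=values)


def empirical_pvalue(observed_fpkm: float, null: NullDistribution) -> float:
    """Add-one permutation p-value: (1 + #{null >= obs}) / (1 + n)."""
    if null.n_shuffles == 0:
        raise ValueError("empty null distribution")
    n_ge = null.n_shuffles - int(np.searchsorted(null.values, observed_fpkm, side="left"))
    return (1 + n_ge) / (1 + null.n_shuffles)


def bonferroni_significant(
    pvalues: Mapping[str, float], n_datasets: int, alpha: float = DEFAULT_ALPHA
) -> tuple[bool, float, str]:
    """Bonferroni across datasets (one test per dataset).

    Returns (significant, best corrected p, dataset attaining it);
    significance requires corrected p <= alpha in at least one dataset.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    best_p = np.inf
    best_ds = ""
    for ds, p in pvalues.items():
        corrected = min(1.0, p * n_datasets)
        if corrected < best_p:
            best_p, best_ds = corrected, ds
    return best_p <= alpha, float(best_p), best_ds


def significance_table(
    catalog: Sequence[TranscriptModel],
    space: BackgroundSpace,
    reads_by_dataset: Mapping[str, Sequence[ReadAlignment]],
    datasets: Sequence[DatasetInfo],
    fpkm_matrix: pd.DataFrame,
    n_shuffles: int,
    rng: np.random.Generator,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-transcript significance vs the shuffled-intergenic null.

    One null distribution per dataset, built from n_shuffles size-matched
    placements; observed FPKMs come from the supplied matrix. Returns a
    DataFrame with per-dataset p-values, the best Bonferroni-corrected p,
    its dataset, and the significance call.
    """
    nulls = {
        ds.dataset_id: build_null_distribution(
            catalog, space, reads_by_dataset.get(ds.dataset_id, ()), ds,
            n_shuffles, rng,
        )
        for ds in datasets
    }
    rows = []
    for t in catalog:
        pvals = {
            ds.dataset_id: empirical_pvalue(
                float(fpkm_matrix.loc[t.id, ds.dataset_id]), nulls[ds.dataset_id]
            )
            for ds in datasets
        }
        sig, best_p, best_ds = bonferroni_significant(pvals, len(datasets), alpha)
        row = {"transcript_id": t.id, **{f"p_{k}": v for k, v in pvals.items()}}
        row.update(
            corrected_p=best_p, best_dataset=best_ds, significant=sig
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")


def exclusion_union_from_annotations(
    genome: GenomeSpec,
    transcript_sets: Sequence[Sequence[TranscriptModel]],
    interval_sets: Sequence[Sequence[GenomicInterval]] = (),
) -> dict[str, list[tuple[int, int]]]:
    """Union of spans of all supplied annotation sets, per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome.chromosomes}
    for tset in transcript_sets:
        for t in tset:
            by_chrom.setdefault(t.chrom, []).append(t.span)
    for iset in interval_sets:
        for iv in iset:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: merge_intervals(ivs) for c, ivs in by_chrom.items() if ivs}
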