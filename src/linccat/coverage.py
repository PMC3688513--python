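"""Genome coverage quantitation: what fraction of the uniquely-mappable
genome shows transcription, and at what depth.

Split reads (exon-exon junction spanning, >=2 blocks) can be counted in two
modes: ``including_inferred`` fills the full span of the read — the
intervening intronic bases are inferred to have been transcribed — while
``excluding_inferred`` fills only the aligned blocks. Coverage fractions in
the first mode dominate the second pointwise at every depth threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomeSpec, ReadAlignment

INCLUDING_INFERRED = "including_inferred"
EXCLUDING_INFERRED = "excluding_inferred"


@dataclass
class DepthProfile:
    """Per-chromosome read depth restricted at query time to the mask.

    Depth vectors are dense per-chromosome arrays; the mappability mask is
    applied when fractions and distributions are computed, not when reads
    are added.
    """

    depths: dict[str, np.ndarray]
    mode: str

    def masked_depths(self, genome: GenomeSpec) -> dict[str, np.ndarray]:
        """Depth values at mappable positions only (concatenated per chrom)."""
        out = {}
        for chrom, depth in self.depths.items():
            mask_ivs = genome.mappability_mask.get(chrom, [])
            if mask_ivs:
                parts = [depth[s:e] for s, e in mask_ivs]
                out[chrom] = np.concatenate(parts) if parts else np.array([], dtype=depth.dtype)
            else:
                out[chrom] = np.array([], dtype=depth.dtype)
        return out


def depth_profile(
    reads: Iterable[ReadAlignment], genome: GenomeSpec, mode: str
) -> DepthProfile:
    """Per-base read depth over the genome in the requested split-read mode."""
    if mode not in (INCLUDING_INFERRED, EXCLUDING_INFERRED):
        raise ValueError(f"unknown mode {mode!r}")
    sizes = genome.chrom_sizes
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in sizes.items()}
    for read in reads:
        if read.chrom not in sizes:
            raise ValueError(f"read on unknown chromosome {read.chrom}")
        if read.end > sizes[read.chrom]:
            raise ValueError(
                f"read beyond end of {read.chrom}: {read.end} > {sizes[read.chrom]}"
            )
        d = diffs[read.chrom]
        if mode == INCLUDING_INFERRED:
            d[read.start] += 1
            d[read.end] -= 1
        else:
            for s, e in read.blocks:
                d[s] += 1
                d[e] -= 1
    depths = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return DepthProfile(depths=depths, mode=mode)


def covered_fraction_at_thresholds(
    profile: DepthProfile, genome: GenomeSpec, thresholds: Sequence[int]
) -> dict[int, float]:
    """Fraction of mappable positions with depth >= k, per threshold k."""
    if any(k < 1 for k in thresholds):
        raise ValueError("thresholds must be >= 1")
    masked = profile.masked_depths(genome)
    total = sum(v.size for v in masked.values())
    if total == 0:
        raise ValueError("empty mappability mask")
    out = {}
    for k in thresholds:
        covered = sum(int((v >= k).sum()) for v in masked.values())
        out[k] = covered / total
    return out


def basecall_depth_distribution(
    profile: DepthProfile,
    genome: GenomeSpec,
    regions: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
) -> dict[str, dict[int, int]]:
    """Depth-weighted base distribution per region label.

    For each label (e.g. exon / intron / intergenic) and depth d >= 1,
    base calls = (number of mappable positions in the label at depth d) x d.
    ``regions`` maps label -> chrom -> interval list.
    """
    out: dict[str, dict[int, int]] = {}
    for label, by_chrom in regions.items():
        dist: dict[int, int] = {}
        for chrom, ivs in by_chrom.items():
            depth = profile.depths.get(chrom)
            if depth is None:
                continue
            mask = np.zeros(depth.size, dtype=bool)
            for s, e in genome.mappability_mask.get(chrom, []):
                mask[s:e] = True
            sel = np.zeros(depth.size, dtype=bool)
            for s, e in ivs:
                sel[s:e] = True
            vals = depth[sel & mask]
            if vals.size:
                counts = np.bincount(vals)
                for d in np.nonzero(counts)[0]:
                    if d >= 1:
                        dist[int(d)] = dist.get(int(d), 0) + int(counts[d]) * int(d)
        out[label] = dist
    return out


def annotation_union_coverage(
    profile: DepthProfile,
    genome: GenomeSpec,
    annotation_spans: Mapping[str, Sequence[tuple[int, int]]],
    min_depth: int = 1,
) -> float:
    """Fraction of the mappable genome covered by reads OR annotation spans.

    Annotation spans include introns (full gene/EST/cDNA structures); the
    union answers "what fraction of the mappable genome has any evidence of
    transcription".
    """
    total = 0
    covered = 0
    for chrom, size in genome.chrom_sizes.items():
        mask = np.zeros(size, dtype=bool)
        for s, e in genome.mappability_mask.get(chrom, []):
            mask[s:e] = True
        total += int(mask.sum())
        ev = np.zeros(size, dtype=bool)
        depth = profile.depths.get(chrom)
        if depth is not None:
            ev |= depth >= min_depth
        for s, e in annotation_spans.get(chrom, []):
            ev[s:e] = True
        covered += int((ev & mask).sum())
    if total == 0:
        raise ValueError("empty mappability mask")
    return covered / total


def read_region_distribution(
    reads_by_dataset: Mapping[str, Sequence[ReadAlignment]],
    coding_exons: Mapping[str, Sequence[tuple[int, int]]],
    chrom_sizes: Mapping[str, int],
) -> dict[str, tuple[float, float]]:
    """Per-dataset fraction of reads in flattened coding exons vs elsewhere.

    Isoforms are flattened (union of exons per gene set) before counting, so
    a read is attributed once regardless of how many isoforms it touches. A
    read counts as exonic if any aligned block overlaps a coding-exon base.
    Returns dataset -> (exonic_fraction, intronic_intergenic_fraction),
    summing to 1.
    """
    flags = {
        c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()
    }
    for chrom, ivs in coding_exons.items():
        for s, e in ivs:
            flags[chrom][s:e] = True
    out = {}
    for ds, reads in reads_by_dataset.items():
        n = 0
        exonic = 0
        for read in reads:
            n += 1
            flag = flags.get(read.chrom)
            if flag is not None and any(flag[s:e].any() for s, e in read.blocks):
                exonic += 1
        if n == 0:
            out[ds] = (0.0, 0.0)
        else:
            out[ds] = (exonic / n, (n - exonic) / n)
    return out


def write_bedgraph(path, profile: DepthProfile) -> None:
    """Run-length encoded bedGraph of nonzero depth."""
    with open(path, "w") as fh:
        for chrom in sorted(profile.depths):
            depth = profile.depths[chrom]
            if depth.size == 0:
                continue
            change = np.nonzero(np.diff(depth))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depth.size]))
            for s, e in zip(starts, ends):
                v = int(depth[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
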