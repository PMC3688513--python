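"""Downstream characterization of the lincRNA catalog: ribosome engagement,
sequence conservation, trait-associated SNP enrichment, polyadenylation
bimorphism, chromatin signal, transcript-end support, and tissue clustering.

Window-based scores (ribosome ratio, conservation) are computed in
transcript (spliced) coordinates and projected to genomic exon blocks, so
windows never straddle introns in genome space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.proportion import proportion_confint

from .expression import count_reads_full_assignment
from .intervals import GenomeSpec, ReadAlignment, TranscriptModel

# Fractional contribution of genotyping platforms to the GWAS catalog,
# used to scale tested-SNP denominators.
W_ILLUMINA = 0.586
W_AFFYMETRIX = 0.414

RIBO_WINDOW = 30
CONS_WINDOW = 50


class SpanIndex:
    """Per-chromosome index for pulling reads near a transcript span.

    Window counting scans every supplied read; this narrows the scan to
    reads that can possibly overlap the transcript.
    """

    def __init__(self, reads: Sequence[ReadAlignment]):
        by_chrom: dict[str, list[ReadAlignment]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
        self._starts: dict[str, np.ndarray] = {}
        self._reads: dict[str, list[ReadAlignment]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: r.start)
            self._reads[chrom] = rs
            self._starts[chrom] = np.array([r.start for r in rs])
            self._max_len[chrom] = max(r.end - r.start for r in rs)

    def overlapping_span(self, chrom: str, start: int, end: int) -> list[ReadAlignment]:
        if chrom not in self._reads:
            return []
        starts = self._starts[chrom]
        lo = int(np.searchsorted(starts, start - self._max_len[chrom], side="left"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return [r for r in self._reads[chrom][lo:hi] if r.end > start]


# ---------------------------------------------------------------------------
# transcript-coordinate projection
# ---------------------------------------------------------------------------

def _to_transcript_coords(
    t: TranscriptModel, genomic: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Project genomic intervals onto the concatenated exonic coordinate."""
    out = []
    offset = 0
    for es, ee in t.exons:
        for gs, ge in genomic:
            s = max(gs, es)
            e = min(ge, ee)
            if s < e:
                out.append((offset + s - es, offset + e - es))
        offset += ee - es
    return sorted(out)


def _window_counts(
    t: TranscriptModel, reads: Sequence[ReadAlignment], window: int
) -> np.ndarray:
    """Number of reads overlapping (>=1 bp) each sliding window.

    Windows are indexed by their start in transcript coordinates,
    0 .. L - window; each read contributes at most 1 to any window.
    """
    L = t.exonic_length
    n_win = L - window + 1
    diff = np.zeros(n_win + 1, dtype=np.int64)
    for read in reads:
        if read.chrom != t.chrom:
            continue
        tx = _to_transcript_coords(t, read.blocks)
        if not tx:
            continue
        # window w overlaps read interval [s, e) iff w in [s-window+1, e-1]
        ranges = [
            (max(0, s - window + 1), min(n_win - 1, e - 1)) for s, e in tx
        ]
        ranges = [(a, b) for a, b in ranges if a <= b]
        if not ranges:
            continue
        ranges.sort()
        merged = [list(ranges[0])]
        for a, b in ranges[1:]:
            if a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            diff[a] += 1
            diff[b + 1] -= 1
    return np.cumsum(diff[:-1])


def max_window_read_ratio(
    t: TranscriptModel,
    ribo_reads: Sequence[ReadAlignment],
    rna_reads: Sequence[ReadAlignment],
    window: int = RIBO_WINDOW,
) -> float | None:
    """Maximum per-window ratio of ribosome-profiling to RNA-seq reads.

    Windows of ``window`` nt tile the spliced transcript with a 1-nt offset;
    windows with zero RNA-seq reads are skipped. Returns None when the
    transcript is shorter than one window or no window has RNA-seq coverage.
    """
    if t.exonic_length < window:
        return None
    ribo = _window_counts(t, ribo_reads, window)
    rna = _window_counts(t, rna_reads, window)
    valid = rna > 0
    if not valid.any():
        return None
    return float(np.max(ribo[valid] / rna[valid]))


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

@dataclass
class ScoreTrack:
    """Sparse per-base score track; positions without scores are NaN."""

    scores: dict[str, np.ndarray]

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: Mapping[str, int]) -> "ScoreTrack":
        arrays = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")
                arrays[chrom][int(s): int(e)] = float(v)
        return cls(scores=arrays)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.scores):
                arr = self.scores[chrom]
                present = ~np.isnan(arr)
                if not present.any():
                    continue
                idx = np.nonzero(present)[0]
                run_start = idx[0]
                for i in range(1, len(idx) + 1):
                    if (
                        i == len(idx)
                        or idx[i] != idx[i - 1] + 1
                        or arr[idx[i]] != arr[run_start]
                    ):
                        fh.write(
                            f"{chrom}\t{run_start}\t{idx[i - 1] + 1}\t{arr[run_start]:g}\n"
                        )
                        if i < len(idx):
                            run_start = idx[i]


def max_conserved_window(
    t: TranscriptModel, track: ScoreTrack, window: int = CONS_WINDOW
) -> float | None:
    """Maximum mean score over sliding windows of fully-scored exonic bases.

    All ``window`` consecutive bases of the spliced transcript must carry
    scores for a window to qualify; returns None when no window does
    (transcripts without 50 contiguous scored bases are unscored).
    """
    arr = track.scores.get(t.chrom)
    if arr is None:
        return None
    vals = np.concatenate([arr[s:e] for s, e in t.exons])
    if vals.size < window:
        return None
    present = ~np.isnan(vals)
    filled = np.where(present, vals, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    cnum = np.concatenate(([0], np.cumsum(present.astype(np.int64))))
    sums = csum[window:] - csum[:-window]
    nums = cnum[window:] - cnum[:-window]
    full = nums == window
    if not full.any():
        return None
    return float(np.max(sums[full] / window))


# ---------------------------------------------------------------------------
# SNP analysis
# ---------------------------------------------------------------------------

SNP_COLUMNS = ["snp_id", "chrom", "pos", "platform", "trait_associated", "common"]


def read_snp_table(path) -> pd.DataFrame:
    """Read a SNP TSV; the pos column is 1-based and converted to 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int) - 1
    df["trait_associated"] = df["trait_associated"].astype(bool)
    df["common"] = df["common"].astype(bool)
    return df


def write_snp_table(path, snps: pd.DataFrame) -> None:
    out = snps.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out["trait_associated"] = out["trait_associated"].astype(int)
    out["common"] = out["common"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def snps_in_region(
    snps: pd.DataFrame, region: Mapping[str, Sequence[tuple[int, int]]]
) -> pd.DataFrame:
    """Rows of the SNP table whose (0-based) position falls in the region."""
    keep = np.zeros(len(snps), dtype=bool)
    pos = snps["pos"].to_numpy()
    chroms = snps["chrom"].to_numpy()
    for chrom, ivs in region.items():
        on = chroms == chrom
        for s, e in ivs:
            keep |= on & (pos >= s) & (pos < e)
    return snps[keep]


def scaled_tested_snps(
    region: Mapping[str, Sequence[tuple[int, int]]],
    snps: pd.DataFrame,
    w_illumina: float = W_ILLUMINA,
    w_affymetrix: float = W_AFFYMETRIX,
) -> float:
    """Platform-weighted tested-SNP count in a region.

    SNPs tested on both platforms contribute to both terms.
    """
    sub = snps_in_region(snps, region)
    n_ill = int(sub["platform"].isin(["illumina", "both"]).sum())
    n_affy = int(sub["platform"].isin(["affymetrix", "both"]).sum())
    return w_illumina * n_ill + w_affymetrix * n_affy


@dataclass
class EnrichmentResult:
    label_a: str
    label_b: str
    rate_a: float
    rate_b: float
    fold: float
    fisher_p: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    tas_a: int
    tas_b: int
    tested_a: float
    tested_b: float


def tas_enrichment(
    region_a: Mapping[str, Sequence[tuple[int, int]]],
    region_b: Mapping[str, Sequence[tuple[int, int]]],
    snps: pd.DataFrame,
    label_a: str = "a",
    label_b: str = "b",
) -> EnrichmentResult:
    """Trait-associated SNPs per platform-scaled tested SNP, region a vs b.

    Fisher's exact test runs on the 2x2 table of (TAS, rounded scaled
    tested minus TAS); 95% Wilson intervals accompany each rate.
    """
    tested_a = scaled_tested_snps(region_a, snps)
    tested_b = scaled_tested_snps(region_b, snps)
    if tested_a <= 0 or tested_b <= 0:
        empty = label_a if tested_a <= 0 else label_b
        raise ValueError(f"region {empty!r} has no scaled tested SNPs")
    tas_a = int(snps_in_region(snps, region_a)["trait_associated"].sum())
    tas_b = int(snps_in_region(snps, region_b)["trait_associated"].sum())
    rate_a = tas_a / tested_a
    rate_b = tas_b / tested_b
    na, nb = round(tested_a), round(tested_b)
    table = [[tas_a, max(0, na - tas_a)], [tas_b, max(0, nb - tas_b)]]
    _, fisher_p = stats.fisher_exact(table)
    ci_a = proportion_confint(tas_a, max(na, 1), alpha=0.05, method="wilson")
    ci_b = proportion_confint(tas_b, max(nb, 1), alpha=0.05, method="wilson")
    return EnrichmentResult(
        label_a=label_a,
        label_b=label_b,
        rate_a=rate_a,
        rate_b=rate_b,
        fold=rate_a / rate_b if rate_b > 0 else np.inf,
        fisher_p=float(fisher_p),
        ci95_a=(float(ci_a[0]), float(ci_a[1])),
        ci95_b=(float(ci_b[0]), float(ci_b[1])),
        tas_a=tas_a,
        tas_b=tas_b,
        tested_a=tested_a,
        tested_b=tested_b,
    )


def common_snp_density(
    region: Mapping[str, Sequence[tuple[int, int]]], snps: pd.DataFrame
) -> tuple[int, int, float]:
    """(common-SNP count, region bp, density) for a region set."""
    bp = sum(e - s for ivs in region.values() for s, e in ivs)
    if bp <= 0:
        raise ValueError("region has zero bp")
    count = int(snps_in_region(snps, region)["common"].sum())
    return count, bp, count / bp


# ---------------------------------------------------------------------------
# polyA+/polyA- bimorphism
# ---------------------------------------------------------------------------

def polya_ratio_analysis(
    counts: pd.DataFrame,
    fpkms: pd.DataFrame,
    cell_types: Sequence[str],
) -> tuple[pd.DataFrame, float]:
    """Per-feature polyA+/polyA- FPKM ratios and cross-cell-type agreement.

    ``counts`` and ``fpkms`` are features x datasets with columns named
    ``{cell}_polyA+`` and ``{cell}_polyA-``. Features qualify when they
    have reads in all datasets and FPKM>1 in at least one fraction of each
    cell type. Returns (log2-ratio table, Pearson r across the first two
    cell types' log2 ratios).
    """
    cols = [f"{c}_{f}" for c in cell_types for f in ("polyA+", "polyA-")]
    missing = [c for c in cols if c not in fpkms.columns]
    if missing:
        raise KeyError(f"missing dataset columns: {missing}")
    qual = (counts[cols] > 0).all(axis=1)
    for cell in cell_types:
        qual &= fpkms[[f"{cell}_polyA+", f"{cell}_polyA-"]].max(axis=1) > 1
    sel = fpkms[qual]
    if len(sel) < 3:
        raise ValueError(f"only {len(sel)} qualifying features; need >= 3")
    ratios = pd.DataFrame(index=sel.index)
    for cell in cell_types:
        ratios[cell] = np.log2(sel[f"{cell}_polyA+"] / sel[f"{cell}_polyA-"])
    r, _ = stats.pearsonr(ratios[cell_types[0]], ratios[cell_types[1]])
    return ratios, float(r)


# ---------------------------------------------------------------------------
# ChIP signal
# ---------------------------------------------------------------------------

def chip_signal_ratio(
    t: TranscriptModel,
    ip_reads: Sequence[ReadAlignment],
    input_reads: Sequence[ReadAlignment],
    ip_total: int,
    input_total: int,
) -> float | None:
    """Depth-normalized IP/input read-count ratio over the transcript.

    Returns None when the input control has no reads on the transcript
    (the ratio is undefined, not infinite).
    """
    ip = count_reads_full_assignment(ip_reads, [t])[t.id]
    inp = count_reads_full_assignment(input_reads, [t])[t.id]
    if inp == 0:
        return None
    return (ip / ip_total) / (inp / input_total)


# ---------------------------------------------------------------------------
# PET end support
# ---------------------------------------------------------------------------

def _end_blocks(cluster: TranscriptModel) -> tuple[tuple[int, int], tuple[int, int]]:
    """(five_prime_block, three_prime_block) honoring cluster strand."""
    first, last = cluster.exons[0], cluster.exons[-1]
    if cluster.strand == "-":
        return last, first
    return first, last


def pet_end_support(
    t: TranscriptModel, pet_clusters: Sequence[TranscriptModel]
) -> tuple[bool, bool]:
    """Whether the transcript's 5' and 3' terminal bases fall within the
    corresponding end blocks of an overlapping PET cluster.

    Strand-ambiguous transcripts are evaluated under both orientations and
    an end is supported if either orientation matches.
    """
    orientations = ["+", "-"] if t.strand == "." else [t.strand]
    five = three = False
    for c in pet_clusters:
        if c.chrom != t.chrom or c.n_exons < 2:
            continue
        if t.span_overlap_bp(c) == 0:
            continue
        c5, c3 = _end_blocks(c)
        for orient in orientations:
            if c.strand != "." and c.strand != orient:
                continue
            t5 = t.start if orient == "+" else t.end - 1
            t3 = t.end - 1 if orient == "+" else t.start
            if c5[0] <= t5 < c5[1]:
                five = True
            if c3[0] <= t3 < c3[1]:
                three = True
    return five, three


# ---------------------------------------------------------------------------
# tissue clustering
# ---------------------------------------------------------------------------

def normalize_log_fpkm(
    fpkm_df: pd.DataFrame,
    min_fpkm: float = 10.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.DataFrame:
    """log2(FPKM + 1) then iterative row-then-column rescaling toward unit
    sum-of-squares, Gene Cluster style.

    The two constraints are only simultaneously satisfiable for a square
    matrix (all-unit rows force a total sum of squares equal to the row
    count, all-unit columns to the column count), so the alternation
    converges to a limit cycle: the procedure ends on a column pass, after
    which every column has exactly unit sum of squares and the rows share a
    common sum of squares of (n_columns / n_rows). Rows failing the max-FPKM
    filter are excluded; all-zero rows after the transform are dropped with
    a warning.
    """
    sel = fpkm_df[fpkm_df.max(axis=1) > min_fpkm]
    if sel.empty:
        raise ValueError("no features pass the FPKM filter")
    x = np.log2(sel.to_numpy(dtype=float) + 1.0)
    nonzero = (x ** 2).sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} all-zero rows before normalization"
        )
        x = x[nonzero]
        sel = sel[nonzero]
    for _ in range(max_iter):
        rss = np.sqrt((x ** 2).sum(axis=1, keepdims=True))
        x = x / np.where(rss > 0, rss, 1.0)
        css = np.sqrt((x ** 2).sum(axis=0, keepdims=True))
        x = x / np.where(css > 0, css, 1.0)
        row_err = np.abs((x ** 2).sum(axis=1) - 1.0).max()
        col_err = np.abs((x ** 2).sum(axis=0) - 1.0).max()
        if row_err <= tol and col_err <= tol:
            break
    return pd.DataFrame(x, index=sel.index, columns=sel.columns)


def cluster_samples(
    fpkm_df: pd.DataFrame, min_fpkm: float = 10.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise sample distances and centroid-linkage merge list.

    Features are filtered to max FPKM > min_fpkm in at least one sample,
    log2 transformed, and row/column normalized; samples are then compared
    by Euclidean distance and agglomerated with centroid linkage.
    """
    if fpkm_df.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    norm = normalize_log_fpkm(fpkm_df, min_fpkm=min_fpkm)
    samples = norm.T.to_numpy()
    dists = squareform(pdist(samples, metric="euclidean"))
    dist_df = pd.DataFrame(dists, index=norm.columns, columns=norm.columns)
    Z = linkage(samples, method="centroid")
    return dist_df, Z
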