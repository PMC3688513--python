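"""Seeded generator of a toy genome with planted ground truth.

Produces everything the discovery pipeline consumes — genome + mappability
mask, chromosome sequence, protein-coding genes with real ORFs, candidate
intergenic transcripts (true lincRNAs plus single-violation decoys),
multi-dataset RNA-seq reads with tissue-specific log-normal expression,
ribosome-profiling and ChIP reads, a conservation track, SNP tables with a
planted trait-associated-SNP enrichment, and PET end clusters — so that
every downstream stage is testable without external downloads.

Each decoy category violates exactly one cascade rule, so per-stage
removals are attributable: running the full cascade on the default
configuration must retain exactly the true-lincRNA set.
"""

from __future__ import annotations

from bisect import bisect_right, insort
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .characterize import ScoreTrack
from .expression import DatasetInfo
from .filters import AnnotationCatalog
from .intervals import (
    GenomeSpec,
    GenomicInterval,
    ReadAlignment,
    TranscriptModel,
    merge_intervals,
    subtract_intervals,
)
from .orf import has_large_orf

CATEGORIES = (
    "true_lincRNA",
    "protein_coding",
    "short_decoy",
    "proximity_decoy",
    "pseudogene",
    "small_ncRNA",
    "utr_extension_victim",
    "large_orf_decoy",
    "orf_neighbor_decoy",
    "extended_gene_decoy",
    "low_expression_decoy",
)

# stage at which each decoy category must be removed
EXPECTED_STAGE = {
    "true_lincRNA": "retained",
    "protein_coding": "annotation_only",
    "short_decoy": "removed_at_length",
    "proximity_decoy": "removed_at_proximity",
    "pseudogene": "removed_at_annotation",
    "small_ncRNA": "removed_at_annotation",
    "utr_extension_victim": "removed_at_annotation",
    "large_orf_decoy": "removed_at_large_orf",
    "orf_neighbor_decoy": "removed_at_large_orf",
    "extended_gene_decoy": "removed_at_extended_gene",
    "low_expression_decoy": "removed_at_expression",
}

_STREAMS = {
    "genome": 0,
    "sequence": 1,
    "annotation": 2,
    "reads": 3,
    "tracks": 4,
    "snps": 5,
    "extras": 6,
}


class GenerationError(RuntimeError):
    """Config infeasible: requested features cannot be placed."""


@dataclass(frozen=True)
class TruthLabel:
    transcript_id: str
    category: str
    expected_fate: str


@dataclass
class DatasetSpec:
    dataset_id: str
    library_type: str  # polyA+ | polyA- | rRNA-depleted
    tissue: str
    read_length: int = 75
    total_mapped_reads: int = 10_000_000


def _default_counts() -> dict[str, int]:
    return {
        "true_lincRNA": 150,
        "protein_coding": 60,
        "short_decoy": 50,
        "proximity_decoy": 50,
        "pseudogene": 40,
        "small_ncRNA": 40,
        "utr_extension_victim": 40,
        "large_orf_decoy": 50,
        "orf_neighbor_decoy": 30,
        "extended_gene_decoy": 20,
        "low_expression_decoy": 30,
    }


def _default_datasets() -> list[DatasetSpec]:
    out = []
    for tissue in ("bcell", "esc", "brain"):
        out.append(DatasetSpec(f"{tissue}_polyA_plus", "polyA+", tissue))
        out.append(DatasetSpec(f"{tissue}_polyA_minus", "polyA-", tissue))
    return out


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int = 42
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    unmappable_fraction: float = 0.10
    counts: dict[str, int] = field(default_factory=_default_counts)
    datasets: list[DatasetSpec] = field(default_factory=_default_datasets)
    # intergenic noise reads: regional log-normal rate field over fixed windows
    noise_rate_per_kb: dict[str, float] = field(
        default_factory=lambda: {"polyA+": 0.6, "polyA-": 1.5, "rRNA-depleted": 1.2}
    )
    noise_window_bp: int = 5_000
    noise_log_sigma: float = 1.5
    # expression (FPKM units)
    linc_fpkm_logmean: float = float(np.log(20.0))
    linc_fpkm_logsd: float = 0.6
    linc_fpkm_clip: tuple[float, float] = (8.0, 300.0)
    gene_fpkm_logmean: float = float(np.log(60.0))
    gene_fpkm_logsd: float = 0.7
    gene_fpkm_clip: tuple[float, float] = (10.0, 1000.0)
    low_expr_fpkm: tuple[float, float] = (0.15, 0.30)
    tissue_mult_logsd: float = 0.3
    tissue_mult_clip: tuple[float, float] = (0.5, 3.0)
    gene_polya_logratio: tuple[float, float] = (float(np.log(4.0)), 0.5)
    linc_polya_logratio: tuple[float, float] = (0.0, 0.8)
    # conservation track
    conservation_baseline_sd: float = 1.0
    conservation_elevation: float = 2.0
    conserved_linc_fraction: float = 0.5
    conserved_window_bp: int = 100
    # SNPs
    n_tested_snps: int = 10_000
    tas_background_rate: float = 0.01
    tas_enrichment_fold: float = 5.0
    platform_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)  # ill/affy/both
    common_snp_rate: float = 0.30
    # ribosome profiling
    ribo_depth_factor: float = 20.0
    ribo_leakage: float = 0.02
    ribo_read_length: int = 30
    ribo_total_mapped: int = 2_000_000
    # ChIP
    n_chip_marks: int = 40
    chip_background_per_kb: float = 1.0
    chip_mark_extra_per_kb: float = 4.0
    chip_total_mapped: int = 1_000_000
    # PET clusters
    n_pet_clusters: int = 60
    pet_block_bp: int = 100
    # placement
    margin_bp: int = 1_100
    max_place_tries: int = 400

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("category counts must be >= 0")
        if not 0 <= self.unmappable_fraction < 1:
            raise ValueError("unmappable_fraction must be in [0, 1)")
        if self.counts.get("orf_neighbor_decoy", 0) > self.counts.get("large_orf_decoy", 0):
            raise ValueError("each orf_neighbor_decoy needs a large_orf_decoy host")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), _STREAMS[stream]])

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for ds in self.datasets:
            if ds.tissue not in seen:
                seen.append(ds.tissue)
        return seen


# ---------------------------------------------------------------------------
# genome + mask
# ---------------------------------------------------------------------------

def generate_genome(cfg: SimConfig) -> GenomeSpec:
    """Chromosomes of configured length with a random unmappable-segment mask.

    Unmappable segments are 50-500 bp, drawn until their union reaches the
    requested fraction of each chromosome; the mappability mask is the
    complement.
    """
    rng = cfg.rng("genome")
    chroms = [(f"chr{i + 1}", cfg.chrom_length) for i in range(cfg.n_chromosomes)]
    mask = {}
    for name, n in chroms:
        target = int(round(cfg.unmappable_fraction * n))
        segments: list[tuple[int, int]] = []
        covered = 0
        while covered < target:
            ln = int(rng.integers(50, 501))
            s = int(rng.integers(0, n - ln))
            segments.append((s, s + ln))
            merged = merge_intervals(segments)
            covered = sum(e - b for b, e in merged)
            segments = merged
        mask[name] = subtract_intervals([(0, n)], segments) if segments else [(0, n)]
    return GenomeSpec(chromosomes=chroms, mappability_mask=mask)


# ---------------------------------------------------------------------------
# sequence design
# ---------------------------------------------------------------------------

_NTS = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _NTS[rng.integers(0, 4, size=n)].tobytes().decode()


def _orf_free_seq(rng: np.random.Generator, n: int, max_tries: int = 200) -> str:
    """Random sequence verified against the ORF oracle to carry no large ORF."""
    for _ in range(max_tries):
        seq = _random_seq(rng, n)
        if n < 3 or not has_large_orf(seq):
            return seq
    raise GenerationError(f"could not draw an ORF-free sequence of length {n}")


def _coding_seq(rng: np.random.Generator, n_codons: int, utr5: int, utr3: int) -> str:
    """UTR5 + ATG + non-stop codons + stop + UTR3 (guaranteed large ORF)."""
    body = "".join(
        _NONSTOP_CODONS[int(i)]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    )
    stop = _STOPS[int(rng.integers(0, 3))]
    return (
        _random_seq(rng, utr5) + "ATG" + body + stop + _random_seq(rng, utr3)
    )


def spliced_sequence(sequences: Mapping[str, str], t: TranscriptModel) -> str:
    """Concatenated exonic sequence of a transcript."""
    seq = sequences[t.chrom]
    return "".join(seq[s:e] for s, e in t.exons)


# ---------------------------------------------------------------------------
# placement machinery
# ---------------------------------------------------------------------------

class _Placer:
    """Places feature bundles on the genome without collisions.

    Bundles are separated by at least ``margin`` bp and every exon of every
    bundle element must fall entirely inside one mappable-mask interval.
    """

    def __init__(self, genome: GenomeSpec, rng: np.random.Generator,
                 margin: int, max_tries: int):
        self.genome = genome
        self.rng = rng
        self.margin = margin
        self.max_tries = max_tries
        self.reserved: dict[str, list[tuple[int, int]]] = {
            c: [] for c, _ in genome.chromosomes
        }
        self._mask_starts = {
            c: [s for s, _ in genome.mappability_mask.get(c, [])]
            for c, _ in genome.chromosomes
        }
        sizes = np.array([n for _, n in genome.chromosomes], dtype=float)
        self._chrom_p = sizes / sizes.sum()
        self._chrom_names = [c for c, _ in genome.chromosomes]

    def _exon_mappable(self, chrom: str, s: int, e: int) -> bool:
        starts = self._mask_starts[chrom]
        i = bisect_right(starts, s) - 1
        if i < 0:
            return False
        return self.genome.mappability_mask[chrom][i][1] >= e

    def _free(self, chrom: str, s: int, e: int) -> bool:
        ivs = self.reserved[chrom]
        i = bisect_right(ivs, (s, s))
        if i > 0 and ivs[i - 1][1] + self.margin > s:
            return False
        if i < len(ivs) and e + self.margin > ivs[i][0]:
            return False
        return True

    def place(self, width: int, rel_exons: Sequence[tuple[int, int]]) -> tuple[str, int]:
        for _ in range(self.max_tries):
            ci = int(self.rng.choice(len(self._chrom_names), p=self._chrom_p))
            chrom = self._chrom_names[ci]
            size = dict(self.genome.chromosomes)[chrom]
            if size <= width:
                continue
            start = int(self.rng.integers(0, size - width))
            if not self._free(chrom, start, start + width):
                continue
            if all(
                self._exon_mappable(chrom, start + s, start + e)
                for s, e in rel_exons
            ):
                insort(self.reserved[chrom], (start, start + width))
                return chrom, start
        raise GenerationError(
            f"could not place a {width}-bp bundle after {self.max_tries} tries; "
            "genome too small or too fragmented for the requested features"
        )


def _split_length(rng: np.random.Generator, total: int, n_parts: int,
                  min_part: int) -> list[int]:
    extra = total - n_parts * min_part
    if extra < 0:
        raise ValueError("total too small for requested parts")
    alloc = rng.multinomial(extra, [1.0 / n_parts] * n_parts)
    return [min_part + int(a) for a in alloc]


def _exon_layout(rng: np.random.Generator, spliced_len: int, n_exons: int,
                 intron_range: tuple[int, int], min_exon: int = 100
                 ) -> list[tuple[int, int]]:
    """Relative exon intervals for a transcript of given spliced length."""
    exon_lens = _split_length(rng, spliced_len, n_exons, min_exon)
    exons = []
    pos = 0
    for i, ln in enumerate(exon_lens):
        exons.append((pos, pos + ln))
        pos += ln
        if i < n_exons - 1:
            pos += int(rng.integers(*intron_range))
    return exons


# ---------------------------------------------------------------------------
# annotation + transcript generation
# ---------------------------------------------------------------------------

@dataclass
class _Feature:
    id: str
    category: str
    chrom: str = ""
    exons: list[tuple[int, int]] = field(default_factory=list)
    true_strand: str = "+"
    reported_strand: str = "."
    meta: dict = field(default_factory=dict)

    def to_transcript(self) -> TranscriptModel:
        return TranscriptModel(
            id=self.id,
            chrom=self.chrom,
            strand=self.reported_strand,
            exons=list(self.exons),
            source_tag=self.category,
        )


@dataclass
class AnnotationBundle:
    """Placed features, their sequence, and the annotation catalog."""

    genome: GenomeSpec
    sequences: dict[str, str]
    catalog: AnnotationCatalog
    candidates: list[TranscriptModel]
    genes: list[TranscriptModel]
    truth: dict[str, TruthLabel]
    features: dict[str, _Feature]
    cds_by_gene: dict[str, list[tuple[int, int]]]  # genomic CDS intervals

    def transcript_sequences(self) -> dict[str, str]:
        out = {}
        for t in self.candidates + self.genes:
            out[t.id] = spliced_sequence(self.sequences, t)
        return out


def _linc_like_layout(rng, spliced_range=(400, 1200), exon_p=(0.45, 0.35, 0.2),
                      intron_range=(150, 600)):
    spliced = int(rng.integers(*spliced_range))
    n_exons = 1 + int(rng.choice(3, p=list(exon_p)))
    n_exons = min(n_exons, max(1, spliced // 150))
    return _exon_layout(rng, spliced, n_exons, intron_range), spliced


def generate_annotations_and_transcripts(
    cfg: SimConfig, genome: GenomeSpec
) -> AnnotationBundle:
    """Place all features, design their sequences, and build the truth map.

    Protein-coding genes carry a complete ORF of >=120 codons; every
    non-coding feature's spliced sequence is verified ORF-free against the
    ORF scanner at generation time. Each decoy category violates exactly
    its one targeted cascade rule.
    """
    rng = cfg.rng("annotation")
    seq_rng = cfg.rng("sequence")
    placer = _Placer(genome, rng, cfg.margin_bp, cfg.max_place_tries)
    counts = cfg.counts

    features: list[_Feature] = []
    catalog = AnnotationCatalog()
    serial = {"gene": 0}

    def _new_id(prefix: str) -> str:
        serial[prefix] = serial.get(prefix, 0) + 1
        return f"{prefix}_{serial[prefix]:04d}"

    def _gene_layout():
        n_codons = int(rng.integers(120, 181))
        utr5 = int(rng.integers(80, 151))
        utr3 = int(rng.integers(80, 151))
        spliced = utr5 + 3 * (n_codons + 1) + utr3
        n_exons = int(rng.integers(1, 4))
        exons = _exon_layout(rng, spliced, n_exons, (150, 500), min_exon=150)
        return exons, dict(n_codons=n_codons, utr5=utr5, utr3=utr3, spliced=spliced)

    # --- protein-coding genes, three roles -------------------------------
    n_genes = counts.get("protein_coding", 0)
    n_prox = counts.get("proximity_decoy", 0)
    n_ext = counts.get("extended_gene_decoy", 0)
    n_anchor = (n_prox + 1) // 2
    if n_anchor + n_ext > n_genes:
        raise GenerationError(
            "not enough protein_coding genes to anchor proximity and "
            "extended-gene decoys"
        )

    gene_features: list[_Feature] = []
    prox_left = n_prox
    ext_placed = 0

    for gi in range(n_genes):
        exons, meta = _gene_layout()
        strand = "+" if rng.integers(2) == 0 else "-"
        gene = _Feature(
            id=_new_id("gene"), category="protein_coding",
            true_strand=strand, reported_strand=strand, meta=meta,
        )
        role = "plain"
        if gi < n_anchor:
            role = "prox_anchor"
        elif gi < n_anchor + n_ext:
            role = "ext_host"
        gene.meta["role"] = role

        elements: list[tuple[_Feature, list[tuple[int, int]]]] = []
        if role == "prox_anchor":
            # decoys flanking the gene within 1 kb (up- and downstream)
            gene_off = 0
            decoys = []
            n_here = min(2, prox_left)
            prox_left -= n_here
            sides = ["down", "up"][:n_here]
            up_block = 0
            for side in sides:
                d_exons, d_spliced = _linc_like_layout(
                    rng, spliced_range=(300, 800), exon_p=(0.6, 0.4, 0.0),
                    intron_range=(150, 400),
                )
                gap = int(rng.integers(100, 901))
                d = _Feature(
                    id=_new_id("prox"), category="proximity_decoy",
                    meta={"spliced": d_spliced},
                )
                decoys.append((d, d_exons, side, gap))
                if side == "up":
                    up_block = d_exons[-1][1] + gap
            gene_off = up_block
            gexons = [(s + gene_off, e + gene_off) for s, e in exons]
            elements.append((gene, gexons))
            for d, d_exons, side, gap in decoys:
                if side == "down":
                    off = gexons[-1][1] + gap
                else:
                    off = 0
                elements.append((d, [(s + off, e + off) for s, e in d_exons]))
        elif role == "ext_host":
            pad5 = int(rng.integers(500, 1001))
            pad3 = 3_500
            gexons = [(s + pad5, e + pad5) for s, e in exons]
            elements.append((gene, gexons))
            d_exons, d_spliced = _linc_like_layout(
                rng, spliced_range=(250, 600), exon_p=(1.0, 0.0, 0.0),
                intron_range=(150, 300),
            )
            d_span = d_exons[-1][1]
            lo = gexons[-1][1] + 1_100
            hi = gexons[-1][1] + pad3 - d_span - 100
            off = int(rng.integers(lo, max(lo + 1, hi)))
            d = _Feature(
                id=_new_id("extd"), category="extended_gene_decoy",
                meta={"spliced": d_spliced},
            )
            elements.append((d, [(s + off, e + off) for s, e in d_exons]))
            gene.meta["pad5"] = pad5
            gene.meta["pad3"] = pad3
            ext_placed += 1
        else:
            elements.append((gene, exons))

        width = max(e for _, ex in elements for _, e in ex)
        if role == "ext_host":
            # reserve the full extended boundary, not just the placed exons
            width = max(width, elements[0][1][-1][1] + gene.meta["pad3"])
        rel_exons = [iv for _, ex in elements for iv in ex]
        chrom, start = placer.place(width, rel_exons)
        for feat, ex in elements:
            feat.chrom = chrom
            feat.exons = [(s + start, e + start) for s, e in ex]
            if feat.category != "protein_coding":
                feat.true_strand = "+" if rng.integers(2) == 0 else "-"
            features.append(feat)
        gene_features.append(gene)
        if role == "ext_host":
            catalog.extended_gene_boundaries.append(
                GenomicInterval(
                    chrom,
                    max(0, gene.exons[0][0] - gene.meta["pad5"]),
                    gene.exons[-1][1] + gene.meta["pad3"],
                    strand=gene.true_strand,
                    name=f"{gene.id}_extended",
                )
            )

    # extended boundaries for a random subset of plain genes (small pads,
    # strictly inside the inter-bundle margin so they cover no candidate)
    plain = [g for g in gene_features if g.meta["role"] == "plain"]
    n_extra = min(len(plain), max(0, len(plain) * 2 // 3))
    for g in list(rng.choice(len(plain), size=n_extra, replace=False)):
        gene = plain[int(g)]
        pad5 = int(rng.integers(500, 1001))
        pad3 = int(rng.integers(500, 1001))
        catalog.extended_gene_boundaries.append(
            GenomicInterval(
                gene.chrom,
                max(0, gene.exons[0][0] - pad5),
                gene.exons[-1][1] + pad3,
                strand=gene.true_strand,
                name=f"{gene.id}_extended",
            )
        )

    # --- large-ORF decoys, some hosting ORF-free neighbors ----------------
    n_orf = counts.get("large_orf_decoy", 0)
    n_neighbor = counts.get("orf_neighbor_decoy", 0)
    for i in range(n_orf):
        n_codons = int(rng.integers(110, 161))
        utr5 = int(rng.integers(30, 81))
        tail = int(rng.integers(250, 401))
        host_len = utr5 + 3 * (n_codons + 1) + tail
        host = _Feature(
            id=_new_id("orfdecoy"), category="large_orf_decoy",
            meta={"n_codons": n_codons, "utr5": utr5, "tail": tail},
        )
        elements = [(host, [(0, host_len)])]
        if i < n_neighbor:
            ov = int(rng.integers(50, min(151, tail)))
            nb_spliced = int(rng.integers(300, 701))
            nb_exons = _exon_layout(
                rng, nb_spliced, int(rng.integers(1, 3)), (150, 400)
            )
            off = host_len - ov
            nb = _Feature(
                id=_new_id("orfnb"), category="orf_neighbor_decoy",
                meta={"overlap": ov, "spliced": nb_spliced},
            )
            elements.append((nb, [(s + off, e + off) for s, e in nb_exons]))
        width = max(e for _, ex in elements for _, e in ex)
        rel_exons = [iv for _, ex in elements for iv in ex]
        chrom, start = placer.place(width, rel_exons)
        for feat, ex in elements:
            feat.chrom = chrom
            feat.exons = [(s + start, e + start) for s, e in ex]
            feat.true_strand = "+" if rng.integers(2) == 0 else "-"
            features.append(feat)

    # --- simple standalone categories ------------------------------------
    def _place_simple(category: str, n: int, layout_fn) -> list[_Feature]:
        placed = []
        prefix = {
            "true_lincRNA": "linc",
            "low_expression_decoy": "lowexpr",
            "small_ncRNA": "ncrna",
            "utr_extension_victim": "utrv",
        }.get(category, category.split("_")[0])
        for _ in range(n):
            exons, meta = layout_fn()
            width = exons[-1][1]
            chrom, start = placer.place(width, exons)
            f = _Feature(
                id=_new_id(prefix), category=category,
                chrom=chrom,
                exons=[(s + start, e + start) for s, e in exons],
                true_strand="+" if rng.integers(2) == 0 else "-",
                meta=meta,
            )
            features.append(f)
            placed.append(f)
        return placed

    def _linc_layout():
        exons, spliced = _linc_like_layout(rng)
        return exons, {"spliced": spliced}

    def _short_layout():
        ln = int(rng.integers(80, 191))
        return [(0, ln)], {"spliced": ln}

    def _long_layout():
        ln = int(rng.integers(1800, 2401))
        return [(0, ln)], {"spliced": ln}

    def _victim_layout():
        exons, spliced = _linc_like_layout(
            rng, spliced_range=(300, 900), exon_p=(0.6, 0.4, 0.0),
            intron_range=(150, 400),
        )
        return exons, {"spliced": spliced}

    _place_simple("true_lincRNA", counts.get("true_lincRNA", 0), _linc_layout)
    _place_simple("short_decoy", counts.get("short_decoy", 0), _short_layout)
    _place_simple(
        "low_expression_decoy", counts.get("low_expression_decoy", 0), _long_layout
    )
    pseudo = _place_simple("pseudogene", counts.get("pseudogene", 0), _victim_layout)
    ncrna = _place_simple("small_ncRNA", counts.get("small_ncRNA", 0), _victim_layout)
    utrv = _place_simple(
        "utr_extension_victim", counts.get("utr_extension_victim", 0), _victim_layout
    )

    # annotation intervals overlapping each victim (strand-blind filter input)
    for f in pseudo:
        s = f.exons[0][0]
        catalog.non_lincRNA_other.append(
            GenomicInterval(f.chrom, max(0, s - 150), s + 150,
                            name=f"pseudogene_ann_{f.id}")
        )
    for f in ncrna:
        s = f.exons[0][0]
        catalog.non_lincRNA_other.append(
            GenomicInterval(f.chrom, max(0, s - 150), s + 150,
                            name=f"ncrna_ann_{f.id}")
        )
    for f in utrv:
        s = f.exons[0][0]
        catalog.utr_extensions.append(
            GenomicInterval(f.chrom, max(0, s - 150), s + 150,
                            name=f"utr_ann_{f.id}")
        )

    # --- chromosome sequence ---------------------------------------------
    chrom_bytes = {
        c: bytearray(_random_seq(seq_rng, n).encode())
        for c, n in genome.chromosomes
    }

    def _write_spliced(f: _Feature, seq: str) -> None:
        pos = 0
        buf = chrom_bytes[f.chrom]
        for s, e in f.exons:
            buf[s:e] = seq[pos : pos + (e - s)].encode()
            pos += e - s
        # canonical splice dinucleotides so strand can be inferred later
        for i in range(len(f.exons) - 1):
            istart, iend = f.exons[i][1], f.exons[i + 1][0]
            if iend - istart >= 4:
                if f.true_strand == "+":
                    buf[istart : istart + 2] = b"GT"
                    buf[iend - 2 : iend] = b"AG"
                else:
                    buf[istart : istart + 2] = b"CT"
                    buf[iend - 2 : iend] = b"AC"

    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    neighbors: list[_Feature] = []
    for f in features:
        spliced_len = sum(e - s for s, e in f.exons)
        if f.category == "protein_coding":
            seq = _coding_seq(seq_rng, f.meta["n_codons"], f.meta["utr5"], f.meta["utr3"])
            _write_spliced(f, seq)
            cds_s = f.meta["utr5"]
            cds_e = cds_s + 3 * (f.meta["n_codons"] + 1)
            cds_by_gene[f.id] = _project_tx_interval(f.exons, cds_s, cds_e)
            f.meta["cds_tx"] = (cds_s, cds_e)
        elif f.category == "large_orf_decoy":
            seq = _coding_seq(seq_rng, f.meta["n_codons"], f.meta["utr5"], f.meta["tail"])
            _write_spliced(f, seq)
        elif f.category == "orf_neighbor_decoy":
            neighbors.append(f)  # needs host bytes first
        else:
            _write_spliced(f, _orf_free_seq(seq_rng, spliced_len))

    for f in neighbors:
        ov = f.meta["overlap"]
        spliced_len = sum(e - s for s, e in f.exons)
        buf = chrom_bytes[f.chrom]
        s0, e0 = f.exons[0]
        prefix = bytes(buf[s0 : s0 + ov]).decode()
        for _ in range(200):
            rest = _random_seq(seq_rng, spliced_len - ov)
            if not has_large_orf(prefix + rest):
                break
        else:
            raise GenerationError("could not design ORF-free neighbor sequence")
        _write_spliced(f, prefix + rest)

    sequences = {c: bytes(b).decode() for c, b in chrom_bytes.items()}

    # --- assemble outputs -------------------------------------------------
    truth: dict[str, TruthLabel] = {}
    candidates: list[TranscriptModel] = []
    genes: list[TranscriptModel] = []
    feat_map: dict[str, _Feature] = {}
    for f in features:
        feat_map[f.id] = f
        truth[f.id] = TruthLabel(f.id, f.category, EXPECTED_STAGE[f.category])
        if f.category == "protein_coding":
            genes.append(f.to_transcript())
        else:
            candidates.append(f.to_transcript())
    catalog.protein_coding = genes
    candidates.sort(key=lambda t: (t.chrom, t.start, t.id))

    bundle = AnnotationBundle(
        genome=genome,
        sequences=sequences,
        catalog=catalog,
        candidates=candidates,
        genes=genes,
        truth=truth,
        features=feat_map,
        cds_by_gene=cds_by_gene,
    )
    # generation-time self-check: every true lincRNA must be ORF-free
    seqs = bundle.transcript_sequences()
    for t in candidates:
        if truth[t.id].category == "true_lincRNA" and has_large_orf(seqs[t.id]):
            raise GenerationError(f"generated lincRNA {t.id} contains a large ORF")
    return bundle


def _project_tx_interval(
    exons: Sequence[tuple[int, int]], tx_start: int, tx_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic intervals."""
    out = []
    off = 0
    for s, e in exons:
        ln = e - s
        a = max(tx_start, off)
        b = min(tx_end, off + ln)
        if a < b:
            out.append((s + a - off, s + b - off))
        off += ln
    return out


# ---------------------------------------------------------------------------
# expression + reads
# ---------------------------------------------------------------------------

def expected_count(fpkm: float, exonic_length: int, total_mapped: int) -> float:
    """Mean read count implied by an FPKM at a given library depth."""
    return fpkm * exonic_length * total_mapped / 1e9


@dataclass
class ReadsBundle:
    datasets: list[DatasetInfo]
    reads_by_dataset: dict[str, list[ReadAlignment]]
    planted_fpkm: pd.DataFrame  # transcripts x datasets (candidates + genes)
    ribo_reads: list[ReadAlignment]
    ribo_dataset: DatasetInfo
    ribo_rna_reads: list[ReadAlignment]
    ribo_rna_dataset: DatasetInfo
    chip_ip_reads: list[ReadAlignment]
    chip_input_reads: list[ReadAlignment]
    chip_marks: list[GenomicInterval]


def _reads_from_transcript(
    t: TranscriptModel, n: int, read_length: int, rng: np.random.Generator,
    dataset_id: str, tx_range: tuple[int, int] | None = None,
) -> list[ReadAlignment]:
    """Place n reads uniformly along the (optionally restricted) spliced
    transcript; junction-crossing reads become split alignments."""
    L = t.exonic_length
    lo, hi = tx_range if tx_range is not None else (0, L)
    rl = min(read_length, hi - lo)
    max_off = hi - rl
    offs = rng.integers(lo, max_off + 1, size=n) if max_off > lo else np.full(n, lo)
    reads = []
    for off in offs:
        blocks = _project_tx_interval(t.exons, int(off), int(off) + rl)
        reads.append(
            ReadAlignment(chrom=t.chrom, blocks=blocks, strand=".", dataset_id=dataset_id)
        )
    return reads


def simulate_reads(cfg: SimConfig, bundle: AnnotationBundle) -> ReadsBundle:
    """Per-dataset reads from planted log-normal tissue-specific expression.

    Counts are Poisson around the FPKM-implied mean; intergenic noise reads
    follow a regional log-normal rate field (shared across datasets, scaled
    per library type) and never overlap planted feature spans — background
    loci stay genuinely non-expressed apart from noise.
    """
    rng = cfg.rng("reads")
    tissues = cfg.tissues
    all_tx = bundle.candidates + bundle.genes
    truth = bundle.truth

    # planted per-transcript expression parameters
    base = {}
    tissue_mult = {}
    polya_ratio = {}
    for t in all_tx:
        cat = truth[t.id].category
        if cat == "protein_coding":
            b = float(np.exp(rng.normal(cfg.gene_fpkm_logmean, cfg.gene_fpkm_logsd)))
            b = float(np.clip(b, *cfg.gene_fpkm_clip))
            on = set(tissues)
            mu, sd = cfg.gene_polya_logratio
        elif cat == "low_expression_decoy":
            b = float(rng.uniform(*cfg.low_expr_fpkm))
            on = set(tissues)
            mu, sd = cfg.linc_polya_logratio
        else:
            b = float(np.exp(rng.normal(cfg.linc_fpkm_logmean, cfg.linc_fpkm_logsd)))
            b = float(np.clip(b, *cfg.linc_fpkm_clip))
            k = 1 + int(rng.integers(0, 2))
            on = set(
                tissues[int(i)]
                for i in rng.choice(len(tissues), size=min(k, len(tissues)), replace=False)
            )
            mu, sd = cfg.linc_polya_logratio
        base[t.id] = b
        rho = float(np.exp(rng.normal(mu, sd)))
        polya_ratio[t.id] = rho
        for tis in tissues:
            if tis in on:
                m = float(np.exp(rng.normal(0.0, cfg.tissue_mult_logsd)))
                tissue_mult[(t.id, tis)] = float(np.clip(m, *cfg.tissue_mult_clip))
            else:
                tissue_mult[(t.id, tis)] = 0.0

    low_ids = {
        tid for tid, lab in truth.items() if lab.category == "low_expression_decoy"
    }

    def _planted(tid: str, ds: DatasetSpec) -> float:
        if tid in low_ids:
            # calibrated: FPKM must stay < 1 in every dataset, so no
            # tissue or library-fraction multipliers apply
            return base[tid]
        rho = polya_ratio[tid]
        if ds.library_type == "polyA+":
            frac = 2.0 * rho / (1.0 + rho)
        elif ds.library_type == "polyA-":
            frac = 2.0 / (1.0 + rho)
        else:
            frac = 1.0
        return base[tid] * tissue_mult[(tid, ds.tissue)] * frac

    fpkm_cols = {
        ds.dataset_id: [_planted(t.id, ds) for t in all_tx] for ds in cfg.datasets
    }
    planted_fpkm = pd.DataFrame(fpkm_cols, index=[t.id for t in all_tx])

    # regional noise rate field, shared across datasets
    win = cfg.noise_window_bp
    noise_mult = {
        c: np.exp(rng.normal(0.0, cfg.noise_log_sigma, size=(n + win - 1) // win))
        for c, n in bundle.genome.chromosomes
    }
    feature_spans = {
        c: [] for c, _ in bundle.genome.chromosomes
    }
    for t in all_tx:
        feature_spans[t.chrom].append(t.span)
    feature_spans = {c: merge_intervals(v) if v else [] for c, v in feature_spans.items()}
    span_starts = {c: [s for s, _ in v] for c, v in feature_spans.items()}

    def _hits_feature(chrom: str, s: int, e: int) -> bool:
        starts = span_starts[chrom]
        i = bisect_right(starts, e - 1) - 1
        return i >= 0 and feature_spans[chrom][i][1] > s

    datasets = []
    reads_by_dataset: dict[str, list[ReadAlignment]] = {}
    for ds in cfg.datasets:
        datasets.append(
            DatasetInfo(ds.dataset_id, ds.library_type, ds.total_mapped_reads)
        )
        reads: list[ReadAlignment] = []
        for t in all_tx:
            mean = expected_count(
                planted_fpkm.loc[t.id, ds.dataset_id],
                t.exonic_length,
                ds.total_mapped_reads,
            )
            n = int(rng.poisson(mean)) if mean > 0 else 0
            if n:
                reads.extend(
                    _reads_from_transcript(t, n, ds.read_length, rng, ds.dataset_id)
                )
        rate = cfg.noise_rate_per_kb.get(ds.library_type, 1.0)
        for chrom, size in bundle.genome.chromosomes:
            mult = noise_mult[chrom]
            for w, m in enumerate(mult):
                ws = w * win
                we = min(size, ws + win)
                lam = rate * m * (we - ws) / 1000.0
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                starts = rng.integers(ws, max(ws + 1, we - ds.read_length), size=n)
                for s in starts:
                    s = int(s)
                    e = min(size, s + ds.read_length)
                    if not _hits_feature(chrom, s, e):
                        reads.append(
                            ReadAlignment(
                                chrom=chrom, blocks=[(s, e)], strand=".",
                                dataset_id=ds.dataset_id,
                            )
                        )
        reads_by_dataset[ds.dataset_id] = reads

    # ribosome profiling + matched mRNA-seq
    ribo_reads: list[ReadAlignment] = []
    ribo_rna_reads: list[ReadAlignment] = []
    ribo_ds = DatasetInfo("ribo", "ribosome_profiling", cfg.ribo_total_mapped)
    rna_ds = DatasetInfo("ribo_matched_rna", "polyA+", 10_000_000)
    for t in all_tx:
        cat = truth[t.id].category
        feat = bundle.features[t.id]
        mean_rna = expected_count(base[t.id], t.exonic_length, rna_ds.total_mapped_reads)
        n_rna = int(rng.poisson(mean_rna)) if mean_rna > 0 else 0
        if n_rna:
            ribo_rna_reads.extend(
                _reads_from_transcript(t, n_rna, 75, rng, "ribo_matched_rna")
            )
        if cat == "protein_coding":
            cds_s, cds_e = feat.meta["cds_tx"]
            cds_len = cds_e - cds_s
            mean_r = base[t.id] * (cds_len / 1000.0) * cfg.ribo_depth_factor
            tx_range = (cds_s, cds_e)
        else:
            mean_r = (
                base[t.id] * (t.exonic_length / 1000.0)
                * cfg.ribo_depth_factor * cfg.ribo_leakage
            )
            tx_range = None
        n_r = int(rng.poisson(mean_r)) if mean_r > 0 else 0
        if n_r:
            ribo_reads.extend(
                _reads_from_transcript(
                    t, n_r, cfg.ribo_read_length, rng, "ribo", tx_range=tx_range
                )
            )

    # ChIP: IP enriched over planted mark intervals; input uniform
    expressed = [t for t in all_tx if base[t.id] > 1.0]
    n_marks = min(cfg.n_chip_marks, len(expressed))
    mark_idx = rng.choice(len(expressed), size=n_marks, replace=False)
    chip_marks = [
        GenomicInterval(
            expressed[int(i)].chrom, expressed[int(i)].start, expressed[int(i)].end,
            name=f"mark_{expressed[int(i)].id}",
        )
        for i in mark_idx
    ]
    chip_ip: list[ReadAlignment] = []
    chip_input: list[ReadAlignment] = []
    for chrom, size in bundle.genome.chromosomes:
        for target, rate in ((chip_ip, cfg.chip_background_per_kb),
                             (chip_input, cfg.chip_background_per_kb)):
            n = int(rng.poisson(rate * size / 1000.0))
            starts = rng.integers(0, size - 50, size=n)
            ds_id = "chip_ip" if target is chip_ip else "chip_input"
            target.extend(
                ReadAlignment(chrom=chrom, blocks=[(int(s), int(s) + 50)],
                              strand=".", dataset_id=ds_id)
                for s in starts
            )
    for mark in chip_marks:
        n = int(rng.poisson(cfg.chip_mark_extra_per_kb * mark.length / 1000.0))
        starts = rng.integers(mark.start, max(mark.start + 1, mark.end - 50), size=n)
        chip_ip.extend(
            ReadAlignment(chrom=mark.chrom, blocks=[(int(s), int(s) + 50)],
                          strand=".", dataset_id="chip_ip")
            for s in starts
        )

    return ReadsBundle(
        datasets=datasets,
        reads_by_dataset=reads_by_dataset,
        planted_fpkm=planted_fpkm,
        ribo_reads=ribo_reads,
        ribo_dataset=ribo_ds,
        ribo_rna_reads=ribo_rna_reads,
        ribo_rna_dataset=rna_ds,
        chip_ip_reads=chip_ip,
        chip_input_reads=chip_input,
        chip_marks=chip_marks,
    )


# ---------------------------------------------------------------------------
# tracks, SNPs, PET clusters
# ---------------------------------------------------------------------------

def simulate_snp_table(
    cfg: SimConfig,
    genome: GenomeSpec,
    linc_exons: Mapping[str, Sequence[tuple[int, int]]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Tested SNPs scattered uniformly, trait-associated at ``fold`` times
    the background rate inside lincRNA exons.

    Factored out of the track generator so enrichment recovery can be
    checked across many SNP-table replicates on one fixed annotation set.
    """
    chrom_names = [c for c, _ in genome.chromosomes]
    sizes = np.array([n for _, n in genome.chromosomes], dtype=float)
    n = cfg.n_tested_snps
    ci = rng.choice(len(chrom_names), size=n, p=sizes / sizes.sum())
    pos = rng.integers(0, sizes[ci].astype(np.int64))
    in_linc = np.zeros(n, dtype=bool)
    for k, chrom in enumerate(chrom_names):
        ivs = linc_exons.get(chrom, [])
        if not ivs:
            continue
        on = ci == k
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        idx = np.searchsorted(starts, pos[on], side="right") - 1
        ok = (idx >= 0) & (pos[on] < ends[np.clip(idx, 0, None)])
        in_linc[on] = ok
    rate = np.where(
        in_linc,
        cfg.tas_background_rate * cfg.tas_enrichment_fold,
        cfg.tas_background_rate,
    )
    platform = np.array(["illumina", "affymetrix", "both"])[
        rng.choice(3, size=n, p=list(cfg.platform_probs))
    ]
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:06d}" for i in range(n)],
            "chrom": [chrom_names[int(c)] for c in ci],
            "pos": pos.astype(int),
            "platform": platform,
            "trait_associated": rng.random(n) < rate,
            "common": rng.random(n) < cfg.common_snp_rate,
        }
    )


def simulate_tracks_and_snps(
    cfg: SimConfig, bundle: AnnotationBundle
) -> tuple[ScoreTrack, pd.DataFrame, list[TranscriptModel]]:
    """Conservation track, SNP table with planted TAS enrichment, and PET
    end clusters.

    The conservation track carries zero-mean Gaussian noise over the
    mappable genome (missing elsewhere), elevated by a fixed offset inside
    coding CDS exons and inside one window of a configured fraction of true
    lincRNAs. Trait-associated flags are assigned at ``fold`` times the
    background rate inside lincRNA exons.
    """
    rng = cfg.rng("tracks")
    genome = bundle.genome
    arrays = {}
    for chrom, n in genome.chromosomes:
        arr = rng.normal(0.0, cfg.conservation_baseline_sd, size=n)
        present = np.zeros(n, dtype=bool)
        for s, e in genome.mappability_mask.get(chrom, []):
            present[s:e] = True
        arr[~present] = np.nan
        arrays[chrom] = arr
    for gid, cds in bundle.cds_by_gene.items():
        chrom = bundle.features[gid].chrom
        for s, e in cds:
            arrays[chrom][s:e] += cfg.conservation_elevation
    lincs = [
        t for t in bundle.candidates
        if bundle.truth[t.id].category == "true_lincRNA"
    ]
    n_cons = int(round(cfg.conserved_linc_fraction * len(lincs)))
    conserved_ids = set()
    for i in rng.choice(len(lincs), size=n_cons, replace=False):
        t = lincs[int(i)]
        L = t.exonic_length
        w = min(cfg.conserved_window_bp, L)
        off = int(rng.integers(0, L - w + 1))
        for s, e in _project_tx_interval(t.exons, off, off + w):
            arrays[t.chrom][s:e] += cfg.conservation_elevation
        conserved_ids.add(t.id)
    track = ScoreTrack(scores=arrays)

    # SNPs
    linc_exons: dict[str, list[tuple[int, int]]] = {}
    for t in lincs:
        linc_exons.setdefault(t.chrom, []).extend(t.exons)
    linc_exons = {c: merge_intervals(v) for c, v in linc_exons.items()}
    snps = simulate_snp_table(cfg, genome, linc_exons, cfg.rng("snps"))

    # PET clusters at the true ends of a subset of genes + lincRNAs
    extras_rng = cfg.rng("extras")
    pool = bundle.genes + lincs
    n_pet = min(cfg.n_pet_clusters, len(pool))
    picks = extras_rng.choice(len(pool), size=n_pet, replace=False)
    clusters = []
    half = cfg.pet_block_bp // 2
    for k, i in enumerate(sorted(int(x) for x in picks)):
        t = pool[i]
        strand = bundle.features[t.id].true_strand
        b1 = (max(0, t.start - half), t.start + half)
        b2 = (t.end - half, min(dict(genome.chromosomes)[t.chrom], t.end + half))
        clusters.append(
            TranscriptModel(
                id=f"pet_{k + 1:03d}", chrom=t.chrom, strand=strand,
                exons=[b1, b2], source_tag=f"pet:{t.id}",
            )
        )
    bundle_conserved = conserved_ids
    for t in lincs:
        bundle.features[t.id].meta["conserved"] = t.id in bundle_conserved
    return track, snps, clusters


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    cfg: SimConfig
    genome: GenomeSpec
    sequences: dict[str, str]
    catalog: AnnotationCatalog
    candidates: list[TranscriptModel]
    genes: list[TranscriptModel]
    truth: dict[str, TruthLabel]
    cds_by_gene: dict[str, list[tuple[int, int]]]
    datasets: list[DatasetInfo]
    reads_by_dataset: dict[str, list[ReadAlignment]]
    planted_fpkm: pd.DataFrame
    conservation: ScoreTrack
    snps: pd.DataFrame
    pet_clusters: list[TranscriptModel]
    ribo_reads: list[ReadAlignment]
    ribo_dataset: DatasetInfo
    ribo_rna_reads: list[ReadAlignment]
    ribo_rna_dataset: DatasetInfo
    chip_ip_reads: list[ReadAlignment]
    chip_input_reads: list[ReadAlignment]
    chip_marks: list[GenomicInterval]
    features: dict[str, _Feature]

    def transcript_sequences(self) -> dict[str, str]:
        out = {}
        for t in self.candidates + self.genes:
            out[t.id] = spliced_sequence(self.sequences, t)
        return out

    def true_linc_ids(self) -> set[str]:
        return {
            tid for tid, lab in self.truth.items() if lab.category == "true_lincRNA"
        }

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": lab.transcript_id,
                    "category": lab.category,
                    "expected_fate": lab.expected_fate,
                }
                for lab in self.truth.values()
            ]
        ).sort_values("transcript_id").reset_index(drop=True)


def simulate(cfg: SimConfig | None = None) -> SimResult:
    """Run the full generator: genome -> features -> reads -> tracks/SNPs."""
    cfg = cfg if cfg is not None else SimConfig()
    genome = generate_genome(cfg)
    bundle = generate_annotations_and_transcripts(cfg, genome)
    reads = simulate_reads(cfg, bundle)
    track, snps, pets = simulate_tracks_and_snps(cfg, bundle)
    return SimResult(
        cfg=cfg,
        genome=genome,
        sequences=bundle.sequences,
        catalog=bundle.catalog,
        candidates=bundle.candidates,
        genes=bundle.genes,
        truth=bundle.truth,
        cds_by_gene=bundle.cds_by_gene,
        datasets=reads.datasets,
        reads_by_dataset=reads.reads_by_dataset,
        planted_fpkm=reads.planted_fpkm,
        conservation=track,
        snps=snps,
        pet_clusters=pets,
        ribo_reads=reads.ribo_reads,
        ribo_dataset=reads.ribo_dataset,
        ribo_rna_reads=reads.ribo_rna_reads,
        ribo_rna_dataset=reads.ribo_rna_dataset,
        chip_ip_reads=reads.chip_ip_reads,
        chip_input_reads=reads.chip_input_reads,
        chip_marks=reads.chip_marks,
        features=bundle.features,
    )
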