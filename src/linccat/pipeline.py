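"""End-to-end orchestration: simulate -> quantify -> filter -> merge ->
background significance -> characterization, with a manifest for provenance.

All outputs are plain tab-separated text (or BED/bedGraph/JSON); a rerun
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import background as bg
from . import characterize as ch
from . import coverage as cov
from .expression import build_expression_matrix
from .filters import run_cascade
from .intervals import TranscriptModel, merge_intervals, write_bed12_file
from .merge import MergedTranscript, build_catalog, write_membership_tsv
from .simulate import SimConfig, SimResult, simulate

PIPELINE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Every numeric threshold of the discovery procedure, plus run inputs."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "linccat_run"
    min_length: int = 200
    max_orf_aa: int = 100
    truncation_nt: int = 300
    proximity_bp: int = 1000
    fpkm_tiers: tuple[float, ...] = (1.0, 10.0, 30.0)
    merge_fraction: float = 0.5
    group_bp: int = 1000
    n_shuffles: int = 2000
    alpha: float = 0.1
    cluster_min_fpkm: float = 10.0

    def __post_init__(self) -> None:
        if list(self.fpkm_tiers) != sorted(self.fpkm_tiers) or len(
            set(self.fpkm_tiers)
        ) != len(self.fpkm_tiers):
            raise ValueError("fpkm_tiers must be strictly increasing")
        for name in ("min_length", "max_orf_aa", "truncation_nt", "proximity_bp",
                     "group_bp", "n_shuffles"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fpkm_tiers"] = list(self.fpkm_tiers)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        datasets = sim_raw.pop("datasets", None)
        sim = SimConfig(**sim_raw)
        if datasets is not None:
            from .simulate import DatasetSpec

            sim.datasets = [DatasetSpec(**d) for d in datasets]
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where a run lands is not part of what it computes
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    sim: SimResult
    matrix: "pd.DataFrame | object"
    tiered: dict[str, list[TranscriptModel]]
    report: object
    catalogs: dict[int, list[MergedTranscript]]
    merged_matrix: object
    significance: pd.DataFrame
    manifest: dict


def _write_tsv(path: Path, df: pd.DataFrame, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g",
              index=index_label is not None, index_label=index_label)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chdir = out / "characterization"
    chdir.mkdir(exist_ok=True)

    # ---- stage 0: simulate -------------------------------------------------
    sim = simulate(config.sim)
    sequences = sim.transcript_sequences()
    write_bed12_file(out / "candidates.bed", sim.candidates)
    write_bed12_file(out / "genes.bed", sim.genes)
    _write_tsv(out / "truth.tsv", sim.truth_frame())
    with open(out / "mappability_mask.bed", "w") as fh:
        for chrom in sorted(sim.genome.mappability_mask):
            for s, e in sim.genome.mappability_mask[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")

    # ---- stage 1: expression quantification -------------------------------
    all_tx = sim.candidates + sim.genes
    matrix = build_expression_matrix(sim.reads_by_dataset, all_tx, sim.datasets)
    matrix.to_tsv(out / "counts.tsv", out / "fpkm.tsv")

    # ---- stage 2: filter cascade ------------------------------------------
    tiered, report, large_orf_set = run_cascade(
        sim.candidates, sim.catalog, sequences, matrix,
        min_length=config.min_length, proximity_bp=config.proximity_bp,
    )
    report.to_tsv(out / "filter_report.tsv")
    write_bed12_file(out / "large_orf_transcripts.bed", large_orf_set)

    # ---- stage 3: merge / group / name per tier ---------------------------
    catalogs: dict[int, list[MergedTranscript]] = {}
    for tier_value, tier_name in zip((1, 10, 30), ("fpkm1", "fpkm10", "fpkm30")):
        merged = build_catalog(tiered[tier_name], tier_value, sequences=sim.sequences)
        catalogs[tier_value] = merged
        write_bed12_file(out / f"catalog_fpkm{tier_value}.bed", [m.model for m in merged])
        write_membership_tsv(out / f"membership_fpkm{tier_value}.tsv", merged)

    merged_models = [m.model for m in catalogs[1]]
    merged_matrix = build_expression_matrix(
        sim.reads_by_dataset, merged_models, sim.datasets
    )
    merged_matrix.to_tsv(out / "merged_counts.tsv", out / "merged_fpkm.tsv")

    # ---- stage 4: significance vs shuffled intergenic background ----------
    exclusions = bg.exclusion_union_from_annotations(
        sim.genome,
        [sim.genes, sim.candidates, merged_models],
        [
            sim.catalog.non_lincRNA_other,
            sim.catalog.utr_extensions,
            sim.catalog.extended_gene_boundaries,
        ],
    )
    space = bg.build_background_space(sim.genome, exclusions)
    rng = np.random.default_rng([config.sim.seed % (2**31), 1_000_003])
    significance = bg.significance_table(
        merged_models,
        space,
        sim.reads_by_dataset,
        sim.datasets,
        merged_matrix.fpkm,
        n_shuffles=config.n_shuffles,
        rng=rng,
        alpha=config.alpha,
    )
    _write_tsv(out / "significance.tsv", significance, index_label="transcript_id")

    # ---- stage 5: coverage quantitation -----------------------------------
    all_reads = [r for reads in sim.reads_by_dataset.values() for r in reads]
    cov_rows = []
    thresholds = [1, 2, 3, 5, 10]
    for mode in (cov.INCLUDING_INFERRED, cov.EXCLUDING_INFERRED):
        profile = cov.depth_profile(all_reads, sim.genome, mode)
        fracs = cov.covered_fraction_at_thresholds(profile, sim.genome, thresholds)
        for k in thresholds:
            cov_rows.append({"mode": mode, "min_reads": k, "fraction": fracs[k]})
    coverage_df = pd.DataFrame(cov_rows)
    _write_tsv(out / "coverage_thresholds.tsv", coverage_df)
    gene_exons: dict[str, list[tuple[int, int]]] = {}
    for g in sim.genes:
        gene_exons.setdefault(g.chrom, []).extend(g.exons)
    gene_exons = {c: merge_intervals(v) for c, v in gene_exons.items()}
    region_dist = cov.read_region_distribution(
        sim.reads_by_dataset, gene_exons, sim.genome.chrom_sizes
    )
    _write_tsv(
        out / "read_region_distribution.tsv",
        pd.DataFrame(
            [
                {"dataset_id": ds, "exonic_fraction": ex, "other_fraction": other}
                for ds, (ex, other) in sorted(region_dist.items())
            ]
        ),
    )

    # ---- stage 6: characterization ----------------------------------------
    ribo_idx = ch.SpanIndex(sim.ribo_reads) if sim.ribo_reads else None
    rna_idx = ch.SpanIndex(sim.ribo_rna_reads) if sim.ribo_rna_reads else None

    def _ratio(t: TranscriptModel) -> float | None:
        if ribo_idx is None or rna_idx is None:
            return None
        return ch.max_window_read_ratio(
            t,
            ribo_idx.overlapping_span(t.chrom, t.start, t.end),
            rna_idx.overlapping_span(t.chrom, t.start, t.end),
        )

    ribo_rows = []
    for m in catalogs[1]:
        ribo_rows.append(
            {"feature": m.name, "class": "lincRNA", "max_window_ratio": _ratio(m.model)}
        )
    for g in sim.genes:
        cds = sim.cds_by_gene.get(g.id)
        if not cds:
            continue
        cds_model = TranscriptModel(
            id=f"{g.id}_CDS", chrom=g.chrom, strand=g.strand, exons=list(cds)
        )
        ribo_rows.append(
            {"feature": cds_model.id, "class": "CDS", "max_window_ratio": _ratio(cds_model)}
        )
    ribo_df = pd.DataFrame(ribo_rows)
    _write_tsv(chdir / "ribosome_ratios.tsv", ribo_df)

    cons_rows = []
    for m in catalogs[1]:
        cons_rows.append(
            {
                "feature": m.name,
                "class": "lincRNA",
                "max_window_phylop": ch.max_conserved_window(m.model, sim.conservation),
            }
        )
    for g in sim.genes:
        cons_rows.append(
            {
                "feature": g.id,
                "class": "coding_gene",
                "max_window_phylop": ch.max_conserved_window(g, sim.conservation),
            }
        )
    cons_df = pd.DataFrame(cons_rows)
    _write_tsv(chdir / "conservation.tsv", cons_df)

    linc_exon_region: dict[str, list[tuple[int, int]]] = {}
    for m in catalogs[1]:
        linc_exon_region.setdefault(m.model.chrom, []).extend(m.model.exons)
    linc_exon_region = {c: merge_intervals(v) for c, v in linc_exon_region.items()}
    background_region = {c: list(ivs) for c, ivs in space.intervals.items()}
    enr = ch.tas_enrichment(
        linc_exon_region, background_region, sim.snps,
        label_a="lincRNA_exons", label_b="background_loci",
    )
    gene_enr = ch.tas_enrichment(
        gene_exons, background_region, sim.snps,
        label_a="coding_exons", label_b="background_loci",
    )
    tas_df = pd.DataFrame(
        [dataclasses.asdict(enr), dataclasses.asdict(gene_enr)]
    )
    _write_tsv(chdir / "tas_enrichment.tsv", tas_df)
    snp_density_rows = []
    for label, region in (
        ("lincRNA_exons", linc_exon_region),
        ("coding_exons", gene_exons),
        ("background_loci", background_region),
    ):
        n_snp, bp, dens = ch.common_snp_density(region, sim.snps)
        snp_density_rows.append(
            {"region": label, "common_snps": n_snp, "bp": bp, "density": dens}
        )
    _write_tsv(chdir / "common_snp_density.tsv", pd.DataFrame(snp_density_rows))

    # polyA bimorphism: lincRNAs and coding genes, first two tissues
    tissues = config.sim.tissues[:2]
    renames = {
        f"{t}_polyA_plus": f"{t}_polyA+" for t in tissues
    } | {f"{t}_polyA_minus": f"{t}_polyA-" for t in tissues}
    polya_out = {}
    for label, mat in (("lincRNA", merged_matrix), ("coding_gene", matrix)):
        counts_df = mat.counts.rename(columns=renames)
        fpkm_df = mat.fpkm.rename(columns=renames)
        if label == "coding_gene":
            gene_ids = [g.id for g in sim.genes]
            counts_df = counts_df.loc[gene_ids]
            fpkm_df = fpkm_df.loc[gene_ids]
        try:
            ratios, r = ch.polya_ratio_analysis(counts_df, fpkm_df, tissues)
            polya_out[label] = (ratios, r)
        except ValueError:
            polya_out[label] = (pd.DataFrame(), float("nan"))
    polya_summary = pd.DataFrame(
        [
            {
                "class": label,
                "n_features": len(ratios),
                "pearson_r_log2_ratios": r,
                "median_log2_ratio": float(ratios.stack().median()) if len(ratios) else float("nan"),
            }
            for label, (ratios, r) in polya_out.items()
        ]
    )
    _write_tsv(chdir / "polya_bimorphism.tsv", polya_summary)

    chip_rows = []
    ip_idx = ch.SpanIndex(sim.chip_ip_reads) if sim.chip_ip_reads else None
    in_idx = ch.SpanIndex(sim.chip_input_reads) if sim.chip_input_reads else None
    for m in catalogs[1]:
        t = m.model
        ratio = None
        if ip_idx is not None and in_idx is not None:
            ratio = ch.chip_signal_ratio(
                t,
                ip_idx.overlapping_span(t.chrom, t.start, t.end),
                in_idx.overlapping_span(t.chrom, t.start, t.end),
                config.sim.chip_total_mapped,
                config.sim.chip_total_mapped,
            )
        chip_rows.append({"feature": m.name, "ip_over_input": ratio})
    _write_tsv(chdir / "chip_signal.tsv", pd.DataFrame(chip_rows))

    pet_rows = []
    for m in catalogs[1]:
        five, three = ch.pet_end_support(m.model, sim.pet_clusters)
        pet_rows.append(
            {"feature": m.name, "five_prime": five, "three_prime": three}
        )
    _write_tsv(chdir / "pet_support.tsv", pd.DataFrame(pet_rows))

    cluster_info = {}
    try:
        dist_df, Z = ch.cluster_samples(
            merged_matrix.fpkm, min_fpkm=config.cluster_min_fpkm
        )
        _write_tsv(chdir / "sample_distances.tsv", dist_df, index_label="sample")
        _write_tsv(
            chdir / "linkage.tsv",
            pd.DataFrame(Z, columns=["left", "right", "distance", "size"]),
        )
        cluster_info = {"n_samples": int(dist_df.shape[0])}
    except ValueError:
        cluster_info = {"n_samples": 0}

    # ---- manifest ----------------------------------------------------------
    stage_counts = report.stage_counts()
    manifest = {
        "version": PIPELINE_VERSION,
        "seed": config.sim.seed,
        "config_hash": config.config_hash(),
        "n_candidates": len(sim.candidates),
        "n_retained_fpkm1": len(tiered["fpkm1"]),
        "n_merged": {str(k): len(v) for k, v in catalogs.items()},
        "n_groups": {
            str(k): len({m.group_id for m in v}) for k, v in catalogs.items()
        },
        "stage_counts": stage_counts,
        "n_significant": int(significance["significant"].sum()),
        "clustering": cluster_info,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    hashes = {
        p.name: _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "checksums.json"
    }
    (out / "checksums.json").write_text(
        json.dumps(hashes, indent=2, sort_keys=True) + "\n"
    )

    return PipelineResult(
        config=config,
        sim=sim,
        matrix=matrix,
        tiered=tiered,
        report=report,
        catalogs=catalogs,
        merged_matrix=merged_matrix,
        significance=significance,
        manifest=manifest,
    )
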