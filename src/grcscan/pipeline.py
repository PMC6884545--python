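"""End-to-end pipeline driver: simulate -> coverage -> SNV -> copy number ->
enrichment -> strata, with full provenance in a single JSON report.

Every threshold of the method is held in :class:`PipelineConfig` with its
published default and can be overridden; the config and seed are embedded in
the report so a rerun regenerates it byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage, copynum, enrichment, io, simulate, snv, strata

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the GRC discovery pipeline.

    Defaults are the published operating point: 5-kb calling windows,
    inclusive log2 >= 2 ratio cut-off, 30-60% GC bounds, 5th-percentile
    low-coverage filter, >=10 germline-read / zero-soma-read SNV rule with
    >=10x soma depth required, >=5 SNVs for high confidence, RNA support at
    >=100 reads and >1% alt/ref ratio, f = 0.364 GRCs per haploid set,
    167.3 Mb GRC size, 10,000 randomisation draws.
    """

    # coverage
    window_size: int = 5000
    plot_window_size: int = 1000
    cutoff_log2: float = 2.0
    gc_bounds: tuple[float, float] = (0.30, 0.60)
    low_pct: float = 5.0
    # snv
    min_germ: int = 10
    min_soma_depth: int = 10
    count_mode: str = "allele"
    min_snvs: int = 5
    rna_min_reads: int = 100
    rna_min_ratio: float = 0.01
    # copy number / cytogenetics
    grc_fraction: float = 0.364
    grc_size_mb: float = 167.3
    germline_genome_size_bp: float | None = None  # explicit override if desired
    # enrichment
    n_reps: int = 10_000
    # simulation (used when no input files are given)
    sim_n_chrom: int = 1
    sim_chrom_len: int = 600_000
    sim_n_genes: int = 24
    sim_gene_length: int = 12_000
    sim_n_grc_genes: int = 6
    sim_copies: tuple[int, ...] = (9, 9, 20, 20, 50, 308)
    sim_divergence_rate: float = 0.01
    sim_depth_soma: float = 20.0
    sim_error_rate: float = 0.0
    sim_gc_profile: tuple[float, float] = (0.32, 0.58)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gc_bounds"] = list(self.gc_bounds)
        d["sim_copies"] = list(self.sim_copies)
        d["sim_gc_profile"] = list(self.sim_gc_profile)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.gc_bounds = tuple(cfg.gc_bounds)
        cfg.sim_copies = tuple(cfg.sim_copies)
        cfg.sim_gc_profile = (
            tuple(cfg.sim_gc_profile)
            if not np.isscalar(cfg.sim_gc_profile)
            else cfg.sim_gc_profile
        )
        return cfg


def _simulate_stage(config: PipelineConfig, seed: int):
    reference, annotation = simulate.simulate_genome(
        config.sim_n_chrom,
        config.sim_chrom_len,
        config.sim_n_genes,
        gc_profile=config.sim_gc_profile,
        seed=seed,
        gene_length=config.sim_gene_length,
    )
    rng = np.random.default_rng(seed + 1)
    n_grc = min(config.sim_n_grc_genes, len(annotation))
    chosen = sorted(rng.choice(len(annotation), size=n_grc, replace=False))
    copies = list(config.sim_copies)
    genes = tuple(
        simulate.GrcGene(
            annotation.iloc[int(i)]["gene_id"],
            int(copies[j % len(copies)]),
            config.sim_divergence_rate,
        )
        for j, i in enumerate(chosen)
    )
    grc = simulate.GrcModel(
        grc_fraction=config.grc_fraction, genes=genes, grc_size_mb=config.grc_size_mb
    )
    return simulate.simulate_pileups(
        reference,
        annotation,
        grc,
        depth_soma=config.sim_depth_soma,
        error_rate=config.sim_error_rate,
        seed=seed + 2,
    )


def run_pipeline(config: PipelineConfig, seed: int = 0, outdir=None) -> dict:
    """Run every stage on a simulated dataset and return the JSON-able report.

    When ``outdir`` is given, windows/blocks BED, the SNV VCF, consensus
    FASTA, copy-number TSV, truth tables and the report itself are written
    there. A stage failure raises with the stage name attached.
    """
    report: dict = {"config": config.to_dict(), "seed": seed}
    stage = "simulate"
    try:
        ds = _simulate_stage(config, seed)
        truth_genes = sorted(ds.grc.gene_ids)
        report["simulate"] = {
            "assembly_size": ds.assembly_size,
            "n_genes": int(len(ds.annotation)),
            "grc_genes": truth_genes,
            "n_truth_snvs": int(len(ds.truth_snvs)),
            "library_bases": ds.library_bases,
        }

        stage = "coverage"
        cov = coverage.scan_coverage(
            ds.germline_pileup,
            ds.soma_pileup,
            ds.reference,
            annotation=ds.annotation,
            window_size=config.window_size,
            cutoff_log2=config.cutoff_log2,
            gc_bounds=config.gc_bounds,
            low_pct=config.low_pct,
        )
        report["coverage"] = {
            "n_amplified_windows": int(cov.windows["amplified"].sum()),
            "n_blocks": int(cov.blocks["is_block"].sum()) if len(cov.blocks) else 0,
            "n_singletons": int((~cov.blocks["is_block"]).sum()) if len(cov.blocks) else 0,
            "n_soma_excess": cov.n_soma_excess,
            "slope": cov.slope,
            "amplified_genes": cov.genes,
        }

        stage = "snv"
        calls = snv.call_specific_snvs(
            ds.germline_pileup,
            ds.soma_pileup,
            ds.reference,
            min_germ=config.min_germ,
            min_soma_depth=config.min_soma_depth,
            count_mode=config.count_mode,
        )
        n_neg = snv.negative_control(
            ds.germline_pileup,
            ds.soma_pileup,
            ds.reference,
            min_germ=config.min_germ,
            min_soma_depth=config.min_soma_depth,
            count_mode=config.count_mode,
        )
        summary = snv.summarise_genes(
            calls, ds.annotation, amplified_genes=cov.genes, min_snvs=config.min_snvs
        )
        high_conf = summary.loc[summary["high_confidence"], "gene_id"].tolist()
        report["snv"] = {
            "n_calls": int(len(calls)),
            "n_soma_specific": int(n_neg),
            "high_confidence_genes": high_conf,
            "n_high_confidence": len(high_conf),
        }

        stage = "copy_number"
        genome_size_germ = (
            config.germline_genome_size_bp
            if config.germline_genome_size_bp is not None
            else ds.germline_genome_size()
        )
        cn_germ = copynum.gene_copy_numbers(
            ds.germline_pileup, ds.annotation, ds.library_bases["germline"], genome_size_germ
        )
        cn_soma = copynum.gene_copy_numbers(
            ds.soma_pileup, ds.annotation, ds.library_bases["soma"], ds.assembly_size
        )
        grc_cn = cn_germ[cn_germ["gene_id"].isin(truth_genes)]
        report["copy_number"] = {
            "germline_genome_size": float(genome_size_germ),
            "grc_gene_estimates": {
                r["gene_id"]: round(float(r["copies_per_haploid"]), 3)
                for _, r in grc_cn.iterrows()
            },
            "median_soma_cn": float(cn_soma["copies_per_haploid"].median()),
        }

        stage = "enrichment"
        expr = simulate.simulate_expression_table(
            max(400, 4 * len(ds.annotation)),
            tissue_probs={"brain": 0.3, "heart": 0.1, "kidney": 0.1, "liver": 0.1, "testis": 0.25, "ovary": 0.15},
            seed=seed + 3,
            frac_unexpressed=0.05,
        )
        background = enrichment.build_background(expr)
        rng = np.random.default_rng(seed + 4)
        query = list(rng.choice(background.index, size=min(40, len(background)), replace=False))
        enr = enrichment.randomisation_test(
            background, query, n_reps=config.n_reps, seed=seed + 5
        )
        report["enrichment"] = {
            "background_size": enr.background_size,
            "observed": enr.observed,
            "p_enrich": enr.p_enrich,
            "p_enrich_plus1": enr.p_enrich_plus1,
            "p_under_other": enr.p_under_other,
        }

        stage = "strata"
        trees = {
            f"sim_s{s}_{i}": simulate.simulate_gene_tree(s, seed=seed * 100 + s * 10 + i)
            for s in (1, 2, 3, 4, 5)
            for i in range(2)
        }
        assigned = strata.assign_strata(trees)
        correct = sum(
            int(str(r["stratum"]) == r["gene_id"].split("_")[1][1])
            for _, r in assigned.iterrows()
        )
        report["strata"] = {
            "n_trees": int(len(assigned)),
            "n_correct": int(correct),
            "assignments": {
                r["gene_id"]: (None if pd.isna(r["stratum"]) else int(r["stratum"]))
                for _, r in assigned.iterrows()
            },
        }
    except Exception as exc:  # tag failures with the stage that raised
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(ds.reference, outdir / "reference.fa")
        io.write_bed(ds.annotation, outdir / "genes.bed")
        io.write_bed(cov.windows[cov.windows["amplified"]], outdir / "amplified_windows.bed", score="log2_ratio")
        io.write_bed(cov.blocks, outdir / "amplified_blocks.bed")
        io.write_vcf(calls, outdir / "germline_specific.vcf",
                     contigs={c: len(s) for c, s in ds.reference.items()})
        cn_germ.to_csv(outdir / "copy_number_germline.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "gene_snv_summary.tsv", sep="\t", index=False)
        io.write_truth(ds, outdir)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
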