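"""End-to-end orchestration: simulate/ingest -> QC -> iHS -> scan -> annotate.

A single flat YAML config drives the whole run.  The default thresholds are
the standard ones for a resequencing-based iHS scan: MAF >= 5%, missing
rate <= 10%, HWE exact p >= 1e-6, 800 kb maximum inter-SNP spacing, EHH
cutoff 0.05, 100 standardization bins, 50 kb windows with >= 10 SNPs and a
top-1% selection fraction, BH-FDR < 0.05 for QTL enrichment.

When no input VCF is configured the pipeline simulates a toy genome with
the built-in Wright-Fisher model, writes it as a phased VCF, and (when no
annotation files are given) generates toy gene/QTL annotations, so a
default run is fully self-contained and deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .annotate import annotation_frame, annotation_summary, intersect, read_gene_annotation
from .ehh_ihs import ScanOptions, scan_chromosome, scores_frame, standardize
from .qtl_enrich import annotate_qtls, enrich, enrichment_frame, read_qtl_table
from .synthetic_data import (
    SimParams,
    simulate_genome,
    write_toy_annotations,
    write_vcf,
)
from .vcf_qc import QCThresholds, apply_qc, qc_report_frame, read_phased_vcf

log = logging.getLogger("sweepscan")


@dataclass
class RunConfig:
    """Flat configuration of one scan run (YAML round-trippable)."""

    seed: int = 0
    out_dir: str = "sweepscan_out"

    # inputs; when vcf is None a simulation is run instead
    vcf: str | None = None
    genes: str | None = None
    qtls: str | None = None
    ancestral_source: str = "REF"

    # simulation (used only when vcf is None)
    n_chromosomes: int = 6
    n_diploids: int = 200
    n_generations: int = 800
    seq_length: int = 1_000_000
    mu: float = 8e-7
    rho: float = 1.5e-6
    s: float = 0.0
    h: float = 0.5
    sweep_pos: int = 525_000
    sweep_intro_gen: int = 756
    sweep_freq_range: list | None = None
    sample_n: int = 60
    missing_rate: float = 0.0

    # site QC
    maf: float = 0.05
    max_missing: float = 0.10
    hwe_p: float = 1e-6

    # EHH / iHS
    max_gap_bp: int = 800_000
    ehh_cutoff: float = 0.05
    n_bins: int = 100

    # window scan
    window_size: int = 50_000
    min_snps: int = 10
    top_fraction: float = 0.01

    # enrichment
    fdr: float = 0.05

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run(config: RunConfig) -> dict:
    """Execute all stages in order and return the summary report.

    Per-stage tables are written as TSV under ``config.out_dir`` together
    with ``summary.json`` and a run log.  Identical config and inputs give
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    log.info(
        "sweepscan %s | seed=%d | config %s", __version__, config.seed, config.digest()
    )
    t0 = time.time()
    report: dict = {"config_digest": config.digest(), "seed": config.seed}

    stage = "input"
    try:
        if config.vcf is None:
            stage = "simulate"
            base = SimParams(
                n_diploids=config.n_diploids,
                n_generations=config.n_generations,
                seq_length=config.seq_length,
                mu=config.mu,
                rho=config.rho,
                s=config.s,
                h=config.h,
                sweep_pos=config.sweep_pos if config.s > 0 else None,
                sweep_intro_gen=config.sweep_intro_gen,
                sweep_freq_range=(
                    tuple(config.sweep_freq_range)
                    if config.sweep_freq_range
                    else None
                ),
                sample_n=config.sample_n,
                missing_rate=config.missing_rate,
                seed=config.seed,
            )
            matrices, truths = simulate_genome(base, config.n_chromosomes)
            vcf_path = out / "simulated.vcf"
            write_vcf(matrices, vcf_path)
            report["simulated"] = True
            report["truth"] = [dataclasses.asdict(t) for t in truths]
            log.info("simulated %d chromosomes -> %s", len(matrices), vcf_path)
        else:
            vcf_path = Path(config.vcf)
            report["simulated"] = False

        genes_path, qtls_path = config.genes, config.qtls
        if config.vcf is None and genes_path is None and qtls_path is None:
            stage = "toy_annotations"
            genes_path = out / "toy_genes.bed"
            qtls_path = out / "toy_qtls.tsv"
            _toy_annotations(config, genes_path, qtls_path)

        stage = "read_vcf"
        matrices, read_report = read_phased_vcf(
            vcf_path, ancestral_source=config.ancestral_source
        )
        report["sites_in"] = read_report.n_kept
        report["sites_excluded_at_read"] = (
            read_report.n_sex_chrom
            + read_report.n_not_biallelic
            + read_report.n_unknown_ancestral
        )

        stage = "qc"
        th = QCThresholds(
            max_missing=config.max_missing,
            min_maf=config.maf,
            min_hwe_p=config.hwe_p,
        )
        clean, qc_records = [], []
        for hm in matrices:
            c, recs = apply_qc(hm, th)
            clean.append(c)
            qc_records.extend(recs)
        qc_report_frame(qc_records).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        report["sites_after_qc"] = sum(hm.n_sites for hm in clean)
        log.info("QC: %d -> %d sites", report["sites_in"], report["sites_after_qc"])

        stage = "ihs"
        opts = ScanOptions(
            ehh_cutoff=config.ehh_cutoff, max_gap_bp=config.max_gap_bp
        )
        scores = []
        for hm in clean:
            scores.extend(scan_chromosome(hm, opts))
        scores, bins = standardize(scores, n_bins=config.n_bins)
        scores_frame(scores).to_csv(out / "ihs.tsv", sep="\t", index=False)
        report["scored_sites"] = sum(1 for s in scores if s.valid)
        log.info("iHS: %d/%d sites scored", report["scored_sites"], len(scores))

        stage = "scan"
        from .window_scan import bin_scores, filter_windows, select_top, windows_frame

        windows = bin_scores(scores, window_size=config.window_size)
        retained = filter_windows(windows, min_snps=config.min_snps)
        selected = select_top(retained, fraction=config.top_fraction)
        windows_frame(retained, selected).to_csv(
            out / "windows.tsv", sep="\t", index=False
        )
        report["windows_total"] = len(windows)
        report["windows_retained"] = len(retained)
        report["regions_selected"] = len(selected)
        report["abs_ihs_threshold"] = selected[-1].threshold if selected else None
        log.info(
            "scan: %d windows, %d retained, %d selected (threshold %s)",
            len(windows),
            len(retained),
            len(selected),
            report["abs_ihs_threshold"],
        )

        if genes_path is not None:
            stage = "annotate"
            genes = read_gene_annotation(genes_path)
            annotations = intersect(selected, genes)
            annotation_frame(annotations).to_csv(
                out / "annotated_regions.tsv", sep="\t", index=False
            )
            summ = annotation_summary(annotations)
            report["regions_with_genes"] = summ["n_regions_with_genes"]
            report["candidate_genes"] = summ["n_distinct_genes"]
            report["gene_list"] = summ["genes"]

        if qtls_path is not None:
            stage = "qtl"
            qtls = read_qtl_table(qtls_path)
            hits, class_table, trait_table = annotate_qtls(selected, qtls)
            class_table.to_csv(out / "qtl_class_proportions.tsv", sep="\t", index=False)
            trait_table.to_csv(out / "qtl_trait_proportions.tsv", sep="\t", index=False)
            report["qtls_overlapping"] = len(hits)
            if hits:
                results = enrich(hits, qtls, fdr_threshold=config.fdr)
                enrichment_frame(results).to_csv(
                    out / "qtl_enrichment.tsv", sep="\t", index=False
                )
                report["significant_traits"] = [
                    r.trait_name for r in results if r.significant
                ]
            else:
                report["significant_traits"] = []
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # runtime goes to the log only, keeping summary.json byte-stable
    (out / "summary.json").write_text(json.dumps(report, indent=2) + "\n")
    config.to_yaml(out / "config_used.yaml")
    log.info("done in %.1fs -> %s", time.time() - t0, out / "summary.json")
    return report


def _toy_annotations(config: RunConfig, genes_path, qtls_path) -> None:
    """Deterministic toy gene/QTL annotations spanning the simulated genome."""
    gene_regions = []
    k = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for start in range(50_000, config.seq_length - 50_000, 150_000):
            k += 1
            gene_regions.append((chrom, start, start + 30_000, f"GENE{k:03d}"))
    trait_counts = {
        "Milk fat percentage": 40,
        "Calving ease": 30,
        "Longissimus muscle area": 20,
        "Stature": 15,
        "Somatic cell score": 15,
    }
    trait_classes = {
        "Milk fat percentage": "Milk",
        "Calving ease": "Reproduction",
        "Longissimus muscle area": "Meat and Carcass",
        "Stature": "Exterior",
        "Somatic cell score": "Health",
    }
    # QTLs are written per chromosome name chr1; spread them over all
    # chromosomes by cycling the chrom field after generation
    write_toy_annotations(
        gene_regions,
        genes_path,
        qtls_path,
        trait_counts=trait_counts,
        trait_classes=trait_classes,
        chrom="chr1",
        seq_length=config.seq_length,
        seed=config.seed + 7,
    )
    _spread_qtls(qtls_path, config.n_chromosomes, config.seed + 11)


def _spread_qtls(path, n_chromosomes: int, seed: int) -> None:
    import numpy as np
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    rng = np.random.default_rng(seed)
    df["chrom"] = [f"chr{rng.integers(1, n_chromosomes + 1)}" for _ in range(len(df))]
    df.to_csv(path, sep="\t", index=False)


def _setup_logging(logfile) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_sweepscan_tag", None) for h in log.handlers}
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if "console" not in have:
        h = logging.StreamHandler()
        h.setFormatter(fmt)
        h._sweepscan_tag = "console"
        log.addHandler(h)
    for h in list(log.handlers):
        if getattr(h, "_sweepscan_tag", None) == "file":
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile, mode="a")
    fh.setFormatter(fmt)
    fh._sweepscan_tag = "file"
    log.addHandler(fh)
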