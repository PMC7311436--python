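"""End-to-end orchestration of the synthetic ASE scan.

simulate -> genotype QC -> diploid counting -> imbalance calling ->
profiling -> annotation, with one config and one seed; every stage writes
its artifact and the run closes with a consolidated JSON report.  Given
the same config and seed, all artifacts are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, io, profiles, synth
from .asecall import AllelicImbalance, CallConfig
from .diploid import build_haplotypes, count_alleles, coverage_filter
from .genoqc import QCConfig, apply_qc
from .panel import Panel
from .synth import SimulationConfig


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    call: CallConfig = field(default_factory=CallConfig)
    min_ase_individuals: int = 5  # direction / restricted subsets

    def __post_init__(self) -> None:
        if self.min_ase_individuals < 1:
            raise ValueError("min_ase_individuals must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.get("sim", {})
        if "theta_classes" in sim:
            sim["theta_classes"] = tuple(tuple(tc) for tc in sim["theta_classes"])
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        return cls(
            sim=SimulationConfig(**sim),
            qc=QCConfig(**raw.get("qc", {})),
            call=CallConfig(**raw.get("call", {})),
            min_ase_individuals=raw.get("min_ase_individuals", 5),
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def simulate_stage(config: RunConfig, outdir: Path) -> tuple[dict, Panel, pd.DataFrame, dict]:
    ref_rng, panel_rng, truth_rng, read_rng = config.sim.spawn_rngs()
    reference = synth.generate_reference(config.sim, ref_rng)
    panel = synth.generate_panel(reference, config.sim, panel_rng)
    truth = synth.assign_truth(panel, config.sim, truth_rng)
    reads = synth.generate_reads(reference, panel, truth, config.sim, read_rng)

    io.write_fasta(reference, outdir / "reference.fa")
    io.write_vcf(panel, outdir / "panel.vcf")
    io.write_tsv(truth, outdir / "truth.tsv")
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for ind in panel.individuals:
        io.write_fastq_gz(reads[ind], reads_dir / f"{ind}.fq.gz")
    return reference, panel, truth, reads


def count_stage(
    reference: dict, panel: Panel, reads: dict, outdir: Path
) -> pd.DataFrame:
    frames = []
    for ind in panel.individuals:
        pair = build_haplotypes(reference, panel, ind)
        frames.append(count_alleles(reads.get(ind, []), pair, panel))
    counts = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["individual", "site_id", "chrom", "pos", "ref_count", "alt_count"])
    )
    io.write_tsv(counts, outdir / "counts.tsv")
    return counts


def run_end_to_end(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage, write all artifacts, return the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.sim.seed}

    try:
        reference, panel, truth, reads = simulate_stage(config, outdir)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    report["n_sites_simulated"] = panel.n_sites
    report["n_individuals_simulated"] = panel.n_individuals

    try:
        qc = apply_qc(panel, config.qc)
        io.write_tsv(qc.site_report, outdir / "qc_report.tsv")
        io.write_vcf(qc.panel, outdir / "qc_panel.vcf")
    except Exception as e:  # noqa: BLE001
        raise StageError("genoqc", e) from e
    report["n_individuals_kept"] = len(qc.kept_individuals)
    report["n_sites_kept"] = qc.panel.n_sites
    report["n_sites_removed"] = panel.n_sites - qc.panel.n_sites

    try:
        counts = count_stage(reference, qc.panel, reads, outdir)
        kept, testable = coverage_filter(counts, config.call.min_coverage)
        io.write_tsv(kept, outdir / "counts_covered.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("count", e) from e
    report["n_het_observations"] = len(counts)
    report["n_observations_covered"] = len(kept)
    report["n_testable_sites"] = int(testable.sum())

    try:
        results = AllelicImbalance(kept, config.call).fit()
        io.write_tsv(results.calls, outdir / "calls.tsv")
        (outdir / "summary.txt").write_text(results.summary())
    except Exception as e:  # noqa: BLE001
        raise StageError("call", e) from e
    report["n_tests"] = results.n_tests
    report["n_significant"] = results.n_significant
    report["n_monoallelic"] = results.n_monoallelic
    report["significant_fraction_pct"] = (
        profiles.round_half_up(100.0 * results.n_significant / results.n_tests)
        if results.n_tests
        else 0.0
    )

    try:
        summaries = results.site_summaries()
        io.write_tsv(summaries, outdir / "site_summary.tsv")
        parts = profiles.classify_sites(summaries)
        hist = profiles.occurrence_histogram(summaries)
        direction = profiles.direction_analysis(
            results.calls, qc.panel.sites, config.min_ase_individuals
        )
        io.write_tsv(direction, outdir / "direction.tsv")
        if len(summaries):
            chrom_dist = profiles.chromosome_distribution(
                summaries, qc.panel.sites, config.min_ase_individuals
            )
            io.write_tsv(chrom_dist, outdir / "chromosomes.tsv")
        ind_tab, r2 = profiles.individual_profile(results.calls)
        io.write_tsv(ind_tab, outdir / "individual_summary.tsv")
        hist_tab = pd.DataFrame(
            {
                "n_ase": hist["counts"].index,
                "n_sites": hist["counts"].to_numpy(),
            }
        )
        io.write_tsv(hist_tab, outdir / "occurrence_histogram.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("profile", e) from e
    report["n_ase_sites"] = len(parts["ase"])
    report["n_biallelic_sites"] = len(parts["biallelic"])
    report["ase_site_pct"] = (
        profiles.round_half_up(100.0 * len(parts["ase"]) / len(summaries))
        if len(summaries)
        else 0.0
    )
    report["occurrence_bins"] = hist["bins"]
    report["occurrence_percent"] = hist["percent"]
    report["tested_vs_ase_r_squared"] = None if r2 is None else round(r2, 4)
    dir_counts = direction["direction"].value_counts().to_dict()
    report["direction_counts"] = {k: int(v) for k, v in dir_counts.items()}

    try:
        models = synth.generate_gene_models(reference, config.sim)
        io.write_gff3(models, outdir / "genes.gff3")
        ase_sites = qc.panel.sites[qc.panel.sites["site_id"].isin(parts["ase"])]
        cons = annotate.classify_sites(ase_sites, models, reference)
        io.write_tsv(cons, outdir / "consequences.tsv")
        top = profiles.top_sites(summaries, 10, qc.panel.sites[["site_id", "chrom", "pos"]])
        top = top.merge(cons[["site_id", "gene_ids", "consequence"]], on="site_id", how="left")
        io.write_tsv(top, outdir / "top_sites.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("annotate", e) from e
    if len(cons):
        pcts = (
            cons["consequence"].value_counts(normalize=True).mul(100).round(2).to_dict()
        )
    else:
        pcts = {}
    report["consequence_percent"] = pcts

    # truth-based evaluation (synthetic runs only)
    merged = results.calls.merge(truth, on=["site_id", "individual"], how="left")
    mono_truth = merged[merged["class_label"] == "monoallelic"]
    if len(mono_truth):
        report["monoallelic_truth_recall_pct"] = profiles.round_half_up(
            100.0 * mono_truth["monoallelic"].mean()
        )
    null_truth = merged[merged["class_label"] == "null"]
    if len(null_truth):
        report["null_significant_pct"] = profiles.round_half_up(
            100.0 * null_truth["significant"].mean()
        )

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
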