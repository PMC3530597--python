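"""End-to-end orchestration: simulate -> harmonize -> QC -> burden ->
phenotypes -> association -> report.

All stage outputs are header-carrying TSVs under one output directory,
plus a JSON summary and an echo of the full configuration; a rerun with
the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, burden, harmonize, phenotypes, qc, synthetic
from .config import PipelineConfig, save_config
from .io import write_gene_bed, write_tsv

logger = logging.getLogger(__name__)

CALLER_A = "caller_A"
CALLER_B = "caller_B"


def truth_as_consensus(truth: pd.DataFrame, marker_map: pd.DataFrame) -> pd.DataFrame:
    """View a truth set in consensus-table form (for burden on ground truth)."""
    idx = harmonize.MarkerIndex.from_frame(marker_map)
    df = truth.copy()
    df["dosage_class"] = np.where(df["copy_number"] < 2, "deletion", "duplication")
    df["length_bp"] = df["end_bp"] - df["start_bp"] + 1
    df["n_markers"] = [
        idx.count(str(r.chromosome), int(r.start_bp), int(r.end_bp))
        for r in df.itertuples(index=False)
    ]
    return df


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Returns a dict of the in-memory stage results. Raises on missing or
    inconsistent inputs with the failing stage named; outputs written by
    earlier stages are left intact.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "run_config.yaml")
    sim = config.simulation
    counts: list[dict] = []
    t0 = time.time()

    def stage(name: str, n: int) -> None:
        counts.append({"stage": name, "records": int(n)})
        logger.info("[%7.2fs] %s: %d records", time.time() - t0, name, n)

    # --- simulate -----------------------------------------------------
    marker_map = synthetic.gen_marker_map(
        config.n_chromosomes,
        config.markers_per_chromosome,
        seed=config.seed,
        chromosome_length_bp=config.chromosome_length_bp,
    )
    samples, truth, qc_metrics = synthetic.gen_truth(sim, marker_map)
    genes = synthetic.gen_genes(marker_map, seed=config.seed)
    regions = synthetic.gen_candidate_regions(marker_map, config.n_regions, seed=config.seed)
    calls_a = synthetic.emit_caller_calls(truth, marker_map, sim, CALLER_A)
    calls_b = synthetic.emit_caller_calls(truth, marker_map, sim, CALLER_B)
    truth_burden = burden.compute_burden(
        truth_as_consensus(truth, marker_map), genes, samples, pad_bp=config.pad_bp
    )
    pheno_raw = synthetic.gen_phenotypes(samples, truth_burden, sim)
    for name, df in [
        ("marker_map", marker_map),
        ("samples", samples),
        ("truth", truth),
        ("qc_metrics", qc_metrics),
        ("regions", regions),
        (f"calls_{CALLER_A}", calls_a),
        (f"calls_{CALLER_B}", calls_b),
        ("phenotypes_raw", pheno_raw),
    ]:
        write_tsv(df, outdir / f"{name}.tsv")
    write_gene_bed(genes, outdir / "genes.bed")
    stage("simulate: truth CNVs", len(truth))
    stage(f"simulate: {CALLER_A} calls", len(calls_a))
    stage(f"simulate: {CALLER_B} calls", len(calls_b))

    # --- harmonize ----------------------------------------------------
    consensus = harmonize.intersect_caller_calls(calls_a, calls_b, marker_map)
    stage("harmonize: consensus", len(consensus))
    consensus = harmonize.merge_adjacent(
        consensus,
        marker_map,
        min_member_length_bp=config.merge_min_member_length_bp,
        max_gap_fraction=config.merge_max_gap_fraction,
    )
    stage("harmonize: after merge", len(consensus))
    write_tsv(consensus, outdir / "consensus.tsv")

    # --- qc -----------------------------------------------------------
    kept_ids, exclusions = qc.filter_samples(qc_metrics, config.filters)
    write_tsv(exclusions, outdir / "sample_exclusions.tsv")
    stage("sample QC: kept", len(kept_ids))
    kept = samples[samples["sample_id"].isin(kept_ids)].reset_index(drop=True)
    cnvs = consensus[consensus["sample_id"].isin(kept_ids)].reset_index(drop=True)
    stage("sample QC: CNVs in kept samples", len(cnvs))
    cnvs = qc.filter_cnvs_basic(cnvs, config.filters)
    stage("CNV QC: markers/length", len(cnvs))
    cohort_of = dict(zip(kept["sample_id"], kept["cohort"]))
    if config.filters.frequency_scope == "whole_sample":
        assignment = qc.whole_sample_assignment(cohort_of)
    else:
        assignment = cohort_of
    freq = qc.marker_cnv_frequency(cnvs, marker_map, assignment)
    rare = qc.filter_rare(cnvs, freq, assignment, config.filters)
    stage("rarity filter: rare CNVs", len(rare))
    write_tsv(rare, outdir / "consensus_rare.tsv")

    # --- burden -------------------------------------------------------
    burden_records = burden.compute_burden(rare, genes, kept, pad_bp=config.pad_bp)
    write_tsv(burden_records, outdir / "burden.tsv")
    tables = burden.cohort_summary(burden_records)
    for name, df in tables.items():
        write_tsv(df, outdir / f"table_{name}.tsv")
    stage("burden: records", len(burden_records))

    # --- phenotypes ---------------------------------------------------
    derived, pca_report = phenotypes.derive_phenotypes(
        pheno_raw[pheno_raw["sample_id"].isin(kept_ids)],
        sex_stratified_cohorts=tuple(config.sex_stratified_cohorts),
    )
    write_tsv(derived, outdir / "phenotypes_derived.tsv")
    write_tsv(pca_report, outdir / "pca_report.tsv")
    stage("phenotypes: derived", len(derived))

    # --- association --------------------------------------------------
    grid = association.regression_grid(
        burden_records,
        derived,
        n_permutations=config.n_permutations,
        seed=config.seed,
        within_cohort=config.within_cohort,
    )
    write_tsv(grid, outdir / "regressions.tsv")
    stage("association: regressions", len(grid))

    region_defs = [
        association.RegionDef(
            region_id=r.region_id,
            chromosome=str(r.chromosome),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            source_disorder=getattr(r, "source_disorder", ""),
        )
        for r in regions.itertuples(index=False)
    ]
    region_tables = {}
    for pheno_name, col in (("gf", "gf_residual"), ("gc", "gc_residual")):
        rt = association.maxT_correction(
            region_defs,
            rare,
            derived,
            value_col=col,
            n_permutations=config.n_permutations,
            seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(1000,) if col == "gf_residual" else (1001,)),
            signed=config.maxt_signed,
        )
        region_tables[pheno_name] = rt
        write_tsv(rt, outdir / f"region_tests_{pheno_name}.tsv")
        stage(f"association: region tests ({pheno_name})", len(rt))

    write_tsv(pd.DataFrame(counts), outdir / "stage_counts.tsv")
    total = tables["burden"].iloc[-1]
    summary = {
        "n_samples": int(len(kept)),
        "n_rare_cnvs": int(total["load_all"]),
        "cnv_rate": float(total["rate_all_exact"]),
        "deletion_share": (
            float(total["load_del"] / total["load_all"]) if total["load_all"] else float("nan")
        ),
        "seed": config.seed,
        "n_permutations": config.n_permutations,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {
        "marker_map": marker_map,
        "samples": samples,
        "kept_samples": kept,
        "truth": truth,
        "qc_metrics": qc_metrics,
        "genes": genes,
        "regions": regions,
        "consensus": consensus,
        "rare": rare,
        "burden": burden_records,
        "tables": tables,
        "phenotypes_raw": pheno_raw,
        "derived": derived,
        "pca_report": pca_report,
        "regressions": grid,
        "region_tests": region_tables,
        "summary": summary,
    }
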