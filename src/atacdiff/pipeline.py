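"""End-to-end pipeline orchestration with provenance.

Runs simulate -> QC -> normalize -> select covariates -> differential test ->
enrichment against GWAS windows, persisting every intermediate artifact and a
run manifest (config hash, per-stage records, output checksums).  Identical
config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .covariates import impute_missing, make_candidates, run_selection
from .differential import LEVEL_PRESETS, run_contrast, select_stratum
from .enrichment import build_gwas_windows, permutation_enrichment
from .normalize import cpm_log, tmm_factors
from .qc import detect_outlier_samples, filter_samples
from .simulate import SimulationConfig, config_to_dict, simulate_dataset

TECHNICAL_COVARIATES = {
    "sort_date", "nrf", "alignment_pct", "nuclei_count", "gc_pct",
    "normalized_peak_calls",
}
BIOLOGICAL_CANDIDATES = {"age", "pmi", "neuronal_fraction_pct", "sex"}


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preset: str = "L2_non_neuronal"
    fdr_q: float = 0.05
    min_norm_peak_calls: float = 100.0
    flank: int = 100_000
    n_perm: int = 10_000
    min_count: int = 10
    select_covariates: bool = True
    n_pcs: int = 10
    seed: int = 0
    output_dir: str = "atacdiff_run"

    def __post_init__(self):
        if self.preset not in LEVEL_PRESETS and self.preset != "custom":
            raise ValueError(f"unknown preset {self.preset!r}")
        self.simulation.seed = self.seed


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed, "preset": config.preset}
    manifest["config"] = {
        k: v for k, v in dataclasses.asdict(config).items() if k != "simulation"
    }
    cfg_json = json.dumps(config_to_dict(config.simulation), sort_keys=True, default=str)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

    def stage(name):
        rec = {"stage": name, "t0": time.time()}
        manifest["stages"].append(rec)
        return rec

    rec = stage("simulate")
    peaks, metadata, counts, regions, truth = simulate_dataset(config.simulation)
    io.write_bed(peaks, out / "peaks.bed")
    io.write_counts_tsv(counts, out / "counts.tsv")
    io.write_metadata_csv(metadata, out / "metadata.csv")
    io.write_regions_tsv(regions, out / "regions.tsv")
    (out / "truth.json").write_text(
        json.dumps(
            {
                "differential_peak_ids": truth.differential_peak_ids,
                "planted_lfc": truth.planted_lfc,
                "gwas_region_ids": truth.gwas_region_ids,
            },
            indent=1,
        )
    )
    rec.update(n_peaks=len(peaks), n_samples=len(metadata))

    rec = stage("qc_filter")
    kept, dropped = filter_samples(metadata, config.min_norm_peak_calls)
    dropped.to_csv(out / "qc_dropped.tsv", sep="\t", index=False)
    counts = counts[kept]
    metadata = metadata.loc[kept]
    rec.update(kept=len(kept), dropped=len(dropped))

    rec = stage("outliers")
    nf = tmm_factors(counts)
    logcpm = cpm_log(counts, nf)
    outliers = detect_outlier_samples(logcpm)
    if outliers:
        counts = counts.drop(columns=outliers)
        metadata = metadata.drop(index=outliers)
    rec.update(flagged=list(map(str, outliers)))

    rec = stage("covariate_selection")
    design = LEVEL_PRESETS[config.preset]
    stratum_meta = select_stratum(metadata, design)
    covariates: list[str] = []
    if config.select_covariates:
        cand_cols = sorted((TECHNICAL_COVARIATES | BIOLOGICAL_CANDIDATES) & set(metadata.columns))
        cand_meta, flags = impute_missing(stratum_meta[cand_cols])
        nf_s = tmm_factors(counts[stratum_meta.index])
        mat = cpm_log(counts[stratum_meta.index], nf_s).T
        cands = make_candidates(cand_meta, technical=TECHNICAL_COVARIATES)
        trace = run_selection(mat, cand_meta, cands, n_pcs=config.n_pcs)
        covariates = list(trace.final_selected)
        (out / "covariate_selection.json").write_text(
            json.dumps(
                {
                    "selected": covariates,
                    "stop_reason": trace.stop_reason,
                    "iterations": [
                        {
                            "selected": it.selected,
                            "threshold": it.threshold,
                            "min_p": float(it.pvalues.min().min()),
                        }
                        for it in trace.iterations
                    ],
                },
                indent=1,
            )
        )
        metadata = metadata.copy()
        metadata.loc[stratum_meta.index, cand_cols] = cand_meta
    rec.update(selected=covariates)

    rec = stage("differential")
    results = run_contrast(
        counts, metadata, design, covariates=covariates,
        min_count=config.min_count, fdr_q=config.fdr_q,
    )
    results.drop(columns=["converged"]).to_csv(
        out / f"results_{config.preset}.tsv", sep="\t", index=False
    )
    sig = results[results["significant"]]
    for direction, tag in (
        ("more_accessible_in_case", "up"),
        ("less_accessible_in_case", "down"),
    ):
        io.write_bed(
            sig.loc[sig["direction"] == direction, ["chrom", "start", "end"]],
            out / f"significant_{tag}.bed",
        )
    rec.update(n_tested=len(results), n_significant=int(results["significant"].sum()))

    rec = stage("enrichment")
    windows = build_gwas_windows(regions, flank=config.flank)
    universe = peaks.merge(
        pd.DataFrame({"chrom": results["chrom"], "start": results["start"], "end": results["end"]}),
        how="inner",
    )
    if len(sig):
        enr = permutation_enrichment(
            sig[["chrom", "start", "end"]], universe, windows,
            n_perm=config.n_perm, seed=config.seed,
        )
        (out / "enrichment.json").write_text(json.dumps(enr.to_dict(), indent=1))
        rec.update(
            observed=enr.observed, empirical_p=enr.empirical_p,
            n_sites=enr.observed_sites_overlapping,
        )
    else:
        rec.update(observed=0, empirical_p=1.0, n_sites=0)

    for r in manifest["stages"]:
        r["wall_s"] = round(time.time() - r.pop("t0"), 3)
    manifest["outputs"] = {
        p.name: _checksum(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
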