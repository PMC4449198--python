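"""End-to-end orchestration: genotype probabilities, per-trait QTL scans,
eQTL mapping, candidate calling and hotspot detection, with per-stage
outputs and a run-metadata record."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .candidates import call_candidates, candidate_table, merge_regions, overlap_pairs
from .eqtl import convert_interval, eqtl_permutation_threshold, eqtl_scan, eqtl_table
from .genoprob import calc_genoprob
from .hotspots import call_hotspots
from .io_formats import (
    Cross,
    ExpressionSet,
    GenomicInterval,
    read_annotation,
    read_expression,
    read_rqtl_csv,
    write_interval_table,
)
from .scan import (
    forward_select,
    lod_support_interval,
    pca_covariates,
    permutation_threshold,
    scanone,
    select_egg_covariate,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one full run."""

    cross_path: str
    out_dir: str
    expression_path: str | None = None
    annotation_path: str | None = None
    traits: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=lambda: ["sex", "batch", "body_weight"])
    sex_filter: str = "all"  # F | M | all
    step_cM: float = 1.0
    n_pcs: int = 0
    alpha: float = 0.05
    n_perm: int = 1000
    eqtl_n_iter: int = 1000
    eqtl_n_subsample: int = 100
    hotspot_n_iter: int = 1000
    qtl_threshold: float | None = None  # bypass the permutation test when set
    forward_max_qtl: int = 5
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_full(config: RunConfig) -> Path:
    """Execute all stages; completed-stage outputs persist on failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"version": __version__, "config": asdict(config), "thresholds": {}}
    summary: dict = {}
    rng = np.random.default_rng(config.seed)

    def persist():
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=str)

    stage = "load"
    try:
        cross = read_rqtl_csv(config.cross_path)
        if config.sex_filter in {"F", "M"}:
            cross = cross.subset_sex(config.sex_filter)
        traits = config.traits or [
            c for c in cross.phenotypes.columns if cross.phenotypes[c].notna().sum() > 0
        ]

        stage = "genoprob"
        probs = calc_genoprob(cross, step_cM=config.step_cM)

        stage = "scan_qtl"
        covariates = list(config.covariates)
        if config.sex_filter in {"F", "M"} and "sex" in covariates:
            covariates.remove("sex")
        if config.n_pcs > 0:
            pcs = pca_covariates(cross, config.n_pcs)
            cross.covariates[pcs.columns] = pcs
            covariates = covariates + list(pcs.columns)
        qtl_intervals: list[GenomicInterval] = []
        model_rows = []
        for trait in traits:
            trait_covs = list(covariates)
            if config.sex_filter == "F" and "eggs" in cross.covariates.columns:
                decision = select_egg_covariate(cross, trait)
                meta.setdefault("egg_covariate", {})[trait] = {
                    "included": decision.include,
                    "p": decision.pvalue,
                }
                trait_covs += decision.covariates
            if config.qtl_threshold is None:
                thr = permutation_threshold(
                    probs, cross, trait, trait_covs, n_perm=config.n_perm,
                    alpha=config.alpha, seed=rng,
                )
            else:
                thr = config.qtl_threshold
            meta["thresholds"][f"qtl:{trait}"] = thr
            scan = scanone(probs, cross, trait, trait_covs)
            scan.table.assign(trait=trait).to_csv(out / f"scan_{trait}.tsv", sep="\t", index=False)
            model = forward_select(
                probs, cross, trait, trait_covs, threshold=thr, max_qtl=config.forward_max_qtl
            )
            for q in model.loci:
                si = lod_support_interval(scan, cross.gmap, peak=(q["chrom"], q["pos_cM"]))
                qtl_intervals.append(si.interval)
            model_rows.append(
                {"trait": trait, "n_qtl": len(model.loci), "lod": model.lod, "pve": model.pve}
            )
        write_interval_table(qtl_intervals, out / "qtl_intervals.tsv")
        pd.DataFrame(model_rows).to_csv(out / "qtl_models.tsv", sep="\t", index=False)
        summary["n_qtl"] = len(qtl_intervals)
        summary["n_merged_qtl_regions"] = len(merge_regions(qtl_intervals))
        persist()

        eqtl_records = []
        if config.expression_path:
            stage = "scan_eqtl"
            matrix = read_expression(config.expression_path)
            annotation = (
                read_annotation(config.annotation_path)
                if config.annotation_path
                else pd.DataFrame(columns=["chrom", "pos_Mb"])
            )
            expr = ExpressionSet(matrix, annotation)
            cis_thr = eqtl_permutation_threshold(
                probs, cross, expr, "cis",
                n_iter=config.eqtl_n_iter,
                n_subsample=min(config.eqtl_n_subsample, len(expr.probesets)),
                alpha=config.alpha, seed=rng,
            )
            trans_thr = eqtl_permutation_threshold(
                probs, cross, expr, "trans",
                n_iter=config.eqtl_n_iter,
                n_subsample=min(config.eqtl_n_subsample, len(expr.probesets)),
                alpha=config.alpha, seed=rng,
            )
            meta["thresholds"]["eqtl_cis"] = cis_thr
            meta["thresholds"]["eqtl_trans"] = trans_thr
            eqtl_records = eqtl_scan(probs, cross, expr, cis_thr, trans_thr)
            eqtl_table(eqtl_records, cross.gmap).to_csv(out / "eqtl.tsv", sep="\t", index=False)
            summary["n_cis_eqtl"] = sum(r.kind == "cis" for r in eqtl_records)
            summary["n_trans_eqtl"] = sum(r.kind == "trans" for r in eqtl_records)
            persist()

            stage = "candidates"
            cis_ivs = [r.interval for r in eqtl_records if r.kind == "cis"]
            pairs = overlap_pairs(qtl_intervals, cis_ivs)
            cands = call_candidates(pairs, cross, expr, alpha=config.alpha)
            candidate_table(cands).to_csv(out / "candidates.tsv", sep="\t", index=False)
            summary["n_candidates"] = sum(c.passed for c in cands)
            persist()

            stage = "hotspots"
            genome = {c: cross.gmap.chrom_length(c) for c in cross.gmap.chromosomes}
            trans_ivs = [r.interval for r in eqtl_records if r.kind == "trans"]
            if trans_ivs:
                thr, calls, maxima = call_hotspots(
                    trans_ivs, genome, n_iter=config.hotspot_n_iter,
                    alpha=config.alpha, seed=rng, qtl=qtl_intervals,
                )
                meta["thresholds"]["hotspot"] = thr
                np.savetxt(out / "hotspot_null_maxima.txt", maxima, fmt="%d")
                rows = [
                    {
                        "chrom": c.region.chrom,
                        "start": c.region.start,
                        "end": c.region.end,
                        "max_depth": c.max_depth,
                        "overlapping_qtl": ";".join(c.overlapping_qtl),
                    }
                    for c in calls
                ]
                pd.DataFrame(
                    rows, columns=["chrom", "start", "end", "max_depth", "overlapping_qtl"]
                ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
                summary["n_hotspots"] = len(calls)
            else:
                summary["n_hotspots"] = 0
            persist()
    except Exception as err:  # persist partial results, then re-raise with context
        meta["failed_stage"] = stage
        persist()
        raise StageError(stage, err) from err

    persist()
    return out
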