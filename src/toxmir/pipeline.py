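"""End-to-end orchestration: simulate -> process -> call -> classify -> report.

A single validated configuration drives every stage; all randomness flows
from one seed through per-stage sub-streams, so a (config, seed) pair
reproduces the run byte-for-byte.  Intermediate tables are written as TSV
and the summary as JSON so any stage can be inspected or re-run in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import detest, enrichment, histopath, io, normalize, simulate, trends
from .design import generate_design, treated_conditions


class PipelineConfig(BaseModel):
    """All thresholds and sizes of a pipeline run; round-trips via JSON/YAML."""

    seed: int = 0
    # design
    n_replicates: int = 3
    doses: list[str] = ["low", "middle", "high"]
    timepoints: list[int] = [3, 7, 14, 28]
    # simulation
    n_mirnas: int = 664
    dispersion: float = 0.1
    lib_size_mean: int = 500_000
    lib_size_cv: float = 0.3
    baseline_logmean_sd: float = 1.8
    n_planted: int = 50
    lfc_low: float = 1.0
    lfc_high: float = 2.0
    # read-level stage (optional; slow at full depth)
    simulate_reads: bool = False
    read_length: int = 50
    error_rate: float = 0.0
    min_len: int = 18
    max_len: int = 25
    min_mean_phred: float = 30.0
    # DE calling
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    rpm_threshold: float = 5.0
    pseudocount: float = 0.5
    # biomarker recovery
    min_conditions_common: int = 12
    # enrichment
    n_genes: int = 2000
    n_algorithms: int = 7
    support_prob: float = 0.05
    min_support: int = 2
    n_pathways: int = 50
    pathway_size: int = 40
    alpha: float = 0.05
    adjust_method: str = "bh"
    # histopathology / ROC
    fc_cutoff: float = 1.5
    link_strength: float = 8.0
    run_enrichment: bool = True
    run_histopath: bool = True

    @field_validator("fc_threshold", "p_threshold", "alpha", "fc_cutoff", "lib_size_mean")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("threshold must be positive")
        return v

    @field_validator("rpm_threshold", "dispersion", "error_rate")
    @classmethod
    def _non_negative(cls, v):
        if v < 0:
            raise ValueError("value must be non-negative")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed).spawn(k + 1)[k].generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage in dependency order; returns the result bundle.

    Bundle keys: design, truth, counts, norm, dems, dem_sets, trend_calls,
    common, enrichment, auc, summary.  When ``outdir`` is given, each
    table is also written as TSV and the summary as JSON.
    """
    cfg = config
    design = generate_design(cfg.n_replicates, cfg.doses, cfg.timepoints)
    conditions = treated_conditions(design)

    params = simulate.SimulationParams(
        n_mirnas=cfg.n_mirnas,
        dispersion=cfg.dispersion,
        lib_size_mean=cfg.lib_size_mean,
        lib_size_cv=cfg.lib_size_cv,
        baseline_logmean_sd=cfg.baseline_logmean_sd,
        seed=_subseed(cfg.seed, 0),
    )
    mirna_ids = simulate.make_mirna_ids(cfg.n_mirnas)
    truths = simulate.plant_effects(
        mirna_ids,
        n_planted=cfg.n_planted,
        seed=_subseed(cfg.seed, 1),
        lfc_range=(cfg.lfc_low, cfg.lfc_high),
        conditions=conditions,
    )
    biomarker_id = truths[0].mirna_id if truths else None
    counts, truth_df = simulate.generate_counts(design, params, truths)

    if cfg.simulate_reads:
        reference = simulate.generate_reference(mirna_ids, seed=_subseed(cfg.seed, 2))
        requant = {}
        for j, sample in enumerate(counts.columns):
            reads = simulate.generate_reads(
                counts[sample],
                reference,
                read_length=cfg.read_length,
                error_rate=cfg.error_rate,
                seed=_subseed(cfg.seed, 100 + j),
            )
            from .readproc import process_reads

            col, _stats = process_reads(
                reads,
                reference,
                simulate.DEFAULT_ADAPTER,
                min_len=cfg.min_len,
                max_len=cfg.max_len,
                min_mean_phred=cfg.min_mean_phred,
            )
            requant[sample] = col
        counts = pd.DataFrame(requant).reindex(counts.index).fillna(0).astype(int)
        counts.index.name = "mirna_id"

    norm, uq_factors, removed = normalize.normalize_counts(counts, cfg.rpm_threshold)
    dems = detest.call_dems(
        counts,
        design,
        norm=norm,
        fc_threshold=cfg.fc_threshold,
        p_threshold=cfg.p_threshold,
        pseudocount=cfg.pseudocount,
    )
    sets = trends.dem_sets(dems)
    calls = trends.trend_calls(dems, cfg.doses, cfg.timepoints)
    common = trends.common_dems(
        dems, min_conditions=min(cfg.min_conditions_common, len(conditions))
    )

    enrich_df = pd.DataFrame()
    planted_pathway = None
    if cfg.run_enrichment:
        target_map = simulate.generate_target_map(
            mirna_ids,
            cfg.n_genes,
            cfg.n_algorithms,
            cfg.support_prob,
            seed=_subseed(cfg.seed, 3),
        )
        filtered = enrichment.filter_targets(target_map, cfg.min_support)
        planted = {}
        if biomarker_id and filtered.get(biomarker_id):
            target_genes = sorted(filtered[biomarker_id])
            take = max(1, int(0.8 * len(target_genes)))
            planted_pathway = "pathway_planted"
            planted[planted_pathway] = target_genes[:take]
        collection = simulate.generate_pathways(
            simulate.gene_ids(cfg.n_genes),
            cfg.n_pathways,
            cfg.pathway_size,
            planted=planted,
            seed=_subseed(cfg.seed, 4),
        )
        per_condition_ids = {c: sorted(ids) for c, ids in sets.per_condition.items()}
        enrich_df = enrichment.enrich_all(
            per_condition_ids,
            filtered,
            collection,
            alpha=cfg.alpha,
            method=cfg.adjust_method,
        )

    auc_df = pd.DataFrame()
    if cfg.run_histopath:
        drivers = {}
        if biomarker_id is not None:
            drivers = {"single cell necrosis": biomarker_id}
        histo = simulate.generate_histopath(
            truths,
            drivers,
            link_strength=cfg.link_strength,
            conditions=conditions,
            seed=_subseed(cfg.seed, 5),
        )
        fc_table = dems.pivot_table(
            index="mirna_id",
            columns=["dose_level", "timepoint_days"],
            values="fold_change",
        )
        focus = list(common["mirna_id"]) or ([biomarker_id] if biomarker_id else [])
        focus = [m for m in focus if m in fc_table.index]
        if focus:
            auc_df = histopath.biomarker_feature_auc(
                fc_table, histo, mirnas=focus, fc_cutoff=cfg.fc_cutoff
            )

    summary = _summarize(
        cfg, design, dems, sets, calls, common, enrich_df, auc_df,
        removed, biomarker_id, planted_pathway,
    )
    bundle = {
        "config": cfg,
        "design": design,
        "truth": truth_df,
        "counts": counts,
        "norm": norm,
        "uq_factors": uq_factors,
        "dems": dems,
        "dem_sets": sets,
        "trend_calls": calls,
        "common": common,
        "enrichment": enrich_df,
        "auc": auc_df,
        "summary": summary,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _summarize(
    cfg, design, dems, sets, calls, common, enrich_df, auc_df,
    removed, biomarker_id, planted_pathway,
) -> dict:
    updown = {
        f"{r.dose_level}:{int(r.timepoint_days)}d": {"up": int(r.up), "down": int(r.down)}
        for r in sets.updown.itertuples()
    }
    flagged = dems[dems["is_dem"]]
    top_enrich = []
    if not enrich_df.empty:
        top = enrich_df.sort_values("p_value").head(10)
        top_enrich = [
            {
                "condition": f"{r.dose_level}:{int(r.timepoint_days)}d",
                "set_id": r.set_id,
                "p_value": float(r.p_value),
                "p_adjusted": float(r.p_adjusted),
                "significant": bool(r.significant),
            }
            for r in top.itertuples()
        ]
    top_auc = []
    if not auc_df.empty:
        top = auc_df.dropna(subset=["auc"]).sort_values("auc", ascending=False).head(10)
        top_auc = [
            {"mirna_id": r.mirna_id, "feature": r.feature, "auc": float(r.auc)}
            for r in top.itertuples()
        ]
    return {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_libraries": int(len(design)),
        "n_treated_conditions": len(treated_conditions(design)),
        "n_mirnas_tested": int(dems["mirna_id"].nunique()),
        "n_mirnas_removed_low_abundance": len(removed),
        "n_unique_dems": int(flagged["mirna_id"].nunique()),
        "n_dem_up_unique": int(flagged.loc[flagged["direction"] == "up", "mirna_id"].nunique()),
        "n_dem_down_unique": int(flagged.loc[flagged["direction"] == "down", "mirna_id"].nunique()),
        "dem_updown_by_condition": updown,
        "n_common_dems": int(len(common)),
        "common_dems": common["mirna_id"].tolist()[:20],
        "n_time_responsive": int(calls["time_responsive"].sum()),
        "n_dose_responsive": int(calls["dose_responsive"].sum()),
        "n_time_and_dose_responsive": int(
            (calls["time_responsive"] & calls["dose_responsive"]).sum()
        ),
        "planted_biomarker": biomarker_id,
        "planted_pathway": planted_pathway,
        "top_enrichment": top_enrich,
        "top_auc": top_auc,
    }


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_design(bundle["design"], outdir / "design.tsv")
    io.write_table(bundle["truth"], outdir / "truth.tsv")
    io.write_counts(bundle["counts"], outdir / "counts.tsv")
    io.write_counts(bundle["norm"].round(6), outdir / "normalized.tsv")
    io.write_table(bundle["dems"], outdir / "dems.tsv")
    calls = bundle["trend_calls"].copy()
    for col in ("time_directions", "dose_directions"):
        calls[col] = calls[col].map(lambda d: json.dumps({str(k): v for k, v in d.items()}))
    io.write_table(calls, outdir / "trend_calls.tsv")
    io.write_table(bundle["common"], outdir / "common_dems.tsv")
    if not bundle["enrichment"].empty:
        io.write_table(bundle["enrichment"], outdir / "enrichment.tsv")
    if not bundle["auc"].empty:
        io.write_table(bundle["auc"], outdir / "roc_auc.tsv")
    io.write_json(bundle["summary"], outdir / "summary.json")


def make_report(bundle: dict) -> str:
    """Human-readable run report assembled from the bundle (no recomputation)."""
    s = bundle["summary"]
    lines = [
        "toxmir pipeline report",
        "======================",
        f"config hash: {s['config_hash']}  seed: {s['seed']}",
        "",
        f"libraries: {s['n_libraries']}  treated conditions: {s['n_treated_conditions']}",
        f"miRNAs tested after abundance filter: {s['n_mirnas_tested']} "
        f"(removed: {s['n_mirnas_removed_low_abundance']})",
        "",
        f"unique DEMs: {s['n_unique_dems']} "
        f"(up: {s['n_dem_up_unique']}, down: {s['n_dem_down_unique']})",
        "",
        "DEM counts by condition (up / down):",
    ]
    for cond in sorted(s["dem_updown_by_condition"]):
        ud = s["dem_updown_by_condition"][cond]
        lines.append(f"  {cond:>12}: {ud['up']:>4} / {ud['down']:>4}")
    lines += [
        "",
        f"common DEMs (>= {bundle['config'].min_conditions_common} conditions): "
        f"{s['n_common_dems']}  {', '.join(s['common_dems']) or '-'}",
        f"time-responsive: {s['n_time_responsive']}  "
        f"dose-responsive: {s['n_dose_responsive']}  "
        f"both: {s['n_time_and_dose_responsive']}",
    ]
    if s["top_enrichment"]:
        lines += ["", "top enriched gene sets:"]
        for rec in s["top_enrichment"][:5]:
            lines.append(
                f"  {rec['condition']:>12}  {rec['set_id']:<20} "
                f"p={rec['p_value']:.3g} adj={rec['p_adjusted']:.3g}"
                f"{'  *' if rec['significant'] else ''}"
            )
    if s["top_auc"]:
        lines += ["", "top miRNA-feature AUC:"]
        for rec in s["top_auc"][:5]:
            lines.append(f"  {rec['mirna_id']:<16} {rec['feature']:<32} AUC={rec['auc']:.3f}")
    return "\n".join(lines) + "\n"
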