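"""End-to-end orchestration: QC -> deconvolution -> differential methylation
-> signature -> scoring -> DMR detection, with per-stage logging.

Each stage appends one structured log record with input/output record
counts. Any stage failure aborts the run with the stage name; when an output
directory is given, a partial-results manifest listing the completed stages
and their files is written before the error propagates.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .celltype import CellTypePanel, compare_cell_proportions, estimate_proportions
from .containers import (
    BetaMatrix, PipelineConfig, ProbeManifest, SampleSheet, write_beta_matrix,
)
from .decompose import partition_sites, summarize_partition
from .diffmeth import DifferentialMethylation
from .dmr import DMRAnalysis, dmrs_to_frame
from .enrich import hypergeom_enrich
from .qc import apply_probe_filters
from .signature import build_reference_profiles, evaluate

STAGES = ("qc", "celltype", "diffmeth", "signature", "score", "dmr")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: object = None
    filtered: BetaMatrix | None = None
    proportions: object = None
    celltype_tests: pd.DataFrame | None = None
    diffmeth: object = None
    signature_probes: list[str] = field(default_factory=list)
    model: object = None
    scores: pd.DataFrame | None = None
    metrics: dict | None = None
    dmr: object = None
    enrichment: pd.DataFrame | None = None
    log: list[dict] = field(default_factory=list)


def _find_monocyte_column(columns) -> str | None:
    for c in columns:
        if "mono" in str(c).lower():
            return c
    return None


def run_pipeline(
    config: PipelineConfig,
    beta: BetaMatrix,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    panel: CellTypePanel | None = None,
    gene_sets: dict | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full signature workflow and optionally write all artifacts."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(config=config)
    written: list[str] = []

    def log_stage(stage: str, n_in: int, n_out: int, **extra) -> None:
        res.log.append({"stage": stage, "n_in": int(n_in), "n_out": int(n_out), **extra})

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        if out is not None:
            df.to_csv(out / name, sep="\t", na_rep="NA", **kw)
            written.append(name)

    def fail(stage: str, exc: Exception) -> PipelineError:
        if out is not None:
            (out / "partial_results.json").write_text(json.dumps({
                "failed_stage": stage,
                "completed_stages": [r["stage"] for r in res.log],
                "files": written,
            }, indent=1))
        return PipelineError(stage, str(exc))

    # qc ---------------------------------------------------------------------
    try:
        filtered, report = apply_probe_filters(beta, manifest, config)
        res.qc_report, res.filtered = report, filtered
        log_stage("qc", report.n_input, report.n_remaining,
                  filters={k: v for k, v in report.filters})
        save(report.to_frame(), "qc_report.tsv", index=False)
        if out is not None:
            write_beta_matrix(filtered, out / "beta_filtered.tsv")
            written.append("beta_filtered.tsv")
    except Exception as exc:
        raise fail("qc", exc) from exc

    # celltype ----------------------------------------------------------------
    monocyte = None
    try:
        if panel is not None:
            props = estimate_proportions(beta.beta, panel)
            res.proportions = props
            res.celltype_tests = compare_cell_proportions(props, sheet.table["group"])
            mono_col = _find_monocyte_column(props.proportions.columns)
            if mono_col is not None:
                monocyte = props.proportions[mono_col]
            log_stage("celltype", beta.shape[1], len(props.proportions))
            save(props.proportions.round(6), "proportions.tsv", index_label="sample_id")
            save(res.celltype_tests, "celltype_tests.tsv")
        else:
            log_stage("celltype", beta.shape[1], 0, skipped="no reference panel supplied")
    except Exception as exc:
        raise fail("celltype", exc) from exc

    # diffmeth ----------------------------------------------------------------
    try:
        dm = DifferentialMethylation.from_sample_sheet(
            filtered, sheet, monocyte=monocyte, min_age=config.min_age
        )
        fit = dm.fit()
        res.diffmeth = fit
        res.signature_probes = fit.select_signature(config.alpha, config.min_abs_delta)
        log_stage("diffmeth", len(filtered.probe_ids), len(fit.table),
                  d0=float(fit.d0) if np.isfinite(fit.d0) else "inf", s0_2=fit.s0_2)
        save(fit.table.round(8), "stats.tsv", index_label="probe_id")
    except Exception as exc:
        raise fail("diffmeth", exc) from exc

    # signature ----------------------------------------------------------------
    try:
        log_stage("signature", len(fit.table), len(res.signature_probes))
        if out is not None:
            (out / "signature_probes.txt").write_text("\n".join(res.signature_probes) + "\n")
            written.append("signature_probes.txt")
        if res.signature_probes:
            res.model = build_reference_profiles(
                filtered, res.signature_probes, dm.case_ids, dm.control_ids
            )
            if out is not None:
                res.model.to_json(out / "signature_model.json")
                written.append("signature_model.json")
    except Exception as exc:
        raise fail("signature", exc) from exc

    # score ----------------------------------------------------------------
    try:
        if res.model is None:
            raise ValueError("empty signature: no probes passed selection, scoring refused")
        res.scores = res.model.score_many(beta.beta.loc[res.signature_probes])
        derivation = dm.case_ids + dm.control_ids
        truth = sheet.table.loc[derivation, "group"].map(
            {"case": "pathogenic", "control": "benign"}
        )
        res.metrics = evaluate(res.scores.loc[derivation], truth)
        log_stage("score", beta.shape[1], len(res.scores),
                  sensitivity=res.metrics["sensitivity"], specificity=res.metrics["specificity"])
        save(res.scores.round(4), "scores.tsv")
    except Exception as exc:
        raise fail("score", exc) from exc

    # dmr ----------------------------------------------------------------
    try:
        dmr_manifest = ProbeManifest(manifest.table.loc[filtered.probe_ids])
        analysis = DMRAnalysis(filtered, dm.design, dmr_manifest,
                               max_gap=config.max_gap, cutoff=config.min_abs_delta)
        res.dmr = analysis.fit(n_boot=config.n_boot, seed=config.seed,
                               p_cut=config.dmr_p, min_len=config.dmr_min_len)
        log_stage("dmr", len(res.dmr.candidates), len(res.dmr.records))
        save(res.dmr.to_frame(), "dmrs.tsv", index=False)
    except Exception as exc:
        raise fail("dmr", exc) from exc

    # optional enrichment ----------------------------------------------------
    if gene_sets:
        try:
            res.enrichment = hypergeom_enrich(
                res.signature_probes, filtered.probe_ids, manifest.gene_map(), gene_sets
            )
            log_stage("enrich", len(gene_sets), len(res.enrichment))
            save(res.enrichment, "enrichment.tsv", index=False)
        except Exception as exc:
            raise fail("enrich", exc) from exc

    if out is not None:
        (out / "run_log.json").write_text(json.dumps({
            "config": {k: (v if np.isfinite(v) else str(v)) if isinstance(v, float) else v
                       for k, v in vars(config).items()},
            "seed": config.seed,
            "versions": {"methsig": __version__, "python": platform.python_version(),
                         "numpy": np.__version__, "pandas": pd.__version__},
            "stages": res.log,
            "files": written,
        }, indent=1, default=str))
    return res
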