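"""Orchestration: simulate -> features -> aggregate -> analyze.

Every stage writes plain-text artifacts stamped (via MANIFEST.json) with
the configuration hash, seed and package version, and logs the counts at
each filter: windows dropped, months excluded, pairs retained.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregate import build_analysis_table, aggregate_months, write_analysis_table
from .config import PipelineConfig
from .features import extract_window_features, summarize_days
from .selection import run_model_selection, screen_covariates, interaction_analysis, table2_like
from .simulate import generate_cohort, PHENOTYPE_COLUMNS, PANSS_DIMENSIONS

log = logging.getLogger("phenolmm.pipeline")

DEFAULT_COVARIATES = {
    "gender": "factor",
    "diagnosis_group": "factor",
    "chlorpromazine_equivalents": "continuous",
    "fluoxetine_equivalents": "continuous",
    "followup_month": "continuous",
}


def _write_manifest(out: Path, config: PipelineConfig, stage: str, complete: bool, extra=None):
    manifest_path = out / "MANIFEST.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.setdefault("config_hash", config.digest())
    manifest.setdefault("seed", config.seed)
    manifest.setdefault("version", __version__)
    manifest.setdefault("stages", {})
    manifest["stages"][stage] = {"complete": complete, **(extra or {})}
    manifest_path.write_text(json.dumps(manifest, indent=2))


def stage_simulate(config: PipelineConfig, out: Path, raw_streams: bool = False):
    truth = config.truth()
    bundle = generate_cohort(truth, raw_streams=raw_streams)
    out.mkdir(parents=True, exist_ok=True)
    if raw_streams:
        win = bundle.windows.copy()
        for col in ("acc_norm", "gyro_norm", "ipi_ms"):
            if col in win.columns:
                win[col] = win[col].map(lambda a: " ".join(f"{v:.6g}" for v in a))
        win.to_csv(out / "windows.csv", index=False)
    else:
        bundle.windows.to_csv(out / "windows.csv", index=False)
    bundle.clinical.to_csv(out / "clinical.csv", index=False)
    (out / "truth.json").write_text(truth.to_json())
    log.info(
        "simulated %d windows, %d clinical rows for %d patients",
        len(bundle.windows), len(bundle.clinical), truth.n_patients,
    )
    _write_manifest(out, config, "simulate", True, {"n_windows": len(bundle.windows)})
    return bundle


def stage_features(config: PipelineConfig, out: Path, windows: pd.DataFrame):
    kw = {}
    if "ipi_band_ms" in config.features:
        kw["band_ms"] = tuple(config.features["ipi_band_ms"])
    if "ipi_tolerance" in config.features:
        kw["tolerance"] = float(config.features["ipi_tolerance"])
    if {"acc_norm", "ipi_ms"} & set(windows.columns):
        feats = extract_window_features(windows, **kw)
    else:
        feats = windows  # already feature-level
    days = summarize_days(feats, min_hours=config.aggregate.get("min_hours_per_day", 18.0))
    feats.to_csv(out / "features.csv", index=False)
    days.to_csv(out / "days.csv", index=False)
    log.info("feature windows: %d; patient-days: %d (%d valid)", len(feats), len(days), int(days["valid"].sum()))
    _write_manifest(out, config, "features", True)
    return feats, days


def stage_aggregate(config: PipelineConfig, out: Path, feats: pd.DataFrame, clinical: pd.DataFrame):
    ag = config.aggregate
    enrollment = None
    if "enrollment_date" in clinical.columns:
        enrollment = (
            clinical.drop_duplicates("patient_id").set_index("patient_id")["enrollment_date"].to_dict()
        )
    months = aggregate_months(
        feats,
        enrollment=enrollment,
        min_wake=ag.get("min_wake_windows", 720),
        min_sleep=ag.get("min_sleep_windows", 480),
        min_hours=ag.get("min_hours_per_day", 18.0),
        sd_scope=ag.get("sd_scope", "windows"),
    )
    n_exc = int((~months["included"]).sum())
    table = build_analysis_table(months, clinical, alignment=ag.get("alignment", "preceding"))
    months.to_csv(out / "patient_months.csv", index=False)
    write_analysis_table(table, out / "analysis_table.csv")
    log.info(
        "patient-months: %d (%d excluded by the 720/480 rule); modelling rows: %d",
        len(months), n_exc, len(table),
    )
    _write_manifest(out, config, "aggregate", True, {"rows": len(table), "months_excluded": n_exc})
    return table


def stage_analyze(config: PipelineConfig, out: Path, table: pd.DataFrame):
    an = config.analyze
    alpha = an.get("alpha", 0.05)
    f2_gate = an.get("f2_gate", 0.01)
    phenos = [p for p in PHENOTYPE_COLUMNS if p in table.columns]
    traces = run_model_selection(table, phenotypes=phenos, alpha=alpha, f2_gate=f2_gate)
    t2 = table2_like(traces)
    t2.to_csv(out / "table2_like.csv", index=False)

    cov_roster = {k: v for k, v in an.get("covariates", DEFAULT_COVARIATES).items() if k in table.columns}
    screen = screen_covariates(table, cov_roster, phenotypes=phenos, alpha=alpha, f2_gate=f2_gate)
    screen.records.to_csv(out / "screening.csv", index=False)

    interactions = []
    for tr in traces:
        if not tr.retained:
            continue
        for cov, kind in cov_roster.items():
            if screen.eligible(cov, tr.phenotype, tr.dimension):
                interactions.append(interaction_analysis(tr, cov, table, screen, kind=kind, alpha=alpha))
    pd.DataFrame(
        [
            {
                "phenotype": r["phenotype"],
                "dimension": r["dimension"],
                "covariate": r["covariate"],
                "interaction_p": r["interaction_effect"]["p"],
                "covariate_p": r["covariate_effect"]["p"],
                "phenotype_p": r["phenotype_effect"]["p"],
                "conclusion": r["conclusion"],
            }
            for r in interactions
        ]
    ).to_csv(out / "interactions.csv", index=False)

    n_screens = len(phenos) * len(PANSS_DIMENSIONS)
    audit = {
        "alpha": alpha,
        "f2_gate": f2_gate,
        "n_screens": n_screens,
        "expected_false_positives_at_alpha": n_screens * alpha,
        "n_retained": int(sum(tr.retained for tr in traces)),
        "traces": [tr.to_dict() for tr in traces],
        "interactions": interactions,
    }
    (out / "audit.json").write_text(json.dumps(audit, indent=2, default=str))
    log.info("retained %d of %d pairs; %d interaction models", audit["n_retained"], n_screens, len(interactions))
    _write_manifest(out, config, "analyze", True, {"n_retained": audit["n_retained"]})
    return traces, t2


def run_pipeline(config: PipelineConfig, raw_streams: bool = False) -> int:
    """Execute all stages; returns 0 on success.

    On stage failure the exception propagates after the MANIFEST records
    the incomplete stage, so partial artifacts remain inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        bundle = stage_simulate(config, out, raw_streams=raw_streams)
        stage = "features"
        feats, _days = stage_features(config, out, bundle.windows)
        stage = "aggregate"
        table = stage_aggregate(config, out, feats, bundle.clinical)
        stage = "analyze"
        stage_analyze(config, out, table)
    except Exception:
        _write_manifest(out, config, stage, False)
        raise
    return 0
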