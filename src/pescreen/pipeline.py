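"""End-to-end screening analysis: MoM QC → re-centering → risks → performance.

The stages run in the order a screening re-analysis would: first the log10
MoM distributions of unaffected pregnancies are tested against zero and
significantly miscentered markers are re-centered by their empirical median;
then posterior preterm-PE risks are computed for each biomarker combination
on the corrected MoMs; finally each combination is classified, aspirin-
adjusted and summarized (SPR, DR at the target FPR, AUC). Every run is
deterministic given the inputs and the manifest seed, and every output
carries the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortRecord, Outcome, compute_cohort_risks
from .errors import DomainError
from .evaluate import (
    MARKER_COMBINATIONS,
    PerformanceSummary,
    ScreeningConfig,
    evaluate_combination,
)
from .mom import DEFAULT_CLINICAL_BAND, RecenteringReport, qc_recenter
from .params import RiskModelParameters, default_parameters

logger = logging.getLogger(__name__)


def config_hash(params: RiskModelParameters, config: ScreeningConfig, seed: int) -> str:
    payload = json.dumps(
        {"params": params.to_dict(), "screening": asdict(config), "seed": seed},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def qc_stage(
    records: Sequence[CohortRecord],
    alpha: float = 0.05,
    clinical_band: tuple[float, float] | None = DEFAULT_CLINICAL_BAND,
) -> tuple[dict[str, np.ndarray], dict[str, RecenteringReport]]:
    """Test and re-center each marker on unaffected pregnancies.

    The re-centering factor is estimated from women without PE and applied to
    the whole cohort. Returns corrected log10 MoM arrays (cohort order) and
    the per-marker reports.
    """
    unaffected = [r.outcome is Outcome.NO_PE for r in records]
    if not any(unaffected):
        raise DomainError("QC needs at least one unaffected pregnancy")
    markers = sorted({m for r in records for m in r.log10_moms})
    corrected: dict[str, np.ndarray] = {}
    reports: dict[str, RecenteringReport] = {}
    for marker in markers:
        log10 = np.array([r.log10_moms[marker] for r in records])
        moms_unaffected = 10.0 ** log10[np.array(unaffected)]
        _, report = qc_recenter(
            moms_unaffected, alpha=alpha, marker=marker, clinical_band=clinical_band
        )
        corrected[marker] = log10 - np.log10(report.recentering_factor)
        reports[marker] = report
        logger.info("QC %s", report.to_text())
    return corrected, reports


def run_pipeline(
    records: Sequence[CohortRecord],
    params: RiskModelParameters | None = None,
    config: ScreeningConfig = ScreeningConfig(),
    seed: int = 0,
    n_boot: int = 2000,
    alpha: float = 0.05,
    clinical_band: tuple[float, float] | None = DEFAULT_CLINICAL_BAND,
    combinations: Mapping[str, tuple[str, ...]] | None = None,
) -> dict:
    """Run the full analysis and return the report bundle (JSON-serializable).

    The bundle holds the re-centering reports, per-combination performance
    summaries (and pre-QC screen-positive rate for comparison), per-woman
    risks, and a manifest with the configuration hash and seed.
    """
    if params is None:
        params = default_parameters()
    if combinations is None:
        combinations = MARKER_COMBINATIONS
    t0 = time.perf_counter()
    is_case = np.array([r.outcome is Outcome.PRETERM_PE for r in records])
    on_aspirin = np.array([r.aspirin for r in records])

    corrected, reports = qc_stage(records, alpha=alpha, clinical_band=clinical_band)
    logger.info("QC stage done in %.2fs (%d records)", time.perf_counter() - t0, len(records))

    all_markers = tuple(m for m in params.marker_names if m in corrected)
    pre_qc_risk = compute_cohort_risks(records, params, all_markers)
    spr_pre_qc = float((pre_qc_risk >= 1.0 / config.threshold_n).mean())

    rng = np.random.default_rng((seed, 2))
    performance: dict[str, PerformanceSummary] = {}
    risk_table = {"id": [r.id for r in records]}
    for label, markers in combinations.items():
        stage_t = time.perf_counter()
        risks = compute_cohort_risks(
            records, params, markers, log10_moms_override=corrected if markers else None
        )
        performance[label] = evaluate_combination(
            risks,
            is_case,
            on_aspirin,
            config=config,
            combination=label,
            n_boot=n_boot,
            seed=rng,
        )
        risk_table[label] = risks
        logger.info(
            "combination %s: %d records in %.2fs", label, len(records), time.perf_counter() - stage_t
        )

    manifest = {
        "seed": seed,
        "n_records": len(records),
        "config_hash": config_hash(params, config, seed),
        "pescreen_version": __version__,
        "screening_config": asdict(config),
        "qc_alpha": alpha,
        "clinical_band": list(clinical_band) if clinical_band else None,
    }
    return {
        "manifest": manifest,
        "recentering": {m: asdict(rep) for m, rep in reports.items()},
        "spr_pre_qc": spr_pre_qc,
        "performance": {label: summary.to_dict() for label, summary in performance.items()},
        "risks": pd.DataFrame(risk_table),
    }


def bundle_to_json(bundle: dict) -> str:
    """Deterministic JSON rendering of a report bundle (risks excluded)."""
    payload = {k: v for k, v in bundle.items() if k != "risks"}
    return json.dumps(payload, indent=2, sort_keys=True)


def render_markdown(bundle: dict) -> str:
    """Human-readable summary: re-centering table and the DR@FPR ladder."""
    lines = ["# Screening performance report", ""]
    manifest = bundle["manifest"]
    lines.append(
        f"n = {manifest['n_records']}, seed {manifest['seed']}, "
        f"config {manifest['config_hash']}, pescreen {manifest['pescreen_version']}"
    )
    lines.append("")
    lines.append("## MoM QC / re-centering")
    lines.append("")
    lines.append("| marker | n | mean log10 MoM | median MoM | p | factor | applied |")
    lines.append("|---|---|---|---|---|---|---|")
    for marker, rep in bundle["recentering"].items():
        lines.append(
            f"| {marker} | {rep['n']} | {rep['mean_log10_mom']:+.4f} | {rep['median_mom']:.2f} "
            f"| {rep['p_value']:.3g} | {rep['recentering_factor']:.4f} | {rep['applied']} |"
        )
    lines.append("")
    lines.append(f"Screen-positive rate before QC: {100 * bundle['spr_pre_qc']:.1f}%")
    lines.append("")
    lines.append("## Performance by biomarker combination")
    lines.append("")
    lines.append("| combination | SPR | risk cutoff | DR @ FPR | AUC (95% CI) |")
    lines.append("|---|---|---|---|---|")
    for label, perf in bundle["performance"].items():
        ci = perf["auc_ci"]
        lines.append(
            f"| {label} | {100 * perf['spr']:.1f}% | {perf['cutoff_at_target_fpr']} "
            f"| {100 * perf['dr_at_target_fpr']:.1f}% @ {100 * perf['target_fpr']:.0f}% "
            f"| {perf['auc']:.2f} ({ci[0]:.2f}-{ci[1]:.2f}) |"
        )
    lines.append("")
    return "\n".join(lines)
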