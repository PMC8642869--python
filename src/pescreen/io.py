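"""Cohort CSV reading and writing.

The on-disk schema mirrors the variables of a first-trimester screening
table: one row per pregnancy with maternal characteristics, gestational ages
in days, biomarkers as MoMs (``*_mom``) or raw measurements (``*_raw*``,
converted through expected-median models at ingest), the pregnancy outcome
and aspirin use. Rows violating invariants are collected into a rejects
report with line numbers and never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRecord, Outcome
from .errors import ConfigurationError
from .mom import ExpectedMedianModel, compute_mom
from .params import MARKERS
from .profiles import Conception, MaternalProfile, ParityClass

logger = logging.getLogger(__name__)

_RAW_COLUMNS = {
    "MAP": "map_raw_mmhg",
    "UtAPI": "utapi_raw",
    "PAPPA": "pappa_raw",
    "PlGF": "plgf_raw",
}
_MOM_COLUMNS = {
    "MAP": "map_mom",
    "UtAPI": "utapi_mom",
    "PAPPA": "pappa_mom",
    "PlGF": "plgf_mom",
}

_REQUIRED = [
    "id",
    "age_years",
    "weight_kg",
    "height_cm",
    "parity_class",
    "chronic_htn",
    "diabetes",
    "sle_aps",
    "conception",
    "smoker",
    "ga_screen_days",
    "outcome",
    "ga_delivery_days",
    "aspirin",
]

_OPTIONAL = ["counterfactual_outcome", "aspirin_dose_mg", "risk", "high_risk"]


@dataclass(frozen=True)
class CohortTableSchema:
    """CSV dialect and validation settings for cohort tables."""

    delimiter: str = ","
    na_token: str = "NA"
    preterm_cutoff_weeks: float = 37.0


@dataclass
class RejectsReport:
    """Rows that failed validation, with 1-based data line numbers."""

    rejects: list[tuple[int, str]] = field(default_factory=list)

    def add(self, line: int, reason: str) -> None:
        logger.warning("rejecting row %d: %s", line, reason)
        self.rejects.append((line, reason))

    def __len__(self) -> int:
        return len(self.rejects)


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age_years": r.profile.age,
            "weight_kg": r.profile.weight,
            "height_cm": r.profile.height,
            "parity_class": r.profile.parity_class.value,
            "chronic_htn": int(r.profile.chronic_hypertension),
            "diabetes": int(r.profile.diabetes),
            "sle_aps": int(r.profile.sle_aps),
            "conception": r.profile.conception.value,
            "smoker": int(r.profile.smoker),
            "ga_screen_days": r.ga_at_screening * 7.0,
            "outcome": r.outcome.value,
            "ga_delivery_days": r.ga_at_delivery * 7.0,
            "aspirin": int(r.aspirin),
            "counterfactual_outcome": r.counterfactual_outcome.value
            if r.counterfactual_outcome
            else r.outcome.value,
        }
        for marker, col in _MOM_COLUMNS.items():
            if marker in r.log10_moms:
                row[col] = 10.0 ** r.log10_moms[marker]
        if r.aspirin_dose_mg is not None:
            row["aspirin_dose_mg"] = r.aspirin_dose_mg
        if r.risk is not None:
            row["risk"] = r.risk
        if r.high_risk is not None:
            row["high_risk"] = int(r.high_risk)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[CohortRecord], path, schema: CohortTableSchema = CohortTableSchema()) -> None:
    """Write a cohort table; gestational ages stored in days."""
    frame = cohort_to_frame(records)
    frame.to_csv(path, index=False, sep=schema.delimiter, na_rep=schema.na_token)


def _parse_row(
    row: pd.Series,
    schema: CohortTableSchema,
    median_models: Mapping[str, ExpectedMedianModel] | None,
) -> CohortRecord:
    profile = MaternalProfile(
        age=float(row["age_years"]),
        weight=float(row["weight_kg"]),
        height=float(row["height_cm"]),
        parity_class=ParityClass(row["parity_class"]),
        chronic_hypertension=bool(int(row["chronic_htn"])),
        diabetes=bool(int(row["diabetes"])),
        sle_aps=bool(int(row["sle_aps"])),
        conception=Conception(row["conception"]),
        smoker=bool(int(row["smoker"])),
    )
    ga_screen = float(row["ga_screen_days"]) / 7.0
    ga_delivery = float(row["ga_delivery_days"]) / 7.0
    outcome = Outcome(row["outcome"])
    if outcome is Outcome.PRETERM_PE and ga_delivery >= schema.preterm_cutoff_weeks:
        raise ValueError(
            f"outcome preterm_pe but delivery at {row['ga_delivery_days']} days "
            f"(>= {schema.preterm_cutoff_weeks} weeks)"
        )
    if outcome is Outcome.TERM_PE and ga_delivery < schema.preterm_cutoff_weeks:
        raise ValueError(
            f"outcome term_pe but delivery at {row['ga_delivery_days']} days "
            f"(< {schema.preterm_cutoff_weeks} weeks)"
        )
    log10_moms: dict[str, float] = {}
    for marker in MARKERS:
        mom_col, raw_col = _MOM_COLUMNS[marker], _RAW_COLUMNS[marker]
        if mom_col in row.index and pd.notna(row[mom_col]):
            value = float(row[mom_col])
            if not value > 0:
                raise ValueError(f"{mom_col} must be > 0, got {value}")
            log10_moms[marker] = float(np.log10(value))
        elif raw_col in row.index and pd.notna(row[raw_col]):
            if median_models is None or marker not in median_models:
                raise ConfigurationError(
                    f"column {raw_col} present but no expected-median model for {marker}"
                )
            mom = compute_mom(float(row[raw_col]), ga_screen, profile, median_models[marker])
            log10_moms[marker] = float(np.log10(mom))
    counterfactual = (
        Outcome(row["counterfactual_outcome"])
        if "counterfactual_outcome" in row.index and pd.notna(row.get("counterfactual_outcome"))
        else outcome
    )
    return CohortRecord(
        id=int(row["id"]),
        profile=profile,
        ga_at_screening=ga_screen,
        log10_moms=log10_moms,
        log10_moms_unshifted=dict(log10_moms),
        outcome=outcome,
        ga_at_delivery=ga_delivery,
        aspirin=bool(int(row["aspirin"])),
        counterfactual_outcome=counterfactual,
        aspirin_dose_mg=int(row["aspirin_dose_mg"])
        if "aspirin_dose_mg" in row.index and pd.notna(row.get("aspirin_dose_mg"))
        else None,
        risk=float(row["risk"]) if "risk" in row.index and pd.notna(row.get("risk")) else None,
        high_risk=bool(int(row["high_risk"]))
        if "high_risk" in row.index and pd.notna(row.get("high_risk"))
        else None,
    )


def read_cohort(
    path,
    schema: CohortTableSchema = CohortTableSchema(),
    median_models: Mapping[str, ExpectedMedianModel] | None = None,
) -> tuple[list[CohortRecord], RejectsReport]:
    """Read and validate a cohort table.

    Returns the accepted records and a rejects report; a missing required
    column raises :class:`ConfigurationError` naming the column, while rows
    that fail validation are logged and rejected, not fatal.
    """
    frame = pd.read_csv(path, sep=schema.delimiter, na_values=[schema.na_token])
    for column in _REQUIRED:
        if column not in frame.columns:
            raise ConfigurationError(f"missing required column: {column!r}")
    for marker in MARKERS:
        if _MOM_COLUMNS[marker] not in frame.columns and _RAW_COLUMNS[marker] not in frame.columns:
            raise ConfigurationError(
                f"need either {_MOM_COLUMNS[marker]!r} or {_RAW_COLUMNS[marker]!r}"
            )
    records: list[CohortRecord] = []
    rejects = RejectsReport()
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            records.append(_parse_row(row, schema, median_models))
        except ConfigurationError:
            raise
        except Exception as exc:  # invalid rows are collected, not fatal
            rejects.add(i, str(exc))
    return records, rejects
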