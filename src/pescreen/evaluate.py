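"""Screening performance: classification, aspirin adjustment, ROC/DR/AUC.

Evaluation follows the logic of a screening study in which some high-risk
women received prophylactic aspirin after screening: the observed number of
preterm-PE cases among aspirin takers under-counts the cases that screening
actually identified, so case counts are inflated by the counterfactual
multiplier 1/(1−effect). Two conventions are provided (see
:func:`aspirin_adjust`). For ROC analysis the prevented cases have no
observed risk scores, so each observed treated case carries the extra weight
implied by the adjustment convention — prevented cases inherit the score
distribution of observed treated cases, and no pseudo-records are invented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import CohortRecord, Outcome
from .errors import DomainError
from .model import risk_to_one_in_n

#: Biomarker combinations evaluated on top of maternal history, in the
#: conventional reporting order (history first, all four markers last).
MARKER_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "history": (),
    "history+MAP": ("MAP",),
    "history+UtAPI": ("UtAPI",),
    "history+PlGF": ("PlGF",),
    "history+MAP+UtAPI+PlGF": ("MAP", "UtAPI", "PlGF"),
    "history+MAP+UtAPI+PlGF+PAPPA": ("MAP", "UtAPI", "PAPPA", "PlGF"),
}


@dataclass(frozen=True)
class ScreeningConfig:
    """Evaluation settings: risk threshold 1:N, target FPR, aspirin adjustment."""

    threshold_n: int = 100
    target_fpr: float = 0.10
    aspirin_effect: float = 0.6
    adjustment_convention: str = "additive_paper"
    preterm_cutoff: float = 37.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fpr < 1.0:
            raise DomainError(f"target_fpr must be in (0, 1), got {self.target_fpr}")
        if not 0.0 <= self.aspirin_effect < 1.0:
            raise DomainError(f"aspirin_effect must be in [0, 1), got {self.aspirin_effect}")
        if self.adjustment_convention not in ("additive_paper", "counterfactual"):
            raise DomainError(
                f"unknown adjustment convention {self.adjustment_convention!r}"
            )


def classify(risk: float, threshold_n: int = 100) -> str:
    """"high" iff risk ≥ 1/N (inclusive boundary), else "low"."""
    if not 0.0 <= risk <= 1.0:
        raise DomainError(f"risk must be a probability, got {risk!r}")
    return "high" if risk >= 1.0 / threshold_n else "low"


@dataclass(frozen=True)
class AdjustedCounts:
    """Observed and aspirin-adjusted preterm-PE case counts."""

    observed_total_cases: int
    observed_high_risk_cases: int
    observed_cases_on_aspirin: int
    prevented_cases: float
    adjusted_total_cases: float
    adjusted_high_risk_cases: float
    multiplier: float
    convention: str


def aspirin_adjust(
    observed_total: int,
    observed_high_risk: int,
    observed_on_aspirin: int,
    effect: float = 0.6,
    convention: str = "additive_paper",
) -> AdjustedCounts:
    """Inflate observed preterm-PE counts for the preventive effect of aspirin.

    The counterfactual multiplier is 1/(1−effect). Under ``additive_paper``
    (default) the full multiplied count of treated cases is *added* as
    prevented cases — adjusted_total = observed_total + multiplier·on_aspirin —
    which reproduces the printed worked-example arithmetic of the study this
    package emulates (25 observed, 6 on aspirin, effect 0.6 → 40 total).
    Under ``counterfactual``, the literal reading of the formula, the treated
    cases are *replaced* by their counterfactual count, so prevented =
    (multiplier−1)·on_aspirin and the same inputs give 34.
    """
    if not 0 <= observed_on_aspirin <= observed_high_risk <= observed_total:
        raise DomainError(
            "need 0 <= on_aspirin <= high_risk <= total, got "
            f"{observed_on_aspirin}, {observed_high_risk}, {observed_total}"
        )
    if not 0.0 <= effect < 1.0:
        raise DomainError(f"effect must be in [0, 1), got {effect}")
    multiplier = 1.0 / (1.0 - effect)
    if convention == "additive_paper":
        prevented = multiplier * observed_on_aspirin
    elif convention == "counterfactual":
        prevented = (multiplier - 1.0) * observed_on_aspirin
    else:
        raise DomainError(f"unknown adjustment convention {convention!r}")
    if effect == 0.0:
        prevented = 0.0
    return AdjustedCounts(
        observed_total_cases=observed_total,
        observed_high_risk_cases=observed_high_risk,
        observed_cases_on_aspirin=observed_on_aspirin,
        prevented_cases=prevented,
        adjusted_total_cases=observed_total + prevented,
        adjusted_high_risk_cases=observed_high_risk + prevented,
        multiplier=multiplier,
        convention=convention,
    )


def aspirin_case_weights(
    labels: np.ndarray,
    on_aspirin: np.ndarray,
    effect: float,
    convention: str = "additive_paper",
) -> np.ndarray:
    """Per-woman ROC weights implied by the aspirin adjustment convention.

    Observed treated cases stand in for the prevented cases, so each carries
    weight 1 + multiplier (additive_paper) or the multiplier itself
    (counterfactual); everyone else has weight 1. With effect 0 all weights
    are 1 and the weighted ROC reduces to the standard empirical ROC.
    """
    labels = np.asarray(labels, dtype=bool)
    on_aspirin = np.asarray(on_aspirin, dtype=bool)
    multiplier = 1.0 / (1.0 - effect)
    extra = multiplier if convention == "additive_paper" else multiplier - 1.0
    if effect == 0.0:
        extra = 0.0
    w = np.ones(labels.shape[0])
    w[labels & on_aspirin] += extra
    return w


@dataclass(frozen=True)
class ROCCurve:
    """Weighted empirical ROC: step curve from (0,0) to (1,1), ties grouped."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def weighted_roc(
    scores: Sequence[float],
    labels: Sequence[bool],
    case_weights: Sequence[float] | None = None,
) -> ROCCurve:
    """Empirical weighted ROC with ties grouped (all tied scores move together)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise DomainError("scores and labels must have the same shape")
    if y.all() or not y.any():
        raise DomainError("ROC needs at least one case and one control")
    w = np.ones(s.shape[0]) if case_weights is None else np.asarray(case_weights, dtype=float)
    if np.any(w < 0):
        raise DomainError("weights must be non-negative")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, sample_weight=w, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def dr_at_fpr(roc: ROCCurve, target_fpr: float) -> tuple[float, float]:
    """Detection rate at the most permissive cutoff with FPR ≤ target.

    No interpolation: the empirical step curve is scanned and the attained
    operating point is returned as (DR, cutoff score). With risk scores the
    cutoff can be displayed via :func:`pescreen.model.risk_to_one_in_n`.
    """
    ok = roc.fpr <= target_fpr + 1e-12
    idx = int(np.nonzero(ok)[0].max())
    return float(roc.tpr[idx]), float(roc.thresholds[idx])


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area under the (weighted) empirical ROC."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def auc_with_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    case_weights: Sequence[float] | None = None,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """AUC with a stratified percentile-bootstrap CI over women.

    Women are resampled within the case and control strata; each woman's
    weight travels with her, so the aspirin adjustment is re-applied in every
    replicate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    w = np.ones(s.shape[0]) if case_weights is None else np.asarray(case_weights, dtype=float)
    point = auc(weighted_roc(s, y, w))
    if n_boot <= 0:
        return point, (float("nan"), float("nan"))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cases = np.nonzero(y)[0]
    controls = np.nonzero(~y)[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(cases, size=cases.size), rng.choice(controls, size=controls.size)]
        )
        reps[b] = auc(weighted_roc(s[idx], y[idx], w[idx]))
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(reps, [tail, 1.0 - tail])
    return point, (float(lo), float(hi))


@dataclass(frozen=True)
class PerformanceSummary:
    """Screening performance for one biomarker combination."""

    combination: str
    spr: float
    auc: float
    auc_ci: tuple[float, float]
    dr_at_target_fpr: float
    cutoff_at_target_fpr: str
    target_fpr: float
    adjusted_counts: AdjustedCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        return d


def evaluate_combination(
    scores: Sequence[float],
    is_case: Sequence[bool],
    on_aspirin: Sequence[bool],
    config: ScreeningConfig = ScreeningConfig(),
    combination: str = "",
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> PerformanceSummary:
    """Full performance summary for one score vector.

    ``is_case`` flags observed preterm-PE; SPR is the unweighted fraction of
    women with score at or above 1/threshold_n; the ROC, DR@FPR and AUC use
    the aspirin-adjusted case weights.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    asp = np.asarray(on_aspirin, dtype=bool)
    threshold = 1.0 / config.threshold_n
    high = s >= threshold
    counts = aspirin_adjust(
        int(y.sum()),
        int((y & high).sum()),
        int((y & high & asp).sum()),
        effect=config.aspirin_effect,
        convention=config.adjustment_convention,
    )
    w = aspirin_case_weights(y, asp, config.aspirin_effect, config.adjustment_convention)
    roc = weighted_roc(s, y, w)
    dr, cutoff = dr_at_fpr(roc, config.target_fpr)
    point, ci = auc_with_ci(s, y, w, n_boot=n_boot, seed=seed)
    cutoff_str = risk_to_one_in_n(cutoff) if 0.0 < cutoff <= 1.0 else f"{cutoff:.4g}"
    return PerformanceSummary(
        combination=combination,
        spr=float(high.mean()),
        auc=point,
        auc_ci=ci,
        dr_at_target_fpr=dr,
        cutoff_at_target_fpr=cutoff_str,
        target_fpr=config.target_fpr,
        adjusted_counts=counts,
    )


# ---------------------------------------------------------------------------
# cohort summary (Table-1 style)
# ---------------------------------------------------------------------------

_CONTINUOUS = {
    "age_years": lambda r: r.profile.age,
    "weight_kg": lambda r: r.profile.weight,
    "height_cm": lambda r: r.profile.height,
    "bmi_kg_m2": lambda r: r.profile.bmi,
    "ga_at_screening_days": lambda r: r.ga_at_screening * 7.0,
    "ga_at_delivery_days": lambda r: r.ga_at_delivery * 7.0,
}

_CATEGORICAL = {
    "assisted_conception": lambda r: r.profile.conception.value == "assisted",
    "chronic_hypertension": lambda r: r.profile.chronic_hypertension,
    "sle_aps": lambda r: r.profile.sle_aps,
    "diabetes": lambda r: r.profile.diabetes,
    "nulliparous": lambda r: r.profile.parity_class.value == "nulliparous",
    "parous_no_previous_pe": lambda r: r.profile.parity_class.value == "parous_no_pe",
    "parous_previous_pe": lambda r: r.profile.parity_class.value == "parous_previous_pe",
}


@dataclass
class CohortSummary:
    """Characteristics by PE status, plus marker ANOVA and incidences."""

    characteristics: pd.DataFrame
    markers: pd.DataFrame
    n_total: int
    n_pe: int
    n_preterm_pe: int

    @property
    def pe_incidence(self) -> float:
        return self.n_pe / self.n_total

    @property
    def preterm_pe_incidence(self) -> float:
        return self.n_preterm_pe / self.n_total

    def to_markdown(self) -> str:
        lines = [
            f"n = {self.n_total}; PE {self.n_pe} ({100 * self.pe_incidence:.2f}%); "
            f"preterm PE {self.n_preterm_pe} ({100 * self.preterm_pe_incidence:.2f}%)",
            "",
            self.characteristics.to_markdown(index=False),
            "",
            self.markers.to_markdown(index=False),
        ]
        return "\n".join(lines)


def cohort_summary(records: Sequence[CohortRecord]) -> CohortSummary:
    """Mean±SD / n(%) by PE status with two-group tests, and a three-group
    ANOVA over the log10 MoMs (no PE / term PE / preterm PE) with Bonferroni
    correction within the marker family. Empty strata yield NA p-values."""
    if not records:
        raise DomainError("empty cohort")
    pe = np.array([r.outcome is not Outcome.NO_PE for r in records])
    rows = []
    for name, getter in _CONTINUOUS.items():
        x = np.array([getter(r) for r in records], dtype=float)
        a, b = x[~pe], x[pe]
        if a.size >= 2 and b.size >= 2:
            if np.array_equal(np.sort(a), np.sort(b)):
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "characteristic": name,
                "no_pe": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}" if a.size > 1 else "NA",
                "pe": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}" if b.size > 1 else "NA",
                "p_value": p,
            }
        )
    for name, getter in _CATEGORICAL.items():
        flag = np.array([getter(r) for r in records], dtype=bool)
        table = np.array(
            [
                [(flag & ~pe).sum(), (~flag & ~pe).sum()],
                [(flag & pe).sum(), (~flag & pe).sum()],
            ]
        )
        if table[0].sum() == 0 or table[1].sum() == 0:
            p = float("nan")
        elif (stats.contingency.expected_freq(table) < 5).any():
            p = float(stats.fisher_exact(table).pvalue)
        else:
            p = float(stats.chi2_contingency(table).pvalue)
        n0, n1 = (~pe).sum(), pe.sum()
        rows.append(
            {
                "characteristic": name,
                "no_pe": f"{table[0, 0]} ({100 * table[0, 0] / max(n0, 1):.1f}%)",
                "pe": f"{table[1, 0]} ({100 * table[1, 0] / max(n1, 1):.1f}%)",
                "p_value": p,
            }
        )
    characteristics = pd.DataFrame(rows)

    outcome = np.array([r.outcome.value for r in records])
    marker_rows = []
    marker_names = sorted({m for r in records for m in r.log10_moms})
    for name in marker_names:
        values = np.array([r.log10_moms.get(name, np.nan) for r in records])
        groups = [
            values[outcome == o.value]
            for o in (Outcome.NO_PE, Outcome.TERM_PE, Outcome.PRETERM_PE)
        ]
        nonempty = [grp for grp in groups if grp.size >= 2]
        if len(nonempty) >= 2:
            p = float(stats.f_oneway(*nonempty).pvalue)
        else:
            p = float("nan")
        marker_rows.append(
            {
                "marker": name,
                "no_pe_mean": groups[0].mean() if groups[0].size else float("nan"),
                "term_pe_mean": groups[1].mean() if groups[1].size else float("nan"),
                "preterm_pe_mean": groups[2].mean() if groups[2].size else float("nan"),
                "anova_p": p,
            }
        )
    markers = pd.DataFrame(marker_rows)
    if not markers.empty:
        markers["anova_p_bonferroni"] = np.minimum(markers["anova_p"] * len(markers), 1.0)
    n_pe = int(pe.sum())
    n_preterm = int(sum(r.outcome is Outcome.PRETERM_PE for r in records))
    return CohortSummary(
        characteristics=characteristics,
        markers=markers,
        n_total=len(records),
        n_pe=n_pe,
        n_preterm_pe=n_preterm,
    )


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------


def hanley_mcneil_variance(auc0: float, n_cases: int, n_controls: int) -> float:
    """Hanley–McNeil approximation of Var(AUC) for given group sizes."""
    a = auc0
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (
        a * (1.0 - a) + (n_cases - 1) * (q1 - a * a) + (n_controls - 1) * (q2 - a * a)
    ) / (n_cases * n_controls)


@dataclass(frozen=True)
class SampleSizeResult:
    n_cases: int
    n_controls: int
    se_achieved: float
    power_vs_null: float
    assumptions: dict


def sample_size_for_auc(
    auc0: float,
    se_target: float,
    alpha: float = 0.05,
    power: float = 0.80,
    control_case_ratio: float = 70.0,
    null_auc: float = 0.5,
    max_cases: int = 100000,
) -> SampleSizeResult:
    """Cases needed for a target standard error of the AUC estimate.

    Uses the Hanley–McNeil variance with ``control_case_ratio`` controls per
    case: the smallest case count whose SE is at or below ``se_target``. The
    achieved power to distinguish ``auc0`` from ``null_auc`` in a two-sided
    level-``alpha`` test (variance taken at ``auc0``) is reported alongside,
    and all assumptions are returned explicitly — published sample-size
    statements of this form rarely pin down a unique formula, so the output
    is an audited computation, not a reproduction of any particular one.
    """
    if not 0.5 < auc0 < 1.0:
        raise DomainError(f"auc0 must be in (0.5, 1), got {auc0}")
    if not se_target > 0:
        raise DomainError(f"se_target must be > 0, got {se_target}")
    if not control_case_ratio > 0:
        raise DomainError("control_case_ratio must be > 0")
    for n_cases in range(2, max_cases + 1):
        n_controls = max(2, int(np.ceil(control_case_ratio * n_cases)))
        se = float(np.sqrt(hanley_mcneil_variance(auc0, n_cases, n_controls)))
        if se <= se_target:
            z = (auc0 - null_auc) / se
            achieved_power = float(stats.norm.cdf(z - stats.norm.ppf(1.0 - alpha / 2.0)))
            return SampleSizeResult(
                n_cases=n_cases,
                n_controls=n_controls,
                se_achieved=se,
                power_vs_null=achieved_power,
                assumptions={
                    "auc0": auc0,
                    "se_target": se_target,
                    "alpha": alpha,
                    "power_requested": power,
                    "control_case_ratio": control_case_ratio,
                    "null_auc": null_auc,
                    "variance": "Hanley-McNeil at auc0",
                    "criterion": "smallest case count with SE(AUC) <= se_target",
                },
            )
    raise DomainError(
        f"no case count up to {max_cases} achieves SE <= {se_target} (infeasible target)"
    )
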